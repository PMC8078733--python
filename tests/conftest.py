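import numpy as np
import pytest
from hypothesis import settings

import emtspectrum as e

settings.register_profile("ci", max_examples=50, derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_population():
    """A 600-cell synthetic EMT population, shared across tests."""
    cfg = e.GeneratorConfig(n_cells=600, seed=11)
    counts, sig, truth = e.generate_emt_population(cfg)
    return cfg, counts, sig, truth


@pytest.fixture(scope="session")
def smoothed_population(small_population):
    """QC'd, scaled, signature-restricted and diffusion-smoothed matrix."""
    cfg, counts, sig, truth = small_population
    filtered, _ = e.qc_filter(counts)
    scaled = e.normalize_and_scale(filtered)
    sig_scaled = scaled.restrict_genes(sig.all_genes)
    op = e.build_diffusion_operator(sig_scaled)
    smoothed = e.impute(sig_scaled, op)
    kept = truth.set_index("cell_id").loc[smoothed.cell_ids]
    return cfg, smoothed, sig, kept


def make_blobs(n_blobs, n_per_blob=40, spread=0.1, n_dims=10, seed=0, scale=3.0):
    """Well-separated blobs with distinct expression profiles, as a
    ScaledMatrix for clustering tests. Each blob's centre is a random
    direction in gene space, so within-blob rows are strongly correlated
    and across-blob rows are not."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for i in range(n_blobs):
        mu = rng.normal(0.0, 1.0, n_dims) * scale
        rows.append(mu + rng.normal(0, spread, (n_per_blob, n_dims)))
        labels += [i] * n_per_blob
    values = np.vstack(rows)
    n = len(values)
    return (
        e.ScaledMatrix(
            values=values,
            cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
            gene_ids=np.array([f"g{j}" for j in range(n_dims)], dtype=object),
            sample_labels=np.array(["s1"] * n, dtype=object),
        ),
        np.array(labels),
    )
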