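"""Synthetic inputs with known ground truth for the whole pipeline.

Emulates the structure the analysis is designed to recover: each cell
carries a latent EMT coordinate z in [0, 1] (0 = fully epithelial pole,
1 = fully mesenchymal pole); every epithelial-arm gene has expected
expression monotonically decreasing in z and every mesenchymal-arm gene
monotonically increasing; counts are negative-binomial (gamma-Poisson)
with Bernoulli dropout.
Cells are drawn from three latent bands — epithelial z ~ U(0, 0.25),
partial-EMT z ~ U(0.35, 0.65), mesenchymal z ~ U(0.75, 1) — at requested
mixture weights, so every downstream stage can be checked against truth.

Genes within an arm do not switch in unison: each signature gene carries
its own sigmoidal switch point, spread evenly along the latent axis, as
EMT programs activate genes at staggered positions on the continuum. A
partial-EMT cell therefore expresses some epithelial and some mesenchymal
genes above their population means, giving genuinely intermediate positive
fractions: the fraction of positive epithelial entries falls roughly as
1 - z and the mesenchymal fraction rises as z, so the E/M score behaves as
log2((1 - z)/z) and the +-1.5 class cutoffs land inside the latent band
gaps, where no cell is generated.
Also generates histology composition tables and marked point patterns with
tunable attraction or exclusion between two cell phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import CountMatrix
from .signature import EMTSignature
from .spatial import PointPattern, Rectangle

CLASSES = ("EPI", "PEMT", "MES")
LATENT_BANDS = {"EPI": (0.0, 0.25), "PEMT": (0.35, 0.65), "MES": (0.75, 1.0)}
HISTOLOGY_CATEGORIES = (
    "normal", "panin", "pdac_well", "pdac_moderate", "pdac_poor", "necrosis",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic EMT population.

    ``high_rate``/``low_rate`` set the relative expression rate of a
    signature gene at its favoured vs disfavoured pole; the off state is
    near-silent by default, as signature genes on the wrong side of the
    continuum are transcriptionally silenced rather than half-expressed
    (this also keeps each gene's positivity boundary at its own switch
    point, independent of the class mixture); ``switch_width`` is the width of
    each gene's sigmoidal on/off transition along the latent axis;
    ``dispersion`` is the negative-binomial shape (smaller = noisier);
    ``dropout_rate`` is the per-entry zero-inflation probability.
    """

    n_cells: int = 3000
    n_epi_genes: int = 60
    n_mes_genes: int = 60
    n_background_genes: int = 300
    n_mito_genes: int = 20
    mixture_weights: tuple[float, float, float] = (0.40, 0.35, 0.25)
    mean_depth: float = 2000.0
    dispersion: float = 2.0
    dropout_rate: float = 0.30
    seed: int = 0
    n_samples: int = 4
    mito_prefix: str = "MT-"
    high_rate: float = 5.0
    low_rate: float = 0.02
    background_rate: float = 1.0
    switch_width: float = 0.05

    def validate(self) -> None:
        if abs(sum(self.mixture_weights) - 1.0) > 1e-12:
            raise ValueError("mixture_weights must sum to 1")
        if any(w < 0 for w in self.mixture_weights):
            raise ValueError("mixture_weights must be non-negative")
        if self.n_cells < 10:
            raise ValueError("n_cells must be at least 10")
        if self.n_epi_genes < 1 or self.n_mes_genes < 1:
            raise ValueError("both signature arms need at least one gene")
        if self.n_background_genes < 0 or self.n_mito_genes < 0:
            raise ValueError("gene counts must be non-negative")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.mean_depth <= 0 or self.dispersion <= 0:
            raise ValueError("mean_depth and dispersion must be positive")


def _gene_names(cfg: GeneratorConfig) -> tuple[list[str], list[str], list[str], list[str]]:
    epi = [f"EPI{i:03d}" for i in range(1, cfg.n_epi_genes + 1)]
    mes = [f"MES{i:03d}" for i in range(1, cfg.n_mes_genes + 1)]
    bg = [f"BG{i:03d}" for i in range(1, cfg.n_background_genes + 1)]
    mito = [f"{cfg.mito_prefix}{i:02d}" for i in range(1, cfg.n_mito_genes + 1)]
    return epi, mes, bg, mito


def _switch_points(n: int) -> np.ndarray:
    """Gene-specific switch positions, spread evenly over the latent axis."""
    return (np.arange(n) + 0.5) / n


def noise_free_rates(cfg: GeneratorConfig, latent: np.ndarray) -> np.ndarray:
    """Expected relative expression rate per (cell, gene), before depth
    normalisation, NB noise and dropout.

    Epithelial gene j follows lo + (hi - lo) * sigmoid((c_j - z)/w): on at
    the epithelial pole, switching off as the cell passes its switch point
    c_j; mesenchymal genes mirror it. Every epithelial-arm mean is strictly
    decreasing in z and every mesenchymal-arm mean strictly increasing.
    """
    from scipy.special import expit

    z = np.asarray(latent, float)[:, None]
    lo, hi = cfg.low_rate, cfg.high_rate
    w = cfg.switch_width
    c_epi = _switch_points(cfg.n_epi_genes)[None, :]
    c_mes = _switch_points(cfg.n_mes_genes)[None, :]
    epi = lo + (hi - lo) * expit((c_epi - z) / w)
    mes = lo + (hi - lo) * expit((z - c_mes) / w)
    bg = np.full((len(z), cfg.n_background_genes), cfg.background_rate)
    mito = np.full((len(z), cfg.n_mito_genes), cfg.background_rate)
    return np.hstack([epi, mes, bg, mito])


def noise_free_means(cfg: GeneratorConfig, latent: np.ndarray) -> np.ndarray:
    """Expected counts per (cell, gene) at depth ``mean_depth``."""
    rates = noise_free_rates(cfg, latent)
    return cfg.mean_depth * rates / rates.sum(axis=1, keepdims=True)


def generate_emt_population(
    cfg: GeneratorConfig,
) -> tuple[CountMatrix, EMTSignature, pd.DataFrame]:
    """Draw a synthetic EMT cell population.

    Returns the raw count matrix, the generating signature, and a truth
    table (cell_id, latent_emt, true_class, sample_id). Deterministic for a
    fixed seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    classes = rng.choice(len(CLASSES), size=cfg.n_cells, p=list(cfg.mixture_weights))
    latent = np.empty(cfg.n_cells)
    for ci, name in enumerate(CLASSES):
        lo, hi = LATENT_BANDS[name]
        sel = classes == ci
        latent[sel] = rng.uniform(lo, hi, size=int(sel.sum()))

    mu = noise_free_means(cfg, latent)
    # gamma-Poisson == negative binomial with shape `dispersion`
    lam = rng.gamma(shape=cfg.dispersion, scale=mu / cfg.dispersion)
    counts = rng.poisson(lam)
    if cfg.dropout_rate > 0:
        keep = rng.random(counts.shape) >= cfg.dropout_rate
        counts = counts * keep

    epi, mes, bg, mito = _gene_names(cfg)
    gene_ids = np.array(epi + mes + bg + mito, dtype=object)
    mito_flags = np.array([g.startswith(cfg.mito_prefix) for g in gene_ids])
    cell_ids = np.array([f"cell{i:05d}" for i in range(cfg.n_cells)], dtype=object)
    sample_labels = np.array(
        [f"sample{1 + (i % cfg.n_samples)}" for i in range(cfg.n_cells)], dtype=object
    )
    cm = CountMatrix(
        counts=counts.astype(np.int64),
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        sample_labels=sample_labels,
        mito_flags=mito_flags,
        lineage_flags=np.ones(cfg.n_cells, dtype=bool),
    )
    sig = EMTSignature(tuple(epi), tuple(mes), name="synthetic-emt")
    truth = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "latent_emt": latent,
            "true_class": [CLASSES[c] for c in classes],
            "sample_id": sample_labels,
        }
    )
    return cm, sig, truth


def generate_mixed_population(
    cfg: GeneratorConfig, n_noncancer: int, noncancer_signature_rate: float = 0.05
) -> tuple[CountMatrix, EMTSignature, pd.DataFrame]:
    """Cancer population plus non-cancer (e.g. stromal/immune) cells that
    lack signature-gene expression; truth gains an ``is_cancer`` column and
    lineage flags mark the cancer cells."""
    cm, sig, truth = generate_emt_population(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    n_genes = cm.n_genes
    rates = np.full((n_noncancer, n_genes), cfg.background_rate)
    n_sig = cfg.n_epi_genes + cfg.n_mes_genes
    rates[:, :n_sig] = noncancer_signature_rate
    mu = cfg.mean_depth * rates / rates.sum(axis=1, keepdims=True)
    lam = rng.gamma(shape=cfg.dispersion, scale=mu / cfg.dispersion)
    counts_nc = rng.poisson(lam)
    if cfg.dropout_rate > 0:
        counts_nc = counts_nc * (rng.random(counts_nc.shape) >= cfg.dropout_rate)

    nc_ids = np.array([f"stroma{i:05d}" for i in range(n_noncancer)], dtype=object)
    all_counts = np.vstack([cm.counts, counts_nc.astype(np.int64)])
    all_cells = np.concatenate([cm.cell_ids, nc_ids])
    all_samples = np.concatenate(
        [cm.sample_labels,
         np.array([f"sample{1 + (i % cfg.n_samples)}" for i in range(n_noncancer)], dtype=object)]
    )
    lineage = np.concatenate(
        [np.ones(cm.n_cells, dtype=bool), np.zeros(n_noncancer, dtype=bool)]
    )
    mixed = CountMatrix(
        counts=all_counts,
        cell_ids=all_cells,
        gene_ids=cm.gene_ids,
        sample_labels=all_samples,
        mito_flags=cm.mito_flags,
        lineage_flags=lineage,
    )
    truth_nc = pd.DataFrame(
        {
            "cell_id": nc_ids,
            "latent_emt": np.nan,
            "true_class": "NONCANCER",
            "sample_id": all_samples[cm.n_cells:],
        }
    )
    truth = pd.concat([truth, truth_nc], ignore_index=True)
    truth["is_cancer"] = truth["true_class"] != "NONCANCER"
    return mixed, sig, truth


def generate_histology_table(
    n_specimens: int,
    seed: int = 0,
    template: dict[str, float] | None = None,
    concentration: float = 1.0,
) -> pd.DataFrame:
    """Specimen histology compositions: six category percentages per row,
    each row summing to 100. With ``template`` the given percentages are
    used for every specimen (e.g. ``{"panin": 100.0}`` for an all-PanIN
    specimen); otherwise rows are Dirichlet-distributed."""
    if n_specimens < 1:
        raise ValueError("n_specimens must be at least 1")
    rng = np.random.default_rng(seed)
    if template is not None:
        unknown = set(template) - set(HISTOLOGY_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown histology categories: {sorted(unknown)}")
        row = np.array([template.get(c, 0.0) for c in HISTOLOGY_CATEGORIES], float)
        if row.sum() <= 0:
            raise ValueError("template percentages must sum to a positive value")
        row = row / row.sum() * 100.0
        comp = np.tile(row, (n_specimens, 1))
    else:
        comp = rng.dirichlet([concentration] * len(HISTOLOGY_CATEGORIES), n_specimens) * 100.0
    df = pd.DataFrame(comp, columns=list(HISTOLOGY_CATEGORIES))
    df.insert(0, "specimen_id", [f"specimen{i:03d}" for i in range(n_specimens)])
    return df


def generate_point_pattern(
    n_cancer: int,
    n_tcell: int,
    window: Rectangle = Rectangle(0.0, 0.0, 400.0, 400.0),
    interaction: str = "csr",
    interaction_scale: float = 20.0,
    seed: int = 0,
    max_rejection_rounds: int = 1000,
) -> PointPattern:
    """Marked point pattern of cancer cells and T cells.

    ``csr`` places both phenotypes independently uniformly; ``attraction``
    places each T cell at a Gaussian offset (SD ``interaction_scale``) from
    a random cancer parent, Thomas-process style; ``exclusion`` rejects and
    resamples T-cell candidates within ``interaction_scale`` um of any
    cancer cell, failing explicitly if the window cannot accommodate them.
    """
    if n_cancer < 1 or n_tcell < 1:
        raise ValueError("counts must be at least 1")
    rng = np.random.default_rng(seed)

    def uniform(n: int) -> np.ndarray:
        return np.column_stack(
            [rng.uniform(window.xmin, window.xmax, n),
             rng.uniform(window.ymin, window.ymax, n)]
        )

    cancer = uniform(n_cancer)
    if interaction == "csr":
        tcell = uniform(n_tcell)
    elif interaction == "attraction":
        pts: list[np.ndarray] = []
        while sum(len(p) for p in pts) < n_tcell:
            need = n_tcell - sum(len(p) for p in pts)
            parents = cancer[rng.integers(0, n_cancer, need)]
            cand = parents + rng.normal(0.0, interaction_scale, (need, 2))
            inside = window.contains(cand[:, 0], cand[:, 1])
            pts.append(cand[inside])
        tcell = np.vstack(pts)[:n_tcell]
    elif interaction == "exclusion":
        from scipy.spatial import cKDTree

        tree = cKDTree(cancer)
        placed: list[np.ndarray] = []
        rounds = 0
        while sum(len(p) for p in placed) < n_tcell:
            rounds += 1
            if rounds > max_rejection_rounds:
                raise RuntimeError(
                    "exclusion sampling failed: window too dense for the "
                    f"requested exclusion radius {interaction_scale} um"
                )
            need = n_tcell - sum(len(p) for p in placed)
            cand = uniform(max(need, 16))
            dist, _ = tree.query(cand)
            ok = dist >= interaction_scale
            placed.append(cand[ok][:need])
        tcell = np.vstack(placed)[:n_tcell]
    else:
        raise ValueError(f"unknown interaction: {interaction!r}")

    df = pd.DataFrame(
        {
            "x_um": np.concatenate([cancer[:, 0], tcell[:, 0]]),
            "y_um": np.concatenate([cancer[:, 1], tcell[:, 1]]),
            "phenotype": ["cancer"] * n_cancer + ["tcell"] * n_tcell,
        }
    )
    return PointPattern(points=df, window=window)
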