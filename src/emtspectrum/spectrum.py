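"""EMT-spectrum analysis: clustering, E/M scores, phenotype classification.

Cells are clustered on diffusion-smoothed signature expression via a
shared-nearest-neighbour (SNN) graph and Leiden modularity optimisation.
Each cluster receives an E/M score,

    score = log2(EPI / MES),

where EPI and MES are the fractions of strictly positive scaled-expression
entries over the cluster's cells for the epithelial and mesenchymal
signature arms (a small pseudocount guards empty fractions). Clusters are
classified epithelial (score >= 1.5), mesenchymal (score <= -1.5) or
partial-EMT (in between), relabelled 1..K from the epithelial to the
mesenchymal end of the spectrum, and summarised as cell-weighted phenotype
proportions overall, per sample, or per patient.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse
from sklearn.neighbors import NearestNeighbors

from .preprocessing import ScaledMatrix
from .signature import EMTSignature

EM_CLASSES = ("EPI", "PEMT", "MES")


@dataclass(frozen=True)
class PhenotypeCutoffs:
    """E/M score boundaries; both are inclusive (score exactly 1.5 is
    epithelial, exactly -1.5 mesenchymal)."""

    epithelial_min: float = 1.5
    mesenchymal_max: float = -1.5
    pseudocount: float = 1e-6

    def __post_init__(self) -> None:
        if not self.mesenchymal_max < self.epithelial_min:
            raise ValueError("mesenchymal_max must be < epithelial_min")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


@dataclass
class ClusterAssignment:
    """Cell -> cluster labels (contiguous 1..n_clusters)."""

    labels: np.ndarray
    n_clusters: int
    resolution: float
    quality: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, int)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(1, self.n_clusters + 1)):
            raise ValueError("cluster labels must be contiguous 1..n_clusters")

    def cells_in(self, cluster: int) -> np.ndarray:
        return self.labels == cluster


def _mean_pairwise_correlation(values: np.ndarray, labels: np.ndarray) -> float:
    """Mean within-cluster pairwise Pearson correlation of expression rows.

    Rows are standardised so that corr(i, j) = z_i . z_j / d; the mean over
    all pairs in a cluster is then (||sum z||^2 - sum ||z||^2) / (m(m-1)d),
    avoiding the explicit pair loop. Singleton clusters are skipped; if all
    clusters are singletons the quality is 0.
    """
    x = np.asarray(values, float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    d = x.shape[1]
    vals = []
    for c in np.unique(labels):
        zc = z[labels == c]
        m = len(zc)
        if m < 2:
            continue
        s = zc.sum(axis=0)
        total = float(s @ s) - float((zc * zc).sum())
        vals.append(total / (m * (m - 1) * d))
    return float(np.mean(vals)) if vals else 0.0


def _snn_graph(values: np.ndarray, k: int) -> ig.Graph:
    """Shared-nearest-neighbour graph with Jaccard edge weights."""
    n = values.shape[0]
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(values)
    _, idx = nn.kneighbors(values)  # includes self in column 0
    rows = np.repeat(np.arange(n), k_eff + 1)
    b = scipy.sparse.csr_matrix(
        (np.ones(idx.size), (rows, idx.ravel())), shape=(n, n)
    )
    inter = (b @ b.T).tocoo()
    r, c, shared = inter.row, inter.col, inter.data
    upper = r < c
    r, c, shared = r[upper], c[upper], shared[upper]
    jacc = shared / (2 * (k_eff + 1) - shared)
    keep = jacc > 0
    edges = list(zip(r[keep].tolist(), c[keep].tolist()))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = jacc[keep].tolist()
    return g


def cluster_cells(
    smoothed: ScaledMatrix,
    resolution: float = 1.0,
    k: int = 15,
    seed: int = 0,
) -> ClusterAssignment:
    """SNN graph + Leiden modularity communities at a given resolution.

    Deterministic for a fixed seed. Quality is the mean within-cluster
    pairwise Pearson correlation of the cells' signature vectors.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if smoothed.n_cells < 2:
        raise ValueError("need at least 2 cells to cluster")
    g = _snn_graph(smoothed.values, k)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    membership = np.asarray(part.membership)
    # contiguous 1..K in order of first appearance
    _, first = np.unique(membership, return_index=True)
    order = membership[np.sort(first)]
    remap = {old: i + 1 for i, old in enumerate(order)}
    labels = np.array([remap[m] for m in membership])
    quality = _mean_pairwise_correlation(smoothed.values, labels)
    return ClusterAssignment(
        labels=labels,
        n_clusters=len(remap),
        resolution=resolution,
        quality=quality,
    )


def select_resolution(
    smoothed: ScaledMatrix,
    resolutions: list[float],
    k: int = 15,
    seed: int = 0,
    quality_floor: float | None = None,
) -> tuple[float, ClusterAssignment]:
    """Pick a clustering resolution by within-cluster expression consistency.

    Returns the smallest resolution whose quality exceeds ``quality_floor``;
    without a floor (or if none qualifies) falls back to the
    quality-maximising resolution.
    """
    if not resolutions:
        raise ValueError("resolution grid is empty")
    results = [
        (r, cluster_cells(smoothed, resolution=r, k=k, seed=seed))
        for r in sorted(resolutions)
    ]
    if quality_floor is not None:
        for r, asg in results:
            if asg.quality >= quality_floor:
                return r, asg
    best = max(results, key=lambda ra: ra[1].quality)
    return best


def positive_fraction(
    scaled: ScaledMatrix, cell_mask: np.ndarray, genes: list[str] | tuple[str, ...]
) -> float:
    """Fraction of strictly positive (cell, gene) entries over a cell
    subset and gene set, pooled across cells and genes."""
    if len(genes) == 0:
        raise ValueError("gene set is empty")
    mask = np.asarray(cell_mask, bool)
    if not mask.any():
        raise ValueError("cell subset is empty")
    idx = scaled.gene_index(genes)
    block = scaled.values[np.ix_(mask, idx)]
    return float((block > 0).mean())


def em_score(
    epi_fraction: float,
    mes_fraction: float,
    cutoffs: PhenotypeCutoffs = PhenotypeCutoffs(),
) -> tuple[float, str]:
    """E/M score log2((EPI + eps)/(MES + eps)) and its phenotype class."""
    for f in (epi_fraction, mes_fraction):
        if not 0.0 <= f <= 1.0:
            raise ValueError("fractions must be in [0, 1]")
    eps = cutoffs.pseudocount
    score = float(np.log2((epi_fraction + eps) / (mes_fraction + eps)))
    return score, classify_score(score, cutoffs)


def classify_score(score: float, cutoffs: PhenotypeCutoffs = PhenotypeCutoffs()) -> str:
    if score >= cutoffs.epithelial_min:
        return "EPI"
    if score <= cutoffs.mesenchymal_max:
        return "MES"
    return "PEMT"


def score_clusters(
    smoothed: ScaledMatrix,
    assignment: ClusterAssignment,
    sig: EMTSignature,
    cutoffs: PhenotypeCutoffs = PhenotypeCutoffs(),
) -> pd.DataFrame:
    """Per-cluster EPI/MES positive fractions, E/M score and class."""
    rows = []
    for c in range(1, assignment.n_clusters + 1):
        mask = assignment.cells_in(c)
        epi = positive_fraction(smoothed, mask, sig.epithelial_genes)
        mes = positive_fraction(smoothed, mask, sig.mesenchymal_genes)
        score, em_class = em_score(epi, mes, cutoffs)
        rows.append(
            {
                "cluster": c,
                "epi_fraction": epi,
                "mes_fraction": mes,
                "score": score,
                "em_class": em_class,
                "n_cells": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)


def order_clusters(
    table: pd.DataFrame, assignment: ClusterAssignment
) -> tuple[pd.DataFrame, ClusterAssignment]:
    """Relabel clusters 1..K in strictly decreasing score order (most
    epithelial first); ties broken by larger n_cells, then original label.
    Cell assignments are remapped consistently."""
    if table.empty:
        raise ValueError("score table is empty")
    ordered = table.sort_values(
        ["score", "n_cells", "cluster"], ascending=[False, False, True]
    ).reset_index(drop=True)
    remap = {int(old): i + 1 for i, old in enumerate(ordered["cluster"])}
    ordered["cluster"] = np.arange(1, len(ordered) + 1)
    new_labels = np.array([remap[int(c)] for c in assignment.labels])
    new_assignment = ClusterAssignment(
        labels=new_labels,
        n_clusters=assignment.n_clusters,
        resolution=assignment.resolution,
        quality=assignment.quality,
    )
    return ordered, new_assignment


def phenotype_proportions(
    assignment: ClusterAssignment,
    table: pd.DataFrame,
    sample_labels: np.ndarray | None = None,
) -> dict:
    """Cell-weighted percentage of cells in clusters of each phenotype.

    Returns ``{"overall": {...}}`` plus a ``"by_sample"`` mapping when
    sample labels are given; each percentage block sums to 100.
    """
    class_of_cluster = dict(zip(table["cluster"].astype(int), table["em_class"]))
    cell_class = np.array([class_of_cluster[int(c)] for c in assignment.labels])

    def pct(classes: np.ndarray) -> dict[str, float]:
        n = len(classes)
        return {c: float((classes == c).sum()) * 100.0 / n for c in EM_CLASSES}

    out: dict = {"overall": pct(cell_class)}
    if sample_labels is not None:
        labels = np.asarray(sample_labels)
        out["by_sample"] = {
            str(s): pct(cell_class[labels == s]) for s in np.unique(labels)
        }
    return out


def classify_sample(
    smoothed: ScaledMatrix,
    assignment: ClusterAssignment,
    table: pd.DataFrame,
    sig: EMTSignature,
    sample_id: str,
    cutoffs: PhenotypeCutoffs = PhenotypeCutoffs(),
    rule: str = "pooled",
) -> dict:
    """Classify one sample along the spectrum.

    ``pooled`` (default) pools the sample's cells, computes positive
    fractions and the E/M score over the pool, and applies the cluster
    cutoffs. ``plurality`` takes the most common per-cell phenotype via
    each cell's cluster class; ties resolve toward PEMT, the middle of the
    spectrum. The rule used is recorded in the output.
    """
    mask = smoothed.sample_labels == sample_id
    if not mask.any():
        raise KeyError(f"unknown sample id: {sample_id!r}")
    if rule == "pooled":
        epi = positive_fraction(smoothed, mask, sig.epithelial_genes)
        mes = positive_fraction(smoothed, mask, sig.mesenchymal_genes)
        score, em_class = em_score(epi, mes, cutoffs)
        return {
            "sample_id": sample_id, "rule": rule, "score": score,
            "em_class": em_class, "n_cells": int(mask.sum()),
        }
    if rule == "plurality":
        class_of_cluster = dict(zip(table["cluster"].astype(int), table["em_class"]))
        cell_class = pd.Series(
            [class_of_cluster[int(c)] for c in assignment.labels[mask]]
        )
        counts = cell_class.value_counts()
        top = counts[counts == counts.max()].index.tolist()
        em_class = top[0] if len(top) == 1 else ("PEMT" if "PEMT" in top else top[0])
        return {
            "sample_id": sample_id, "rule": rule, "score": float("nan"),
            "em_class": em_class, "n_cells": int(mask.sum()),
        }
    raise ValueError(f"unknown sample classification rule: {rule!r}")


def classify_samples(
    smoothed: ScaledMatrix,
    assignment: ClusterAssignment,
    table: pd.DataFrame,
    sig: EMTSignature,
    cutoffs: PhenotypeCutoffs = PhenotypeCutoffs(),
    rule: str = "pooled",
) -> pd.DataFrame:
    rows = [
        classify_sample(smoothed, assignment, table, sig, str(s), cutoffs, rule)
        for s in np.unique(smoothed.sample_labels)
    ]
    return pd.DataFrame(rows)
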