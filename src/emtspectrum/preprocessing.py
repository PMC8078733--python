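"""Count-matrix containers, QC filtering, normalisation and cancer-cell selection.

Mirrors the pre-smoothing steps of a standard droplet scRNA-seq workflow:
cells are kept if they detect between ``min_genes`` and ``max_genes`` genes
(defaults 200 and 5000) and at most 10% mitochondrial counts (cells with
strictly more than 10% are removed); counts are then depth-normalised,
log1p-transformed and z-scored per gene ("scaled data"); cancer cells are
selected by mean scaled expression of epithelial markers and/or a lineage
label (e.g. YFP tracing), modelled as a per-cell boolean flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

DEFAULT_MITO_PREFIX = ("MT-", "mt-")


@dataclass
class CountMatrix:
    """Cells x genes raw counts with identifiers and per-cell metadata."""

    counts: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    sample_labels: np.ndarray
    mito_flags: np.ndarray | None = None
    lineage_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_labels = np.asarray(self.sample_labels, dtype=object)
        n, g = self.counts.shape
        if len(self.cell_ids) != n or len(self.sample_labels) != n:
            raise ValueError("cell metadata length does not match counts")
        if len(self.gene_ids) != g:
            raise ValueError("gene metadata length does not match counts")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell_ids must be unique")
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene_ids must be unique")
        if self.mito_flags is None:
            self.mito_flags = np.array(
                [str(gid).startswith(DEFAULT_MITO_PREFIX) for gid in self.gene_ids]
            )
        else:
            self.mito_flags = np.asarray(self.mito_flags, dtype=bool)
        if self.lineage_flags is not None:
            self.lineage_flags = np.asarray(self.lineage_flags, dtype=bool)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(
            counts=self.counts[mask],
            cell_ids=self.cell_ids[mask],
            gene_ids=self.gene_ids,
            sample_labels=self.sample_labels[mask],
            mito_flags=self.mito_flags,
            lineage_flags=None if self.lineage_flags is None else self.lineage_flags[mask],
        )


@dataclass(frozen=True)
class QCThresholds:
    """Gene-count bounds are inclusive; the mitochondrial bound removes
    cells with strictly more than ``max_mito_fraction`` mitochondrial
    counts (so exactly 10.0% is retained under the default)."""

    min_genes: int = 200
    max_genes: int = 5000
    max_mito_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not self.min_genes < self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        if not 0.0 < self.max_mito_fraction < 1.0:
            raise ValueError("max_mito_fraction must be in (0, 1)")


@dataclass(frozen=True)
class QCReport:
    n_input: int
    n_removed_low_genes: int
    n_removed_high_genes: int
    n_removed_mito: int
    n_retained: int


def qc_filter(
    counts: CountMatrix, thr: QCThresholds = QCThresholds()
) -> tuple[CountMatrix, QCReport]:
    """Remove low-quality cells; the gene set is left unchanged."""
    detected = (counts.counts > 0).sum(axis=1)
    total = counts.counts.sum(axis=1).astype(float)
    mito = counts.counts[:, counts.mito_flags].sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1.0), 0.0)
    low = detected < thr.min_genes
    high = detected > thr.max_genes
    mito_bad = mito_frac > thr.max_mito_fraction
    keep = ~(low | high | mito_bad)
    if not keep.any():
        raise ValueError("QC filtering removed every cell")
    report = QCReport(
        n_input=counts.n_cells,
        n_removed_low_genes=int(low.sum()),
        n_removed_high_genes=int(high.sum()),
        n_removed_mito=int(mito_bad.sum()),
        n_retained=int(keep.sum()),
    )
    return counts.subset_cells(keep), report


@dataclass
class ScaledMatrix:
    """Per-gene standardised expression ("scaled data").

    Nonconstant gene columns have mean 0 and SD 1; zero-variance genes map
    to all-zero columns. ``provenance`` records the normalisation settings.
    """

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    sample_labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_labels = np.asarray(self.sample_labels, dtype=object)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return np.array([lookup[g] for g in genes])

    def restrict_genes(self, genes: Sequence[str]) -> "ScaledMatrix":
        idx = self.gene_index(genes)
        return ScaledMatrix(
            values=self.values[:, idx],
            cell_ids=self.cell_ids,
            gene_ids=self.gene_ids[idx],
            sample_labels=self.sample_labels,
            provenance=dict(self.provenance, restricted_to=len(idx)),
        )

    def subset_cells(self, mask: np.ndarray) -> "ScaledMatrix":
        mask = np.asarray(mask)
        return ScaledMatrix(
            values=self.values[mask],
            cell_ids=self.cell_ids[mask],
            gene_ids=self.gene_ids,
            sample_labels=self.sample_labels[mask],
            provenance=dict(self.provenance),
        )


def normalize_and_scale(
    counts: CountMatrix, target_sum: float = 1e4
) -> ScaledMatrix:
    """Depth-normalise to ``target_sum`` counts per cell, log1p, z-score per gene.

    Two cells with proportional count vectors become identical rows after
    the depth step, so the result is invariant to per-cell depth rescaling.
    """
    if counts.n_cells == 0 or counts.n_genes == 0:
        raise ValueError("empty count matrix")
    x = counts.counts.astype(float)
    depth = x.sum(axis=1, keepdims=True)
    if np.any(depth == 0):
        raise ValueError("cells with zero total counts; run qc_filter first")
    x = np.log1p(x / depth * target_sum)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    nonconst = sd > 0
    z = np.zeros_like(x)
    z[:, nonconst] = (x[:, nonconst] - mu[nonconst]) / sd[nonconst]
    return ScaledMatrix(
        values=z,
        cell_ids=counts.cell_ids,
        gene_ids=counts.gene_ids,
        sample_labels=counts.sample_labels,
        provenance={"target_sum": target_sum, "log": "log1p", "scale": "z-score"},
    )


@dataclass(frozen=True)
class SelectionReport:
    n_input: int
    n_by_score: int
    n_by_lineage: int
    n_selected: int
    threshold: float


def select_cancer_cells(
    scaled: ScaledMatrix,
    epithelial_markers: Iterable[str],
    lineage_flags: np.ndarray | None = None,
    threshold: float = 0.0,
) -> tuple[np.ndarray, SelectionReport]:
    """Select cancer cells by epithelial marker score OR lineage label.

    A cell is selected if its mean scaled expression over
    ``epithelial_markers`` is >= ``threshold``, or its lineage flag (e.g.
    YFP tracing) is true. Returns a boolean mask over cells plus a report.
    """
    markers = list(epithelial_markers)
    if not markers and lineage_flags is None:
        raise ValueError("need epithelial markers or lineage flags")
    if markers:
        idx = scaled.gene_index(markers)
        score = scaled.values[:, idx].mean(axis=1)
        by_score = score >= threshold
    else:
        by_score = np.zeros(scaled.n_cells, dtype=bool)
    if lineage_flags is not None:
        by_lineage = np.asarray(lineage_flags, dtype=bool)
        if len(by_lineage) != scaled.n_cells:
            raise ValueError("lineage_flags length does not match cells")
    else:
        by_lineage = np.zeros(scaled.n_cells, dtype=bool)
    mask = by_score | by_lineage
    if not mask.any():
        raise ValueError("cancer-cell selection is empty")
    report = SelectionReport(
        n_input=scaled.n_cells,
        n_by_score=int(by_score.sum()),
        n_by_lineage=int(by_lineage.sum()),
        n_selected=int(mask.sum()),
        threshold=threshold,
    )
    return mask, report


# ---------------------------------------------------------------------------
# MatrixMarket I/O with TSV sidecars

def write_count_matrix(cm: CountMatrix, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "matrix.mtx", scipy.sparse.csr_matrix(cm.counts))
    genes = pd.DataFrame({"gene_id": cm.gene_ids, "is_mito": cm.mito_flags})
    genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    cells = pd.DataFrame({"cell_id": cm.cell_ids, "sample_id": cm.sample_labels})
    if cm.lineage_flags is not None:
        cells["lineage"] = cm.lineage_flags
    cells.to_csv(out / "cells.tsv", sep="\t", index=False)


def read_count_matrix(in_dir: str | Path) -> CountMatrix:
    src = Path(in_dir)
    mat = scipy.io.mmread(src / "matrix.mtx")
    counts = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    counts = counts.astype(np.int64)
    genes = pd.read_csv(src / "genes.tsv", sep="\t")
    cells = pd.read_csv(src / "cells.tsv", sep="\t")
    return CountMatrix(
        counts=counts,
        cell_ids=cells["cell_id"].to_numpy(dtype=object),
        gene_ids=genes["gene_id"].to_numpy(dtype=object),
        sample_labels=cells["sample_id"].to_numpy(dtype=object),
        mito_flags=genes["is_mito"].to_numpy(dtype=bool) if "is_mito" in genes else None,
        lineage_flags=cells["lineage"].to_numpy(dtype=bool) if "lineage" in cells else None,
    )


def read_count_matrix_csv(path: str | Path) -> CountMatrix:
    """Dense CSV alternative: rows = cells (index cell_id), columns = genes,
    with an optional ``sample_id`` column."""
    df = pd.read_csv(path, index_col=0)
    sample = df.pop("sample_id") if "sample_id" in df else pd.Series(
        ["sample1"] * len(df), index=df.index
    )
    return CountMatrix(
        counts=df.to_numpy(dtype=np.int64),
        cell_ids=df.index.to_numpy(dtype=object),
        gene_ids=df.columns.to_numpy(dtype=object),
        sample_labels=sample.to_numpy(dtype=object),
    )
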