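"""End-to-end pipeline: counts -> QC -> scale -> select -> smooth -> cluster
-> E/M score -> phenotype proportions, with a machine-readable run report.

Every stage's parameters and input/output cell counts are recorded so a
run is auditable, and the whole pipeline is deterministic for a fixed
configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffusion as diff
from . import preprocessing as prep
from . import signature as sigmod
from . import spectrum as spec
from . import synthetic


@dataclass
class PipelineConfig:
    """Single-document configuration for a full run.

    Either ``simulate`` holds generator-config overrides (synthetic input),
    or ``counts_dir``/``counts_csv`` + ``signature_path`` point at data on
    disk. All stage parameters carry the package defaults and are echoed in
    the run report.
    """

    seed: int = 0
    simulate: dict | None = None
    counts_dir: str | None = None
    counts_csv: str | None = None
    signature_path: str | None = None
    ortholog_table: str | None = None

    min_genes: int = 200
    max_genes: int = 5000
    max_mito_fraction: float = 0.10
    target_sum: float = 1e4

    select_threshold: float = 0.0
    use_lineage: bool = True

    diffusion_k: int = 15
    diffusion_decay: float = 2.0
    diffusion_t: int = 3

    resolutions: list = field(default_factory=lambda: [1.0])
    cluster_k: int = 15
    quality_floor: float | None = None

    epithelial_min: float = 1.5
    mesenchymal_max: float = -1.5
    pseudocount: float = 1e-6
    sample_rule: str = "pooled"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.simulate is None:
            if self.counts_dir is None and self.counts_csv is None:
                raise ValueError("config needs either 'simulate' or a counts path")
            if self.signature_path is None:
                raise ValueError("config needs 'signature_path' when loading counts")
            for p in (self.counts_dir, self.counts_csv, self.signature_path,
                      self.ortholog_table):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"configured path does not exist: {p}")


@dataclass
class PipelineResult:
    scaled: prep.ScaledMatrix
    smoothed: prep.ScaledMatrix
    assignment: spec.ClusterAssignment
    score_table: pd.DataFrame
    proportions: dict
    samples: pd.DataFrame
    report: dict


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        gen = synthetic.GeneratorConfig(
            **{**config.simulate, "seed": config.simulate.get("seed", config.seed)}
        )
        counts, sig, _ = synthetic.generate_emt_population(gen)
        return counts, sig, {"source": "simulate", "generator": asdict(gen)}
    if config.counts_dir is not None:
        counts = prep.read_count_matrix(config.counts_dir)
        source = config.counts_dir
    else:
        counts = prep.read_count_matrix_csv(config.counts_csv)
        source = config.counts_csv
    sig = sigmod.load_signature(config.signature_path)
    if config.ortholog_table is not None:
        table = sigmod.load_ortholog_table(config.ortholog_table)
        sig, _ = sigmod.map_orthologs(sig, table=table)
    return counts, sig, {"source": source, "signature": config.signature_path}


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path | None = None
) -> PipelineResult:
    """Execute the full analysis and optionally write standard outputs
    (clusters.csv, em_scores.csv, proportions.json, samples.csv,
    report.json) into ``out_dir``."""
    config.validate()
    counts, sig, input_info = _load_inputs(config)
    stages: list[dict] = [
        {"stage": "load", "n_cells_in": counts.n_cells, "n_cells_out": counts.n_cells,
         **input_info}
    ]

    thr = prep.QCThresholds(
        min_genes=config.min_genes,
        max_genes=config.max_genes,
        max_mito_fraction=config.max_mito_fraction,
    )
    n_in = counts.n_cells
    counts, qc_report = prep.qc_filter(counts, thr)
    stages.append(
        {"stage": "qc", "n_cells_in": n_in, "n_cells_out": counts.n_cells,
         "params": asdict(thr), "report": asdict(qc_report)}
    )

    scaled = prep.normalize_and_scale(counts, target_sum=config.target_sum)
    stages.append(
        {"stage": "normalize_and_scale", "n_cells_in": counts.n_cells,
         "n_cells_out": scaled.n_cells, "params": {"target_sum": config.target_sum}}
    )

    sig, discovered = sigmod.restrict_to_matrix(sig, scaled.gene_ids)
    mask, sel_report = prep.select_cancer_cells(
        scaled,
        sig.epithelial_genes,
        lineage_flags=counts.lineage_flags if config.use_lineage else None,
        threshold=config.select_threshold,
    )
    scaled = scaled.subset_cells(mask)
    counts = counts.subset_cells(mask)
    stages.append(
        {"stage": "select_cancer_cells", "n_cells_in": sel_report.n_input,
         "n_cells_out": sel_report.n_selected, "params": asdict(sel_report),
         "signature_genes_discovered": discovered}
    )

    sig_scaled = scaled.restrict_genes(sig.all_genes)
    op = diff.build_diffusion_operator(
        sig_scaled, k=config.diffusion_k, decay=config.diffusion_decay,
        t=config.diffusion_t,
    )
    smoothed = diff.impute(sig_scaled, op)
    stages.append(
        {"stage": "diffusion", "n_cells_in": sig_scaled.n_cells,
         "n_cells_out": smoothed.n_cells,
         "params": {"k": config.diffusion_k, "decay": config.diffusion_decay,
                    "t": config.diffusion_t}}
    )

    resolution, assignment = spec.select_resolution(
        smoothed, list(config.resolutions), k=config.cluster_k, seed=config.seed,
        quality_floor=config.quality_floor,
    )
    cutoffs = spec.PhenotypeCutoffs(
        epithelial_min=config.epithelial_min,
        mesenchymal_max=config.mesenchymal_max,
        pseudocount=config.pseudocount,
    )
    table = spec.score_clusters(smoothed, assignment, sig, cutoffs)
    table, assignment = spec.order_clusters(table, assignment)
    proportions = spec.phenotype_proportions(
        assignment, table, sample_labels=smoothed.sample_labels
    )
    samples = spec.classify_samples(
        smoothed, assignment, table, sig, cutoffs, rule=config.sample_rule
    )
    stages.append(
        {"stage": "spectrum", "n_cells_in": smoothed.n_cells,
         "n_cells_out": smoothed.n_cells,
         "params": {"resolution": resolution, "k": config.cluster_k,
                    "seed": config.seed, "cutoffs": asdict(cutoffs),
                    "sample_rule": config.sample_rule},
         "n_clusters": assignment.n_clusters, "quality": assignment.quality}
    )

    report = {
        "seed": config.seed,
        "config": asdict(config),
        "stages": stages,
        "n_clusters": assignment.n_clusters,
        "proportions": proportions,
    }
    result = PipelineResult(
        scaled=scaled, smoothed=smoothed, assignment=assignment,
        score_table=table, proportions=proportions, samples=samples,
        report=report,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    class_of_cluster = dict(
        zip(result.score_table["cluster"].astype(int), result.score_table["em_class"])
    )
    clusters = pd.DataFrame(
        {
            "cell_id": result.smoothed.cell_ids,
            "cluster": result.assignment.labels,
            "em_class": [class_of_cluster[int(c)] for c in result.assignment.labels],
        }
    )
    clusters.to_csv(out / "clusters.csv", index=False)
    result.score_table.to_csv(out / "em_scores.csv", index=False)
    with open(out / "proportions.json", "w") as fh:
        json.dump(result.proportions, fh, indent=2, sort_keys=True)
    result.samples.to_csv(out / "samples.csv", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True, default=str)
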