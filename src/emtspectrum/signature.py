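"""EMT gene signatures: loading, validation, restriction and ortholog mapping.

An EMT signature is two disjoint gene sets — an epithelial arm and a
mesenchymal arm — such as the published ~315-gene universal EMT
signature. The signature file is user-supplied data (two-column TSV:
``gene``, ``arm``); this package never ships a published gene list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

ARMS = ("epithelial", "mesenchymal")


@dataclass(frozen=True)
class EMTSignature:
    """Two disjoint, non-empty, duplicate-free gene arms.

    Parameters
    ----------
    epithelial_genes, mesenchymal_genes
        Ordered gene symbols for each arm.
    name
        Free-text label carried through outputs.
    """

    epithelial_genes: tuple[str, ...]
    mesenchymal_genes: tuple[str, ...]
    name: str = "signature"

    def __post_init__(self) -> None:
        epi = tuple(self.epithelial_genes)
        mes = tuple(self.mesenchymal_genes)
        object.__setattr__(self, "epithelial_genes", epi)
        object.__setattr__(self, "mesenchymal_genes", mes)
        if not epi or not mes:
            raise ValueError("both signature arms must be non-empty")
        if len(set(epi)) != len(epi) or len(set(mes)) != len(mes):
            raise ValueError("duplicate gene symbols within a signature arm")
        overlap = set(epi) & set(mes)
        if overlap:
            raise ValueError(
                f"genes present in both arms: {sorted(overlap)}"
            )

    @property
    def all_genes(self) -> tuple[str, ...]:
        return self.epithelial_genes + self.mesenchymal_genes

    @property
    def n_genes(self) -> int:
        return len(self.epithelial_genes) + len(self.mesenchymal_genes)


@dataclass(frozen=True)
class OrthologMap:
    """Result of mapping signature symbols to another species.

    ``pairs`` maps each mapped source symbol to exactly one target symbol;
    ``unmapped`` holds source symbols with no target. Together they
    partition the input symbols.
    """

    pairs: Mapping[str, str]
    unmapped: frozenset[str] = field(default_factory=frozenset)


def load_signature(path: str | Path, name: str | None = None) -> EMTSignature:
    """Read a signature TSV with columns ``gene`` and ``arm``.

    Duplicate (gene, arm) rows are collapsed; a gene listed under both arms
    is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene", "arm"} - set(df.columns)
    if missing:
        raise ValueError(f"signature file missing columns: {sorted(missing)}")
    bad = set(df["arm"]) - set(ARMS)
    if bad:
        raise ValueError(f"unknown arm labels: {sorted(bad)} (expected {ARMS})")
    df = df.drop_duplicates(subset=["gene", "arm"])
    epi = tuple(df.loc[df["arm"] == "epithelial", "gene"])
    mes = tuple(df.loc[df["arm"] == "mesenchymal", "gene"])
    if not epi or not mes:
        raise ValueError("signature file must contain genes in both arms")
    return EMTSignature(epi, mes, name=name or Path(path).stem)


def write_signature(sig: EMTSignature, path: str | Path) -> None:
    """Write a signature as a two-column TSV (gene, arm)."""
    df = pd.DataFrame(
        {
            "gene": sig.all_genes,
            "arm": ["epithelial"] * len(sig.epithelial_genes)
            + ["mesenchymal"] * len(sig.mesenchymal_genes),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def restrict_to_matrix(
    sig: EMTSignature, genes: Iterable[str]
) -> tuple[EMTSignature, int]:
    """Keep only signature genes discoverable in a gene universe.

    Returns the restricted signature and the number of discovered genes
    (|E ∩ universe| + |M ∩ universe|). Raises if either arm would vanish.
    """
    universe = set(genes)
    if not universe:
        raise ValueError("gene universe is empty")
    epi = tuple(g for g in sig.epithelial_genes if g in universe)
    mes = tuple(g for g in sig.mesenchymal_genes if g in universe)
    if not epi:
        raise ValueError("epithelial arm entirely absent from the gene universe")
    if not mes:
        raise ValueError("mesenchymal arm entirely absent from the gene universe")
    return EMTSignature(epi, mes, name=sig.name), len(epi) + len(mes)


def load_ortholog_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"human_symbol", "mouse_symbol"} - set(df.columns)
    if missing:
        raise ValueError(f"ortholog table missing columns: {sorted(missing)}")
    return df


def map_orthologs(
    sig: EMTSignature,
    table: pd.DataFrame | None = None,
    rule: str = "title-case",
) -> tuple[EMTSignature, OrthologMap]:
    """Map signature symbols to another species.

    With ``table`` (columns ``human_symbol``, ``mouse_symbol``) each source
    symbol maps to at most one target; conflicting duplicate rows are an
    error, as is a target claimed by sources from different arms. Without a
    table, the default ``"title-case"`` rule converts e.g. CDH1 → Cdh1, the
    common human→mouse symbol convention. Unmapped genes are dropped and
    recorded.
    """
    if table is not None:
        pairs: dict[str, str] = {}
        for src, tgt in zip(table["human_symbol"], table["mouse_symbol"]):
            if src in pairs and pairs[src] != tgt:
                raise ValueError(f"conflicting targets for source symbol {src!r}")
            pairs[src] = tgt
        mapper = pairs.get
    elif rule == "title-case":
        mapper = lambda g: g.capitalize()  # noqa: E731
    else:
        raise ValueError(f"unknown ortholog rule: {rule!r}")

    arm_of_target: dict[str, str] = {}
    mapped: dict[str, list[str]] = {"epithelial": [], "mesenchymal": []}
    pairs_out: dict[str, str] = {}
    unmapped: set[str] = set()
    for arm, arm_genes in (
        ("epithelial", sig.epithelial_genes),
        ("mesenchymal", sig.mesenchymal_genes),
    ):
        for g in arm_genes:
            tgt = mapper(g)
            if tgt is None:
                unmapped.add(g)
                continue
            prior = arm_of_target.get(tgt)
            if prior is not None and prior != arm:
                raise ValueError(
                    f"target symbol {tgt!r} claimed by both signature arms"
                )
            if tgt not in arm_of_target:
                mapped[arm].append(tgt)
            arm_of_target[tgt] = arm
            pairs_out[g] = tgt
    if not mapped["epithelial"] or not mapped["mesenchymal"]:
        raise ValueError("ortholog mapping left a signature arm empty")
    out = EMTSignature(
        tuple(mapped["epithelial"]), tuple(mapped["mesenchymal"]), name=sig.name
    )
    return out, OrthologMap(pairs=pairs_out, unmapped=frozenset(unmapped))
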