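"""Single-cell vs single-nucleus comparison statistics.

Operates on pairs of normalized AnnData groups (e.g. 24 hr APF cells vs
nuclei) sharing one gene universe: detected-gene overlap, intron read
fractions, library-composition top genes, and dropout panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData

from .qc import _dense

__all__ = [
    "GeneOverlap",
    "gene_overlap",
    "intron_fraction",
    "top_expressed_genes",
    "dropout_panel",
]


@dataclass(frozen=True)
class GeneOverlap:
    a_only: frozenset[str]
    b_only: frozenset[str]
    shared: frozenset[str]

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.a_only), len(self.b_only), len(self.shared))


def _detected_genes(
    adata: AnnData, threshold: float, mode: str, cell_fraction: float
) -> frozenset[str]:
    values = _dense(adata.X)
    if mode == "mean":
        hit = values.mean(axis=0) >= threshold
    elif mode == "cell_fraction":
        hit = (values >= threshold).mean(axis=0) >= cell_fraction
    else:
        raise ValueError(f"unknown detection mode: {mode!r}")
    return frozenset(adata.var_names[hit])


def gene_overlap(
    group_a: AnnData,
    group_b: AnnData,
    expr_threshold: float = 2.0,
    mode: str = "mean",
    cell_fraction: float = 0.05,
) -> GeneOverlap:
    """Venn-style detected-gene comparison between two groups.

    Default detection rule: group-mean log2(CPM+1) >= ``expr_threshold``.
    ``mode="cell_fraction"`` instead calls a gene detected when at least
    ``cell_fraction`` of the group's cells reach the threshold.
    """
    if set(group_a.var_names) != set(group_b.var_names):
        raise ValueError("gene universes differ between the two groups")
    det_a = _detected_genes(group_a, expr_threshold, mode, cell_fraction)
    det_b = _detected_genes(group_b, expr_threshold, mode, cell_fraction)
    return GeneOverlap(
        a_only=det_a - det_b, b_only=det_b - det_a, shared=det_a & det_b
    )


def intron_fraction(adata: AnnData) -> float:
    """Fraction of the group's total reads that are intronic."""
    if "exon" not in adata.layers or "intron" not in adata.layers:
        raise ValueError("intron_fraction requires exon and intron layers")
    intron = float(_dense(adata.layers["intron"]).sum())
    exon = float(_dense(adata.layers["exon"]).sum())
    total = exon + intron
    if total == 0:
        raise ValueError("group has zero total reads")
    return intron / total


def top_expressed_genes(adata: AnnData, n: int = 20) -> pd.DataFrame:
    """Genes ranked by percentage of the group's summed raw counts.

    Library-composition statistic, so raw counts, not CPM.  Ties are broken
    by gene identifier.
    """
    layer = adata.layers["counts"] if "counts" in adata.layers else adata.X
    counts = _dense(layer).astype(np.float64)
    per_gene = counts.sum(axis=0)
    total = per_gene.sum()
    pct = 100.0 * per_gene / total if total > 0 else np.zeros_like(per_gene)
    df = pd.DataFrame({"gene": adata.var_names, "pct_of_reads": pct})
    df = df.sort_values(
        ["pct_of_reads", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df.head(n)


def dropout_panel(
    group_a: AnnData, group_b: AnnData, panel_genes: list[str]
) -> pd.DataFrame:
    """Per-gene mean value and detection rate in each group, with the
    detection-rate difference (A - B).  Missing panel genes are reported
    with NaN rows, not fatal."""
    rows = []
    va, vb = _dense(group_a.X), _dense(group_b.X)
    for g in panel_genes:
        row: dict[str, float | str] = {"gene": g}
        for tag, adata, vals in (("a", group_a, va), ("b", group_b, vb)):
            if g in adata.var_names:
                col = vals[:, adata.var_names.get_loc(g)]
                row[f"mean_{tag}"] = float(col.mean())
                row[f"detection_rate_{tag}"] = float((col > 0).mean())
            else:
                # absent gene: undetectable in this group, rate 0 by definition
                row[f"mean_{tag}"] = np.nan
                row[f"detection_rate_{tag}"] = 0.0
        row["rate_difference"] = row["detection_rate_a"] - row["detection_rate_b"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")
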