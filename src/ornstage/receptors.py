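"""Receptor binarization and co-expression statistics.

Sensory receptors (Or/Ir/Gr families) are type-identifying markers: a
receptor is "on" in a cell at log2(CPM+1) >= 3, and "expressed" in a dataset
when on in strictly more than five cells.  Broadly expressed co-receptor
subunits (Orco, Ir8a, Ir25a, Ir76b) are excluded from per-cell receptor
counting unless requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from anndata import AnnData

from .params import AnalysisParams, DEFAULT_PARAMS, CO_RECEPTORS
from .qc import _dense

__all__ = [
    "ReceptorCalls",
    "call_receptors",
    "receptor_count_distribution",
    "ReceptorCountDistribution",
    "coexpression_pairs",
    "expressed_receptors",
    "coreceptor_coexpression",
    "receptor_correlation",
]


@dataclass
class ReceptorCalls:
    """Boolean cells x receptors on/off matrix under a stated threshold."""

    calls: pd.DataFrame
    threshold_used: float
    family_of_gene: pd.Series
    co_receptor: pd.Series
    excluded_co_receptors: bool

    @property
    def receptors(self) -> list[str]:
        return list(self.calls.columns)

    def per_cell_counts(self) -> pd.Series:
        """Number of receptors on per cell (co-receptors already excluded at
        call time if requested)."""
        return self.calls.sum(axis=1)


def _receptor_genes(adata: AnnData) -> list[str]:
    if "category" not in adata.var.columns:
        raise ValueError("gene metadata lacks a 'category' column")
    return list(adata.var_names[adata.var["category"] == "receptor"])


def call_receptors(
    adata: AnnData,
    receptor_genes: list[str] | None = None,
    threshold: float | None = None,
    exclude_co_receptors: bool = True,
    params: AnalysisParams = DEFAULT_PARAMS,
) -> ReceptorCalls:
    """Binarize receptor expression on a normalized matrix.

    ``calls[i, g]`` iff log2(CPM+1) of gene g in cell i >= threshold
    (inclusive).  With ``exclude_co_receptors`` the co-receptor genes are
    dropped from the call matrix entirely.
    """
    thr = params.receptor_threshold if threshold is None else threshold
    genes = _receptor_genes(adata) if receptor_genes is None else list(receptor_genes)
    if not genes:
        raise ValueError("empty receptor list")
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        raise ValueError(f"receptor genes absent from matrix: {missing}")
    co_flag = (
        adata.var["co_receptor"].reindex(genes).fillna(False).astype(bool)
        if "co_receptor" in adata.var.columns
        else pd.Series([g in CO_RECEPTORS for g in genes], index=genes)
    )
    if exclude_co_receptors:
        genes = [g for g in genes if not co_flag[g]]
        co_flag = co_flag.reindex(genes)
    idx = [adata.var_names.get_loc(g) for g in genes]
    values = _dense(adata.X)[:, idx]
    calls = pd.DataFrame(values >= thr, index=adata.obs_names, columns=genes)
    family = (
        adata.var["family"].reindex(genes).fillna("")
        if "family" in adata.var.columns
        else pd.Series("", index=genes)
    )
    return ReceptorCalls(
        calls=calls,
        threshold_used=thr,
        family_of_gene=family,
        co_receptor=co_flag,
        excluded_co_receptors=exclude_co_receptors,
    )


@dataclass(frozen=True)
class ReceptorCountDistribution:
    """Histogram of receptors-on per cell (bins 0, 1, 2, 3+)."""

    counts: dict[str, int]
    fraction_single_among_positive: float | None


def receptor_count_distribution(calls: ReceptorCalls) -> ReceptorCountDistribution:
    """Cells expressing zero, one, two, or three-plus receptors, plus the
    fraction of receptor-positive cells expressing exactly one."""
    per_cell = calls.per_cell_counts().to_numpy()
    counts = {
        "0": int((per_cell == 0).sum()),
        "1": int((per_cell == 1).sum()),
        "2": int((per_cell == 2).sum()),
        "3+": int((per_cell >= 3).sum()),
    }
    n_positive = int((per_cell >= 1).sum())
    fraction = counts["1"] / n_positive if n_positive else None
    return ReceptorCountDistribution(counts=counts, fraction_single_among_positive=fraction)


def coexpression_pairs(calls: ReceptorCalls) -> pd.DataFrame:
    """Unordered receptor pairs co-called in the same cell.

    Restricted to cells with >= 2 receptors on; a cell with three receptors
    contributes all three pairs (chord-diagram edge semantics).
    """
    mat = calls.calls.to_numpy()
    receptors = calls.receptors
    pair_counts: dict[tuple[str, str], int] = {}
    for row in mat[mat.sum(axis=1) >= 2]:
        on = [receptors[j] for j in np.flatnonzero(row)]
        for a, b in combinations(sorted(on), 2):
            pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
    df = pd.DataFrame(
        [(a, b, n) for (a, b), n in sorted(pair_counts.items())],
        columns=["receptor_a", "receptor_b", "n_cells"],
    )
    return df


def expressed_receptors(
    adata: AnnData,
    receptor_genes: list[str] | None = None,
    threshold: float | None = None,
    min_cells: int | None = None,
    params: AnalysisParams = DEFAULT_PARAMS,
) -> frozenset[str]:
    """Receptors "expressed" in the dataset: on in strictly more than
    ``min_cells`` cells at the call threshold."""
    thr = params.receptor_threshold if threshold is None else threshold
    floor = params.receptor_min_cells if min_cells is None else min_cells
    calls = call_receptors(
        adata, receptor_genes=receptor_genes, threshold=thr,
        exclude_co_receptors=False, params=params,
    )
    n_on = calls.calls.sum(axis=0)
    return frozenset(n_on.index[n_on > floor])


def coreceptor_coexpression(
    adata: AnnData,
    co_receptors: tuple[str, ...] = CO_RECEPTORS,
    threshold: float | None = None,
    orco: str = "Orco",
    params: AnalysisParams = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """For each Ir co-receptor, the fraction of its positive cells that are
    also Orco-positive, at a stringent threshold (default log2(CPM+1) >= 5).
    """
    thr = params.high_threshold if threshold is None else threshold
    values = _dense(adata.X)
    if orco in adata.var_names:
        orco_pos = values[:, adata.var_names.get_loc(orco)] >= thr
    else:
        orco_pos = np.zeros(adata.n_obs, dtype=bool)
    rows = []
    for g in co_receptors:
        if g == orco:
            continue
        if g not in adata.var_names:
            rows.append({"co_receptor": g, "n_positive": 0, "n_also_orco": 0,
                         "fraction": np.nan})
            continue
        pos = values[:, adata.var_names.get_loc(g)] >= thr
        n_pos = int(pos.sum())
        n_both = int((pos & orco_pos).sum())
        rows.append(
            {
                "co_receptor": g,
                "n_positive": n_pos,
                "n_also_orco": n_both,
                "fraction": n_both / n_pos if n_pos else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("co_receptor")


def receptor_correlation(
    adata: AnnData, query_genes: list[str], anchor_genes: list[str]
) -> pd.DataFrame:
    """Pearson correlation of each (query, anchor) gene pair across cells.

    Pairs involving a zero-variance gene are reported as NaN.  Requires at
    least three cells.
    """
    if adata.n_obs < 3:
        raise ValueError("receptor correlation needs >= 3 cells")
    for g in list(query_genes) + list(anchor_genes):
        if g not in adata.var_names:
            raise ValueError(f"gene absent from matrix: {g}")
    values = _dense(adata.X)
    out = pd.DataFrame(index=list(query_genes), columns=list(anchor_genes), dtype=float)
    for q in query_genes:
        x = values[:, adata.var_names.get_loc(q)]
        for a in anchor_genes:
            y = values[:, adata.var_names.get_loc(a)]
            if x.std() == 0 or y.std() == 0:
                out.loc[q, a] = np.nan
            else:
                out.loc[q, a] = float(np.corrcoef(x, y)[0, 1])
    return out
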