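"""Count-layer merging, CPM normalization, and cell-quality filters.

The working convention throughout the package: an AnnData whose ``X`` holds
integer counts (cells x genes) is a *count* matrix; :func:`normalize`
returns a copy whose ``X`` holds log2(CPM+1) values with the original counts
preserved in ``layers["counts"]``.  Downstream stages state which form they
expect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from anndata import AnnData

from .params import (
    AnalysisParams,
    DEFAULT_PARAMS,
    AUDITORY_GENES,
    ORN_IDENTITY_GENE,
)

__all__ = [
    "merge_layers",
    "normalize",
    "filter_cells",
    "remove_off_target_cells",
    "detection_stats",
]


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense() if hasattr(x, "todense") else x)


def merge_layers(adata: AnnData, include_intron: str = "nucleus") -> AnnData:
    """Build the working count matrix from exon/intron layers.

    Nuclear transcriptomes are quantified over exons plus introns; whole-cell
    ones over exons only.  ``include_intron`` is one of ``"nucleus"``
    (default: add introns for nucleus cells only), ``"all"`` or ``"none"``.
    The per-cell merge decision is recorded in ``obs["intron_merged"]``.
    """
    if "exon" not in adata.layers:
        raise ValueError("merge_layers requires an 'exon' layer")
    if include_intron not in {"nucleus", "all", "none"}:
        raise ValueError(f"unknown include_intron policy: {include_intron!r}")
    exon = _dense(adata.layers["exon"])
    out = adata.copy()
    if "intron" in adata.layers:
        intron = _dense(adata.layers["intron"])
        if intron.shape != exon.shape:
            raise ValueError("exon and intron layer shapes differ")
        if include_intron == "all":
            merged_mask = np.ones(adata.n_obs, dtype=bool)
        elif include_intron == "nucleus":
            merged_mask = (adata.obs["modality"] == "nucleus").to_numpy()
        else:
            merged_mask = np.zeros(adata.n_obs, dtype=bool)
        X = exon.copy()
        X[merged_mask] += intron[merged_mask]
    else:
        X = exon.copy()
        merged_mask = np.zeros(adata.n_obs, dtype=bool)
    out.X = X
    out.obs["intron_merged"] = merged_mask
    return out


def normalize(adata: AnnData) -> AnnData:
    """log2(CPM+1) per gene per cell.

    CPM_g = 1e6 * count_g / total; zeros map to zero, so sparsity is
    preserved.  A zero-total cell is an upstream error and raises with the
    offending cell names rather than being dropped silently.
    """
    counts = _dense(adata.X).astype(np.float64)
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        names = list(adata.obs_names[zero][:5])
        raise ValueError(
            f"{int(zero.sum())} cell(s) with zero total counts, e.g. {names}; "
            "filter before normalizing"
        )
    cpm = counts * (1e6 / totals[:, None])
    out = adata.copy()
    out.layers["counts"] = _dense(adata.X).copy()
    out.X = np.log2(cpm + 1.0)
    return out


def filter_cells(
    adata: AnnData, params: AnalysisParams = DEFAULT_PARAMS
) -> tuple[AnnData, pd.DataFrame]:
    """Depth + neuronal-marker quality filter.

    A cell is retained iff its total (working) counts are >= ``min_reads``
    AND at least ``min_markers`` of the marker genes are at
    log2(CPM+1) >= ``marker_threshold`` (both comparisons inclusive).
    Returns the filtered count matrix and a per-cell report with each rule's
    verdict.
    """
    missing = [g for g in params.marker_genes if g not in adata.var_names]
    if missing:
        raise ValueError(f"marker genes absent from the matrix: {missing}")
    counts = _dense(adata.X).astype(np.float64)
    totals = counts.sum(axis=1)
    marker_idx = [adata.var_names.get_loc(g) for g in params.marker_genes]
    # normalized marker values; zero-total cells fail the depth rule anyway
    safe_totals = np.where(totals > 0, totals, 1.0)
    marker_vals = np.log2(counts[:, marker_idx] * (1e6 / safe_totals[:, None]) + 1.0)
    n_markers = (marker_vals >= params.marker_threshold).sum(axis=1)
    pass_depth = totals >= params.min_reads
    pass_markers = n_markers >= params.min_markers
    retained = pass_depth & pass_markers
    report = pd.DataFrame(
        {
            "total_reads": totals.astype(np.int64),
            "n_markers": n_markers,
            "pass_depth": pass_depth,
            "pass_markers": pass_markers,
            "retained": retained,
        },
        index=adata.obs_names,
    )
    return adata[retained].copy(), report


def remove_off_target_cells(
    adata: AnnData,
    auditory_genes: tuple[str, ...] = AUDITORY_GENES,
    identity_gene: str = ORN_IDENTITY_GENE,
    threshold: float | None = None,
    identity_stages: tuple[str, ...] = ("24hAPF", "adult"),
    params: AnalysisParams = DEFAULT_PARAMS,
) -> tuple[AnnData, pd.DataFrame]:
    """Drop auditory neurons and identity-gene-negative cells.

    Operates on a *normalized* matrix.  A cell expressing any auditory gene
    at >= threshold is removed; at stages listed in ``identity_stages`` a
    cell with the identity gene below threshold is removed.  Genes absent
    from the matrix are tolerated (that rule simply cannot fire) and listed
    in the report attrs.
    """
    thr = params.marker_threshold if threshold is None else threshold
    values = _dense(adata.X)
    present_aud = [g for g in auditory_genes if g in adata.var_names]
    missing = [g for g in auditory_genes if g not in adata.var_names]
    if present_aud:
        aud_idx = [adata.var_names.get_loc(g) for g in present_aud]
        auditory_hit = (values[:, aud_idx] >= thr).any(axis=1)
    else:
        auditory_hit = np.zeros(adata.n_obs, dtype=bool)
    if identity_gene in adata.var_names:
        ident = values[:, adata.var_names.get_loc(identity_gene)]
        in_scope = adata.obs["stage"].isin(identity_stages).to_numpy()
        identity_fail = in_scope & (ident < thr)
    else:
        missing.append(identity_gene)
        identity_fail = np.zeros(adata.n_obs, dtype=bool)
    removed = auditory_hit | identity_fail
    report = pd.DataFrame(
        {
            "auditory_hit": auditory_hit,
            "identity_fail": identity_fail,
            "removed": removed,
        },
        index=adata.obs_names,
    )
    report.attrs["missing_genes"] = missing
    return adata[~removed].copy(), report


def detection_stats(adata: AnnData) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell (total counts, genes detected) and per-gene (mean normalized
    value, detection rate) tables from a normalized matrix."""
    values = _dense(adata.X)
    counts = _dense(adata.layers["counts"]) if "counts" in adata.layers else None
    detected = values > 0
    cell_df = pd.DataFrame(
        {
            "genes_detected": detected.sum(axis=1),
        },
        index=adata.obs_names,
    )
    if counts is not None:
        cell_df.insert(0, "total_reads", counts.sum(axis=1).astype(np.int64))
    gene_df = pd.DataFrame(
        {
            "mean_value": values.mean(axis=0),
            "detection_rate": detected.mean(axis=0),
        },
        index=adata.var_names,
    )
    return cell_df, gene_df
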