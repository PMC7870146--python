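"""Cluster-vs-rest and two-group differential expression.

The workhorse is the Mann-Whitney U test on log2(CPM+1) values.  Per-cluster
enrichment tests are one-sided (cluster > rest) by default — markers are
genes *highly* expressed in a cluster — with Benjamini-Hochberg adjustment
across genes within each cluster's test series.  Two-group comparisons used
to hand gene lists to external enrichment tools are two-sided with
Bonferroni adjustment and a fold-change pseudocount of 0.1.

Tie handling: mid-ranks with the normal approximation (tie-corrected, with
continuity correction) when either group exceeds eight observations;
exhaustive permutation enumeration otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .qc import _dense

__all__ = [
    "DEResult",
    "mann_whitney",
    "mann_whitney_cluster_vs_rest",
    "mann_whitney_two_group",
    "build_feature_set",
    "category_fractions",
]

_EXACT_MAX_N = 8


def mann_whitney(
    x: np.ndarray, y: np.ndarray, alternative: str = "greater"
) -> tuple[float, float]:
    """U statistic of ``x`` and its p-value for a single gene.

    Uses exhaustive permutation enumeration (handles ties exactly) when both
    groups have at most eight observations, the tie-corrected normal
    approximation with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) <= _EXACT_MAX_N and len(y) <= _EXACT_MAX_N:
        u = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic").statistic
        if np.ptp(np.concatenate([x, y])) == 0:
            return float(u), 1.0

        def _u_stat(a, b):
            return stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic"
            ).statistic

        res = stats.permutation_test(
            (x, y),
            _u_stat,
            permutation_type="independent",
            alternative=alternative,
            n_resamples=np.inf,
        )
        return float(u), float(res.pvalue)
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclass
class DEResult:
    """Differential-expression output.

    ``table`` has one row per (cluster, gene) with the U statistic, raw and
    BH-adjusted p-values, and group means; ``de_sets`` maps each cluster to
    its DE gene set (adjusted p < alpha).
    """

    table: pd.DataFrame
    de_sets: dict[str, frozenset[str]]
    alpha: float


def _vectorized_mw(
    values: np.ndarray, mask: np.ndarray, alternative: str
) -> tuple[np.ndarray, np.ndarray]:
    """U and p per gene for mask vs rest, tie-corrected asymptotic."""
    x = values[mask]
    y = values[~mask]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic", axis=0)
    u = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # genes constant across both groups carry no evidence: p = 1
    constant = values.max(axis=0) == values.min(axis=0)
    p = np.where(constant | ~np.isfinite(p), 1.0, p)
    return u, p


def mann_whitney_cluster_vs_rest(
    adata: AnnData,
    labels: pd.Series | np.ndarray,
    de_alpha: float = 0.01,
    alternative: str = "greater",
) -> DEResult:
    """One-vs-rest DE genes for every cluster.

    For each cluster, every gene is tested cluster-vs-rest; BH adjustment is
    applied across genes within that cluster's series; a gene is DE for the
    cluster iff adjusted p < ``de_alpha``.  Clusters with fewer than two
    cells are skipped with a warning.  Unassigned cells (label < 0 or NaN)
    are excluded entirely.
    """
    labels = pd.Series(np.asarray(labels), index=adata.obs_names)
    valid = labels.notna()
    numeric = pd.to_numeric(labels, errors="coerce")
    if numeric.notna().all():
        valid &= numeric >= 0
    labels = labels[valid]
    clusters = sorted(labels.unique(), key=str)
    if len(clusters) < 2:
        raise ValueError("cluster-vs-rest DE needs at least two clusters")
    values = _dense(adata[valid.to_numpy()].X).astype(float)
    frames = []
    de_sets: dict[str, frozenset[str]] = {}
    genes = np.asarray(adata.var_names)
    for c in clusters:
        mask = (labels == c).to_numpy()
        if mask.sum() < 2:
            warnings.warn(f"cluster {c!r} has fewer than 2 cells; skipped")
            de_sets[str(c)] = frozenset()
            continue
        u, p = _vectorized_mw(values, mask, alternative)
        p_adj = multipletests(p, method="fdr_bh")[1]
        mean_in = values[mask].mean(axis=0)
        mean_rest = values[~mask].mean(axis=0)
        frames.append(
            pd.DataFrame(
                {
                    "cluster": str(c),
                    "gene": genes,
                    "U": u,
                    "p": p,
                    "p_adj": p_adj,
                    "mean_in": mean_in,
                    "mean_rest": mean_rest,
                }
            )
        )
        de_sets[str(c)] = frozenset(genes[p_adj < de_alpha])
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["cluster", "gene", "U", "p", "p_adj", "mean_in", "mean_rest"])
    )
    return DEResult(table=table, de_sets=de_sets, alpha=de_alpha)


def mann_whitney_two_group(
    group_a: AnnData,
    group_b: AnnData,
    bonferroni_p: float = 1e-5,
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Two-sided two-group DE list for enrichment hand-off.

    Returns genes with Bonferroni-adjusted p <= ``bonferroni_p``, ranked by
    fold change log2((mean_A + 0.1) / (mean_B + 0.1)) in descending order.
    """
    if list(group_a.var_names) != list(group_b.var_names):
        raise ValueError("two-group DE requires identical gene universes")
    if group_a.n_obs < 2 or group_b.n_obs < 2:
        raise ValueError("both groups need at least 2 cells")
    va = _dense(group_a.X).astype(float)
    vb = _dense(group_b.X).astype(float)
    small = va.shape[0] <= _EXACT_MAX_N and vb.shape[0] <= _EXACT_MAX_N
    genes = np.asarray(group_a.var_names)
    if small:
        u = np.empty(len(genes))
        p = np.empty(len(genes))
        for j in range(len(genes)):
            u[j], p[j] = mann_whitney(va[:, j], vb[:, j], alternative="two-sided")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.mannwhitneyu(
                va, vb, alternative="two-sided", method="asymptotic", axis=0
            )
        u = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
        both = np.vstack([va, vb])
        constant = both.max(axis=0) == both.min(axis=0)
        p = np.where(constant | ~np.isfinite(p), 1.0, p)
    p_bonf = np.minimum(p * len(genes), 1.0)
    lfc = np.log2((va.mean(axis=0) + pseudocount) / (vb.mean(axis=0) + pseudocount))
    df = pd.DataFrame(
        {"gene": genes, "U": u, "p": p, "p_bonf": p_bonf, "log2_fold": lfc}
    )
    df = df[df["p_bonf"] <= bonferroni_p]
    return df.sort_values(
        ["log2_fold", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def build_feature_set(
    de_sets,
    receptor_genes,
    universe=None,
) -> list[str]:
    """Union of reference DE sets and the receptor list, de-duplicated and
    restricted to genes present in the matrix; the gene set used for
    dimensionality reduction at every stage."""
    if hasattr(de_sets, "values"):
        iterable = list(de_sets.values())
    elif isinstance(de_sets, (set, frozenset)):
        iterable = [de_sets]
    else:
        iterable = list(de_sets)
    union: set[str] = set()
    for s in iterable:
        union |= set(s)
    union |= set(receptor_genes)
    if universe is not None:
        union &= set(universe)
    if not union:
        raise ValueError("feature set is empty")
    return sorted(union)


def category_fractions(
    gene_list,
    gene_meta: pd.DataFrame,
    categories: tuple[str, ...] = ("TF", "CSM"),
) -> pd.DataFrame:
    """Fraction of each gene category in a list vs the genome-wide fraction.

    Genes absent from the annotation count as "other".
    """
    gene_list = list(gene_list)
    cat = gene_meta["category"]
    list_cats = [cat.get(g, "other") for g in gene_list]
    rows = []
    for c in categories:
        n = sum(1 for x in list_cats if x == c)
        rows.append(
            {
                "category": c,
                "count_in_list": n,
                "fraction_in_list": n / len(gene_list) if gene_list else np.nan,
                "genome_fraction": float((cat == c).mean()),
            }
        )
    return pd.DataFrame(rows).set_index("category")
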