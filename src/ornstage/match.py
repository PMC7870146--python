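"""Cluster annotation and cross-stage matching.

Two complementary strategies link transcriptomic clusters to neuron types
and to each other across developmental stages:

* **Manual (marker-based)**: a receptor or marker-gene rule that fires in
  exactly one cluster assigns that cluster its glomerular type.
* **Automatic (Jaccard)**: per-cluster DE gene sets from two stages are
  compared by Jaccard similarity J(X, Y) = |X n Y| / |X u Y|; a mutual best
  hit is a *two-way* match, a best hit in one direction only is a *one-way*
  match.  One-way matches are only trusted between stages profiled with the
  same technology (pupal-pupal), never between pupal and adult.

Cluster-level transcriptome similarity (Pearson over a DE gene set) and
average-linkage dendrograms on mean cluster profiles round out the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .qc import _dense
from .receptors import ReceptorCalls

__all__ = [
    "ClusterProfiles",
    "cluster_profiles",
    "AnnotationRule",
    "annotate_by_receptor",
    "annotate_by_rules",
    "jaccard",
    "jaccard_matrix",
    "Match",
    "MatchResult",
    "match_clusters",
    "default_one_way_policy",
    "pearson_cluster_similarity",
    "dendrogram",
]


@dataclass
class ClusterProfiles:
    """Mean log2(CPM+1) per gene for each cluster ("taking the average
    across all cells within that cluster")."""

    means: pd.DataFrame  # genes x clusters
    n_cells: pd.Series
    stage: str | None = None

    @property
    def clusters(self) -> list[str]:
        return list(self.means.columns)


def cluster_profiles(
    adata: AnnData, labels: pd.Series | np.ndarray, stage: str | None = None
) -> ClusterProfiles:
    """Average a normalized matrix within each cluster; unassigned cells
    (label < 0) are ignored."""
    labels = pd.Series(np.asarray(labels), index=adata.obs_names)
    values = _dense(adata.X).astype(float)
    cols = {}
    n_cells = {}
    for c in sorted(labels.dropna().unique(), key=str):
        try:
            if float(c) < 0:  # noise label from density clustering
                continue
        except (TypeError, ValueError):
            pass
        mask = (labels == c).to_numpy()
        cols[str(c)] = values[mask].mean(axis=0)
        n_cells[str(c)] = int(mask.sum())
    if not cols:
        raise ValueError("no assigned cells to profile")
    return ClusterProfiles(
        means=pd.DataFrame(cols, index=adata.var_names),
        n_cells=pd.Series(n_cells),
        stage=stage,
    )


# ---------------------------------------------------------------------------
# manual annotation


@dataclass(frozen=True)
class AnnotationRule:
    """Marker rule: all required genes at/above their thresholds, all
    forbidden genes below, in exactly one cluster."""

    label: str
    required: tuple[tuple[str, float], ...]
    forbidden: tuple[tuple[str, float], ...] = ()
    stages: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.required:
            raise ValueError("an annotation rule needs at least one required gene")


def annotate_by_receptor(
    assignment: pd.Series | np.ndarray,
    calls: ReceptorCalls,
    receptor_to_type: Mapping[str, str],
    min_cells: int = 5,
    majority: float = 0.5,
) -> dict[str, str]:
    """Label clusters by cluster-specific receptor expression.

    A receptor is cluster-specific when strictly more than ``majority`` of
    its positive cells fall in one cluster AND it is expressed there
    (strictly more than ``min_cells`` positive cells in-cluster).  Clusters
    hosting receptors of several distinct types get compound labels joined
    by underscores; clusters without a specific receptor are absent from the
    result and keep their numeric ids.
    """
    if not receptor_to_type:
        raise ValueError("empty receptor-to-type map")
    labels = pd.Series(np.asarray(assignment), index=calls.calls.index)
    types_of_cluster: dict[str, set[str]] = {}
    for r in calls.receptors:
        if r not in receptor_to_type:
            continue
        positive = calls.calls[r]
        n_positive = int(positive.sum())
        if n_positive == 0:
            continue
        in_clusters = labels[positive.to_numpy()]
        in_clusters = in_clusters[
            pd.to_numeric(in_clusters, errors="coerce").fillna(0) >= 0
        ]
        if in_clusters.empty:
            continue
        counts = in_clusters.value_counts()
        top_cluster, top_count = str(counts.index[0]), int(counts.iloc[0])
        if top_count > min_cells and top_count / n_positive > majority:
            types_of_cluster.setdefault(top_cluster, set()).add(
                receptor_to_type[r]
            )
    return {
        c: "_".join(sorted(ts)) for c, ts in sorted(types_of_cluster.items())
    }


def annotate_by_rules(
    profiles: ClusterProfiles, rules: Iterable[AnnotationRule]
) -> tuple[dict[str, str], dict[str, list[str]]]:
    """Apply marker rules to cluster profiles.

    A rule firing in exactly one cluster assigns its label; rules firing in
    several clusters are reported as ambiguous and assign nothing.  Rules
    naming genes absent from the profiles are skipped with a warning.
    """
    labels: dict[str, str] = {}
    ambiguous: dict[str, list[str]] = {}
    genes = set(profiles.means.index)
    for rule in rules:
        named = [g for g, _ in rule.required] + [g for g, _ in rule.forbidden]
        missing = [g for g in named if g not in genes]
        if missing:
            warnings.warn(
                f"rule {rule.label!r} names absent genes {missing}; skipped"
            )
            continue
        if rule.stages is not None and profiles.stage is not None:
            if profiles.stage not in rule.stages:
                continue
        fired = []
        for c in profiles.clusters:
            prof = profiles.means[c]
            ok = all(prof[g] >= thr for g, thr in rule.required) and all(
                prof[g] < thr for g, thr in rule.forbidden
            )
            if ok:
                fired.append(c)
        if len(fired) == 1:
            labels[fired[0]] = rule.label
        elif len(fired) > 1:
            ambiguous[rule.label] = fired
    return labels, ambiguous


# ---------------------------------------------------------------------------
# automatic (Jaccard) matching


def jaccard(x: Iterable, y: Iterable) -> float:
    """Jaccard similarity |X n Y| / |X u Y|; 0 for two empty sets."""
    x, y = set(x), set(y)
    union = x | y
    if not union:
        warnings.warn("Jaccard of two empty sets defined as 0")
        return 0.0
    return len(x & y) / len(union)


def jaccard_matrix(
    sets_a: Mapping[str, Iterable], sets_b: Mapping[str, Iterable]
) -> pd.DataFrame:
    """All-pairs Jaccard similarity between two families of gene sets."""
    rows = {}
    b_items = {k: set(v) for k, v in sets_b.items()}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ka, va in sets_a.items():
            rows[ka] = {kb: jaccard(va, vb) for kb, vb in b_items.items()}
    return pd.DataFrame.from_dict(rows, orient="index").loc[
        list(sets_a.keys()), list(sets_b.keys())
    ]


@dataclass(frozen=True)
class Match:
    cluster_a: str
    cluster_b: str
    score: float
    kind: str  # two_way | one_way | manual


@dataclass
class MatchResult:
    """Cross-stage match table plus argmax ties that blocked a match."""

    matches: list[Match]
    ties: list[str] = field(default_factory=list)
    unmatched: list[str] = field(default_factory=list)
    allow_one_way: bool = True

    @property
    def two_way(self) -> dict[str, str]:
        return {m.cluster_a: m.cluster_b for m in self.matches if m.kind == "two_way"}

    @property
    def one_way(self) -> dict[str, str]:
        return {m.cluster_a: m.cluster_b for m in self.matches if m.kind == "one_way"}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m.cluster_a, m.cluster_b, m.score, m.kind) for m in self.matches],
            columns=["cluster_a", "cluster_b", "jaccard", "class"],
        )


def default_one_way_policy(stage_a: str, stage_b: str) -> bool:
    """One-way matches are allowed between same-technology (pupal) stages
    and forbidden between pupal and adult."""
    pupal_a = "APF" in stage_a
    pupal_b = "APF" in stage_b
    return pupal_a == pupal_b


def _argmax_unique(row: pd.Series) -> str | None:
    """Index of the strict maximum, or None on ties."""
    top = row.max()
    winners = row.index[row == top]
    return str(winners[0]) if len(winners) == 1 else None


def match_clusters(
    similarity: pd.DataFrame, allow_one_way: bool = True
) -> MatchResult:
    """Mutual-best-hit matching over a similarity matrix.

    For each row cluster X the argmax column Y is computed and vice versa;
    mutual argmax pairs are two-way matches.  A non-mutual row argmax is a
    one-way match, reported only when the policy allows.  Argmax ties are
    never broken silently: the tied cluster is reported in ``ties`` and left
    unmatched.  A cluster whose row is all zero is unmatched (no evidence).
    """
    if similarity.empty:
        raise ValueError("empty similarity matrix")
    if not np.all(np.isfinite(similarity.to_numpy())):
        raise ValueError("similarity matrix contains non-finite values")
    best_of_a: dict[str, str | None] = {}
    ties: list[str] = []
    unmatched: list[str] = []
    for a in similarity.index:
        row = similarity.loc[a]
        if (row == 0).all():
            best_of_a[str(a)] = None
            unmatched.append(str(a))
            continue
        best = _argmax_unique(row)
        if best is None:
            ties.append(str(a))
        best_of_a[str(a)] = best
    best_of_b: dict[str, str | None] = {}
    for b in similarity.columns:
        col = similarity[b]
        if (col == 0).all():
            best_of_b[str(b)] = None
            continue
        best = _argmax_unique(col)
        if best is None and str(b) not in ties:
            ties.append(str(b))
        best_of_b[str(b)] = best
    matches: list[Match] = []
    for a, b in best_of_a.items():
        if b is None:
            continue
        score = float(similarity.loc[a, b])
        if best_of_b.get(b) == a:
            matches.append(Match(a, b, score, "two_way"))
        elif allow_one_way:
            matches.append(Match(a, b, score, "one_way"))
    for a in similarity.index:
        a = str(a)
        if a not in ties and a not in unmatched:
            if not any(m.cluster_a == a for m in matches):
                unmatched.append(a)
    return MatchResult(
        matches=matches, ties=ties, unmatched=unmatched, allow_one_way=allow_one_way
    )


# ---------------------------------------------------------------------------
# cluster-level similarity and dendrograms


def pearson_cluster_similarity(
    profiles_a: ClusterProfiles,
    profiles_b: ClusterProfiles,
    genes: Iterable[str],
) -> pd.DataFrame:
    """Pearson correlation between cluster mean profiles over a gene set.

    Zero-variance profiles yield NaN entries (flagged with a warning).
    """
    genes = list(genes)
    for p in (profiles_a, profiles_b):
        missing = [g for g in genes if g not in p.means.index]
        if missing:
            raise ValueError(f"genes absent from profiles: {missing[:5]}")
    A = profiles_a.means.loc[genes]
    B = profiles_b.means.loc[genes]
    out = pd.DataFrame(
        index=profiles_a.clusters, columns=profiles_b.clusters, dtype=float
    )
    degenerate = []
    for ca in profiles_a.clusters:
        x = A[ca].to_numpy()
        for cb in profiles_b.clusters:
            y = B[cb].to_numpy()
            if x.std() == 0 or y.std() == 0:
                out.loc[ca, cb] = np.nan
                degenerate.append((ca, cb))
            else:
                out.loc[ca, cb] = float(np.corrcoef(x, y)[0, 1])
    if degenerate:
        warnings.warn(f"{len(degenerate)} zero-variance profile pairs set to NaN")
    return out


def dendrogram(
    profiles: ClusterProfiles,
    genes: Iterable[str] | None = None,
    method: str = "average",
) -> tuple[str, np.ndarray]:
    """Agglomerative tree over cluster mean profiles.

    Average linkage on Euclidean distances between mean profiles restricted
    to the DE gene set; returns (newick string, scipy linkage matrix) with
    cluster labels as tips.
    """
    if len(profiles.clusters) < 2:
        raise ValueError("need at least two profiles for a dendrogram")
    mat = profiles.means if genes is None else profiles.means.loc[list(genes)]
    X = mat.T.to_numpy()
    Z = linkage(pdist(X, metric="euclidean"), method=method)
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(Z, profiles.clusters)
    newick = str(tree).strip()
    return newick, Z
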