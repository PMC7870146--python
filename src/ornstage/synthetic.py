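"""Synthetic antennal sensory-neuron count data with planted ground truth.

The generator emulates plate-based SMART-seq2 transcriptomes of *Drosophila*
olfactory receptor neuron (ORN) types profiled at several developmental
stages: each neuron type expresses one (rarely 2-3) type-specific receptor
genes, carries a core of type-specific differentially expressed (DE) genes
that persists across stages plus stage-specific additions, and every cell is
sampled at its own sequencing depth with zero-inflated negative-binomial
noise.  Reads are split into exon and intron layers with modality-specific
expected intron fractions (nuclei retain far more intronic reads than whole
cells), ambient contaminant genes are added to nucleus transcriptomes, and a
small fraction of doublets (two transcriptomes summed) can be injected.

The planted :class:`GroundTruth` (per-cell type, per-type receptor code and
DE gene sets, cross-stage type correspondence, doublet flags) makes every
downstream stage of the pipeline testable by parameter recovery without any
external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

from .params import NEURONAL_MARKERS, AUDITORY_GENES, ORN_IDENTITY_GENE, CO_RECEPTORS

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "TypePrograms",
    "InfeasibleConfigError",
    "generate_type_programs",
    "simulate_counts",
    "inject_doublets",
    "simulate",
    "write_dataset",
    "read_dataset",
]


class InfeasibleConfigError(ValueError):
    """Raised when a configuration demands more genes than exist."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic-data generator.

    Defaults describe a desk-scale version of the study conditions: three
    stages (two pupal cell stages, one adult nucleus stage) sharing the same
    neuron types, ~1M-read depth ceiling, plate-style metadata.

    Attributes
    ----------
    n_types:
        Number of neuron types shared by all stages.
    stages:
        Ordered stage labels; ``nucleus_stages`` marks which of them were
        profiled as nuclei (the rest are whole cells).
    cells_per_type_per_stage:
        Cells sampled per type at each stage.
    n_genes:
        Total gene universe (special genes + receptors + background).
    n_receptor_genes:
        Size of the receptor pool; must allow disjoint codes for all types.
    n_de_genes_per_type:
        Type-specific DE genes planted per type (core + stage-specific).
    de_turnover:
        Fraction of each type's DE genes that are stage-specific rather than
        part of the cross-stage core.
    multi_receptor_fraction:
        Fraction of types assigned 2-3 receptors instead of one.
    linked_pair:
        Plant one two-receptor type even when ``multi_receptor_fraction`` is
        zero (mimics genomically linked receptor pairs such as Or85b/Or85c).
    de_log_fold:
        Mean log2 fold elevation of a type's DE genes over the baseline
        mean scale.  Type-specific genes behave like real markers: in their
        type they sit at ``baseline_mean * 2**de_log_fold``, elsewhere at the
        near-silent ``baseline_mean * de_off_scale``.
    de_off_scale:
        Out-of-type relative level of planted DE genes (fraction of
        ``baseline_mean``).
    receptor_log_fold:
        log2 fold elevation of a type's receptor-code genes over the
        baseline mean scale (receptors are highly expressed when on, silent
        otherwise).
    baseline_mean:
        Mean relative-expression scale of background genes.
    dispersion:
        Negative-binomial shape (inverse dispersion); variance is
        mu + mu**2 / dispersion.
    depth_range:
        (min, max) of the per-cell total-read target, drawn uniformly.
    dropout_rate:
        Per-entry zero-inflation probability.
    intron_fraction_cell, intron_fraction_nucleus:
        Expected fraction of a gene's reads assigned to the intron layer for
        cells and nuclei respectively.
    doublet_rate:
        Fraction of cells replaced by the sum of two transcriptomes.
    contaminant_genes:
        (gene, per-cell ambient Poisson scale) pairs added to nucleus
        transcriptomes; names beginning ``mt:`` are flagged mitochondrial.
    off_target_cells_per_stage:
        Auditory-like (acj6-negative, auditory-marker-positive) cells
        appended per stage, for exercising the identity filters.
    """

    n_types: int = 20
    stages: tuple[str, ...] = ("24hAPF", "42hAPF", "adult")
    nucleus_stages: tuple[str, ...] = ("adult",)
    cells_per_type_per_stage: int = 30
    n_genes: int = 2000
    n_receptor_genes: int = 30
    n_de_genes_per_type: int = 50
    de_turnover: float = 0.2
    multi_receptor_fraction: float = 0.15
    linked_pair: bool = False
    de_log_fold: float = 2.0
    de_off_scale: float = 0.05
    receptor_log_fold: float = 7.0
    baseline_mean: float = 5.0
    dispersion: float = 2.0
    depth_range: tuple[float, float] = (100_000.0, 1_000_000.0)
    dropout_rate: float = 0.2
    intron_fraction_cell: float = 0.105
    intron_fraction_nucleus: float = 0.30
    doublet_rate: float = 0.02
    contaminant_genes: tuple[tuple[str, float], ...] = (
        ("Obp19a", 40.0),
        ("Obp83a", 40.0),
        ("mt:CoI", 30.0),
    )
    off_target_cells_per_stage: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("stages must be nonempty")
        fractions = {
            "de_turnover": self.de_turnover,
            "multi_receptor_fraction": self.multi_receptor_fraction,
            "dropout_rate": self.dropout_rate,
            "intron_fraction_cell": self.intron_fraction_cell,
            "intron_fraction_nucleus": self.intron_fraction_nucleus,
            "doublet_rate": self.doublet_rate,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_receptor_genes < self.n_types:
            raise ValueError(
                "n_receptor_genes must be >= n_types so every type can own "
                "a receptor code"
            )
        if self.depth_range[0] < 1:
            raise ValueError("depth_range minimum must be >= 1")
        if self.depth_range[0] > self.depth_range[1]:
            raise ValueError("depth_range must be (min, max) with min <= max")
        if self.n_types < 1 or self.n_genes < 1:
            raise ValueError("n_types and n_genes must be positive")

    def modality_of(self, stage: str) -> str:
        return "nucleus" if stage in self.nucleus_stages else "cell"

    def intron_fraction_of(self, stage: str) -> float:
        return (
            self.intron_fraction_nucleus
            if self.modality_of(stage) == "nucleus"
            else self.intron_fraction_cell
        )


@dataclass
class GroundTruth:
    """Planted truth accompanying a synthetic dataset.

    ``type_of_cell`` maps each cell to its neuron type ("off_target" for
    planted auditory-like cells); ``receptor_code`` gives each sensory type
    its receptor gene set; ``de_genes`` maps type -> stage -> planted DE gene
    set; ``stage_correspondence`` is the (identity) bijection linking a
    type's cluster across stages; ``doublet_flags`` marks injected doublets.
    """

    type_of_cell: pd.Series
    receptor_code: dict[str, tuple[str, ...]]
    de_genes: dict[str, dict[str, frozenset[str]]]
    stage_correspondence: dict[str, str]
    doublet_flags: pd.Series

    @property
    def receptor_to_type(self) -> dict[str, str]:
        """Invert receptor codes (codes are disjoint across types)."""
        out: dict[str, str] = {}
        for t, code in self.receptor_code.items():
            for r in code:
                out[r] = t
        return out

    def copy(self) -> "GroundTruth":
        return GroundTruth(
            type_of_cell=self.type_of_cell.copy(),
            receptor_code=dict(self.receptor_code),
            de_genes={t: dict(d) for t, d in self.de_genes.items()},
            stage_correspondence=dict(self.stage_correspondence),
            doublet_flags=self.doublet_flags.copy(),
        )


@dataclass
class TypePrograms:
    """Per-type, per-stage mean relative-expression programs.

    ``means[stage]`` is a genes x types DataFrame of nonnegative relative
    expression levels (normalized to per-cell depth at simulation time).
    """

    means: dict[str, pd.DataFrame]
    gene_meta: pd.DataFrame
    receptor_code: dict[str, tuple[str, ...]]
    de_genes: dict[str, dict[str, frozenset[str]]]
    stage_correspondence: dict[str, str]
    off_target_program: pd.Series
    config: SyntheticConfig


def _build_gene_table(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Lay out the gene universe: markers, identity gene, auditory genes,
    co-receptors, receptor pool, contaminants, then background fill."""
    rows: list[tuple[str, str, str, bool, bool]] = []
    for g in NEURONAL_MARKERS:
        rows.append((g, "neuronal_marker", "", False, False))
    rows.append((ORN_IDENTITY_GENE, "TF", "", False, False))
    for g in AUDITORY_GENES:
        rows.append((g, "auditory_marker", "", False, False))
    for g in CO_RECEPTORS:
        family = "Or" if g == "Orco" else "Ir"
        rows.append((g, "receptor", family, True, False))
    # receptor pool: mostly Ors, some Irs/Grs, mirroring antennal family sizes
    for i in range(config.n_receptor_genes):
        if i % 10 < 7:
            name, family = f"Or{i + 1}F", "Or"
        elif i % 10 < 9:
            name, family = f"Ir{i + 1}F", "Ir"
        else:
            name, family = f"Gr{i + 1}F", "Gr"
        rows.append((name, "receptor", family, False, False))
    for name, _scale in config.contaminant_genes:
        category = "mitochondrial" if name.startswith("mt:") else "other"
        rows.append((name, category, "", False, True))
    n_special = len(rows)
    n_background = config.n_genes - n_special
    if n_background < 0:
        raise InfeasibleConfigError(
            f"n_genes={config.n_genes} is smaller than the {n_special} "
            "special genes (markers, receptors, contaminants)"
        )
    # sprinkle TF/CSM annotations over the background at sub-genome-scale
    # rates so category-composition statistics have something to count
    cats = rng.choice(
        ["other", "TF", "CSM"], size=n_background, p=[0.90, 0.05, 0.05]
    )
    for i in range(n_background):
        rows.append((f"gene{i + 1:04d}", str(cats[i]), "", False, False))
    meta = pd.DataFrame(
        rows, columns=["gene", "category", "family", "co_receptor", "contaminant"]
    ).set_index("gene")
    if meta.index.duplicated().any():
        raise InfeasibleConfigError("duplicate gene identifiers in layout")
    return meta


def _assign_receptor_codes(
    config: SyntheticConfig, receptors: list[str], rng: np.random.Generator
) -> dict[str, tuple[str, ...]]:
    """Sample disjoint receptor codes; a configurable fraction of types gets
    2-3 receptors."""
    types = [f"T{i + 1:02d}" for i in range(config.n_types)]
    n_multi = int(round(config.multi_receptor_fraction * config.n_types))
    if config.linked_pair and n_multi == 0:
        n_multi = 1
    sizes = np.ones(config.n_types, dtype=int)
    multi_idx = rng.choice(config.n_types, size=n_multi, replace=False)
    for j, idx in enumerate(multi_idx):
        sizes[idx] = 2 if (j % 2 == 0) else 3
    if sizes.sum() > len(receptors):
        raise InfeasibleConfigError(
            f"receptor codes need {int(sizes.sum())} receptors but the pool "
            f"has only {len(receptors)}"
        )
    order = rng.permutation(len(receptors))
    pool = [receptors[i] for i in order]
    codes: dict[str, tuple[str, ...]] = {}
    pos = 0
    for t, size in zip(types, sizes):
        codes[t] = tuple(sorted(pool[pos : pos + size]))
        pos += size
    return codes


def generate_type_programs(config: SyntheticConfig) -> TypePrograms:
    """Construct per-type, per-stage mean-expression programs.

    Each type's DE genes are elevated ~``de_log_fold`` log2 units over their
    baseline; its receptor-code genes are expressed only in that type.  A
    core of DE genes is shared across stages, the remaining ``de_turnover``
    fraction is stage-specific, so cross-stage cluster matching has both
    signal and noise.

    Raises
    ------
    InfeasibleConfigError
        When the DE-gene demand exceeds the background gene pool.
    """
    rng = np.random.default_rng([config.seed, 0])
    gene_meta = _build_gene_table(config, rng)
    genes = gene_meta.index
    types = [f"T{i + 1:02d}" for i in range(config.n_types)]

    background = [g for g in genes if g.startswith("gene")]
    n_core = int(round((1.0 - config.de_turnover) * config.n_de_genes_per_type))
    n_stage_specific = config.n_de_genes_per_type - n_core
    demand = config.n_types * (n_core + n_stage_specific * len(config.stages))
    if demand > len(background):
        raise InfeasibleConfigError(
            f"configuration demands {demand} distinct DE genes but only "
            f"{len(background)} background genes are available "
            f"(n_genes={config.n_genes})"
        )

    codes = _assign_receptor_codes(
        config, [g for g in genes if gene_meta.loc[g, "category"] == "receptor"
                 and not gene_meta.loc[g, "co_receptor"]], rng
    )

    # baseline relative expression; broad genes sit well above baseline
    sigma = 0.5
    baseline = pd.Series(
        config.baseline_mean
        * np.exp(rng.normal(-(sigma**2) / 2, sigma, size=len(genes))),
        index=genes,
    )
    baseline[gene_meta["category"] == "receptor"] = 0.0
    baseline[gene_meta["category"] == "auditory_marker"] = 0.0
    baseline[gene_meta["contaminant"]] = 0.0
    baseline[list(NEURONAL_MARKERS)] = config.baseline_mean * 30.0
    baseline[ORN_IDENTITY_GENE] = config.baseline_mean * 20.0
    baseline[list(CO_RECEPTORS)] = config.baseline_mean * 2 ** (
        config.receptor_log_fold - 2.0
    )

    # disjoint DE gene assignment: per-type core + per-(type, stage) extras
    shuffled = [background[i] for i in rng.permutation(len(background))]
    pos = 0

    def take(k: int) -> list[str]:
        nonlocal pos
        out = shuffled[pos : pos + k]
        pos += k
        return out

    receptor_level = config.baseline_mean * 2**config.receptor_log_fold
    de_off_level = config.baseline_mean * config.de_off_scale
    de_genes: dict[str, dict[str, frozenset[str]]] = {}
    level_of: dict[tuple[str, str], float] = {}
    core_of: dict[str, list[str]] = {}
    for t in types:
        core_of[t] = take(n_core)
        de_genes[t] = {}
        for s in config.stages:
            extra = take(n_stage_specific)
            de_genes[t][s] = frozenset(core_of[t]) | frozenset(extra)
            for g in extra:
                level_of[(t, g)] = config.baseline_mean * 2 ** rng.normal(
                    config.de_log_fold, 0.25
                )
        for g in core_of[t]:
            level_of[(t, g)] = config.baseline_mean * 2 ** rng.normal(
                config.de_log_fold, 0.25
            )

    # planted DE genes are marker-like: near-silent outside their type,
    # elevated ~de_log_fold log2 units over the baseline scale within it
    all_de = sorted({g for t in types for s in config.stages for g in de_genes[t][s]})
    baseline[all_de] = de_off_level

    means: dict[str, pd.DataFrame] = {}
    for s in config.stages:
        mat = pd.DataFrame(
            np.tile(baseline.to_numpy()[:, None], (1, config.n_types)),
            index=genes,
            columns=types,
        )
        for t in types:
            for g in de_genes[t][s]:
                mat.loc[g, t] = level_of[(t, g)]
            for r in codes[t]:
                mat.loc[r, t] = receptor_level
        means[s] = mat

    off_target = baseline.copy()
    off_target[ORN_IDENTITY_GENE] = 0.0
    off_target[list(AUDITORY_GENES)] = config.baseline_mean * 2**5

    return TypePrograms(
        means=means,
        gene_meta=gene_meta,
        receptor_code=codes,
        de_genes=de_genes,
        stage_correspondence={t: t for t in types},
        off_target_program=off_target,
        config=config,
    )


def _sample_block(
    rng: np.random.Generator,
    program: np.ndarray,
    n_cells: int,
    config: SyntheticConfig,
) -> np.ndarray:
    """Zero-inflated NB counts for ``n_cells`` cells sharing one program."""
    depths = rng.uniform(*config.depth_range, size=n_cells)
    p = program / program.sum()
    mu = depths[:, None] * p[None, :]
    lam = rng.gamma(config.dispersion, mu / config.dispersion)
    counts = rng.poisson(lam)
    if config.dropout_rate > 0:
        keep = rng.random(counts.shape) >= config.dropout_rate
        counts = counts * keep
    return counts.astype(np.int64)


def simulate_counts(
    programs: TypePrograms, config: SyntheticConfig | None = None
) -> tuple[AnnData, GroundTruth]:
    """Draw a count matrix from type programs.

    Counts are negative-binomial with per-cell depth scaling and independent
    dropout, split per entry into exon and intron layers by a binomial with
    the modality-appropriate intron probability; ambient contaminant counts
    are added to nucleus transcriptomes (exonic).
    """
    config = programs.config if config is None else config
    rng = np.random.default_rng([config.seed, 1])
    gene_meta = programs.gene_meta
    genes = gene_meta.index
    types = list(programs.means[config.stages[0]].columns)
    contam_idx = np.where(gene_meta["contaminant"].to_numpy())[0]
    contam_scale = {name: scale for name, scale in config.contaminant_genes}

    blocks: list[np.ndarray] = []
    obs_rows: list[tuple[str, str, str, str, str]] = []
    cell_types: list[str] = []
    counter = 0
    for s in config.stages:
        modality = config.modality_of(s)
        driver = "elav-GAL4" if s == config.stages[0] else "nSyb-GAL4"
        stage_cell = 0
        mat = programs.means[s].to_numpy()
        for j, t in enumerate(types):
            counts = _sample_block(
                rng, mat[:, j], config.cells_per_type_per_stage, config
            )
            blocks.append(counts)
            for _ in range(config.cells_per_type_per_stage):
                plate = f"{s}-P{stage_cell // 384 + 1}"
                obs_rows.append((f"{s}_{counter:05d}", s, modality, plate, driver))
                cell_types.append(t)
                counter += 1
                stage_cell += 1
        if config.off_target_cells_per_stage:
            counts = _sample_block(
                rng,
                programs.off_target_program.to_numpy(),
                config.off_target_cells_per_stage,
                config,
            )
            blocks.append(counts)
            for _ in range(config.off_target_cells_per_stage):
                plate = f"{s}-P{stage_cell // 384 + 1}"
                obs_rows.append((f"{s}_{counter:05d}", s, modality, plate, driver))
                cell_types.append("off_target")
                counter += 1
                stage_cell += 1

    X = np.vstack(blocks)
    obs = pd.DataFrame(
        obs_rows, columns=["cell", "stage", "modality", "plate", "driver"]
    ).set_index("cell")

    # ambient contamination in nuclei only
    is_nucleus = (obs["modality"] == "nucleus").to_numpy()
    if contam_idx.size and is_nucleus.any():
        for idx in contam_idx:
            scale = contam_scale[genes[idx]]
            X[is_nucleus, idx] += rng.poisson(scale, size=int(is_nucleus.sum()))

    intron_p = np.array([config.intron_fraction_of(s) for s in obs["stage"]])
    intron = rng.binomial(X, intron_p[:, None])
    exon = X - intron

    adata = AnnData(
        X=X,
        obs=obs,
        var=gene_meta.copy(),
        layers={"exon": exon, "intron": intron.astype(np.int64)},
    )
    truth = GroundTruth(
        type_of_cell=pd.Series(cell_types, index=obs.index, name="type"),
        receptor_code=dict(programs.receptor_code),
        de_genes={t: dict(d) for t, d in programs.de_genes.items()},
        stage_correspondence=dict(programs.stage_correspondence),
        doublet_flags=pd.Series(False, index=obs.index, name="doublet"),
    )
    return adata, truth


def inject_doublets(
    adata: AnnData, truth: GroundTruth, rate: float, seed: int
) -> tuple[AnnData, GroundTruth]:
    """Replace ``floor(rate * n_cells)`` cells by the gene-wise sum of two
    randomly paired same-stage transcriptomes.

    The host cell keeps its identity in ``type_of_cell``; its doublet flag is
    set.  Layers are summed alongside the totals so exon + intron
    conservation holds for doublets too.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"doublet rate must be in [0, 1), got {rate}")
    if adata.n_obs < 2:
        raise ValueError("need at least 2 cells to form doublets")
    out = adata.copy()
    new_truth = truth.copy()
    k = int(np.floor(rate * adata.n_obs))
    if k == 0:
        return out, new_truth
    rng = np.random.default_rng(seed)
    hosts = rng.choice(adata.n_obs, size=k, replace=False)
    stages = adata.obs["stage"].to_numpy()
    X = out.X
    for h in hosts:
        same_stage = np.where(stages == stages[h])[0]
        same_stage = same_stage[same_stage != h]
        partner = int(rng.choice(same_stage)) if same_stage.size else int(
            rng.choice([i for i in range(adata.n_obs) if i != h])
        )
        X[h] += adata.X[partner]
        for layer in out.layers.keys():
            out.layers[layer][h] += adata.layers[layer][partner]
    flags = new_truth.doublet_flags.copy()
    flags.iloc[hosts] = True
    new_truth.doublet_flags = flags
    return out, new_truth


def simulate(config: SyntheticConfig) -> tuple[AnnData, GroundTruth]:
    """End-to-end generation: programs -> counts -> doublets."""
    programs = generate_type_programs(config)
    adata, truth = simulate_counts(programs, config)
    if config.doublet_rate > 0:
        rng = np.random.default_rng([config.seed, 2])
        adata, truth = inject_doublets(
            adata, truth, config.doublet_rate, int(rng.integers(2**31))
        )
    return adata, truth


# ---------------------------------------------------------------------------
# plain-text IO: MTX count layers + TSV sidecars + JSON truth


def write_dataset(adata: AnnData, outdir: str | Path, truth: GroundTruth | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "counts.mtx", sp.coo_matrix(adata.X), field="integer")
    for layer in adata.layers.keys():
        scipy.io.mmwrite(
            outdir / f"{layer}.mtx", sp.coo_matrix(adata.layers[layer]), field="integer"
        )
    adata.obs.to_csv(outdir / "cells.tsv", sep="\t")
    adata.var.to_csv(outdir / "genes.tsv", sep="\t")
    if truth is not None:
        payload = {
            "type_of_cell": truth.type_of_cell.to_dict(),
            "receptor_code": {t: list(c) for t, c in truth.receptor_code.items()},
            "de_genes": {
                t: {s: sorted(g) for s, g in d.items()}
                for t, d in truth.de_genes.items()
            },
            "stage_correspondence": truth.stage_correspondence,
            "doublet_flags": truth.doublet_flags.to_dict(),
        }
        (outdir / "truth.json").write_text(json.dumps(payload, indent=1))


def read_dataset(indir: str | Path) -> tuple[AnnData, GroundTruth | None]:
    indir = Path(indir)
    X = np.asarray(scipy.io.mmread(indir / "counts.mtx").todense()).astype(np.int64)
    obs = pd.read_csv(indir / "cells.tsv", sep="\t", index_col=0)
    var = pd.read_csv(indir / "genes.tsv", sep="\t", index_col=0)
    var["family"] = var["family"].fillna("")
    layers = {}
    for layer in ("exon", "intron"):
        path = indir / f"{layer}.mtx"
        if path.exists():
            layers[layer] = np.asarray(scipy.io.mmread(path).todense()).astype(np.int64)
    adata = AnnData(X=X, obs=obs, var=var, layers=layers)
    truth = None
    truth_path = indir / "truth.json"
    if truth_path.exists():
        payload = json.loads(truth_path.read_text())
        truth = GroundTruth(
            type_of_cell=pd.Series(payload["type_of_cell"], name="type").reindex(obs.index),
            receptor_code={t: tuple(c) for t, c in payload["receptor_code"].items()},
            de_genes={
                t: {s: frozenset(g) for s, g in d.items()}
                for t, d in payload["de_genes"].items()
            },
            stage_correspondence=payload["stage_correspondence"],
            doublet_flags=pd.Series(payload["doublet_flags"], name="doublet").reindex(
                obs.index
            ),
        )
    return adata, truth
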