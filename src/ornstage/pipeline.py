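"""End-to-end orchestration: simulate/load -> QC -> cluster -> DE ->
receptors -> annotate -> cross-stage matching -> report.

Mirrors the published workflow: the feature set for dimensionality
reduction is built once, from the DE genes of the reference stage (the
stage with maximal transcriptomic diversity) combined with the known
sensory receptors, and reused at every stage.  Stage pairs are matched by
Jaccard similarity of per-cluster DE sets, with one-way matches allowed
only between same-technology stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from anndata import AnnData

from . import __version__
from .params import AnalysisParams
from .synthetic import SyntheticConfig, GroundTruth, simulate, read_dataset
from . import qc, receptors as rec, diffexp, cluster as clu, match as mat

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]

_REQUIRED_KEYS = {"synthetic"}
_OPTIONAL_KEYS = {"input_dir", "params", "n_pcs", "n_hvg", "embedding", "reference_stage", "seed"}


@dataclass
class PipelineConfig:
    synthetic: SyntheticConfig
    params: AnalysisParams = field(default_factory=AnalysisParams)
    input_dir: str | None = None
    n_pcs: int = 20
    n_hvg: int = 1000
    embedding: str = "none"
    reference_stage: str | None = None
    seed: int = 0

    def config_hash(self) -> str:
        payload = {
            "synthetic": asdict(self.synthetic),
            "params": self.params.to_dict(),
            "n_pcs": self.n_pcs,
            "n_hvg": self.n_hvg,
            "embedding": self.embedding,
            "reference_stage": self.reference_stage,
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration.

    Unknown or missing required fields raise with the offending field named.
    """
    raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _REQUIRED_KEYS - _OPTIONAL_KEYS
    if unknown:
        raise ValueError(f"unknown config field(s): {sorted(unknown)}")
    missing = _REQUIRED_KEYS - set(raw)
    if missing:
        raise ValueError(f"missing required config field(s): {sorted(missing)}")
    syn = raw["synthetic"] or {}
    for key in ("stages", "nucleus_stages"):
        if key in syn and isinstance(syn[key], list):
            syn[key] = tuple(syn[key])
    if "depth_range" in syn:
        syn["depth_range"] = tuple(syn["depth_range"])
    if "contaminant_genes" in syn:
        syn["contaminant_genes"] = tuple(
            (str(g), float(s)) for g, s in syn["contaminant_genes"]
        )
    params_raw = raw.get("params") or {}
    if "marker_genes" in params_raw:
        params_raw["marker_genes"] = tuple(params_raw["marker_genes"])
    return PipelineConfig(
        synthetic=SyntheticConfig(**syn),
        params=AnalysisParams(**params_raw),
        input_dir=raw.get("input_dir"),
        n_pcs=int(raw.get("n_pcs", 20)),
        n_hvg=int(raw.get("n_hvg", 1000)),
        embedding=str(raw.get("embedding", "none")),
        reference_stage=raw.get("reference_stage"),
        seed=int(raw.get("seed", 0)),
    )


@dataclass
class PipelineResult:
    normalized: AnnData
    truth: GroundTruth | None
    labels: dict[str, pd.Series]
    de: dict[str, diffexp.DEResult]
    calls: dict[str, rec.ReceptorCalls]
    annotations: dict[str, dict[str, str]]
    matches: dict[tuple[str, str], mat.MatchResult]
    report: dict


def _stage_view(adata: AnnData, stage: str) -> AnnData:
    return adata[(adata.obs["stage"] == stage).to_numpy()].copy()


def run_pipeline(
    config: PipelineConfig, outdir: str | Path | None = None
) -> PipelineResult:
    """Execute all stages and optionally write TSV/JSON outputs.

    Every output file header carries the tool version and config hash so a
    run directory is self-describing; identical config and seed give
    byte-identical outputs.
    """
    report: dict[str, Any] = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    syn = config.synthetic
    if syn.seed != config.seed:
        syn = SyntheticConfig(**{**asdict(syn), "seed": config.seed})
    if config.input_dir:
        adata, truth = read_dataset(config.input_dir)
    else:
        adata, truth = simulate(syn)
    report["n_cells_input"] = int(adata.n_obs)

    # ---- QC
    merged = qc.merge_layers(adata) if "exon" in adata.layers else adata.copy()
    filtered, qc_report = qc.filter_cells(merged, config.params)
    report["n_cells_after_quality_filter"] = int(filtered.n_obs)
    norm = qc.normalize(filtered)
    norm, offtarget_report = qc.remove_off_target_cells(norm, params=config.params)
    report["n_cells_after_identity_filter"] = int(norm.n_obs)

    stages = [s for s in syn.stages if (norm.obs["stage"] == s).any()]
    ref_stage = config.reference_stage or (stages[len(stages) // 2] if stages else None)

    # ---- pass 1: cluster the reference stage on overdispersed genes to get
    # its DE sets, then build the shared feature set (ref DE u receptors)
    receptor_genes = list(norm.var_names[norm.var["category"] == "receptor"])
    ref = _stage_view(norm, ref_stage)
    hvg = clu.select_overdispersed_genes(ref, n=min(config.n_hvg, ref.n_vars))
    emb = clu.reduce_and_embed(ref, hvg, n_pcs=config.n_pcs, seed=config.seed)
    ref_assign = clu.density_cluster(emb.pcs, params=config.params)
    ref_de = diffexp.mann_whitney_cluster_vs_rest(
        ref, ref_assign.labels, de_alpha=config.params.de_alpha
    )
    features = diffexp.build_feature_set(
        ref_de.de_sets, receptor_genes, universe=norm.var_names
    )
    report["feature_set_size"] = len(features)

    # ---- pass 2: per-stage clustering, DE, receptor calls, annotation
    labels: dict[str, pd.Series] = {}
    de: dict[str, diffexp.DEResult] = {}
    calls: dict[str, rec.ReceptorCalls] = {}
    annotations: dict[str, dict[str, str]] = {}
    receptor_to_type = truth.receptor_to_type if truth is not None else {}
    for s in stages:
        sub = _stage_view(norm, s)
        emb_s = clu.reduce_and_embed(
            sub, features, n_pcs=config.n_pcs,
            method=config.embedding if config.embedding != "none" else "none",
            seed=config.seed,
        )
        assign = clu.density_cluster(emb_s.pcs, params=config.params)
        labels[s] = assign.as_series(sub.obs_names)
        de[s] = diffexp.mann_whitney_cluster_vs_rest(
            sub, assign.labels, de_alpha=config.params.de_alpha
        )
        calls[s] = rec.call_receptors(sub, params=config.params)
        if receptor_to_type:
            annotations[s] = mat.annotate_by_receptor(
                labels[s], calls[s], receptor_to_type,
                min_cells=config.params.receptor_min_cells,
            )
    report["n_clusters"] = {s: int(labels[s].max()) + 1 for s in stages}

    # ---- cross-stage matching on DE-set Jaccard similarity
    matches: dict[tuple[str, str], mat.MatchResult] = {}
    pairs = [(stages[i], stages[i + 1]) for i in range(len(stages) - 1)]
    if len(stages) > 2:
        pairs.append((stages[0], stages[-1]))
    for sa, sb in pairs:
        sim = mat.jaccard_matrix(de[sa].de_sets, de[sb].de_sets)
        matches[(sa, sb)] = mat.match_clusters(
            sim, allow_one_way=mat.default_one_way_policy(sa, sb)
        )
    report["matches"] = {
        f"{sa}->{sb}": {
            "two_way": len(m.two_way),
            "one_way": len(m.one_way),
            "ties": len(m.ties),
        }
        for (sa, sb), m in matches.items()
    }

    # receptor-count summary over all stages
    all_calls = rec.call_receptors(norm, params=config.params)
    dist = rec.receptor_count_distribution(all_calls)
    report["receptor_count_distribution"] = dist.counts
    report["fraction_single_receptor"] = dist.fraction_single_among_positive

    if truth is not None:
        report["match_recovery"] = {
            f"{sa}->{sb}": _match_recovery(m, labels[sa], labels[sb], truth)
            for (sa, sb), m in matches.items()
        }

    result = PipelineResult(
        normalized=norm,
        truth=truth,
        labels=labels,
        de=de,
        calls=calls,
        annotations=annotations,
        matches=matches,
        report=report,
    )
    if outdir is not None:
        _write_outputs(result, qc_report, offtarget_report, config, Path(outdir))
    return result


def _majority_type(labels: pd.Series, truth: GroundTruth) -> dict[str, str]:
    types = truth.type_of_cell.reindex(labels.index)
    out = {}
    for c in sorted(labels[labels >= 0].unique()):
        out[str(c)] = types[labels == c].mode().iloc[0]
    return out


def _match_recovery(
    m: mat.MatchResult, labels_a: pd.Series, labels_b: pd.Series, truth: GroundTruth
) -> dict:
    """Fraction of two-way matches linking clusters of the same planted type."""
    type_a = _majority_type(labels_a, truth)
    type_b = _majority_type(labels_b, truth)
    two_way = m.two_way
    correct = sum(
        1 for a, b in two_way.items()
        if truth.stage_correspondence.get(type_a.get(a, "?")) == type_b.get(b, "??")
    )
    n_types = len(truth.stage_correspondence)
    return {
        "two_way_total": len(two_way),
        "two_way_correct": correct,
        "planted_types": n_types,
        "recovery": correct / n_types if n_types else None,
    }


def _write_tsv(df: pd.DataFrame, path: Path, header: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=index)


def _write_outputs(
    result: PipelineResult,
    qc_report: pd.DataFrame,
    offtarget_report: pd.DataFrame,
    config: PipelineConfig,
    outdir: Path,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# ornstage {__version__} config_sha={config.config_hash()}\n"
    _write_tsv(qc_report, outdir / "qc_report.tsv", header)
    _write_tsv(offtarget_report, outdir / "offtarget_report.tsv", header)
    for s, lab in result.labels.items():
        _write_tsv(lab.to_frame(), outdir / f"labels_{s}.tsv", header)
        _write_tsv(result.de[s].table, outdir / f"de_{s}.tsv", header, index=False)
        if s in result.annotations:
            ann = pd.DataFrame(
                sorted(result.annotations[s].items()), columns=["cluster", "type"]
            )
            _write_tsv(ann, outdir / f"annotation_{s}.tsv", header, index=False)
    for (sa, sb), m in result.matches.items():
        _write_tsv(
            m.to_frame(), outdir / f"matches_{sa}_vs_{sb}.tsv", header, index=False
        )
    (outdir / "report.json").write_text(
        json.dumps(result.report, indent=1, default=str) + "\n"
    )
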