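"""Analysis parameters and canonical gene lists.

All thresholds operate on log2(CPM+1) values unless stated otherwise.
Defaults reproduce the published antennal sensory-neuron analysis settings;
every pipeline stage takes an :class:`AnalysisParams` so deviations are
explicit overrides, never silent edits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

#: Pan-neuronal markers used for cell-quality filtering.
NEURONAL_MARKERS: tuple[str, ...] = ("elav", "brp", "CadN", "nSyb", "Syt1")

#: Genes specific to Johnston's-organ auditory neurons; antennal ORNs must not
#: express these.
AUDITORY_GENES: tuple[str, ...] = ("iav", "nompC", "CG9492", "CG10186", "fd3F")

#: Transcription factor expressed by all antennal ORNs; its absence marks
#: non-ORN cells.
ORN_IDENTITY_GENE: str = "acj6"

#: Broadly expressed co-receptor subunits, excluded from type-identifying
#: receptor calls (Orco partners Ors; Ir8a/Ir25a/Ir76b partner Irs).
CO_RECEPTORS: tuple[str, ...] = ("Orco", "Ir8a", "Ir25a", "Ir76b")


@dataclass(frozen=True)
class AnalysisParams:
    """Thresholds and settings shared across pipeline stages.

    Attributes
    ----------
    min_reads:
        Minimum uniquely mapped reads per cell/nucleus (applied to the merged
        working counts).
    marker_genes, min_markers, marker_threshold:
        A retained cell must express at least ``min_markers`` of
        ``marker_genes`` at log2(CPM+1) >= ``marker_threshold`` (inclusive).
    receptor_threshold:
        A receptor is "on" in a cell at log2(CPM+1) >= this value.
    receptor_min_cells:
        A receptor is "expressed" in a dataset when on in strictly more than
        this many cells.
    high_threshold:
        Stringent cutoff for co-receptor co-expression analyses.
    de_alpha:
        BH-adjusted p-value cutoff for cluster-vs-rest differential
        expression.
    go_p:
        Bonferroni-adjusted p-value cutoff for two-group gene lists handed to
        external enrichment tools.
    hdbscan_min_cluster_size, hdbscan_min_samples:
        Density-clustering settings.
    """

    min_reads: int = 50_000
    marker_genes: tuple[str, ...] = NEURONAL_MARKERS
    min_markers: int = 2
    marker_threshold: float = 2.0
    receptor_threshold: float = 3.0
    receptor_min_cells: int = 5
    high_threshold: float = 5.0
    de_alpha: float = 0.01
    go_p: float = 1e-5
    hdbscan_min_cluster_size: int = 6
    hdbscan_min_samples: int = 4
    # documented switch: apply the depth rule to exon-only counts instead of
    # the merged (exon+intron for nuclei) working counts
    depth_on_merged: bool = True

    def __post_init__(self) -> None:
        numeric = {
            "min_reads": self.min_reads,
            "marker_threshold": self.marker_threshold,
            "receptor_threshold": self.receptor_threshold,
            "receptor_min_cells": self.receptor_min_cells,
            "high_threshold": self.high_threshold,
            "de_alpha": self.de_alpha,
            "go_p": self.go_p,
        }
        for name, value in numeric.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.min_markers > len(self.marker_genes):
            raise ValueError(
                f"min_markers={self.min_markers} exceeds the number of "
                f"marker genes ({len(self.marker_genes)})"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["marker_genes"] = list(self.marker_genes)
        return d


DEFAULT_PARAMS = AnalysisParams()
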