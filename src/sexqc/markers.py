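"""Sex-marker panel definition and correlation-based probeset quality filtering.

A panel maps marker genes (XIST female-specific; KDM5D and RPS4Y1 Y-linked,
male-specific) to the probesets representing them on a given platform.  On a
concrete dataset, probesets that fail to behave like sex markers — poorly
correlated with their own direction, or positively correlated with the
opposite direction — are excluded before inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import PanelError
from .io import ExpressionMatrix

__all__ = [
    "GENE_DIRECTIONS",
    "MarkerProbe",
    "MarkerPanel",
    "ProbeQC",
    "load_panel",
    "filter_probesets",
]

GENE_DIRECTIONS = {
    "XIST": "female_high",
    "KDM5D": "male_high",
    "RPS4Y1": "male_high",
}


@dataclass(frozen=True)
class MarkerProbe:
    probe_id: str
    gene: str
    direction: str


@dataclass
class MarkerPanel:
    """An ordered set of marker probesets with sex directions, for one platform."""

    entries: list[MarkerProbe]
    platform: str = "custom"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for entry in self.entries:
            if entry.gene not in GENE_DIRECTIONS:
                raise PanelError(f"unknown marker gene: {entry.gene!r}")
            if entry.direction != GENE_DIRECTIONS[entry.gene]:
                raise PanelError(
                    f"probe {entry.probe_id!r}: gene {entry.gene} must have "
                    f"direction {GENE_DIRECTIONS[entry.gene]}"
                )
            if entry.probe_id in seen:
                raise PanelError(f"duplicate probe id in panel: {entry.probe_id!r}")
            seen.add(entry.probe_id)

    @property
    def probe_ids(self) -> list[str]:
        return [e.probe_id for e in self.entries]

    def direction_of(self, probe_id: str) -> str:
        for entry in self.entries:
            if entry.probe_id == probe_id:
                return entry.direction
        raise PanelError(f"probe {probe_id!r} not in panel")

    def probes_with_direction(self, direction: str) -> list[str]:
        return [e.probe_id for e in self.entries if e.direction == direction]

    def require_both_directions(self) -> None:
        for direction in ("female_high", "male_high"):
            if not self.probes_with_direction(direction):
                raise PanelError(f"panel has no {direction} probes")


@dataclass
class ProbeQC:
    """Per-probe filtering record: mean within/cross-direction correlations."""

    probe_id: str
    gene: str
    direction: str
    mean_same_direction_r: float | None
    mean_opposite_direction_r: float | None
    excluded: bool
    reasons: list[str] = field(default_factory=list)


def _default_config_path():
    return resources.files("sexqc").joinpath("data/panels.yaml")


def load_panel(config: str | Path | None = None, platform: str = "GPL570") -> MarkerPanel:
    """Load the marker panel for ``platform`` from a YAML config.

    The config maps platform labels to ``gene: [probeset, ...]`` blocks.  With
    ``config=None`` the packaged defaults (GPL96, GPL570) are used.
    """
    if config is None:
        text = _default_config_path().read_text()
        source = "<default panels>"
    else:
        text = Path(config).read_text()
        source = str(config)
    try:
        mapping = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise PanelError(f"{source}: invalid YAML: {exc}") from exc
    if not isinstance(mapping, dict) or platform not in mapping:
        known = sorted(mapping) if isinstance(mapping, dict) else []
        raise PanelError(f"{source}: unknown platform {platform!r} (known: {known})")
    block = mapping[platform]
    entries: list[MarkerProbe] = []
    for gene in GENE_DIRECTIONS:
        probes = block.get(gene)
        if not probes:
            raise PanelError(f"{source}: platform {platform}: gene {gene} has no probesets")
        for probe_id in probes:
            entries.append(MarkerProbe(str(probe_id), gene, GENE_DIRECTIONS[gene]))
    unknown_genes = set(block) - set(GENE_DIRECTIONS)
    if unknown_genes:
        raise PanelError(f"{source}: platform {platform}: unknown genes {sorted(unknown_genes)}")
    return MarkerPanel(entries, platform=platform)


def filter_probesets(
    m: ExpressionMatrix, panel: MarkerPanel, min_r: float = 0.3
) -> tuple[MarkerPanel, list[ProbeQC]]:
    """Exclude panel probesets that do not track their sex direction.

    Pearson correlations across samples are computed on the full panel once;
    exclusions are then applied simultaneously (order-independent).  A probe is
    excluded when its mean correlation with same-direction probes falls below
    ``min_r`` or its mean correlation with opposite-direction probes is
    positive.  Probes with undefined correlations (constant across samples)
    are treated as correlation 0 and hence excluded.
    """
    for probe_id in panel.probe_ids:
        if probe_id not in m.probe_ids:
            raise PanelError(f"panel probe {probe_id!r} missing from matrix")
    if m.n_samples < 3:
        raise PanelError("probeset filtering needs at least 3 samples")
    sub = m.subset_probes(panel.probe_ids)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub.values)
    corr = np.atleast_2d(np.nan_to_num(corr, nan=0.0))
    directions = [e.direction for e in panel.entries]
    qc: list[ProbeQC] = []
    for i, entry in enumerate(panel.entries):
        same = [j for j in range(len(panel.entries)) if j != i and directions[j] == entry.direction]
        opposite = [j for j in range(len(panel.entries)) if directions[j] != entry.direction]
        mean_same = float(np.mean(corr[i, same])) if same else None
        mean_opp = float(np.mean(corr[i, opposite])) if opposite else None
        reasons = []
        if mean_same is not None and mean_same < min_r:
            reasons.append(f"mean same-direction r {mean_same:.3f} < {min_r}")
        if mean_opp is not None and mean_opp > 0:
            reasons.append(f"mean opposite-direction r {mean_opp:.3f} > 0")
        qc.append(
            ProbeQC(
                probe_id=entry.probe_id,
                gene=entry.gene,
                direction=entry.direction,
                mean_same_direction_r=mean_same,
                mean_opposite_direction_r=mean_opp,
                excluded=bool(reasons),
                reasons=reasons,
            )
        )
    kept = [e for e, record in zip(panel.entries, qc) if not record.excluded]
    filtered = MarkerPanel(kept, platform=panel.platform)
    try:
        filtered.require_both_directions()
    except PanelError as exc:
        raise PanelError(f"filtering removed all probes of one direction: {exc}") from exc
    return filtered, qc
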