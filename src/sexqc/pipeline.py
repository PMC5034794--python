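"""End-to-end orchestration: preprocess -> filter panel -> infer -> compare."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import SingleSexDatasetError
from .inference import DEFAULT_RESTARTS, DEFAULT_SEED, assign_sex
from .io import ExpressionMatrix, SampleMetadata
from .markers import MarkerPanel, ProbeQC, filter_probesets
from .preprocess import PreprocessConfig, log2_quantile_normalize
from .report import DatasetReport, compare_annotations

__all__ = ["PipelineResult", "run_dataset"]


@dataclass
class PipelineResult:
    report: DatasetReport
    panel: MarkerPanel  # panel after probeset filtering
    panel_qc: list[ProbeQC]


def run_dataset(
    matrix: ExpressionMatrix,
    metadata: list[SampleMetadata],
    panel: MarkerPanel,
    *,
    dataset_id: str = "dataset",
    preprocess_cfg: PreprocessConfig | None = None,
    min_r: float = 0.3,
    filter_panel: bool = True,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = DEFAULT_SEED,
) -> PipelineResult:
    """Run the full per-dataset analysis and return the comparison report.

    Raises :class:`SingleSexDatasetError` when the metadata annotates only one
    sex: with a single sex present, two-cluster sex assignment is meaningless
    and such datasets are excluded from analysis.
    """
    annotated_sexes = {m.annotated_sex for m in metadata} - {"unknown"}
    if len(annotated_sexes) < 2:
        raise SingleSexDatasetError(
            f"dataset {dataset_id!r} annotates only {sorted(annotated_sexes)}; "
            "sex inference skipped"
        )
    normalized = log2_quantile_normalize(matrix, preprocess_cfg)
    qc: list[ProbeQC] = []
    if filter_panel:
        panel, qc = filter_probesets(normalized, panel, min_r=min_r)
    calls = assign_sex(normalized, panel, restarts=restarts, seed=seed)
    report = compare_annotations(calls, metadata, dataset_id=dataset_id)
    return PipelineResult(report=report, panel=panel, panel_qc=qc)
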