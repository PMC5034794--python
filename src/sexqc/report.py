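"""Compare gene-based sex calls to annotations; dataset and corpus accounting.

Sample statuses:

* ``mismatch`` — a definite (female/male) call contradicting a definite
  annotation; the detector's positive.
* ``unclassified`` — the call is ambiguous, or the annotation is unknown.
  Ambiguous samples are excluded from the mismatch count even when their
  cluster assignment contradicts the annotation; that sub-count is surfaced
  separately (``n_ambiguous_cluster_discrepant``).
* ``match`` — everything else.

A dataset is ``correctly_annotated`` only when it has zero mismatched and
zero unclassified samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

from .errors import ReportError

if TYPE_CHECKING:  # pragma: no cover
    from .inference import SexCall
    from .io import SampleMetadata

__all__ = [
    "DatasetReport",
    "StratumSummary",
    "CorpusSummary",
    "compare_annotations",
    "summarize_corpus",
    "cross_study_concordance",
]

SAMPLE_STATUSES = ("match", "mismatch", "unclassified")
CONCORDANCE_CLASSES = ("consistent_metadata_error", "study_specific_mixup", "indeterminate")


@dataclass
class DatasetReport:
    """Per-dataset outcome: calls vs annotations plus derived counts.

    Normally produced by :func:`compare_annotations`; :meth:`from_counts`
    builds a counts-only report (no per-sample records) for corpus-level
    arithmetic on externally tabulated numbers.
    """

    dataset_id: str
    calls: list["SexCall"] = field(default_factory=list)
    annotated: dict[str, str] = field(default_factory=dict)
    sample_status: dict[str, str] = field(default_factory=dict)
    n_ambiguous_cluster_discrepant: int = 0
    subject_by_sample: dict[str, str] = field(default_factory=dict)
    _n_samples: int | None = None
    _n_mismatch: int | None = None
    _n_unclassified: int | None = None

    @classmethod
    def from_counts(
        cls,
        dataset_id: str,
        n_samples: int,
        n_mismatch: int,
        n_unclassified: int,
        n_ambiguous_cluster_discrepant: int = 0,
    ) -> "DatasetReport":
        if min(n_samples, n_mismatch, n_unclassified) < 0:
            raise ReportError("counts must be non-negative")
        if n_mismatch + n_unclassified > n_samples:
            raise ReportError("mismatch + unclassified cannot exceed sample count")
        if n_ambiguous_cluster_discrepant > n_unclassified:
            raise ReportError("cluster-discrepant count cannot exceed unclassified count")
        return cls(
            dataset_id=dataset_id,
            n_ambiguous_cluster_discrepant=n_ambiguous_cluster_discrepant,
            _n_samples=n_samples,
            _n_mismatch=n_mismatch,
            _n_unclassified=n_unclassified,
        )

    def _count(self, status: str) -> int:
        return sum(1 for s in self.sample_status.values() if s == status)

    @property
    def n_samples(self) -> int:
        return self._n_samples if self._n_samples is not None else len(self.sample_status)

    @property
    def n_mismatch(self) -> int:
        return self._n_mismatch if self._n_mismatch is not None else self._count("mismatch")

    @property
    def n_unclassified(self) -> int:
        return (
            self._n_unclassified
            if self._n_unclassified is not None
            else self._count("unclassified")
        )

    @property
    def n_match(self) -> int:
        return self.n_samples - self.n_mismatch - self.n_unclassified

    @property
    def mismatched_ids(self) -> list[str]:
        return [s for s, st in self.sample_status.items() if st == "mismatch"]

    @property
    def unclassified_ids(self) -> list[str]:
        return [s for s, st in self.sample_status.items() if st == "unclassified"]

    @property
    def dataset_status(self) -> str:
        return (
            "correctly_annotated"
            if self.n_mismatch == 0 and self.n_unclassified == 0
            else "affected"
        )

    def summary_dict(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            "dataset_status": self.dataset_status,
            "n_samples": self.n_samples,
            "n_match": self.n_match,
            "n_mismatch": self.n_mismatch,
            "n_unclassified": self.n_unclassified,
            "n_ambiguous_cluster_discrepant": self.n_ambiguous_cluster_discrepant,
            "mismatched_ids": sorted(self.mismatched_ids),
            "unclassified_ids": sorted(self.unclassified_ids),
            "subject_by_sample": self.subject_by_sample,
        }

    @classmethod
    def from_summary_dict(cls, d: Mapping) -> "DatasetReport":
        return cls.from_counts(
            dataset_id=d["dataset_id"],
            n_samples=d["n_samples"],
            n_mismatch=d["n_mismatch"],
            n_unclassified=d["n_unclassified"],
            n_ambiguous_cluster_discrepant=d.get("n_ambiguous_cluster_discrepant", 0),
        )


def compare_annotations(
    calls: Sequence["SexCall"],
    metadata: Sequence["SampleMetadata"],
    dataset_id: str = "dataset",
) -> DatasetReport:
    """Assign per-sample statuses by comparing calls with annotations."""
    meta_by_id = {m.sample_id: m for m in metadata}
    annotated: dict[str, str] = {}
    status: dict[str, str] = {}
    subjects: dict[str, str] = {}
    n_discrepant = 0
    for call in calls:
        meta = meta_by_id.get(call.sample_id)
        if meta is None:
            raise ReportError(f"call for sample {call.sample_id!r} has no metadata")
        annotated[call.sample_id] = meta.annotated_sex
        if meta.subject_id is not None:
            subjects[call.sample_id] = meta.subject_id
        if call.final_call == "ambiguous" or meta.annotated_sex == "unknown":
            status[call.sample_id] = "unclassified"
            if (
                call.final_call == "ambiguous"
                and meta.annotated_sex in ("female", "male")
                and call.cluster_sex is not None
                and call.cluster_sex != meta.annotated_sex
            ):
                n_discrepant += 1
        elif call.final_call != meta.annotated_sex:
            status[call.sample_id] = "mismatch"
        else:
            status[call.sample_id] = "match"
    return DatasetReport(
        dataset_id=dataset_id,
        calls=list(calls),
        annotated=annotated,
        sample_status=status,
        n_ambiguous_cluster_discrepant=n_discrepant,
        subject_by_sample=subjects,
    )


@dataclass
class StratumSummary:
    """Dataset- and sample-level counts for one stratum of the corpus."""

    label: str
    n_datasets: int = 0
    n_datasets_mismatch: int = 0
    n_datasets_unclassified: int = 0
    n_datasets_both: int = 0
    n_datasets_correct: int = 0
    n_samples: int = 0
    n_samples_match: int = 0
    n_samples_mismatch: int = 0
    n_samples_unclassified: int = 0
    n_ambiguous_cluster_discrepant: int = 0

    def _pct(self, num: int, den: int) -> float:
        return 100.0 * num / den if den else 0.0

    @property
    def pct_datasets_mismatch(self) -> float:
        return self._pct(self.n_datasets_mismatch, self.n_datasets)

    @property
    def pct_datasets_unclassified(self) -> float:
        return self._pct(self.n_datasets_unclassified, self.n_datasets)

    @property
    def pct_datasets_correct(self) -> float:
        return self._pct(self.n_datasets_correct, self.n_datasets)

    @property
    def pct_samples_mismatch(self) -> float:
        return self._pct(self.n_samples_mismatch, self.n_samples)

    @property
    def pct_samples_unclassified(self) -> float:
        return self._pct(self.n_samples_unclassified, self.n_samples)

    @property
    def pct_samples_match(self) -> float:
        return self._pct(self.n_samples_match, self.n_samples)

    @property
    def pct_ambiguous_cluster_discrepant(self) -> float:
        return self._pct(self.n_ambiguous_cluster_discrepant, self.n_samples_unclassified)


@dataclass
class CorpusSummary:
    """Stratified corpus accounting; the ``"all"`` stratum is always present."""

    strata: dict[str, StratumSummary]

    def __getitem__(self, label: str) -> StratumSummary:
        return self.strata[label]

    def to_rows(self) -> list[dict]:
        rows = []
        for label, s in self.strata.items():
            rows.append(
                {
                    "stratum": label,
                    "datasets_total": s.n_datasets,
                    "datasets_correct": s.n_datasets_correct,
                    "datasets_correct_pct": round(s.pct_datasets_correct),
                    "datasets_mismatch": s.n_datasets_mismatch,
                    "datasets_mismatch_pct": round(s.pct_datasets_mismatch),
                    "datasets_unclassified": s.n_datasets_unclassified,
                    "datasets_unclassified_pct": round(s.pct_datasets_unclassified),
                    "datasets_both": s.n_datasets_both,
                    "samples_total": s.n_samples,
                    "samples_match": s.n_samples_match,
                    "samples_mismatch": s.n_samples_mismatch,
                    "samples_mismatch_pct": round(s.pct_samples_mismatch, 2),
                    "samples_unclassified": s.n_samples_unclassified,
                    "samples_unclassified_pct": round(s.pct_samples_unclassified, 2),
                }
            )
        return rows


def summarize_corpus(
    reports: Sequence[DatasetReport],
    strata: Mapping[str, str] | None = None,
) -> CorpusSummary:
    """Aggregate dataset reports into per-stratum counts and percentages.

    ``strata`` maps dataset_id -> label (e.g. cancer / non-cancer); when given,
    every dataset must be labeled.  Aggregation is order-independent.
    """
    if not reports:
        raise ReportError("summarize_corpus needs at least one dataset report")
    labels: dict[str, str] = {}
    if strata is not None:
        for report in reports:
            if report.dataset_id not in strata:
                raise ReportError(f"dataset {report.dataset_id!r} missing from strata mapping")
            labels[report.dataset_id] = str(strata[report.dataset_id])
    summaries: dict[str, StratumSummary] = {"all": StratumSummary("all")}
    for label in sorted(set(labels.values())):
        summaries[label] = StratumSummary(label)
    for report in sorted(reports, key=lambda r: r.dataset_id):
        targets = [summaries["all"]]
        if report.dataset_id in labels:
            targets.append(summaries[labels[report.dataset_id]])
        for s in targets:
            s.n_datasets += 1
            has_mismatch = report.n_mismatch > 0
            has_unclassified = report.n_unclassified > 0
            s.n_datasets_mismatch += has_mismatch
            s.n_datasets_unclassified += has_unclassified
            s.n_datasets_both += has_mismatch and has_unclassified
            s.n_datasets_correct += report.dataset_status == "correctly_annotated"
            s.n_samples += report.n_samples
            s.n_samples_match += report.n_match
            s.n_samples_mismatch += report.n_mismatch
            s.n_samples_unclassified += report.n_unclassified
            s.n_ambiguous_cluster_discrepant += report.n_ambiguous_cluster_discrepant
    return CorpusSummary(summaries)


def cross_study_concordance(
    reports: Sequence[DatasetReport],
    subjects: Iterable[str] | None = None,
) -> dict[str, str]:
    """Classify discrepant subjects shared across studies.

    A subject mismatched in every study where it appears (>= 2 studies) points
    to a consistently wrong annotation (``consistent_metadata_error``); one
    mismatched in some but not all studies points to a physical mix-up in a
    particular laboratory (``study_specific_mixup``); a subject seen in a
    single study is ``indeterminate``.

    By default only subjects with at least one mismatched sample are
    classified; pass ``subjects`` to query an explicit set (unknown ids are an
    error).
    """
    if len(reports) < 2:
        raise ReportError("cross-study concordance needs at least 2 studies")
    present: dict[str, set[str]] = {}
    mismatched: dict[str, set[str]] = {}
    for report in reports:
        if not report.subject_by_sample:
            continue
        for sample_id, subject in report.subject_by_sample.items():
            present.setdefault(subject, set()).add(report.dataset_id)
            if report.sample_status.get(sample_id) == "mismatch":
                mismatched.setdefault(subject, set()).add(report.dataset_id)
    if not present:
        raise ReportError("no subject identifiers found in any study")
    if not any(len(studies) >= 2 for studies in present.values()):
        raise ReportError("no subject is shared by two or more studies")
    if subjects is None:
        query = sorted(mismatched)
    else:
        query = list(subjects)
        for subject in query:
            if subject not in present:
                raise ReportError(f"subject {subject!r} not present in any study")
    classes: dict[str, str] = {}
    for subject in query:
        n_present = len(present[subject])
        n_mismatch = len(mismatched.get(subject, ()))
        if n_present < 2:
            classes[subject] = "indeterminate"
        elif n_mismatch == n_present:
            classes[subject] = "consistent_metadata_error"
        elif n_mismatch >= 1:
            classes[subject] = "study_specific_mixup"
        else:
            classes[subject] = "indeterminate"
    return classes
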