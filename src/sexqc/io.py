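"""Reading and writing of expression matrices, metadata and per-sample reports.

Supported inputs are plain tab-separated tables and the GEO series-matrix
dialect (the expression table delimited by ``!series_matrix_table_begin`` /
``!series_matrix_table_end`` lines).  Values are taken as-is at read time;
any log/normalization decisions belong to :mod:`sexqc.preprocess`.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .errors import FormatError, MetadataError

if TYPE_CHECKING:  # pragma: no cover
    from .report import DatasetReport

__all__ = [
    "ExpressionMatrix",
    "SampleMetadata",
    "read_expression_matrix",
    "read_metadata",
    "write_report",
    "read_report",
]

SERIES_TABLE_BEGIN = "!series_matrix_table_begin"
SERIES_TABLE_END = "!series_matrix_table_end"

#: Accepted sex vocabulary (lower-cased token -> normalized value).  Anything
#: outside this table is a hard error: silently coercing unexpected tokens
#: would hide exactly the annotation problems being hunted.
SEX_SYNONYMS = {
    "f": "female",
    "female": "female",
    "m": "male",
    "male": "male",
    "": "unknown",
    "na": "unknown",
    "nan": "unknown",
    "unknown": "unknown",
}

_MISSING_VALUE_TOKENS = {"", "na", "nan", "null"}


@dataclass
class ExpressionMatrix:
    """A probe-by-sample numeric matrix with ordered, unique identifiers."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("expression values must form a 2-D matrix")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        for kind, ids in (("probe", self.probe_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise FormatError(f"duplicate {kind} id: {dup!r}")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def probe_index(self, probe_id: str) -> int:
        try:
            return self.probe_ids.index(probe_id)
        except ValueError:
            raise KeyError(f"probe {probe_id!r} not present in matrix") from None

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionMatrix":
        rows = [self.probe_index(p) for p in probe_ids]
        return ExpressionMatrix(list(probe_ids), list(self.sample_ids), self.values[rows, :])

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            cols = [index[s] for s in sample_ids]
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not present in matrix") from None
        return ExpressionMatrix(list(self.probe_ids), list(sample_ids), self.values[:, cols])

    def sample_values(self, sample_id: str) -> dict[str, float]:
        """Probe -> value mapping for one sample."""
        col = self.values[:, self.sample_ids.index(sample_id)]
        return dict(zip(self.probe_ids, col.tolist()))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df) -> "ExpressionMatrix":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(dtype=float))


@dataclass
class SampleMetadata:
    """One annotated sample: identifier, recorded sex and optional linking info."""

    sample_id: str
    annotated_sex: str  # {female, male, unknown}
    subject_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if self.annotated_sex not in ("female", "male", "unknown"):
            raise MetadataError(f"invalid normalized sex value: {self.annotated_sex!r}")


def _first_duplicate(ids: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            return i
        seen.add(i)
    return None


def _unquote(token: str) -> str:
    token = token.strip()
    if len(token) >= 2 and token[0] == '"' and token[-1] == '"':
        token = token[1:-1]
    return token


def _parse_value(token: str, path: Path, row: str) -> float:
    token = _unquote(token)
    if token.lower() in _MISSING_VALUE_TOKENS:
        return math.nan
    try:
        return float(token)
    except ValueError:
        raise FormatError(f"{path}: non-numeric value {token!r} in row {row!r}") from None


def normalize_sex(token: str) -> str:
    """Map a raw sex annotation to {female, male, unknown} or raise."""
    key = token.strip().lower()
    if key not in SEX_SYNONYMS:
        raise MetadataError(f"unrecognized sex token: {token!r}")
    return SEX_SYNONYMS[key]


def _extract_series_matrix_table(lines: list[str], path: Path) -> list[str]:
    begin = end = None
    for i, line in enumerate(lines):
        stripped = line.strip()
        if stripped == SERIES_TABLE_BEGIN:
            begin = i
        elif stripped == SERIES_TABLE_END:
            end = i
    if begin is None or end is None or end <= begin:
        raise FormatError(
            f"{path}: series-matrix table delimiters "
            f"{SERIES_TABLE_BEGIN!r}/{SERIES_TABLE_END!r} not found"
        )
    # All other '!'-prefixed lines are header/comment lines and are ignored.
    return [l for l in lines[begin + 1 : end] if not l.startswith("!")]


def read_expression_matrix(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a probe-by-sample matrix from a TSV or GEO series-matrix file.

    Parameters
    ----------
    path
        Input file.  First row holds sample identifiers, first column probe
        identifiers.
    dialect
        ``"tsv"`` for a bare table, ``"series_matrix"`` for a table wrapped in
        GEO series-matrix delimiter lines.
    """
    path = Path(path)
    if dialect not in ("tsv", "series_matrix"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    with open(path, newline="") as fh:
        lines = [line.rstrip("\n").rstrip("\r") for line in fh]
    if dialect == "series_matrix":
        lines = _extract_series_matrix_table(lines, path)
    rows = [line.split("\t") for line in lines if line.strip() != ""]
    if len(rows) < 2:
        raise FormatError(f"{path}: empty expression table")
    header = [_unquote(t) for t in rows[0]]
    sample_ids = header[1:]
    if not sample_ids:
        raise FormatError(f"{path}: no sample columns")
    width = len(header)
    probe_ids: list[str] = []
    data = np.empty((len(rows) - 1, len(sample_ids)), dtype=float)
    for r, row in enumerate(rows[1:]):
        if len(row) != width:
            raise FormatError(
                f"{path}: ragged row {r + 2} has {len(row)} fields, expected {width}"
            )
        probe_ids.append(_unquote(row[0]))
        data[r, :] = [_parse_value(tok, path, row[0]) for tok in row[1:]]
    return ExpressionMatrix(probe_ids, sample_ids, data)


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read a sample metadata TSV with at least ``sample_id`` and ``sex`` columns.

    Optional columns ``subject_id`` and ``group`` are carried through.  Sex
    values are normalized via :data:`SEX_SYNONYMS`; unknown tokens and
    duplicate sample ids are hard errors.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise MetadataError(f"{path}: empty metadata file")
        fields = [f.strip() for f in reader.fieldnames]
        for required in ("sample_id", "sex"):
            if required not in fields:
                raise MetadataError(f"{path}: missing required column {required!r}")
        records: list[SampleMetadata] = []
        seen: set[str] = set()
        for row in reader:
            sample_id = _unquote(row["sample_id"])
            if sample_id in seen:
                raise MetadataError(f"{path}: duplicate sample_id {sample_id!r}")
            seen.add(sample_id)
            subject = _unquote(row.get("subject_id") or "") or None
            group = _unquote(row.get("group") or "") or None
            records.append(
                SampleMetadata(
                    sample_id=sample_id,
                    annotated_sex=normalize_sex(row["sex"] or ""),
                    subject_id=subject,
                    group=group,
                )
            )
    if not records:
        raise MetadataError(f"{path}: no sample rows")
    return records


_REPORT_COLUMNS = ("sample_id", "annotated_sex", "cluster_sex", "D", "final_call", "status")


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        return repr(value)
    return str(value)


def write_report(report: "DatasetReport", path: str | Path) -> None:
    """Write a per-sample report TSV plus a JSON summary sidecar.

    The TSV has columns ``sample_id, annotated_sex, cluster_sex, D,
    final_call, status``.  The sidecar at ``<path>.summary.json`` holds the
    dataset-level counts and status and is what :func:`sexqc.report.summarize_corpus`
    consumes when auditing a directory of reports.
    """
    path = Path(path)
    try:
        with open(path, "w", newline="") as fh:
            fh.write("\t".join(_REPORT_COLUMNS) + "\n")
            for call in report.calls:
                fh.write(
                    "\t".join(
                        [
                            call.sample_id,
                            report.annotated[call.sample_id],
                            _fmt(call.cluster_sex),
                            _fmt(call.D),
                            call.final_call,
                            report.sample_status[call.sample_id],
                        ]
                    )
                    + "\n"
                )
        with open(_sidecar_path(path), "w") as fh:
            json.dump(report.summary_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".summary.json")


def read_report(path: str | Path) -> "DatasetReport":
    """Re-read a report written by :func:`write_report` (round-trip safe)."""
    from .inference import SexCall
    from .report import DatasetReport

    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or tuple(reader.fieldnames) != _REPORT_COLUMNS:
            raise FormatError(f"{path}: not a sexqc per-sample report")
        calls: list[SexCall] = []
        annotated: dict[str, str] = {}
        status: dict[str, str] = {}
        for row in reader:
            d_tok = row["D"]
            d_val = None if d_tok == "NA" else float(d_tok)
            cluster = None if row["cluster_sex"] == "NA" else row["cluster_sex"]
            calls.append(
                SexCall(
                    sample_id=row["sample_id"],
                    cluster_sex=cluster,
                    D=d_val,
                    final_call=row["final_call"],
                )
            )
            annotated[row["sample_id"]] = row["annotated_sex"]
            status[row["sample_id"]] = row["status"]
    with open(_sidecar_path(path)) as fh:
        summary = json.load(fh)
    return DatasetReport(
        dataset_id=summary["dataset_id"],
        calls=calls,
        annotated=annotated,
        sample_status=status,
        n_ambiguous_cluster_discrepant=summary["n_ambiguous_cluster_discrepant"],
        subject_by_sample=summary.get("subject_by_sample") or {},
    )
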