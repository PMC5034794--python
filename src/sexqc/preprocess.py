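"""Bring raw expression matrices to analysis scale: log2 + quantile normalization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import PreprocessError
from .io import ExpressionMatrix

__all__ = ["PreprocessConfig", "log2_quantile_normalize", "quantile_normalize_values"]


@dataclass
class PreprocessConfig:
    """Controls the log2 step of preprocessing.

    ``force_log`` is tri-state: ``"auto"`` applies log2 when the matrix
    maximum exceeds ``log_detect_threshold`` (a matrix already on log2 scale
    never gets near 30), ``"always"``/``"never"`` override the heuristic.
    """

    log_detect_threshold: float = 30.0
    force_log: str = "auto"

    def __post_init__(self) -> None:
        if self.log_detect_threshold <= 0:
            raise ValueError("log_detect_threshold must be > 0")
        if self.force_log not in ("auto", "always", "never"):
            raise ValueError(f"invalid force_log: {self.force_log!r}")


def _quantile_normalize_dense(x: np.ndarray) -> np.ndarray:
    # Rank-mean algorithm: replace the value at rank r in each column by the
    # mean of the r-th order statistics across columns.  Tied values receive
    # the mean of the rank-means they span.
    mu = np.sort(x, axis=0).mean(axis=1)
    rmin = rankdata(x, method="min", axis=0).astype(int)
    rmax = rankdata(x, method="max", axis=0).astype(int)
    cum = np.concatenate([[0.0], np.cumsum(mu)])
    return (cum[rmax] - cum[rmin - 1]) / (rmax - rmin + 1)


def _quantile_normalize_with_missing(x: np.ndarray) -> np.ndarray:
    # Missing entries stay missing; observed values in each column are mapped
    # onto the mean quantile curve by interpolation (limma-style handling).
    n_rows, n_cols = x.shape
    grid = (np.arange(n_rows) + 0.5) / n_rows
    curves = np.empty((n_rows, n_cols))
    for j in range(n_cols):
        col = x[:, j]
        obs = np.sort(col[np.isfinite(col)])
        if obs.size == 0:
            raise PreprocessError(f"column {j} has no observed values")
        q = (np.arange(obs.size) + 0.5) / obs.size
        curves[:, j] = np.interp(grid, q, obs)
    ref = curves.mean(axis=1)
    out = np.full_like(x, np.nan)
    for j in range(n_cols):
        col = x[:, j]
        mask = np.isfinite(col)
        ranks = rankdata(col[mask], method="average")
        out[mask, j] = np.interp((ranks - 0.5) / mask.sum(), grid, ref)
    return out


def quantile_normalize_values(x: np.ndarray) -> np.ndarray:
    """Quantile-normalize a probes-by-samples array (columns = samples)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise PreprocessError("expected a 2-D array")
    if x.shape[1] < 2:
        raise PreprocessError("quantile normalization needs at least 2 samples")
    if np.isnan(x).any():
        return _quantile_normalize_with_missing(x)
    return _quantile_normalize_dense(x)


def log2_quantile_normalize(
    m: ExpressionMatrix, cfg: PreprocessConfig | None = None
) -> ExpressionMatrix:
    """Optionally log2-transform, then quantile-normalize, an expression matrix.

    After normalization every (complete) column carries the identical multiset
    of values and the within-column rank order is preserved.
    """
    cfg = cfg or PreprocessConfig()
    if m.n_samples < 2:
        raise PreprocessError("quantile normalization undefined for a single sample")
    values = m.values
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise PreprocessError("matrix has no observed values")
    apply_log = cfg.force_log == "always" or (
        cfg.force_log == "auto" and finite.max() > cfg.log_detect_threshold
    )
    if apply_log:
        if (finite <= 0).any():
            raise PreprocessError("non-positive value encountered while log2-transforming")
        values = np.log2(values)
    normalized = quantile_normalize_values(values)
    return ExpressionMatrix(list(m.probe_ids), list(m.sample_ids), normalized)
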