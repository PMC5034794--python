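"""Per-sample sex inference from marker expression.

Samples are clustered into two groups by k-means on the marker probes
(unscaled log2 values), clusters are labeled female/male from their centroid
geometry, and each sample's cluster sex is checked against the sign of its
median-difference score

    D = median(female-marker values) - median(male-marker values).

A sample whose cluster sex and score sign disagree (or whose score is exactly
zero, or that lacks marker values) gets no confident call and is reported as
``ambiguous``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from sklearn.cluster import KMeans

from .errors import ClusteringError, DegenerateClusteringError, LabelingError, ScoreError
from .io import ExpressionMatrix
from .markers import MarkerPanel

__all__ = [
    "SexCall",
    "ClusterResult",
    "cluster_samples",
    "label_clusters",
    "median_sex_score",
    "call_sample_sex",
    "assign_sex",
]

DEFAULT_RESTARTS = 25
DEFAULT_SEED = 0


@dataclass
class SexCall:
    """Final per-sample record.

    ``cluster_sex`` is ``None`` for samples excluded from clustering because
    of missing marker values; such samples are always ``ambiguous``.
    """

    sample_id: str
    cluster_sex: str | None
    D: float | None
    final_call: str


@dataclass
class ClusterResult:
    sample_ids: list[str]
    assignment: dict[str, int]
    centroids: np.ndarray  # shape (2, n_probes)
    probe_ids: list[str]
    inertia: float
    n_restarts: int
    seed: int


def cluster_samples(
    m: ExpressionMatrix, restarts: int = DEFAULT_RESTARTS, seed: int = DEFAULT_SEED
) -> ClusterResult:
    """Two-cluster Lloyd's k-means over samples, best of ``restarts`` random starts.

    ``m`` must already be restricted to panel probes.  Samples containing any
    missing value are excluded from clustering (the caller forces them
    ambiguous).  Deterministic given ``seed``.
    """
    if m.n_probes < 1:
        raise ClusteringError("no probes to cluster on")
    complete = [s for i, s in enumerate(m.sample_ids) if np.isfinite(m.values[:, i]).all()]
    if len(complete) < 2:
        raise ClusteringError("need at least 2 samples with complete marker data")
    x = m.subset_samples(complete).values.T  # samples x probes
    if np.allclose(x, x[0]):
        raise DegenerateClusteringError("all samples have identical marker values")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        km = KMeans(
            n_clusters=2,
            init="random",
            n_init=restarts,
            algorithm="lloyd",
            random_state=seed,
        ).fit(x)
    labels = km.labels_.astype(int)
    if len(set(labels)) < 2:
        raise DegenerateClusteringError("best k-means solution has an empty cluster")
    if np.allclose(km.cluster_centers_[0], km.cluster_centers_[1]):
        raise DegenerateClusteringError("cluster centroids coincide")
    return ClusterResult(
        sample_ids=complete,
        assignment=dict(zip(complete, labels.tolist())),
        centroids=km.cluster_centers_.copy(),
        probe_ids=list(m.probe_ids),
        inertia=float(km.inertia_),
        n_restarts=restarts,
        seed=seed,
    )


def label_clusters(cr: ClusterResult, panel: MarkerPanel) -> dict[int, str]:
    """Map cluster indices to sexes by a per-probe centroid vote.

    Each female-marker probe votes for its higher-centroid cluster as the
    female cluster; each male-marker probe votes for its lower-centroid
    cluster.  Probes with exactly equal centroids abstain.  A tied vote is a
    labeling failure (no calls can be emitted for the dataset).
    """
    votes = {0: 0, 1: 0}  # votes for "cluster i is the female cluster"
    for j, probe_id in enumerate(cr.probe_ids):
        direction = panel.direction_of(probe_id)
        c0, c1 = cr.centroids[0, j], cr.centroids[1, j]
        if c0 == c1:
            continue
        higher = 0 if c0 > c1 else 1
        if direction == "female_high":
            votes[higher] += 1
        else:
            votes[1 - higher] += 1
    if votes[0] == votes[1]:
        raise LabelingError(f"tied centroid vote ({votes[0]} vs {votes[1]}); cannot label clusters")
    female = 0 if votes[0] > votes[1] else 1
    return {female: "female", 1 - female: "male"}


def median_sex_score(expression: Mapping[str, float], panel: MarkerPanel) -> float:
    """D = median over female-marker values minus median over male-marker values.

    The male-marker median pools all male-direction probesets (KDM5D and
    RPS4Y1 together).  Raises :class:`ScoreError` when either direction has no
    finite value.
    """
    female_vals = [
        expression[p]
        for p in panel.probes_with_direction("female_high")
        if p in expression and math.isfinite(expression[p])
    ]
    male_vals = [
        expression[p]
        for p in panel.probes_with_direction("male_high")
        if p in expression and math.isfinite(expression[p])
    ]
    if not female_vals or not male_vals:
        raise ScoreError("median sex score undefined: a marker direction has no values")
    return float(np.median(female_vals) - np.median(male_vals))


def call_sample_sex(cluster_sex: str, D: float) -> str:
    """Final call: the cluster sex when the score sign agrees, else ambiguous.

    ``D == 0`` (and non-finite D) never agrees with either cluster sex.
    """
    if cluster_sex not in ("female", "male"):
        raise ValueError(f"invalid cluster sex: {cluster_sex!r}")
    if D is None or not math.isfinite(D):
        return "ambiguous"
    if cluster_sex == "female" and D > 0:
        return "female"
    if cluster_sex == "male" and D < 0:
        return "male"
    return "ambiguous"


def assign_sex(
    m: ExpressionMatrix,
    panel: MarkerPanel,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = DEFAULT_SEED,
) -> list[SexCall]:
    """Run clustering, labeling and scoring over a full dataset.

    Returns one :class:`SexCall` per sample in matrix order.  Samples with
    incomplete marker data are excluded from clustering and called ambiguous
    (their D is still reported when both directions have a value).
    """
    panel.require_both_directions()
    sub = m.subset_probes(panel.probe_ids)
    cr = cluster_samples(sub, restarts=restarts, seed=seed)
    sex_of_cluster = label_clusters(cr, panel)
    calls: list[SexCall] = []
    for sample_id in m.sample_ids:
        expression = sub.sample_values(sample_id)
        try:
            d_val: float | None = median_sex_score(expression, panel)
        except ScoreError:
            d_val = None
        if sample_id in cr.assignment:
            cluster_sex = sex_of_cluster[cr.assignment[sample_id]]
            final = call_sample_sex(cluster_sex, d_val) if d_val is not None else "ambiguous"
        else:
            cluster_sex, final = None, "ambiguous"
        calls.append(SexCall(sample_id=sample_id, cluster_sex=cluster_sex, D=d_val, final_call=final))
    return calls
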