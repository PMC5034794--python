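"""Synthetic expression data with planted annotation errors.

The generator emulates the bimodal log2 pattern the detector relies on:
female-marker probes are expressed (``mu_on``) in females and silent
(``mu_off``) in males, male-marker probes the reverse, with Gaussian noise on
the log2 scale.  It can plant

* label swaps — the annotation is flipped while expression follows true sex
  (the tube-swap signature the detector targets);
* ambiguous samples — every marker sits exactly at the midpoint
  ``(mu_on + mu_off) / 2``, so the median-difference score is exactly zero
  and no confident call is possible;
* a poor-performing probeset — one extra female-assigned probe whose values
  are independent of sex, for exercising correlation-based filtering.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .io import ExpressionMatrix, SampleMetadata
from .markers import GENE_DIRECTIONS, MarkerPanel, MarkerProbe

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimulatedDataset",
    "generate_dataset",
    "generate_corpus",
    "generate_shared_cohort",
    "panel_for_config",
    "BAD_PROBE_ID",
]

BAD_PROBE_ID = "XIST_bad"

_DEFAULT_PROBES = {"XIST": 2, "KDM5D": 1, "RPS4Y1": 1}


@dataclass
class SimConfig:
    n_samples: int = 50
    p_female: float = 0.5
    mu_on: float = 10.0
    mu_off: float = 5.0
    sigma: float = 0.3
    probes_per_gene: Mapping[str, int] = field(default_factory=lambda: dict(_DEFAULT_PROBES))
    n_mislabels: int = 0
    n_ambiguous: int = 0
    bad_probe: bool = False
    n_background_probes: int = 50
    heavy_tails: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0 <= self.p_female <= 1:
            raise ValueError("p_female must be a proportion")
        if self.mu_on <= self.mu_off:
            raise ValueError("mu_on must exceed mu_off")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.n_mislabels < 0 or self.n_ambiguous < 0:
            raise ValueError("planted counts must be non-negative")
        if self.n_mislabels + self.n_ambiguous > self.n_samples:
            raise ValueError("cannot plant more mislabels + ambiguous samples than samples")
        for gene in self.probes_per_gene:
            if gene not in GENE_DIRECTIONS:
                raise ValueError(f"unknown marker gene: {gene!r}")
        if not any(self.probes_per_gene.get(g, 0) > 0 for g in ("XIST",)):
            raise ValueError("need at least one female-marker probe")
        if not any(self.probes_per_gene.get(g, 0) > 0 for g in ("KDM5D", "RPS4Y1")):
            raise ValueError("need at least one male-marker probe")


@dataclass
class SimTruth:
    true_sex: dict[str, str]
    mislabeled_ids: list[str]
    ambiguous_ids: list[str]
    bad_probe_id: str | None


@dataclass
class SimulatedDataset:
    dataset_id: str
    matrix: ExpressionMatrix
    metadata: list[SampleMetadata]
    truth: SimTruth


def panel_for_config(cfg: SimConfig) -> MarkerPanel:
    """The marker panel matching a generated matrix (bad probe included)."""
    entries = []
    for gene, count in cfg.probes_per_gene.items():
        for i in range(count):
            entries.append(MarkerProbe(f"{gene}_{i + 1}", gene, GENE_DIRECTIONS[gene]))
    if cfg.bad_probe:
        entries.append(MarkerProbe(BAD_PROBE_ID, "XIST", "female_high"))
    return MarkerPanel(entries, platform="synthetic")


def _flip(sex: str) -> str:
    return "male" if sex == "female" else "female"


def _noise(rng: np.random.Generator, cfg: SimConfig, size) -> np.ndarray:
    if cfg.heavy_tails:
        return cfg.sigma * rng.standard_t(df=3, size=size)
    return rng.normal(0.0, cfg.sigma, size=size)


def generate_dataset(
    cfg: SimConfig,
    *,
    dataset_id: str = "sim",
    rng: np.random.Generator | None = None,
    sample_ids: Sequence[str] | None = None,
    subject_ids: Sequence[str | None] | None = None,
    true_sex: Sequence[str] | None = None,
    mislabel_ids: Sequence[str] | None = None,
    ambiguous_ids: Sequence[str] | None = None,
) -> tuple[ExpressionMatrix, list[SampleMetadata], SimTruth]:
    """Draw one expression matrix with (optionally corrupted) metadata.

    The keyword overrides let corpus-level generators control sexes, planted
    samples and identifiers; by default everything is drawn from ``cfg.seed``.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    if sample_ids is None:
        sample_ids = [f"{dataset_id}_S{i + 1:04d}" for i in range(n)]
    sample_ids = list(sample_ids)
    if len(sample_ids) != n:
        raise ValueError("sample_ids length must equal n_samples")

    if true_sex is None:
        true_sex = np.where(rng.random(n) < cfg.p_female, "female", "male").tolist()
    true_sex = list(true_sex)

    if ambiguous_ids is None:
        ambiguous_ids = rng.choice(sample_ids, size=cfg.n_ambiguous, replace=False).tolist()
    ambiguous_ids = list(ambiguous_ids)
    if mislabel_ids is None:
        eligible = [s for s in sample_ids if s not in set(ambiguous_ids)]
        if cfg.n_mislabels > len(eligible):
            raise ValueError("not enough non-ambiguous samples to mislabel")
        mislabel_ids = rng.choice(eligible, size=cfg.n_mislabels, replace=False).tolist()
    mislabel_ids = list(mislabel_ids)
    if set(mislabel_ids) & set(ambiguous_ids):
        raise ValueError("mislabeled and ambiguous sample sets must be disjoint")

    panel = panel_for_config(cfg)
    mid = (cfg.mu_on + cfg.mu_off) / 2.0
    ambiguous = set(ambiguous_ids)
    probe_ids: list[str] = []
    rows: list[np.ndarray] = []
    for entry in panel.entries:
        probe_ids.append(entry.probe_id)
        if entry.probe_id == BAD_PROBE_ID:
            base = np.full(n, mid)  # sex-independent
        else:
            on_for_female = entry.direction == "female_high"
            expressed = np.array([(s == "female") == on_for_female for s in true_sex])
            base = np.where(expressed, cfg.mu_on, cfg.mu_off).astype(float)
        row = base + _noise(rng, cfg, n)
        row[[s in ambiguous for s in sample_ids]] = mid
        rows.append(row)
    for b in range(cfg.n_background_probes):
        probe_ids.append(f"BG_{b + 1:05d}")
        rows.append(cfg.mu_off + _noise(rng, cfg, n))

    matrix = ExpressionMatrix(probe_ids, sample_ids, np.vstack(rows))
    mislabeled = set(mislabel_ids)
    metadata = []
    for i, sample_id in enumerate(sample_ids):
        annotated = _flip(true_sex[i]) if sample_id in mislabeled else true_sex[i]
        metadata.append(
            SampleMetadata(
                sample_id=sample_id,
                annotated_sex=annotated,
                subject_id=None if subject_ids is None else subject_ids[i],
            )
        )
    truth = SimTruth(
        true_sex=dict(zip(sample_ids, true_sex)),
        mislabeled_ids=mislabel_ids,
        ambiguous_ids=ambiguous_ids,
        bad_probe_id=BAD_PROBE_ID if cfg.bad_probe else None,
    )
    return matrix, metadata, truth


def generate_corpus(
    n_datasets: int,
    affected: int,
    cfg: SimConfig | None = None,
    seed: int = 0,
) -> list[SimulatedDataset]:
    """Generate a corpus where exactly ``affected`` datasets carry mislabels.

    Affected datasets receive ``max(1, cfg.n_mislabels)`` planted swaps; the
    rest receive none.  Which datasets are affected, and each dataset's
    stream, derive deterministically from ``seed``.
    """
    if not 0 <= affected <= n_datasets:
        raise ValueError("require 0 <= affected <= n_datasets")
    cfg = cfg or SimConfig()
    master = np.random.default_rng(seed)
    affected_idx = set(master.choice(n_datasets, size=affected, replace=False).tolist())
    children = np.random.SeedSequence(seed).spawn(n_datasets)
    corpus: list[SimulatedDataset] = []
    for i in range(n_datasets):
        dataset_id = f"D{i + 1:03d}"
        n_mislabels = max(1, cfg.n_mislabels) if i in affected_idx else 0
        dcfg = replace(cfg, n_mislabels=n_mislabels)
        matrix, metadata, truth = generate_dataset(
            dcfg, dataset_id=dataset_id, rng=np.random.default_rng(children[i])
        )
        corpus.append(SimulatedDataset(dataset_id, matrix, metadata, truth))
    return corpus


def generate_shared_cohort(
    n_studies: int,
    n_subjects: int,
    swaps_per_study: Sequence[int],
    n_metadata_errors: int = 0,
    cfg: SimConfig | None = None,
    seed: int = 0,
) -> tuple[list[SimulatedDataset], dict]:
    """Generate studies that all assay the same cohort of subjects.

    Metadata-error subjects carry a wrong annotation in *every* study;
    swapped subjects are discrepant in exactly one study each (swaps are
    planted disjointly across studies), so cross-study concordance can
    separate the two classes.  Returns the studies plus a truth dict with the
    planted classes.
    """
    if len(swaps_per_study) != n_studies:
        raise ValueError("swaps_per_study must have one entry per study")
    if n_metadata_errors + sum(swaps_per_study) > n_subjects:
        raise ValueError("more planted discrepancies than subjects")
    cfg = cfg or SimConfig()
    cfg = replace(cfg, n_samples=n_subjects, n_mislabels=0, n_ambiguous=0)
    master = np.random.default_rng(seed)
    subjects = [f"P{i + 1:04d}" for i in range(n_subjects)]
    true_sex = np.where(master.random(n_subjects) < cfg.p_female, "female", "male").tolist()
    pool = list(subjects)
    meta_error_subjects = master.choice(pool, size=n_metadata_errors, replace=False).tolist()
    pool = [s for s in pool if s not in set(meta_error_subjects)]
    mixups: dict[str, list[str]] = {}
    children = np.random.SeedSequence(seed).spawn(n_studies)
    studies: list[SimulatedDataset] = []
    for i in range(n_studies):
        study_id = f"Study{i + 1}"
        swapped = master.choice(pool, size=swaps_per_study[i], replace=False).tolist()
        pool = [s for s in pool if s not in set(swapped)]
        mixups[study_id] = swapped
        sample_ids = [f"{study_id}_{subj}" for subj in subjects]
        # Both planted classes manifest as annotation contradicting expression
        # in a study; the classes differ in *which* studies are affected.
        discrepant = set(meta_error_subjects) | set(swapped)
        mislabel_ids = [f"{study_id}_{subj}" for subj in subjects if subj in discrepant]
        matrix, metadata, truth = generate_dataset(
            cfg,
            dataset_id=study_id,
            rng=np.random.default_rng(children[i]),
            sample_ids=sample_ids,
            subject_ids=subjects,
            true_sex=true_sex,
            mislabel_ids=mislabel_ids,
            ambiguous_ids=[],
        )
        studies.append(SimulatedDataset(study_id, matrix, metadata, truth))
    truth_dict = {
        "true_sex": dict(zip(subjects, true_sex)),
        "metadata_error_subjects": meta_error_subjects,
        "mixup_subjects": mixups,
    }
    return studies, truth_dict
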