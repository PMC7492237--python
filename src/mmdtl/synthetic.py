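"""Synthetic source / intermediate / target cohorts for end-to-end testing.

The generator emulates the statistical structure the transfer framework
assumes, without simulating BOLD time series: correlation-valued connectome
edges arise from a low-rank latent-factor model shared (controllably) across
cohorts, with additive per-site offsets, per-task planted discriminative
edges, and a small mixed-type clinical table.

* Source cohort: large, multi-site (17 sites by default), one binary label
  whose positive class shifts the task factors — the stand-in for a labeled
  autism-vs-control collection.
* Intermediate cohort: unlabeled, same latent factors but shifted factor
  means (a domain gap), the stand-in for unlabeled neonatal scans.
* Target cohort: small (33 by default), three positively correlated binary
  outcomes at the published prevalences (5/33, 7/33, 5/33), plus an
  84-column clinical table with predictive and decoy features.

The first C latent factors are task-specific outcome factors and factor C is
a shared outcome factor; all have dense loadings like the background factors
(so they carry reconstruction variance and an autoencoder has reason to
encode them — the premise that makes unsupervised adaptation transferable)
plus boosted loadings on their planted-edge support.  The shared factor owns
the 9 edges common to all three tasks and carries most of the label signal
(co-occurring deficits share a pathway — the premise that makes joint
multi-task training pay off); each task factor owns its task-specific edges,
giving 20 planted edges per task, mirroring the overlap structure of
discriminative connections reported for real cohorts.  Planted edges are the
individually most discriminative edges.  Labels are assigned by exact counts
(not Bernoulli draws) so tiny-cohort tests are deterministic in class
composition; the separation delta shifts positives along the shared outcome
factor (scaled by each subject's overall risk load) and, attenuated by
task_delta_fraction, along their task-specific factor, so delta = 0 makes
labels independent of features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import ClinicalDictionary, SubjectRecord, n_edges

__all__ = [
    "SyntheticConfig",
    "TargetCohort",
    "generate_source_cohort",
    "generate_intermediate_cohort",
    "generate_target_cohort",
    "planted_edges",
    "make_time_series",
]

TASK_NAMES = ("cognitive", "language", "motor")
DOMAINS = (
    "maternal_demographics",
    "pregnancy_complications",
    "labor_delivery",
    "neonatal_birth",
    "medical_history",
    "followup",
)


@dataclass
class SyntheticConfig:
    """Study conditions of the simulated three-cohort design."""

    n_roi: int = 90
    n_source: int = 884
    n_intermediate: int = 291
    n_target: int = 33
    n_sites: int = 17                 # source cohort sites
    site_sd: float = 0.3              # SD of per-site additive edge offsets
    n_factors: int = 8                # latent factors (first C+1 outcome-related)
    loading_sd: float = 0.4           # background factor loading SD (dense)
    task_dense_sd: float = 0.4        # outcome factors' dense loading SD
    task_loading: float = 3.0         # loading boost on planted edges
    squash_scale: float = 0.25        # pre-tanh scale; < 1 keeps edges near-linear
    task_count: int = 3
    prevalence: tuple[float, ...] = (0.15, 0.21, 0.15)
    n_planted_common: int = 9         # edges shared by all task factors
    n_planted_per_task: int = 20      # total planted edges per task
    delta: float = 4.0                # shared-factor shift for positive subjects
    task_delta_fraction: float = 0.25  # task-specific shift as a fraction of delta
    source_delta: float = 1.0         # factor shift for source positives
    task_label_correlation: float = 0.6
    # cosine between the adult/source domain's dense factor structure and the
    # neonatal (intermediate + target) domain's: the gap stage 2 must bridge
    source_neonate_sharing: float = 0.5
    # cosine between target and intermediate loadings (1 = same neonatal
    # domain); 0 makes the target unrelated to both pre-training cohorts
    latent_sharing: float = 1.0
    n_clinical: int = 84
    n_clinical_predictive: int = 10
    clinical_effect: float = 0.8
    noise_sd: float = 0.5
    intermediate_shift: float = 0.5   # factor-mean domain gap
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.prevalence) != self.task_count:
            raise ValueError("one prevalence per task required")
        if any(not (0.0 < p < 1.0) for p in self.prevalence):
            raise ValueError("prevalences must lie in (0, 1)")
        if self.n_planted_common > self.n_planted_per_task:
            raise ValueError("common planted edges cannot exceed per-task count")
        if not (0.0 <= self.latent_sharing <= 1.0):
            raise ValueError("latent_sharing must lie in [0, 1]")
        if self.n_factors < self.task_count + 2:
            raise ValueError(
                "need at least task_count + 1 outcome factors plus one "
                "background factor"
            )

    @property
    def n_edges(self) -> int:
        return n_edges(self.n_roi)

    def positive_counts(self) -> list[int]:
        counts = [int(round(p * self.n_target)) for p in self.prevalence]
        if any(c < 1 for c in counts):
            raise ValueError("prevalence * n_target < 1 for some task")
        return counts


@dataclass
class TargetCohort:
    """Target records plus the raw clinical table and its dictionary."""

    records: list[SubjectRecord]
    clinical_table: pd.DataFrame
    clinical_dictionary: ClinicalDictionary
    risk: np.ndarray = field(default=None)  # latent per-subject mean risk


def _dense(cfg: SyntheticConfig, stream: int) -> np.ndarray:
    rng = np.random.default_rng((cfg.seed, stream))
    L = rng.normal(0.0, cfg.loading_sd, (cfg.n_factors, cfg.n_edges))
    L[: cfg.task_count + 1] = rng.normal(
        0.0, cfg.task_dense_sd, (cfg.task_count + 1, cfg.n_edges)
    )
    return L


def _boosts(cfg: SyntheticConfig):
    """Domain-invariant planted supports and signed boosts."""
    zero = np.zeros((cfg.n_factors, cfg.n_edges))
    # reuse _loadings machinery on a zero dense part
    support_rng = np.random.default_rng((cfg.seed, 101))
    all_edges = support_rng.permutation(cfg.n_edges)
    common = all_edges[: cfg.n_planted_common]
    zero[cfg.task_count, common] += cfg.task_loading * support_rng.choice(
        [-1.0, 1.0], len(common)
    )
    cursor = cfg.n_planted_common
    planted: list[np.ndarray] = []
    for c in range(cfg.task_count):
        extra_n = cfg.n_planted_per_task - cfg.n_planted_common
        extra = all_edges[cursor: cursor + extra_n]
        cursor += extra_n
        zero[c, extra] += cfg.task_loading * support_rng.choice(
            [-1.0, 1.0], len(extra)
        )
        planted.append(np.sort(np.concatenate([common, extra])))
    return zero, planted


def _cohort_loadings(cfg: SyntheticConfig, cohort: str):
    """Loadings seen by one cohort, reflecting the two-hop domain geometry.

    The source (adult) domain and the neonatal domain (intermediate and
    target cohorts) share the planted boosts but their dense factor
    structures only overlap with cosine ``source_neonate_sharing`` — the gap
    the unsupervised adaptation stage exists to bridge.  ``latent_sharing``
    blends the target's dense structure with the neonatal domain's; at 0 the
    target is unrelated to both pre-training cohorts (negative control).
    """
    boosts, planted = _boosts(cfg)
    dense_src = _dense(cfg, 102)
    if cohort == "source":
        return dense_src + boosts, planted
    g = cfg.source_neonate_sharing
    dense_neo = g * dense_src + np.sqrt(1.0 - g**2) * _dense(cfg, 103)
    if cohort == "intermediate":
        return dense_neo + boosts, planted
    t = cfg.latent_sharing
    dense_tgt = t * dense_neo + np.sqrt(1.0 - t**2) * _dense(cfg, 104)
    return dense_tgt + boosts, planted


def _edges_from_factors(z, L, site_offsets, rng, cfg):
    raw = z @ L + site_offsets + rng.normal(0.0, cfg.noise_sd, (len(z), cfg.n_edges))
    return np.tanh(cfg.squash_scale * raw)


def planted_edges(cfg: SyntheticConfig) -> list[np.ndarray]:
    """Per-task planted edge indices (sorted), as seen by the target cohort."""
    _, planted = _cohort_loadings(cfg, "target")
    return planted


def generate_source_cohort(cfg: SyntheticConfig, seed: int) -> list[SubjectRecord]:
    """Large labeled multi-site cohort; exactly half the subjects positive."""
    rng = np.random.default_rng((cfg.seed, seed, 1))
    L, _ = _cohort_loadings(cfg, "source")
    n = cfg.n_source
    sites = np.arange(n) % cfg.n_sites
    site_vectors = rng.normal(0.0, cfg.site_sd, (cfg.n_sites, cfg.n_edges))
    y = np.zeros(n, dtype=int)
    y[rng.permutation(n)[: n // 2]] = 1
    z = rng.normal(0.0, 1.0, (n, cfg.n_factors))
    z[y == 1, : cfg.task_count + 1] += cfg.source_delta
    X = _edges_from_factors(z, L, site_vectors[sites], rng, cfg)
    return [
        SubjectRecord(
            f"src{i:04d}", f"site{sites[i]:02d}", "source", X[i],
            labels={"source_task": int(y[i])},
        )
        for i in range(n)
    ]


def generate_intermediate_cohort(cfg: SyntheticConfig, seed: int) -> list[SubjectRecord]:
    """Unlabeled cohort sharing latent structure with a shifted factor mean."""
    rng = np.random.default_rng((cfg.seed, seed, 2))
    L, _ = _cohort_loadings(cfg, "intermediate")
    n = cfg.n_intermediate
    shift = rng.normal(0.0, cfg.intermediate_shift, cfg.n_factors)
    z = rng.normal(0.0, 1.0, (n, cfg.n_factors)) + shift
    X = _edges_from_factors(z, L, 0.0, rng, cfg)
    return [
        SubjectRecord(f"int{i:04d}", "site_int", "intermediate", X[i])
        for i in range(n)
    ]


def _exact_count_labels(scores: np.ndarray, n_pos: int) -> np.ndarray:
    """1 for the n_pos highest scores — exact class counts by construction."""
    y = np.zeros(len(scores), dtype=int)
    y[np.argsort(-scores, kind="stable")[:n_pos]] = 1
    return y


def _clinical_table(cfg, rng, risk, sites) -> tuple[pd.DataFrame, ClinicalDictionary]:
    n = len(risk)
    n_cat = max(cfg.n_clinical // 10, 1)
    n_bin = max(cfg.n_clinical // 5, 1)
    n_cont = cfg.n_clinical - n_cat - n_bin
    entries, data = [], {}
    for j in range(n_cont):
        name = f"cont{j:02d}"
        entries.append((name, "continuous", DOMAINS[j % len(DOMAINS)]))
        if j < cfg.n_clinical_predictive:
            col = cfg.clinical_effect * risk + rng.normal(0.0, 1.0, n)
        elif j < cfg.n_clinical_predictive + 5:
            col = sites.astype(float) + rng.normal(0.0, 0.5, n)  # site decoys
        else:
            col = rng.normal(0.0, 1.0, n)
        data[name] = col
    for j in range(n_bin):
        name = f"bin{j:02d}"
        entries.append((name, "binary", DOMAINS[j % len(DOMAINS)]))
        data[name] = rng.choice(["no", "yes"], n)
    for j in range(n_cat):
        name = f"cat{j:02d}"
        entries.append((name, "categorical", DOMAINS[j % len(DOMAINS)]))
        data[name] = rng.choice(["a", "b", "c"], n)
    df = pd.DataFrame(data, index=[f"tgt{i:04d}" for i in range(n)])
    # sprinkle a little missingness to exercise imputation
    miss = rng.random(df.shape) < 0.02
    df = df.mask(miss)
    return df, ClinicalDictionary(entries)


def generate_target_cohort(cfg: SyntheticConfig, seed: int) -> TargetCohort:
    """Small cohort with C correlated outcomes and a mixed clinical table."""
    rng = np.random.default_rng((cfg.seed, seed, 3))
    L, _ = _cohort_loadings(cfg, "target")
    n = cfg.n_target
    counts = cfg.positive_counts()
    rho = cfg.task_label_correlation
    u = rng.normal(0.0, 1.0, n)  # shared liability -> positive task correlation
    risk = np.zeros((n, cfg.task_count))
    Y = np.zeros((n, cfg.task_count), dtype=int)
    for c in range(cfg.task_count):
        r_c = rho * u + np.sqrt(1.0 - rho**2) * rng.normal(0.0, 1.0, n)
        risk[:, c] = r_c
        Y[:, c] = _exact_count_labels(r_c, counts[c])
    z = rng.normal(0.0, 1.0, (n, cfg.n_factors))
    for c in range(cfg.task_count):
        z[Y[:, c] == 1, c] += cfg.delta * cfg.task_delta_fraction
    # the shared outcome factor shifts with each subject's overall risk load
    z[:, cfg.task_count] += cfg.delta * Y.mean(axis=1)
    sites = np.arange(n) % 2
    site_vectors = rng.normal(0.0, cfg.site_sd, (2, cfg.n_edges))
    X = _edges_from_factors(z, L, site_vectors[sites], rng, cfg)
    mean_risk = risk.mean(axis=1)
    table, dictionary = _clinical_table(cfg, rng, mean_risk, sites)
    records = [
        SubjectRecord(
            f"tgt{i:04d}", f"site_t{sites[i]}", "target", X[i],
            labels={TASK_NAMES[c]: int(Y[i, c]) for c in range(cfg.task_count)},
        )
        for i in range(n)
    ]
    return TargetCohort(records, table, dictionary, mean_risk)


def make_time_series(
    n_frames: int, n_roi: int, seed: int, ar: float = 0.3
) -> np.ndarray:
    """Minimal correlated time-series generator to exercise connectivity code.

    Columns mix a few latent temporal signals; not a realistic BOLD model.
    """
    rng = np.random.default_rng(seed)
    latent = rng.normal(0.0, 1.0, (n_frames, 3))
    for t in range(1, n_frames):
        latent[t] += ar * latent[t - 1]
    mix = rng.normal(0.0, 1.0, (3, n_roi))
    return latent @ mix + rng.normal(0.0, 0.5, (n_frames, n_roi))
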