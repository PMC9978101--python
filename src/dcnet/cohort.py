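"""Synthetic multi-group resting-state cohorts with planted connectivity effects.

The study design this generator emulates is a three-group cross-sectional
resting-state fMRI comparison: healthy controls (HC), subclinically depressed
(SD) and major depressive disorder (MDD) subjects, each contributing one ROI
time-series matrix (T volumes x g parcels), one six-parameter rigid-body
realignment trace, and a phenotype row (age, sex, education, depression
scores).  Group differences are planted as known increments ``delta_r`` on the
correlations between a hub node and a set of partner nodes, so every
downstream stage (scrubbing, network construction, degree centrality, group
inference, ROC) can be validated by parameter recovery against ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

GROUPS = ("HC", "SD", "MDD")


@dataclass(frozen=True)
class EffectSpec:
    """A planted connectivity effect: ``delta_r`` added to the correlations
    between ``hub_node`` and its ``partner_count`` partner nodes, in one group
    only.  Partners are the nodes cyclically following the hub (deterministic,
    so ground truth is reproducible from the spec alone)."""

    group: str
    hub_node: int
    partner_count: int
    delta_r: float


@dataclass(frozen=True)
class MotionModel:
    """Head-motion trace model: slow random-walk drift plus Poisson-placed
    single-volume spikes.

    spike_rate is per volume (expected spikes per scan = rate * T);
    spike_amplitude_mm is the translation displacement of one spiked volume;
    drift_scale_mm is the per-step SD of the translation random walk
    (rotations drift at drift_scale_mm / 50 rad, i.e. the same FD scale under
    the 50 mm sphere convention).
    """

    spike_rate: float = 0.02
    spike_amplitude_mm: float = 0.3
    drift_scale_mm: float = 0.01


@dataclass(frozen=True)
class CovariateModel:
    """Per-group phenotype distribution (ages/education in years)."""

    age_mean: float
    age_sd: float
    education_mean: float
    education_sd: float
    female_fraction: float
    bdi_mean: float | None = None
    bdi_sd: float | None = None
    hamd_mean: float | None = None
    hamd_sd: float | None = None


#: Defaults follow the emulated study's enrolled cohort: sex proportions from
#: the enrolment counts (19/40, 23/34, 29/40 female), age/education/score
#: moments from its demographic table.  BDI-II is recorded for HC and SD,
#: HAMD for MDD; no clinical realism is claimed for the score distributions.
DEFAULT_COVARIATES: dict[str, CovariateModel] = {
    "HC": CovariateModel(19.24, 0.94, 13.18, 0.87, 19 / 40, bdi_mean=1.55, bdi_sd=1.44),
    "SD": CovariateModel(19.65, 1.77, 13.36, 0.92, 23 / 34, bdi_mean=22.46, bdi_sd=7.73),
    "MDD": CovariateModel(21.13, 6.17, 12.94, 2.60, 29 / 40, hamd_mean=21.51, hamd_sd=4.58),
}


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort.

    Defaults reproduce the emulated study's shape: 40/34/40 enrolled subjects
    (HC/SD/MDD), 200 volumes at TR 2.5 s, 246 parcels.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"HC": 40, "SD": 34, "MDD": 40}
    )
    g: int = 246
    T: int = 200
    tr_seconds: float = 2.5
    effects: tuple[EffectSpec, ...] = ()
    ar_coefficient: float = 0.3
    motion: MotionModel = field(default_factory=MotionModel)
    covariates: dict[str, CovariateModel] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    n_factors: int = 10
    seed: int = 0

    def validate(self) -> None:
        for grp in GROUPS:
            if grp not in self.n_per_group:
                raise ValueError(f"n_per_group missing group {grp!r}")
            if self.n_per_group[grp] < 2:
                raise ValueError(f"n_per_group[{grp!r}] must be >= 2")
        if self.g < 3:
            raise ValueError("g must be >= 3")
        if self.T <= 20:
            raise ValueError("T must be > 20")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        for eff in self.effects:
            if eff.group not in GROUPS:
                raise ValueError(f"effect group {eff.group!r} not in {GROUPS}")
            if not 0 <= eff.hub_node < self.g:
                raise ValueError(f"hub_node {eff.hub_node} out of range for g={self.g}")
            if not 1 <= eff.partner_count < self.g:
                raise ValueError("partner_count must be in [1, g)")
            if abs(eff.delta_r) >= 1:
                raise ValueError("|delta_r| must be < 1")


@dataclass
class SubjectRecord:
    """One subject: identity, phenotype, ROI series and realignment trace.

    ``series`` is T x g; ``realignment`` is T x 6 in the SPM rp-file dialect
    (x, y, z translations in mm, then pitch/roll/yaw rotations in radians).
    """

    subject_id: str
    group: str
    age: float
    sex: str
    education: float
    series: np.ndarray
    realignment: np.ndarray
    bdi: float | None = None
    hamd: float | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.series)):
            raise ValueError(f"{self.subject_id}: series contains non-finite values")
        if self.realignment.shape != (self.series.shape[0], 6):
            raise ValueError(
                f"{self.subject_id}: realignment shape {self.realignment.shape} "
                f"does not match series ({self.series.shape[0]} rows x 6)"
            )


def effect_partners(spec: CohortSpec, effect: EffectSpec) -> np.ndarray:
    """Partner nodes of an effect: the ``partner_count`` nodes most
    correlated with the hub in the base matrix — the hub's natural
    community, whose coupling the effect strengthens (or weakens)."""
    base = _base_correlation(spec)
    order = np.argsort(-base[effect.hub_node], kind="stable")
    order = order[order != effect.hub_node]
    return order[: effect.partner_count]


def weakest_hub(spec: CohortSpec) -> int:
    """Node with the lowest total base coupling: the natural place to plant
    an elevated-connectivity effect (its gained connections are new edges
    rather than reinforcements of existing ones)."""
    return int(np.argmin(_base_correlation(spec).sum(axis=0)))


def _base_correlation(spec: CohortSpec) -> np.ndarray:
    """Shared base correlation matrix: overlapping-modules factor model.

    Each latent factor loads on a random ~25% subset of nodes (overlapping
    community structure, like resting-state networks) on top of a weak
    positive global factor and diagonal noise.  The resulting correlation
    distribution is wide and right-skewed, so a sparsity threshold falls in
    a low-density region and degree values are stable across subjects.
    """
    rng = np.random.default_rng([spec.seed, 101])
    g, k = spec.g, spec.n_factors
    member = rng.random((g, k)) < 0.25
    loadings = member * rng.normal(0.75, 0.15, size=(g, k))
    loadings[:, 0] = rng.uniform(0.2, 0.4, size=g)
    cov = loadings @ loadings.T + np.diag(rng.uniform(0.6, 1.0, size=g))
    return _cov_to_corr(cov)


def _cov_to_corr(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return (corr + corr.T) / 2.0


def _nearest_pd_correlation(corr: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue clipping at a small positive floor, then re-standardization
    to unit diagonal."""
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= floor:
        return corr
    vals = np.clip(vals, floor, None)
    repaired = (vecs * vals) @ vecs.T
    return _cov_to_corr(repaired)


def build_group_covariance(
    spec: CohortSpec, group: str
) -> tuple[np.ndarray, list[int]]:
    """Group covariance (as a correlation matrix) and its affected hub nodes.

    A base correlation matrix shared by all groups is perturbed, for every
    effect matching ``group``, by adding ``delta_r`` to the covariances
    between the hub and its partners.  The increment is realized as a
    rank-one module factor with loading sqrt(|delta_r|) on the hub and its
    partners: this keeps the matrix positive definite by construction for
    elevations (no attenuation by eigenvalue clipping) and also strengthens
    the partners' mutual coupling, as a shared latent signal would.  The
    factor's loadings are balanced to sum to zero across all nodes, so the
    planted component is orthogonal to the parcellation-mean signal and
    survives global-signal regression instead of being absorbed by it.
    The final matrix is re-standardized to unit diagonal and, as a safety
    net (negative ``delta_r`` can be indefinite), projected to the nearest
    positive-definite correlation matrix.
    """
    spec.validate()
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    corr = _base_correlation(spec)
    affected: list[int] = []
    for eff in spec.effects:
        if eff.group != group:
            continue
        partners = effect_partners(spec, eff)
        if np.any(np.abs(corr[eff.hub_node, partners] + eff.delta_r) >= 1.0):
            raise ValueError(
                f"effect {eff} drives |r| >= 1 between hub {eff.hub_node} "
                "and a partner; reduce |delta_r|"
            )
        module = np.r_[eff.hub_node, partners]
        other = np.setdiff1d(np.arange(spec.g), module)
        a = np.sqrt(abs(eff.delta_r))
        w = np.zeros(spec.g)
        w[module] = a
        w[other] = -a * module.size / other.size  # zero-sum: GSR-orthogonal
        corr = _cov_to_corr(corr + np.sign(eff.delta_r) * np.outer(w, w))
        affected.append(eff.hub_node)
    return _nearest_pd_correlation(corr), affected


def _simulate_series(
    rng: np.random.Generator, chol: np.ndarray, T: int, phi: float
) -> np.ndarray:
    """Stationary AR(1) process with marginal covariance chol @ chol.T."""
    g = chol.shape[0]
    innov = rng.standard_normal((T, g)) @ chol.T
    x = np.empty((T, g))
    x[0] = innov[0]
    scale = np.sqrt(1.0 - phi * phi)
    for t in range(1, T):
        x[t] = phi * x[t - 1] + scale * innov[t]
    return x


def _simulate_realignment(rng: np.random.Generator, T: int, motion: MotionModel) -> np.ndarray:
    rp = np.empty((T, 6))
    # slow drift: random walk; rotations kept on the same FD scale via /50
    rp[:, :3] = np.cumsum(rng.normal(0.0, motion.drift_scale_mm, (T, 3)), axis=0)
    rp[:, 3:] = np.cumsum(rng.normal(0.0, motion.drift_scale_mm / 50.0, (T, 3)), axis=0)
    n_spikes = rng.poisson(motion.spike_rate * T)
    for _ in range(n_spikes):
        t = int(rng.integers(1, T))
        col = int(rng.integers(0, 3))
        rp[t, col] += rng.choice((-1.0, 1.0)) * motion.spike_amplitude_mm
    return rp


def _draw_covariates(rng: np.random.Generator, model: CovariateModel):
    age = max(18.0, float(rng.normal(model.age_mean, model.age_sd)))
    education = max(6.0, float(rng.normal(model.education_mean, model.education_sd)))
    sex = "female" if rng.random() < model.female_fraction else "male"
    bdi = hamd = None
    if model.bdi_mean is not None:
        bdi = max(0.0, float(rng.normal(model.bdi_mean, model.bdi_sd)))
    if model.hamd_mean is not None:
        hamd = max(0.0, float(rng.normal(model.hamd_mean, model.hamd_sd)))
    return age, sex, education, bdi, hamd


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectRecord], dict]:
    """Generate the cohort and its ground truth.

    Per-subject random streams are keyed by (seed, group index, subject
    index), so a subject's data is invariant to the other groups' sizes and
    two calls with the same spec are bit-identical.

    Returns
    -------
    records : list of SubjectRecord, ordered HC, SD, MDD.
    truth : dict with the planted effects and, per group, the affected hub
        nodes and their partner lists.
    """
    spec.validate()
    records: list[SubjectRecord] = []
    truth: dict = {
        "effects": [
            {
                "group": e.group,
                "hub_node": int(e.hub_node),
                "partner_count": int(e.partner_count),
                "delta_r": float(e.delta_r),
                "partners": [int(p) for p in effect_partners(spec, e)],
            }
            for e in spec.effects
        ],
        "affected_nodes": {},
    }
    for gi, group in enumerate(GROUPS):
        corr, affected = build_group_covariance(spec, group)
        truth["affected_nodes"][group] = [int(a) for a in affected]
        chol = np.linalg.cholesky(corr)
        cov_model = spec.covariates[group]
        for si in range(spec.n_per_group[group]):
            rng = np.random.default_rng([spec.seed, gi, si])
            series = _simulate_series(rng, chol, spec.T, spec.ar_coefficient)
            rp = _simulate_realignment(rng, spec.T, spec.motion)
            age, sex, education, bdi, hamd = _draw_covariates(rng, cov_model)
            records.append(
                SubjectRecord(
                    subject_id=f"sub-{group}{si + 1:03d}",
                    group=group,
                    age=age,
                    sex=sex,
                    education=education,
                    series=series,
                    realignment=rp,
                    bdi=bdi,
                    hamd=hamd,
                )
            )
    return records, truth


def plant_motion_failures(
    records: list[SubjectRecord], counts: dict[str, int], amplitude_mm: float = 3.0
) -> list[str]:
    """Inject a large translation spike into the first ``counts[group]``
    subjects of each group so they fail the >2 mm motion rule.

    Modifies the records in place; returns the affected subject ids.  Used to
    reproduce stated exclusion bookkeeping exactly.
    """
    planted: list[str] = []
    for group, k in counts.items():
        in_group = [r for r in records if r.group == group]
        if k > len(in_group):
            raise ValueError(f"cannot fail {k} subjects in group {group} of {len(in_group)}")
        for rec in in_group[:k]:
            t = rec.realignment.shape[0] // 2
            rec.realignment[t, 0] += amplitude_mm
            planted.append(rec.subject_id)
    if planted:
        logger.info("planted motion failures in %d subjects", len(planted))
    return planted
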