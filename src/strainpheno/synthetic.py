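"""Synthetic strain-curve cohorts with known phenogroup structure.

The generator emulates a community cohort of single-cycle LV longitudinal
strain recordings: each latent group has a template curve (piecewise-linear
skeleton: zero strain at the R-peak, systolic rise to peak strain at aortic
valve closure, early-diastolic release to the diastasis level, a mid-diastolic
plateau, then late-diastolic decline after atrial activation), smoothed at
the corners, sampled at a subject-specific frame rate over one cycle of
length 60/heart-rate, with additive Gaussian measurement noise.  Covariates
and exponential time-to-event outcomes with group-dependent hazards complete
each subject, so every downstream stage — QC, alignment, feature extraction,
clustering, explanation and survival analysis — can be validated against
known truth.

Default group parameters sketch four phenogroups ranging from a young cohort
with fast early-diastolic release and long diastasis to an older, stiffer
phenotype with slow release, short diastasis and reduced peak strain; the
accompanying covariate distributions follow the same gradient.  Cardiac
events are generated as a sub-hazard of cardiovascular (CV) events, so a
cardiac event always implies a CV event.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import write_cohort_table, write_trace
from .preprocess import CardiacLandmarks, StrainTrace

__all__ = [
    "GroupCurveParams",
    "CovariateModel",
    "GroupParams",
    "GeneratorConfig",
    "SyntheticSubject",
    "default_config",
    "generate_cohort",
    "cohort_table",
    "write_cohort",
]

#: Minimum late-diastolic duration (s) the generator guarantees after the
#: diastasis plateau: atrial activation precedes the next R-peak by roughly
#: a PR interval, so the terminal phase is never shorter than ~120 ms (which
#: also keeps the late-slope estimate from degenerating to a handful of
#: frames).
_MIN_LATE_S = 0.12


@dataclass
class GroupCurveParams:
    """Template curve for one latent phenogroup (all magnitudes, positive).

    Slopes are in %/s, durations in s, strain levels in % magnitude.  The
    two diastolic slopes are release rates (the signed extracted features
    will be negative).
    """

    peak_strain: float
    slope_systole: float
    slope_early_diastole: float
    slope_late_diastole: float
    diastasis_duration: float
    diastasis_height: float
    heart_rate_range: tuple[float, float] | None = None  # overrides global

    def phase_time(self) -> float:
        """Time from R-peak to the end of diastasis."""
        t_sys = self.peak_strain / self.slope_systole
        t_ed = (self.peak_strain - self.diastasis_height) / self.slope_early_diastole
        return t_sys + t_ed + self.diastasis_duration


@dataclass
class CovariateModel:
    """Per-group covariate distributions: normals for continuous variables
    (clipped at zero for physiologic quantities), Bernoulli for binaries."""

    continuous: dict[str, tuple[float, float]] = field(default_factory=dict)
    binary: dict[str, float] = field(default_factory=dict)


@dataclass
class GroupParams:
    curve: GroupCurveParams
    covariates: CovariateModel
    log_hr_cv: float = 0.0  # log hazard ratio for CV events vs baseline


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic cohort.

    ``noise_sd`` is additive Gaussian measurement noise in % strain;
    ``param_jitter`` is the relative SD of per-subject deviations from the
    group template (within-group biological variation); ``smooth_ms`` is the
    moving-average window used to round the skeleton's corners, as real
    strain curves are smooth.  ``cardiac_fraction`` is the share of the CV
    hazard attributable to cardiac events (cardiac events are a subset of CV
    events).
    """

    n_subjects: int
    cluster_weights: Sequence[float]
    groups: Sequence[GroupParams]
    heart_rate_range: tuple[float, float] = (55.0, 75.0)
    frame_rate_range: tuple[float, float] = (45.0, 80.0)
    noise_sd: float = 0.3
    param_jitter: float = 0.04
    smooth_ms: float = 30.0
    baseline_hazard: float = 0.011  # CV events per person-year
    cardiac_fraction: float = 0.7
    censoring_time_range: tuple[float, float] = (3.0, 12.0)
    seed: int = 0

    def validate(self) -> None:
        w = np.asarray(self.cluster_weights, dtype=float)
        if w.size != len(self.groups):
            raise ValueError("cluster_weights must match number of groups")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("cluster_weights must sum to 1 within 1e-9")
        if np.any(w < 0):
            raise ValueError("cluster_weights must be nonnegative")
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not 0.0 < self.cardiac_fraction <= 1.0:
            raise ValueError("cardiac_fraction must be in (0, 1]")
        for attr in ("noise_sd", "param_jitter", "smooth_ms"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be nonnegative")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be strictly positive")
        for g, grp in enumerate(self.groups, start=1):
            c = grp.curve
            for name in (
                "peak_strain",
                "slope_systole",
                "slope_early_diastole",
                "slope_late_diastole",
                "diastasis_duration",
                "diastasis_height",
            ):
                if getattr(c, name) <= 0:
                    raise ValueError(f"group {g}: {name} must be strictly positive")
            if c.diastasis_height >= c.peak_strain:
                raise ValueError(f"group {g}: diastasis_height must be < peak_strain")
            hr_hi = (c.heart_rate_range or self.heart_rate_range)[1]
            min_cycle = 60.0 / hr_hi
            if c.phase_time() + _MIN_LATE_S > min_cycle:
                raise ValueError(
                    f"group {g}: phase durations ({c.phase_time():.3f}s + "
                    f"{_MIN_LATE_S}s late diastole) exceed the cycle length "
                    f"({min_cycle:.3f}s) at the maximum heart rate {hr_hi} bpm"
                )


@dataclass
class SyntheticSubject:
    """One simulated participant: trace, latent group, covariates, outcomes."""

    subject_id: str
    trace: StrainTrace
    true_cluster: int  # 1-based latent group label
    covariates: dict[str, float]
    follow_up: float  # administrative censoring time, years
    event_time_cv: float
    event_cv: int
    event_time_cardiac: float
    event_cardiac: int
    # noiseless per-subject template truth, for oracle tests
    truth: dict[str, float] = field(default_factory=dict)


# --- default study conditions -------------------------------------------------

# late-diastolic slopes are kept below height / max-diastolic-window so the
# decline does not reach the zero-strain baseline mid-phase for part of a
# group only: a partial floor would split a group's slope_ld into two
# regimes and break the premise of unimodal within-group feature spread
_DEFAULT_CURVES = [
    GroupCurveParams(19.8, 60.0, 70.0, 14.0, 0.25, 5.0, heart_rate_range=(53, 64)),
    GroupCurveParams(18.4, 55.0, 55.0, 22.0, 0.17, 8.0, heart_rate_range=(58, 72)),
    GroupCurveParams(20.4, 50.0, 42.0, 30.0, 0.14, 11.0, heart_rate_range=(55, 66)),
    GroupCurveParams(17.7, 48.0, 34.0, 32.0, 0.07, 8.5, heart_rate_range=(62, 71)),
]

# (mean, sd) continuous / probability binary, one dict pair per group; values
# sketch the gradient from a young low-risk group (1) to an older high-risk
# phenotype (4).
_DEFAULT_COVARIATES = [
    CovariateModel(
        continuous={
            "age": (42.7, 12.8), "bmi": (24.9, 3.8), "sbp": (121.9, 13.4),
            "dbp": (77.6, 8.9), "total_cholesterol": (4.88, 0.93),
            "creatinine": (70.7, 12.3), "e_over_eprime": (6.23, 1.39),
            "eprime": (13.25, 2.95), "e_a_ratio": (1.79, 0.50),
            "lvmi_gm27": (40.0, 8.0), "la_peak_strain": (32.0, 6.0),
            "lavi": (22.0, 6.0), "tr_velocity": (2.00, 0.30),
            "mitral_a_duration_ms": (130.0, 15.0),
            "pv_reversal_duration_ms": (110.0, 20.0),
        },
        binary={
            "female": 0.533, "smoking": 0.196, "alcohol": 0.467,
            "hypertension": 0.216, "treated_hypertension": 0.110,
            "cardiac_history": 0.012, "diabetes": 0.012,
        },
    ),
    CovariateModel(
        continuous={
            "age": (46.8, 14.1), "bmi": (26.3, 4.1), "sbp": (128.2, 14.9),
            "dbp": (82.2, 9.3), "total_cholesterol": (4.93, 0.87),
            "creatinine": (73.0, 18.8), "e_over_eprime": (6.52, 1.72),
            "eprime": (11.43, 3.05), "e_a_ratio": (1.38, 0.42),
            "lvmi_gm27": (40.5, 8.0), "la_peak_strain": (30.0, 6.0),
            "lavi": (23.0, 6.0), "tr_velocity": (2.05, 0.30),
            "mitral_a_duration_ms": (132.0, 15.0),
            "pv_reversal_duration_ms": (112.0, 20.0),
        },
        binary={
            "female": 0.503, "smoking": 0.172, "alcohol": 0.398,
            "hypertension": 0.352, "treated_hypertension": 0.153,
            "cardiac_history": 0.040, "diabetes": 0.035,
        },
    ),
    CovariateModel(
        continuous={
            "age": (61.6, 10.9), "bmi": (27.4, 4.2), "sbp": (136.7, 16.1),
            "dbp": (83.1, 9.4), "total_cholesterol": (4.92, 0.94),
            "creatinine": (76.4, 23.5), "e_over_eprime": (7.92, 2.41),
            "eprime": (8.58, 2.30), "e_a_ratio": (1.01, 0.27),
            "lvmi_gm27": (45.0, 9.0), "la_peak_strain": (27.0, 6.0),
            "lavi": (25.0, 7.0), "tr_velocity": (2.20, 0.35),
            "mitral_a_duration_ms": (135.0, 15.0),
            "pv_reversal_duration_ms": (120.0, 22.0),
        },
        binary={
            "female": 0.525, "smoking": 0.101, "alcohol": 0.379,
            "hypertension": 0.627, "treated_hypertension": 0.421,
            "cardiac_history": 0.107, "diabetes": 0.075,
        },
    ),
    CovariateModel(
        continuous={
            "age": (63.9, 12.9), "bmi": (28.1, 4.3), "sbp": (141.8, 18.3),
            "dbp": (86.2, 10.7), "total_cholesterol": (5.17, 0.98),
            "creatinine": (78.9, 21.5), "e_over_eprime": (8.89, 3.81),
            "eprime": (7.00, 2.55), "e_a_ratio": (0.84, 0.30),
            "lvmi_gm27": (48.0, 10.0), "la_peak_strain": (24.0, 6.0),
            "lavi": (27.0, 8.0), "tr_velocity": (2.30, 0.40),
            "mitral_a_duration_ms": (138.0, 16.0),
            "pv_reversal_duration_ms": (128.0, 24.0),
        },
        binary={
            "female": 0.481, "smoking": 0.131, "alcohol": 0.322,
            "hypertension": 0.749, "treated_hypertension": 0.432,
            "cardiac_history": 0.159, "diabetes": 0.109,
        },
    ),
]

_DEFAULT_LOG_HR = [-1.2, -0.4, 0.4, 0.8]
_DEFAULT_WEIGHTS = [0.215, 0.314, 0.316, 0.155]


def default_config(n_subjects: int = 1185, seed: int = 0, **overrides) -> GeneratorConfig:
    """The package's reference four-phenogroup study conditions.

    Group weights and covariate distributions follow the gradient of a
    general-population cohort; curve templates are well separated (several
    within-group SDs apart in at least two of the six features).  Keyword
    overrides replace top-level :class:`GeneratorConfig` fields.
    """
    groups = [
        GroupParams(curve=copy.deepcopy(c), covariates=copy.deepcopy(cov), log_hr_cv=lhr)
        for c, cov, lhr in zip(_DEFAULT_CURVES, _DEFAULT_COVARIATES, _DEFAULT_LOG_HR)
    ]
    cfg = GeneratorConfig(
        n_subjects=n_subjects,
        cluster_weights=list(_DEFAULT_WEIGHTS),
        groups=groups,
        seed=seed,
    )
    for key, val in overrides.items():
        if not hasattr(cfg, key):
            raise TypeError(f"unknown GeneratorConfig field {key!r}")
        setattr(cfg, key, val)
    return cfg


# --- curve synthesis ----------------------------------------------------------

def _skeleton_knots(c: GroupCurveParams, cycle: float) -> tuple[np.ndarray, np.ndarray]:
    """Knot times/values (signed strain) of the piecewise-linear template."""
    t1 = c.peak_strain / c.slope_systole
    t2 = t1 + (c.peak_strain - c.diastasis_height) / c.slope_early_diastole
    t3 = t2 + c.diastasis_duration
    end_level = c.diastasis_height - c.slope_late_diastole * (cycle - t3)
    if end_level >= 0:
        tk = [0.0, t1, t2, t3, cycle]
        yk = [0.0, -c.peak_strain, -c.diastasis_height, -c.diastasis_height, -end_level]
    else:
        t_zero = t3 + c.diastasis_height / c.slope_late_diastole
        tk = [0.0, t1, t2, t3, t_zero, cycle]
        yk = [0.0, -c.peak_strain, -c.diastasis_height, -c.diastasis_height, 0.0, 0.0]
    return np.array(tk), np.array(yk)


def template_curve(
    c: GroupCurveParams, cycle: float, times: np.ndarray, smooth_ms: float = 0.0
) -> np.ndarray:
    """Evaluate the (optionally corner-smoothed) template at ``times``.

    Smoothing convolves the skeleton with a boxcar of width ``smooth_ms`` on
    a 1 kHz grid before sampling, which rounds the corners without moving
    straight-line sections.
    """
    tk, yk = _skeleton_knots(c, cycle)
    if smooth_ms <= 0:
        return np.interp(times, tk, yk)
    dt = 1e-3
    half = smooth_ms / 2000.0
    fine_t = np.arange(-half, cycle + half + dt, dt)
    fine_y = np.interp(fine_t, tk, yk)  # np.interp clamps at the ends
    w = max(int(round(smooth_ms / 1000.0 / dt)) | 1, 1)
    kernel = np.ones(w) / w
    sm = np.convolve(fine_y, kernel, mode="same")
    return np.interp(times, fine_t, sm)


def _jittered(c: GroupCurveParams, rel_sd: float, cycle: float, rng: np.random.Generator) -> GroupCurveParams:
    """Per-subject template: multiplicative Gaussian jitter, truncated so the
    phases always fit within the cycle (bounded rejection, then shrink)."""
    for _ in range(100):
        factors = 1.0 + rel_sd * np.clip(rng.standard_normal(6), -2.5, 2.5)
        cand = GroupCurveParams(
            peak_strain=c.peak_strain * factors[0],
            slope_systole=c.slope_systole * factors[1],
            slope_early_diastole=c.slope_early_diastole * factors[2],
            slope_late_diastole=c.slope_late_diastole * factors[3],
            diastasis_duration=c.diastasis_duration * factors[4],
            diastasis_height=min(c.diastasis_height * factors[5], 0.9 * c.peak_strain * factors[0]),
        )
        if cand.phase_time() + _MIN_LATE_S <= cycle:
            return cand
        if rel_sd == 0:
            break
    cand.diastasis_duration = max(cycle - _MIN_LATE_S - cand.phase_time()
                                  + cand.diastasis_duration, 0.01)
    return cand


def _make_trace(
    subject_id: str,
    c: GroupCurveParams,
    heart_rate: float,
    frame_rate: float,
    noise_sd: float,
    smooth_ms: float,
    rng: np.random.Generator,
) -> StrainTrace:
    cycle = 60.0 / heart_rate
    n = int(np.floor(cycle * frame_rate)) + 1
    times = np.arange(n) / frame_rate
    y = template_curve(c, cycle, times, smooth_ms=smooth_ms)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    t1 = c.peak_strain / c.slope_systole
    t3 = c.phase_time()
    landmarks = CardiacLandmarks(r_peak=0.0, avc=t1, p_peak=t3)
    return StrainTrace(
        subject_id=subject_id,
        time=times,
        strain=y,
        frame_rate=frame_rate,
        landmarks=landmarks,
    )


def generate_cohort(config: GeneratorConfig) -> list[SyntheticSubject]:
    """Draw a full synthetic cohort (deterministic given config + seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    weights = np.asarray(config.cluster_weights, dtype=float)
    n = config.n_subjects
    groups_idx = rng.choice(len(weights), size=n, p=weights / weights.sum())
    width = len(str(n))
    subjects: list[SyntheticSubject] = []
    for i in range(n):
        g = int(groups_idx[i])
        grp = config.groups[g]
        hr_lo, hr_hi = grp.curve.heart_rate_range or config.heart_rate_range
        heart_rate = rng.uniform(hr_lo, hr_hi)
        frame_rate = rng.uniform(*config.frame_rate_range)
        cycle = 60.0 / heart_rate
        c = _jittered(grp.curve, config.param_jitter, cycle, rng)
        sid = f"S{i:0{width}d}"
        trace = _make_trace(
            sid, c, heart_rate, frame_rate, config.noise_sd, config.smooth_ms, rng
        )

        cov: dict[str, float] = {"heart_rate": heart_rate}
        for name, (mu, sd) in grp.covariates.continuous.items():
            cov[name] = max(float(rng.normal(mu, sd)), 0.0)
        for name, p in grp.covariates.binary.items():
            cov[name] = int(rng.uniform() < p)

        # hierarchical events: cardiac is a sub-hazard of CV, so a cardiac
        # event implies a (simultaneous) CV event
        h_cv = config.baseline_hazard * np.exp(grp.log_hr_cv)
        h_card = config.cardiac_fraction * h_cv
        h_other = h_cv - h_card
        t_card = rng.exponential(1.0 / h_card) if h_card > 0 else np.inf
        t_other = rng.exponential(1.0 / h_other) if h_other > 0 else np.inf
        censor = rng.uniform(*config.censoring_time_range)
        t_cv = min(t_card, t_other)

        # truth features are the extraction functionals applied to the
        # continuous noiseless skeleton; the late-diastolic slope is the
        # least-squares slope over the late phase, which differs from the
        # raw parameter when the decline reaches zero strain before the
        # cycle ends (the curve then stays at baseline)
        t3 = c.phase_time()
        t_rec = np.floor(cycle * frame_rate) / frame_rate  # last recorded sample
        grid = np.linspace(t3, t_rec, 2001)
        late_mag = np.maximum(c.diastasis_height - c.slope_late_diastole * (grid - t3), 0.0)
        gm = grid - grid.mean()
        true_slope_ld = float(gm @ late_mag / (gm @ gm))
        subjects.append(
            SyntheticSubject(
                subject_id=sid,
                trace=trace,
                true_cluster=g + 1,
                covariates=cov,
                follow_up=censor,
                event_time_cv=min(t_cv, censor),
                event_cv=int(t_cv <= censor),
                event_time_cardiac=min(t_card, censor),
                event_cardiac=int(t_card <= censor),
                truth={
                    "slope_sys": c.slope_systole,
                    "slope_ed": -c.slope_early_diastole,
                    "slope_ld": true_slope_ld,
                    "diastasis_dur": c.diastasis_duration,
                    "diastasis_height": c.diastasis_height,
                    "peak_strain": c.peak_strain,
                },
            )
        )
    return subjects


def cohort_table(subjects: Sequence[SyntheticSubject]) -> pd.DataFrame:
    """Covariate/outcome table, one row per subject in input order."""
    rows = []
    for s in subjects:
        row = {"subject_id": s.subject_id, "true_cluster": s.true_cluster}
        row.update(s.covariates)
        row.update(
            follow_up_years=s.follow_up,
            event_cv=s.event_cv,
            event_time_cv_years=s.event_time_cv,
            event_cardiac=s.event_cardiac,
            event_time_cardiac_years=s.event_time_cardiac,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(
    subjects: Sequence[SyntheticSubject], directory: str | Path, overwrite: bool = False
) -> Path:
    """Write one trace file per subject plus ``cohort.csv`` to ``directory``."""
    if not subjects:
        raise ValueError("empty subject list")
    if str(directory) in ("", "."):
        raise ValueError("empty directory path")
    directory = Path(directory)
    trace_dir = directory / "traces"
    table_path = directory / "cohort.csv"
    if table_path.exists() and not overwrite:
        raise FileExistsError(f"{table_path} exists; pass overwrite=True to replace")
    trace_dir.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        write_trace(s.trace, trace_dir / f"{s.subject_id}.tsv")
    write_cohort_table(cohort_table(subjects), table_path)
    return directory
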