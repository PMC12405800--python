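"""Seeded synthetic cohorts with known latent truth.

Every estimator in this package is exercised on simulated data whose ground
truth (per-subject time shifts, amyloid onset ages, structural coefficients)
is recorded, so recovery can be tested without any restricted data.

The generators invert the models the estimators assume:

* cognitive trajectories follow a shared decline curve ``g`` observed from a
  subject-specific latent position ``delta``:
  ``y_ij = g(delta_i + t_ij) - g(delta_i) + practice + noise``;
* amyloid trajectories follow a four-parameter logistic in age whose
  midpoint is placed so the noise-free curve crosses the positivity
  threshold exactly at the recorded onset age;
* the path table is drawn from linear structural equations on a DAG;
* conversion events are exponential with a log-linear hazard in c-time.
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .curves import GroupCurveParams, group_curve_eval, predict_shifted
from .exceptions import ParameterError

__all__ = [
    "VisitSchedule",
    "SyntheticTruth",
    "COGNITIVE_SCHEDULE",
    "AMYLOID_SCHEDULE",
    "gen_cognitive_cohort",
    "gen_amyloid_cohort",
    "gen_path_table",
    "gen_event_times",
]


@dataclass(frozen=True)
class VisitSchedule:
    """Number of visits, follow-up span and timing jitter for a cohort.

    First visit is at t=0 and the last at the drawn span; interior visits are
    evenly spaced with uniform jitter of standard deviation ``jitter_sd``.
    """

    n_visits_range: tuple[int, int] = (4, 10)
    span_years_range: tuple[float, float] = (1.7, 11.6)
    jitter_sd: float = 0.15

    def __post_init__(self):
        lo, hi = self.n_visits_range
        if lo < 1 or hi < lo:
            raise ParameterError("n_visits_range must satisfy 1 <= min <= max")
        slo, shi = self.span_years_range
        if slo < 0 or shi < slo:
            raise ParameterError("span_years_range must satisfy 0 <= min <= max")
        if self.jitter_sd < 0:
            raise ParameterError("jitter_sd must be >= 0")


# Schedules emulating the source cohort: >=3 neuropsychological assessments
# spanning 1.7-11.6 years, and >=3 amyloid PET scans spanning 4.2-9.7 years.
COGNITIVE_SCHEDULE = VisitSchedule((4, 10), (1.7, 11.6), 0.15)
AMYLOID_SCHEDULE = VisitSchedule((3, 5), (4.2, 9.7), 0.15)


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort.

    ``subjects`` holds one row per subject (true shift or onset age plus any
    per-subject nuisance values); ``params`` echoes the generating
    parameters; ``seed`` reproduces the cohort bit-identically.
    """

    subjects: pd.DataFrame
    params: dict = field(default_factory=dict)
    seed: int | None = None


def _sample_dist(rng: np.random.Generator, spec, n: int) -> np.ndarray:
    """Draw n values from a distribution spec.

    Accepted forms: a scalar (degenerate), an array of length n (verbatim
    per-subject values), or a mapping with key ``dist`` in {"uniform",
    "normal"} and parameters (low/high or mean/sd).
    """
    if np.isscalar(spec):
        return np.full(n, float(spec))
    if isinstance(spec, (list, tuple, np.ndarray, pd.Series)):
        arr = np.asarray(spec, float)
        if arr.shape != (n,):
            raise ParameterError(f"per-subject value array must have length {n}")
        return arr.copy()
    if not isinstance(spec, Mapping) or "dist" not in spec:
        raise ParameterError(f"invalid distribution spec: {spec!r}")
    kind = spec["dist"]
    if kind == "uniform":
        low, high = float(spec["low"]), float(spec["high"])
        if high < low:
            raise ParameterError("uniform spec requires low <= high")
        return rng.uniform(low, high, n)
    if kind == "normal":
        sd = float(spec["sd"])
        if sd < 0:
            raise ParameterError("normal spec requires sd >= 0")
        return rng.normal(float(spec["mean"]), sd, n)
    raise ParameterError(f"unknown distribution kind {kind!r}")


def _visit_times(rng: np.random.Generator, schedule: VisitSchedule) -> np.ndarray:
    """One subject's visit times: t1=0, last = drawn span, jittered interior."""
    lo, hi = schedule.n_visits_range
    n = int(rng.integers(lo, hi + 1))
    span = float(rng.uniform(*schedule.span_years_range))
    if n == 1:
        return np.zeros(1)
    t = np.linspace(0.0, span, n)
    if n > 2 and schedule.jitter_sd > 0:
        gap = span / (n - 1)
        # uniform jitter with the requested sd, clipped to keep strict order
        half = min(schedule.jitter_sd * np.sqrt(3.0), 0.45 * gap)
        t[1:-1] += rng.uniform(-half, half, n - 2)
    return t


def gen_cognitive_cohort(
    n_subjects: int,
    curve: GroupCurveParams | None = None,
    shift_dist=None,
    schedule: VisitSchedule = COGNITIVE_SCHEDULE,
    noise_sd: float = 0.1,
    practice_effect: float = 0.0,
    seed: int = 0,
    baseline_age_dist=None,
    id_prefix: str = "s",
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate baseline-anchored cognitive trajectories on a shared curve.

    Parameters
    ----------
    curve : GroupCurveParams
        The true group decline curve g. Default has both quadratic and
        exponential curvature so shifts are identifiable.
    shift_dist : distribution spec
        Distribution of true latent positions delta (years). Default
        Uniform(-15, 5): most subjects well before the steep-decline region.
    practice_effect : float
        One-time additive bump (z units) applied from visit 2 onward,
        emulating retest learning that masks early decline.

    Returns
    -------
    (cohort, truth)
        cohort: long table ``subject_id, age, t_years, value, modality``;
        truth.subjects: ``subject_id, delta, baseline_age``.
    """
    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if curve is None:
        # mild practice-like improvement at very early latent times, then
        # accelerating decline; quadratic curvature keeps early positions
        # identifiable against measurement noise
        curve = GroupCurveParams(lin=-0.125, quad=-0.0075, exp_amp=-0.03, exp_rate=0.25)
    if shift_dist is None:
        shift_dist = {"dist": "uniform", "low": -15.0, "high": 5.0}
    if baseline_age_dist is None:
        baseline_age_dist = {"dist": "normal", "mean": 71.5, "sd": 8.0}

    rng = np.random.default_rng(seed)
    deltas = _sample_dist(rng, shift_dist, n_subjects)
    ages0 = _sample_dist(rng, baseline_age_dist, n_subjects)

    rows = []
    for i in range(n_subjects):
        t = _visit_times(rng, schedule)
        y = predict_shifted(curve, deltas[i], t)
        if practice_effect != 0.0 and t.size > 1:
            y = y + practice_effect * (np.arange(t.size) >= 1)
        y = y + rng.normal(0.0, noise_sd, t.size)
        sid = f"{id_prefix}{i:04d}"
        for tj, yj in zip(t, y):
            rows.append((sid, ages0[i] + tj, tj, yj, "cognition"))

    cohort = pd.DataFrame(rows, columns=["subject_id", "age", "t_years", "value", "modality"])
    truth = SyntheticTruth(
        subjects=pd.DataFrame(
            {
                "subject_id": [f"{id_prefix}{i:04d}" for i in range(n_subjects)],
                "delta": deltas,
                "baseline_age": ages0,
            }
        ),
        params={
            "curve": curve.as_dict(),
            "noise_sd": noise_sd,
            "practice_effect": practice_effect,
            "shift_dist": shift_dist,
        },
        seed=seed,
    )
    return cohort, truth


def logistic_value(age, floor: float, ceiling: float, k: float, midpoint) -> np.ndarray:
    """Four-parameter logistic accumulation curve in age."""
    z = np.clip(k * (np.asarray(age, float) - midpoint), -500, 500)
    return floor + (ceiling - floor) / (1.0 + np.exp(-z))


def gen_amyloid_cohort(
    n_subjects: int,
    floor: float = 0.70,
    ceiling: float = 1.40,
    slope: float = 0.25,
    onset_age_dist=None,
    threshold: float = 0.87,
    schedule: VisitSchedule = AMYLOID_SCHEDULE,
    noise_sd: float = 0.02,
    seed: int = 0,
    baseline_offset_dist=None,
    id_prefix: str = "a",
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate sigmoidal amyloid (DVR) trajectories with known onset ages.

    Each subject accumulates along a logistic curve in age whose midpoint is
    placed so the noise-free curve crosses ``threshold`` exactly at the
    subject's true onset age. Baseline scan age is onset + a draw from
    ``baseline_offset_dist`` (default Uniform(-12, 4)), so a realistic
    fraction of subjects straddle the threshold during follow-up.
    """
    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    if not (floor < threshold < ceiling):
        raise ParameterError("threshold must lie strictly between floor and ceiling")
    if slope <= 0:
        raise ParameterError("slope k must be > 0")
    if onset_age_dist is None:
        onset_age_dist = {"dist": "normal", "mean": 72.0, "sd": 9.0}
    if baseline_offset_dist is None:
        baseline_offset_dist = {"dist": "uniform", "low": -12.0, "high": 4.0}

    rng = np.random.default_rng(seed)
    onset = _sample_dist(rng, onset_age_dist, n_subjects)
    # midpoint m such that floor + (C-F)*logistic(k*(onset - m)) == threshold
    p = (threshold - floor) / (ceiling - floor)
    midpoints = onset - np.log(p / (1.0 - p)) / slope
    ages0 = onset + _sample_dist(rng, baseline_offset_dist, n_subjects)

    rows = []
    for i in range(n_subjects):
        t = _visit_times(rng, schedule)
        ages = ages0[i] + t
        v = logistic_value(ages, floor, ceiling, slope, midpoints[i])
        v = v + rng.normal(0.0, noise_sd, t.size)
        sid = f"{id_prefix}{i:04d}"
        for tj, aj, vj in zip(t, ages, v):
            rows.append((sid, aj, tj, vj, "amyloid"))

    cohort = pd.DataFrame(rows, columns=["subject_id", "age", "t_years", "value", "modality"])
    truth = SyntheticTruth(
        subjects=pd.DataFrame(
            {
                "subject_id": [f"{id_prefix}{i:04d}" for i in range(n_subjects)],
                "onset_age": onset,
                "midpoint": midpoints,
                "baseline_age": ages0,
            }
        ),
        params={
            "floor": floor,
            "ceiling": ceiling,
            "slope": slope,
            "threshold": threshold,
            "noise_sd": noise_sd,
        },
        seed=seed,
    )
    return cohort, truth


_BINARY_EXOG = {"sex", "apoe4"}


def gen_path_table(
    n_subjects: int,
    coefficients: Mapping[tuple[str, str], float],
    noise_sds: Mapping[str, float] | float = 1.0,
    seed: int = 0,
    extra_exogenous: Sequence[str] = (),
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw a cross-sectional table from linear structural equations.

    ``coefficients`` maps directed edges (source, target) to weights; the
    implied graph must be acyclic. Exogenous variables named ``sex`` or
    ``apoe4`` are Bernoulli(0.5); all other exogenous variables are
    N(0, sd^2). Endogenous variables are the weighted sum of their parents
    plus N(0, sd^2) noise, with sd taken from ``noise_sds`` (scalar applies
    to every variable; per-variable mapping overrides).
    """
    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")

    nodes: set[str] = set(extra_exogenous)
    for (src, dst) in coefficients:
        nodes.update((src, dst))
    parents: dict[str, list[tuple[str, float]]] = {v: [] for v in nodes}
    graph: dict[str, set[str]] = {v: set() for v in nodes}
    for (src, dst), w in coefficients.items():
        parents[dst].append((src, float(w)))
        graph[dst].add(src)
    try:
        order = list(graphlib.TopologicalSorter(graph).static_order())
    except graphlib.CycleError as exc:
        raise ParameterError("coefficient map contains a cycle") from exc

    def sd_of(v: str) -> float:
        if isinstance(noise_sds, Mapping):
            return float(noise_sds.get(v, 1.0))
        return float(noise_sds)

    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for v in order:
        if not parents[v]:
            if v in _BINARY_EXOG:
                cols[v] = rng.integers(0, 2, n_subjects).astype(float)
            else:
                cols[v] = rng.normal(0.0, sd_of(v), n_subjects)
        else:
            val = np.zeros(n_subjects)
            for src, w in parents[v]:
                val += w * cols[src]
            sd = sd_of(v)
            if sd > 0:
                val = val + rng.normal(0.0, sd, n_subjects)
            cols[v] = val

    table = pd.DataFrame(cols)
    table.insert(0, "subject_id", [f"p{i:04d}" for i in range(n_subjects)])
    truth = SyntheticTruth(
        subjects=table[["subject_id"]].copy(),
        params={
            "coefficients": {f"{s}->{d}": w for (s, d), w in coefficients.items()},
            "noise_sds": dict(noise_sds) if isinstance(noise_sds, Mapping) else noise_sds,
        },
        seed=seed,
    )
    return table, truth


def gen_event_times(
    ctimes,
    log_hr: float,
    baseline_rate: float,
    censor_time: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential conversion times with hazard rate*exp(log_hr * ctime).

    Administrative censoring at ``censor_time``. Returns a table with
    columns ``ctime, time, event``.
    """
    if baseline_rate <= 0:
        raise ParameterError("baseline_rate must be > 0")
    if censor_time <= 0:
        raise ParameterError("censor_time must be > 0")
    ctimes = np.asarray(ctimes, float)
    rng = np.random.default_rng(seed)
    rates = baseline_rate * np.exp(log_hr * ctimes)
    raw = rng.exponential(1.0 / rates)
    event = raw <= censor_time
    return pd.DataFrame(
        {"ctime": ctimes, "time": np.minimum(raw, censor_time), "event": event.astype(int)}
    )
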