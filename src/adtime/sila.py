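"""SILA: time-to-amyloid-positivity from longitudinal PET.

Sampled iterative local approximation (SILA) turns longitudinal amyloid
measurements (DVR) into a per-subject chronicity estimate in three steps:

1. sample each subject's accumulation rate (within-subject slope of DVR
   versus age) against their mean DVR, and bin these samples into a
   rate-versus-level function r(v);
2. numerically integrate dv/dt = r(v) into a DVR-versus-duration curve
   anchored so that duration 0 corresponds to the positivity threshold;
3. solve the curve for each observed DVR and subtract the resulting
   duration from the age at observation, giving an estimated onset age;
   time-to-Ab+ is baseline age minus onset age (positive = already
   positive).

The positivity threshold itself comes from a two-component Gaussian mixture
fit to baseline values (0.87 DVR in the source cohort), or can be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .exceptions import (
    CensoredValue,
    InsufficientDataError,
    ParameterError,
    ThresholdUndeterminedError,
)

__all__ = [
    "DEFAULT_ABETA_THRESHOLD",
    "RateCurve",
    "SilaCurve",
    "SilaEstimate",
    "gmm_threshold",
    "subject_rates",
    "bin_rate_curve",
    "integrate_curve",
    "invert_curve",
    "estimate_subject_time",
    "SilaModel",
]

#: Amyloid positivity threshold (DVR) of the source longitudinal PiB pipeline.
DEFAULT_ABETA_THRESHOLD = 0.87


# ---------------------------------------------------------------------------
# positivity threshold


def gmm_threshold(
    baseline_values=None,
    min_n: int = 20,
    random_state: int = 0,
) -> float:
    """Aβ positivity threshold from a two-component Gaussian mixture.

    Returns the density-crossing point between the two component means;
    falls back to mean + 2 SD of the lower component when the densities do
    not cross between the means. With no data, returns the packaged default
    of 0.87 DVR.

    Raises
    ------
    ThresholdUndeterminedError
        If the fitted mixture is not bimodal (no interior density minimum
        between the component means), e.g. for a unimodal sample.
    """
    if baseline_values is None:
        return DEFAULT_ABETA_THRESHOLD
    x = np.asarray(baseline_values, float)
    if x.size < min_n:
        raise ParameterError(f"need at least {min_n} baseline values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ParameterError("baseline values must be finite")

    gm = GaussianMixture(n_components=2, n_init=5, random_state=random_state)
    gm.fit(x[:, None])
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    m1, m2 = means[order]
    s1, s2 = sds[order]
    w1, w2 = weights[order]

    if (m2 - m1) < 1e-8 or min(w1, w2) < 1e-3:
        raise ThresholdUndeterminedError("mixture components collapsed")

    # require bimodality: the mixture density must dip between the means
    grid = np.linspace(m1, m2, 512)
    dens = w1 * stats.norm.pdf(grid, m1, s1) + w2 * stats.norm.pdf(grid, m2, s2)
    imin = int(np.argmin(dens))
    if imin == 0 or imin == len(grid) - 1:
        raise ThresholdUndeterminedError(
            "mixture density has no interior minimum between component means"
        )

    def diff(v):
        return w1 * stats.norm.pdf(v, m1, s1) - w2 * stats.norm.pdf(v, m2, s2)

    # crossing of the weighted component densities nearest the density dip
    lo, hi = grid[max(imin - 64, 0)], grid[min(imin + 64, len(grid) - 1)]
    try:
        if diff(lo) * diff(hi) < 0:
            return float(optimize.brentq(diff, lo, hi))
        if diff(m1) * diff(m2) < 0:
            return float(optimize.brentq(diff, m1, m2))
    except ValueError:
        pass
    return float(m1 + 2.0 * s1)


# ---------------------------------------------------------------------------
# step 1: rate sampling and binning


def subject_rates(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-subject accumulation rate versus mean level.

    Rate is the least-squares slope of value on age over all of a subject's
    scans; v_mid is the subject's mean value. Subjects with fewer than two
    scans are excluded (not an error). Returns columns
    ``subject_id, v_mid, rate, n_scans``.
    """
    rows = []
    for sid, grp in cohort.sort_values(["subject_id", "age"], kind="stable").groupby(
        "subject_id", sort=False
    ):
        age = grp["age"].to_numpy(float)
        v = grp["value"].to_numpy(float)
        if age.size < 2:
            continue
        if np.any(np.diff(age) <= 0):
            raise ParameterError(f"ages not strictly increasing for {sid}")
        slope = np.polyfit(age, v, 1)[0]
        rows.append((sid, float(v.mean()), float(slope), int(age.size)))
    return pd.DataFrame(rows, columns=["subject_id", "v_mid", "rate", "n_scans"])


@dataclass
class RateCurve:
    """Binned accumulation rate as a function of level."""

    centers: np.ndarray  # DVR, ascending
    rates: np.ndarray  # DVR/year, floored positive
    counts: np.ndarray
    bin_width: float
    rate_floor: float

    def rate_at(self, v) -> np.ndarray:
        """Linear interpolation between bin centers, constant beyond ends."""
        return np.interp(np.asarray(v, float), self.centers, self.rates)


def bin_rate_curve(
    samples: pd.DataFrame,
    bin_width: float = 0.025,
    min_per_bin: int = 5,
    rate_floor: float = 1e-4,
    trim: float = 0.1,
) -> RateCurve:
    """Discretely sample the rate-versus-level relationship.

    Rate samples are grouped into fixed-width bins of v_mid; each bin
    reports a trimmed mean rate. Bins with fewer than ``min_per_bin``
    samples are merged into the nearest neighbouring bin (sample counts
    conserved). Rates are floored at ``rate_floor`` (> 0) so the integrated
    level-versus-duration curve is strictly increasing, hence invertible.
    """
    if bin_width <= 0:
        raise ParameterError("bin_width must be > 0")
    if rate_floor <= 0:
        raise ParameterError("rate_floor must be > 0")
    v = samples["v_mid"].to_numpy(float)
    r = samples["rate"].to_numpy(float)
    if v.size == 0:
        raise InsufficientDataError("no rate samples")

    start = np.floor(v.min() / bin_width) * bin_width
    idx = np.floor((v - start) / bin_width).astype(int)
    # members per occupied bin, kept ordered by bin index
    bins = [np.flatnonzero(idx == k) for k in np.unique(idx)]

    # merge undersized bins into the nearest neighbour (by member centroid)
    while len(bins) > 1:
        counts = np.array([len(b) for b in bins])
        small = np.flatnonzero(counts < min_per_bin)
        if small.size == 0:
            break
        i = int(small[np.argmin(counts[small])])
        cent = [float(v[b].mean()) for b in bins]
        if i == 0:
            j = 1
        elif i == len(bins) - 1:
            j = i - 1
        else:
            j = i - 1 if abs(cent[i] - cent[i - 1]) <= abs(cent[i] - cent[i + 1]) else i + 1
        lo, hi = min(i, j), max(i, j)
        bins[lo] = np.concatenate([bins[lo], bins[hi]])
        del bins[hi]
    if len(bins) == 1 and len(bins[0]) < min_per_bin:
        raise InsufficientDataError("too few rate samples to form a single bin")

    centers = np.array([float(v[b].mean()) for b in bins])
    rates = np.array([float(stats.trim_mean(r[b], trim)) for b in bins])
    counts = np.array([len(b) for b in bins])
    order = np.argsort(centers)
    return RateCurve(
        centers=centers[order],
        rates=np.maximum(rates[order], rate_floor),
        counts=counts[order],
        bin_width=bin_width,
        rate_floor=rate_floor,
    )


# ---------------------------------------------------------------------------
# step 2: numerical integration


@dataclass
class SilaCurve:
    """Level-versus-duration curve; duration 0 is the positivity threshold."""

    durations: np.ndarray  # years, evenly spaced, ascending
    values: np.ndarray  # DVR, strictly increasing
    threshold: float
    dt: float

    def value_at(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, float), self.durations, self.values)


def integrate_curve(
    rc: RateCurve,
    threshold: float,
    t_range: tuple[float, float] = (-30.0, 30.0),
    dt: float = 0.01,
) -> SilaCurve:
    """Euler-integrate dv/dt = r(v) from the anchor (duration 0, threshold).

    Forward steps v += r(v)*dt and backward steps v -= r(v)*dt out to
    ``t_range``; r is the rate curve linearly interpolated between bin
    centers and held constant beyond them. The positive rate floor
    guarantees a strictly increasing, invertible curve.
    """
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    t_lo, t_hi = t_range
    if not (t_lo <= 0.0 <= t_hi):
        raise ParameterError("t_range must contain 0 (the threshold anchor)")
    n_back = int(round(-t_lo / dt))
    n_fwd = int(round(t_hi / dt))

    fwd = np.empty(n_fwd + 1)
    fwd[0] = threshold
    for i in range(n_fwd):
        rate = rc.rate_at(fwd[i])
        if rate <= 0:
            raise RuntimeError("non-positive interpolated rate during integration")
        fwd[i + 1] = fwd[i] + rate * dt
    back = np.empty(n_back + 1)
    back[0] = threshold
    for i in range(n_back):
        rate = rc.rate_at(back[i])
        if rate <= 0:
            raise RuntimeError("non-positive interpolated rate during integration")
        back[i + 1] = back[i] - rate * dt

    durations = np.concatenate([-dt * np.arange(n_back, 0, -1), dt * np.arange(n_fwd + 1)])
    values = np.concatenate([back[1:][::-1], fwd])
    return SilaCurve(durations=durations, values=values, threshold=float(threshold), dt=dt)


def invert_curve(curve: SilaCurve, v: float) -> float:
    """Duration at which the curve reaches value v (linear interpolation).

    Raises :class:`CensoredValue` when v lies outside the curve's range.
    """
    if v < curve.values[0]:
        raise CensoredValue(v, "below")
    if v > curve.values[-1]:
        raise CensoredValue(v, "above")
    return float(np.interp(v, curve.values, curve.durations))


# ---------------------------------------------------------------------------
# step 3: subject estimates


@dataclass
class SilaEstimate:
    """A subject's estimated amyloid onset age and time-to-Ab+."""

    subject_id: str
    onset_age: float  # nan when censored
    time_to_positive: float  # baseline age - onset age; positive = already Ab+
    censored: bool
    censored_side: str | None
    n_obs_used: int


def estimate_subject_time(
    traj: pd.DataFrame,
    curve: SilaCurve,
    method: str = "all-obs",
) -> SilaEstimate:
    """Solve the curve for one subject's observations.

    Each usable observation j yields an onset-age candidate
    age_j - invert_curve(v_j); ``all-obs`` (default) averages the
    candidates, ``last-obs`` keeps the final scan's. When every observation
    falls outside the curve range the estimate is censored (onset bounded,
    not estimated) and the side records whether the subject sits below or
    above the modelled range.
    """
    if method not in ("all-obs", "last-obs"):
        raise ParameterError(f"unknown method {method!r}")
    grp = traj.sort_values("age", kind="stable")
    sid = str(grp["subject_id"].iloc[0])
    ages = grp["age"].to_numpy(float)
    vals = grp["value"].to_numpy(float)

    candidates, sides = [], []
    for a, v in zip(ages, vals):
        try:
            candidates.append(a - invert_curve(curve, v))
            sides.append(None)
        except CensoredValue as cv:
            candidates.append(np.nan)
            sides.append(cv.side)
    usable = ~np.isnan(candidates)
    if not usable.any():
        side = sides[-1]
        return SilaEstimate(sid, np.nan, np.nan, True, side, 0)
    cand = np.asarray(candidates, float)
    if method == "last-obs":
        onset = float(cand[usable][-1])
        n_used = 1
    else:
        onset = float(cand[usable].mean())
        n_used = int(usable.sum())
    baseline_age = float(ages[0])
    return SilaEstimate(sid, onset, baseline_age - onset, False, None, n_used)


# ---------------------------------------------------------------------------
# estimator


class SilaModel(BaseEstimator):
    """Fit the SILA level-versus-duration curve and estimate onset ages.

    Parameters
    ----------
    threshold : float or "fit"
        Positivity threshold (DVR). ``"fit"`` estimates it from baseline
        values with a two-component Gaussian mixture; the packaged default
        is the source pipeline's 0.87 DVR.
    bin_width, min_per_bin, rate_floor, trim
        Rate-curve binning (see :func:`bin_rate_curve`).
    dt, t_range
        Euler integration step (years) and duration span.
    method : "all-obs" or "last-obs"
        How per-observation onset candidates combine per subject.

    Attributes
    ----------
    threshold_ : float
    rate_samples_ : DataFrame
    rate_curve_ : RateCurve
    curve_ : SilaCurve
    """

    def __init__(
        self,
        threshold=DEFAULT_ABETA_THRESHOLD,
        bin_width=0.025,
        min_per_bin=5,
        rate_floor=1e-4,
        trim=0.1,
        dt=0.01,
        t_range=(-30.0, 30.0),
        method="all-obs",
        random_state=0,
    ):
        self.threshold = threshold
        self.bin_width = bin_width
        self.min_per_bin = min_per_bin
        self.rate_floor = rate_floor
        self.trim = trim
        self.dt = dt
        self.t_range = t_range
        self.method = method
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        """Derive the rate curve and integrated duration curve from a cohort.

        X is a long table ``subject_id, age, value`` (t_years/modality
        columns are ignored here).
        """
        if self.threshold == "fit":
            baselines = (
                X.sort_values(["subject_id", "age"], kind="stable")
                .groupby("subject_id", sort=False)["value"]
                .first()
                .to_numpy()
            )
            self.threshold_ = gmm_threshold(baselines, random_state=self.random_state)
        else:
            self.threshold_ = float(self.threshold)
        self.rate_samples_ = subject_rates(X)
        self.rate_curve_ = bin_rate_curve(
            self.rate_samples_,
            bin_width=self.bin_width,
            min_per_bin=self.min_per_bin,
            rate_floor=self.rate_floor,
            trim=self.trim,
        )
        self.curve_ = integrate_curve(
            self.rate_curve_, self.threshold_, tuple(self.t_range), self.dt
        )
        return self

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-subject onset age and time-to-Ab+ for the subjects in X."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "curve_")
        rows = []
        for sid, grp in X.groupby("subject_id", sort=False):
            est = estimate_subject_time(grp, self.curve_, self.method)
            rows.append(
                (
                    est.subject_id,
                    est.onset_age,
                    est.time_to_positive,
                    est.censored,
                    est.censored_side,
                    est.n_obs_used,
                )
            )
        return pd.DataFrame(
            rows,
            columns=[
                "subject_id",
                "onset_age",
                "time_to_positive",
                "censored",
                "censored_side",
                "n_obs_used",
            ],
        )

    def fit_predict(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).predict(X)
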