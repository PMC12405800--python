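"""Latent cognitive time (c-time) by iterative trajectory alignment.

Each subject's baseline-anchored cognitive trajectory is slid along a shared
group decline curve g to the position ``delta`` minimizing squared error;
the group curve is then refit at the new positions, and the two steps
alternate until the curve parameters converge. The resulting positions are
anchored at a "hinge point" — the c-time value at which longitudinal
cognitive slopes before and after differ significantly (piecewise linear
mixed model scanned on a regular grid) — which defines c-time zero. Larger
(positive) c-time means further into decline; negative means stability or
practice-effect improvement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from sklearn.base import BaseEstimator, TransformerMixin

from .curves import GroupCurveParams, group_curve_eval, predict_shifted, translate_curve
from .exceptions import (
    InputDataError,
    ModelFitError,
    ParameterError,
    UnidentifiableShiftError,
)

__all__ = [
    "ShiftEstimate",
    "CTimeConfig",
    "CTimeResult",
    "HingeScan",
    "baseline_anchor",
    "fit_shift",
    "fit_group_curve",
    "optimize_ctime",
    "hinge_scan",
    "anchor_ctime",
    "CTimeAligner",
]


# ---------------------------------------------------------------------------
# data plumbing


def baseline_anchor(traj: pd.DataFrame) -> pd.DataFrame:
    """Subtract each subject's baseline value so every trajectory starts at 0.

    ``traj`` is a long table with at least ``subject_id, t_years, value``.
    Idempotent: anchoring an anchored table is a no-op.
    """
    if len(traj) == 0:
        raise InputDataError("empty trajectory table")
    out = traj.sort_values(["subject_id", "t_years"], kind="stable").reset_index(drop=True)
    baselines = out.groupby("subject_id", sort=False)["value"].transform("first")
    out["value"] = out["value"] - baselines
    return out


def _split_subjects(cohort: pd.DataFrame) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Long table -> list of (subject_id, t array, y array), t ascending."""
    out = []
    for sid, grp in cohort.sort_values(["subject_id", "t_years"], kind="stable").groupby(
        "subject_id", sort=False
    ):
        t = grp["t_years"].to_numpy(float)
        y = grp["value"].to_numpy(float)
        if t.size and np.any(np.diff(t) <= 0):
            raise InputDataError(f"visit times not strictly increasing for {sid}")
        out.append((sid, t, y))
    return out


# ---------------------------------------------------------------------------
# per-subject shift fit


@dataclass
class ShiftEstimate:
    """A subject's latent position on the group timeline."""

    subject_id: str
    delta: float
    sse: float
    n_obs: int
    converged: bool
    low_information: bool = False


def _shift_sse_grid(theta: GroupCurveParams, t: np.ndarray, y: np.ndarray, grid: np.ndarray):
    """SSE over a vector of candidate shifts (vectorized)."""
    pred = group_curve_eval(theta, grid[:, None] + t[None, :]) - group_curve_eval(theta, grid)[
        :, None
    ]
    return np.sum((y[None, :] - pred) ** 2, axis=1)


def fit_shift(
    traj,
    theta: GroupCurveParams,
    bounds: tuple[float, float] = (-25.0, 10.0),
    init_grid_step: float = 0.5,
    subject_id: str | None = None,
) -> ShiftEstimate:
    """Least-squares latent position of one baseline-anchored trajectory.

    ``traj`` is either a (t, y) pair of arrays or a one-subject long table.
    The objective sum_j (y_j - [g(delta + t_j) - g(delta)])^2 is minimized
    over [delta_min, delta_max] by a coarse grid followed by bounded local
    refinement around the best grid cell.

    Raises
    ------
    UnidentifiableShiftError
        If the curve has no curvature (pure linear g): the shifted
        prediction is then independent of delta.
    """
    if isinstance(traj, pd.DataFrame):
        subject_id = subject_id or str(traj["subject_id"].iloc[0])
        t = traj["t_years"].to_numpy(float)
        y = traj["value"].to_numpy(float)
    else:
        t, y = (np.asarray(a, float) for a in traj)
    lo, hi = float(bounds[0]), float(bounds[1])
    if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
        raise ParameterError("bounds must be finite with min < max")
    if not theta.has_curvature:
        raise UnidentifiableShiftError(
            "group curve is linear: time shifts are unidentifiable"
        )

    grid = np.arange(lo, hi + init_grid_step / 2, init_grid_step)
    sse = _shift_sse_grid(theta, t, y, grid)
    best = grid[int(np.argmin(sse))]

    def obj(d):
        return _shift_sse_grid(theta, t, y, np.array([d]))[0]

    res = optimize.minimize_scalar(
        obj,
        bounds=(max(lo, best - init_grid_step), min(hi, best + init_grid_step)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    candidates = [(float(np.min(sse)), best), (float(res.fun), float(res.x))]
    best_sse, best_d = min(candidates)
    return ShiftEstimate(
        subject_id=subject_id or "",
        delta=best_d,
        sse=best_sse,
        n_obs=int(t.size),
        converged=bool(res.success),
        low_information=t.size < 2,
    )


# ---------------------------------------------------------------------------
# group-curve refit


_THETA_LOWER = np.array([-5.0, -2.0, -20.0, 1e-3])
_THETA_UPPER = np.array([5.0, 2.0, 20.0, 1.5])


def fit_group_curve(
    subjects: list[tuple[str, np.ndarray, np.ndarray]],
    deltas: dict[str, float] | np.ndarray,
    theta_init: GroupCurveParams,
) -> GroupCurveParams:
    """Refit the group curve at fixed subject positions.

    Minimizes the pooled squared error sum_i sum_j
    (y_ij - [g(delta_i + t_ij) - g(delta_i)])^2 over the four curve
    parameters, starting from ``theta_init`` (trust-region least squares, so
    the pooled error never increases relative to the start).
    """
    if len(subjects) < 2:
        raise InputDataError("need at least 2 subjects to refit the group curve")
    if isinstance(deltas, dict):
        dvec = np.array([deltas[sid] for sid, _, _ in subjects])
    else:
        dvec = np.asarray(deltas, float)
    t_all = np.concatenate([t for _, t, _ in subjects])
    y_all = np.concatenate([y for _, _, y in subjects])
    d_all = np.concatenate([np.full(t.size, d) for (_, t, _), d in zip(subjects, dvec)])

    def resid(p):
        th = GroupCurveParams(*p)
        return y_all - (group_curve_eval(th, d_all + t_all) - group_curve_eval(th, d_all))

    x0 = np.clip(theta_init.as_array(), _THETA_LOWER, _THETA_UPPER)
    res = optimize.least_squares(
        resid, x0, bounds=(_THETA_LOWER, _THETA_UPPER), method="trf", xtol=1e-12, ftol=1e-12
    )
    if not np.all(np.isfinite(res.x)):
        raise ModelFitError(f"group curve refit diverged: {res.message}")
    return GroupCurveParams(*res.x)


# ---------------------------------------------------------------------------
# alternating optimization


@dataclass
class CTimeConfig:
    """Knobs of the alternating alignment.

    ``refit_fraction`` < 1 makes the first curve refit use a random subject
    subset (a warm start); all later refits always use every subject.
    """

    theta_init: GroupCurveParams | None = None
    bounds: tuple[float, float] = (-25.0, 10.0)
    tol: float = 1e-4
    max_iter: int = 300
    grid_step: float = 0.5
    min_visits: int = 3
    refit_fraction: float = 1.0
    random_state: int = 0

    def __post_init__(self):
        if self.tol <= 0 or self.max_iter < 1 or self.grid_step <= 0:
            raise ParameterError("tol, max_iter, grid_step must be positive")
        if not (0.0 < self.refit_fraction <= 1.0):
            raise ParameterError("refit_fraction must be in (0, 1]")


@dataclass
class CTimeResult:
    theta: GroupCurveParams
    shifts: pd.DataFrame  # subject_id, delta, sse, n_obs, converged
    trace: list[float] = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0
    n_excluded: int = 0
    config: CTimeConfig | None = None


def _pooled_sse(subjects, theta, deltas):
    return float(
        sum(
            np.sum((y - predict_shifted(theta, deltas[sid], t)) ** 2)
            for sid, t, y in subjects
        )
    )


def optimize_ctime(cohort: pd.DataFrame, config: CTimeConfig | None = None) -> CTimeResult:
    """Alternate per-subject shift fits and group-curve refits to convergence.

    The cohort is baseline-anchored first. Subjects with fewer than
    ``config.min_visits`` visits are excluded (counted, not an error). The
    mean shift is re-centred to zero after every shift pass, with the exactly
    compensating curve reparameterization, pinning the translation gauge
    without changing the objective. Convergence: max parameter change
    relative to max(1, |old|) below ``tol``, or ``max_iter`` reached (result
    flagged, not an error). The recorded objective trace is non-increasing.
    """
    config = config or CTimeConfig()
    anchored = baseline_anchor(cohort)
    subjects = _split_subjects(anchored)
    n0 = len(subjects)
    subjects = [s for s in subjects if s[1].size >= config.min_visits]
    n_excluded = n0 - len(subjects)
    if len(subjects) < 2:
        raise InputDataError("fewer than 2 subjects with enough visits")

    rng = np.random.default_rng(config.random_state)
    shift_rows: dict[str, ShiftEstimate] = {}

    def iterate(theta, deltas, first_iteration):
        """One alternating step; returns (theta, deltas, rel change, sse)."""
        for sid, t, y in subjects:
            est = fit_shift((t, y), theta, config.bounds, config.grid_step, subject_id=sid)
            prev_sse = _shift_sse_grid(theta, t, y, np.array([deltas[sid]]))[0]
            if prev_sse < est.sse:
                # keep the previous position if the refit is no better
                est = ShiftEstimate(sid, deltas[sid], float(prev_sse), t.size, est.converged)
            deltas[sid] = est.delta
            shift_rows[sid] = est

        # pin the translation gauge: recentre shifts, compensate the curve
        c = float(np.mean(list(deltas.values())))
        deltas = {sid: d - c for sid, d in deltas.items()}
        theta = translate_curve(theta, c)

        if first_iteration and config.refit_fraction < 1.0:
            k = max(2, int(round(config.refit_fraction * len(subjects))))
            idx = rng.choice(len(subjects), size=k, replace=False)
            refit_set = [subjects[i] for i in idx]
        else:
            refit_set = subjects
        theta_new = fit_group_curve(refit_set, deltas, theta)
        # a subset refit may not lower the pooled objective; keep monotone
        if _pooled_sse(subjects, theta_new, deltas) <= _pooled_sse(subjects, theta, deltas):
            theta_chg = np.abs(theta_new.as_array() - theta.as_array()) / np.maximum(
                1.0, np.abs(theta.as_array())
            )
            theta = theta_new
        else:
            theta_chg = np.full(4, np.inf)
        return theta, deltas, float(np.max(theta_chg)), _pooled_sse(subjects, theta, deltas)

    if config.theta_init is not None:
        theta = config.theta_init
        deltas = {sid: 0.0 for sid, _, _ in subjects}
        trace = [_pooled_sse(subjects, theta, deltas)]
        pilot_spent = 0
    else:
        # multi-start pilot: the alignment objective has a near-mirror local
        # optimum (rising vs declining curve); run a few alternating steps
        # from each starting curve and keep the branch with the lowest
        # pooled error
        pilot_iters = min(3, config.max_iter)
        best = None
        starts = (
            fit_group_curve(
                subjects, np.zeros(len(subjects)), GroupCurveParams(-0.01, -0.001, -0.01, 0.3)
            ),
            GroupCurveParams(-0.1, -0.005, -0.01, 0.3),
            GroupCurveParams(-0.25, -0.01, -0.05, 0.2),
        )
        for th in starts:
            dl = {sid: 0.0 for sid, _, _ in subjects}
            tr = [_pooled_sse(subjects, th, dl)]
            for _ in range(pilot_iters):
                th, dl, _, sse = iterate(th, dl, first_iteration=False)
                tr.append(sse)
            if best is None or tr[-1] < best[2][-1]:
                best = (th, dl, tr)
        theta, deltas, trace = best
        pilot_spent = pilot_iters

    converged = False
    it = pilot_spent
    for it in range(pilot_spent + 1, config.max_iter + 1):
        theta, deltas, chg, sse = iterate(theta, deltas, first_iteration=(it == pilot_spent + 1))
        trace.append(sse)
        if chg < config.tol:
            converged = True
            break

    shifts = pd.DataFrame(
        {
            "subject_id": [sid for sid, _, _ in subjects],
            "delta": [deltas[sid] for sid, _, _ in subjects],
            "sse": [
                float(_shift_sse_grid(theta, t, y, np.array([deltas[sid]]))[0])
                for sid, t, y in subjects
            ],
            "n_obs": [t.size for _, t, _ in subjects],
            "converged": [shift_rows[sid].converged for sid, _, _ in subjects],
        }
    )
    if not converged:
        warnings.warn("c-time alignment hit max_iter without convergence", stacklevel=2)
    return CTimeResult(
        theta=theta,
        shifts=shifts,
        trace=trace,
        converged=converged,
        n_iter=it,
        n_excluded=n_excluded,
        config=config,
    )


# ---------------------------------------------------------------------------
# hinge point


@dataclass
class HingeScan:
    """Piecewise-slope scan along the group timeline.

    ``table`` has one row per candidate threshold: pre/post slopes, the
    slope-difference Wald statistic, p-value, and model log-likelihood.
    ``hinge`` is the best-fitting (highest log-likelihood) candidate among
    the significant ones, or None (no-hinge sentinel) when no candidate
    reaches significance.
    """

    table: pd.DataFrame
    hinge: float | None
    step: float
    alpha: float


def _fit_hinge_lme(y, exog, t, groups, random_slope, start):
    """One continuous-hinge mixed model fit; None if invalid."""
    exog_re = np.column_stack([np.ones_like(t), t]) if random_slope else np.ones((t.size, 1))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(y, exog, groups=groups, exog_re=exog_re).fit(
                reml=False, method="lbfgs", maxiter=100, disp=False, start_params=start
            )
    except (np.linalg.LinAlgError, ValueError):
        return None
    if np.all(np.isfinite(res.bse[:3])) and res.bse[2] > 0:
        return res
    return None


def hinge_scan(
    cohort: pd.DataFrame,
    ctimes: pd.Series | dict,
    step: float = 0.1,
    alpha: float = 0.05,
    min_obs_side: int = 10,
    min_subjects_side: int = 3,
    correction: str = "bonferroni",
) -> HingeScan:
    """Scan candidate hinge points every ``step`` units along the timeline.

    Each observation is positioned at delta_i + t_ij on the group timeline
    (a subject can cross the hinge mid-follow-up). For each candidate h a
    linear mixed model with a continuous slope break at h (random intercept
    and slope per subject) tests the pre/post slope difference. Candidates
    need at least ``min_obs_side`` observations and ``min_subjects_side``
    subjects on each side. Significance is Bonferroni-corrected across the
    scanned grid by default (``correction="none"`` disables); the chosen
    hinge is the significant candidate with the highest model log-likelihood
    (profile-likelihood knot location), or the no-hinge sentinel (None) when
    none is significant.
    """
    if step <= 0:
        raise ParameterError("step must be > 0")
    anchored = baseline_anchor(cohort)
    dmap = dict(ctimes) if not isinstance(ctimes, dict) else ctimes
    df = anchored[anchored["subject_id"].isin(dmap)].copy()
    df["position"] = df["subject_id"].map(dmap) + df["t_years"]

    pos = df["position"].to_numpy(float)
    y = df["value"].to_numpy(float)
    t = df["t_years"].to_numpy(float)
    groups = df["subject_id"].to_numpy()

    lo = np.ceil(pos.min() / step) * step
    candidates = np.arange(lo, pos.max(), step)

    def estimable(h):
        post = pos >= h
        n_post = int(post.sum())
        if n_post < min_obs_side or (len(post) - n_post) < min_obs_side:
            return False
        return (
            len(np.unique(groups[post])) >= min_subjects_side
            and len(np.unique(groups[~post])) >= min_subjects_side
        )

    usable = [h for h in candidates if estimable(h)]
    if not usable:
        return HingeScan(
            table=pd.DataFrame(
                columns=["hinge", "slope_pre", "slope_post", "stat", "pvalue", "loglik"]
            ),
            hinge=None, step=step, alpha=alpha,
        )
    # choose the random-effects structure ONCE, on a central candidate, so
    # log-likelihoods stay comparable across the scan: random slope if it is
    # estimable there (it degenerates when slope variance is ~0), else
    # random intercept only
    h_mid = usable[len(usable) // 2]
    exog_mid = np.column_stack([np.ones_like(pos), pos, np.maximum(pos - h_mid, 0.0)])
    random_slope = _fit_hinge_lme(y, exog_mid, t, groups, True, None) is not None

    rows = []
    start = None
    for h in usable:
        exog = np.column_stack([np.ones_like(pos), pos, np.maximum(pos - h, 0.0)])
        res = _fit_hinge_lme(y, exog, t, groups, random_slope, start)
        if res is None and start is not None:
            res = _fit_hinge_lme(y, exog, t, groups, random_slope, None)
        if res is None:
            continue
        start = res.params_object
        stat = float(res.params[2] / res.bse[2])
        rows.append(
            {
                "hinge": float(h),
                "slope_pre": float(res.params[1]),
                "slope_post": float(res.params[1] + res.params[2]),
                "stat": stat,
                "pvalue": float(res.pvalues[2]),
                "loglik": float(res.llf),
            }
        )
    table = pd.DataFrame(
        rows, columns=["hinge", "slope_pre", "slope_post", "stat", "pvalue", "loglik"]
    )
    if correction == "bonferroni" and len(table):
        thresh = alpha / len(table)
    else:
        thresh = alpha
    sig = table[table["pvalue"] < thresh]
    # the knot is located by profile likelihood: among significant
    # candidates the best-fitting break point, not the largest t (which
    # peaks where the contrast is most precise, not where the break is)
    hinge = None if sig.empty else float(sig.loc[sig["loglik"].idxmax(), "hinge"])
    return HingeScan(table=table, hinge=hinge, step=step, alpha=alpha)


def anchor_ctime(ctimes, hinge: float):
    """Subtract the hinge so a subject at the hinge maps to c-time 0."""
    if not np.isfinite(hinge):
        raise ParameterError("hinge must be finite")
    if isinstance(ctimes, pd.Series):
        return ctimes - hinge
    return np.asarray(ctimes, float) - hinge


# ---------------------------------------------------------------------------
# estimator


class CTimeAligner(TransformerMixin, BaseEstimator):
    """Estimate latent cognitive time by aligning trajectories to a shared curve.

    Parameters mirror :class:`CTimeConfig` plus the hinge scan. ``fit``
    expects a long table ``subject_id, t_years, value`` (extra columns
    ignored); fitted attributes follow sklearn conventions.

    Attributes
    ----------
    curve_params_ : GroupCurveParams
        Converged group decline curve.
    shifts_ : DataFrame
        Per-subject latent positions (unanchored).
    hinge_ : float or None
        Chosen hinge point on the unanchored scale (None if no significant
        slope break was found; c-times are then left unanchored).
    ctimes_ : DataFrame
        ``subject_id, delta, ctime`` with ctime = delta - hinge.
    trace_ : list of float
        Pooled squared error per iteration (non-increasing).
    """

    def __init__(
        self,
        theta_init=None,
        bounds=(-25.0, 10.0),
        tol=1e-4,
        max_iter=300,
        grid_step=0.5,
        min_visits=3,
        refit_fraction=1.0,
        hinge_step=0.1,
        alpha=0.05,
        scan_hinge=True,
        random_state=0,
    ):
        self.theta_init = theta_init
        self.bounds = bounds
        self.tol = tol
        self.max_iter = max_iter
        self.grid_step = grid_step
        self.min_visits = min_visits
        self.refit_fraction = refit_fraction
        self.hinge_step = hinge_step
        self.alpha = alpha
        self.scan_hinge = scan_hinge
        self.random_state = random_state

    def _config(self) -> CTimeConfig:
        return CTimeConfig(
            theta_init=self.theta_init,
            bounds=tuple(self.bounds),
            tol=self.tol,
            max_iter=self.max_iter,
            grid_step=self.grid_step,
            min_visits=self.min_visits,
            refit_fraction=self.refit_fraction,
            random_state=self.random_state,
        )

    def fit(self, X: pd.DataFrame, y=None):
        result = optimize_ctime(X, self._config())
        self.result_ = result
        self.curve_params_ = result.theta
        self.shifts_ = result.shifts
        self.trace_ = result.trace
        self.converged_ = result.converged
        self.n_iter_ = result.n_iter
        deltas = result.shifts.set_index("subject_id")["delta"]
        if self.scan_hinge:
            self.hinge_scan_ = hinge_scan(X, deltas, step=self.hinge_step, alpha=self.alpha)
            self.hinge_ = self.hinge_scan_.hinge
        else:
            self.hinge_scan_ = None
            self.hinge_ = None
        ct = deltas if self.hinge_ is None else anchor_ctime(deltas, self.hinge_)
        self.ctimes_ = pd.DataFrame(
            {"subject_id": deltas.index, "delta": deltas.to_numpy(), "ctime": ct.to_numpy()}
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Anchored c-times for the subjects in X (refit against the curve)."""
        return self.predict(X)

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "curve_params_")
        anchored = baseline_anchor(X)
        rows = []
        for sid, t, y in _split_subjects(anchored):
            est = fit_shift((t, y), self.curve_params_, tuple(self.bounds), self.grid_step, sid)
            ct = est.delta - (self.hinge_ or 0.0)
            rows.append((sid, est.delta, ct, est.sse, est.n_obs, est.converged))
        return pd.DataFrame(
            rows, columns=["subject_id", "delta", "ctime", "sse", "n_obs", "converged"]
        )
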