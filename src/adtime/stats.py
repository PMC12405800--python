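"""Inferential layer: diagnostics, associations, survival, mediation, paths.

These are the analyses run downstream of the two latent-time estimates:
distribution diagnostics (moment skewness/kurtosis, Jarque-Bera), Spearman
correlation with an exact small-sample permutation p, Kruskal-Wallis and
age-adjusted regressions, Cox validation of c-time against conversion,
linear mixed models for longitudinal biomarker slopes, single-mediator
mediation with percent mediated, and a recursive multi-mediator path model
on standardized variables.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats as sps

from .exceptions import InputDataError, ModelFitError, ParameterError

__all__ = [
    "DistributionStats",
    "SurvivalValidation",
    "SlopeModelResult",
    "MediationResult",
    "PathModelResult",
    "dist_stats",
    "spearman",
    "kruskal_wallis",
    "age_adjusted_regression",
    "cox_validation",
    "slope_model",
    "mediate",
    "path_fit",
]


# ---------------------------------------------------------------------------
# distribution diagnostics


@dataclass
class DistributionStats:
    n: int
    skewness: float  # standardized third moment
    kurtosis: float  # standardized fourth moment, normal = 3 (non-excess)
    jb_stat: float
    jb_p: float


def dist_stats(x) -> DistributionStats:
    """Moment-based skewness/kurtosis and the Jarque-Bera normality test.

    Kurtosis uses the non-excess convention (normal = 3);
    JB = n/6 * (S^2 + (K-3)^2 / 4), with p from chi-squared(2).
    """
    x = np.asarray(x, float)
    n = x.size
    if n < 4:
        raise ParameterError("need at least 4 observations")
    xc = x - x.mean()
    m2 = np.mean(xc**2)
    if m2 <= 0:
        raise InputDataError("zero variance: moments undefined")
    s = np.mean(xc**3) / m2**1.5
    k = np.mean(xc**4) / m2**2
    jb = n / 6.0 * (s**2 + (k - 3.0) ** 2 / 4.0)
    return DistributionStats(n, float(s), float(k), float(jb), float(sps.chi2.sf(jb, 2)))


# ---------------------------------------------------------------------------
# correlations / group tests


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc, ryc = rx - rx.mean(), ry - ry.mean()
    denom = np.sqrt(np.sum(rxc**2) * np.sum(ryc**2))
    return float(np.sum(rxc * ryc) / denom)


def spearman(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties.

    p-value by the t approximation, or by exhaustive permutation of the rank
    vector for n <= ``exact_max_n`` (two-sided).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 4:
        raise ParameterError("x and y must have equal length >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputDataError("constant input: correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rank_corr(rx, ry)
    n = x.size
    if n <= exact_max_n:
        perms = np.array(list(itertools.permutations(ry)))
        rxc = rx - rx.mean()
        pc = perms - ry.mean()
        stats_all = pc @ rxc / np.sqrt(np.sum(rxc**2) * np.sum((ry - ry.mean()) ** 2))
        p = float(np.mean(np.abs(stats_all) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            tstat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * sps.t.sf(abs(tstat), n - 2))
    return rho, p


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis H test of a value across group labels."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in np.unique(groups)]
    if len(samples) < 2:
        raise ParameterError("need at least 2 groups")
    h, p = sps.kruskal(*samples)
    return float(h), float(p)


def age_adjusted_regression(y, x, age) -> tuple[float, float, float]:
    """OLS of y on x adjusting for age; returns (coef_x, se, p)."""
    X = sm.add_constant(np.column_stack([np.asarray(x, float), np.asarray(age, float)]))
    res = sm.OLS(np.asarray(y, float), X).fit()
    return float(res.params[1]), float(res.bse[1]), float(res.pvalues[1])


# ---------------------------------------------------------------------------
# survival validation


@dataclass
class SurvivalValidation:
    hazard_ratio: float  # per unit of c-time
    se_log_hr: float
    p: float
    n_events: int
    ci_low: float  # 95% CI on the HR scale
    ci_high: float


def cox_validation(ctimes, survival: pd.DataFrame) -> SurvivalValidation:
    """Cox proportional-hazards association of c-time with conversion.

    ``survival`` has columns ``time`` and ``event``; ``ctimes`` aligns with
    its rows. Partial-likelihood fit with Efron tie handling.
    """
    df = pd.DataFrame(
        {
            "ctime": np.asarray(ctimes, float),
            "time": survival["time"].to_numpy(float),
            "event": survival["event"].to_numpy(int),
        }
    )
    if df["event"].sum() < 1:
        raise ModelFitError("no events: Cox model cannot be fit")
    if df["ctime"].nunique() == 1:
        # no information in the covariate: beta-hat is exactly 0
        return SurvivalValidation(1.0, np.inf, 1.0, int(df["event"].sum()), 0.0, np.inf)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises several convergence types
        raise ModelFitError(f"Cox fit failed: {exc}") from exc
    beta = float(cph.params_["ctime"])
    se = float(cph.standard_errors_["ctime"])
    return SurvivalValidation(
        hazard_ratio=float(np.exp(beta)),
        se_log_hr=se,
        p=float(cph.summary.loc["ctime", "p"]),
        n_events=int(df["event"].sum()),
        ci_low=float(np.exp(beta - 1.959964 * se)),
        ci_high=float(np.exp(beta + 1.959964 * se)),
    )


# ---------------------------------------------------------------------------
# longitudinal slopes


@dataclass
class SlopeModelResult:
    outcome: str
    estimate: float  # metric x time interaction
    se: float
    p: float
    covariates: tuple = ("age", "sex")
    random_slope: bool = True
    fallback: str = "none"  # "intercept-only" or "ols" when the LME degenerates


def slope_model(
    long_table: pd.DataFrame,
    metric: pd.Series,
    covariates: pd.DataFrame,
    outcome_name: str = "value",
) -> SlopeModelResult:
    """Effect of a per-subject metric on an outcome's longitudinal slope.

    Linear mixed model value ~ metric + time + metric:time + age + sex with
    a subject random intercept and slope on time; falls back to a random
    intercept only when the slope model does not converge. Returns the
    metric-by-time interaction.
    """
    # the long table's per-visit "age" column must not shadow the baseline
    # age covariate
    df = long_table.merge(
        metric.rename("metric"), left_on="subject_id", right_index=True
    ).merge(
        covariates, left_on="subject_id", right_index=True, suffixes=("_visit", "")
    )
    n_multi = df.groupby("subject_id")["t_years"].nunique()
    if (n_multi >= 2).mean() < 0.5:
        raise InputDataError("fewer than half the subjects have repeat visits")

    formula = "value ~ metric + t_years + metric:t_years + age + sex"
    for re_formula, random_slope, fb in (
        ("~t_years", True, "none"),
        ("~1", False, "intercept-only"),
    ):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.MixedLM.from_formula(
                    formula, groups="subject_id", re_formula=re_formula, data=df
                ).fit(reml=True, method="lbfgs", maxiter=300, disp=False)
            se = float(res.bse["metric:t_years"])
            if np.isfinite(se) and se > 0:
                return SlopeModelResult(
                    outcome=outcome_name,
                    estimate=float(res.params["metric:t_years"]),
                    se=se,
                    p=float(res.pvalues["metric:t_years"]),
                    random_slope=random_slope,
                    fallback=fb,
                )
        except (np.linalg.LinAlgError, ValueError):
            continue
    # degenerate (e.g. zero residual variance): plain OLS still identifies
    # the fixed effects, with exact coefficients in the noise-free limit
    try:
        res = sm.OLS.from_formula(formula, data=df).fit()
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise ModelFitError("slope model singular even as OLS") from exc
    se = float(res.bse["metric:t_years"])
    return SlopeModelResult(
        outcome=outcome_name,
        estimate=float(res.params["metric:t_years"]),
        se=se if np.isfinite(se) and se > 0 else 0.0,
        p=float(res.pvalues["metric:t_years"]),
        random_slope=False,
        fallback="ols",
    )


# ---------------------------------------------------------------------------
# mediation


@dataclass
class MediationResult:
    """Product-of-coefficients single-mediator decomposition.

    a: X->M; b: M->Y given X; c_prime: direct X->Y given M.
    indirect = a*b; total = a*b + c_prime;
    proportion_mediated = a*b / (a*b + c_prime), flagged unreliable when the
    indirect and total effects disagree in sign.
    """

    a: float
    b: float
    c_prime: float
    indirect: float
    total: float
    proportion_mediated: float
    proportion_reliable: bool
    ci: dict = field(default_factory=dict)  # percentile bootstrap CIs
    n: int = 0
    n_boot: int = 0
    covariates: tuple = ()


def _lstsq_coef(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(X, y, rcond=None)[0]


def mediate(
    x,
    m,
    y,
    covariates: pd.DataFrame | np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> MediationResult:
    """Single-mediator mediation with a seeded percentile bootstrap.

    a from m ~ x + covariates; b and c' from y ~ x + m + covariates.
    Subjects are resampled whole; the same seed reproduces identical CIs.
    """
    x = np.asarray(x, float)
    m = np.asarray(m, float)
    yv = np.asarray(y, float)
    n = x.size
    cov_names: tuple = ()
    if covariates is not None:
        if isinstance(covariates, pd.DataFrame):
            cov_names = tuple(covariates.columns)
            cov = covariates.to_numpy(float)
        else:
            cov = np.asarray(covariates, float)
            if cov.ndim == 1:
                cov = cov[:, None]
            cov_names = tuple(f"cov{i}" for i in range(cov.shape[1]))
    else:
        cov = np.empty((n, 0))
    mask = np.isfinite(x) & np.isfinite(m) & np.isfinite(yv) & np.all(np.isfinite(cov), axis=1)
    x, m, yv, cov = x[mask], m[mask], yv[mask], cov[mask]
    n = x.size
    if n < 30:
        raise ParameterError("need at least 30 complete cases")
    if n_boot < 500:
        raise ParameterError("n_boot must be >= 500")

    ones = np.ones((n, 1))
    Xm = np.hstack([ones, x[:, None], cov])
    Xy = np.hstack([ones, x[:, None], m[:, None], cov])

    def effects(idx):
        a = _lstsq_coef(Xm[idx], m[idx])[1]
        coefs = _lstsq_coef(Xy[idx], yv[idx])
        c_prime, b = coefs[1], coefs[2]
        ab = a * b
        return np.array([a, b, c_prime, ab, ab + c_prime, _safe_prop(ab, ab + c_prime)])

    point = effects(np.arange(n))
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, 6))
    for i in range(n_boot):
        boot[i] = effects(rng.integers(0, n, n))
    alpha = (1.0 - ci_level) / 2.0
    qs = np.nanquantile(boot, [alpha, 1.0 - alpha], axis=0)
    names = ["a", "b", "c_prime", "indirect", "total", "proportion_mediated"]
    ci = {nm: (float(qs[0, j]), float(qs[1, j])) for j, nm in enumerate(names)}

    ab, tot = point[3], point[4]
    return MediationResult(
        a=float(point[0]),
        b=float(point[1]),
        c_prime=float(point[2]),
        indirect=float(ab),
        total=float(tot),
        proportion_mediated=float(point[5]),
        proportion_reliable=bool(ab * tot >= 0),
        ci=ci,
        n=n,
        n_boot=n_boot,
        covariates=cov_names,
    )


def _safe_prop(ab, total):
    return np.nan if total == 0 else ab / total


# ---------------------------------------------------------------------------
# path analysis


@dataclass
class PathModelResult:
    """Recursive path model on standardized variables.

    ``edges`` has one row per directed edge (src, dst, beta, se, p);
    ``indirect`` one row per declared path with its product-of-coefficients
    estimate and percentile bootstrap CI.
    """

    edges: pd.DataFrame
    indirect: pd.DataFrame
    covariates: tuple = ()
    n: int = 0


def _topo_endogenous(edge_list):
    import graphlib

    nodes = set()
    graph: dict[str, set[str]] = {}
    for src, dst in edge_list:
        nodes.update((src, dst))
        graph.setdefault(dst, set()).add(src)
        graph.setdefault(src, set())
    try:
        order = list(graphlib.TopologicalSorter(graph).static_order())
    except graphlib.CycleError as exc:
        raise ParameterError("path DAG contains a cycle") from exc
    return [v for v in order if graph[v]], {v: sorted(graph[v]) for v in nodes}


def path_fit(
    table: pd.DataFrame,
    dag: list[tuple[str, str]],
    covariates: list[str] | tuple = (),
    indirect_paths: list[tuple[str, ...]] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> PathModelResult:
    """Estimate a recursive path model as DAG-ordered least squares.

    All model variables are z-standardized; each endogenous variable is
    regressed on its DAG parents plus the adjustment covariates, so the
    reported coefficients are standardized partial regression weights.
    Indirect effects are products of coefficients along declared paths, with
    seeded percentile bootstrap CIs (subjects resampled whole).
    """
    endo, parents = _topo_endogenous(dag)
    model_vars = sorted({v for e in dag for v in e} | set(covariates))
    missing = [v for v in model_vars if v not in table.columns]
    if missing:
        raise ParameterError(f"columns missing from table: {missing}")
    data = table[model_vars].dropna()
    n = len(data)
    z = (data - data.mean()) / data.std(ddof=1)

    def fit_edges(zdf):
        coef = {}
        for node in endo:
            preds = parents[node] + [c for c in covariates if c not in parents[node]]
            X = np.hstack([np.ones((len(zdf), 1)), zdf[preds].to_numpy()])
            beta = _lstsq_coef(X, zdf[node].to_numpy())
            for j, p in enumerate(preds, start=1):
                if (p, node) in dag_set:
                    coef[(p, node)] = beta[j]
        return coef

    dag_set = set(dag)
    # point estimates with SEs/p-values from OLS per equation
    rows = []
    coef_point = {}
    for node in endo:
        preds = parents[node] + [c for c in covariates if c not in parents[node]]
        X = sm.add_constant(z[preds].to_numpy())
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            warnings.warn(f"collinear predictors in equation for {node!r}", stacklevel=2)
        res = sm.OLS(z[node].to_numpy(), X).fit()
        for j, p in enumerate(preds, start=1):
            if (p, node) in dag_set:
                coef_point[(p, node)] = float(res.params[j])
                rows.append(
                    {
                        "src": p,
                        "dst": node,
                        "beta": float(res.params[j]),
                        "se": float(res.bse[j]),
                        "p": float(res.pvalues[j]),
                    }
                )
    edges_df = pd.DataFrame(rows, columns=["src", "dst", "beta", "se", "p"])

    indirect_paths = indirect_paths or []
    ind_rows = []
    if indirect_paths:
        rng = np.random.default_rng(seed)
        boot = np.empty((n_boot, len(indirect_paths)))
        idx_all = np.arange(n)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            zb_raw = data.iloc[idx]
            zb = (zb_raw - zb_raw.mean()) / zb_raw.std(ddof=1)
            cb = fit_edges(zb.reset_index(drop=True))
            for k, path in enumerate(indirect_paths):
                prod = 1.0
                for s, d in zip(path[:-1], path[1:]):
                    prod *= cb.get((s, d), np.nan)
                boot[b, k] = prod
        alpha = (1.0 - ci_level) / 2.0
        for k, path in enumerate(indirect_paths):
            prod = 1.0
            for s, d in zip(path[:-1], path[1:]):
                prod *= coef_point.get((s, d), np.nan)
            lo, hi = np.nanquantile(boot[:, k], [alpha, 1.0 - alpha])
            ind_rows.append(
                {
                    "path": " -> ".join(path),
                    "estimate": float(prod),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
            )
        _ = idx_all
    indirect_df = pd.DataFrame(ind_rows, columns=["path", "estimate", "ci_low", "ci_high"])
    return PathModelResult(
        edges=edges_df, indirect=indirect_df, covariates=tuple(covariates), n=n
    )
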