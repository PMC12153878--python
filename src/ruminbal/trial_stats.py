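"""Crossover-trial statistics.

Quality filters, robust outlier screening, the crossover linear mixed
model with its transformation/fallback ladder, Tukey-Kramer pairwise
contrasts, and the two design-planning calculations (equivalence TOST
sample size and two-sample t-test sample size).

Model structure
---------------
Fixed effects: group, period, sequence, block (plus an optional time
factor and its group interaction for repeated measures); random intercept
per cow. Inference uses Wald F/t statistics with between-within
("containment") denominator degrees of freedom, which for balanced
complete crossover designs coincide with the Satterthwaite values.

Fallback ladder (applied in order, the path taken is recorded):
``lmm`` -> ``lmm-log2`` (residual non-normality) -> ``glmm-gamma``
(non-normality persists after log2) and, whenever a random-intercept fit
is singular, ``lm`` (fixed effects only). Heteroscedasticity is recorded
as a diagnostic but never triggers a fallback.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.optimize import minimize_scalar
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan

__all__ = [
    "ModelSpec",
    "ModelFit",
    "Contrast",
    "PowerSpec",
    "robust_z_outliers",
    "exclusion_filter",
    "fit_crossover_model",
    "tukey_kramer",
    "tost_power",
    "tost_sample_size",
    "t_power_n",
]

#: chamber cow-periods with mean DMI/mBW below this are excluded
MIN_DMI_PER_MBW = 0.1


# ---------------------------------------------------------------------------
# screening

def robust_z_outliers(values, threshold: float = 3.5) -> np.ndarray:
    """Flag values whose robust z score ``(x - median) / (1.4826 MAD)``
    exceeds ``threshold`` in absolute value.

    A zero MAD yields no flags and a warning (the screen is undefined for
    majority-constant data).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("robust_z_outliers needs a 1-d sample of >= 3 values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        warnings.warn(
            "MAD is zero: robust z scores undefined, no values flagged",
            UserWarning,
            stacklevel=2,
        )
        return np.zeros(x.shape, dtype=bool)
    z = (x - med) / (1.4826 * mad)
    return np.abs(z) > threshold


def exclusion_filter(
    records: pd.DataFrame, min_dmi_per_mbw: float = MIN_DMI_PER_MBW
) -> tuple[pd.DataFrame, list[dict]]:
    """Drop chamber cow-periods whose mean DMI per metabolic body weight is
    strictly below ``min_dmi_per_mbw`` kg/kg^0.75.

    ``records`` must carry ``cow_id``, ``period``, ``dmi_kg_d`` and either
    ``mbw`` or ``bw_kg``. Returns the retained rows plus an exclusion log.
    """
    df = records.copy()
    if "mbw" not in df.columns:
        if "bw_kg" not in df.columns:
            raise ValueError("records need an 'mbw' or 'bw_kg' column")
        df["mbw"] = df["bw_kg"].astype(float) ** 0.75
    log: list[dict] = []
    keep = pd.Series(True, index=df.index)
    for (cow, period), grp in df.groupby(["cow_id", "period"]):
        ratio = grp["dmi_kg_d"].mean() / grp["mbw"].mean()
        if ratio < min_dmi_per_mbw:
            keep.loc[grp.index] = False
            log.append(
                {
                    "cow_id": cow,
                    "period": period,
                    "dmi_per_mbw": float(ratio),
                    "reason": (
                        f"mean DMI/mBW {ratio:.4f} < {min_dmi_per_mbw:g} "
                        "kg/kg^0.75"
                    ),
                }
            )
    return df[keep], log


# ---------------------------------------------------------------------------
# model specification / results

@dataclass
class ModelSpec:
    """Configuration for one response's crossover model."""

    response: str
    factors: tuple[str, ...] = ("group", "period", "sequence", "block")
    time: str | None = None  # adds `time` and group x time fixed effects
    transformation: str = "none"  # none | log2 | gamma-glmm
    alpha: float = 0.05
    trend_alpha: float = 0.10
    diag_alpha: float = 0.05
    singular_tol: float = 1e-4  # on sd(cow)/sd(resid)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.transformation not in ("none", "log2", "gamma-glmm"):
            raise ValueError(f"unknown transformation {self.transformation!r}")


@dataclass(frozen=True)
class Contrast:
    """One pairwise group contrast on the model (link) scale."""

    level_a: str
    level_b: str
    estimate: float
    se: float
    df: float
    p_tukey: float


@dataclass
class ModelFit:
    """Fitted crossover model for one response."""

    response: str
    fallback_path: str  # lmm | lmm-log2 | glmm-gamma | lm
    transformation: str  # none | log2 | gamma-log
    emm: dict[str, float]  # response scale (back-transformed)
    emm_se: dict[str, float]
    emm_link: dict[str, float]  # model/link scale
    emm_link_se: dict[str, float]
    p_values: dict[str, float]
    contrasts: list[Contrast]
    diagnostics: dict = field(default_factory=dict)

    def effect_estimate(self, level_a: str = "HEMP", level_b: str = "CON") -> float:
        """Group difference on the model scale."""
        return self.emm_link[level_a] - self.emm_link[level_b]


# ---------------------------------------------------------------------------
# design-matrix machinery (treatment coding, first sorted level = reference)

@dataclass
class _DesignInfo:
    columns: list[tuple[str, tuple[tuple[str, object], ...]]]
    factor_levels: dict[str, list]
    terms: list[str]

    def build(self, data: pd.DataFrame) -> np.ndarray:
        n = len(data)
        X = np.ones((n, len(self.columns)))
        for j, (_, conds) in enumerate(self.columns):
            for fac, lev in conds:
                X[:, j] *= (data[fac].to_numpy() == lev).astype(float)
        return X

    def row(self, combo: dict) -> np.ndarray:
        x = np.ones(len(self.columns))
        for j, (_, conds) in enumerate(self.columns):
            for fac, lev in conds:
                x[j] *= float(combo[fac] == lev)
        return x

    def term_columns(self, term: str) -> list[int]:
        return [j for j, (t, _) in enumerate(self.columns) if t == term]


def _design_info(data: pd.DataFrame, factors, time: str | None) -> _DesignInfo:
    columns: list[tuple[str, tuple[tuple[str, object], ...]]] = [
        ("Intercept", ())
    ]
    levels: dict[str, list] = {}
    terms = ["Intercept"]
    all_factors = list(factors) + ([time] if time else [])
    for fac in all_factors:
        levs = sorted(data[fac].unique().tolist())
        if len(levs) < 2:
            raise ValueError(f"factor {fac!r} has a single level {levs}")
        levels[fac] = levs
        terms.append(fac)
        for lev in levs[1:]:
            columns.append((fac, ((fac, lev),)))
    if time:
        term = f"group:{time}"
        terms.append(term)
        for glev in levels["group"][1:]:
            for tlev in levels[time][1:]:
                columns.append((term, (("group", glev), (time, tlev))))
    return _DesignInfo(columns, levels, terms)


def _between_within_dfs(
    data: pd.DataFrame, di: _DesignInfo, X: np.ndarray
) -> tuple[float, float, dict[str, str]]:
    """Containment denominator dfs and per-term classification."""
    cows = data["cow"].to_numpy()
    uniq = pd.unique(cows)
    n_cows = len(uniq)
    n_obs = len(data)
    scope: dict[str, str] = {"Intercept": "between"}
    within_cols: list[int] = []
    between_cols: list[int] = [0]
    for term in di.terms:
        if term == "Intercept":
            continue
        cols = di.term_columns(term)
        varies = False
        for cow in uniq:
            sub = X[cows == cow][:, cols]
            if not np.allclose(sub, sub[0]):
                varies = True
                break
        scope[term] = "within" if varies else "between"
        (within_cols if varies else between_cols).extend(cols)
    # between design collapsed to one row per cow
    rows = []
    for cow in uniq:
        rows.append(X[cows == cow][0, between_cols])
    rank_between = np.linalg.matrix_rank(np.asarray(rows))
    rank_full = np.linalg.matrix_rank(X)
    df_between = max(n_cows - rank_between, 1)
    df_within = max(n_obs - n_cows - (rank_full - rank_between), 1)
    return df_within, df_between, scope


@dataclass
class _FitCore:
    params: np.ndarray
    cov: np.ndarray
    resid: np.ndarray
    fitted: np.ndarray
    kind: str  # lmm | lm | glmm
    var_cow: float
    scale: float
    singular: bool
    converged: bool


def _reml_profile(
    y: np.ndarray, X: np.ndarray, group_idx: list[np.ndarray], lam: float
):
    """GLS quantities for V0 = I + lam * J within each group (Woodbury)."""
    p = X.shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    ytVy = 0.0
    logdet_v0 = 0.0
    for idx in group_idx:
        Xg, yg = X[idx], y[idx]
        ng = len(idx)
        shrink = lam / (1.0 + ng * lam)
        xs, ys = Xg.sum(axis=0), yg.sum()
        XtVX += Xg.T @ Xg - shrink * np.outer(xs, xs)
        XtVy += Xg.T @ yg - shrink * xs * ys
        ytVy += yg @ yg - shrink * ys * ys
        logdet_v0 += np.log1p(ng * lam)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = max(ytVy - beta @ XtVy, 1e-300)
    return beta, XtVX, rss, logdet_v0


def _fit_lmm(y: np.ndarray, X: np.ndarray, cows: np.ndarray, tol: float) -> _FitCore:
    """Random-intercept linear mixed model by profiled REML.

    The variance ratio lam = var(cow) / var(resid) is profiled out,
    leaving a one-dimensional REML criterion optimized on the log scale
    with an explicit boundary check at lam = 0.
    """
    n, p = X.shape
    codes = pd.factorize(cows)[0]
    group_idx = [np.flatnonzero(codes == g) for g in range(codes.max() + 1)]

    def nll(log_lam: float) -> float:
        lam = np.exp(log_lam)
        beta, XtVX, rss, logdet_v0 = _reml_profile(y, X, group_idx, lam)
        sign, logdet_x = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf
        return 0.5 * ((n - p) * np.log(rss) + logdet_v0 + logdet_x)

    # coarse grid then local refinement; compare against the lam=0 boundary
    grid = np.linspace(-12.0, 12.0, 33)
    values = [nll(g) for g in grid]
    k = int(np.argmin(values))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    opt = minimize_scalar(nll, bounds=(lo, hi), method="bounded")
    lam_hat = float(np.exp(opt.x))
    if nll(np.log(1e-12)) <= opt.fun:
        lam_hat = 0.0

    beta, XtVX, rss, _ = _reml_profile(y, X, group_idx, max(lam_hat, 0.0))
    sigma2 = rss / (n - p)
    cov = sigma2 * np.linalg.inv(XtVX)
    var_cow = lam_hat * sigma2
    # conditional fit: BLUP of the cow intercepts
    r = y - X @ beta
    fitted = X @ beta
    for idx in group_idx:
        ng = len(idx)
        b = lam_hat * ng / (1.0 + ng * lam_hat) * r[idx].mean()
        fitted[idx] += b
    resid = y - fitted
    singular = np.sqrt(lam_hat) < tol
    return _FitCore(beta, cov, resid, fitted, "lmm", var_cow, sigma2, singular, True)


def _fit_ols(y: np.ndarray, X: np.ndarray) -> _FitCore:
    res = sm.OLS(y, X).fit()
    return _FitCore(
        np.asarray(res.params),
        np.asarray(res.cov_params()),
        np.asarray(res.resid),
        np.asarray(res.fittedvalues),
        "lm",
        0.0,
        float(res.scale),
        False,
        True,
    )


def _fit_gamma_pql(
    y: np.ndarray,
    X: np.ndarray,
    cows: np.ndarray,
    tol: float,
    max_iter: int = 50,
) -> _FitCore:
    """Gamma GLMM with natural-log link via penalized quasi-likelihood.

    For the gamma family with a log link the working weights are constant,
    so each PQL step reduces to a linear mixed model on the working
    response ``eta + (y - mu) / mu``.
    """
    if np.any(y <= 0):
        raise ValueError("gamma GLMM requires strictly positive responses")
    eta = np.log(y)
    core = None
    for _ in range(max_iter):
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        core = _fit_lmm(z, X, cows, tol)
        if not core.converged:
            break
        # conditional linear predictor from the working fit
        eta_new = core.fitted
        if np.max(np.abs(eta_new - eta)) < 1e-8:
            eta = eta_new
            break
        eta = eta_new
    mu = np.exp(eta)
    pearson = (y - mu) / mu
    core = _FitCore(
        core.params, core.cov, pearson, mu, "glmm",
        core.var_cow, core.scale, core.singular, core.converged,
    )
    return core


# ---------------------------------------------------------------------------
# Tukey-Kramer

def tukey_kramer(
    estimates, cov, df: float, labels=None
) -> list[Contrast]:
    """Studentized-range adjusted pairwise comparisons.

    ``estimates`` are the k group means (any scale), ``cov`` their
    covariance matrix and ``df`` the denominator degrees of freedom. The
    Kramer correction for unequal precision enters through the contrast
    standard error. With k = 2 the adjusted p equals the two-sided t-test p.
    """
    est = np.asarray(estimates, dtype=float)
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    k = est.size
    if k < 2:
        raise ValueError("tukey_kramer needs >= 2 groups")
    if labels is None:
        labels = [str(i) for i in range(k)]
    out = []
    for i, j in itertools.combinations(range(k), 2):
        diff = est[i] - est[j]
        var = cov[i, i] + cov[j, j] - 2.0 * cov[i, j]
        se = float(np.sqrt(max(var, 0.0)))
        if se == 0:
            p = 0.0 if diff != 0 else 1.0
        else:
            q = abs(diff) * np.sqrt(2.0) / se
            p = float(stats.studentized_range.sf(q, k, df))
        out.append(Contrast(labels[i], labels[j], float(diff), se, df, min(p, 1.0)))
    return out


# ---------------------------------------------------------------------------
# the crossover model

def _wald_p(L_params, LCL, q, df_den) -> float:
    Fstat = float(L_params @ np.linalg.solve(LCL, L_params)) / q
    return float(stats.f.sf(Fstat, q, df_den))


def fit_crossover_model(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit the crossover model for ``spec.response`` with the fallback
    ladder, returning EMMs, effect p-values and Tukey-Kramer contrasts.

    ``data`` must carry one row per observation with columns ``cow``,
    ``group``, ``period``, ``sequence``, ``block`` (plus the time column
    for repeated measures) and the response.
    """
    required = {"cow", *spec.factors} | ({spec.time} if spec.time else set())
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"data missing columns {sorted(missing)}")
    if spec.response not in data.columns:
        raise ValueError(f"response column {spec.response!r} not in data")
    df_data = data.dropna(subset=[spec.response]).reset_index(drop=True)
    y_raw = df_data[spec.response].to_numpy(dtype=float)

    glevels = sorted(df_data["group"].unique().tolist())
    if len(glevels) < 2:
        raise ValueError("both treatment levels must be present")
    for seq, grp in df_data.groupby("sequence"):
        if grp["cow"].nunique() < 2:
            raise ValueError(f"sequence {seq!r} has < 2 cows")
    # estimability: every group x period cell must be populated
    for g in glevels:
        for p in sorted(df_data["period"].unique()):
            if len(df_data[(df_data["group"] == g) & (df_data["period"] == p)]) == 0:
                p_plain = p.item() if hasattr(p, "item") else p
                raise ValueError(
                    "non-estimable contrast: empty cell "
                    f"group={g!r}, period={p_plain!r}"
                )

    di = _design_info(df_data, spec.factors, spec.time)
    X = di.build(df_data)
    cows = df_data["cow"].to_numpy()
    df_within, df_between, scope = _between_within_dfs(df_data, di, X)

    diagnostics: dict = {}
    transformation = "none"
    path = "lmm"

    def _normal_ok(resid: np.ndarray) -> tuple[bool, float]:
        if np.allclose(resid, resid[0]):
            return True, 1.0
        p = float(stats.shapiro(resid).pvalue)
        return p >= spec.diag_alpha, p

    def _lmm_or_lm(yv: np.ndarray) -> tuple[_FitCore, bool]:
        core = _fit_lmm(yv, X, cows, spec.singular_tol)
        if core.singular or not core.converged:
            return _fit_ols(yv, X), True
        return core, False

    start = spec.transformation
    if start == "gamma-glmm":
        core = _fit_gamma_pql(y_raw, X, cows, spec.singular_tol)
        path, transformation = "glmm-gamma", "gamma-log"
        diagnostics["normality_p"] = np.nan
    else:
        if start == "log2":
            if np.any(y_raw <= 0):
                raise ValueError("log2 transformation requires positive values")
            y0, transformation = np.log2(y_raw), "log2"
        else:
            y0 = y_raw
        core, fell_lm = _lmm_or_lm(y0)
        if fell_lm:
            path = "lm"
            ok, p_norm = _normal_ok(core.resid)
            diagnostics["normality_p"] = p_norm
        else:
            path = "lmm" if transformation == "none" else "lmm-log2"
            ok, p_norm = _normal_ok(core.resid)
            diagnostics["normality_p"] = p_norm
            if not ok and transformation == "none":
                if np.all(y_raw > 0):
                    ylog = np.log2(y_raw)
                    core2, fell_lm2 = _lmm_or_lm(ylog)
                    if fell_lm2:
                        core, path, transformation = core2, "lm", "log2"
                        _, diagnostics["normality_p_log2"] = _normal_ok(core.resid)
                    else:
                        ok2, p2 = _normal_ok(core2.resid)
                        diagnostics["normality_p_log2"] = p2
                        if ok2:
                            core, path, transformation = core2, "lmm-log2", "log2"
                        else:
                            core = _fit_gamma_pql(y_raw, X, cows, spec.singular_tol)
                            path, transformation = "glmm-gamma", "gamma-log"
                else:
                    diagnostics["normality_note"] = (
                        "non-normal residuals but non-positive values: "
                        "transformation impossible, model kept"
                    )

    # heteroscedasticity: recorded, never a trigger
    try:
        bp = het_breuschpagan(core.resid, X)
        diagnostics["heteroscedasticity_p"] = float(bp[1])
        diagnostics["heteroscedastic"] = bp[1] < spec.diag_alpha
    except Exception:
        diagnostics["heteroscedasticity_p"] = np.nan
    diagnostics["singular"] = path == "lm"
    diagnostics["var_cow"] = core.var_cow
    diagnostics["residual_var"] = core.scale

    # per-term Wald tests
    n_obs, rank_full = X.shape[0], np.linalg.matrix_rank(X)
    df_resid_lm = n_obs - rank_full
    p_values: dict[str, float] = {}
    for term in di.terms:
        if term == "Intercept":
            continue
        cols = di.term_columns(term)
        q = len(cols)
        L_params = core.params[cols]
        LCL = core.cov[np.ix_(cols, cols)]
        if core.kind == "lm":
            df_den = df_resid_lm
        else:
            df_den = df_within if scope[term] == "within" else df_between
        p_values[term] = _wald_p(L_params, LCL, q, df_den)

    # estimated marginal means for the group factor
    other = [f for f in di.factor_levels if f != "group"]
    emm_link: dict[str, float] = {}
    emm_link_se: dict[str, float] = {}
    cvecs = {}
    for g in di.factor_levels["group"]:
        combos = itertools.product(*[di.factor_levels[f] for f in other])
        rows = []
        for combo in combos:
            d = dict(zip(other, combo))
            d["group"] = g
            rows.append(di.row(d))
        c = np.mean(rows, axis=0)
        cvecs[g] = c
        emm_link[g] = float(c @ core.params)
        emm_link_se[g] = float(np.sqrt(c @ core.cov @ c))

    if core.kind == "lm":
        df_group = df_resid_lm
    else:
        df_group = df_within if scope["group"] == "within" else df_between
    gl = list(di.factor_levels["group"])
    est = np.array([emm_link[g] for g in gl])
    C = np.array([cvecs[g] for g in gl])
    cov_emm = C @ core.cov @ C.T
    contrasts = tukey_kramer(est, cov_emm, df_group, labels=gl)

    # back-transform to the response scale
    emm: dict[str, float] = {}
    emm_se: dict[str, float] = {}
    for g in gl:
        m, s = emm_link[g], emm_link_se[g]
        if transformation == "log2":
            emm[g] = float(2.0**m)
            emm_se[g] = float(np.log(2.0) * 2.0**m * s)
        elif transformation == "gamma-log":
            emm[g] = float(np.exp(m))
            emm_se[g] = float(np.exp(m) * s)
        else:
            emm[g], emm_se[g] = m, s

    return ModelFit(
        response=spec.response,
        fallback_path=path,
        transformation=transformation,
        emm=emm,
        emm_se=emm_se,
        emm_link=emm_link,
        emm_link_se=emm_link_se,
        p_values=p_values,
        contrasts=contrasts,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# design planning

@dataclass(frozen=True)
class PowerSpec:
    """Planning inputs for the equivalence and superiority calculations."""

    cv: float = 0.15
    theta0: float = 0.9
    limits: tuple[float, float] = (0.75, 1.33)
    alpha: float = 0.05
    beta: float = 0.2
    cohens_d: float = 1.0

    def __post_init__(self) -> None:
        if self.cv <= 0 or self.theta0 <= 0:
            raise ValueError("cv and theta0 must be > 0")
        if not 0 < self.alpha < 1 or not 0 < self.beta < 1:
            raise ValueError("alpha and beta must be in (0, 1)")


def tost_power(
    n: int,
    cv: float,
    theta0: float,
    limits: tuple[float, float],
    alpha: float = 0.05,
) -> float:
    """Exact power of the log-scale TOST in a balanced 2x2 crossover with
    ``n`` total subjects.

    The within-subject log SD is ``sqrt(log(1 + cv^2))``; power integrates
    the joint acceptance probability of the two one-sided tests over the
    chi-square law of the variance estimate.
    """
    if n < 4 or n % 2:
        raise ValueError("n must be an even integer >= 4")
    sigma = np.sqrt(np.log1p(cv**2))
    se = sigma * np.sqrt(2.0 / n)
    dfree = n - 2
    tcrit = stats.t.ppf(1.0 - alpha, dfree)
    l1, l2 = np.log(limits[0]), np.log(limits[1])
    d = np.log(theta0)

    def integrand(u: float) -> float:
        sehat = se * np.sqrt(u / dfree)
        upper = (l2 - tcrit * sehat - d) / se
        lower = (l1 + tcrit * sehat - d) / se
        width = stats.norm.cdf(upper) - stats.norm.cdf(lower)
        return max(width, 0.0) * stats.chi2.pdf(u, dfree)

    power, _ = integrate.quad(integrand, 0.0, stats.chi2.ppf(1 - 1e-12, dfree))
    return float(power)


def tost_sample_size(spec: PowerSpec, n_max: int = 10_000) -> int:
    """Smallest even total n whose TOST power reaches ``1 - beta``.

    Raises when ``theta0`` lies on or outside an equivalence limit (power
    can never reach the target there).
    """
    lo, hi = spec.limits
    if not lo < spec.theta0 < hi:
        raise ValueError(
            f"theta0={spec.theta0} must lie strictly inside the equivalence "
            f"limits ({lo}, {hi})"
        )
    target = 1.0 - spec.beta
    for n in range(4, n_max + 1, 2):
        if tost_power(n, spec.cv, spec.theta0, spec.limits, spec.alpha) >= target:
            return n
    raise RuntimeError(f"no n <= {n_max} reaches power {target}")


def t_power_n(
    d: float,
    alpha: float = 0.05,
    power: float = 0.8,
    design: str = "two-sample",
    n_max: int = 10_000,
) -> int:
    """Smallest per-group n whose two-sided t-test power reaches ``power``
    for standardized effect ``d``, via the noncentral t distribution."""
    if d <= 0:
        raise ValueError("d must be > 0")
    if design not in ("two-sample", "paired"):
        raise ValueError("design must be 'two-sample' or 'paired'")
    for n in range(2, n_max + 1):
        if design == "two-sample":
            dfree = 2 * n - 2
            ncp = d * np.sqrt(n / 2.0)
        else:
            dfree = n - 1
            ncp = d * np.sqrt(n)
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, dfree)
        pw = stats.nct.sf(tcrit, dfree, ncp) + stats.nct.cdf(-tcrit, dfree, ncp)
        if pw >= power:
            return n
    raise RuntimeError(f"no n <= {n_max} reaches power {power}")
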