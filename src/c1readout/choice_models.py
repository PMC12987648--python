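"""Design-matrix construction and the regression battery.

Coding conventions (applied everywhere): upper-field targets/choices,
correct responses and the 600 ms deadline are coded 1; lower-field,
incorrect and 400 ms are coded 0.  Continuous predictors are z-scored over
the included trials; RT enters in seconds.  Trials flagged excluded (failed
artifact screening) or with RT above 600 ms are omitted.

The central model is a (mixed-effects) logistic regression of choice on the
single-trial C1 amplitude, the physical target location, the previous
trial's choice and every other choice-predictive signal found in the data,
each entering with a main effect plus linear- and quadratic-RT interaction
terms — 48 regressors for 16 predictors.  An RT-band-limited choice
probability then shows up as a significant quadratic RT interaction with
the C1, and the implied vertex of the quadratic gives the RT of peak choice
probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DesignSpec", "ModelFit", "WindowSeries", "build_design", "fit_logistic",
    "fit_linear", "quadratic_vertex", "sliding_rt_models",
    "accuracy_window_models", "collinearity_prune", "fit_c1_dv_model",
    "fit_behavioural_models",
]

BINARY_PREDICTORS = {"target", "prev_choice", "choice", "deadline",
                     "correct"}


class PerfectSeparationWarning(UserWarning):
    pass


# ------------------------------------------------------------------- fitting
@dataclass
class ModelFit:
    names: list[str]
    params: np.ndarray
    se: np.ndarray
    n_obs: int
    converged: bool
    df_resid: int

    @property
    def tvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2 * stats.t.sf(np.abs(self.tvalues), self.df_resid)

    def __getitem__(self, name: str) -> dict:
        i = self.names.index(name)
        return {"beta": self.params[i], "se": self.se[i],
                "t": self.tvalues[i], "p": self.pvalues[i]}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.names, "beta": self.params,
                             "se": self.se, "t": self.tvalues,
                             "p": self.pvalues, "n": self.n_obs})


def _irls(X: np.ndarray, y: np.ndarray, max_iter: int = 50,
          tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton/IRLS maximum-likelihood logistic fit.

    Returns (beta, covariance, converged); perfect separation shows up as
    diverging coefficients and is reported as non-convergence."""
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        if w.max() < 1e-10:
            break
        XtW = X.T * w
        H = XtW @ X
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    if np.max(np.abs(beta)) > 1e3:
        converged = False
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1 - mu), 1e-12)
    try:
        cov = np.linalg.inv((X.T * w) @ X)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return beta, cov, converged


def _laplace_mixed_logistic(X: np.ndarray, y: np.ndarray,
                            group_idx: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Random-intercept logistic regression via the Laplace approximation.

    Jointly maximises the penalised likelihood in (beta, u) for a given
    random-intercept variance, profiling the variance with the Laplace
    marginal likelihood.  Returns (beta, cov_beta, sigma, converged)."""
    from scipy.optimize import minimize_scalar

    n, p = X.shape
    q = int(group_idx.max()) + 1
    Z = np.zeros((n, q))
    Z[np.arange(n), group_idx] = 1.0
    A = np.hstack([X, Z])

    def joint_mode(log_sigma):
        sigma2 = np.exp(2 * log_sigma)
        pen = np.concatenate([np.zeros(p), np.full(q, 1.0 / sigma2)])
        theta = np.zeros(p + q)
        for _ in range(60):
            eta = np.clip(A @ theta, -30, 30)
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = np.maximum(mu * (1 - mu), 1e-12)
            H = (A.T * w) @ A + np.diag(pen)
            g = A.T @ (y - mu) - pen * theta
            step = np.linalg.solve(H, g)
            theta = theta + step
            if np.max(np.abs(step)) < 1e-9:
                break
        eta = np.clip(A @ theta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll = float(y @ np.log(np.maximum(mu, 1e-300))
                   + (1 - y) @ np.log(np.maximum(1 - mu, 1e-300)))
        return theta, H, ll

    def neg_marginal(log_sigma):
        sigma2 = np.exp(2 * log_sigma)
        theta, H, ll = joint_mode(log_sigma)
        u = theta[p:]
        Huu = H[p:, p:]
        sign, logdet = np.linalg.slogdet(Huu / (2 * np.pi))
        lap = ll - float(u @ u) / (2 * sigma2) \
            - q / 2 * np.log(2 * np.pi * sigma2) - 0.5 * logdet \
            + q / 2 * np.log(2 * np.pi)
        return -lap

    res = minimize_scalar(neg_marginal, bounds=(-5.0, 2.0), method="bounded",
                          options={"xatol": 1e-3})
    theta, H, _ = joint_mode(res.x)
    cov = np.linalg.inv(H)[:p, :p]
    return theta[:p], cov, float(np.exp(res.x)), res.success


def fit_logistic(design: pd.DataFrame, response: np.ndarray,
                 random_intercepts: bool = False,
                 groups: np.ndarray | None = None,
                 add_intercept: bool = True) -> ModelFit:
    """Maximum-likelihood logistic regression (Wald t and p per term).

    With ``random_intercepts`` the per-group intercepts are marginalised by
    a Laplace approximation; without, a plain IRLS fit (the two agree when
    the intercept variance shrinks to zero, and the study's key results are
    robust to dropping the random intercepts)."""
    y = np.asarray(response, dtype=float)
    if y.min() == y.max():
        raise ValueError("response is constant; both classes required")
    names = list(design.columns)
    X = design.to_numpy(dtype=float)
    if add_intercept:
        X = np.hstack([np.ones((X.shape[0], 1)), X])
        names = ["intercept"] + names
    if random_intercepts:
        if groups is None:
            raise ValueError("random intercepts require groups")
        codes = pd.factorize(np.asarray(groups))[0]
        beta, cov, sigma, ok = _laplace_mixed_logistic(X, y, codes)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        return ModelFit(names, beta, se, len(y), ok,
                        len(y) - X.shape[1])
    beta, cov, ok = _irls(X, y)
    if not ok:
        warnings.warn("possible perfect separation; fit did not converge",
                      PerfectSeparationWarning)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return ModelFit(names, beta, se, len(y), ok, len(y) - X.shape[1])


def fit_linear(design: pd.DataFrame, response: np.ndarray,
               random_intercepts: bool = False,
               groups: np.ndarray | None = None,
               add_intercept: bool = True) -> ModelFit:
    """OLS (or random-intercept mixed) linear regression via statsmodels."""
    import statsmodels.api as sm

    X = design.copy()
    names = list(X.columns)
    if add_intercept:
        X = sm.add_constant(X, prepend=True)
        names = ["intercept"] + names
    if random_intercepts:
        import statsmodels.formula.api  # noqa: F401  (MixedLM import path)
        md = sm.MixedLM(np.asarray(response, float), np.asarray(X, float),
                        groups=np.asarray(groups))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = md.fit(reml=True, method="lbfgs")
        k = len(names)
        return ModelFit(names, np.asarray(fit.fe_params)[:k],
                        np.asarray(fit.bse)[:k], len(response),
                        bool(fit.converged), len(response) - k)
    fit = sm.OLS(np.asarray(response, float), np.asarray(X, float)).fit()
    return ModelFit(names, fit.params, fit.bse, len(response), True,
                    int(fit.df_resid))


# --------------------------------------------------------------- design spec
@dataclass
class DesignSpec:
    """Which predictors enter the choice model and how."""

    predictors: list[str] = field(default_factory=list)
    rt_interactions: str = "quadratic"      # or "none"
    z_score: bool = True
    random_intercepts: bool = False

    def n_regressors(self) -> int:
        mult = 3 if self.rt_interactions == "quadratic" else 1
        return mult * len(self.predictors)


def included_trials(trials: pd.DataFrame,
                    rt_limit_ms: float = 600.0) -> np.ndarray:
    keep = trials["rt_ms"].to_numpy(float) <= rt_limit_ms
    if "excluded" in trials:
        keep &= ~trials["excluded"].to_numpy(bool)
    return keep


def build_design(trials: pd.DataFrame, covariates: pd.DataFrame | None,
                 spec: DesignSpec, response_col: str = "choice",
                 rt_limit_ms: float = 600.0
                 ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Assemble the regressor matrix and response vector.

    Predictors are looked up in ``covariates`` first, then in ``trials``.
    Continuous columns are z-scored over the included trials; binary codes
    are left as 0/1.  With quadratic RT interactions each predictor
    contributes ``x``, ``x:rt`` and ``x:rt2`` (RT in seconds, uncentred).
    Returns (design, response, groups) with listwise deletion of missing
    covariate values.
    """
    keep = included_trials(trials, rt_limit_ms)
    cols: dict[str, np.ndarray] = {}
    for name in spec.predictors:
        if covariates is not None and name in covariates.columns:
            x = covariates[name].to_numpy(dtype=float)
        elif name in trials.columns:
            x = trials[name].to_numpy(dtype=float)
        else:
            raise KeyError(f"predictor {name!r} not found")
        cols[name] = x
    valid = keep.copy()
    for x in cols.values():
        valid &= np.isfinite(x)
    if not valid.any():
        raise ValueError("all trials missing")
    rt_s = trials["rt_ms"].to_numpy(float)[valid] / 1000.0
    out: dict[str, np.ndarray] = {}
    for name, x in cols.items():
        x = x[valid]
        if spec.z_score and name not in BINARY_PREDICTORS:
            sd = x.std(ddof=0)
            if sd < 1e-12:
                warnings.warn(f"constant predictor {name!r} dropped")
                continue
            x = (x - x.mean()) / sd
        out[name] = x
        if spec.rt_interactions == "quadratic":
            out[f"{name}:rt"] = x * rt_s
            out[f"{name}:rt2"] = x * rt_s ** 2
    design = pd.DataFrame(out)
    response = trials[response_col].to_numpy(dtype=float)[valid]
    groups = trials["participant"].to_numpy()[valid] \
        if "participant" in trials else np.zeros(valid.sum(), dtype=int)
    return design, response, groups


def _valid_rows(trials: pd.DataFrame, covariates: pd.DataFrame | None,
                predictors: list[str], rt_limit_ms: float = 600.0
                ) -> np.ndarray:
    """The exact row filter build_design applies: inclusion criteria plus
    listwise deletion over the predictors."""
    valid = included_trials(trials, rt_limit_ms)
    for name in predictors:
        if covariates is not None and name in covariates.columns:
            valid &= np.isfinite(covariates[name].to_numpy(float))
        elif name in trials.columns:
            valid &= np.isfinite(trials[name].to_numpy(float))
    return valid


def quadratic_vertex(beta_main: float, beta_lin: float, beta_quad: float
                     ) -> tuple[float, str]:
    """RT (ms) at which the coefficient implied by
    ``beta_main + beta_lin * rt + beta_quad * rt^2`` (rt in seconds) is
    extremal, with the extremum type."""
    if beta_quad == 0:
        raise ValueError("beta_quad is zero: vertex undefined")
    rt_s = -beta_lin / (2.0 * beta_quad)
    kind = "min" if beta_quad > 0 else "max"
    return rt_s * 1000.0, kind


# ------------------------------------------------------------ sliding windows
@dataclass
class WindowSeries:
    """Per-RT-window model fits over the sliding percentile grid."""

    centers_pct: np.ndarray
    centers_ms: np.ndarray
    names: list[str]
    beta: np.ndarray          # (n_windows, n_terms)
    se: np.ndarray
    sig: np.ndarray           # (n_windows, n_terms) bool, alpha two-sided
    valid: np.ndarray         # window fit usable
    n_per_window: np.ndarray
    alpha: float = 0.05

    def term(self, name: str) -> int:
        return self.names.index(name)

    def coefficients(self, name: str, flip: bool = False) -> np.ndarray:
        b = self.beta[:, self.term(name)]
        return -b if flip else b

    def significance(self, name: str) -> np.ndarray:
        return self.sig[:, self.term(name)] & self.valid

    def to_frame(self, flip_terms: tuple[str, ...] = ("c1",)
                 ) -> pd.DataFrame:
        rows = []
        for j, name in enumerate(self.names):
            s = -1.0 if name in flip_terms else 1.0
            for i in range(len(self.centers_pct)):
                rows.append((self.centers_pct[i], self.centers_ms[i], name,
                             s * self.beta[i, j], self.se[i, j],
                             bool(self.sig[i, j] and self.valid[i])))
        return pd.DataFrame(rows, columns=["center_pct", "center_ms", "term",
                                           "beta", "se", "sig"])


def rt_window_bounds(rt_ms: np.ndarray, center_pct: float,
                     width_pct: float = 20.0) -> tuple[float, float]:
    lo = np.percentile(rt_ms, max(center_pct - width_pct / 2, 0.0))
    hi = np.percentile(rt_ms, min(center_pct + width_pct / 2, 100.0))
    return float(lo), float(hi)


def sliding_rt_models(trials: pd.DataFrame,
                      covariates: pd.DataFrame | None,
                      predictors: list[str],
                      response_col: str = "choice",
                      centers: np.ndarray | None = None,
                      width_pct: float = 20.0, alpha: float = 0.05,
                      rt_limit_ms: float = 600.0) -> WindowSeries:
    """The window model: at each of 81 sliding RT-percentile windows
    (width 20 points, centres at unit percentiles 10..90 of the pooled
    included-trial RT distribution), fit the full covariate model without
    RT interactions or random intercepts and record each coefficient with
    its Wald significance."""
    centers = np.arange(10.0, 90.0 + 1e-9, 1.0) if centers is None \
        else np.asarray(centers, dtype=float)
    spec = DesignSpec(predictors=predictors, rt_interactions="none")
    design, response, _ = build_design(trials, covariates, spec,
                                       response_col=response_col,
                                       rt_limit_ms=rt_limit_ms)
    valid_rows = _valid_rows(trials, covariates, predictors, rt_limit_ms)
    rt = trials["rt_ms"].to_numpy(float)[valid_rows]

    names = list(design.columns)
    n_w, n_t = len(centers), len(names) + 1
    beta = np.full((n_w, n_t), np.nan)
    se = np.full((n_w, n_t), np.nan)
    sig = np.zeros((n_w, n_t), dtype=bool)
    ok = np.zeros(n_w, dtype=bool)
    n_per = np.zeros(n_w, dtype=int)
    centers_ms = np.percentile(rt, centers)
    X = design.to_numpy(dtype=float)
    for i, c in enumerate(centers):
        lo, hi = rt_window_bounds(rt, c, width_pct)
        m = (rt >= lo) & (rt <= hi)
        n_per[i] = m.sum()
        if n_per[i] <= n_t or response[m].min() == response[m].max():
            continue
        Xw = np.hstack([np.ones((n_per[i], 1)), X[m]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            b, cov, conv = _irls(Xw, response[m])
        if not np.all(np.isfinite(cov)):
            continue
        s = np.sqrt(np.maximum(np.diag(cov), 0.0))
        beta[i], se[i], ok[i] = b, s, True
        with np.errstate(divide="ignore", invalid="ignore"):
            t = b / s
        p = 2 * stats.t.sf(np.abs(t), n_per[i] - n_t)
        sig[i] = p < alpha
    return WindowSeries(centers, centers_ms, ["intercept"] + names,
                        beta, se, sig, ok, n_per, alpha)


def accuracy_window_models(trials: pd.DataFrame,
                           centers: np.ndarray | None = None,
                           width_pct: float = 20.0, alpha: float = 0.05,
                           rt_limit_ms: float = 600.0) -> WindowSeries:
    """Intercept-only logistic model of correctness per RT window; a window
    is significant when accuracy differs from chance (and the intercept is
    positive, i.e. above chance)."""
    centers = np.arange(10.0, 90.0 + 1e-9, 1.0) if centers is None \
        else np.asarray(centers, dtype=float)
    keep = included_trials(trials, rt_limit_ms)
    rt = trials["rt_ms"].to_numpy(float)[keep]
    y = trials["correct"].to_numpy(float)[keep]
    n_w = len(centers)
    beta = np.full((n_w, 1), np.nan)
    se = np.full((n_w, 1), np.nan)
    sig = np.zeros((n_w, 1), dtype=bool)
    ok = np.zeros(n_w, dtype=bool)
    n_per = np.zeros(n_w, dtype=int)
    for i, c in enumerate(centers):
        lo, hi = rt_window_bounds(rt, c, width_pct)
        m = (rt >= lo) & (rt <= hi)
        n_per[i] = m.sum()
        if n_per[i] < 5 or y[m].min() == y[m].max():
            continue
        k = y[m].sum()
        p_hat = k / n_per[i]
        b = np.log(p_hat / (1 - p_hat))
        s = np.sqrt(1.0 / (n_per[i] * p_hat * (1 - p_hat)))
        beta[i, 0], se[i, 0], ok[i] = b, s, True
        p = 2 * stats.t.sf(abs(b / s), n_per[i] - 1)
        sig[i, 0] = (p < alpha) and (b > 0)
    return WindowSeries(centers, np.percentile(rt, centers), ["intercept"],
                        beta, se, sig, ok, n_per, alpha)


# --------------------------------------------------------------- collinearity
def collinearity_prune(design: pd.DataFrame, max_abs_r: float = 0.5,
                       protected: tuple[str, ...] = ("c1", "c1:rt", "c1:rt2")
                       ) -> tuple[pd.DataFrame, list[str]]:
    """Greedily drop regressors (as few as possible) until every pairwise
    |correlation| is at or below ``max_abs_r``; protected columns (the C1
    terms) are never removed."""
    if design.shape[1] < 2:
        raise ValueError("need at least two regressors")
    cols = list(design.columns)
    X = design.to_numpy(dtype=float)
    dropped: list[str] = []
    while True:
        live = [c for c in cols if c not in dropped]
        idx = [cols.index(c) for c in live]
        R = np.corrcoef(X[:, idx], rowvar=False)
        np.fill_diagonal(R, 0.0)
        viol = np.abs(R) > max_abs_r
        if not viol.any():
            break
        counts = viol.sum(axis=0)
        removable = [k for k in range(len(live)) if live[k] not in protected
                     and counts[k] > 0]
        if not removable:
            i, j = np.unravel_index(np.argmax(np.abs(R)), R.shape)
            raise ValueError(
                f"threshold unreachable: protected pair "
                f"({live[i]}, {live[j]}) correlates at {R[i, j]:.3f}")
        worst = max(removable,
                    key=lambda k: (counts[k], np.abs(R[k]).max()))
        dropped.append(live[worst])
    return design.drop(columns=dropped), dropped


# -------------------------------------------------------- C1 as the DV model
def fit_c1_dv_model(trials: pd.DataFrame, covariates: pd.DataFrame | None,
                    c1: np.ndarray | str = "c1",
                    include_current_choice: bool = True,
                    extra_predictors: list[str] | None = None,
                    random_intercepts: bool = False) -> ModelFit:
    """Swap the choice and C1 variables: linear model of single-trial C1 on
    current choice, previous choice, target location (and covariates), each
    with quadratic RT interactions.  Refitting with the current choice
    omitted probes whether the choice-history effect depends on it."""
    predictors = (["choice"] if include_current_choice else []) \
        + ["prev_choice", "target"] + (extra_predictors or [])
    if isinstance(c1, str):
        yv = trials[c1].to_numpy(float)
    else:
        yv = np.asarray(c1, dtype=float)
    trials = trials.copy()
    trials["excluded"] = (~included_trials(trials)) | ~np.isfinite(yv)
    spec = DesignSpec(predictors=predictors, rt_interactions="quadratic")
    design, _, groups = build_design(trials, covariates, spec,
                                     response_col="choice")
    valid = _valid_rows(trials, covariates, predictors)
    return fit_linear(design, yv[valid], random_intercepts=random_intercepts,
                      groups=groups)


# ------------------------------------------------------- behavioural battery
def fit_behavioural_models(trials: pd.DataFrame,
                           random_intercepts: bool = False
                           ) -> dict[str, ModelFit | pd.DataFrame]:
    """The behavioural regression battery.

    * ``accuracy_trend``: accuracy ~ block (performance stability);
    * ``accuracy_rt``: accuracy ~ deadline + RT + RT^2 (conditional-accuracy
      shape plus the residual deadline advantage);
    * ``choice_history``: choice ~ previous choice (+ RT interactions);
    * ``rt_deadline``: RT ~ deadline and RT ~ correctness contrasts;
    * ``rt_variability``: per-participant RT SD by deadline for a paired
      test (variability is not defined at the single-trial level).
    """
    keep = included_trials(trials)
    t = trials.loc[keep].copy()
    t["rt_s"] = t["rt_ms"] / 1000.0
    t["rt_s2"] = t["rt_s"] ** 2
    t["deadline"] = (t["deadline_ms"] == 600).astype(float)
    groups = t["participant"].to_numpy() if "participant" in t else None
    ri = random_intercepts and groups is not None

    out: dict[str, ModelFit | pd.DataFrame] = {}
    out["accuracy_trend"] = fit_logistic(
        t[["block"]].astype(float), t["correct"].to_numpy(float),
        random_intercepts=ri, groups=groups)
    acc_cols = ["deadline", "rt_s", "rt_s2"] if t["deadline"].nunique() > 1 \
        else ["rt_s", "rt_s2"]      # single-regime data: no deadline term
    out["accuracy_rt"] = fit_logistic(
        t[acc_cols], t["correct"].to_numpy(float),
        random_intercepts=ri, groups=groups)
    out["choice_history"] = fit_logistic(
        pd.DataFrame({"prev_choice": t["prev_choice"].astype(float),
                      "prev_choice:rt": t["prev_choice"] * t["rt_s"],
                      "prev_choice:rt2": t["prev_choice"] * t["rt_s2"]}),
        t["choice"].to_numpy(float), random_intercepts=ri, groups=groups)
    out["rt_deadline"] = fit_linear(
        t[["deadline"]], t["rt_ms"].to_numpy(float),
        random_intercepts=ri, groups=groups)
    out["rt_correct"] = fit_linear(
        t[["correct"]].astype(float), t["rt_ms"].to_numpy(float),
        random_intercepts=ri, groups=groups)
    if "participant" in t and t["deadline"].nunique() == 2:
        sd = t.groupby(["participant", "deadline"])["rt_ms"].std().unstack()
        out["rt_variability"] = sd.rename(columns={0.0: "sd_400",
                                                   1.0: "sd_600"})
    return out
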