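"""Marginal linear mixed models for repeated measures under REML.

The model for subject :math:`i` in group :math:`g` observed at time levels
:math:`t` is

.. math:: y_{it} = \\mu + \\alpha_g + \\beta_t + (\\alpha\\beta)_{gt} + \\varepsilon_{it},
          \\qquad \\varepsilon_i \\sim N(0, \\Sigma(\\theta)),

with time as a categorical factor, subjects independent, and the
within-subject residual covariance :math:`\\Sigma` following one of four
structures:

* ``ante1`` — first-order ante-dependence: heterogeneous standard
  deviations :math:`\\sigma_1..\\sigma_T` and adjacent correlations
  :math:`\\rho_1..\\rho_{T-1}` with
  :math:`\\mathrm{Cov}(y_t,y_s) = \\sigma_t\\sigma_s\\prod_{k=\\min(t,s)}^{\\max(t,s)-1}\\rho_k`
* ``cs`` — compound symmetry
* ``ar1`` — first-order autoregressive
* ``diag`` — independence with a common variance (scaled identity)

Covariance parameters are estimated by numerically maximizing the
restricted likelihood (profiled over the fixed effects); missing cells are
handled by the likelihood, with no imputation.  ``AIC = -2 l_R + 2 q`` where
``q`` counts covariance parameters only (the REML convention).  Marginal
group means average the fitted cell means over time levels; 1-df contrasts
use Satterthwaite degrees of freedom by default (residual df available as a
fallback), multi-df Wald F tests use residual denominator df.

Estimation is deterministic: three fixed starting points, a bounded
quasi-Newton optimizer on log-sigma / atanh-rho transforms, and a 1e-8
tolerance on the log-likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

log = logging.getLogger(__name__)

STRUCTURES = ("ante1", "cs", "ar1", "diag")


class ConvergenceError(RuntimeError):
    """REML optimization failed for every starting point."""


# ---------------------------------------------------------------------------
# covariance structures


def n_cov_params(kind: str, T: int) -> int:
    return {"ante1": 2 * T - 1, "cs": 2, "ar1": 2, "diag": 1}[kind]


def build_covariance(kind: str, theta: np.ndarray, T: int) -> np.ndarray:
    """Build the T x T within-subject covariance from unconstrained theta."""
    theta = np.asarray(theta, dtype=float)
    if kind == "ante1":
        sig = np.exp(theta[:T])
        rho = np.tanh(theta[T:])
        cum = np.concatenate([[0.0], np.cumsum(np.log(np.clip(np.abs(rho), 1e-12, None)))])
        sgn = np.concatenate([[1.0], np.cumprod(np.where(rho >= 0, 1.0, -1.0))])
        # prod_{k=s}^{t-1} rho_k via cumulative sums of logs, sign-tracked
        i, j = np.meshgrid(np.arange(T), np.arange(T), indexing="ij")
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        corr = (sgn[hi] * sgn[lo]) * np.exp(cum[hi] - cum[lo])
        return np.outer(sig, sig) * corr
    if kind == "cs":
        s2 = np.exp(2 * theta[0])
        lb = -1.0 / (T - 1) if T > 1 else -1.0
        # map R -> (lb, 1) keeping the matrix positive definite
        rho = lb + (1.0 - lb) / (1.0 + np.exp(-theta[1]))
        return s2 * ((1 - rho) * np.eye(T) + rho * np.ones((T, T)))
    if kind == "ar1":
        s2 = np.exp(2 * theta[0])
        rho = np.tanh(theta[1])
        lags = np.abs(np.subtract.outer(np.arange(T), np.arange(T)))
        return s2 * rho**lags
    if kind == "diag":
        return np.exp(2 * theta[0]) * np.eye(T)
    raise ValueError(f"unknown covariance structure {kind!r}")


def _starting_points(kind: str, T: int, resid: pd.DataFrame) -> list[np.ndarray]:
    """Three documented starts: empirical, iid, high-correlation."""
    sd_t = resid.std(ddof=1).reindex(range(T)).to_numpy()
    pooled = float(np.nanmean(sd_t)) if np.isfinite(np.nanmean(sd_t)) else 1.0
    pooled = max(pooled, 1e-3)
    sd_t = np.where(np.isfinite(sd_t) & (sd_t > 1e-6), sd_t, pooled)
    lag1 = []
    vals = resid.to_numpy()
    for k in range(T - 1):
        a, b = vals[:, k], vals[:, k + 1]
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() >= 3 and a[ok].std() > 0 and b[ok].std() > 0:
            lag1.append(np.clip(np.corrcoef(a[ok], b[ok])[0, 1], -0.95, 0.95))
        else:
            lag1.append(0.3)
    lag1 = np.asarray(lag1) if T > 1 else np.empty(0)

    def pack(sigmas, rhos):
        if kind == "ante1":
            return np.concatenate([np.log(sigmas), np.arctanh(rhos)])
        if kind == "diag":
            return np.array([np.log(np.mean(sigmas))])
        if kind == "cs":
            lb = -1.0 / (T - 1) if T > 1 else -1.0
            r = float(np.clip(np.mean(rhos) if len(rhos) else 0.0, lb + 0.02, 0.98))
            z = -np.log((1.0 - lb) / (r - lb) - 1.0)
            return np.array([np.log(np.mean(sigmas)), z])
        if kind == "ar1":
            r = float(np.clip(np.mean(rhos) if len(rhos) else 0.0, -0.95, 0.95))
            return np.array([np.log(np.mean(sigmas)), np.arctanh(r)])
        raise ValueError(kind)

    ones = np.full(T, pooled)
    return [
        pack(sd_t, np.clip(lag1, -0.9, 0.9)),
        pack(ones, np.zeros(max(T - 1, 0))),
        pack(ones, np.full(max(T - 1, 0), 0.8)),
    ]


# ---------------------------------------------------------------------------
# design and REML machinery


@dataclass
class _Problem:
    groups: list[str]
    times: list
    X_cells: np.ndarray                  # (2T, p) design rows per (g, t) cell
    patterns: list[dict]                 # grouped subjects sharing (g, obs-pattern)
    n_obs: int
    p: int
    y: np.ndarray                        # stacked responses (for reference)


def _cell_design(G: int, T: int) -> np.ndarray:
    """Full-rank treatment-coded design for group*time cell (g, t)."""
    p = 2 * T  # intercept + group + (T-1) time + (T-1) interaction, G = 2
    X = np.zeros((G * T, p))
    for g in range(G):
        for t in range(T):
            row = np.zeros(p)
            row[0] = 1.0
            if g == 1:
                row[1] = 1.0
            if t >= 1:
                row[1 + t] = 1.0
                if g == 1:
                    row[T + t] = 1.0
            X[g * T + t] = row
    return X


def _prepare(data: pd.DataFrame, parameter: str | None) -> _Problem:
    df = data
    if parameter is not None and "parameter" in df.columns:
        df = df[df["parameter"] == parameter]
    df = df.dropna(subset=["value"])
    if df.duplicated(subset=["subject", "time"]).any():
        raise ValueError("more than one value per (subject, time)")
    groups = sorted(df["group"].unique(), key=str)
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    if set(map(str, groups)) == {"CCC", "30:2"}:
        groups = ["CCC", "30:2"]  # study convention: difference = CCC - 30:2
    times = sorted(df["time"].unique())
    T = len(times)
    if T < 2:
        raise ValueError("need at least 2 time levels")
    t_index = {t: k for k, t in enumerate(times)}
    g_index = {g: k for k, g in enumerate(groups)}
    for g in groups:
        if df[df["group"] == g]["subject"].nunique() < 2:
            raise ValueError(f"need >= 2 subjects in group {g!r}")

    X_cells = _cell_design(2, T)
    buckets: dict[tuple, dict] = {}
    for (subj, grp), sub in df.groupby(["subject", "group"], sort=True):
        obs = tuple(sorted(t_index[t] for t in sub["time"]))
        y = sub.set_index("time")["value"].loc[[times[k] for k in obs]].to_numpy(float)
        key = (g_index[grp], obs)
        b = buckets.setdefault(key, {"g": g_index[grp], "obs": np.array(obs), "ys": []})
        b["ys"].append(y)
    patterns = []
    n_obs = 0
    for key in sorted(buckets):
        b = buckets[key]
        Y = np.column_stack(b["ys"])
        rows = [b["g"] * T + k for k in b["obs"]]
        patterns.append({"g": b["g"], "obs": b["obs"], "X": X_cells[rows], "Y": Y})
        n_obs += Y.size
    return _Problem(
        groups=list(map(str, groups)), times=times, X_cells=X_cells,
        patterns=patterns, n_obs=n_obs, p=2 * T,
        y=np.concatenate([p_["Y"].ravel(order="F") for p_ in patterns]),
    )


def _reml_pieces(prob: _Problem, Sigma: np.ndarray):
    """Cholesky-based accumulation of the REML quantities."""
    p = prob.p
    W = np.zeros((p, p))
    u = np.zeros(p)
    quad_y = 0.0
    logdetV = 0.0
    for pat in prob.patterns:
        idx = pat["obs"]
        S = Sigma[np.ix_(idx, idx)]
        try:
            c, low = linalg.cho_factor(S, lower=True)
        except linalg.LinAlgError:
            return None
        ns = pat["Y"].shape[1]
        logdetV += 2.0 * np.log(np.diag(c)).sum() * ns
        Xs = linalg.cho_solve((c, low), pat["X"])
        Ys = linalg.cho_solve((c, low), pat["Y"])
        W += pat["X"].T @ Xs * ns
        u += pat["X"].T @ Ys.sum(axis=1)
        quad_y += float(np.sum(pat["Y"] * Ys))
    try:
        cW, lowW = linalg.cho_factor(W)
    except linalg.LinAlgError:
        return None
    beta = linalg.cho_solve((cW, lowW), u)
    logdetW = 2.0 * np.log(np.diag(cW)).sum()
    rss = quad_y - 2.0 * beta @ u + beta @ W @ beta
    return W, beta, quad_y, logdetV, logdetW, rss


def reml_loglik(
    data: pd.DataFrame, parameter: str | None, kind: str, theta: np.ndarray
) -> float:
    """Restricted log-likelihood at given covariance parameters.

    Convention: :math:`l_R = -\\tfrac12[(n-p)\\log 2\\pi + \\log|V| +
    \\log|X'V^{-1}X| + r'V^{-1}r]`.
    """
    prob = _prepare(data, parameter)
    return _loglik_from_prob(prob, kind, np.asarray(theta, float))


def _loglik_from_prob(prob: _Problem, kind: str, theta: np.ndarray) -> float:
    T = len(prob.times)
    Sigma = build_covariance(kind, theta, T)
    pieces = _reml_pieces(prob, Sigma)
    if pieces is None:
        return -1e12  # finite penalty keeps quasi-Newton steps well-defined
    _, _, _, logdetV, logdetW, rss = pieces
    n, p = prob.n_obs, prob.p
    return -0.5 * ((n - p) * np.log(2 * np.pi) + logdetV + logdetW + rss)


@dataclass
class MixedModelFit:
    """Result of one REML fit."""

    parameter: str
    structure: str
    groups: list[str]
    times: list
    beta: np.ndarray
    cov_beta: np.ndarray
    theta: np.ndarray
    sigma: np.ndarray                    # fitted within-subject covariance
    loglik: float
    aic: float
    n_cov_params: int
    n_obs: int
    df_method: str
    group_means: pd.DataFrame            # group, estimate, se, df, ci_lo, ci_hi
    group_difference: dict
    time_p: float
    interaction_p: float
    cell_means: pd.DataFrame             # group, time, estimate, se
    converged: bool = True

    def summary_row(self) -> dict:
        g0, g1 = self.groups
        m = self.group_means.set_index("group")
        d = self.group_difference
        return {
            "parameter": self.parameter,
            f"mean_{g0}": m.loc[g0, "estimate"],
            f"ci_lo_{g0}": m.loc[g0, "ci_lo"],
            f"ci_hi_{g0}": m.loc[g0, "ci_hi"],
            f"mean_{g1}": m.loc[g1, "estimate"],
            f"ci_lo_{g1}": m.loc[g1, "ci_lo"],
            f"ci_hi_{g1}": m.loc[g1, "ci_hi"],
            "diff": d["estimate"], "diff_ci_lo": d["ci_lo"],
            "diff_ci_hi": d["ci_hi"], "diff_p": d["p"],
            "time_p": self.time_p, "interaction_p": self.interaction_p,
            "structure": self.structure, "aic": self.aic,
        }


def _satterthwaite_df(prob, kind, theta, L, hess_inv, step=1e-4):
    """Satterthwaite df for the 1-df contrast L via numerical gradient of
    Var(L beta) w.r.t. theta and the REML information."""

    def var_L(th):
        Sigma = build_covariance(kind, th, len(prob.times))
        pieces = _reml_pieces(prob, Sigma)
        if pieces is None:
            return np.nan
        W = pieces[0]
        return float(L @ linalg.solve(W, L, assume_a="pos"))

    v0 = var_L(theta)
    g = np.zeros(len(theta))
    for k in range(len(theta)):
        e = np.zeros(len(theta))
        e[k] = step
        g[k] = (var_L(theta + e) - var_L(theta - e)) / (2 * step)
    denom = float(g @ hess_inv @ g)
    if not np.isfinite(denom) or denom <= 0:
        return None
    return 2.0 * v0**2 / denom


def _numerical_hessian(f, x, step=1e-4):
    k = len(x)
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = step
            ej = np.zeros(k); ej[j] = step
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / step**2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * step**2)
    return H


def fit_lmm(
    data: pd.DataFrame,
    parameter: str | None = None,
    structure: str = "ante1",
    df_method: str = "satterthwaite",
    ci_level: float = 0.95,
) -> MixedModelFit:
    """Fit the group x time marginal model under REML.

    ``data`` is long format with columns subject, group, time, value (and
    optionally parameter, filtered by ``parameter``).  Raises
    :class:`ConvergenceError` if no starting point converges.
    """
    if structure not in STRUCTURES:
        raise ValueError(f"structure must be one of {STRUCTURES}")
    prob = _prepare(data, parameter)
    T = len(prob.times)

    # OLS residuals by time level for the empirical start
    resid_rows = {}
    Xc = prob.X_cells
    # cheap OLS: cell means
    cell_sum = np.zeros(2 * T)
    cell_n = np.zeros(2 * T)
    for pat in prob.patterns:
        rows = pat["g"] * T + pat["obs"]
        cell_sum[rows] += pat["Y"].sum(axis=1)
        cell_n[rows] += pat["Y"].shape[1]
    cell_mean = np.divide(cell_sum, np.maximum(cell_n, 1))
    rid = 0
    for pat in prob.patterns:
        rows = pat["g"] * T + pat["obs"]
        for s in range(pat["Y"].shape[1]):
            r = np.full(T, np.nan)
            r[pat["obs"]] = pat["Y"][:, s] - cell_mean[rows]
            resid_rows[rid] = r
            rid += 1
    resid = pd.DataFrame.from_dict(resid_rows, orient="index")

    def neg(theta):
        return -_loglik_from_prob(prob, structure, theta)

    best = None
    bounds = [(-12.0, 12.0)] * n_cov_params(structure, T)
    for x0 in _starting_points(structure, T, resid):
        try:
            res = optimize.minimize(
                neg, np.clip(x0, -11.9, 11.9), method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-8},
            )
        except Exception:  # pragma: no cover - defensive
            continue
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    if best is None:
        raise ConvergenceError(f"REML failed for structure {structure!r}")
    theta = best.x
    ll = -best.fun
    q = n_cov_params(structure, T)
    Sigma = build_covariance(structure, theta, T)
    pieces = _reml_pieces(prob, Sigma)
    if pieces is None:
        raise ConvergenceError("covariance not positive definite at optimum")
    W, beta, *_ = pieces
    Vb = linalg.inv(W)

    hess_inv = None
    if df_method == "satterthwaite":
        try:
            H = _numerical_hessian(neg, theta)
            hess_inv = linalg.inv(H)
            if not np.all(np.isfinite(hess_inv)):
                hess_inv = None
        except linalg.LinAlgError:
            hess_inv = None
        if hess_inv is None:
            log.warning("Satterthwaite information singular; using residual df")
    df_resid = prob.n_obs - prob.p

    def contrast(L):
        est = float(L @ beta)
        se = float(np.sqrt(L @ Vb @ L))
        df = None
        if hess_inv is not None:
            df = _satterthwaite_df(prob, structure, theta, L, hess_inv)
        if df is None or not np.isfinite(df) or df < 1:
            df = df_resid
        tval = est / se if se > 0 else np.inf
        p = 2 * stats.t.sf(abs(tval), df)
        tcrit = stats.t.ppf(0.5 + ci_level / 2, df)
        return est, se, df, p, est - tcrit * se, est + tcrit * se

    L_groups = []
    for g in range(2):
        L_groups.append(prob.X_cells[g * T : (g + 1) * T].mean(axis=0))
    rows = []
    cell_rows = []
    for g, lab in enumerate(prob.groups):
        est, se, df, _, lo, hi = contrast(L_groups[g])
        rows.append({"group": lab, "estimate": est, "se": se, "df": df,
                     "ci_lo": lo, "ci_hi": hi})
        for k, tlev in enumerate(prob.times):
            Lc = prob.X_cells[g * T + k]
            cell_rows.append({
                "group": lab, "time": tlev,
                "estimate": float(Lc @ beta),
                "se": float(np.sqrt(Lc @ Vb @ Lc)),
            })
    group_means = pd.DataFrame(rows)
    Ld = L_groups[0] - L_groups[1]
    est, se, df, p, lo, hi = contrast(Ld)
    group_difference = {"estimate": est, "se": se, "df": df, "p": p,
                        "ci_lo": lo, "ci_hi": hi}

    def wald_F(Lmat):
        Lb = Lmat @ beta
        M = Lmat @ Vb @ Lmat.T
        f = float(Lb @ linalg.solve(M, Lb, assume_a="pos")) / Lmat.shape[0]
        return float(stats.f.sf(f, Lmat.shape[0], df_resid))

    # time main effect: averaged over groups, differences to time level 1
    Ltime = np.stack([
        0.5 * (prob.X_cells[k] + prob.X_cells[T + k])
        - 0.5 * (prob.X_cells[0] + prob.X_cells[T])
        for k in range(1, T)
    ])
    # interaction: group difference of (cell - first time level)
    Linter = np.stack([
        (prob.X_cells[k] - prob.X_cells[0])
        - (prob.X_cells[T + k] - prob.X_cells[T])
        for k in range(1, T)
    ])
    time_p = wald_F(Ltime)
    interaction_p = wald_F(Linter)

    return MixedModelFit(
        parameter=parameter or "value", structure=structure, groups=prob.groups,
        times=list(prob.times), beta=beta, cov_beta=Vb, theta=theta, sigma=Sigma,
        loglik=ll, aic=-2.0 * ll + 2.0 * q, n_cov_params=q, n_obs=prob.n_obs,
        df_method=df_method if hess_inv is not None else "residual",
        group_means=group_means, group_difference=group_difference,
        time_p=time_p, interaction_p=interaction_p,
        cell_means=pd.DataFrame(cell_rows),
    )


def gls_beta(
    data: pd.DataFrame, parameter: str | None, kind: str, theta: np.ndarray
) -> np.ndarray:
    """Profiled GLS fixed effects at fixed covariance parameters."""
    prob = _prepare(data, parameter)
    Sigma = build_covariance(kind, np.asarray(theta, float), len(prob.times))
    pieces = _reml_pieces(prob, Sigma)
    if pieces is None:
        raise ValueError("covariance not positive definite")
    return pieces[1]


def select_covariance(
    data: pd.DataFrame,
    parameter: str | None = None,
    candidates: Sequence[str] = STRUCTURES,
    df_method: str = "satterthwaite",
) -> pd.DataFrame:
    """Fit all candidate covariance structures and rank them by AIC.

    Ties (within 1e-6) break toward fewer covariance parameters.  Candidate
    failures are recorded, not fatal, provided at least one succeeds; the
    returned frame carries the fit objects in the ``fit`` column.
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate")
    rows = []
    for kind in candidates:
        try:
            fit = fit_lmm(data, parameter, structure=kind, df_method=df_method)
            rows.append({"structure": kind, "aic": fit.aic, "loglik": fit.loglik,
                         "n_cov_params": fit.n_cov_params, "fit": fit, "error": ""})
        except Exception as exc:
            log.warning("structure %s failed: %s", kind, exc)
            rows.append({"structure": kind, "aic": np.inf, "loglik": np.nan,
                         "n_cov_params": np.nan, "fit": None, "error": str(exc)})
    out = pd.DataFrame(rows)
    if not (out["fit"].notna()).any():
        raise ConvergenceError("every candidate covariance structure failed")
    out = out.sort_values(
        by=["aic", "n_cov_params"], kind="mergesort"
    ).reset_index(drop=True)
    return out


def simulate_longitudinal(
    n_per_group: int,
    T: int,
    group_means: np.ndarray,
    sigma: np.ndarray,
    rng: np.random.Generator,
    group_labels: tuple[str, str] = ("CCC", "30:2"),
) -> pd.DataFrame:
    """Draw a balanced two-group repeated-measures dataset with residual
    covariance ``sigma`` (T x T); ``group_means`` is (2, T)."""
    rows = []
    chol = np.linalg.cholesky(sigma)
    for g, lab in enumerate(group_labels):
        for s in range(n_per_group):
            eps = chol @ rng.standard_normal(T)
            for t in range(T):
                rows.append({
                    "subject": f"{lab}_{s}", "group": lab, "time": t + 1,
                    "value": group_means[g, t] + eps[t],
                })
    return pd.DataFrame(rows)
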