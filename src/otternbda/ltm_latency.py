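"""Long-term-memory stage: interact-to-solve latencies and a gamma GLMM.

The latency of interest is the time (seconds) from an individual's first
interaction with a task type to its first solve of that task type, per
presentation round.  Latencies are positive and right-skewed, so they are
modelled with a gamma response and log link:

    y_ij ~ Gamma(shape alpha, mean mu_ij),   log mu_ij = x_ij' beta + u_i
    u_i ~ Normal(0, sigma_id^2)

with a random intercept per individual to absorb repeated measures.  The
marginal likelihood integrates the random effect out by adaptive
Gauss-Hermite quadrature (the integrand's mode and curvature are found per
individual by Newton steps, then a scaled Hermite rule is applied), and the
fit maximises it directly (ML, not REML) so that AIC comparisons across
fixed-effect subsets are valid.

Subset selection fits all 2^4 = 16 combinations of the fixed effects
{round, age, sex, task_type} (task type as a categorical factor, level 1
reference; the random intercept always present), ranks them by AIC, and
forms the "top set" of models within dAIC <= 2 of the best after removing
any model whose fixed effects strictly contain another top-set candidate's
with an AIC at least as good (the nesting rule), renormalising weights over
the retained set.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize, special
import statsmodels.api as sm

from .diffusion_data import DiffusionSet
from .exceptions import ConfigurationError, ConsistencyError, FitError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "FIXED_EFFECTS",
    "LatencyTable",
    "GammaGLMM",
    "GlmmResults",
    "SelectionTable",
    "build_latency_table",
    "fit_gamma_glmm",
    "aic_subset_selection",
    "fitted_latency_summaries",
]

FIXED_EFFECTS = ("round", "age", "sex", "task_type")
LATENCY_COLUMNS = ("individual_id", "round", "task_type", "sex", "age_years",
                   "latency_s")
#: Gauss-Hermite nodes for the random-effect integral
_GH_NODES = 20
_GH_X, _GH_W = hermegauss(_GH_NODES)  # probabilists' rule: weights sum to sqrt(2 pi)

#: below this estimated random-intercept SD the variance is reported as 0
SINGULAR_SD = 1e-3

LatencyTable = pd.DataFrame  # columns LATENCY_COLUMNS


def build_latency_table(interact: DiffusionSet, solve: DiffusionSet) -> LatencyTable:
    """Interact-to-solve latencies per (individual, round, task type).

    A solve without a preceding first interaction, or a solve earlier than
    the first interaction, is a data error; task types an individual never
    solved contribute no row (no censored-latency modelling).
    """
    first_interact: dict[tuple, float] = {}
    for d in interact.diffusions:
        for ind, t in d.events:
            first_interact[(ind, d.round, d.task_type)] = t
    rows = []
    ilv = solve.ilv_table or interact.ilv_table
    for d in solve.diffusions:
        for ind, t_solve in d.events:
            key = (ind, d.round, d.task_type)
            if key not in first_interact:
                raise ConsistencyError(
                    f"{ind} solved task {d.task_type} (round {d.round}) without a "
                    "recorded first interaction")
            t_int = first_interact[key]
            if t_solve < t_int:
                raise ConsistencyError(
                    f"{ind} task {d.task_type} round {d.round}: solve at {t_solve}s "
                    f"precedes first interaction at {t_int}s")
            info = ilv.get(ind)
            rows.append({
                "individual_id": ind, "round": d.round, "task_type": d.task_type,
                "sex": info.sex if info else np.nan,
                "age_years": info.age_at(d.round) if info else np.nan,
                "latency_s": t_solve - t_int,
            })
    df = pd.DataFrame(rows, columns=list(LATENCY_COLUMNS))
    if not df.empty and (df["latency_s"] <= 0).any():
        # exact ties (solve at the instant of first touch) are biologically a
        # solve-on-first-contact; nudge to stay inside the gamma support
        df.loc[df["latency_s"] <= 0, "latency_s"] = 0.5
    return df


def _design_matrix(table: pd.DataFrame, fixed: Sequence[str]):
    """Intercept + requested fixed effects; task_type as dummies vs level 1."""
    bad = [f for f in fixed if f not in FIXED_EFFECTS]
    if bad:
        raise ConfigurationError(f"unknown fixed effect(s) {bad}")
    cols = [np.ones(len(table))]
    names = ["intercept"]
    for f in FIXED_EFFECTS:  # deterministic order
        if f not in fixed:
            continue
        if f == "round":
            cols.append((table["round"].to_numpy() == 2).astype(float))
            names.append("round2")
        elif f == "age":
            cols.append(table["age_years"].to_numpy(dtype=float))
            names.append("age")
        elif f == "sex":
            cols.append(table["sex"].to_numpy(dtype=float))
            names.append("sex")
        else:
            levels = sorted(table["task_type"].unique())
            for lv in levels[1:]:
                cols.append((table["task_type"].to_numpy() == lv).astype(float))
                names.append(f"task{lv}")
    return np.column_stack(cols), names


class GammaGLMM:
    """Gamma GLMM with log link and an individual random intercept.

    statsmodels-style model object: build from a latency table and a fixed
    effect subset, call :meth:`fit` for :class:`GlmmResults`.
    """

    def __init__(self, table: pd.DataFrame, fixed: Iterable[str] = FIXED_EFFECTS):
        if table.empty:
            raise InputError("latency table is empty")
        if (table["latency_s"] <= 0).any():
            raise InputError("latencies must be positive")
        self.table = table.reset_index(drop=True)
        self.fixed = tuple(f for f in FIXED_EFFECTS if f in set(fixed))
        self.X, self.fe_names = _design_matrix(self.table, self.fixed)
        self.y = self.table["latency_s"].to_numpy(dtype=float)
        codes, self.individuals = pd.factorize(self.table["individual_id"])
        self.groups = codes
        self.n_groups = len(self.individuals)
        self.p = self.X.shape[1]
        # parameter count: fixed effects + gamma shape + RE variance
        self.k = self.p + 2

    # -- marginal log-likelihood -------------------------------------------
    def _loglik(self, beta: np.ndarray, log_alpha: float, log_sigma: float) -> float:
        alpha = math.exp(log_alpha)
        sigma = math.exp(log_sigma)
        eta0 = self.X @ beta
        logy = np.log(self.y)
        const = alpha * math.log(alpha) - special.gammaln(alpha)
        # per-row pieces depending on u:  -alpha*(eta0+u) - alpha*y*exp(-eta0-u)
        a_row = const + (alpha - 1.0) * logy - alpha * eta0
        c_row = alpha * self.y * np.exp(-eta0)     # multiplies exp(-u)
        total = 0.0
        for g in range(self.n_groups):
            idx = self.groups == g
            a_g = a_row[idx].sum()
            c_g = c_row[idx].sum()
            n_g = idx.sum()
            # g(u) = a_g - alpha*n_g*u - c_g*exp(-u) - u^2/(2 sigma^2) - log(sigma sqrt(2pi))
            if sigma < 1e-8:
                total += a_g - c_g
                continue
            inv_v = 1.0 / (sigma * sigma)

            # Newton for the mode of the integrand exponent
            u = 0.0
            for _ in range(50):
                eu = math.exp(-u)
                g1 = -alpha * n_g + c_g * eu - u * inv_v
                g2 = -c_g * eu - inv_v
                step = g1 / g2
                u -= step
                if abs(step) < 1e-10:
                    break
            tau = 1.0 / math.sqrt(c_g * math.exp(-u) + inv_v)  # curvature scale
            nodes = u + tau * _GH_X
            en = np.exp(-nodes)
            g_nodes = (a_g - alpha * n_g * nodes - c_g * en
                       - 0.5 * nodes * nodes * inv_v
                       - math.log(sigma) - 0.5 * math.log(2.0 * math.pi))
            # int e^{g(u)} du ~= tau * sum w_j e^{g(u_j) + x_j^2/2}
            expo = g_nodes + 0.5 * _GH_X * _GH_X
            m = expo.max()
            total += m + math.log(np.dot(_GH_W, np.exp(expo - m))) + math.log(tau)
        return total

    def _nll(self, theta: np.ndarray) -> float:
        beta = theta[:self.p]
        try:
            ll = self._loglik(beta, theta[self.p], theta[self.p + 1])
        except (OverflowError, FloatingPointError):
            return 1e300
        return -ll if np.isfinite(ll) else 1e300

    def _start(self) -> np.ndarray:
        glm = sm.GLM(self.y, self.X, family=sm.families.Gamma(sm.families.links.Log()))
        try:
            res = glm.fit()
            beta0 = np.asarray(res.params)
            alpha0 = max(1.0 / res.scale, 0.05)
        except Exception:  # pragma: no cover - degenerate inputs
            beta0 = np.zeros(self.p)
            beta0[0] = math.log(self.y.mean())
            alpha0 = 1.0
        return np.concatenate([beta0, [math.log(alpha0), math.log(0.3)]])

    def fit(self, maxiter: int = 2000) -> "GlmmResults":
        theta0 = self._start()
        bounds = [(None, None)] * self.p + [(-5.0, 8.0), (-8.0, 3.0)]
        res = optimize.minimize(self._nll, theta0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": maxiter, "ftol": 1e-13})
        if not np.isfinite(res.fun) or res.fun >= 1e299:
            raise FitError(f"gamma GLMM fit failed for effects {self.fixed}")
        # one restart from a perturbed point if the first stalls early
        if not res.success:
            res2 = optimize.minimize(self._nll, res.x, method="Nelder-Mead",
                                     options={"maxiter": 4000, "fatol": 1e-10,
                                              "xatol": 1e-8})
            if res2.fun < res.fun:
                res = res2
        beta = res.x[:self.p]
        alpha = math.exp(res.x[self.p])
        sigma = math.exp(res.x[self.p + 1])
        singular = sigma < SINGULAR_SD
        if singular:
            logger.warning("random-intercept variance is singular (sd=%.2g); "
                           "reported as 0", sigma)
        loglik = -res.fun
        aic = 2 * self.k - 2 * loglik
        return GlmmResults(model=self, fixed=self.fixed, fe_names=self.fe_names,
                           beta=np.asarray(beta), shape=alpha,
                           sigma_id=0.0 if singular else sigma,
                           singular=singular, loglik=loglik, aic=aic, k=self.k,
                           converged=True)


@dataclass
class GlmmResults:
    """Fitted gamma GLMM: coefficients on the log scale, gamma shape,
    random-intercept SD, marginal log-likelihood and AIC."""

    model: GammaGLMM
    fixed: tuple[str, ...]
    fe_names: list[str]
    beta: np.ndarray
    shape: float
    sigma_id: float
    singular: bool
    loglik: float
    aic: float
    k: int
    converged: bool
    _fitted: np.ndarray | None = field(default=None, repr=False)

    @property
    def fittedvalues(self) -> np.ndarray:
        """Conditional fitted means exp(X beta + u_hat) with empirical Bayes
        random-effect modes."""
        if self._fitted is None:
            m = self.model
            eta0 = m.X @ self.beta
            u_hat = np.zeros(m.n_groups)
            if self.sigma_id > 0:
                alpha = self.shape
                inv_v = 1.0 / (self.sigma_id ** 2)
                c_row = alpha * m.y * np.exp(-eta0)
                for g in range(m.n_groups):
                    idx = m.groups == g
                    c_g = c_row[idx].sum()
                    n_g = idx.sum()
                    u = 0.0
                    for _ in range(50):
                        eu = math.exp(-u)
                        g1 = -alpha * n_g + c_g * eu - u * inv_v
                        g2 = -c_g * eu - inv_v
                        step = g1 / g2
                        u -= step
                        if abs(step) < 1e-10:
                            break
                    u_hat[g] = u
            self._fitted = np.exp(eta0 + u_hat[self.model.groups])
        return self._fitted

    def summary(self) -> str:
        lines = [
            "Gamma GLMM (log link, individual random intercept)",
            f"  fixed effects: {', '.join(self.fixed) or '(intercept only)'}",
            f"  n rows: {len(self.model.y)}   n individuals: {self.model.n_groups}",
            f"  logLik: {self.loglik:.3f}   AIC: {self.aic:.3f}   df: {self.k}",
            f"  gamma shape: {self.shape:.4f}   sigma_id: {self.sigma_id:.4f}"
            + ("  [singular]" if self.singular else ""),
            "  coefficients (log scale):",
        ]
        for name, b in zip(self.fe_names, self.beta):
            lines.append(f"    {name:>10s} = {b:+.4f}   (x{math.exp(b):.3f})")
        return "\n".join(lines)


def fit_gamma_glmm(table: pd.DataFrame,
                   fixed: Iterable[str] = FIXED_EFFECTS) -> GlmmResults:
    """ML fit of the gamma GLMM for one fixed-effect subset."""
    return GammaGLMM(table, fixed).fit()


@dataclass
class SelectionTable:
    """AIC ranking of all fixed-effect subsets plus the nested-rule top set."""

    rows: pd.DataFrame
    fits: dict[tuple[str, ...], GlmmResults]
    top_set: list[tuple[str, ...]]

    @property
    def best(self) -> GlmmResults:
        return self.fits[self.top_set[0]]

    def to_csv(self, path) -> None:
        out = self.rows.drop(columns=["fixed"]).copy()
        out.insert(0, "fixed_effects", ["+".join(f) or "(intercept)"
                                        for f in self.rows["fixed"]])
        out.to_csv(path, index=False)


def _apply_nesting_rule(cand: pd.DataFrame) -> pd.DataFrame:
    """Within a dAIC <= 2 candidate set, drop any model whose fixed effects
    strictly contain another candidate's with an AIC at least as low."""
    keep = []
    for _, row in cand.iterrows():
        fx = set(row["fixed"])
        nested_better = any(
            set(other["fixed"]) < fx and other["aic"] <= row["aic"]
            for _, other in cand.iterrows())
        if not nested_better:
            keep.append(row.name)
    return cand.loc[keep]


def aic_subset_selection(table: pd.DataFrame, delta_max: float = 2.0,
                         ) -> SelectionTable:
    """Exhaustive AIC subset selection over the 16 fixed-effect combinations.

    Ranks by AIC; the top set is the dAIC <= ``delta_max`` models after the
    nesting rule, with adjusted Akaike weights renormalised over the
    retained set.
    """
    subsets = [tuple(c for c in FIXED_EFFECTS if c in combo)
               for r in range(len(FIXED_EFFECTS) + 1)
               for combo in itertools.combinations(FIXED_EFFECTS, r)]
    fits: dict[tuple[str, ...], GlmmResults] = {}
    records = []
    for subset in subsets:
        try:
            res = fit_gamma_glmm(table, subset)
        except FitError as exc:
            logger.warning("subset %s excluded: %s", subset, exc)
            continue
        fits[subset] = res
        records.append({"fixed": subset, "intercept": float(res.beta[0]),
                        "df": res.k, "loglik": res.loglik, "aic": res.aic})
    if not fits:
        raise FitError("every subset fit failed")
    df = pd.DataFrame.from_records(records)
    df["delta_aic"] = df["aic"] - df["aic"].min()
    w = np.exp(-df["delta_aic"] / 2.0)
    df["weight"] = w / w.sum()
    df = df.sort_values("aic", kind="stable").reset_index(drop=True)
    cand = df[df["delta_aic"] <= delta_max]
    top = _apply_nesting_rule(cand)
    top_weights = np.exp(-top["delta_aic"] / 2.0)
    adj = dict(zip([tuple(f) for f in top["fixed"]], top_weights / top_weights.sum()))
    df["in_top_set"] = [tuple(f) in adj for f in df["fixed"]]
    df["adj_weight"] = [adj.get(tuple(f), np.nan) for f in df["fixed"]]
    top_set = [tuple(f) for f in top.sort_values("aic", kind="stable")["fixed"]]
    return SelectionTable(rows=df, fits=fits, top_set=top_set)


def fitted_latency_summaries(fit: GlmmResults, grouping: str) -> pd.DataFrame:
    """Mean and sample SD of row-level fitted latencies per level of
    ``grouping`` (round, task_type or sex)."""
    if grouping not in ("round", "task_type", "sex"):
        raise ConfigurationError(f"grouping must be round/task_type/sex, got {grouping!r}")
    df = fit.model.table.copy()
    df["fitted"] = fit.fittedvalues
    out = (df.groupby(grouping)["fitted"]
           .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
           .reset_index())
    return out
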