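"""Continuous-time network-based diffusion analysis (TADA).

The model
---------
During a diffusion, a naive individual *i* acquires the behaviour with
hazard

    lambda_i(t) = lambda0(t) * R_i(t)

where ``lambda0`` is the baseline asocial acquisition rate (constant, or
the hazard of a gamma distribution to allow the asocial rate to change over
the trial) and ``R_i`` is the relative rate built from the social
transmission rate ``s``, the individual's network connection to informed
group-mates ``T_i = sum_j a_ij z_j(t)`` (``z_j`` = 1 once *j* has acquired)
and individual-level variables (ILVs) ``x_i`` with coefficients ``B``:

    asocial        R_i = exp(B x_i)
    additive       R_i = s * T_i + exp(B x_i)
    multiplicative R_i = exp(B x_i) * (s * T_i + 1)
    no-ILV social  R_i = s * T_i + 1

``s`` measures transmission per unit network connection relative to the
baseline asocial rate; ``s = 0`` recovers pure asocial learning.  ``s`` may
be shared across task types ("same") or task-specific ("different").

Because ``z`` changes only at acquisition events, ``R_i`` is piecewise
constant and the log-likelihood over a set of diffusions is

    sum_events [ log lambda0(t_e) + log R_{i_e}(t_e-) ]
    - sum_i sum_intervals R_i(interval) * [Lambda0(t_hi) - Lambda0(t_lo)]

with censored individuals integrating their cumulative hazard up to the
trial end.  Maximisation uses multi-start L-BFGS-B on transformed scales
(``s`` box-constrained at zero, baseline parameters on log scales);
confidence intervals on any parameter come from the profile likelihood
(chi-square(1) cut-off), and the percentage of non-innovator acquisition
events attributable to social transmission (%ST) is the mean over events of
the social share of the acquirer's relative rate.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
from scipy import optimize, stats

from .association_networks import AssociationNetwork
from .diffusion_data import DiffusionSet, IlvMatrix, build_ilv_matrix
from .exceptions import ConfigurationError, FitError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "TadaModelSpec",
    "TadaParams",
    "FitOptions",
    "TadaModel",
    "TadaResults",
    "STEstimate",
    "relative_rate",
    "baseline_hazard",
    "tada_loglik",
    "fit_tada",
    "profile_ci",
    "percent_social_transmission",
    "CHI2_95_1DF",
]

MODEL_TYPES = ("asocial", "additive", "multiplicative", "social_no_ilv")
BASELINES = ("constant", "gamma")
NETWORK_KINDS = ("social", "group")
S_CONSTRAINTS = ("same", "different")
#: 95% quantile of chi-square with 1 df, used by the profile-likelihood CI
CHI2_95_1DF = 3.841


@dataclass(frozen=True)
class TadaModelSpec:
    """One point in the model space.

    model_type x baseline x network kind x s-constraint x ILV subset.
    Asocial specs have no social transmission parameter (s-constraint is
    normalised to "same"); the no-ILV social spec has an empty ILV subset.
    """

    model_type: str
    baseline: str = "constant"
    network_kind: str = "social"
    s_constraint: str = "same"
    ilv_subset: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.model_type not in MODEL_TYPES:
            raise ConfigurationError(f"unknown model_type {self.model_type!r}")
        if self.baseline not in BASELINES:
            raise ConfigurationError(f"unknown baseline {self.baseline!r}")
        if self.network_kind not in NETWORK_KINDS:
            raise ConfigurationError(f"unknown network_kind {self.network_kind!r}")
        if self.s_constraint not in S_CONSTRAINTS:
            raise ConfigurationError(f"unknown s_constraint {self.s_constraint!r}")
        subset = tuple(c for c in ("age", "sex") if c in self.ilv_subset)
        if set(subset) != set(self.ilv_subset):
            raise ConfigurationError(f"unknown ILV(s) in {self.ilv_subset}")
        object.__setattr__(self, "ilv_subset", subset)
        if self.model_type == "social_no_ilv" and self.ilv_subset:
            raise ConfigurationError("social_no_ilv spec cannot carry ILVs")
        if self.model_type == "asocial" and self.s_constraint != "same":
            object.__setattr__(self, "s_constraint", "same")

    @property
    def is_social(self) -> bool:
        return self.model_type != "asocial"

    def n_baseline_params(self) -> int:
        return 1 if self.baseline == "constant" else 2

    def label(self) -> str:
        ilv = "+".join(self.ilv_subset) if self.ilv_subset else "none"
        base = f"{self.model_type}/{self.baseline}/ilv={ilv}"
        if self.is_social:
            base += f"/{self.network_kind}/s-{self.s_constraint}"
        return base

    def to_dict(self) -> dict:
        return {"model_type": self.model_type, "baseline": self.baseline,
                "network_kind": self.network_kind, "s_constraint": self.s_constraint,
                "ilv_subset": list(self.ilv_subset)}


@dataclass
class TadaParams:
    """Parameter values for one spec.

    ``s`` holds one value when the rate is shared ("same") or one per task
    type, in the order of ``task_types``; ``B`` follows the spec's ILV
    subset order (age before sex).  The baseline is either ``lambda0`` or a
    gamma hazard's (shape, rate).
    """

    s: np.ndarray = field(default_factory=lambda: np.zeros(0))
    B: np.ndarray = field(default_factory=lambda: np.zeros(0))
    lambda0: float | None = None
    shape: float | None = None
    rate: float | None = None
    task_types: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.s = np.atleast_1d(np.asarray(self.s, dtype=float))
        self.B = np.atleast_1d(np.asarray(self.B, dtype=float)) if np.size(self.B) \
            else np.zeros(0)
        if np.any(self.s < 0):
            raise InputError("social transmission rate s must be >= 0")
        if self.lambda0 is not None and not self.lambda0 > 0:
            raise InputError("lambda0 must be > 0")
        if self.shape is not None and not (self.shape > 0 and self.rate > 0):
            raise InputError("gamma baseline shape and rate must be > 0")

    def s_for_task(self, task: int) -> float:
        if self.s.size == 0:
            return 0.0
        if self.s.size == 1:
            return float(self.s[0])
        try:
            idx = self.task_types.index(task)
        except ValueError:
            raise ConfigurationError(f"task {task} not among {self.task_types}")
        return float(self.s[idx])

    def to_dict(self) -> dict:
        d: dict = {"s": self.s.tolist(), "B": self.B.tolist(),
                   "task_types": list(self.task_types)}
        if self.lambda0 is not None:
            d["lambda0"] = self.lambda0
        if self.shape is not None:
            d["shape"] = self.shape
            d["rate"] = self.rate
        return d


@dataclass
class FitOptions:
    """Optimisation settings: number of seeded starts, tolerances and the
    cap used when a profile upper bound is unbounded."""

    starts: int = 5
    seed: int = 0
    s_max: float = 1e3
    gtol: float = 1e-8
    maxiter: int = 1000


# ---------------------------------------------------------------------------
# baseline hazard


def baseline_hazard(t, params: TadaParams, baseline: str):
    """Return ``(log lambda0(t), Lambda0(t))`` for the requested baseline.

    The gamma baseline is the hazard of a Gamma(shape, rate) distribution,
    evaluated in log-survival space (``Lambda0 = -log S(t)``) so that large
    ``t`` never produces NaN.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InputError("baseline hazard requested at negative time")
    if baseline == "constant":
        lam = params.lambda0
        return np.log(lam) * np.ones_like(t), lam * t
    if baseline == "gamma":
        k, r = params.shape, params.rate
        logpdf = stats.gamma.logpdf(t, k, scale=1.0 / r)
        logsf = stats.gamma.logsf(t, k, scale=1.0 / r)
        # far in the tail the survival function underflows even in log space;
        # there the hazard approaches the rate, so sf ~= pdf / r
        bad = ~np.isfinite(logsf)
        if np.any(bad):
            logsf = np.where(bad, logpdf - math.log(r), logsf)
        loghaz = logpdf - logsf
        return loghaz, -logsf
    raise ConfigurationError(f"unknown baseline {baseline!r}")


def relative_rate(informed: np.ndarray, net: AssociationNetwork, x: IlvMatrix,
                  params: TadaParams, spec: TadaModelSpec, task: int) -> np.ndarray:
    """Per-individual relative acquisition rate ``R_i`` given the informed set.

    ``informed`` is a boolean vector over the network's roster order.  The
    network connection to informed individuals is ``T_i = sum_j a_ij z_j``.
    """
    z = np.asarray(informed, dtype=float)
    if z.shape != (net.n,):
        raise InputError("informed vector length does not match network roster")
    T = net.matrix @ z
    if x.values.shape[1]:
        bx = x.values @ params.B
    else:
        bx = np.zeros(net.n)
    s = params.s_for_task(task)
    if spec.model_type == "asocial":
        return np.exp(bx)
    if spec.model_type == "additive":
        return s * T + np.exp(bx)
    if spec.model_type == "multiplicative":
        return np.exp(bx) * (s * T + 1.0)
    return s * T + 1.0  # social_no_ilv


# ---------------------------------------------------------------------------
# workspace: precomputed per-diffusion arrays for fast likelihood evaluation


class _DiffusionBlock:
    """Static arrays for one diffusion under one spec."""

    __slots__ = ("n", "K", "E", "bounds", "Tmat", "risk", "event_rows",
                 "event_cols", "event_times", "X", "task", "key")

    def __init__(self, diff, net: AssociationNetwork, x: IlvMatrix):
        if diff.has_ties:
            raise InputError(f"{diff.key()}: tied event times; apply resolve_ties "
                             "before fitting")
        ids = diff.roster_ids
        # network may carry a wider roster (e.g. round-2 returnees); align
        if tuple(net.ids) != ids:
            net = net.subnetwork([i for i in ids])
        pos = {i: k for k, i in enumerate(ids)}
        n = len(ids)
        E = diff.n_events
        times = np.array([t for _, t in diff.events])
        event_rows = np.array([pos[i] for i, _ in diff.events], dtype=int)
        # interval k spans [bounds[k], bounds[k+1]); event e closes interval e
        bounds = np.concatenate([[0.0], times, [max(diff.trial_end_s, times[-1] if E else 0.0)]])
        K = E + 1
        z = np.zeros((n, K))
        for e in range(E):
            z[event_rows[e], e + 1:] = 1.0  # informed from interval e+1 on
        self.Tmat = net.matrix @ z                      # (n, K)
        risk = np.ones((n, K))
        for e in range(E):
            risk[event_rows[e], e + 1:] = 0.0           # leaves risk set after event
        self.risk = risk
        self.n, self.K, self.E = n, K, E
        self.bounds = bounds
        self.event_rows = event_rows
        self.event_cols = np.arange(E)                  # event e uses interval e's R
        self.event_times = times
        self.X = x.values
        self.task = diff.task_type
        self.key = diff.key()


class _Workspace:
    """All static quantities for evaluating the likelihood of one spec on
    one diffusion set."""

    def __init__(self, data: DiffusionSet, spec: TadaModelSpec):
        if not data.diffusions:
            raise InputError("empty diffusion set")
        self.spec = spec
        self.task_types = data.task_types
        self.blocks: list[_DiffusionBlock] = []
        for diff in data.diffusions:
            if spec.network_kind == "group":
                from .association_networks import homogeneous_network
                net = homogeneous_network(diff.roster_ids)
            else:
                net = data.network_for(diff)
            roster = [data.ilv_table[i] for i in diff.roster_ids] if data.ilv_table \
                else []
            if spec.ilv_subset and not roster:
                raise ConfigurationError("spec requires ILVs but diffusion set has no "
                                         "ILV table")
            x = build_ilv_matrix(roster, spec.ilv_subset, round_=diff.round) if roster \
                else IlvMatrix(diff.roster_ids, (), np.zeros((len(diff.roster_ids), 0)))
            self.blocks.append(_DiffusionBlock(diff, net, x))
        # concatenated times for single-shot baseline evaluation
        self._bounds_cat = np.concatenate([b.bounds for b in self.blocks])
        self._bounds_slices = np.cumsum([0] + [b.bounds.size for b in self.blocks])
        self._etimes_cat = np.concatenate([b.event_times for b in self.blocks]) \
            if any(b.E for b in self.blocks) else np.zeros(0)
        self._etimes_slices = np.cumsum([0] + [b.E for b in self.blocks])
        self.n_events = int(self._etimes_cat.size)
        self.total_exposure = float(sum((b.risk * np.diff(b.bounds)).sum()
                                        for b in self.blocks))
        # tasks with zero events (s pinned to 0 under "different")
        counts = {t: 0 for t in self.task_types}
        for b in self.blocks:
            counts[b.task] += b.E
        self.zero_event_tasks = tuple(t for t in self.task_types if counts[t] == 0)

    def loglik(self, params: TadaParams, check: bool = False) -> float:
        spec = self.spec
        loghaz_cat, Lam_cat = baseline_hazard(self._bounds_cat, params, spec.baseline)
        if self._etimes_cat.size:
            loghaz_e_cat, _ = baseline_hazard(self._etimes_cat, params, spec.baseline)
        total = 0.0
        for bi, b in enumerate(self.blocks):
            Lam = Lam_cat[self._bounds_slices[bi]:self._bounds_slices[bi + 1]]
            dLam = np.diff(Lam)
            if b.X.shape[1]:
                A = np.exp(b.X @ params.B)
            else:
                A = np.ones(b.n)
            s = params.s_for_task(b.task) if spec.is_social else 0.0
            if spec.model_type == "asocial":
                R = np.repeat(A[:, None], b.K, axis=1)
            elif spec.model_type == "additive":
                R = s * b.Tmat + A[:, None]
            elif spec.model_type == "multiplicative":
                R = A[:, None] * (s * b.Tmat + 1.0)
            else:
                R = s * b.Tmat + 1.0
            contrib = -np.sum((b.risk * R) @ dLam)
            if b.E:
                loghaz_e = loghaz_e_cat[self._etimes_slices[bi]:self._etimes_slices[bi + 1]]
                Re = R[b.event_rows, b.event_cols]
                with np.errstate(divide="ignore"):
                    contrib += np.sum(loghaz_e) + np.sum(np.log(Re))
            if check and not np.isfinite(contrib):
                raise FitError(f"non-finite log-likelihood contribution in diffusion "
                               f"{b.key} (params {params.to_dict()})")
            total += contrib
        return float(total)


# ---------------------------------------------------------------------------
# parameter packing


class _Packing:
    """Maps a flat optimisation vector to TadaParams.

    Layout: [s (linear, >=0, free tasks only)] [B (linear)] [log baseline].
    Tasks with no events under the "different" constraint get s pinned at 0.
    """

    def __init__(self, ws: _Workspace):
        spec = ws.spec
        self.spec = spec
        self.task_types = ws.task_types
        if spec.is_social:
            self.n_s_total = 1 if spec.s_constraint == "same" else len(ws.task_types)
            if spec.s_constraint == "different" and ws.zero_event_tasks:
                logger.warning("tasks %s have no events; s fixed at 0",
                               ws.zero_event_tasks)
                self.free_s_idx = [i for i, t in enumerate(ws.task_types)
                                   if t not in ws.zero_event_tasks]
            else:
                self.free_s_idx = list(range(self.n_s_total))
        else:
            self.n_s_total = 0
            self.free_s_idx = []
        self.n_s = len(self.free_s_idx)
        self.n_B = len(spec.ilv_subset)
        self.n_base = spec.n_baseline_params()
        self.k = self.n_s + self.n_B + self.n_base
        self.names = ([f"s:{self.task_types[i]}" for i in self.free_s_idx]
                      if self.n_s_total > 1 else (["s"] if self.n_s else []))
        self.names += [f"B:{c}" for c in spec.ilv_subset]
        self.names += ["lambda0"] if spec.baseline == "constant" else ["shape", "rate"]

    def bounds(self, s_max: float):
        out = [(0.0, s_max)] * self.n_s + [(None, None)] * self.n_B
        out += [(-30.0, 30.0)] * self.n_base
        return out

    def unpack(self, theta: np.ndarray) -> TadaParams:
        s_full = np.zeros(self.n_s_total)
        s_full[self.free_s_idx] = theta[:self.n_s]
        B = np.asarray(theta[self.n_s:self.n_s + self.n_B])
        base = theta[self.n_s + self.n_B:]
        if self.spec.baseline == "constant":
            return TadaParams(s=s_full, B=B, lambda0=float(np.exp(base[0])),
                              task_types=self.task_types)
        return TadaParams(s=s_full, B=B, shape=float(np.exp(base[0])),
                          rate=float(np.exp(base[1])), task_types=self.task_types)

    def pack(self, params: TadaParams) -> np.ndarray:
        s_part = [params.s[i] if params.s.size > 1 else params.s[0]
                  for i in self.free_s_idx] if self.n_s else []
        base = ([math.log(params.lambda0)] if self.spec.baseline == "constant"
                else [math.log(params.shape), math.log(params.rate)])
        return np.array(list(s_part) + list(params.B) + base, dtype=float)


# ---------------------------------------------------------------------------
# model / results objects


class TadaModel:
    """A TADA model: one spec bound to one diffusion set.

    statsmodels-style: construct from data, call :meth:`fit` to obtain a
    :class:`TadaResults`.
    """

    def __init__(self, data: DiffusionSet, spec: TadaModelSpec):
        data.validate_homogeneous()
        self.data = data
        self.spec = spec
        self._ws = _Workspace(data, spec)
        self._packing = _Packing(self._ws)

    @property
    def k_params(self) -> int:
        return self._packing.k

    def loglike(self, params: TadaParams, check: bool = False) -> float:
        return self._ws.loglik(params, check=check)

    def _negloglik(self, theta: np.ndarray) -> float:
        try:
            ll = self._ws.loglik(self._packing.unpack(theta))
        except (FloatingPointError, InputError):
            return 1e300
        if not np.isfinite(ll):
            return 1e300
        return -ll

    def _starts(self, opts: FitOptions) -> list[np.ndarray]:
        ws = self._ws
        lam_hat = max(ws.n_events, 1) / max(ws.total_exposure, 1e-12)
        base0 = ([math.log(lam_hat)] if self.spec.baseline == "constant"
                 else [0.0, math.log(lam_hat)])  # shape 1 ~ constant-equivalent
        p = self._packing
        rng = np.random.default_rng(opts.seed)
        starts = []
        for j in range(opts.starts):
            if j == 0:
                s0 = [1.0] * p.n_s
                B0 = [0.0] * p.n_B
                b0 = list(base0)
            elif j == 1:
                s0 = [0.01] * p.n_s
                B0 = [0.0] * p.n_B
                b0 = list(base0)
            else:
                s0 = list(np.abs(rng.normal(0, 5, p.n_s)))
                B0 = list(rng.normal(0, 0.5, p.n_B))
                b0 = list(np.asarray(base0) + rng.normal(0, 0.5, p.n_base))
            starts.append(np.array(s0 + B0 + b0))
        return starts

    def fit(self, opts: FitOptions | None = None, start_params: TadaParams | None = None,
            ) -> "TadaResults":
        opts = opts or FitOptions()
        p = self._packing
        bounds = p.bounds(opts.s_max)
        best = None
        n_ok = 0
        solutions = []
        start_list = self._starts(opts)
        if start_params is not None:
            start_list = [p.pack(start_params)] + start_list
        for theta0 in start_list:
            res = optimize.minimize(self._negloglik, theta0, method="L-BFGS-B",
                                    bounds=bounds,
                                    options={"maxiter": opts.maxiter,
                                             "ftol": 1e-12, "gtol": opts.gtol})
            if np.isfinite(res.fun) and res.fun < 1e299:
                solutions.append(res)
                if best is None or res.fun < best.fun - 1e-12:
                    best = res
        if best is None:
            raise FitError(f"all {len(start_list)} starts failed for spec "
                           f"{self.spec.label()}")
        n_ok = sum(1 for r in solutions if r.fun < best.fun + 1e-4)
        params = p.unpack(best.x)
        loglik = -best.fun
        aic = 2 * p.k - 2 * loglik
        return TadaResults(model=self, spec=self.spec, params=params, loglik=loglik,
                           aic=aic, k=p.k, converged=bool(best.success or n_ok > 1),
                           n_starts=len(start_list), n_starts_agreeing=n_ok,
                           theta=np.array(best.x), opts=opts)


@dataclass
class STEstimate:
    """Per-task social transmission rate and %ST with profile-based CIs."""

    task_types: tuple[int, ...]
    s_hat: dict[int, float]
    s_ci: dict[int, tuple[float, float]]
    percent_st: dict[int, float]
    percent_ci: dict[int, tuple[float, float]]
    pooled: bool
    upper_open: dict[int, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "task_types": list(self.task_types),
            "s_hat": {str(t): v for t, v in self.s_hat.items()},
            "s_ci": {str(t): list(v) for t, v in self.s_ci.items()},
            "percent_st": {str(t): v for t, v in self.percent_st.items()},
            "percent_ci": {str(t): list(v) for t, v in self.percent_ci.items()},
            "pooled": self.pooled,
            "upper_open": {str(t): v for t, v in self.upper_open.items()},
        }


class TadaResults:
    """Fitted TADA model: MLE, log-likelihood, AIC, profile CIs and %ST."""

    def __init__(self, model: TadaModel, spec: TadaModelSpec, params: TadaParams,
                 loglik: float, aic: float, k: int, converged: bool, n_starts: int,
                 n_starts_agreeing: int, theta: np.ndarray, opts: FitOptions):
        self.model = model
        self.spec = spec
        self.params = params
        self.loglik = loglik
        self.aic = aic
        self.k = k
        self.converged = converged
        self.n_starts = n_starts
        self.n_starts_agreeing = n_starts_agreeing
        self._theta = theta
        self._opts = opts
        self._profile_cache: dict[tuple[str, float], dict] = {}

    # -- profile likelihood -------------------------------------------------
    def _profile_max(self, idx: int, value: float, warm: np.ndarray) -> tuple[float, np.ndarray]:
        """Maximise over nuisance parameters with theta[idx] fixed at value."""
        p = self.model._packing
        free = [i for i in range(p.k) if i != idx]
        if not free:
            theta = warm.copy()
            theta[idx] = value
            return -self.model._negloglik(theta), theta

        def nll(sub):
            theta = warm.copy()
            theta[free] = sub
            theta[idx] = value
            return self.model._negloglik(theta)

        bounds_all = p.bounds(self._opts.s_max)
        sub_bounds = [bounds_all[i] for i in free]
        res = optimize.minimize(nll, warm[free], method="L-BFGS-B", bounds=sub_bounds,
                                options={"maxiter": 500, "ftol": 1e-12})
        theta = warm.copy()
        theta[free] = res.x
        theta[idx] = value
        return -res.fun, theta

    def _param_index(self, target: str) -> int:
        names = self.model._packing.names
        if target in names:
            return names.index(target)
        if target == "s" and any(n.startswith("s") for n in names):
            cands = [i for i, n in enumerate(names) if n == "s"]
            if cands:
                return cands[0]
        raise ConfigurationError(f"unknown profile target {target!r}; available: {names}")

    def profile_ci(self, target: str = "s", level: float = 0.95,
                   ) -> tuple[float, float]:
        """Profile-likelihood CI for one parameter (natural scale for s and B,
        log scale internally for baseline parameters).

        The interval is the set of values whose profile log-likelihood lies
        within ``chi2_1(level)/2`` of the maximum, found by root bisection on
        each side with nuisance parameters re-optimised at every step.  For
        ``s`` the lower bound is clipped at 0 and an upper bound that never
        crosses the threshold is capped at ``s_max`` and flagged open.
        """
        ci, _ = self._profile_ci_full(target, level)
        return ci

    def _profile_ci_full(self, target: str, level: float = 0.95):
        key = (target, level)
        if key in self._profile_cache:
            c = self._profile_cache[key]
            return (c["lo"], c["hi"]), c
        idx = self._param_index(target)
        p = self.model._packing
        lo_bound, hi_bound = p.bounds(self._opts.s_max)[idx]
        mle = self._theta[idx]
        thr = self.loglik - stats.chi2.ppf(level, 1) / 2.0

        warm = {"theta": self._theta.copy()}

        def prof(v: float) -> tuple[float, np.ndarray]:
            ll, th = self._profile_max(idx, v, warm["theta"])
            warm["theta"] = th
            return ll, th

        def f(v: float) -> float:
            return prof(v)[0] - thr

        # lower side
        theta_lo = None
        if lo_bound is not None and mle - lo_bound < 1e-10:
            lo = lo_bound
            _, theta_lo = prof(lo)
        else:
            step = max(abs(mle) * 0.25, 0.1)
            v = mle - step
            fv = None
            for _ in range(100):
                if lo_bound is not None and v <= lo_bound:
                    v = lo_bound
                    fv = f(v)
                    break
                fv = f(v)
                if fv < 0:
                    break
                step *= 2.0
                v = mle - step
            if fv >= 0:  # profile never drops below threshold before the bound
                lo = lo_bound
                _, theta_lo = prof(lo)
            else:
                lo = optimize.brentq(f, v, mle, xtol=1e-4 * max(1.0, abs(mle)))
                _, theta_lo = prof(lo)
        # upper side
        open_upper = False
        step = max(abs(mle) * 0.25, 0.1)
        v = mle + step
        fv = 0.0
        for _ in range(100):
            if hi_bound is not None and v >= hi_bound:
                v = hi_bound
                fv = f(v)
                break
            fv = f(v)
            if fv < 0:
                break
            step *= 2.0
            v = mle + step
        if fv >= 0:
            hi = hi_bound if hi_bound is not None else v
            open_upper = True
            _, theta_hi = prof(hi)
            logger.warning("profile for %s unbounded above; capped at %.3g", target, hi)
        else:
            hi = optimize.brentq(f, mle, v, xtol=1e-4 * max(1.0, abs(mle)))
            _, theta_hi = prof(hi)
        cache = {"lo": float(lo), "hi": float(hi), "theta_lo": theta_lo,
                 "theta_hi": theta_hi, "open_upper": open_upper, "idx": idx}
        self._profile_cache[key] = cache
        return (float(lo), float(hi)), cache

    # -- %ST ----------------------------------------------------------------
    def _event_social_fractions(self, theta: np.ndarray) -> dict[int, list[float]]:
        """Social share of the acquirer's relative rate for every
        non-innovator event, grouped by task type."""
        p = self.model._packing
        params = p.unpack(theta)
        spec = self.spec
        out: dict[int, list[float]] = {t: [] for t in self.model._ws.task_types}
        for b in self.model._ws.blocks:
            if b.X.shape[1]:
                A = np.exp(b.X @ params.B)
            else:
                A = np.ones(b.n)
            s = params.s_for_task(b.task)
            for e in range(1, b.E):  # event 0 is the innovator
                i = b.event_rows[e]
                T = b.Tmat[i, e]
                social = s * T
                if spec.model_type == "additive":
                    asocial = A[i]
                else:  # multiplicative and social_no_ilv: R = A*(sT+1) or sT+1
                    asocial = 1.0
                tot = social + asocial
                out[b.task].append(social / tot if tot > 0 else 0.0)
        return out

    def percent_social_transmission(self, level: float = 0.95,
                                    ci: bool = True) -> STEstimate:
        """%ST per task type with CIs propagated from the s profile bounds.

        Excluding the innovator (the first acquirer of each diffusion), each
        event's social share is ``s T / (s T + asocial)``; %ST is 100 times
        the mean share over the task's events.  Under the "same" constraint
        events are pooled across tasks and one value is reported for all.
        ``ci=False`` skips the (slower) profile-based interval.
        """
        if not self.spec.is_social:
            raise ConfigurationError("%ST is defined only for social models")
        tasks = self.model._ws.task_types
        pooled = self.spec.s_constraint == "same"
        fr_mle = self._event_social_fractions(self._theta)

        def summarise(fr: dict[int, list[float]]) -> dict[int, float]:
            if pooled:
                allv = [v for t in tasks for v in fr[t]]
                if not allv:
                    raise ConfigurationError("no non-innovator events; %ST undefined")
                val = 100.0 * float(np.mean(allv))
                return {t: val for t in tasks}
            out = {}
            for t in tasks:
                out[t] = 100.0 * float(np.mean(fr[t])) if fr[t] else float("nan")
            return out

        pct = summarise(fr_mle)
        s_hat: dict[int, float] = {}
        s_ci: dict[int, tuple[float, float]] = {}
        pct_ci: dict[int, tuple[float, float]] = {}
        upper_open: dict[int, bool] = {}
        if not ci:
            nan = float("nan")
            for t in tasks:
                s_hat[t] = self.params.s_for_task(t)
                s_ci[t] = (nan, nan)
                pct_ci[t] = (nan, nan)
                upper_open[t] = False
            return STEstimate(task_types=tasks, s_hat=s_hat, s_ci=s_ci,
                              percent_st=pct, percent_ci=pct_ci, pooled=pooled,
                              upper_open=upper_open)
        targets = ["s"] if pooled else [f"s:{t}" for t in tasks]
        for tgt, task_group in zip(targets, [tasks] if pooled else [[t] for t in tasks]):
            try:
                (lo, hi), cache = self._profile_ci_full(tgt, level)
            except ConfigurationError:
                # s pinned at 0 (task without events)
                for t in task_group:
                    s_hat[t] = 0.0
                    s_ci[t] = (0.0, 0.0)
                    pct_ci[t] = (0.0, 0.0)
                    upper_open[t] = False
                continue
            p_lo = summarise(self._event_social_fractions(cache["theta_lo"]))
            p_hi = summarise(self._event_social_fractions(cache["theta_hi"]))
            for t in task_group:
                s_hat[t] = self.params.s_for_task(t)
                s_ci[t] = (lo, hi)
                bounds = sorted([p_lo[t], p_hi[t]])
                pct_ci[t] = (bounds[0], bounds[1])
                upper_open[t] = cache["open_upper"]
        return STEstimate(task_types=tasks, s_hat=s_hat, s_ci=s_ci,
                          percent_st=pct, percent_ci=pct_ci, pooled=pooled,
                          upper_open=upper_open)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        p = self.model._packing
        lines = [
            "TADA fit",
            f"  spec:      {self.spec.label()}",
            f"  loglik:    {self.loglik:.4f}",
            f"  k:         {self.k}",
            f"  AIC:       {self.aic:.4f}",
            f"  converged: {self.converged} ({self.n_starts_agreeing}/{self.n_starts}"
            " starts agree)",
            "  parameters:",
        ]
        for name, val in zip(p.names, self._theta):
            if name in ("lambda0", "shape", "rate"):
                val = math.exp(val)
            lines.append(f"    {name:>10s} = {val:.6g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"spec": self.spec.to_dict(), "params": self.params.to_dict(),
                "loglik": self.loglik, "aic": self.aic, "k": self.k,
                "converged": self.converged,
                "n_starts_agreeing": self.n_starts_agreeing}

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# functional wrappers (spec-module surface)


def tada_loglik(data: DiffusionSet, spec: TadaModelSpec, params: TadaParams) -> float:
    """Log-likelihood of ``params`` under ``spec`` for a diffusion set."""
    return _Workspace(data, spec).loglik(params, check=True)


def fit_tada(data: DiffusionSet, spec: TadaModelSpec,
             opts: FitOptions | None = None) -> TadaResults:
    """Maximum-likelihood TADA fit (multi-start L-BFGS-B)."""
    return TadaModel(data, spec).fit(opts)


def profile_ci(fit: TadaResults, target: str = "s", level: float = 0.95):
    """Profile-likelihood confidence interval for one parameter of a fit."""
    return fit.profile_ci(target, level)


def percent_social_transmission(fit: TadaResults, level: float = 0.95,
                                ci: bool = True) -> STEstimate:
    """Percentage of non-innovator acquisitions attributed to social
    transmission under the fitted model, with profile-propagated CIs."""
    return fit.percent_social_transmission(level, ci=ci)
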