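"""Model competition over the TADA model space.

Enumerates the candidate set — {additive, multiplicative} x non-empty ILV
subsets plus the no-ILV social model, crossed with same/different social
transmission across task types, constant/gamma baselines and social/group
networks, together with the asocial models (all ILV subsets x baselines) —
fits every candidate, and summarises support with Akaike weights
``w_m = exp(-dAIC_m/2) / sum`` and category-summed support percentages.
"""
from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .diffusion_data import DiffusionSet
from .exceptions import ConfigurationError, FitError, OtterNbdaError
from .tada_core import FitOptions, TadaModel, TadaModelSpec, TadaResults

logger = logging.getLogger(__name__)

__all__ = [
    "FitTable",
    "enumerate_model_set",
    "fit_all",
    "summed_support",
    "render_support",
    "best_model_report",
]

#: support cells below this (percent) render as "<0.01" in text output
RENDER_FLOOR = 0.01


def enumerate_model_set(ilvs: Iterable[str] = ("age", "sex"),
                        task_types: int = 5,
                        use_aicc: bool = False) -> list[TadaModelSpec]:
    """Deterministically ordered candidate model specs.

    With both ILVs and >1 task type this is the 64-model space: 7 social
    model forms (additive x 3 ILV subsets, multiplicative x 3, no-ILV)
    x 2 s-constraints x 2 baselines x 2 networks = 56, plus 4 x 2 = 8
    asocial models.  With a single task type the same/different constraint
    is degenerate and duplicates are removed.
    """
    ilvs = tuple(c for c in ("age", "sex") if c in set(ilvs))
    if set(ilvs) != set(ilvs):
        raise ConfigurationError("ilvs must be a subset of {age, sex}")
    if task_types < 1:
        raise ConfigurationError("need at least one task type")
    nonempty_subsets = [s for r in range(1, len(ilvs) + 1)
                        for s in itertools.combinations(ilvs, r)]
    all_subsets = [()] + nonempty_subsets
    specs: list[TadaModelSpec] = []
    social_forms = ([("additive", s) for s in nonempty_subsets]
                    + [("multiplicative", s) for s in nonempty_subsets]
                    + [("social_no_ilv", ())])
    constraints = ("same", "different") if task_types > 1 else ("same",)
    for model_type, subset in social_forms:
        for constraint in constraints:
            for baseline in ("constant", "gamma"):
                for network in ("social", "group"):
                    specs.append(TadaModelSpec(model_type=model_type,
                                               baseline=baseline,
                                               network_kind=network,
                                               s_constraint=constraint,
                                               ilv_subset=subset))
    for subset in all_subsets:
        for baseline in ("constant", "gamma"):
            specs.append(TadaModelSpec(model_type="asocial", baseline=baseline,
                                       ilv_subset=subset))
    # degenerate constraints may create duplicates; keep first occurrence
    seen: set[TadaModelSpec] = set()
    unique = []
    for s in specs:
        if s not in seen:
            seen.add(s)
            unique.append(s)
    return unique


@dataclass
class FitTable:
    """All fitted candidates of one competition with AIC-based weights."""

    rows: pd.DataFrame
    fits: dict[TadaModelSpec, TadaResults]
    failures: list[tuple[TadaModelSpec, str]] = field(default_factory=list)

    @property
    def best(self) -> TadaResults:
        spec = self.rows.iloc[0]["spec"]
        return self.fits[spec]

    def best_specs(self) -> list[TadaModelSpec]:
        """Min-AIC spec(s); more than one on an exact tie."""
        amin = self.rows["aic"].min()
        return list(self.rows.loc[np.isclose(self.rows["aic"], amin, atol=1e-9),
                                  "spec"])


def _weights_from_aic(aic: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    delta = aic - aic.min()
    w = np.exp(-delta / 2.0)
    return delta, w / w.sum()


def fit_all(data: DiffusionSet, specs: Sequence[TadaModelSpec],
            opts: FitOptions | None = None, use_aicc: bool = False) -> FitTable:
    """Fit every candidate independently and assemble the weight table.

    Failed fits are excluded from the weight normalisation with a warning;
    the competition only aborts if every fit fails.  ``use_aicc`` switches
    to the small-sample corrected criterion (n = acquisition events).
    """
    if not specs:
        raise ConfigurationError("empty candidate list")
    fits: dict[TadaModelSpec, TadaResults] = {}
    failures: list[tuple[TadaModelSpec, str]] = []
    for spec in specs:
        try:
            fits[spec] = TadaModel(data, spec).fit(opts)
        except OtterNbdaError as exc:
            logger.warning("fit failed for %s: %s", spec.label(), exc)
            failures.append((spec, str(exc)))
    if not fits:
        raise FitError("every candidate fit failed")
    if failures:
        logger.warning("%d/%d fits failed and are excluded from the weights",
                       len(failures), len(specs))
    records = []
    n_events = data.n_events
    for spec, fit in fits.items():
        aic = fit.aic
        if use_aicc:
            denom = max(n_events - fit.k - 1, 1)
            aic = aic + 2.0 * fit.k * (fit.k + 1) / denom
        records.append({"spec": spec, "label": spec.label(),
                        "model_type": spec.model_type, "baseline": spec.baseline,
                        "network_kind": spec.network_kind,
                        "s_constraint": spec.s_constraint,
                        "ilv_subset": "+".join(spec.ilv_subset) or "none",
                        "k": fit.k, "loglik": fit.loglik, "aic": aic})
    df = pd.DataFrame.from_records(records)
    delta, w = _weights_from_aic(df["aic"].to_numpy())
    df["delta_aic"] = delta
    df["akaike_weight"] = w
    df = df.sort_values("aic", kind="stable").reset_index(drop=True)
    return FitTable(rows=df, fits=fits, failures=failures)


def summed_support(table: FitTable, keys: Sequence[str] = ("model_type",
                                                           "network_kind",
                                                           "s_constraint"),
                   ) -> pd.DataFrame:
    """Summed Akaike weights per category, as percentages.

    ``keys`` must be grouping columns of the fit table (they always form a
    partition of the candidate set, so the percentages sum to 100).  With
    ``keys=()`` a single all-models cell of 100% is returned.
    """
    df = table.rows
    valid = {"model_type", "baseline", "network_kind", "s_constraint", "ilv_subset"}
    keys = list(keys)
    bad = [k for k in keys if k not in valid]
    if bad:
        raise ConfigurationError(f"invalid grouping key(s) {bad}; valid: {sorted(valid)}")
    if not keys:
        return pd.DataFrame({"support_pct": [100.0 * df["akaike_weight"].sum()]})
    out = (df.groupby(keys, sort=True)["akaike_weight"].sum() * 100.0
           ).rename("support_pct").reset_index()
    return out.sort_values("support_pct", ascending=False).reset_index(drop=True)


def render_support(support: pd.DataFrame) -> str:
    """Aligned-text rendering with tiny supports shown as ``<0.01``."""
    df = support.copy()
    df["support_pct"] = [f"<{RENDER_FLOOR:g}" if v < RENDER_FLOOR else f"{v:.2f}"
                         for v in df["support_pct"]]
    return df.to_string(index=False)


def best_model_report(table: FitTable, level: float = 0.95,
                      profile: bool = True) -> dict:
    """Report the minimum-AIC model: per-task social transmission rates with
    profile CIs, %ST with CIs, and per-ILV rate multipliers ``exp(B_j)``.

    Exact AIC ties are all reported, flagged under ``"tied"``.
    """
    best_specs = table.best_specs()
    reports = []
    for spec in best_specs:
        fit = table.fits[spec]
        entry: dict = {"spec": spec.to_dict(), "label": spec.label(),
                       "loglik": fit.loglik, "aic": fit.aic, "k": fit.k}
        if spec.is_social:
            entry["s"] = {str(t): fit.params.s_for_task(t)
                          for t in fit.params.task_types}
            st = fit.percent_social_transmission(level, ci=profile)
            entry["percent_st"] = {str(t): st.percent_st[t] for t in st.task_types}
            if profile:
                entry["s_ci"] = {str(t): list(st.s_ci[t]) for t in st.task_types}
                entry["percent_st_ci"] = {str(t): list(st.percent_ci[t])
                                          for t in st.task_types}
        multipliers = {}
        for j, name in enumerate(spec.ilv_subset):
            b = float(fit.params.B[j])
            m: dict = {"multiplier": float(np.exp(b)), "coef": b}
            if profile:
                lo, hi = fit.profile_ci(f"B:{name}", level)
                m["multiplier_ci"] = [float(np.exp(lo)), float(np.exp(hi))]
            multipliers[name] = m
        entry["ilv_multipliers"] = multipliers
        reports.append(entry)
    return {"tied": len(reports) > 1, "models": reports}


def save_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
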