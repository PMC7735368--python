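"""Acquisition-event data model for diffusion analysis.

A *diffusion* is the spread of one novel behaviour (first interaction with,
or first solve of, one task type) through one group during one presentation
round: an ordered sequence of (individual, time-in-seconds) first-acquisition
events plus a right-censoring time for the individuals that never acquired.
A :class:`DiffusionSet` bundles the diffusions entering one model fit with
the association network of each (group, round) and the individual-level
variables (ILVs: age in years, sex coded female = 1 / male = 0).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .association_networks import AssociationNetwork, Individual
from .exceptions import ConfigurationError, ConsistencyError, IdentityError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "Diffusion",
    "DiffusionSet",
    "IlvMatrix",
    "read_acquisition_events",
    "build_ilv_matrix",
    "resolve_ties",
    "TIE_EPSILON",
]

BEHAVIOURS = ("interact", "solve")
#: perturbation step used to break tied event times (seconds)
TIE_EPSILON = 1e-6


@dataclass(frozen=True)
class Diffusion:
    """One trial's acquisition record.

    ``events`` are (individual id, seconds from trial start), ordered;
    individuals in ``roster_ids`` without an event are right-censored at
    ``trial_end_s``.  ``original_times`` keeps pre-tie-break times.
    """

    group: str
    round: int
    task_type: int
    behaviour: str
    events: tuple[tuple[str, float], ...]
    trial_end_s: float
    roster_ids: tuple[str, ...]
    original_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.behaviour not in BEHAVIOURS:
            raise InputError(f"behaviour must be one of {BEHAVIOURS}, got {self.behaviour!r}")
        ids = [i for i, _ in self.events]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ConsistencyError(
                f"{self.key()}: individual(s) {dup} acquire more than once")
        unknown = set(ids) - set(self.roster_ids)
        if unknown:
            raise IdentityError(f"{self.key()}: event individual(s) {sorted(unknown)} "
                                "not in roster")
        times = [t for _, t in self.events]
        if any(t < 0 for t in times):
            raise InputError(f"{self.key()}: negative event time")
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ConsistencyError(f"{self.key()}: event times must be non-decreasing")
        if times and times[-1] > self.trial_end_s:
            raise InputError(f"{self.key()}: event time exceeds trial_end_s")

    def key(self) -> tuple[str, int, int, str]:
        return (self.group, self.round, self.task_type, self.behaviour)

    @property
    def has_ties(self) -> bool:
        times = [t for _, t in self.events]
        return len(set(times)) != len(times)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def censored_ids(self) -> tuple[str, ...]:
        acquired = {i for i, _ in self.events}
        return tuple(i for i in self.roster_ids if i not in acquired)

    def acquisition_order(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self.events)


@dataclass
class IlvMatrix:
    """Individual-level variable design matrix in roster order.

    Columns are a subset of (age, sex), age always before sex, values raw
    (uncentred) so coefficients read as per-year / female-vs-male log-rate
    effects.
    """

    ids: tuple[str, ...]
    columns: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(len(self.ids),
                                                                   len(self.columns))
        if not np.all(np.isfinite(self.values)):
            raise InputError("ILV matrix contains non-finite values")


@dataclass
class DiffusionSet:
    """Diffusions entering one analysis, plus network and ILV lookups.

    ``network_map`` resolves (group, round) to the association network in
    force for that round; ``ilv_table`` maps individual id to its
    :class:`~otternbda.association_networks.Individual` record.
    """

    diffusions: list[Diffusion]
    network_map: dict[tuple[str, int], AssociationNetwork] = field(default_factory=dict)
    ilv_table: dict[str, Individual] = field(default_factory=dict)

    def network_for(self, diff: Diffusion) -> AssociationNetwork:
        key = (diff.group, diff.round)
        if key not in self.network_map:
            raise ConfigurationError(f"no network registered for group/round {key}")
        return self.network_map[key]

    def subset(self, round: int | None = None, behaviour: str | None = None,
               group: str | None = None) -> "DiffusionSet":
        keep = [d for d in self.diffusions
                if (round is None or d.round == round)
                and (behaviour is None or d.behaviour == behaviour)
                and (group is None or d.group == group)]
        return DiffusionSet(keep, dict(self.network_map), dict(self.ilv_table))

    @property
    def task_types(self) -> tuple[int, ...]:
        return tuple(sorted({d.task_type for d in self.diffusions}))

    @property
    def n_events(self) -> int:
        return sum(d.n_events for d in self.diffusions)

    def validate_homogeneous(self) -> None:
        """Check all diffusions share one round and one behaviour (fit contract)."""
        rounds = {d.round for d in self.diffusions}
        behaviours = {d.behaviour for d in self.diffusions}
        if len(rounds) > 1 or len(behaviours) > 1:
            raise ConsistencyError(
                f"diffusions mix rounds {sorted(rounds)} / behaviours {sorted(behaviours)}")

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "diffusions": [
                {
                    "group": d.group, "round": d.round, "task_type": d.task_type,
                    "behaviour": d.behaviour,
                    "events": [[i, t] for i, t in d.events],
                    "trial_end_s": d.trial_end_s,
                    "roster_ids": list(d.roster_ids),
                    "original_times": list(d.original_times),
                }
                for d in self.diffusions
            ]
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path,
                  network_map: Mapping[tuple[str, int], AssociationNetwork] | None = None,
                  ilv_table: Mapping[str, Individual] | None = None) -> "DiffusionSet":
        text = Path(source).read_text() if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and Path(source).exists()
        ) else str(source)
        payload = json.loads(text)
        diffs = [
            Diffusion(group=d["group"], round=d["round"], task_type=d["task_type"],
                      behaviour=d["behaviour"],
                      events=tuple((i, float(t)) for i, t in d["events"]),
                      trial_end_s=float(d["trial_end_s"]),
                      roster_ids=tuple(d["roster_ids"]),
                      original_times=tuple(d.get("original_times", ())))
            for d in payload["diffusions"]
        ]
        return cls(diffs, dict(network_map or {}), dict(ilv_table or {}))


def resolve_ties(diffusion: Diffusion, policy: str = "input-order",
                 seed: int | None = None) -> Diffusion:
    """Perturb tied event times to a strict order.

    Times recorded to the nearest second can tie; tied events get
    ``index * TIE_EPSILON`` added in the policy's order (``input-order`` or
    ``random`` with a seed).  Original times are kept in metadata.
    """
    if policy not in ("input-order", "random"):
        raise ConfigurationError(f"unknown tie policy {policy!r}")
    events = list(diffusion.events)
    times = [t for _, t in events]
    if len(set(times)) == len(times):
        return diffusion
    if policy == "random":
        rng = np.random.default_rng(seed)
        order = sorted(range(len(events)), key=lambda k: (times[k], rng.random()))
    else:
        order = sorted(range(len(events)), key=lambda k: (times[k], k))
    new_events = []
    prev_t = None
    offset = 0
    for k in order:
        i, t = events[k]
        if prev_t is not None and t == prev_t:
            offset += 1
        else:
            offset = 0
        prev_t = t
        new_events.append((i, t + offset * TIE_EPSILON))
    return replace(diffusion, events=tuple(new_events),
                   original_times=tuple(times[k] for k in order))


def read_acquisition_events(path: str | Path, roster: Iterable[Individual],
                            tie_policy: str = "input-order",
                            seed: int | None = None) -> DiffusionSet:
    """Read an events CSV into a :class:`DiffusionSet`.

    Columns: ``group,round,task_type,behaviour,individual_id,time_s[,trial_end_s]``.
    Rows are grouped into diffusions by (group, round, task_type, behaviour);
    a missing trial end is imputed as the diffusion's last event time with a
    logged warning.  Every individual of the roster belonging to the
    diffusion's group is treated as at risk; absentees are right-censored.
    """
    roster = list(roster)
    by_id = {ind.id: ind for ind in roster}
    df = pd.read_csv(path, dtype={"group": str, "individual_id": str})
    if df.empty:
        raise InputError(f"events file {path} contains no rows")
    required = {"group", "round", "task_type", "behaviour", "individual_id", "time_s"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"events file missing columns {sorted(missing)}")
    if (df["time_s"] < 0).any():
        bad = df[df["time_s"] < 0].iloc[0]
        raise InputError(f"negative time_s for individual {bad['individual_id']!r}")
    unknown = set(df["individual_id"]) - set(by_id)
    if unknown:
        raise IdentityError(f"events reference unknown individual(s) {sorted(unknown)}")
    diffusions: list[Diffusion] = []
    group_rosters = {}
    for ind in roster:
        group_rosters.setdefault(ind.group, []).append(ind.id)
    for (group, rnd, task, behaviour), block in df.groupby(
            ["group", "round", "task_type", "behaviour"], sort=True):
        block = block.sort_values("time_s", kind="stable")
        ids = list(block["individual_id"])
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ConsistencyError(
                f"({group}, r{rnd}, task {task}, {behaviour}): duplicate acquisition "
                f"for {dup}")
        if "trial_end_s" in block.columns and block["trial_end_s"].notna().any():
            trial_end = float(block["trial_end_s"].dropna().max())
        else:
            trial_end = float(block["time_s"].max())
            logger.warning("(%s, r%s, task %s, %s): trial_end_s missing; using last "
                           "event time %.1f s", group, rnd, task, behaviour, trial_end)
        diff = Diffusion(
            group=str(group), round=int(rnd), task_type=int(task),
            behaviour=str(behaviour),
            events=tuple((i, float(t)) for i, t in zip(ids, block["time_s"])),
            trial_end_s=trial_end,
            roster_ids=tuple(group_rosters.get(str(group), ids)),
        )
        diffusions.append(resolve_ties(diff, policy=tie_policy, seed=seed))
    return DiffusionSet(diffusions, ilv_table=by_id)


def build_ilv_matrix(roster: Sequence[Individual], subset: Iterable[str],
                     round_: int | None = None) -> IlvMatrix:
    """ILV design matrix for a roster, columns drawn from {age, sex}.

    Values are left on their natural scales (years; 0/1) so that fitted
    coefficients read directly as per-year and female-vs-male multipliers.
    ``round_`` selects round-specific ages where the roster carries them.
    """
    subset = list(subset)
    known = ("age", "sex")
    bad = [s for s in subset if s not in known]
    if bad:
        raise ConfigurationError(f"unknown ILV name(s) {bad}; valid: {list(known)}")
    cols = tuple(c for c in known if c in subset)  # deterministic: age before sex
    ids = tuple(ind.id for ind in roster)
    values = np.empty((len(ids), len(cols)))
    for j, c in enumerate(cols):
        if c == "age":
            values[:, j] = [ind.age_at(round_) if round_ is not None else ind.age
                            for ind in roster]
        else:
            values[:, j] = [ind.sex for ind in roster]
    return IlvMatrix(ids=ids, columns=cols, values=values)
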