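"""Synthetic study generator with known ground truth.

Emulates the design of a captive social-learning study on three otter
groups: per-group rosters with mixed ages (including pups under one year),
scan-sampled association data from heterogeneous dyadic association
probabilities, continuous-time diffusions of two behaviours (first
interaction and first solve) over five task types in two presentation
rounds, and interact-to-solve latencies following the gamma GLMM.  Every
generator is a pure function of (config, seed), so ground-truth parameters
can be recovered and coverage checked end to end.

Diffusion events are generated by the exact competing-risks counterpart of
the TADA hazard model: with relative rates ``R_i`` piecewise constant, the
waiting time to the next acquisition satisfies

    sum_i R_i * [Lambda0(t) - Lambda0(t_now)] = E,   E ~ Exponential(1)

solved in closed form via the gamma survival-function inverse (Gillespie
sampling when the baseline is constant), and the acquirer is drawn with
probability proportional to ``R_i``.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .association_networks import (AssociationNetwork, Individual, Scan,
                                    ScanDataset, compute_sri_network)
from .diffusion_data import Diffusion, DiffusionSet, resolve_ties
from .exceptions import InputError
from .tada_core import TadaModelSpec, TadaParams, relative_rate
from .diffusion_data import build_ilv_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "StudyConfig",
    "SyntheticStudy",
    "simulate_individuals",
    "simulate_scans",
    "simulate_diffusion",
    "simulate_latencies",
    "simulate_study",
]


@dataclass
class StudyConfig:
    """Generating parameters for one synthetic study.

    Defaults mirror the emulated design: three groups of 12, 12 and 5
    animals, two rounds of five task types, 180 scan samples per round
    (15 observation hours at one scan per 5 min), dyadic association
    probabilities drawn from a Beta distribution calibrated so realised
    networks have social differentiation around 0.3-0.6, and diffusion /
    latency truths at the magnitudes such studies report (interaction
    transmission rate ~5.5, solving ~1.5, age multiplier ~1.15/yr, round-2
    solve latencies ~40% of round-1).
    """

    groups: tuple[tuple[str, int], ...] = (("A", 12), ("B", 12), ("C", 5))
    seed: int = 0
    rounds: int = 2
    task_types: int = 5
    n_scans: int = 180
    # dyadic association probability p_ij ~ Beta(a, b) (pilot-calibrated)
    assoc_beta: tuple[float, float] = (0.7, 8.0)
    # calibration target for the study-median social differentiation
    differentiation_band: tuple[float, float] = (0.3, 0.6)
    pup_fraction: float = 0.3
    pup_age_range: tuple[float, float] = (0.25, 0.75)
    adult_age_range: tuple[float, float] = (1.0, 8.0)
    inter_round_gap_years: float = 0.33
    # diffusion truth
    diffusion_model_type: str = "multiplicative"
    diffusion_baseline: str = "gamma"
    baseline_params: tuple[float, ...] = (2.0, 1.0 / 300.0)  # shape, rate
    s_interact: tuple[float, ...] | float = 5.5
    s_solve: tuple[float, ...] | float = 1.5
    ilv_subset: tuple[str, ...] = ("age",)
    B: tuple[float, ...] = (0.14,)  # log(1.15)/yr age multiplier
    trial_end_s: float = 7200.0
    # latency truth (log-scale): intercept, round2, sex, age, task2..task5
    latency_beta: tuple[float, ...] = (3.0, -0.9, 0.17, 0.0, 1.0, 3.0, 3.2, 2.6)
    latency_sigma_id: float = 0.3
    latency_shape: float = 2.0

    def s_for(self, behaviour: str) -> np.ndarray:
        s = self.s_interact if behaviour == "interact" else self.s_solve
        arr = np.atleast_1d(np.asarray(s, dtype=float))
        if arr.size == 1:
            arr = np.repeat(arr, self.task_types)
        if arr.size != self.task_types:
            raise InputError("per-task s truth length must equal task_types")
        return arr

    def latency_beta_for_tasks(self) -> np.ndarray:
        """Latency truth adapted to the configured task count: the four base
        coefficients plus the first (task_types - 1) task offsets, padded
        with zeros if fewer were given."""
        beta = np.asarray(self.latency_beta, dtype=float)
        base, offsets = beta[:4], beta[4:]
        need = self.task_types - 1
        if len(offsets) < need:
            offsets = np.concatenate([offsets, np.zeros(need - len(offsets))])
        return np.concatenate([base, offsets[:need]])

    def diffusion_spec(self) -> TadaModelSpec:
        return TadaModelSpec(model_type=self.diffusion_model_type,
                             baseline=self.diffusion_baseline,
                             network_kind="social", s_constraint="different",
                             ilv_subset=self.ilv_subset
                             if self.diffusion_model_type in ("additive",
                                                              "multiplicative")
                             else ())

    def truth_dict(self) -> dict:
        d = asdict(self)
        d["s_interact"] = np.atleast_1d(self.s_interact).tolist()
        d["s_solve"] = np.atleast_1d(self.s_solve).tolist()
        return d


@dataclass
class SyntheticStudy:
    """Everything one analysis run consumes, plus the generating truth."""

    config: StudyConfig
    rosters: dict[str, list[Individual]]
    scans: dict[tuple[str, int], ScanDataset]
    networks: dict[tuple[str, int], AssociationNetwork]
    diffusion_sets: dict[tuple[str, int], DiffusionSet]  # (behaviour, round)
    latency_table: pd.DataFrame
    truth: dict

    @property
    def all_individuals(self) -> dict[str, Individual]:
        return {ind.id: ind for r in self.rosters.values() for ind in r}

    def diffusion_set(self, behaviour: str, round_: int) -> DiffusionSet:
        return self.diffusion_sets[(behaviour, round_)]

    def derived_latency_table(self) -> pd.DataFrame:
        """Interact-to-solve latencies extracted from the simulated event
        logs (the real pipeline's path), as opposed to the GLMM-truth
        ``latency_table``."""
        from .ltm_latency import build_latency_table
        nets = dict(self.networks)
        ilv = self.all_individuals
        interact_all = DiffusionSet(
            [d for (b, _), ds in self.diffusion_sets.items()
             if b == "interact" for d in ds.diffusions], nets, ilv)
        solve_all = DiffusionSet(
            [d for (b, _), ds in self.diffusion_sets.items()
             if b == "solve" for d in ds.diffusions], nets, ilv)
        return build_latency_table(interact_all, solve_all)

    def write_run_dir(self, path: str | Path) -> dict:
        """Emit roster/scans/events/latency CSVs, truth JSON and a manifest."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        roster_rows = []
        for group, roster in self.rosters.items():
            for ind in roster:
                roster_rows.append({
                    "individual_id": ind.id, "group": group,
                    "sex": "F" if ind.sex == 1 else "M",
                    "age_years": ind.age,
                    **{f"age_years_r{r}": ind.age_by_round.get(r, ind.age)
                       for r in range(1, self.config.rounds + 1)},
                })
        pd.DataFrame(roster_rows).to_csv(path / "roster.csv", index=False)
        scan_files = []
        for (group, rnd), ds in self.scans.items():
            rows = []
            for scan in ds.scans:
                for pi, party in enumerate(sorted(scan.parties, key=sorted)):
                    for ind in sorted(party):
                        rows.append({"group": group, "session": scan.session,
                                     "scan_index": scan.scan_index,
                                     "individual_id": ind, "party_id": f"p{pi}"})
            fname = f"scans_{group}_r{rnd}.csv"
            pd.DataFrame(rows).to_csv(path / fname, index=False)
            scan_files.append(fname)
        ev_rows = []
        for (behaviour, rnd), dset in self.diffusion_sets.items():
            for d in dset.diffusions:
                for ind, t in d.events:
                    ev_rows.append({"group": d.group, "round": d.round,
                                    "task_type": d.task_type, "behaviour": behaviour,
                                    "individual_id": ind, "time_s": t,
                                    "trial_end_s": d.trial_end_s})
        pd.DataFrame(ev_rows).to_csv(path / "events.csv", index=False)
        self.latency_table.to_csv(path / "latency.csv", index=False)
        (path / "truth.json").write_text(json.dumps(self.truth, indent=2))
        manifest = {"seed": self.config.seed,
                    "files": ["roster.csv", "events.csv", "latency.csv",
                              "truth.json"] + scan_files}
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest


def simulate_individuals(config: StudyConfig,
                         rng: np.random.Generator | None = None,
                         ) -> dict[str, list[Individual]]:
    """Rosters per group: Bernoulli(0.5) sexes, ages from a pup/adult
    mixture, round-2 ages shifted by the inter-round gap."""
    rng = rng or np.random.default_rng(config.seed)
    rosters: dict[str, list[Individual]] = {}
    for group, size in config.groups:
        roster = []
        for i in range(size):
            sex = int(rng.integers(0, 2))
            if rng.random() < config.pup_fraction:
                age = float(rng.uniform(*config.pup_age_range))
            else:
                age = float(rng.uniform(*config.adult_age_range))
            ages = {r: age + (r - 1) * config.inter_round_gap_years
                    for r in range(1, config.rounds + 1)}
            roster.append(Individual(id=f"{group}{i + 1:02d}", group=group,
                                     sex=sex, age=age, age_by_round=ages))
        rosters[group] = roster
    return rosters


def draw_association_probabilities(n: int, beta_params: tuple[float, float],
                                   rng: np.random.Generator) -> np.ndarray:
    """Symmetric dyadic association probability matrix p_ij ~ Beta(a, b)."""
    a, b = beta_params
    p = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    p[iu] = rng.beta(a, b, size=len(iu[0]))
    return p + p.T


def simulate_scans(roster: Sequence[Individual], p: np.ndarray, n_scans: int,
                   seed: int | np.random.Generator) -> ScanDataset:
    """Scan samples: per scan, dyad edges ~ Bernoulli(p_ij); parties are the
    connected components of the drawn edge graph (transitive closure of the
    pairwise association rule)."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    ids = [ind.id for ind in roster]
    n = len(ids)
    if p.shape != (n, n):
        raise InputError("p matrix shape does not match roster")
    iu = np.triu_indices(n, k=1)
    scans = []
    draws = rng.random((n_scans, len(iu[0])))
    for k in range(n_scans):
        edges = draws[k] < p[iu]
        adj = sparse.coo_matrix((np.ones(edges.sum()),
                                 (iu[0][edges], iu[1][edges])), shape=(n, n))
        n_comp, labels = connected_components(adj, directed=False)
        parties = tuple(frozenset(ids[i] for i in np.flatnonzero(labels == c))
                        for c in range(n_comp))
        scans.append(Scan(session=f"s{k // 12 + 1}", scan_index=k, parties=parties))
    return ScanDataset(group=roster[0].group, scans=scans, roster=list(roster))


def simulate_diffusion(net: AssociationNetwork, spec: TadaModelSpec,
                       truth: TadaParams, roster: Sequence[Individual],
                       task: int, seed: int | np.random.Generator,
                       round_: int = 1, behaviour: str = "interact",
                       trial_end_s: float = 7200.0) -> Diffusion:
    """Exact stochastic simulation of one diffusion under the TADA model.

    Competing risks with piecewise-constant relative rates: waiting times
    invert the cumulative baseline hazard (closed form via the gamma
    quantile for the gamma baseline), acquirers drawn proportional to R_i.
    Individuals not reached by the horizon are right-censored.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    ids = list(net.ids)
    n = len(ids)
    x = build_ilv_matrix(list(roster), spec.ilv_subset, round_=round_)
    if tuple(x.ids) != tuple(ids):
        raise InputError("roster order must match network roster")
    informed = np.zeros(n, dtype=bool)
    t = 0.0
    events: list[tuple[str, float]] = []
    if spec.baseline == "gamma":
        k, r = truth.shape, truth.rate
        Lam_now = 0.0
    while not informed.all():
        R = relative_rate(informed, net, x, truth, spec, task)
        R = np.where(informed, 0.0, R)
        total = R.sum()
        if total <= 0:
            break
        E = rng.exponential(1.0)
        if spec.baseline == "constant":
            t_next = t + E / (truth.lambda0 * total)
        else:
            Lam_target = Lam_now + E / total
            # Lambda0(t) = -log S(t)  =>  t = isf(exp(-Lam_target))
            if Lam_target > 700.0:
                break  # survival underflow: beyond any representable horizon
            t_next = float(stats.gamma.isf(np.exp(-Lam_target), k, scale=1.0 / r))
            if not np.isfinite(t_next):
                break
        if t_next > trial_end_s:
            break
        probs = R / total
        chosen = int(rng.choice(n, p=probs))
        t = t_next
        if spec.baseline == "gamma":
            Lam_now = Lam_target
        events.append((ids[chosen], t))
        informed[chosen] = True
    diff = Diffusion(group=roster[0].group, round=round_, task_type=task,
                     behaviour=behaviour, events=tuple(events),
                     trial_end_s=trial_end_s, roster_ids=tuple(ids))
    return resolve_ties(diff)


def simulate_latencies(rosters: dict[str, list[Individual]] | Sequence[Individual],
                       beta: Sequence[float], sigma_id: float, shape: float,
                       seed: int | np.random.Generator, rounds: int = 2,
                       task_types: int = 5) -> pd.DataFrame:
    """Latency table drawn from the gamma GLMM truth.

    ``beta`` is (intercept, round2, sex, age, task2, ..., taskT) on the log
    scale; one row per (individual, round, task type).
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if isinstance(rosters, dict):
        individuals = [ind for r in rosters.values() for ind in r]
    else:
        individuals = list(rosters)
    beta = np.asarray(beta, dtype=float)
    expected = 4 + (task_types - 1)
    if beta.size != expected:
        raise InputError(f"latency beta must have {expected} entries "
                         "(intercept, round2, sex, age, task offsets)")
    rows = []
    for ind in individuals:
        u = rng.normal(0.0, sigma_id)
        for rnd in range(1, rounds + 1):
            age = ind.age_at(rnd)
            for task in range(1, task_types + 1):
                eta = (beta[0] + beta[1] * (rnd == 2) + beta[2] * ind.sex
                       + beta[3] * age + (beta[3 + task - 1] if task > 1 else 0.0)
                       + u)
                mu = np.exp(eta)
                y = rng.gamma(shape, mu / shape)
                rows.append({"individual_id": ind.id, "round": rnd,
                             "task_type": task, "sex": ind.sex,
                             "age_years": age, "latency_s": float(y)})
    return pd.DataFrame(rows)


def simulate_study(config: StudyConfig) -> SyntheticStudy:
    """Compose a full synthetic study from one root seed.

    Named substreams (roster, scans, diffusions, latency) are derived from
    the root seed so each stage is independently reproducible.  Solve event
    times are offset by the same individual's interact time within the
    trial, so interact-to-solve latencies are well defined.
    """
    root = np.random.SeedSequence(config.seed)
    streams = {name: np.random.default_rng(s) for name, s in
               zip(("roster", "scans", "diffusion", "latency"), root.spawn(4))}
    rosters = simulate_individuals(config, streams["roster"])
    scans: dict[tuple[str, int], ScanDataset] = {}
    networks: dict[tuple[str, int], AssociationNetwork] = {}
    for group, roster in rosters.items():
        p = draw_association_probabilities(len(roster), config.assoc_beta,
                                           streams["scans"])
        for rnd in range(1, config.rounds + 1):
            ds = simulate_scans(roster, p, config.n_scans, streams["scans"])
            scans[(group, rnd)] = ds
            networks[(group, rnd)] = compute_sri_network(ds, label=f"round{rnd}")
    spec = config.diffusion_spec()
    ilv_table = {ind.id: ind for r in rosters.values() for ind in r}
    diffusion_sets: dict[tuple[str, int], DiffusionSet] = {}
    interact_times: dict[tuple[str, int, int], float] = {}
    tasks = tuple(range(1, config.task_types + 1))
    for behaviour in ("interact", "solve"):
        s_truth = config.s_for(behaviour)
        for rnd in range(1, config.rounds + 1):
            diffs = []
            for group, roster in rosters.items():
                net = networks[(group, rnd)]
                for task in tasks:
                    truth = TadaParams(
                        s=s_truth, B=np.asarray(config.B)[:len(spec.ilv_subset)],
                        lambda0=(config.baseline_params[0]
                                 if config.diffusion_baseline == "constant" else None),
                        shape=(config.baseline_params[0]
                               if config.diffusion_baseline == "gamma" else None),
                        rate=(config.baseline_params[1]
                              if config.diffusion_baseline == "gamma" else None),
                        task_types=tasks)
                    d = simulate_diffusion(net, spec, truth, roster, task,
                                           streams["diffusion"], round_=rnd,
                                           behaviour=behaviour,
                                           trial_end_s=config.trial_end_s)
                    if behaviour == "interact":
                        for ind, t in d.events:
                            interact_times[(ind, rnd, task)] = t
                    else:
                        # keep solves after the same animal's first interaction
                        shifted = []
                        for ind, t in d.events:
                            t0 = interact_times.get((ind, rnd, task))
                            if t0 is None:
                                continue  # never interacted: cannot solve
                            shifted.append((ind, t0 + t))
                        shifted.sort(key=lambda e: e[1])
                        end = max([config.trial_end_s * 2.0]
                                  + [t for _, t in shifted])
                        d = Diffusion(group=d.group, round=rnd, task_type=task,
                                      behaviour="solve",
                                      events=tuple(shifted), trial_end_s=end,
                                      roster_ids=d.roster_ids)
                        d = resolve_ties(d)
                    diffs.append(d)
            diffusion_sets[(behaviour, rnd)] = DiffusionSet(
                diffs, network_map=dict(networks), ilv_table=ilv_table)
    # the latency table follows its own generating truth (the gamma-GLMM
    # coefficients in the config); the event-derived alternative is
    # available via SyntheticStudy.derived_latency_table()
    latency_table = simulate_latencies(rosters, config.latency_beta_for_tasks(),
                                       config.latency_sigma_id,
                                       config.latency_shape,
                                       streams["latency"],
                                       rounds=config.rounds,
                                       task_types=config.task_types)
    truth = {"config": config.truth_dict(),
             "spec": spec.to_dict(),
             "differentiation": {f"{g}_r{r}": None for (g, r) in networks}}
    from .association_networks import social_differentiation
    for key, net in networks.items():
        truth["differentiation"][f"{key[0]}_r{key[1]}"] = social_differentiation(net)
    return SyntheticStudy(config=config, rosters=rosters, scans=scans,
                          networks=networks, diffusion_sets=diffusion_sets,
                          latency_table=latency_table, truth=truth)
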