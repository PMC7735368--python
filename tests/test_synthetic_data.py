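"""Synthetic-study generators: determinism, degenerate cases, calibration."""
import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from otternbda import (Individual, StudyConfig, TadaModelSpec, TadaParams,
                       compute_sri_network, homogeneous_network,
                       simulate_diffusion, simulate_individuals,
                       simulate_latencies, simulate_scans, simulate_study,
                       social_differentiation)
from otternbda.synthetic_data import draw_association_probabilities
from otternbda.tada_core import baseline_hazard, relative_rate
from otternbda.diffusion_data import build_ilv_matrix


class TestSimulateIndividuals:
    def test_group_sizes(self):
        rosters = simulate_individuals(StudyConfig(seed=0))
        assert sum(len(r) for r in rosters.values()) == 29
        assert [len(r) for r in rosters.values()] == [12, 12, 5]

    def test_determinism(self):
        a = simulate_individuals(StudyConfig(seed=5))
        b = simulate_individuals(StudyConfig(seed=5))
        for g in a:
            assert [(i.id, i.sex, i.age) for i in a[g]] == \
                [(i.id, i.sex, i.age) for i in b[g]]

    def test_inter_round_age_gap(self):
        cfg = StudyConfig(seed=2, inter_round_gap_years=0.3)
        rosters = simulate_individuals(cfg)
        for roster in rosters.values():
            for ind in roster:
                assert ind.age_at(2) - ind.age_at(1) == pytest.approx(0.3)


class TestSimulateScans:
    def _roster(self, n):
        return [Individual(f"i{k}", "g", 0, 2.0) for k in range(n)]

    def test_p_zero_all_singletons(self):
        roster = self._roster(5)
        ds = simulate_scans(roster, np.zeros((5, 5)), 30, seed=0)
        net = compute_sri_network(ds)
        assert np.all(net.matrix == 0)
        assert all(len(s.parties) == 5 for s in ds.scans)

    def test_p_one_single_party(self):
        roster = self._roster(5)
        p = np.ones((5, 5))
        np.fill_diagonal(p, 0.0)
        ds = simulate_scans(roster, p, 30, seed=0)
        net = compute_sri_network(ds)
        off = net.matrix[~np.eye(5, dtype=bool)]
        assert np.all(off == 1.0)
        assert all(len(s.parties) == 1 for s in ds.scans)

    def test_isolated_dyad_converges(self):
        roster = self._roster(2)
        p = np.array([[0.0, 0.3], [0.3, 0.0]])
        ds = simulate_scans(roster, p, 5000, seed=3)
        net = compute_sri_network(ds)
        assert abs(net.matrix[0, 1] - 0.3) < 0.05

    def test_sri_error_decreases_with_scan_count(self):
        roster = self._roster(6)
        rng = np.random.default_rng(8)
        p = draw_association_probabilities(6, (0.7, 8.0), rng)
        errs = []
        for n_scans in (50, 400, 3200):
            ds = simulate_scans(roster, p, n_scans, seed=11)
            net = compute_sri_network(ds)
            # compare against the long-run SRI at a much larger sample
            ref = compute_sri_network(simulate_scans(roster, p, 12000,
                                                     seed=99))
            iu = np.triu_indices(6, 1)
            errs.append(np.mean(np.abs(net.matrix[iu] - ref.matrix[iu])))
        assert errs[0] > errs[-1]


class TestSimulateDiffusion:
    def test_deterministic(self, toy_net, toy_roster):
        spec = TadaModelSpec("social_no_ilv", "constant")
        truth = TadaParams(s=[2.0], lambda0=0.01, task_types=(1,))
        d1 = simulate_diffusion(toy_net, spec, truth, toy_roster, 1, seed=4)
        d2 = simulate_diffusion(toy_net, spec, truth, toy_roster, 1, seed=4)
        assert d1.events == d2.events

    def test_high_s_spreads_through_community(self):
        """With very large s on a two-community network, acquisition stays
        within the innovator's community more than under s = 0."""
        ids = tuple(f"i{k}" for k in range(8))
        roster = [Individual(i, "g", 0, 2.0) for i in ids]
        m = np.zeros((8, 8))
        for block in (range(0, 4), range(4, 8)):
            for i in block:
                for j in block:
                    if i != j:
                        m[i, j] = 1.0
        net_comm = __import__("otternbda").AssociationNetwork(ids, m)
        spec = TadaModelSpec("social_no_ilv", "constant")

        def contiguity(s, seed):
            truth = TadaParams(s=[s], lambda0=0.001, task_types=(1,))
            count = 0
            rng = np.random.default_rng(seed)
            for _ in range(200):
                d = simulate_diffusion(net_comm, spec, truth, roster, 1, rng)
                order = [ids.index(i) // 4 for i, _ in d.events]
                # second acquirer in the innovator's community?
                count += len(order) > 1 and order[1] == order[0]
            return count

        assert contiguity(50.0, 1) > contiguity(0.0, 1) + 20

    def test_censoring_at_horizon(self, toy_net, toy_roster):
        spec = TadaModelSpec("social_no_ilv", "constant")
        truth = TadaParams(s=[0.0], lambda0=1e-7, task_types=(1,))
        d = simulate_diffusion(toy_net, spec, truth, toy_roster, 1, seed=0,
                               trial_end_s=100.0)
        assert d.trial_end_s == 100.0
        assert d.n_events + len(d.censored_ids) == 3


class TestSimulateLatencies:
    def test_moment_check(self):
        roster = [Individual(f"i{k}", "g", 0, 2.0) for k in range(500)]
        beta = [np.log(100.0), 0, 0, 0] + [0, 0, 0, 0]
        tab = simulate_latencies(roster, beta, 0.0, 2.0, seed=6, rounds=2,
                                 task_types=5)
        n = len(tab)
        assert n == 5000
        se = 100.0 / np.sqrt(2.0) / np.sqrt(n)  # gamma sd = mu/sqrt(shape)
        assert abs(tab["latency_s"].mean() - 100.0) < 3 * se

    def test_positive_and_deterministic(self):
        roster = [Individual("x", "g", 1, 3.0)]
        cfg = StudyConfig()
        t1 = simulate_latencies(roster, cfg.latency_beta, 0.3, 2.0, seed=1)
        t2 = simulate_latencies(roster, cfg.latency_beta, 0.3, 2.0, seed=1)
        assert (t1["latency_s"] > 0).all()
        pd.testing.assert_frame_equal(t1, t2)


class TestSimulateStudy:
    def test_structure_counts(self, default_study):
        assert sum(len(ds.diffusions)
                   for ds in default_study.diffusion_sets.values()) == 60
        assert len(default_study.networks) == 6
        assert set(default_study.diffusion_sets) == {
            (b, r) for b in ("interact", "solve") for r in (1, 2)}

    def test_truth_round_trip(self, default_study, tmp_path):
        default_study.write_run_dir(tmp_path)
        back = json.loads((tmp_path / "truth.json").read_text())
        assert back == json.loads(json.dumps(default_study.truth))
        assert (tmp_path / "roster.csv").exists()
        assert (tmp_path / "events.csv").exists()

    def test_differentiation_band_median(self):
        """Study-median social differentiation sits in the configured band."""
        for seed in (0, 1, 2):
            study = simulate_study(StudyConfig(seed=seed))
            vals = [social_differentiation(net)
                    for net in study.networks.values()]
            lo, hi = study.config.differentiation_band
            assert lo <= float(np.median(vals)) <= hi

    def test_solves_follow_interactions(self, default_study):
        interact = {}
        for rnd in (1, 2):
            for d in default_study.diffusion_set("interact", rnd).diffusions:
                for i, t in d.events:
                    interact[(i, rnd, d.task_type)] = t
        for rnd in (1, 2):
            for d in default_study.diffusion_set("solve", rnd).diffusions:
                for i, t in d.events:
                    assert t >= interact[(i, rnd, d.task_type)]

    def test_pure_function_of_seed(self):
        s1 = simulate_study(StudyConfig(seed=9))
        s2 = simulate_study(StudyConfig(seed=9))
        for key in s1.diffusion_sets:
            for d1, d2 in zip(s1.diffusion_sets[key].diffusions,
                              s2.diffusion_sets[key].diffusions):
                assert d1.events == d2.events
        pd.testing.assert_frame_equal(s1.latency_table, s2.latency_table)


def test_simulate_and_score_consistency(small_study):
    """PIT residuals of inter-event waiting times, computed from the same
    hazard quantities the likelihood uses, are uniform under the generating
    model (Kolmogorov-Smirnov, alpha = 0.01)."""
    cfg = StudyConfig(seed=77, groups=(("A", 8),), task_types=1, rounds=1,
                      diffusion_model_type="social_no_ilv",
                      diffusion_baseline="constant", baseline_params=(0.002,),
                      s_interact=3.0, s_solve=3.0, ilv_subset=(), B=())
    rng = np.random.default_rng(77)
    roster = simulate_individuals(cfg, rng)["A"]
    ids = tuple(i.id for i in roster)
    net = homogeneous_network(ids)
    spec = cfg.diffusion_spec()
    spec = TadaModelSpec("social_no_ilv", "constant", network_kind="social")
    truth = TadaParams(s=[3.0], lambda0=0.002, task_types=(1,))
    x = build_ilv_matrix(roster, ())
    pits = []
    for rep in range(120):
        d = simulate_diffusion(net, spec, truth, roster, 1, rng,
                               trial_end_s=1e7)
        informed = np.zeros(len(ids), dtype=bool)
        t_prev = 0.0
        for i, t in d.events:
            R = relative_rate(informed, net, x, truth, spec, 1)
            R = np.where(informed, 0.0, R)
            total = R.sum()
            _, Lam_hi = baseline_hazard(t, truth, "constant")
            _, Lam_lo = baseline_hazard(t_prev, truth, "constant")
            pits.append(1.0 - np.exp(-total * (Lam_hi - Lam_lo)))
            informed[ids.index(i)] = True
            t_prev = t
    stat, p = stats.kstest(pits, "uniform")
    assert p > 0.01
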