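"""Shared fixtures: toy rosters, networks, diffusions and a small synthetic
study reused across test modules."""
import numpy as np
import pytest

from otternbda import (AssociationNetwork, Diffusion, DiffusionSet, Individual,
                       StudyConfig, simulate_study)


@pytest.fixture
def toy_roster():
    return [
        Individual("a", "g", sex=1, age=2.0),
        Individual("b", "g", sex=0, age=3.0),
        Individual("c", "g", sex=1, age=0.5),
    ]


@pytest.fixture
def toy_net(toy_roster):
    m = np.array([[0.0, 0.5, 0.2],
                  [0.5, 0.0, 0.4],
                  [0.2, 0.4, 0.0]])
    return AssociationNetwork(("a", "b", "c"), m)


@pytest.fixture
def toy_diffusion(toy_roster):
    return Diffusion(group="g", round=1, task_type=1, behaviour="interact",
                     events=(("a", 30.0), ("b", 80.0)), trial_end_s=200.0,
                     roster_ids=("a", "b", "c"))


@pytest.fixture
def toy_data(toy_roster, toy_net, toy_diffusion):
    return DiffusionSet([toy_diffusion], {("g", 1): toy_net},
                        {i.id: i for i in toy_roster})


@pytest.fixture(scope="session")
def small_study():
    """Reduced synthetic study (two groups, three tasks) shared by tests that
    only need realistic structure, not the full design."""
    cfg = StudyConfig(seed=42, groups=(("A", 6), ("B", 5)), task_types=3,
                      n_scans=60)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def default_study():
    """Full-scale synthetic study at the emulated design (3 groups 12/12/5,
    5 tasks, 2 rounds)."""
    return simulate_study(StudyConfig(seed=7))
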