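"""Shared fixtures.

The full 600-s arrest simulations are expensive, so each scenario is run
once per session and shared across tests.
"""

from __future__ import annotations

import copy

import numpy as np
import pytest

import zeroflow as zf
from zeroflow.scenarios import ScenarioConfig, run_scenario


@pytest.fixture(scope="session")
def human_topo():
    return zf.build_default_model()


@pytest.fixture(scope="session")
def pig_topo():
    return zf.build_default_model("pig_calibrated")


@pytest.fixture(scope="session")
def anchors():
    return zf.load_anchor_table()


@pytest.fixture(scope="session")
def eu_on_trace(human_topo):
    """Euvolemic arrest with reflexes active (VF analogue), 600 s."""
    return run_scenario(human_topo, ScenarioConfig("euvolemia", True))


@pytest.fixture(scope="session")
def eu_off_trace(human_topo):
    """Euvolemic arrest with reflexes off (pentobarbital analogue), 600 s."""
    return run_scenario(human_topo, ScenarioConfig("euvolemia", False))


@pytest.fixture(scope="session")
def pig_on_trace(pig_topo):
    return run_scenario(pig_topo, ScenarioConfig("euvolemia", True))


@pytest.fixture(scope="session")
def pig_off_trace(pig_topo):
    return run_scenario(pig_topo, ScenarioConfig("euvolemia", False))


@pytest.fixture(scope="session")
def noiseless_cohort(anchors):
    """Two identical (noise-free) animals per group - the deterministic
    reference recordings."""
    spec = zf.CohortSpec(
        n_per_group={"pento_eu": 2, "vf_eu": 2, "vf_hypo": 2}, seed=1
    ).noiseless()
    traces, _ = zf.synthesize_cohort(spec, anchors)
    return traces


def perturb_model_config(cfg: dict, seed: int) -> dict:
    """Random but physiological perturbation of a model config (used by the
    equilibrium-oracle tests)."""
    rng = np.random.default_rng(seed)
    c = copy.deepcopy(cfg)
    for row in c["compartments"]:
        f = rng.uniform(0.7, 1.3)
        if "C" in row:
            row["C"] *= f
        else:
            row["E_min"] *= f
            row["E_max"] *= f
        row["V0"] *= rng.uniform(0.85, 1.15)
    for e in c["connections"]:
        e["R"] *= rng.uniform(0.7, 1.3)
    c["total_blood_volume_ml"] *= rng.uniform(0.9, 1.1)
    return c
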