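"""Shared fixtures: simulated populations at reduced scale.

The 16-scenario grid mirrors the simulation study design: four effect
configurations (no IGEs; IGEs with DGE-IGE correlation 0, 0.5 or 1) crossed
with four strengths of assortative mating (spousal phenotypic correlation 0,
0.25, 0.5, 0.75). Reduced scale keeps 1000 causal SNPs and 20 generations of
mating after the random-mating founder generation, with 3000 families instead
of 30000. All seeds are fixed constants.
"""

from __future__ import annotations

import pytest

from igeam.simulate import SimConfig, run_simulation

N_FAMILIES = 3000
N_VARIANTS = 1000
N_GENERATIONS = 20
SCENARIO_SEED_BASE = 1000

EFFECT_CONFIGS = [
    (0.0, 0.0),
    (0.125, 0.0),
    (0.125, 0.5),
    (0.125, 1.0),
]
RY_VALUES = [0.0, 0.25, 0.5, 0.75]

SCENARIOS = [
    (ve_g0, r0, ry) for ve_g0, r0 in EFFECT_CONFIGS for ry in RY_VALUES
]


def scenario_config(ve_g0, r0, ry, index, **overrides) -> SimConfig:
    fields = dict(
        n_families=N_FAMILIES,
        n_variants=N_VARIANTS,
        n_generations=N_GENERATIONS,
        vg0=0.5,
        ve_g0=ve_g0,
        r_dg_ig_0=r0,
        r_y=ry,
        seed=SCENARIO_SEED_BASE + index,
    )
    fields.update(overrides)
    return SimConfig(**fields)


@pytest.fixture(scope="session")
def scenario_results():
    """All 16 scenarios simulated once per session, keyed (ve_g0, r0, ry)."""
    results = {}
    for i, (ve_g0, r0, ry) in enumerate(SCENARIOS):
        results[(ve_g0, r0, ry)] = run_simulation(scenario_config(ve_g0, r0, ry, i))
    return results


@pytest.fixture(scope="session")
def sim_am_ige(scenario_results):
    """IGEs correlated with DGEs (r0 = 0.5) under moderate AM (ry = 0.5)."""
    return scenario_results[(0.125, 0.5, 0.5)]


@pytest.fixture(scope="session")
def sim_am_noige(scenario_results):
    """Pure-DGE phenotype under moderate AM."""
    return scenario_results[(0.0, 0.0, 0.5)]


@pytest.fixture(scope="session")
def sim_random(scenario_results):
    """Random mating throughout (with IGEs present)."""
    return scenario_results[(0.125, 0.5, 0.0)]


@pytest.fixture(scope="session")
def tiny_sim():
    """Small, fast population for regression/CLI plumbing tests."""
    cfg = SimConfig(
        n_families=800, n_variants=300, n_generations=4,
        ve_g0=0.125, r_dg_ig_0=0.5, r_y=0.5, seed=42,
    )
    return run_simulation(cfg)
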