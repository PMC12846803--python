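"""Shared fixtures.

The expensive agent-based runs (shear sweep, net-adhesion cross-validation
point, density-field run) are session-scoped and shared between the
simulator invariant tests and the end-to-end acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from active_leveque import pipeline, theory
from active_leveque.parameters import DimensionlessGroups, E_COLI, P_AERUGINOSA
from active_leveque.simulate import SimConfig, run_simulation

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ecoli():
    return E_COLI


@pytest.fixture(scope="session")
def p_aeruginosa():
    return P_AERUGINOSA


@pytest.fixture(scope="session")
def ecoli_sweep():
    """Reduced E. coli shear sweep (L = 750 µm, log grid 0.1–50 1/s)."""
    grid = np.geomspace(0.1, 50.0, 6)
    df, summaries = pipeline.sweep_shear("e_coli", grid, preset="desk", seed=0)
    assert not df["error"].astype(bool).any(), df["error"].tolist()
    return df


@pytest.fixture(scope="session")
def lowshear_sweep():
    """Two-point low-shear sweep at L = 7500 µm (small relative swim speed),
    spanning [crit/30, crit/3] of the E. coli critical shear rate."""
    df, _ = pipeline.sweep_shear(
        "e_coli", [0.0357, 0.357], preset="desk", lengthscale=7500.0, seed=3
    )
    assert not df["error"].astype(bool).any()
    return df


@pytest.fixture(scope="session")
def jbar_run():
    """Net-adhesion cross-validation run at (Per=1, Vs=0.01, beta=0).

    Reduced scale: ~3000 injected agents (≈10⁷ agent-steps), four windows.
    Returns (summary, groups, eff_peclet).
    """
    groups = DimensionlessGroups(rel_swim_speed=0.01, rot_peclet=1.0)
    pe_eff = theory.effective_peclet(groups, 0.0)
    config = SimConfig(
        rel_swim_speed=0.01,
        rot_peclet=1.0,
        beta=0.0,
        domain_height=0.25,
        t_end=1500.0,
        n_inject=0.02,
        t_burnin=300.0,
        window_length=300.0,
        seed=11,
        record_density=False,
    )
    summary, _ = run_simulation(config)
    return summary, groups, pe_eff


@pytest.fixture(scope="session")
def density_run():
    """Density-field run at (Per=1, Vs=0.01, beta=0), H=0.8, l=3.

    Returns (summary, field, comparison, eff_peclet).
    """
    groups = DimensionlessGroups(rel_swim_speed=0.01, rot_peclet=1.0)
    pe_eff = theory.effective_peclet(groups, 0.0)
    config = pipeline.make_sim_config(groups, 0.0, "desk_density", seed=5)
    summary, field = run_simulation(config)
    comparison = pipeline.compare_density(field, pe_eff, exclusion_x=0.5)
    return summary, field, comparison, pe_eff
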