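"""Shared fixtures; expensive trajectories are computed once per session."""

import pytest
from hypothesis import settings

import nomadcolony as nc

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def run_scenario(name: str, **option_overrides):
    from dataclasses import replace

    cfg = nc.load_scenario(name)
    options = replace(cfg.options, **option_overrides) if option_overrides else cfg.options
    traj = nc.simulate(cfg.params, cfg.policy, cfg.init, options)
    return cfg, options, traj


@pytest.fixture(scope="session")
def fig5_run():
    """Adaptive optimal-rule run to t=1000 (the long-term growth scenario)."""
    cfg, options, traj = run_scenario("fig5")
    return cfg, options, traj


@pytest.fixture(scope="session")
def fig2b_run():
    """Fixed-threshold survival scenario (the paradox witness)."""
    cfg, options, traj = run_scenario("fig2b")
    return cfg, options, traj
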