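"""Integration tests for the event-driven solver."""

import numpy as np
import pytest

from nomadcolony import (
    ModelParams,
    SimOptions,
    SimState,
    SwitchPolicy,
    simulate,
)
from nomadcolony.engine import adaptive_policy_events, fixed_policy_events


def test_decoupled_nomadic_decay_matches_closed_form():
    """With switching off, n1 decouples and must follow n1(0) e^{-r1 t}."""
    params = ModelParams(r1=0.7, r2=10.0, rs=0.0, A=0.5)
    init = SimState(t=0.0, n1=2.0, n2=2.0, K=5.0)
    opts = SimOptions(t_end=20.0)
    traj = simulate(params, SwitchPolicy.none(), init, opts)
    exact = 2.0 * np.exp(-0.7 * traj.times)
    # mixed-tolerance accuracy: relative where resolvable, atol-limited below
    assert np.all(np.abs(traj.n1 - exact) <= 10 * (opts.rtol * exact + opts.atol))


def test_subcritical_allee_colony_stabilizes_at_long_term_capacity():
    """A < 1 with A < n2 < K: trajectory converges to n2 = K = 1."""
    params = ModelParams(r1=1.0, r2=10.0, rs=0.0, A=0.5)
    init = SimState(t=0.0, n1=2.0, n2=2.0, K=5.0)
    traj = simulate(params, SwitchPolicy.none(), init, SimOptions(t_end=50.0))
    assert traj.n2[-1] == pytest.approx(1.0, abs=1e-4)
    assert traj.K[-1] == pytest.approx(1.0, abs=1e-4)


def test_transfer_conservation_across_switching_events():
    """With growth negligible, switching only moves organisms between the
    sub-populations: n1 + n2 stays constant through events."""
    # growth cannot be switched off exactly (r1, r2 > 0), so make it
    # negligible relative to the transfer rate
    params = ModelParams(r1=1e-12, r2=1e-12, rs=10.0, A=1.5)
    init = SimState(t=0.0, n1=1.0, n2=0.3, K=3.5)
    policy = SwitchPolicy.fixed(L1=2.0, L2=3.0)
    traj = simulate(params, policy, init, SimOptions(t_end=5.0))
    assert len(traj.events) > 0
    total = traj.total
    assert np.abs(total - total[0]).max() < 1e-8


def test_reported_populations_never_negative():
    params = ModelParams(r1=1.0, r2=10.0, rs=1000.0, A=1.001)
    init = SimState(t=0.0, n1=2.0, n2=2.0, K=5.0)
    traj = simulate(params, SwitchPolicy.fixed(3.0, 4.5), init, SimOptions(t_end=50.0))
    assert traj.n1.min() >= 0.0
    assert traj.n2.min() >= 0.0


def test_bounded_capacity_never_exceeds_cap():
    params = ModelParams(r1=1.0, r2=10.0, rs=1000.0, A=1.001, Kmax=20.0)
    init = SimState(t=0.0, n1=0.0, n2=2.0, K=5.0)
    traj = simulate(params, SwitchPolicy.adaptive(), init, SimOptions(t_end=50.0))
    assert traj.K.max() <= 20.0 + 1e-6


def test_fixed_policy_event_sequence_is_periodic_alternation():
    """Fig-2-style survival: entry/exit events alternate, and the L2
    up-crossing switches colonization on."""
    params = ModelParams(r1=1.0, r2=10.0, rs=1000.0, A=1.001)
    init = SimState(t=0.0, n1=2.0, n2=2.0, K=5.0)
    traj = simulate(params, SwitchPolicy.fixed(3.0, 4.0), init, SimOptions(t_end=30.0))
    kinds = [e.kind for e in traj.events]
    assert kinds.count("K_crossed_L2_up") >= 3
    assert kinds.count("K_crossed_L1_down") >= 3
    # every up-crossing of L2 is eventually followed by a down-crossing
    up = [e.time for e in traj.events if e.kind == "K_crossed_L2_up"]
    down = [e.time for e in traj.events if e.kind == "K_crossed_L2_down"]
    for t_up in up[:-1]:
        assert any(t_down > t_up for t_down in down)


def test_adaptive_overshoot_nomads_exceed_capacity():
    """Under the optimal rule the switch-out conversion produces extra
    colonial offspring, so late nomadic peaks exceed the capacity."""
    params = ModelParams(r1=1.0, r2=10.0, rs=1000.0, A=1.001)
    init = SimState(t=0.0, n1=0.0, n2=2.0, K=5.0)
    traj = simulate(params, SwitchPolicy.adaptive(), init, SimOptions(t_end=10.0))
    assert (traj.n1 - traj.K).max() > 0.0


def test_tolerance_refinement_stability():
    """Refining tolerances 10x moves the final state by far less than 1%."""
    params = ModelParams(r1=1.0, r2=10.0, rs=1000.0, A=1.001)
    init = SimState(t=0.0, n1=2.0, n2=2.0, K=5.0)
    policy = SwitchPolicy.fixed(3.0, 4.0)
    t1 = simulate(params, policy, init, SimOptions(t_end=30.0))
    t2 = simulate(params, policy, init, SimOptions(t_end=30.0, rtol=1e-10, atol=1e-10))
    for a, b in zip(
        (t1.n1[-1], t1.n2[-1], t1.K[-1]), (t2.n1[-1], t2.n2[-1], t2.K[-1])
    ):
        assert abs(a - b) / max(abs(a), abs(b), 1e-6) < 0.01


def test_output_grid_sampling():
    grid = np.linspace(0.0, 5.0, 101)
    params = ModelParams(r1=1.0, r2=10.0, rs=0.0, A=0.5)
    init = SimState(t=0.0, n1=2.0, n2=2.0, K=5.0)
    traj = simulate(params, SwitchPolicy.none(), init,
                    SimOptions(t_end=5.0, output_grid=grid))
    assert np.all(np.diff(traj.times) > 0)
    assert set(np.round(grid, 9)).issubset(set(np.round(traj.times, 9)))


def test_phases_partition_horizon(fig2b_run):
    cfg, options, traj = fig2b_run
    phases = traj.phases
    assert phases[0].start == traj.times[0]
    assert phases[-1].end == pytest.approx(traj.times[-1])
    for a, b in zip(phases[:-1], phases[1:]):
        assert a.end == b.start
    assert {p.label for p in phases} == {"nomadic", "colonial", "switching"}


class TestPolicyEventFunctions:
    def test_fixed_crossing_functions(self):
        pol = SwitchPolicy.fixed(3.0, 4.0)
        s = SimState(t=0.0, n1=1.0, n2=1.0, K=3.0)
        assert fixed_policy_events(s, pol) == (0.0, -1.0)
        s = SimState(t=0.0, n1=1.0, n2=1.0, K=3.5)
        g1, g2 = fixed_policy_events(s, pol)
        assert g1 > 0 and g2 < 0

    def test_adaptive_direction_filters(self):
        pol = SwitchPolicy.adaptive(B=1.5)
        s = SimState(t=0.0, n1=0.1, n2=4.0, K=4.0)
        ev = adaptive_policy_events(s, (0.0, 2.0, -3.0), pol)
        g, accepted = ev["n2_reached_K"]
        assert g == 0.0 and accepted          # colony still growing
        ev = adaptive_policy_events(s, (0.0, -2.0, -3.0), pol)
        _, accepted = ev["n2_reached_K"]
        assert not accepted                    # touching K while shrinking
        s = SimState(t=0.0, n1=1.5, n2=0.0, K=6.0)
        ev = adaptive_policy_events(s, (-1.5, 0.0, 1.0), pol)
        g, accepted = ev["n1_reached_B"]
        assert g == 0.0 and accepted           # nomads decaying through B

    def test_wrong_mode_rejected(self):
        s = SimState(t=0.0, n1=1.0, n2=1.0, K=3.0)
        with pytest.raises(ValueError):
            fixed_policy_events(s, SwitchPolicy.none())
        with pytest.raises(ValueError):
            adaptive_policy_events(s, (0, 0, 0), SwitchPolicy.fixed(3, 4))


class TestPolicyValidation:
    def test_misordered_thresholds(self):
        with pytest.raises(ValueError):
            SwitchPolicy.fixed(4.0, 3.0)

    def test_adaptive_needs_supercritical_B(self):
        with pytest.raises(ValueError):
            SwitchPolicy.adaptive(B=0.9)

    def test_default_B_resolves_to_corrected_level(self):
        from nomadcolony import corrected_critical_level

        params = ModelParams(r1=1.0, r2=10.0, rs=1000.0, A=1.001)
        pol = SwitchPolicy.adaptive()
        assert pol.resolve_B(params) == pytest.approx(
            corrected_critical_level(params), rel=1e-12
        )
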