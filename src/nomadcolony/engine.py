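"""Event-driven integration of the nomadic-colonial ODE system.

The right-hand side is discontinuous: the threshold rule turns the
switching rates on and off as K crosses the levels L1/L2, and the adaptive
optimal rule additionally reassigns those levels when n2 rises to K or n1
decays to the critical level B.  Between such events the system is smooth,
so the integrator runs an adaptive explicit Runge-Kutta pair segment by
segment, stops exactly at each located event (scipy's terminal-event
machinery), applies the policy change, and restarts.  This mirrors the
event-location approach standard for piecewise-smooth ODEs and keeps the
solver's local error control valid across the discontinuities.

Phase bookkeeping: each trajectory is annotated with ``nomadic``,
``colonial`` and ``switching`` intervals, where "switching" covers the
short windows in which one of the conversion rates is active.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from . import model
from .model import EPS_K, ModelParams, SimState

__all__ = [
    "SwitchPolicy",
    "SimOptions",
    "Event",
    "Phase",
    "Trajectory",
    "SolverError",
    "simulate",
    "fixed_policy_events",
    "adaptive_policy_events",
]

# event kinds
K_L1_DOWN = "K_crossed_L1_down"
K_L1_UP = "K_crossed_L1_up"
K_L2_UP = "K_crossed_L2_up"
K_L2_DOWN = "K_crossed_L2_down"
N2_K = "n2_reached_K_growing"
N1_B = "n1_reached_B_decaying"

COLONIAL_ENTRY_EVENTS = {K_L2_UP, N1_B}


@dataclass(frozen=True)
class SwitchPolicy:
    """Behavioral switching rule.

    ``mode`` is one of:

    * ``"none"`` -- no switching (equivalent to rs = 0);
    * ``"fixed"`` -- static thresholds: colonists turn nomad at rate rs
      while K < L1, nomads turn colonist while K > L2 (0 < L1 <= L2);
    * ``"adaptive"`` -- the optimal rule: when n2 rises to K (with the gap
      closing), set L1 = K and disable colonial entry; when n1 decays to B,
      set L2 = K, triggering immediate recolonization.  ``B`` defaults to
      the corrected critical level for the model parameters; ``L1``/``L2``
      may supply initial thresholds active before the first reassignment.
    """

    mode: str = "none"
    L1: float | None = None
    L2: float | None = None
    B: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("none", "fixed", "adaptive"):
            raise ValueError(f"unknown policy mode {self.mode!r}")
        if self.mode == "fixed":
            if self.L1 is None or self.L2 is None:
                raise ValueError("fixed policy requires both L1 and L2")
            if not 0 < self.L1 <= self.L2:
                raise ValueError(
                    f"fixed policy requires 0 < L1 <= L2, got L1={self.L1}, L2={self.L2}"
                )
        if self.mode == "adaptive" and self.B is not None and not self.B > 1:
            raise ValueError(f"adaptive policy requires B > 1, got B={self.B}")

    @classmethod
    def none(cls) -> "SwitchPolicy":
        return cls(mode="none")

    @classmethod
    def fixed(cls, L1: float, L2: float) -> "SwitchPolicy":
        return cls(mode="fixed", L1=L1, L2=L2)

    @classmethod
    def adaptive(
        cls, B: float | None = None, L1: float | None = None, L2: float | None = None
    ) -> "SwitchPolicy":
        return cls(mode="adaptive", B=B, L1=L1, L2=L2)

    def resolve_B(self, params: ModelParams) -> float | None:
        """Entry level actually used: explicit B, or the corrected default."""
        if self.mode != "adaptive":
            return self.B
        if self.B is not None:
            return self.B
        from .theory import corrected_critical_level

        return corrected_critical_level(params)


@dataclass(frozen=True)
class SimOptions:
    """Integration and classification options.

    Tolerances default to 1e-9 (both relative and absolute); accuracy of a
    run can be re-checked by refining them tenfold and confirming the final
    state moves by less than 1%.  ``extinction_floor`` is the population
    level below which a sub-population counts as extinct for classification
    (the continuum model never reaches zero in finite time).
    """

    t_end: float = 50.0
    rtol: float = 1e-9
    atol: float = 1e-9
    max_step: float | None = None
    extinction_floor: float = 1e-6
    output_grid: np.ndarray | None = None
    method: str = "RK45"
    max_segments: int = 200_000

    def __post_init__(self) -> None:
        if not self.t_end > 0:
            raise ValueError(f"t_end must be > 0, got {self.t_end}")
        if not (self.rtol > 0 and self.atol > 0):
            raise ValueError("tolerances must be positive")
        if not self.extinction_floor > 0:
            raise ValueError("extinction_floor must be positive")


@dataclass(frozen=True)
class Event:
    time: float
    kind: str


@dataclass(frozen=True)
class Phase:
    start: float
    end: float
    label: str  # nomadic | colonial | switching


@dataclass
class Trajectory:
    """Sampled solution with event and phase annotations."""

    times: np.ndarray
    n1: np.ndarray
    n2: np.ndarray
    K: np.ndarray
    events: list[Event] = field(default_factory=list)
    phases: list[Phase] = field(default_factory=list)
    policy_mode: str = "none"

    @property
    def total(self) -> np.ndarray:
        return self.n1 + self.n2

    def final_state(self) -> SimState:
        return SimState(
            t=float(self.times[-1]),
            n1=float(self.n1[-1]),
            n2=float(self.n2[-1]),
            K=float(self.K[-1]),
        )

    def to_frame(self):
        """Tidy DataFrame with columns t, n1, n2, K, phase."""
        import pandas as pd

        return pd.DataFrame(
            {"t": self.times, "n1": self.n1, "n2": self.n2, "K": self.K,
             "phase": self.phase_at(self.times)}
        )

    def phase_at(self, t: np.ndarray) -> np.ndarray:
        """Phase label for each time (boundary points go to the later phase)."""
        starts = np.array([ph.start for ph in self.phases])
        idx = np.searchsorted(starts, t, side="right") - 1
        idx = np.clip(idx, 0, len(self.phases) - 1)
        return np.array([self.phases[i].label for i in idx], dtype=object)


class SolverError(RuntimeError):
    """Integration failure; carries the last valid state."""

    def __init__(self, message: str, last_state: SimState):
        super().__init__(f"{message} (last state: {last_state})")
        self.last_state = last_state


# ---------------------------------------------------------------------------
# pure event-test operations (unit-testable views of the event machinery)

def fixed_policy_events(state: SimState, policy: SwitchPolicy) -> tuple[float, float]:
    """Signed crossing functions (K - L1, K - L2) for the fixed rule."""
    if policy.mode != "fixed":
        raise ValueError("fixed_policy_events requires a fixed-threshold policy")
    return state.K - policy.L1, state.K - policy.L2


def adaptive_policy_events(
    state: SimState,
    rates: tuple[float, float, float],
    policy: SwitchPolicy,
) -> dict[str, tuple[float, bool]]:
    """Crossing functions and direction-filter acceptance for the adaptive rule.

    Returns ``{"n2_reached_K": (n2 - K, accepted), "n1_reached_B": (n1 - B,
    accepted)}`` where acceptance applies the derivative conditions of the
    optimal rule: the n2 = K crossing counts only while the colony is still
    growing (dn2/dt > 0), and the n1 = B crossing only while the nomads are
    decaying (dn1/dt < 0).
    """
    if policy.mode != "adaptive":
        raise ValueError("adaptive_policy_events requires an adaptive policy")
    dn1, dn2, _ = rates
    B = policy.B if policy.B is not None else math.inf
    return {
        "n2_reached_K": (state.n2 - state.K, dn2 > 0),
        "n1_reached_B": (state.n1 - B, dn1 < 0),
    }


# ---------------------------------------------------------------------------
# integrator internals

def _make_rhs(params: ModelParams, s12: float, s21: float):
    r1, r2, A, Kmax = params.r1, params.r2, params.A, params.Kmax

    def f(t, y):
        n1 = y[0] if y[0] > 0.0 else 0.0
        n2 = y[1] if y[1] > 0.0 else 0.0
        K = y[2] if y[2] > EPS_K else EPS_K
        g1 = model._g1(n1, r1)
        g2 = model._g2(n2, K, r2, A)
        dK = model._dK(n2, K, Kmax)
        return (g1 + s12 * n2 - s21 * n1, g2 + s21 * n1 - s12 * n2, dK)

    return f


@dataclass
class _RuntimePolicy:
    """Mutable switching state carried across integration segments."""

    mode: str
    rs: float
    L1: float | None
    L2: float | None
    B: float | None
    s12_on: bool = False
    s21_on: bool = False
    stage: str = "colonial"  # colonial | to_nomadic | nomadic | to_colonial

    @property
    def label(self) -> str:
        if self.s12_on or self.s21_on or self.stage in ("to_nomadic", "to_colonial"):
            return "switching"
        return self.stage

    @property
    def s12(self) -> float:
        return self.rs if self.s12_on else 0.0

    @property
    def s21(self) -> float:
        return self.rs if self.s21_on else 0.0


def _init_runtime(params: ModelParams, policy: SwitchPolicy, init: SimState) -> _RuntimePolicy:
    rs = params.rs if policy.mode != "none" else 0.0
    st = _RuntimePolicy(
        mode=policy.mode, rs=rs, L1=policy.L1, L2=policy.L2,
        B=policy.resolve_B(params),
    )
    K = init.K
    st.s12_on = rs > 0 and st.L1 is not None and K < st.L1
    st.s21_on = rs > 0 and st.L2 is not None and K > st.L2
    if st.s12_on or st.s21_on:
        # entering mid-switch; the phase it resolves into depends on direction
        st.stage = "to_nomadic" if st.s12_on else "to_colonial"
    else:
        st.stage = "colonial" if init.n2 >= init.n1 else "nomadic"
    return st


def _segment_events(st: _RuntimePolicy):
    """Terminal event functions + names for the current policy state."""
    evs, names = [], []
    if st.rs > 0 and st.L1 is not None:
        def eL1(t, y, L=st.L1):
            return y[2] - L

        eL1.terminal = True
        eL1.direction = 1.0 if st.s12_on else -1.0
        evs.append(eL1)
        names.append("L1")
    if st.rs > 0 and st.L2 is not None and math.isfinite(st.L2):
        def eL2(t, y, L=st.L2):
            return y[2] - L

        eL2.terminal = True
        eL2.direction = -1.0 if st.s21_on else 1.0
        evs.append(eL2)
        names.append("L2")
    if st.mode == "adaptive" and st.rs > 0:
        if st.stage in ("colonial", "to_colonial"):
            def en2K(t, y):
                return y[1] - y[2]

            en2K.terminal = True
            en2K.direction = 1.0
            evs.append(en2K)
            names.append("n2K")
        if st.stage in ("to_nomadic", "nomadic") and st.B is not None:
            def en1B(t, y, B=st.B):
                return y[0] - B

            en1B.terminal = True
            en1B.direction = -1.0
            evs.append(en1B)
            names.append("n1B")
    return evs, names


def _apply_event(name: str, t: float, y, st: _RuntimePolicy,
                 params: ModelParams) -> str:
    """Mutate the runtime policy for a located event; return the event kind."""
    if name == "L1":
        st.s12_on = not st.s12_on
        if st.s12_on:
            st.stage = "to_nomadic"
        elif st.stage == "to_nomadic":
            st.stage = "nomadic"
        return K_L1_DOWN if st.s12_on else K_L1_UP
    if name == "L2":
        st.s21_on = not st.s21_on
        if st.s21_on:
            st.stage = "to_colonial"
        elif st.stage == "to_colonial":
            st.stage = "colonial"
        return K_L2_UP if st.s21_on else K_L2_DOWN
    if name == "n2K":
        # optimal exit: remember the capacity, forbid re-entry
        st.L1 = float(y[2])
        st.L2 = None
        st.s21_on = False
        st.s12_on = False  # K == L1 exactly; the down-crossing event re-arms it
        st.stage = "to_nomadic"
        return N2_K
    if name == "n1B":
        # optimal entry: open the door at the current capacity
        st.L2 = float(y[2])
        st.s21_on = False  # K == L2 exactly; rising K triggers the up-crossing
        st.stage = "to_colonial"
        return N1_B
    raise AssertionError(name)


def simulate(
    params: ModelParams,
    policy: SwitchPolicy,
    init: SimState,
    options: SimOptions,
) -> Trajectory:
    """Integrate the system under a switching policy with event location.

    The integration restarts at every located event so that discontinuous
    switching rates and adaptive threshold reassignments apply exactly at
    event times, never mid-step.
    """
    st = _init_runtime(params, policy, init)
    t, y = init.t, [init.n1, init.n2, init.K]
    t_end = init.t + options.t_end

    ts_parts: list[np.ndarray] = []
    ys_parts: list[np.ndarray] = []
    events: list[Event] = []
    phase_log: list[tuple[float, str]] = [(t, st.label)]

    ivp_kwargs = dict(method=options.method, rtol=options.rtol, atol=options.atol)
    if options.max_step is not None:
        ivp_kwargs["max_step"] = options.max_step

    n_seg = 0
    t_stop = t_end - 1e-12 * max(1.0, abs(t_end))
    while t < t_stop:
        n_seg += 1
        if n_seg > options.max_segments:
            raise SolverError(
                f"exceeded {options.max_segments} integration segments "
                "(possible event chattering)",
                SimState(t=t, n1=max(y[0], 0.0), n2=max(y[1], 0.0), K=y[2]),
            )
        f = _make_rhs(params, st.s12, st.s21)
        evs, names = _segment_events(st)
        t_eval = None
        if options.output_grid is not None:
            grid = np.asarray(options.output_grid, dtype=float)
            t_eval = grid[(grid >= t) & (grid <= t_end)]
        sol = solve_ivp(f, (t, t_end), y, events=evs, t_eval=t_eval, **ivp_kwargs)
        if sol.status == -1:
            raise SolverError(
                sol.message,
                SimState(t=t, n1=max(y[0], 0.0), n2=max(y[1], 0.0), K=y[2]),
            )
        if len(sol.t):
            ts_parts.append(sol.t)
            ys_parts.append(sol.y)
        if sol.status == 0:
            break
        # terminal event: earliest located zero wins; simultaneous events
        # (within 1e-10) are processed with policy reassignments first
        cand = [(te[0], i) for i, te in enumerate(sol.t_events) if len(te)]
        te_min = min(c[0] for c in cand)
        tie_tol = 1e-10 * max(1.0, abs(te_min))
        te, i = min(
            ((te_c, i_c) for te_c, i_c in cand if te_c <= te_min + tie_tol),
            key=lambda c: (names[c[1]] not in ("n2K", "n1B"), c[0]),
        )
        ye = sol.y_events[i][0]
        kind = _apply_event(names[i], te, ye, st, params)
        events.append(Event(time=float(te), kind=kind))
        phase_log.append((float(te), st.label))
        t, y = float(te), list(ye)
        if t_eval is not None:
            # keep the event point itself so phase boundaries stay sampled
            ts_parts.append(np.array([t]))
            ys_parts.append(np.array(y)[:, None])

    times = np.concatenate(ts_parts) if ts_parts else np.array([init.t])
    Y = np.concatenate(ys_parts, axis=1) if ys_parts else np.array([[init.n1], [init.n2], [init.K]])
    # de-duplicate any equal consecutive times left by event stitching
    keep = np.empty(len(times), dtype=bool)
    keep[0] = True
    np.greater(times[1:], times[:-1], out=keep[1:])
    times, Y = times[keep], Y[:, keep]

    phases = _phases_from_log(phase_log, float(times[-1]))
    return Trajectory(
        times=times,
        n1=np.maximum(Y[0], 0.0),
        n2=np.maximum(Y[1], 0.0),
        K=Y[2],
        events=events,
        phases=phases,
        policy_mode=policy.mode,
    )


def _phases_from_log(log: list[tuple[float, str]], t_end: float) -> list[Phase]:
    merged: list[tuple[float, str]] = []
    for t, lbl in log:
        if merged and merged[-1][1] == lbl:
            continue
        merged.append((t, lbl))
    phases = []
    for (t0, lbl), (t1, _) in zip(merged, merged[1:] + [(t_end, "")]):
        if t1 > t0:
            phases.append(Phase(start=t0, end=t1, label=lbl))
    if not phases:
        phases = [Phase(start=log[0][0], end=t_end, label=log[0][1])]
    return phases
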