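"""Trajectory post-processing: regime taxonomy, cycle peaks, growth checks.

The long-run behavior of a run falls into one of five regimes:

* without switching -- extinction of both sub-populations, or colonial
  survival (n2 and K settle at the long-term capacity 1);
* with switching -- extinction, survival through periodic alternation, or
  long-term growth (per-cycle peak capacity keeps increasing).

A "cycle" is anchored at colonial-entry events: K rising through L2 under
the fixed rule, or the n1 = B entry trigger under the adaptive rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import (
    COLONIAL_ENTRY_EVENTS,
    K_L2_UP,
    N1_B,
    SimOptions,
    SwitchPolicy,
    Trajectory,
)
from .model import ModelParams

__all__ = [
    "RegimeLabel",
    "PhasePeaks",
    "classify_regime",
    "phase_peaks",
    "detect_plateau",
    "check_growth_condition",
]

# relative per-cycle peak-K increase that counts as growth (well above the
# integration tolerance, well below the ~10%/cycle seen in growing runs)
GROWTH_EPS = 1e-3


class RegimeLabel:
    BOTH_EXTINCT = "both_extinct_no_switching"
    COLONIAL_SURVIVES = "colonial_survives_no_switching"
    EXTINCT_SWITCHING = "extinct_with_switching"
    PERIODIC_SURVIVAL = "periodic_survival"
    LONG_TERM_GROWTH = "long_term_growth"
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class PhasePeaks:
    """Per-cycle maxima between consecutive colonial-entry events."""

    cycle_index: int
    cycle_start: float
    cycle_end: float
    peak_n1: float
    peak_n2: float
    peak_K: float


def _entry_times(traj: Trajectory) -> list[float]:
    kinds = {e.kind for e in traj.events}
    anchor = N1_B if N1_B in kinds else K_L2_UP
    return [e.time for e in traj.events if e.kind == anchor]


def phase_peaks(traj: Trajectory) -> list[PhasePeaks]:
    """Per-cycle maxima of n1, n2 and K.

    One record per complete nomadic+colonial cycle, cycles delimited by
    consecutive colonial-entry events.  Empty if fewer than one complete
    cycle exists.
    """
    entries = _entry_times(traj)
    peaks: list[PhasePeaks] = []
    for idx, (a, b) in enumerate(zip(entries[:-1], entries[1:])):
        m = (traj.times >= a) & (traj.times <= b)
        if not m.any():
            continue
        peaks.append(
            PhasePeaks(
                cycle_index=idx,
                cycle_start=a,
                cycle_end=b,
                peak_n1=float(traj.n1[m].max()),
                peak_n2=float(traj.n2[m].max()),
                peak_K=float(traj.K[m].max()),
            )
        )
    return peaks


def detect_plateau(
    peaks: list[PhasePeaks], rel_change: float = 0.01
) -> float | None:
    """Onset time of the peak-capacity plateau.

    Returns the start time of the first cycle after which the per-cycle
    peak K changes by less than ``rel_change`` (relative) at every
    subsequent cycle; ``None`` if the peaks never settle (or fewer than two
    complete cycles exist).
    """
    if len(peaks) < 2:
        return None
    pk = np.array([p.peak_K for p in peaks])
    d = np.abs(np.diff(pk)) / pk[:-1]
    ok = d < rel_change
    # first index j with all changes from cycle j onward below threshold
    j = len(ok)
    while j > 0 and ok[j - 1]:
        j -= 1
    if j >= len(ok):
        return None
    return peaks[j].cycle_start


def check_growth_condition(traj: Trajectory, L1: float) -> list[bool]:
    """Per colonial phase: does n2 meet K at a level at least L1?

    Survival through alternation requires the colony to grow fast enough
    that it intersects the (falling) carrying capacity at or above the
    lower switching level before switching back begins.  Returns one
    boolean per colonial phase, True iff an intersection n2(t*) = K(t*)
    with value >= L1 occurs within the phase.
    """
    out = []
    for ph in traj.phases:
        if ph.label != "colonial":
            continue
        m = (traj.times >= ph.start) & (traj.times <= ph.end)
        if not m.any():
            out.append(False)
            continue
        gap = traj.n2[m] - traj.K[m]
        reached = np.flatnonzero(gap >= 0)
        if len(reached) == 0:
            out.append(False)
            continue
        i = reached[0]
        out.append(bool(traj.K[m][i] >= L1))
    return out


def classify_regime(
    traj: Trajectory,
    params: ModelParams,
    policy: SwitchPolicy,
    options: SimOptions,
) -> str:
    """Assign one of the five outcome regimes (or ``undetermined``).

    Classification is based on the end state relative to the extinction
    floor and, for switching runs, on the per-cycle peak capacities: a run
    whose last few cycles still show a relative peak-K increase above
    ``GROWTH_EPS`` per cycle counts as long-term growth.
    """
    floor = options.extinction_floor
    end = traj.final_state()
    switching = policy.mode != "none" and params.rs > 0

    if not switching:
        if end.n1 < floor and end.n2 < floor:
            return RegimeLabel.BOTH_EXTINCT
        if abs(end.n2 - 1.0) <= 0.01:
            return RegimeLabel.COLONIAL_SURVIVES
        return RegimeLabel.UNDETERMINED

    if end.total < floor:
        return RegimeLabel.EXTINCT_SWITCHING
    peaks = phase_peaks(traj)
    pk = [p.peak_K for p in peaks]
    # the trailing partial cycle counts toward growth detection: its running
    # peak can only underestimate the completed-cycle peak
    entries = _entry_times(traj)
    if entries and entries[-1] < traj.times[-1]:
        m = traj.times >= entries[-1]
        pk.append(float(traj.K[m].max()))
    if len(pk) >= 3:
        # growth = peak K still rising across the last three cycles
        tail = np.array(pk[-3:])
        rel = np.diff(tail) / tail[:-1]
        if np.all(rel > GROWTH_EPS):
            return RegimeLabel.LONG_TERM_GROWTH
    if peaks or any(e.kind in COLONIAL_ENTRY_EVENTS for e in traj.events):
        return RegimeLabel.PERIODIC_SURVIVAL
    return RegimeLabel.UNDETERMINED
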