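"""Analytic survival theory for the nomadic-colonial model.

For an Allee capacity ``A > 1`` the colony is doomed on its own, and
persistence through alternation hinges on three closed-form quantities, all
expressible through the principal branch of the Lambert W function:

* the critical nomadic level ``B`` -- the minimum nomadic population at the
  end of a nomadic phase that lets the next colony overcome the Allee
  effect.  ``A`` and ``B`` are linked by

      A = B - (1 - B) * W0( B/(1-B) * exp(B/(1-B)) ),

  which this module evaluates forward (``allee_from_critical``) and inverts
  by bracketed root finding (``critical_from_allee``);

* a strict lower bound on the lower switching level,
  ``L1 > B e^B / (e^B - 1)``;

* a strict upper bound on the upper switching level given ``L1``,
  ``L2 < L1 + (1/r1) ln[ (L1 + W0(-L1 e^{-L1})) / B ]``.

These relations are derived in the fast-switching limit (rs much larger
than r1 and r2).  ``corrected_critical_level`` adds the first-order
finite-rate correction needed when an adaptive policy cuts the entry margin
to zero; see docs/methods.md.

A subtlety worth knowing: the forward map A(B) is increasing but saturates
strictly below 2 (A -> 2 - (2/3)/(B-1) as B grows), so the inverse exists
only for A in (1, 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq
from scipy.special import lambertw

from .model import ModelParams

__all__ = [
    "lambert_w0",
    "allee_from_critical",
    "critical_from_allee",
    "l1_lower_bound",
    "l2_upper_bound",
    "colonial_outcome",
    "corrected_critical_level",
    "TheoryBounds",
    "survival_bounds",
]

_INV_E = math.exp(-1.0)


def lambert_w0(x: float) -> float:
    """Principal branch of the Lambert W function (real, w >= -1).

    Delegates to :func:`scipy.special.lambertw`; defined for x >= -1/e.
    """
    if x < -_INV_E - 1e-15:
        raise ValueError(f"lambert_w0 requires x >= -1/e, got {x}")
    w = float(lambertw(max(x, -_INV_E), 0).real)
    return w


def allee_from_critical(B: float) -> float:
    """Allee capacity A as a function of the critical nomadic level B > 1.

    Satisfies 1 < A <= B, A -> 1 as B -> 1+, and A < 2 for every finite B.
    """
    if B <= 1.0:
        raise ValueError(f"the survival relation requires B > 1, got {B}")
    if B >= 1e4:
        # near the Lambert branch point the direct evaluation loses ~sqrt(eps)
        # precision, amplified by (B-1); use the asymptotic series instead:
        # A = 2 - (2/3)v + (4/9)v^2 + O(v^3),  v = 1/(B-1)
        v = 1.0 / (B - 1.0)
        return 2.0 - (2.0 / 3.0) * v + (4.0 / 9.0) * v * v
    x = B / (1.0 - B)  # < -1 for B > 1
    # x*exp(x) underflows to -0.0 for B very close to 1; W0(-0.0) = 0.
    return B - (1.0 - B) * lambert_w0(x * math.exp(x))


def critical_from_allee(A: float, tol: float = 1e-10) -> float:
    """Critical nomadic level B solving allee_from_critical(B) = A.

    Defined for Allee capacities A in (1, 2): the forward map saturates
    strictly below 2, so no finite B exists for A >= 2.  Inverted by
    bracketed root search (the map is monotone increasing).
    """
    if A <= 1.0:
        raise ValueError(
            f"survival analysis applies only to A > 1, got {A}"
        )
    if A >= 2.0 or allee_from_critical(1e9) <= A:
        raise ValueError(
            f"no critical level exists for A={A}: the Allee-critical relation "
            "saturates below 2 as B grows, so it is invertible only on (1, 2)"
        )
    lo = 1.0 + 1e-13
    hi = max(2.0, A * 2.0)
    while allee_from_critical(hi) < A:
        hi = 1.0 + (hi - 1.0) * 4.0
    return float(brentq(lambda b: allee_from_critical(b) - A, lo, hi,
                        xtol=tol, rtol=4 * 2.3e-16))


def l1_lower_bound(B: float) -> float:
    """Strict lower bound ``B e^B / (e^B - 1)`` on the lower switching level.

    Any fixed-threshold policy that guarantees survival must place L1
    strictly above this value (which itself exceeds B).
    """
    if B <= 1.0:
        raise ValueError(f"requires B > 1, got {B}")
    eB = math.exp(B)
    return B * eB / (eB - 1.0)


def l2_upper_bound(L1: float, B: float, r1: float) -> float | None:
    """Strict upper bound on the upper switching level L2 given L1.

    ``L1 + (1/r1) * ln[(L1 + W0(-L1 e^{-L1})) / B]``.  Survival by periodic
    alternation requires L2 strictly below this value.  Returns ``None``
    when the logarithm argument is non-positive, i.e. when L1 is at or
    below its own lower bound and no admissible L2 exists.
    """
    if B <= 1.0:
        raise ValueError(f"requires B > 1, got {B}")
    if r1 <= 0:
        raise ValueError(f"requires r1 > 0, got {r1}")
    if L1 <= 0:
        raise ValueError(f"requires L1 > 0, got {L1}")
    if L1 <= 1.0:
        # principal-branch W of -L1*e^{-L1} is exactly -L1 here: ln argument 0
        return None
    arg = (L1 + lambert_w0(-L1 * math.exp(-L1))) / B
    if arg <= 0:
        return None
    return L1 + math.log(arg) / r1


def colonial_outcome(A: float) -> str:
    """Long-run fate of a pure colony: extinction iff A > 1.

    Returns ``"extinction_guaranteed"`` (A > 1) or ``"survival_possible"``
    (A < 1).  The boundary A = 1 is not covered by the theory.
    """
    if A <= 0:
        raise ValueError(f"A must be positive, got {A}")
    if A == 1.0:
        raise ValueError("A = 1 is the undetermined boundary case")
    return "extinction_guaranteed" if A > 1.0 else "survival_possible"


def corrected_critical_level(params: ModelParams) -> float:
    """Critical entry level with the first-order finite-switching correction.

    The Lambert-W critical level ``B_c`` is exact only in the limit of
    instantaneous switching.  At a finite switching constant rs, the
    nomad->colonist conversion takes a time of order 1/rs during which the
    arriving colony sits below the Allee level and loses

        (r1 * B_c  +  (r2/2) * B_c**2) / rs

    of its size (nomadic decay of the yet-unswitched organisms plus the
    integrated Allee deficit over the conversion ramp).  An adaptive policy
    that triggers colonial entry exactly at ``B_c`` therefore arrives just
    below A and dies; triggering at ``B_c`` plus the loss restores the
    idealized rule's behavior.
    """
    if params.rs <= 0:
        raise ValueError("the correction requires a positive switching constant")
    Bc = critical_from_allee(params.A)
    loss = (params.r1 * Bc + 0.5 * params.r2 * Bc * Bc) / params.rs
    return Bc + loss


@dataclass(frozen=True)
class TheoryBounds:
    """Derived survival quantities for one parameter set."""

    A: float
    B: float
    L1_min: float
    L1: float | None = None
    L2_max: float | None = None


def survival_bounds(
    A: float, L1: float | None = None, r1: float | None = None
) -> TheoryBounds:
    """Compute B, the L1 lower bound, and (optionally) the L2 upper bound."""
    B = critical_from_allee(A)
    L1_min = l1_lower_bound(B)
    L2_max = None
    if L1 is not None:
        if r1 is None:
            raise ValueError("r1 is required to evaluate the L2 bound")
        L2_max = l2_upper_bound(L1, B, r1)
    return TheoryBounds(A=A, B=B, L1_min=L1_min, L1=L1, L2_max=L2_max)
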