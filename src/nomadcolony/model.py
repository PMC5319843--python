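"""Core population model: parameters, state, and growth-rate functions.

The model tracks two behaviorally distinct sub-populations sharing a common
gene pool -- nomads ``n1``, who live independently and decay exponentially,
and colonists ``n2``, who grow logistically with an Allee effect inside a
habitat whose carrying capacity ``K`` is itself dynamic: colonists destroy
it, and it regenerates when they are few.  All quantities are expressed in
reduced units in which the habitat regeneration rate and the per-colonist
destruction rate are both 1, so the long-term carrying capacity (the
colonist level at which destruction and regeneration balance) is exactly 1.

The functions here are pure and operate on scalars; the time integration
with switching events lives in :mod:`nomadcolony.engine`.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "EPS_K",
    "ModelParams",
    "SimState",
    "nomadic_growth",
    "colonial_growth",
    "capacity_rate",
    "switching_rates",
    "rhs",
]

#: Floor applied to K in the 1/K terms.  The colonial growth law is singular
#: at K = 0; the habitat-recovery law can in principle push K to 0 under a
#: large sustained colony, so the rate functions must be defined there.
EPS_K = 1e-9


@dataclass(frozen=True)
class ModelParams:
    """Rate constants of the nomadic-colonial system (reduced units).

    Parameters
    ----------
    r1 : float
        Nomadic decay constant (> 0).  Nomads decay as ``dn1/dt = -r1*n1``,
        making pure nomadism a losing strategy.
    r2 : float
        Colonial growth constant (> 0).
    rs : float
        Behavioral switching constant (>= 0).  ``rs = 0`` disables switching.
    A : float
        Allee critical capacity (> 0): colonial growth is negative below
        ``n2 = A`` (cooperation is required to persist).
    Kmax : float or None
        Optional cap on the carrying capacity.  ``None`` means unbounded
        habitat recovery, ``dK/dt = 1 - n2``; a finite value switches to
        ``dK/dt = (1 - n2)(1 - K/Kmax)``.
    """

    r1: float
    r2: float
    rs: float = 0.0
    A: float = 1.001
    Kmax: float | None = None

    def __post_init__(self) -> None:
        if not self.r1 > 0:
            raise ValueError(f"r1 must be > 0, got {self.r1}")
        if not self.r2 > 0:
            raise ValueError(f"r2 must be > 0, got {self.r2}")
        if not self.rs >= 0:
            raise ValueError(f"rs must be >= 0, got {self.rs}")
        if not self.A > 0:
            raise ValueError(f"A must be > 0, got {self.A}")
        if self.Kmax is not None and not self.Kmax > 0:
            raise ValueError(f"Kmax must be > 0 or None, got {self.Kmax}")

    @property
    def bounded(self) -> bool:
        return self.Kmax is not None


@dataclass(frozen=True)
class SimState:
    """Instantaneous state ``(t, n1, n2, K)`` of the system."""

    t: float
    n1: float
    n2: float
    K: float

    def __post_init__(self) -> None:
        if self.n1 < 0 or self.n2 < 0:
            raise ValueError(
                f"populations must be non-negative, got n1={self.n1}, n2={self.n2}"
            )

    @property
    def total(self) -> float:
        return self.n1 + self.n2


# ---------------------------------------------------------------------------
# unchecked scalar kernels (used in the integrator's hot loop; inputs are
# clamped by the caller, see engine.make_rhs)

def _g1(n1: float, r1: float) -> float:
    return -r1 * n1


def _g2(n2: float, K: float, r2: float, A: float) -> float:
    mAK = A if A < K else K
    return r2 * n2 * (n2 / mAK - 1.0) * (1.0 - n2 / K)


def _dK(n2: float, K: float, Kmax: float | None) -> float:
    rate = 1.0 - n2
    if Kmax is not None:
        rate *= 1.0 - K / Kmax
    return rate


# ---------------------------------------------------------------------------
# public, validated operations

def nomadic_growth(n1: float, params: ModelParams) -> float:
    """Nomadic growth rate ``-r1*n1`` (always <= 0 for n1 >= 0)."""
    if n1 < 0:
        raise ValueError(f"n1 must be non-negative, got {n1}")
    return _g1(n1, params.r1)


def colonial_growth(n2: float, K: float, params: ModelParams) -> float:
    """Allee-logistic colonial growth rate.

    ``r2 * n2 * (n2/min(A, K) - 1) * (1 - n2/K)`` -- positive exactly when
    ``A < n2 < K`` (for ``K > A``); never positive once the capacity has
    fallen to or below the Allee level, because ``min(A, K)`` then equals K.
    """
    if n2 < 0:
        raise ValueError(f"n2 must be non-negative, got {n2}")
    if K <= 0:
        raise ValueError(f"K must be positive, got {K}")
    return _g2(n2, K, params.r2, params.A)


def capacity_rate(n2: float, K: float, params: ModelParams) -> float:
    """Rate of change of the carrying capacity.

    Unbounded habitat: ``1 - n2`` (recovery below the long-term capacity
    n* = 1, destruction above).  Bounded habitat (finite ``Kmax``):
    ``(1 - n2)(1 - K/Kmax)``.
    """
    if n2 < 0:
        raise ValueError(f"n2 must be non-negative, got {n2}")
    return _dK(n2, K, params.Kmax)


def switching_rates(
    K: float, L1: float | None, L2: float | None, params: ModelParams
) -> tuple[float, float]:
    """Threshold switching rates ``(s12, s21)`` at capacity ``K``.

    ``s12`` (colonist -> nomad) equals ``rs`` iff ``K < L1``; ``s21``
    (nomad -> colonist) equals ``rs`` iff ``K > L2``.  A ``None`` threshold
    disables the corresponding direction.  Equality with a threshold falls
    in the "otherwise" branch (rate 0).
    """
    if L1 is not None and L2 is not None and L1 > L2:
        raise ValueError(f"switching levels must satisfy L1 <= L2, got {L1} > {L2}")
    s12 = params.rs if (L1 is not None and K < L1) else 0.0
    s21 = params.rs if (L2 is not None and K > L2) else 0.0
    return s12, s21


def rhs(
    state: SimState,
    params: ModelParams,
    L1: float | None = None,
    L2: float | None = None,
) -> tuple[float, float, float]:
    """Full right-hand side ``(dn1/dt, dn2/dt, dK/dt)`` at a state.

    Switching moves organisms between the sub-populations without birth or
    death: the switching contributions to ``dn1`` and ``dn2`` cancel exactly.
    """
    K = max(state.K, EPS_K)
    s12, s21 = switching_rates(K, L1, L2, params)
    g1 = nomadic_growth(state.n1, params)
    g2 = colonial_growth(state.n2, K, params)
    dn1 = g1 + s12 * state.n2 - s21 * state.n1
    dn2 = g2 + s21 * state.n1 - s12 * state.n2
    return dn1, dn2, _dK(state.n2, K, params.Kmax)
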