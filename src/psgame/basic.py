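"""Single-phenotype producer-scrounger game.

Mean-field model of a foraging group of ``G`` predators in which a
proportion ``q`` scrounge (steal prey held by group-mates) while the rest
produce (hunt).  The state variables are the *average number of prey in the
mouth* of a producer, P, and of a scrounger, S.  Prey arrive to each
producer at capture rate ``lam`` (prey/h), every held prey is consumed or
escapes at combined rate ``gamma`` (1/h, so 1/gamma is the mean handling
time), and each scrounger steals from a given group member at rate
``alpha`` per prey currently held (per scrounger per hour).

There is no finder's share: prey are swallowed whole, so a successful
theft transfers the entire item.  Scrounger-on-scrounger theft within the
single phenotype does not alter the class average and is absent from the
equations.

The fast prey dynamics (P, S) equilibrate for a given ``q``; behavioural
change in ``q`` happens on a slower timescale tau and follows a logistic
imitation rule, ``dq/dtau = (S*(q) - P*(q)) q (1 - q)``.  Its stable rest
point is the Nash equilibrium of the game:

    q* = max(0, 1 - gamma / (alpha G)),

interior whenever the group is large enough for scrounging to invade
(``G > gamma / alpha``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "BasicParams",
    "PayoffPair",
    "prey_dynamics_rhs",
    "payoff_equilibrium",
    "behavior_rhs",
    "nash_q",
    "can_invade",
    "integrate_behavior",
]


@dataclass(frozen=True)
class BasicParams:
    """Parameters of the single-phenotype game (baseline: field estimates).

    lam : prey captured per producer per hour.
    alpha : successful thefts per scrounger per hour per prey held by the
        target.
    gamma : combined consumption + escape rate per hour.
    G : group size; accepted as a positive real so that mean-field sweeps
        may use non-integer grids (the stochastic counterpart requires an
        integer).
    """

    lam: float = 0.6
    alpha: float = 0.40
    gamma: float = 1.2
    G: float = 15.0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.G <= 0:
            raise ValueError(f"G must be > 0, got {self.G}")


@dataclass(frozen=True)
class PayoffPair:
    """Mean prey in the mouth of a producer / scrounger."""

    producer: float
    scrounger: float


def _check_q(q: float) -> None:
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must lie in [0, 1], got {q}")


def prey_dynamics_rhs(
    params: BasicParams, q: float, state: PayoffPair
) -> tuple[float, float]:
    """Time derivatives (dP/dt, dS/dt) of the fast prey-holding dynamics.

    dP/dt = lam - alpha q G P - gamma P
    dS/dt = alpha (1 - q) G P - gamma S

    The theft rate per producer is alpha*qG (the qG scroungers each steal at
    alpha per prey held) while the per-scrounger gain is alpha*(1-q)G*P
    because the class averages are over different head counts.
    """
    _check_q(q)
    P, S = state.producer, state.scrounger
    dP = params.lam - params.alpha * q * params.G * P - params.gamma * P
    dS = params.alpha * (1.0 - q) * params.G * P - params.gamma * S
    return dP, dS


def payoff_equilibrium(params: BasicParams, q: float) -> PayoffPair:
    """Equilibrium payoffs P*(q), S*(q) of the prey dynamics at fixed q.

    P*(q) = lam / (gamma + alpha q G)
    S*(q) = (1 - q) G alpha lam / (gamma (gamma + alpha q G))
    """
    _check_q(q)
    denom = params.gamma + params.alpha * q * params.G
    P = params.lam / denom
    S = (1.0 - q) * params.G * params.alpha * params.lam / (params.gamma * denom)
    return PayoffPair(producer=P, scrounger=S)


def behavior_rhs(params: BasicParams, q: float) -> float:
    """Rate of change of the scrounger proportion, dq/dtau.

    Logistic imitation dynamics (S*(q) - P*(q)) q (1 - q) with the
    proportionality constant fixed at one: tau is an arbitrary slow
    timescale and only rest points and their stability matter.
    """
    pay = payoff_equilibrium(params, q)
    return (pay.scrounger - pay.producer) * q * (1.0 - q)


def nash_q(params: BasicParams) -> float:
    """Nash-equilibrium scrounger proportion, clamped to [0, 1).

    The interior solution of P*(q) = S*(q) is q* = 1 - gamma/(alpha G).
    When alpha*G <= gamma that expression is non-positive and the
    pure-producer state q=0 is the Nash outcome (a lone scrounger would
    earn S*(0) <= P*(0)), so 0 is returned rather than an error.
    """
    ag = params.alpha * params.G
    if ag <= 0.0:
        return 0.0
    q = 1.0 - params.gamma / ag
    # alpha*G == gamma up to roundoff is the no-invasion boundary
    return 0.0 if q < 1e-12 else q


def can_invade(params: BasicParams) -> bool:
    """Whether scrounging can invade a group of producers (q* > 0).

    True iff G > gamma / alpha (strict); with alpha = 0 scrounging never
    pays and the result is False.
    """
    if params.alpha <= 0.0:
        return False
    # strict inequality with a roundoff guard: alpha*G == gamma means a
    # lone scrounger earns exactly the producer payoff and cannot invade
    return params.alpha * params.G > params.gamma * (1.0 + 1e-12)


def integrate_behavior(
    params: BasicParams,
    q0: float = 0.5,
    horizon: float = 5000.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-integrate dq/dtau from ``q0``; returns (tau, q) arrays.

    Terminates early once |dq/dtau| falls below 1e-13 (rest point reached
    to solver precision).  [0, 1] is forward-invariant; the returned q is
    clipped to correct roundoff only.
    """
    _check_q(q0)

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        return [behavior_rhs(params, min(max(y[0], 0.0), 1.0))]

    def settled(_t: float, y: np.ndarray) -> float:
        return abs(rhs(_t, y)[0]) - 1e-13

    settled.terminal = True  # type: ignore[attr-defined]
    settled.direction = -1  # type: ignore[attr-defined]

    sol = solve_ivp(
        rhs, (0.0, horizon), [q0], rtol=rtol, atol=atol, events=settled,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"behaviour integration failed: {sol.message}")
    return sol.t, np.clip(sol.y[0], 0.0, 1.0)
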