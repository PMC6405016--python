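"""Two-phenotype (size-structured) producer-scrounger game.

Extends the single-phenotype game to a group containing two body-size
classes — small (subscript 1) and large (subscript 2) — whose ability to
steal, and susceptibility to theft, differ.  A proportion ``theta`` of the
``G`` group members is small.  A proportion ``q1`` of the small class and
``q2`` of the large class scrounge.  Theft is governed by a 2x2 rate table
``alpha[i][j]``: successful thefts per scrounger of size *i* per hour per
prey held by a target of size *j*.  Consumption-or-escape rates ``gamma1``,
``gamma2`` are size specific (large predators handle prey faster, so
``gamma2 > gamma1`` at the field baseline).

Class head counts at strategy profile (q1, q2):

    n1p = (1-q1) theta G      small producers
    n1s = q1 theta G          small scroungers
    n2p = (1-q2)(1-theta) G   large producers
    n2s = q2 (1-theta) G      large scroungers

Per-capita prey-holding dynamics (P_i producers, S_i scroungers):

    dP1/dt = lam1 - (a11 n1s + a21 n2s) P1 - gamma1 P1
    dP2/dt = lam2 - (a12 n1s + a22 n2s) P2 - gamma2 P2
    dS1/dt = a11 n1p P1 + a12 n2p P2 + [a12 n2s S2 - a21 n2s S1] - gamma1 S1
    dS2/dt = a21 n1p P1 + a22 n2p P2 + [a21 n1s S1 - a12 n1s S2] - gamma2 S2

Same-class scrounger-on-scrounger theft cancels in the class average and
never appears.  The bracketed *cross-phenotype* scrounger-on-scrounger
transfers do change the class averages; they are included by default and
can be switched off with ``scrounger_theft=False``.  Either way the theft
terms cancel exactly in the group aggregate, so total prey is conserved by
theft.

The behavioural dynamics are matching logistic equations driven by the
steady-state payoffs:

    dq1/dtau = (S1* - P1*) q1 (1 - q1)
    dq2/dtau = (S2* - P2*) q2 (1 - q2)

Scenario presets (field-motivated stealing-rate tables):

    A - stealing independent of size: all alpha_ij = 0.36
    B - large steal more, indiscriminately: 0.36 / 0.12 / 0.60 / 0.36
    C - large steal only from small:        0.36 / 0.12 / 0.60 / 0.00
        (order a11 / a12 / a21 / a22)
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .basic import PayoffPair  # noqa: F401  (re-export convenience)

__all__ = [
    "AsymmetricParams",
    "StrategyPair",
    "PayoffQuad",
    "SCENARIOS",
    "class_counts",
    "asym_dynamics_rhs",
    "steady_payoffs",
    "steady_payoffs_from_counts",
    "asym_behavior_rhs",
    "group_average_payoff",
    "composite_scrounger_fraction",
]

#: Stealing-rate tables (alpha11, alpha12, alpha21, alpha22) per scenario.
SCENARIOS: dict[str, tuple[float, float, float, float]] = {
    "A": (0.36, 0.36, 0.36, 0.36),
    "B": (0.36, 0.12, 0.60, 0.36),
    "C": (0.36, 0.12, 0.60, 0.00),
}


@dataclass(frozen=True)
class AsymmetricParams:
    """Parameters of the size-structured game (defaults: field baseline)."""

    lam1: float = 0.6
    lam2: float = 0.6
    alpha11: float = 0.36
    alpha12: float = 0.36
    alpha21: float = 0.36
    alpha22: float = 0.36
    gamma1: float = 1.002
    gamma2: float = 1.914
    theta: float = 0.5
    G: float = 15.0
    scrounger_theft: bool = True

    def __post_init__(self) -> None:
        for name in ("lam1", "lam2", "alpha11", "alpha12", "alpha21", "alpha22"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.gamma1 <= 0 or self.gamma2 <= 0:
            raise ValueError("gamma1 and gamma2 must be > 0")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta must lie in [0, 1], got {self.theta}")
        if self.G <= 0:
            raise ValueError(f"G must be > 0, got {self.G}")

    @classmethod
    def scenario(cls, name: str, **overrides: object) -> "AsymmetricParams":
        """Baseline parameters with the stealing table of scenario A, B or C."""
        key = name.upper()
        if key not in SCENARIOS:
            raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
        a11, a12, a21, a22 = SCENARIOS[key]
        return cls(alpha11=a11, alpha12=a12, alpha21=a21, alpha22=a22, **overrides)  # type: ignore[arg-type]

    def with_(self, **changes: object) -> "AsymmetricParams":
        return replace(self, **changes)  # type: ignore[arg-type]


@dataclass(frozen=True)
class StrategyPair:
    """Scrounging proportions (q1 small, q2 large)."""

    q1: float
    q2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.q1 <= 1.0 and 0.0 <= self.q2 <= 1.0):
            raise ValueError(f"q1, q2 must lie in [0, 1], got ({self.q1}, {self.q2})")


@dataclass(frozen=True)
class PayoffQuad:
    """Mean prey in mouth: small/large producers and small/large scroungers."""

    P1: float
    P2: float
    S1: float
    S2: float


def class_counts(
    params: AsymmetricParams, s: StrategyPair
) -> tuple[float, float, float, float]:
    """Head counts (n1p, n1s, n2p, n2s); continuous reals summing to G."""
    n1 = params.theta * params.G
    n2 = (1.0 - params.theta) * params.G
    return (1.0 - s.q1) * n1, s.q1 * n1, (1.0 - s.q2) * n2, s.q2 * n2


def _rhs_from_counts(
    p: AsymmetricParams,
    n1p: float,
    n1s: float,
    n2p: float,
    n2s: float,
    state: PayoffQuad,
) -> tuple[float, float, float, float]:
    P1, P2, S1, S2 = state.P1, state.P2, state.S1, state.S2
    dP1 = p.lam1 - (p.alpha11 * n1s + p.alpha21 * n2s) * P1 - p.gamma1 * P1
    dP2 = p.lam2 - (p.alpha12 * n1s + p.alpha22 * n2s) * P2 - p.gamma2 * P2
    dS1 = p.alpha11 * n1p * P1 + p.alpha12 * n2p * P2 - p.gamma1 * S1
    dS2 = p.alpha21 * n1p * P1 + p.alpha22 * n2p * P2 - p.gamma2 * S2
    if p.scrounger_theft:
        dS1 += p.alpha12 * n2s * S2 - p.alpha21 * n2s * S1
        dS2 += p.alpha21 * n1s * S1 - p.alpha12 * n1s * S2
    return dP1, dP2, dS1, dS2


def asym_dynamics_rhs(
    params: AsymmetricParams, s: StrategyPair, state: PayoffQuad
) -> tuple[float, float, float, float]:
    """Time derivatives (dP1, dP2, dS1, dS2)/dt of the prey-holding dynamics."""
    n1p, n1s, n2p, n2s = class_counts(params, s)
    return _rhs_from_counts(params, n1p, n1s, n2p, n2s, state)


def steady_payoffs_from_counts(
    p: AsymmetricParams, n1p: float, n1s: float, n2p: float, n2s: float
) -> PayoffQuad:
    """Steady-state payoffs at explicit class head counts.

    Producer payoffs are closed-form; scrounger payoffs solve the 2x2
    linear system from dS/dt = 0 (Cramer's rule — this sits inside tight
    sweep loops).
    """
    P1 = p.lam1 / (p.gamma1 + p.alpha11 * n1s + p.alpha21 * n2s)
    P2 = p.lam2 / (p.gamma2 + p.alpha12 * n1s + p.alpha22 * n2s)
    b1 = p.alpha11 * n1p * P1 + p.alpha12 * n2p * P2
    b2 = p.alpha21 * n1p * P1 + p.alpha22 * n2p * P2
    if p.scrounger_theft:
        a11 = p.gamma1 + p.alpha21 * n2s
        a12 = -p.alpha12 * n2s
        a21 = -p.alpha21 * n1s
        a22 = p.gamma2 + p.alpha12 * n1s
    else:
        a11, a12, a21, a22 = p.gamma1, 0.0, 0.0, p.gamma2
    det = a11 * a22 - a12 * a21
    if det == 0.0:
        raise ZeroDivisionError("singular scrounger-payoff system (gamma = 0?)")
    S1 = (b1 * a22 - a12 * b2) / det
    S2 = (a11 * b2 - a21 * b1) / det
    return PayoffQuad(P1=P1, P2=P2, S1=S1, S2=S2)


def steady_payoffs(params: AsymmetricParams, s: StrategyPair) -> PayoffQuad:
    """Equilibrium payoffs P1*, P2*, S1*, S2* at strategy profile (q1, q2)."""
    n1p, n1s, n2p, n2s = class_counts(params, s)
    return steady_payoffs_from_counts(params, n1p, n1s, n2p, n2s)


def asym_behavior_rhs(
    params: AsymmetricParams, s: StrategyPair
) -> tuple[float, float]:
    """(dq1/dtau, dq2/dtau): logistic imitation dynamics of both classes."""
    pay = steady_payoffs(params, s)
    d1 = (pay.S1 - pay.P1) * s.q1 * (1.0 - s.q1)
    d2 = (pay.S2 - pay.P2) * s.q2 * (1.0 - s.q2)
    return d1, d2


def group_average_payoff(params: AsymmetricParams, s: StrategyPair) -> float:
    """Mean prey per predator: payoffs weighted by class/strategy shares."""
    pay = steady_payoffs(params, s)
    th = params.theta
    return th * ((1.0 - s.q1) * pay.P1 + s.q1 * pay.S1) + (1.0 - th) * (
        (1.0 - s.q2) * pay.P2 + s.q2 * pay.S2
    )


def composite_scrounger_fraction(s: StrategyPair, theta: float) -> float:
    """Group-wide scrounging frequency theta*q1 + (1-theta)*q2."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must lie in [0, 1], got {theta}")
    return theta * s.q1 + (1.0 - theta) * s.q2
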