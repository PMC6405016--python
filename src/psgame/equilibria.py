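"""Phase-plane analysis of the two-class behavioural dynamics.

The strategy square [0,1]^2 is forward-invariant for the logistic
behavioural dynamics (both boundary factors vanish on the edges).  Rest
points come in three flavours:

* the four corners (always rest points);
* edge points with one coordinate pinned at 0 or 1 and the other solving
  its payoff-equality S_i* = P_i*;
* interior intersections of the two payoff-equality nullclines.

Dynamical stability is read from the eigenvalues of a numerically
differentiated Jacobian.  A *Nash* equilibrium must be dynamically stable
and, at boundary coordinates, pass the unilateral-deviation test (at
q_i = 0 a lone scrounger of class i must not profit, S_i* <= P_i*; at
q_i = 1 a lone producer must not profit, S_i* >= P_i*).  Stable boundary
rest points that fail the deviation test can occur only degenerately;
conversely the basic model's q=1 corner is dynamically reachable but never
Nash because S*(1) = 0 < P*(1).

When several stable equilibria coexist (the scenario-C gamma sweep has a
genuine bistable band), the reported Nash is the one reached by forward
integration from the group-centroid start (0.5, 0.5), mirroring the
flow-field confirmation used to produce the published phase planes; all
stable equilibria remain available.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .asymmetric import (
    AsymmetricParams,
    PayoffQuad,
    StrategyPair,
    composite_scrounger_fraction,
    group_average_payoff,
    steady_payoffs,
    steady_payoffs_from_counts,
)

__all__ = [
    "EquilibriumRecord",
    "Nullclines",
    "nullclines",
    "find_equilibria",
    "classify_stability",
    "nash_equilibrium",
    "integrate_behavior",
    "sweep_group_size",
    "sweep_gamma",
    "sweep_theta",
    "q1_extinction_threshold",
]

RESIDUAL_TOL = 1e-8  # |dq/dtau| below which a point counts as a rest point
MERGE_TOL = 1e-8  # duplicate-equilibrium merge radius
JAC_STEP = 1e-6  # central-difference step for the Jacobian
EIG_ZERO_BAND = 1e-7  # |Re(eig)| below this -> boundary-degenerate
BOUNDARY_SNAP = 1e-9  # coordinates this close to 0/1 are treated as boundary


@dataclass(frozen=True)
class EquilibriumRecord:
    """A rest point of the behavioural dynamics with its classification."""

    q1: float
    q2: float
    stability: str  # stable | unstable | saddle | boundary-degenerate
    is_nash: bool
    payoffs: PayoffQuad
    composite: float
    residual: float


@dataclass(frozen=True)
class Nullclines:
    """Point sets where dq1/dtau = 0 and dq2/dtau = 0 on [0,1]^2.

    Each array has rows (q1, q2) and includes the trivial boundary lines
    (q1 in {0,1} for the q1-nullcline, q2 in {0,1} for the q2-nullcline)
    sampled at the requested resolution, plus the interior payoff-equality
    locus.
    """

    q1_nullcline: np.ndarray
    q2_nullcline: np.ndarray


def _payoffs_raw(params: AsymmetricParams, q1: float, q2: float) -> PayoffQuad:
    # Raw evaluation without StrategyPair bounds checks: root solvers, the
    # Jacobian differencing and the ODE solver all step marginally outside
    # [0,1].
    n1 = params.theta * params.G
    n2 = (1.0 - params.theta) * params.G
    return steady_payoffs_from_counts(
        params, (1.0 - q1) * n1, q1 * n1, (1.0 - q2) * n2, q2 * n2
    )


def _payoff_gap(params: AsymmetricParams, q1: float, q2: float, i: int) -> float:
    """S_i* - P_i* at (q1, q2); the sign drives class i's dynamics."""
    pay = _payoffs_raw(params, q1, q2)
    return (pay.S1 - pay.P1) if i == 1 else (pay.S2 - pay.P2)


def _rhs(params: AsymmetricParams, q1: float, q2: float) -> tuple[float, float]:
    pay = _payoffs_raw(params, q1, q2)
    return (pay.S1 - pay.P1) * q1 * (1.0 - q1), (pay.S2 - pay.P2) * q2 * (1.0 - q2)


def _scan_roots(f, grid: np.ndarray) -> list[float]:
    """Roots of a scalar function on the open interval spanned by ``grid``."""
    vals = np.array([f(x) for x in grid])
    roots: list[float] = []
    for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if fa == 0.0 and a not in roots:
            roots.append(float(a))
        if np.isfinite(fa) and np.isfinite(fb) and fa * fb < 0.0:
            roots.append(float(brentq(f, a, b, xtol=1e-13, rtol=8.9e-16)))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    return roots


def nullclines(params: AsymmetricParams, resolution: float = 0.01) -> Nullclines:
    """Nullcline point sets of both behavioural equations."""
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    grid = np.arange(0.0, 1.0 + resolution / 2, resolution)
    grid[-1] = 1.0

    def build(i: int) -> np.ndarray:
        pts: list[tuple[float, float]] = []
        # trivial boundary lines q_i = 0 and q_i = 1
        for fixed in (0.0, 1.0):
            for other in grid:
                pts.append((fixed, other) if i == 1 else (other, fixed))
        # interior payoff-equality locus, scanned along the other axis
        for other in grid:
            if i == 1:
                roots = _scan_roots(
                    lambda x: _payoff_gap(params, x, other, 1), grid
                )
                pts.extend((r, other) for r in roots)
            else:
                roots = _scan_roots(
                    lambda x: _payoff_gap(params, other, x, 2), grid
                )
                pts.extend((other, r) for r in roots)
        return np.array(pts)

    return Nullclines(q1_nullcline=build(1), q2_nullcline=build(2))


def classify_stability(
    params: AsymmetricParams, point: StrategyPair
) -> str:
    """Stability class from the Jacobian of the behavioural dynamics.

    Central differences with step 1e-6; eigenvalue real parts within
    +/-1e-7 of zero are reported as ``boundary-degenerate``.  Raises if the
    point is not a rest point (residual >= 1e-8).
    """
    q1, q2 = point.q1, point.q2
    r = _rhs(params, q1, q2)
    if max(abs(r[0]), abs(r[1])) >= RESIDUAL_TOL:
        raise ValueError(
            f"({q1}, {q2}) is not an equilibrium (residual {max(map(abs, r)):.3g})"
        )
    h = JAC_STEP
    jac = np.empty((2, 2))
    fp1 = _rhs(params, q1 + h, q2)
    fm1 = _rhs(params, q1 - h, q2)
    fp2 = _rhs(params, q1, q2 + h)
    fm2 = _rhs(params, q1, q2 - h)
    jac[:, 0] = [(fp1[0] - fm1[0]) / (2 * h), (fp1[1] - fm1[1]) / (2 * h)]
    jac[:, 1] = [(fp2[0] - fm2[0]) / (2 * h), (fp2[1] - fm2[1]) / (2 * h)]
    re = np.real(np.linalg.eigvals(jac))
    signs = [0 if abs(x) <= EIG_ZERO_BAND else (1 if x > 0 else -1) for x in re]
    if 0 in signs:
        return "boundary-degenerate"
    if all(s < 0 for s in signs):
        return "stable"
    if all(s > 0 for s in signs):
        return "unstable"
    return "saddle"


def _deviation_ok(params: AsymmetricParams, q1: float, q2: float) -> bool:
    """Unilateral-deviation test at (possibly) boundary coordinates."""
    pay = steady_payoffs(params, StrategyPair(q1=q1, q2=q2))
    gaps = (pay.S1 - pay.P1, pay.S2 - pay.P2)
    for q, gap in zip((q1, q2), gaps):
        if q <= BOUNDARY_SNAP and gap > 1e-9:  # lone scrounger would profit
            return False
        if q >= 1.0 - BOUNDARY_SNAP and gap < -1e-9:  # lone producer would profit
            return False
    return True


def _make_record(params: AsymmetricParams, q1: float, q2: float) -> EquilibriumRecord:
    q1 = min(max(q1, 0.0), 1.0)
    q2 = min(max(q2, 0.0), 1.0)
    point = StrategyPair(q1=q1, q2=q2)
    stability = classify_stability(params, point)
    pay = steady_payoffs(params, point)
    r = _rhs(params, q1, q2)
    is_nash = stability == "stable" and _deviation_ok(params, q1, q2)
    return EquilibriumRecord(
        q1=q1,
        q2=q2,
        stability=stability,
        is_nash=is_nash,
        payoffs=pay,
        composite=composite_scrounger_fraction(point, params.theta),
        residual=float(max(abs(r[0]), abs(r[1]))),
    )


def find_equilibria(
    params: AsymmetricParams,
    n_starts: int = 5,
    extra_starts: tuple[tuple[float, float], ...] = (),
    scan_points: int = 101,
) -> list[EquilibriumRecord]:
    """All rest points of the behavioural dynamics in [0,1]^2.

    Corners, edge payoff-equality points (1-D bracketing + Brent), and
    interior roots of {S1*=P1*, S2*=P2*} from an ``n_starts`` x
    ``n_starts`` grid of interior starts (plus any ``extra_starts``, e.g.
    sweep warm starts).  Duplicates are merged within 1e-8.
    """
    pts: list[tuple[float, float]] = [(0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0)]
    grid = np.linspace(0.0, 1.0, scan_points)

    for q1_fixed in (0.0, 1.0):  # edges q1 = const: solve class 2 equality
        for r_ in _scan_roots(lambda x: _payoff_gap(params, q1_fixed, x, 2), grid):
            if 0.0 < r_ < 1.0:
                pts.append((q1_fixed, r_))
    for q2_fixed in (0.0, 1.0):  # edges q2 = const: solve class 1 equality
        for r_ in _scan_roots(lambda x: _payoff_gap(params, x, q2_fixed, 1), grid):
            if 0.0 < r_ < 1.0:
                pts.append((r_, q2_fixed))

    def gap_vec(x: np.ndarray) -> list[float]:
        try:
            return [
                _payoff_gap(params, x[0], x[1], 1),
                _payoff_gap(params, x[0], x[1], 2),
            ]
        except ZeroDivisionError:
            # solver wandered into a singular region far outside [0,1]^2
            return [1e6, 1e6]

    starts = [
        (a, b)
        for a, b in itertools.product(
            np.linspace(0.1, 0.9, n_starts), np.linspace(0.1, 0.9, n_starts)
        )
    ]
    starts.extend(extra_starts)
    for s0 in starts:
        sol = root(gap_vec, list(s0), method="hybr", tol=1e-12)
        if not sol.success:
            continue
        x1, x2 = float(sol.x[0]), float(sol.x[1])
        if 1e-9 < x1 < 1.0 - 1e-9 and 1e-9 < x2 < 1.0 - 1e-9:
            pts.append((x1, x2))

    merged: list[tuple[float, float]] = []
    for p in pts:
        if not any(abs(p[0] - m[0]) < MERGE_TOL and abs(p[1] - m[1]) < MERGE_TOL
                   for m in merged):
            merged.append(p)

    records = []
    for q1, q2 in merged:
        r = _rhs(params, q1, q2)
        if max(abs(r[0]), abs(r[1])) < RESIDUAL_TOL:
            records.append(_make_record(params, q1, q2))
    return records


@dataclass(frozen=True)
class Trajectory:
    """A behavioural-dynamics trajectory; q has rows (q1, q2)."""

    t: np.ndarray
    q: np.ndarray


def integrate_behavior(
    params: AsymmetricParams,
    start: StrategyPair,
    horizon: float = 5000.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    settle_tol: float | None = 1e-12,
) -> Trajectory:
    """Numerically integrate the behavioural dynamics from ``start``.

    [0,1]^2 is forward-invariant; the returned coordinates are clipped only
    to correct solver roundoff.  If ``settle_tol`` is given, integration
    stops once the flow speed drops below it.
    """

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        return list(_rhs(params, y[0], y[1]))

    events = None
    if settle_tol is not None:
        def settled(_t: float, y: np.ndarray) -> float:
            d1, d2 = _rhs(params, y[0], y[1])
            return max(abs(d1), abs(d2)) - settle_tol

        settled.terminal = True  # type: ignore[attr-defined]
        settled.direction = -1  # type: ignore[attr-defined]
        events = settled

    sol = solve_ivp(
        rhs, (0.0, horizon), [start.q1, start.q2], rtol=rtol, atol=atol,
        events=events, method="LSODA",
    )
    if not sol.success:
        raise RuntimeError(f"behaviour integration failed: {sol.message}")
    return Trajectory(t=sol.t, q=np.clip(sol.y, 0.0, 1.0))


def nash_equilibrium(
    params: AsymmetricParams,
    start: StrategyPair = StrategyPair(0.5, 0.5),
    full: bool = False,
    extra_starts: tuple[tuple[float, float], ...] = (),
):
    """The Nash equilibrium reached from the centroid of the phase plane.

    All rest points are found and classified; among the dynamically stable
    ones the record selected is the one reached by forward integration from
    ``start`` (integration is skipped when a single stable rest point
    exists).  With ``full=True`` returns ``(record, all_stable_records)``.
    """
    records = find_equilibria(params, extra_starts=extra_starts)
    stable = [r for r in records if r.stability == "stable"]
    if len(stable) == 1:
        chosen = stable[0]
    else:
        traj = integrate_behavior(params, start)
        end = traj.q[:, -1]
        near = [
            r for r in stable
            if (r.q1 - end[0]) ** 2 + (r.q2 - end[1]) ** 2 < 1e-10
        ]
        # attractors with a marginal eigenvalue (|Re| inside the zero band)
        # are admissible landing points: approach can be algebraically slow
        candidates = stable + [
            r for r in records if r.stability == "boundary-degenerate"
        ]
        if near:
            chosen = near[0]
        elif max(abs(v) for v in _rhs(params, end[0], end[1])) < RESIDUAL_TOL and not any(
            (r.q1 - end[0]) ** 2 + (r.q2 - end[1]) ** 2 < 1e-10 for r in candidates
        ):
            # Attractor not among the isolated rest points: typically a
            # neutral line of equilibria (all stealing rates equal), where
            # the flow settles transversally onto a start-dependent point.
            chosen = _make_record(params, float(end[0]), float(end[1]))
        elif candidates:
            chosen = min(
                candidates,
                key=lambda r: (r.q1 - end[0]) ** 2 + (r.q2 - end[1]) ** 2,
            )
        else:
            raise RuntimeError(
                "no stable equilibrium found; rest points: "
                + ", ".join(f"({r.q1:.4g},{r.q2:.4g})[{r.stability}]" for r in records)
            )
    return (chosen, stable) if full else chosen


def _sweep_row(params: AsymmetricParams, rec: EquilibriumRecord) -> dict:
    point = StrategyPair(q1=rec.q1, q2=rec.q2)
    return {
        "q1_star": rec.q1,
        "q2_star": rec.q2,
        "stability": rec.stability,
        "is_nash": rec.is_nash,
        "P1": rec.payoffs.P1,
        "P2": rec.payoffs.P2,
        "S1": rec.payoffs.S1,
        "S2": rec.payoffs.S2,
        "composite": rec.composite,
        "group_avg_payoff": group_average_payoff(params, point),
    }


def _warm(rec: EquilibriumRecord | None) -> tuple[tuple[float, float], ...]:
    """Previous equilibrium, nudged off the boundary, as an extra root start."""
    if rec is None:
        return ()
    return ((min(max(rec.q1, 1e-3), 1.0 - 1e-3), min(max(rec.q2, 1e-3), 1.0 - 1e-3)),)


def sweep_group_size(params: AsymmetricParams, G_values) -> pd.DataFrame:
    """Nash equilibrium and payoffs along a group-size grid."""
    rows = []
    prev: EquilibriumRecord | None = None
    for g in G_values:
        p = params.with_(G=float(g))
        rec = nash_equilibrium(p, extra_starts=_warm(prev))
        rows.append({"G": float(g), **_sweep_row(p, rec)})
        prev = rec
    return pd.DataFrame(rows)


def sweep_gamma(params: AsymmetricParams, gamma1_grid, gamma2_grid) -> pd.DataFrame:
    """Nash surfaces over a (gamma1, gamma2) grid at fixed G and theta."""
    rows = []
    for g2 in gamma2_grid:
        prev: EquilibriumRecord | None = None
        for g1 in gamma1_grid:
            p = params.with_(gamma1=float(g1), gamma2=float(g2))
            rec = nash_equilibrium(p, extra_starts=_warm(prev))
            rows.append({"gamma1": float(g1), "gamma2": float(g2), **_sweep_row(p, rec)})
            prev = rec
    return pd.DataFrame(rows)


def sweep_theta(params: AsymmetricParams, theta_grid, G_grid) -> pd.DataFrame:
    """Nash surfaces over a (G, theta) grid.

    At theta = 0 or 1 one class is absent: its equilibrium proportion is
    reported as 0 with the matching ``*_present`` flag set to False (the
    present class plays the embedded one-phenotype game).
    """
    rows = []
    for th in theta_grid:
        prev: EquilibriumRecord | None = None
        for g in G_grid:
            p = params.with_(theta=float(th), G=float(g))
            rec = nash_equilibrium(p, extra_starts=_warm(prev))
            row = {"theta": float(th), "G": float(g), **_sweep_row(p, rec)}
            row["small_present"] = th > 0.0
            row["large_present"] = th < 1.0
            if th == 0.0:
                row["q1_star"] = 0.0
            if th == 1.0:
                row["q2_star"] = 0.0
            rows.append(row)
            prev = rec
    return pd.DataFrame(rows)


def q1_extinction_threshold(
    gamma_sweep: pd.DataFrame, tol: float = 1e-9
) -> float:
    """Smallest grid gamma2 at and above which q1* = 0 for every gamma1.

    Operates on a ``sweep_gamma`` table.  Returns NaN if no such grid value
    exists.
    """
    by_g2 = gamma_sweep.groupby("gamma2")["q1_star"].max().sort_index()
    threshold = float("nan")
    for g2 in reversed(by_g2.index):
        if by_g2.loc[g2] <= tol:
            threshold = float(g2)
        else:
            break
    return threshold
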