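"""Exact event-driven stochastic counterpart of the prey-holding dynamics.

Continuous-time Markov jump process on integer prey holdings of ``G``
individually tracked foragers.  Event rates mirror the mean-field
equations exactly:

* capture: each producer of size class *i* captures at constant rate
  ``lam_i`` (holdings are unbounded and capture never pauses, so the
  process is linear and its class means obey the ODEs with no mean-field
  error);
* theft: each (scrounger of class *i*, target of class *j*) pair transfers
  one prey at rate ``alpha_ij`` times the target's current holdings;
  targets are producers, plus scroungers when ``scrounger_theft`` is on
  (same-class scrounger-on-scrounger theft leaves the class mean
  unchanged but is simulated faithfully);
* handling end: each held prey is consumed or escapes at rate ``gamma_i``
  of its holder's class.

Because capture is a constant-rate immigration and every other rate is
linear in holdings, the expected class means solve the mean-field system
exactly; ``compare_to_ode`` turns that into per-class z-scores against the
closed-form steady state.  A ``cap_one`` variant (holdings limited to a
single prey, closer to the biology) is available but is *not* the
validation oracle — it breaks the linearity that makes the comparison
exact.

Sampling uses a single seeded generator with total-rate exponential
waiting times and categorical event choice (classic Gillespie), so runs
are reproducible bit-for-bit for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .asymmetric import AsymmetricParams, PayoffQuad, steady_payoffs_from_counts

__all__ = [
    "Assignment",
    "SimConfig",
    "SimSummary",
    "simulate",
    "compare_to_ode",
    "CLASS_KEYS",
]

#: summary keys, ordered as (size, strategy) = (1,p), (1,s), (2,p), (2,s)
CLASS_KEYS = (
    "small_producer",
    "small_scrounger",
    "large_producer",
    "large_scrounger",
)


@dataclass(frozen=True)
class Assignment:
    """Integer head counts per (size, strategy) class."""

    n1p: int
    n1s: int
    n2p: int
    n2s: int

    def __post_init__(self) -> None:
        for name in ("n1p", "n1s", "n2p", "n2s"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.n1p + self.n1s + self.n2p + self.n2s

    @classmethod
    def from_strategy(
        cls, params: AsymmetricParams, q1: float, q2: float
    ) -> "Assignment":
        """Round theta*G*q1 etc. to realised integer counts summing to G."""
        G = int(round(params.G))
        if abs(params.G - G) > 1e-9:
            raise ValueError("stochastic runs need an integer group size")
        n1 = int(round(params.theta * G))
        n2 = G - n1
        n1s = int(round(q1 * n1))
        n2s = int(round(q2 * n2))
        return cls(n1p=n1 - n1s, n1s=n1s, n2p=n2 - n2s, n2s=n2s)


@dataclass(frozen=True)
class SimConfig:
    """Run-length and reproducibility settings (times in hours)."""

    seed: int
    horizon: float = 2000.0
    burn_in: float = 200.0
    n_batches: int = 20
    record_events: bool = False
    cap_one: bool = False

    def __post_init__(self) -> None:
        if not self.horizon > self.burn_in >= 0:
            raise ValueError("need horizon > burn_in >= 0")
        if self.n_batches < 2:
            raise ValueError("need at least 2 batches for a standard error")


@dataclass(frozen=True)
class SimSummary:
    """Time-averaged class means with batch-means standard errors."""

    means: dict
    se: dict
    event_counts: dict
    assignment: Assignment
    horizon: float
    burn_in: float
    seed: int
    events: list | None = field(default=None, repr=False)


def simulate(
    params: AsymmetricParams, assignment: Assignment, config: SimConfig
) -> SimSummary:
    """Run the jump process and time-average holdings per class.

    Means and standard errors are computed from ``n_batches`` equal-width
    batch means over the post-burn-in window.  Recorded events (when
    requested) are tuples: ``("capture", t, actor, item)``,
    ``("theft", t, thief, target, item)``, ``("handled", t, actor, item)``
    with agent indices into the class layout [n1p | n1s | n2p | n2s].
    """
    if assignment.total != int(round(params.G)) or abs(
        params.G - round(params.G)
    ) > 1e-9:
        raise ValueError(
            f"class counts must sum to G={params.G}, got {assignment.total}"
        )
    G = assignment.total
    rng = np.random.default_rng(config.seed)

    cls = np.array(
        [0] * assignment.n1p + [0] * assignment.n1s
        + [1] * assignment.n2p + [1] * assignment.n2s
    )
    scr = np.array(
        [False] * assignment.n1p + [True] * assignment.n1s
        + [False] * assignment.n2p + [True] * assignment.n2s
    )
    hold = np.zeros(G, dtype=np.int64)
    items: list[list[int]] = [[] for _ in range(G)]
    next_item = 0

    lam = np.where(cls == 0, params.lam1, params.lam2) * (~scr)
    gam = np.where(cls == 0, params.gamma1, params.gamma2)
    alpha = np.array(
        [[params.alpha11, params.alpha12], [params.alpha21, params.alpha22]]
    )
    n_scr = np.array([(scr & (cls == 0)).sum(), (scr & (cls == 1)).sum()])
    # theft pressure per target: sum over scroungers (excluding self) of
    # alpha[scrounger class, target class]
    pressure = alpha[0, cls] * n_scr[0] + alpha[1, cls] * n_scr[1]
    pressure[scr] -= alpha[cls[scr], cls[scr]]
    if not params.scrounger_theft:
        pressure[scr] = 0.0

    # class-membership masks for the four summary classes
    masks = [
        (cls == 0) & ~scr,
        (cls == 0) & scr,
        (cls == 1) & ~scr,
        (cls == 1) & scr,
    ]
    class_sizes = np.array([m.sum() for m in masks])

    edges = np.linspace(config.burn_in, config.horizon, config.n_batches + 1)
    batch_int = np.zeros((config.n_batches, 4))
    events: list[tuple] | None = [] if config.record_events else None
    counts = {"capture": 0, "handled": 0}
    for i in (0, 1):
        for j in (0, 1):
            counts[f"theft_{i + 1}{j + 1}"] = 0

    def accumulate(a: float, b: float) -> None:
        if b <= config.burn_in:
            return
        lo = np.maximum(a, edges[:-1])
        hi = np.minimum(b, edges[1:])
        dt = np.clip(hi - lo, 0.0, None)
        if dt.any():
            h4 = np.array([hold[m].sum() for m in masks], dtype=float)
            batch_int[:, :] += np.outer(dt, h4)

    t = 0.0
    while True:
        cap_w = lam if not config.cap_one else lam * (hold == 0)
        cons_w = gam * hold
        theft_w = pressure * hold
        if config.cap_one:
            # a laden scrounger cannot steal: recompute pressure each event
            free = scr & (hold == 0)
            nf = np.array([(free & (cls == 0)).sum(), (free & (cls == 1)).sum()])
            theft_w = (alpha[0, cls] * nf[0] + alpha[1, cls] * nf[1]) * hold
            theft_w[free] -= alpha[cls[free], cls[free]] * hold[free]
            if not params.scrounger_theft:
                theft_w[scr] = 0.0
            theft_w = np.clip(theft_w, 0.0, None)
        cap_total = cap_w.sum()
        cons_total = cons_w.sum()
        theft_total = theft_w.sum()
        total = cap_total + cons_total + theft_total
        if total <= 0.0:
            accumulate(t, config.horizon)
            break
        t_new = t + rng.exponential(1.0 / total)
        if t_new >= config.horizon:
            accumulate(t, config.horizon)
            break
        accumulate(t, t_new)
        t = t_new

        u = rng.random() * total
        if u < cap_total:
            idx = int(np.searchsorted(np.cumsum(cap_w), u, side="right"))
            hold[idx] += 1
            items[idx].append(next_item)
            counts["capture"] += 1
            if events is not None:
                events.append(("capture", t, idx, next_item))
            next_item += 1
        elif u < cap_total + cons_total:
            v = u - cap_total
            idx = int(np.searchsorted(np.cumsum(cons_w), v, side="right"))
            k = int(rng.integers(len(items[idx])))
            item = items[idx].pop(k)
            hold[idx] -= 1
            counts["handled"] += 1
            if events is not None:
                events.append(("handled", t, idx, item))
        else:
            v = u - cap_total - cons_total
            tgt = int(np.searchsorted(np.cumsum(theft_w), v, side="right"))
            thief_w = np.where(scr, alpha[cls, cls[tgt]], 0.0)
            if config.cap_one:
                thief_w = np.where(scr & (hold == 0), alpha[cls, cls[tgt]], 0.0)
            thief_w[tgt] = 0.0
            cw = np.cumsum(thief_w)
            thief = int(np.searchsorted(cw, rng.random() * cw[-1], side="right"))
            k = int(rng.integers(len(items[tgt])))
            item = items[tgt].pop(k)
            hold[tgt] -= 1
            hold[thief] += 1
            items[thief].append(item)
            counts[f"theft_{cls[thief] + 1}{cls[tgt] + 1}"] += 1
            if events is not None:
                events.append(("theft", t, thief, tgt, item))

    widths = np.diff(edges)
    means: dict[str, float] = {}
    se: dict[str, float] = {}
    for k, key in enumerate(CLASS_KEYS):
        if class_sizes[k] == 0:
            means[key] = float("nan")
            se[key] = float("nan")
            continue
        per_batch = batch_int[:, k] / widths / class_sizes[k]
        means[key] = float(per_batch.mean())
        se[key] = float(per_batch.std(ddof=1) / np.sqrt(config.n_batches))
    return SimSummary(
        means=means,
        se=se,
        event_counts=counts,
        assignment=assignment,
        horizon=config.horizon,
        burn_in=config.burn_in,
        seed=config.seed,
        events=events,
    )


def compare_to_ode(
    summary: SimSummary, params: AsymmetricParams, assignment: Assignment
) -> dict:
    """Per-class z-scores of simulated means against the ODE steady state.

    The ODE payoffs are recomputed at the *realised* integer counts, so
    strategy-rounding introduces no bias into the comparison.  Empty
    classes are skipped and listed under ``"skipped"``.
    """
    ode: PayoffQuad = steady_payoffs_from_counts(
        params,
        float(assignment.n1p),
        float(assignment.n1s),
        float(assignment.n2p),
        float(assignment.n2s),
    )
    expected = dict(zip(CLASS_KEYS, (ode.P1, ode.S1, ode.P2, ode.S2)))
    sizes = dict(
        zip(
            CLASS_KEYS,
            (assignment.n1p, assignment.n1s, assignment.n2p, assignment.n2s),
        )
    )
    z: dict[str, float] = {}
    skipped: list[str] = []
    for key in CLASS_KEYS:
        if sizes[key] == 0:
            skipped.append(key)
            continue
        z[key] = (summary.means[key] - expected[key]) / summary.se[key]
    return {"z": z, "expected": expected, "skipped": skipped}
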