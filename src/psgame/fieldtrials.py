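"""Synthetic behavioural-trial logs and the estimators that invert them.

An observation layer over the stochastic simulator that emulates how a
field crew scores a one-hour foraging trial of a predator group: strikes
(lunges at prey, successful or not), captures, attempted and successful
thefts, escapes and consumptions, with the size class of the actors and —
for thefts — of the targeted predator.

The underlying jump process only produces captures, successful thefts and
handling terminations, so the observation layer adds the parts of the
record the single-rate model does not distinguish:

* each capture is the last of a geometric number of strikes
  (success probability ``strike_success``, default 0.436);
* each successful theft is preceded by a geometric number of failed
  attempts, logged as ``attempted_theft`` (success probability
  ``theft_success``, default 0.15);
* a handling termination is scored as an ``escape`` with probability
  ``escape_fraction`` (default 0.2) and otherwise as a ``consumption``;
* any record is independently dropped with probability ``miss_prob``
  (imperfect observation), and size labels are independently replaced by
  ``"unknown"`` with probability ``unknown_prob``.

Handling durations attach to the acquisition records (capture or
successful theft): the time until the holder's item was consumed/escaped
(uncensored) or until it was stolen away or the trial ended (censored) —
exactly the right-censoring structure a handling-time survival analysis
expects.  ``estimate_gamma`` is the matching exponential maximum-
likelihood estimator; ``rate_table`` recovers per-class hourly behaviour
rates as count / (class size x duration).

Field crews often score three relative size classes (small / medium /
large) while the game model has two phenotypes; ``coarsen_sizes`` applies
the configurable mapping (default: small stays small, medium and large
merge into large) before estimation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .asymmetric import AsymmetricParams
from .stochastic import Assignment, SimConfig, simulate

__all__ = [
    "EventRecord",
    "TrialConfig",
    "GammaEstimate",
    "generate_trial",
    "estimate_gamma",
    "rate_table",
    "coarsen_sizes",
    "events_to_frame",
    "write_events_csv",
    "read_events_csv",
]

BEHAVIORS = (
    "strike",
    "capture",
    "attempted_theft",
    "successful_theft",
    "escape",
    "consumption",
)

#: default mapping from three observational classes to the two phenotypes
DEFAULT_SIZE_MAP = {"small": "small", "medium": "large", "large": "large"}


@dataclass(frozen=True)
class EventRecord:
    """One scored behaviour in a trial; times in hours from trial start."""

    trial_id: str
    time: float
    behavior: str
    actor_size: str  # small | large | medium | unknown
    target_size: str | None = None  # thefts only
    handling: float | None = None  # capture / successful_theft only
    censored: bool | None = None  # whether handling ended unobserved


@dataclass(frozen=True)
class TrialConfig:
    """Observation-layer settings for one synthetic trial."""

    seed: int
    trial_id: str = "trial-1"
    duration: float = 1.0
    q1: float = 0.5
    q2: float = 0.5
    strike_success: float = 0.436
    theft_success: float = 0.15
    escape_fraction: float = 0.2
    miss_prob: float = 0.0
    unknown_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        for name in (
            "strike_success",
            "theft_success",
            "escape_fraction",
            "miss_prob",
            "unknown_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.strike_success == 0.0 or self.theft_success == 0.0:
            raise ValueError("strike/theft success probabilities must be > 0")
        if not 0.0 <= self.q1 <= 1.0 and 0.0 <= self.q2 <= 1.0:
            raise ValueError("q1, q2 must lie in [0, 1]")


def _size_name(size_idx: int) -> str:
    return "small" if size_idx == 0 else "large"


def generate_trial(
    params: AsymmetricParams, tc: TrialConfig
) -> list[EventRecord]:
    """Simulate one trial and score it as a list of EventRecords.

    Runs the jump process for ``tc.duration`` hours from empty mouths (no
    burn-in: a trial starts when predators first meet the prey school) and
    overlays the observation model described in the module docstring.
    Fully reproducible from ``tc.seed``.
    """
    assignment = Assignment.from_strategy(params, tc.q1, tc.q2)
    sim = simulate(
        params,
        assignment,
        SimConfig(
            seed=tc.seed, horizon=tc.duration, burn_in=0.0, n_batches=2,
            record_events=True,
        ),
    )
    assert sim.events is not None
    rng = np.random.default_rng(np.random.SeedSequence([tc.seed, 0xF1E1D]))

    sizes = np.array(
        [0] * assignment.n1p + [0] * assignment.n1s
        + [1] * assignment.n2p + [1] * assignment.n2s
    )

    # item -> (holder, acquisition record index) for handling durations
    open_items: dict[int, tuple[int, int]] = {}
    raw: list[dict] = []

    def close_item(item: int, t_end: float, censored: bool) -> None:
        holder, rec_idx = open_items.pop(item)
        raw[rec_idx]["handling"] = t_end - raw[rec_idx]["time"]
        raw[rec_idx]["censored"] = censored

    for ev in sim.events:
        kind, t = ev[0], ev[1]
        if kind == "capture":
            _, _, actor, item = ev
            n_fail = rng.geometric(tc.strike_success) - 1
            for ft in sorted(rng.uniform(max(0.0, t - 0.1), t, n_fail)):
                raw.append(
                    {"time": float(ft), "behavior": "strike",
                     "actor": actor, "target": None}
                )
            raw.append({"time": t, "behavior": "strike", "actor": actor,
                        "target": None})
            raw.append({"time": t, "behavior": "capture", "actor": actor,
                        "target": None, "handling": None, "censored": None})
            open_items[item] = (actor, len(raw) - 1)
        elif kind == "theft":
            _, _, thief, target, item = ev
            n_fail = rng.geometric(tc.theft_success) - 1
            for ft in sorted(rng.uniform(max(0.0, t - 0.1), t, n_fail)):
                raw.append(
                    {"time": float(ft), "behavior": "attempted_theft",
                     "actor": thief, "target": target}
                )
            if item in open_items:
                close_item(item, t, censored=True)
            raw.append(
                {"time": t, "behavior": "successful_theft", "actor": thief,
                 "target": target, "handling": None, "censored": None}
            )
            open_items[item] = (thief, len(raw) - 1)
        else:  # handled
            _, _, actor, item = ev
            if item in open_items:
                close_item(item, t, censored=False)
            behavior = (
                "escape" if rng.random() < tc.escape_fraction else "consumption"
            )
            raw.append({"time": t, "behavior": behavior, "actor": actor,
                        "target": None})

    for item in list(open_items):
        close_item(item, tc.duration, censored=True)

    records: list[EventRecord] = []
    for r in sorted(raw, key=lambda d: d["time"]):
        if rng.random() < tc.miss_prob:
            continue
        actor_size = _size_name(sizes[r["actor"]])
        if rng.random() < tc.unknown_prob:
            actor_size = "unknown"
        target_size: str | None = None
        if r["target"] is not None:
            target_size = _size_name(sizes[r["target"]])
            if rng.random() < tc.unknown_prob:
                target_size = "unknown"
        records.append(
            EventRecord(
                trial_id=tc.trial_id,
                time=r["time"],
                behavior=r["behavior"],
                actor_size=actor_size,
                target_size=target_size,
                handling=r.get("handling"),
                censored=r.get("censored"),
            )
        )
    return records


@dataclass(frozen=True)
class GammaEstimate:
    """Exponential-hazard rate estimate with a confidence interval (1/h)."""

    rate: float
    ci_low: float
    ci_high: float
    n_events: int
    total_time: float
    conf: float = 0.95


def estimate_gamma(
    durations, censored=None, conf: float = 0.95
) -> GammaEstimate:
    """Exponential maximum-likelihood handling rate from durations.

    The MLE under right censoring is (number of uncensored terminations) /
    (total observed handling time); the interval comes from the exact
    gamma sampling distribution of the rate (rate_hat ~ Gamma(k, 1/T)).
    """
    d = np.asarray(list(durations), dtype=float)
    if d.size == 0:
        raise ValueError("no durations supplied")
    if np.any(d < 0):
        raise ValueError("durations must be >= 0")
    c = (
        np.zeros(d.size, dtype=bool)
        if censored is None
        else np.asarray(list(censored), dtype=bool)
    )
    if c.size != d.size:
        raise ValueError("censored flags must match durations")
    k = int((~c).sum())
    if k == 0:
        raise ValueError("all durations censored; rate not identifiable")
    total = float(d.sum())
    lo, hi = gamma_dist.ppf(
        [(1 - conf) / 2, 1 - (1 - conf) / 2], a=k, scale=1.0 / total
    )
    return GammaEstimate(
        rate=k / total, ci_low=float(lo), ci_high=float(hi),
        n_events=k, total_time=total, conf=conf,
    )


def coarsen_sizes(
    events: list[EventRecord], size_map: dict[str, str] | None = None
) -> list[EventRecord]:
    """Map observational size labels onto model phenotypes.

    ``size_map`` defaults to small->small, medium->large, large->large;
    labels missing from the map (e.g. "unknown") pass through.
    """
    m = DEFAULT_SIZE_MAP if size_map is None else size_map
    out = []
    for e in events:
        out.append(
            EventRecord(
                trial_id=e.trial_id,
                time=e.time,
                behavior=e.behavior,
                actor_size=m.get(e.actor_size, e.actor_size),
                target_size=(
                    None if e.target_size is None
                    else m.get(e.target_size, e.target_size)
                ),
                handling=e.handling,
                censored=e.censored,
            )
        )
    return out


def rate_table(
    events: list[EventRecord], composition: dict[str, int], duration: float
) -> pd.DataFrame:
    """Per-class hourly behaviour rates: count / (class size x duration).

    Rows are the six behaviours (zeros reported, never dropped — sparse
    behaviours are the norm in these data); columns are the classes in
    ``composition`` plus an ``unknown`` column holding the *count* of
    events whose actor size could not be scored (no per-capita denominator
    exists for it).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    for k, v in composition.items():
        if v <= 0:
            raise ValueError(f"composition count for {k!r} must be > 0")
    classes = list(composition)
    table = pd.DataFrame(
        0.0, index=list(BEHAVIORS), columns=classes + ["unknown"]
    )
    for e in events:
        if e.behavior not in table.index:
            continue
        col = e.actor_size if e.actor_size in composition else "unknown"
        table.loc[e.behavior, col] += 1.0
    for cl in classes:
        table[cl] = table[cl] / (composition[cl] * duration)
    return table


_CSV_FIELDS = (
    "trial_id", "time_h", "behavior", "actor_size", "target_size",
    "handling_h", "censored",
)


def events_to_frame(events: list[EventRecord]) -> pd.DataFrame:
    """Events as a tidy DataFrame with the CSV column layout."""
    return pd.DataFrame(
        [
            {
                "trial_id": e.trial_id,
                "time_h": e.time,
                "behavior": e.behavior,
                "actor_size": e.actor_size,
                "target_size": e.target_size if e.target_size else "",
                "handling_h": "" if e.handling is None else e.handling,
                "censored": "" if e.censored is None else int(e.censored),
            }
            for e in events
        ],
        columns=list(_CSV_FIELDS),
    )


def write_events_csv(events: list[EventRecord], path) -> None:
    """Write events as comma-separated UTF-8 with a header row."""
    events_to_frame(events).to_csv(path, index=False)


def read_events_csv(path) -> list[EventRecord]:
    """Read an events CSV written by :func:`write_events_csv`."""
    records: list[EventRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            records.append(
                EventRecord(
                    trial_id=row["trial_id"],
                    time=float(row["time_h"]),
                    behavior=row["behavior"],
                    actor_size=row["actor_size"],
                    target_size=row["target_size"] or None,
                    handling=(
                        float(row["handling_h"]) if row["handling_h"] else None
                    ),
                    censored=(
                        bool(int(row["censored"])) if row["censored"] else None
                    ),
                )
            )
    return records
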