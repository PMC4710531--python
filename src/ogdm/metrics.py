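"""Reproduction metrics for the 21-day fathead minnow assay.

The three scalar endpoints are

    average fecundity  = (n_egg_total / n_female) / n_days   (eggs female^-1 day^-1)
    eggs per spawn     =  n_egg_total / n_spawns
    spawns per female  =  n_spawns / n_female

plus cumulative fecundity, the running total of eggs over study days.  For
group spawning designs (several females sharing a tank) the model's
per-female spawn events are reconciled with what an observer can count by
"binning": all eggs a group spawns on the same day are treated as one
spawning event whose clutch is the day's sum.  Binning conserves eggs (and
hence average fecundity) while reducing the spawn count.

Eggs per spawn is mathematically undefined for a fish that never spawned;
that case is carried as the typed :data:`UNDEFINED` sentinel, converted to
zero only at presentation time.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import SimulationResult, SpawnEvent

__all__ = [
    "UNDEFINED",
    "ReproductionMetrics",
    "average_fecundity",
    "eggs_per_spawn",
    "spawns_per_female",
    "cumulative_fecundity",
    "bin_group_spawns",
    "ks_two_sample",
    "metrics_from_events",
    "metrics_table",
]


class _Undefined:
    """Sentinel for a mathematically undefined metric (0 spawns)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNDEFINED"

    def __bool__(self) -> bool:
        return False


UNDEFINED = _Undefined()


def as_plotted(value: float | _Undefined) -> float:
    """Presentation rule: undefined eggs-per-spawn is rendered as zero."""
    return 0.0 if value is UNDEFINED else float(value)


def average_fecundity(n_egg_total: int, n_female: int, n_days: int) -> float:
    """Eggs per female per day over the observation period."""
    if n_female < 1:
        raise ValueError("n_female must be >= 1")
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    return (n_egg_total / n_female) / n_days


def eggs_per_spawn(n_egg_total: int, n_spawns: int) -> float | _Undefined:
    """Mean clutch size; UNDEFINED when no spawning occurred."""
    if n_egg_total < 0 or n_spawns < 0:
        raise ValueError("counts must be non-negative")
    if n_spawns == 0:
        return UNDEFINED
    return n_egg_total / n_spawns


def spawns_per_female(n_spawns: int, n_female: int) -> float:
    if n_female < 1:
        raise ValueError("n_female must be >= 1")
    return n_spawns / n_female


def cumulative_fecundity(
    events: list[SpawnEvent],
    day_range: tuple[int, int],
    n_female: int | None = None,
) -> pd.Series:
    """Running total of eggs spawned per study day.

    ``day_range = (first, last)`` is inclusive; each entry of the returned
    series is the total eggs spawned by all fish/groups up to and including
    that day.  With ``n_female`` given, the series is divided by the female
    count ("cumulative number of eggs spawned per female").
    """
    first, last = day_range
    if last < first:
        raise ValueError("empty day range")
    days = np.arange(first, last + 1)
    daily = np.zeros(days.size)
    for event in events:
        if first <= event.study_day <= last:
            daily[event.study_day - first] += event.clutch_size
    series = pd.Series(np.cumsum(daily), index=days, name="cumulative_eggs")
    if n_female is not None:
        if n_female < 1:
            raise ValueError("n_female must be >= 1")
        series = series / n_female
    return series


def bin_group_spawns(
    events: list[SpawnEvent],
    fish_to_group: dict[str, str],
) -> list[SpawnEvent]:
    """Merge same-day spawns within a group into single events.

    Each (group, day) with at least one spawn yields exactly one event whose
    clutch size is the sum of the members' clutches; the event carries the
    group id in the ``fish_id`` slot.  Total eggs are conserved.
    """
    totals: dict[tuple[str, int], int] = defaultdict(int)
    for event in events:
        if event.fish_id not in fish_to_group:
            raise ValueError(f"fish {event.fish_id!r} has no group assignment")
        totals[(fish_to_group[event.fish_id], event.study_day)] += event.clutch_size
    return [
        SpawnEvent(fish_id=group, study_day=day, clutch_size=eggs)
        for (group, day), eggs in sorted(totals.items())
    ]


def ks_two_sample(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic two-sided p-value).

    D is the supremum distance between the two empirical CDFs; used at
    alpha = 0.05 to compare predicted and observed metric distributions.
    """
    from scipy.stats import ks_2samp

    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ReproductionMetrics:
    """The assay's endpoint bundle for one unit (fish, group or treatment)."""

    average_fecundity: float
    eggs_per_spawn: float | _Undefined
    spawns_per_female: float
    cumulative: pd.Series
    n_egg_total: int
    n_spawns: int
    n_female: int
    n_days: int


def metrics_from_events(
    events: list[SpawnEvent],
    n_female: int,
    day_range: tuple[int, int],
) -> ReproductionMetrics:
    """Compute the full metric bundle from a spawn-event list.

    Only events inside ``day_range`` (inclusive) contribute; ``n_days`` is
    the length of the range.
    """
    first, last = day_range
    selected = [e for e in events if first <= e.study_day <= last]
    n_eggs = sum(e.clutch_size for e in selected)
    n_spawns = len(selected)
    n_days = last - first + 1
    return ReproductionMetrics(
        average_fecundity=average_fecundity(n_eggs, n_female, n_days),
        eggs_per_spawn=eggs_per_spawn(n_eggs, n_spawns),
        spawns_per_female=spawns_per_female(n_spawns, n_female),
        cumulative=cumulative_fecundity(selected, day_range),
        n_egg_total=n_eggs,
        n_spawns=n_spawns,
        n_female=n_female,
        n_days=n_days,
    )


def metrics_table(
    replicates: list[list[SimulationResult]],
    *,
    design: str = "paired",
    exposure_days: int | None = None,
) -> pd.DataFrame:
    """Tidy per-(treatment, group, replicate) metric table over the exposure window.

    With ``design="group"`` same-day spawns within a group are binned before
    the spawn-count metrics are computed; average fecundity is unaffected by
    binning.  Suitable for boxplots and KS comparisons at either grouping.
    """
    if design not in ("paired", "group"):
        raise ValueError("design must be 'paired' or 'group'")
    rows = []
    for rep_index, results in enumerate(replicates):
        if not results:
            continue
        n_days = exposure_days or results[0].simulation_days
        by_group: dict[tuple[str, str], list[SimulationResult]] = defaultdict(list)
        for res in results:
            by_group[(res.spec.treatment, res.spec.group_id)].append(res)
        for (treatment, group), members in sorted(by_group.items()):
            events = [e for r in members for e in r.events if e.study_day >= 0]
            if design == "group":
                mapping = {r.fish_id: group for r in members}
                events = bin_group_spawns(events, mapping)
            m = metrics_from_events(events, n_female=len(members), day_range=(0, n_days - 1))
            rows.append(
                {
                    "replicate": rep_index,
                    "treatment": treatment,
                    "group_id": group,
                    "n_female": m.n_female,
                    "n_egg_total": m.n_egg_total,
                    "n_spawns": m.n_spawns,
                    "average_fecundity": m.average_fecundity,
                    "eggs_per_spawn": as_plotted(m.eggs_per_spawn),
                    "spawns_per_female": m.spawns_per_female,
                }
            )
    return pd.DataFrame(rows)
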