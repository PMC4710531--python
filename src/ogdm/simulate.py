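"""Individual-based simulation of female fathead minnows.

Each simulated female runs through an 81-day start-up period (60 days of
oogonia recruitment from sexual maturation plus a 21-day acclimation
window) followed by the user-specified exposure window.  Times are kept on
the study clock: day 0 is the first exposure day, start-up days are
negative.  Batches of oogonia are recruited at truncated-lognormal
intervals with truncated-lognormal clutch sizes, grow under the fish's
two-phase plasma VTG protocol, and spawn on reaching the threshold volume.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np

from .growth import BatchStatus, OocyteBatch, VtgProtocol, grow_batch
from .params import ModelParameters, sample_clutch_size, sample_recruitment_interval

__all__ = ["FishSpec", "SpawnEvent", "SimulationResult", "simulate_fish", "simulate_cohort"]


@dataclass(frozen=True)
class FishSpec:
    """One simulated female: identity, grouping and VTG protocol inputs."""

    fish_id: str
    c_vtg_exposure: float
    group_id: str = "g1"
    treatment: str = "control"
    c_vtg_pre: float | None = None  # None -> params.c_vtg_pre_default

    def __post_init__(self) -> None:
        if self.c_vtg_exposure < 0:
            raise ValueError(f"{self.fish_id}: c_vtg_exposure must be non-negative")
        if self.c_vtg_pre is not None and self.c_vtg_pre < 0:
            raise ValueError(f"{self.fish_id}: c_vtg_pre must be non-negative")


@dataclass(frozen=True)
class SpawnEvent:
    """One spawning event: integer study day (negative during start-up) and clutch size."""

    fish_id: str
    study_day: int
    clutch_size: int

    def __post_init__(self) -> None:
        if self.clutch_size < 1:
            raise ValueError("clutch_size must be >= 1")


@dataclass
class SimulationResult:
    """Full record of one simulated female.

    ``events`` are chronological; ``batches`` include every recruited batch,
    spawned or not.  Exposure-period totals count only events with
    ``study_day >= 0``.
    """

    fish_id: str
    spec: FishSpec
    simulation_days: int
    startup_days: int
    events: list[SpawnEvent] = field(default_factory=list)
    batches: list[OocyteBatch] = field(default_factory=list)

    @property
    def eggs_full(self) -> int:
        return sum(e.clutch_size for e in self.events)

    @property
    def spawns_full(self) -> int:
        return len(self.events)

    @property
    def eggs_exposure(self) -> int:
        return sum(e.clutch_size for e in self.events if e.study_day >= 0)

    @property
    def spawns_exposure(self) -> int:
        return sum(1 for e in self.events if e.study_day >= 0)


def simulate_fish(
    spec: FishSpec,
    simulation_days: int,
    params: ModelParameters,
    rng: np.random.Generator,
    *,
    first_recruit_at_start: bool = True,
) -> SimulationResult:
    """Simulate one female through start-up plus ``simulation_days`` of exposure.

    Recruitment starts at study day ``-startup_days`` (immediately, by
    default, with the first sampled interval separating the second batch)
    and continues through the whole window.  Every batch is grown under the
    fish's two-phase VTG protocol; threshold crossings within the window
    become spawn events binned to integer study days (floor of the
    continuous spawn time, matching daily egg collection in the assay).
    """
    if simulation_days < 1:
        raise ValueError(f"simulation_days must be >= 1, got {simulation_days}")
    c_pre = spec.c_vtg_pre if spec.c_vtg_pre is not None else params.c_vtg_pre_default
    protocol = VtgProtocol.two_phase(c_pre, spec.c_vtg_exposure, params.startup_days)
    t_start = -float(params.startup_days)
    t_end = float(simulation_days)

    result = SimulationResult(
        fish_id=spec.fish_id,
        spec=spec,
        simulation_days=simulation_days,
        startup_days=params.startup_days,
    )

    t = t_start
    if not first_recruit_at_start:
        t += sample_recruitment_interval(params, rng)
    while t < t_end:
        batch = OocyteBatch(recruit_time=t, n_oogonia=sample_clutch_size(params, rng))
        grow_batch(batch, protocol, t_end, params)
        result.batches.append(batch)
        if batch.status is BatchStatus.SPAWNED:
            # a crossing landing exactly on the window end belongs to the last day
            day = min(int(math.floor(batch.spawn_time)), simulation_days - 1)
            result.events.append(
                SpawnEvent(fish_id=spec.fish_id, study_day=day, clutch_size=batch.n_oogonia)
            )
        t += sample_recruitment_interval(params, rng)
    result.events.sort(key=lambda e: e.study_day)
    return result


def _fish_stream_key(fish_id: str) -> int:
    """Stable 31-bit key for a fish id, so per-fish substreams do not depend
    on cohort composition or ordering."""
    digest = hashlib.blake2s(fish_id.encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "big") & 0x7FFFFFFF


def fish_rng(seed: int, fish_id: str, replicate: int) -> np.random.Generator:
    """Independent generator for one (fish, replicate) pair under a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), int(replicate), _fish_stream_key(fish_id)))
    )


def simulate_cohort(
    specs: list[FishSpec],
    simulation_days: int,
    n_replicates: int,
    params: ModelParameters,
    seed: int,
    *,
    first_recruit_at_start: bool = True,
) -> list[list[SimulationResult]]:
    """Replicated cohort simulation: ``n_replicates`` lists of per-fish results.

    Randomness is keyed by (master seed, replicate, fish id), so adding or
    removing a fish leaves every other fish's draws untouched and the whole
    run is reproducible bit for bit from the seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ids = [s.fish_id for s in specs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate fish_id(s): {dupes}")
    replicates = []
    for rep in range(n_replicates):
        replicates.append(
            [
                simulate_fish(
                    spec,
                    simulation_days,
                    params,
                    fish_rng(seed, spec.fish_id, rep),
                    first_recruit_at_start=first_recruit_at_start,
                )
                for spec in specs
            ]
        )
    return replicates
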