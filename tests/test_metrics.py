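"""Reproduction metrics, group binning and the KS comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ogdm.metrics import (
    UNDEFINED,
    as_plotted,
    average_fecundity,
    bin_group_spawns,
    cumulative_fecundity,
    eggs_per_spawn,
    ks_two_sample,
    metrics_from_events,
    spawns_per_female,
)
from ogdm.simulate import SpawnEvent


@pytest.mark.parametrize(
    "eggs, females, days, expected",
    [
        (749, 8, 1, 93.625),  # a full cohort spawning 94 eggs/female on one day
        (0, 4, 21, 0.0),
        (420, 4, 21, 5.0),
    ],
)
def test_average_fecundity_exact_quotient(eggs, females, days, expected):
    assert average_fecundity(eggs, females, days) == pytest.approx(expected)


def test_average_fecundity_domain_errors():
    with pytest.raises(ValueError):
        average_fecundity(10, 0, 21)
    with pytest.raises(ValueError):
        average_fecundity(10, 4, 0)


@pytest.mark.parametrize(
    "eggs, spawns, expected", [(300, 3, 100.0), (96, 1, 96.0)]
)
def test_eggs_per_spawn(eggs, spawns, expected):
    assert eggs_per_spawn(eggs, spawns) == pytest.approx(expected)


def test_eggs_per_spawn_undefined_sentinel_is_not_zero():
    value = eggs_per_spawn(0, 0)
    assert value is UNDEFINED
    assert value != 0
    assert as_plotted(value) == 0.0  # presentation-only conversion


@pytest.mark.parametrize("spawns, females, expected", [(7, 4, 1.75), (0, 4, 0.0), (12, 1, 12.0)])
def test_spawns_per_female(spawns, females, expected):
    assert spawns_per_female(spawns, females) == pytest.approx(expected)


def test_cumulative_fecundity_step_function():
    events = [SpawnEvent("f1", 3, 50)]
    series = cumulative_fecundity(events, (1, 5))
    assert list(series.index) == [1, 2, 3, 4, 5]
    assert list(series) == [0, 0, 50, 50, 50]
    empty = cumulative_fecundity([], (1, 5))
    assert (empty == 0).all()


def test_per_female_cumulative_dilutes_single_big_spawner():
    """One 662-egg fish in a 12-fish cohort: the cohort-level per-female
    cumulative fecundity reaches 160 only if the other 11 fish contribute
    1258 eggs (662 + 1258 = 12 * 160)."""
    events = [SpawnEvent("big", 20, 662)] + [
        SpawnEvent(f"f{i}", 5 + i, eggs)
        for i, eggs in enumerate([115] * 10 + [108])
    ]
    series = cumulative_fecundity(events, (0, 20), n_female=12)
    assert sum(e.clutch_size for e in events) == 662 + 1258
    assert series.iloc[-1] == pytest.approx((662 + 1258) / 12) == pytest.approx(160.0)


def test_binning_merges_same_day_same_group_spawns():
    events = [SpawnEvent("a", 5, 40), SpawnEvent("b", 5, 60)]
    binned = bin_group_spawns(events, {"a": "g1", "b": "g1"})
    assert len(binned) == 1
    assert binned[0].study_day == 5 and binned[0].clutch_size == 100


def test_binning_identity_on_distinct_days():
    events = [SpawnEvent("a", 1, 40), SpawnEvent("a", 2, 60)]
    binned = bin_group_spawns(events, {"a": "g1"})
    assert [(e.study_day, e.clutch_size) for e in binned] == [(1, 40), (2, 60)]


def test_binning_requires_full_group_mapping():
    with pytest.raises(ValueError, match="no group assignment"):
        bin_group_spawns([SpawnEvent("x", 1, 5)], {})


@settings(derandomize=True, max_examples=200, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.sampled_from(["a", "b", "c", "d"]),
            st.integers(min_value=-81, max_value=20),
            st.integers(min_value=1, max_value=317),
        ),
        max_size=60,
    )
)
def test_binning_conserves_eggs_and_never_raises_spawn_count(raw):
    events = [SpawnEvent(f, d, c) for f, d, c in raw]
    mapping = {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
    binned = bin_group_spawns(events, mapping)
    assert sum(e.clutch_size for e in binned) == sum(e.clutch_size for e in events)
    assert len(binned) <= len(events)
    # one event per (group, day)
    keys = [(e.fish_id, e.study_day) for e in binned]
    assert len(keys) == len(set(keys))


def test_binning_changes_only_per_spawn_metrics():
    events = [
        SpawnEvent("a", 2, 30),
        SpawnEvent("b", 2, 50),
        SpawnEvent("a", 7, 20),
    ]
    raw = metrics_from_events(events, n_female=4, day_range=(0, 20))
    binned = metrics_from_events(
        bin_group_spawns(events, {"a": "g1", "b": "g1"}), n_female=4, day_range=(0, 20)
    )
    assert binned.average_fecundity == raw.average_fecundity
    assert binned.n_egg_total == raw.n_egg_total
    assert binned.n_spawns == 2 < raw.n_spawns == 3
    assert binned.eggs_per_spawn > raw.eggs_per_spawn


def test_metric_identity_fecundity_vs_per_spawn_decomposition(params, rng):
    """average_fecundity == eggs_per_spawn * spawns_per_female / n_days,
    whenever eggs_per_spawn is defined (algebraic identity)."""
    rng_local = np.random.default_rng(0)
    events = [
        SpawnEvent("f1", int(d), int(c))
        for d, c in zip(rng_local.integers(0, 21, 15), rng_local.integers(1, 317, 15))
    ]
    m = metrics_from_events(events, n_female=4, day_range=(0, 20))
    assert m.eggs_per_spawn is not UNDEFINED
    assert m.average_fecundity == pytest.approx(
        m.eggs_per_spawn * m.spawns_per_female / m.n_days
    )
    assert m.cumulative.iloc[-1] == m.n_egg_total


def brute_force_ks(a, b):
    points = np.concatenate([a, b])
    gaps = [
        abs((a <= x).mean() - (b <= x).mean())
        for x in points
    ]
    return max(gaps)


def test_ks_statistic_matches_exhaustive_ecdf_oracle(rng):
    for _ in range(20):
        a = rng.normal(size=rng.integers(2, 30))
        b = rng.normal(loc=rng.uniform(-1, 1), size=rng.integers(2, 30))
        stat, p = ks_two_sample(a, b)
        assert stat == pytest.approx(brute_force_ks(a, b), abs=1e-12)
        assert 0 <= p <= 1


def test_ks_degenerate_cases():
    stat, _ = ks_two_sample([1, 2, 3], [1, 2, 3])
    assert stat == 0
    stat, p = ks_two_sample([0, 1, 2] * 10, [10, 11, 12] * 10)
    assert stat == 1
    assert p < 0.05
    with pytest.raises(ValueError):
        ks_two_sample([], [1.0])
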