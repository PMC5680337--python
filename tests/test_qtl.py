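import numpy as np
import pytest

from photoacclim import (
    call_qtl_snps,
    classify_temporal,
    window_merge,
)
from photoacclim.qtl import SignificanceGrid, call_and_classify


def make_grid(schedule, neglog, pos=None, chrom=None):
    neglog = np.asarray(neglog, dtype=float)
    m = neglog.shape[0]
    pos = np.asarray(pos if pos is not None else np.arange(1, m + 1) * 1000)
    chrom = np.asarray(
        chrom if chrom is not None else ["Chr1"] * m, dtype=object
    )
    return SignificanceGrid(neglog, chrom, pos, schedule)


def row(schedule, sig_indices, value=5.0):
    r = np.zeros(len(schedule))
    r[list(sig_indices)] = value
    return r


def test_two_plus_two_hits_is_not_called(schedule):
    # significant at 2 LL and 2 HL points: neither phase reaches 3
    ll, hl = schedule.ll_indices, schedule.hl_indices
    grid = make_grid(schedule, [row(schedule, ll[:2] + hl[:2])])
    out = call_qtl_snps(grid)
    assert not out["called"][0]
    assert out["ll_hits"][0] == 2 and out["hl_hits"][0] == 2


def test_three_hits_in_one_phase_is_called(schedule):
    grid = make_grid(
        schedule,
        [row(schedule, schedule.hl_indices[:3]), row(schedule, schedule.ll_indices[:3])],
    )
    assert call_qtl_snps(grid)["called"].all()


def test_calling_matches_bruteforce_row_counting(schedule):
    rng = np.random.default_rng(81)
    neglog = rng.exponential(2.0, size=(200, len(schedule)))
    grid = make_grid(schedule, neglog)
    out = call_qtl_snps(grid, threshold=4, min_recurrence=3)
    ll, hl = schedule.ll_indices, schedule.hl_indices
    for j in range(200):
        hits = neglog[j] >= 4
        expect = hits[ll].sum() >= 3 or hits[hl].sum() >= 3
        assert out["called"][j] == expect


# ---------------------------------------------------------------------------
# window merging


def test_windows_150kb_apart_merge(schedule):
    grid = make_grid(
        schedule,
        [row(schedule, schedule.hl_indices[:3])] * 2,
        pos=[1_000_000, 1_150_000],
    )
    called = call_qtl_snps(grid)
    assert len(window_merge(grid, called)) == 1


def test_windows_250kb_apart_stay_separate(schedule):
    grid = make_grid(
        schedule,
        [row(schedule, schedule.hl_indices[:3])] * 2,
        pos=[1_000_000, 1_250_000],
    )
    called = call_qtl_snps(grid)
    qtls = window_merge(grid, called)
    assert len(qtls) == 2
    assert [q.qtl_id for q in qtls] == [1, 2]


def test_touching_windows_merge(schedule):
    grid = make_grid(
        schedule,
        [row(schedule, schedule.hl_indices[:3])] * 2,
        pos=[1_000_000, 1_200_000],  # windows touch exactly
    )
    assert len(window_merge(grid, call_qtl_snps(grid))) == 1


def brute_force_union(positions, half_window):
    """Oracle: union of [p-h, p+h] intervals by exhaustive point sweep."""
    intervals = sorted((max(p - half_window, 1), p + half_window) for p in positions)
    merged = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@pytest.mark.parametrize("trial", range(20))
def test_merge_matches_union_oracle(schedule, trial):
    rng = np.random.default_rng(100 + trial)
    m = 50
    pos = np.sort(rng.choice(np.arange(1, 5_000_000), size=m, replace=False))
    sig = rng.random(m) < 0.4
    neglog = np.zeros((m, len(schedule)))
    neglog[sig][:, :] = 0
    rows = [row(schedule, schedule.hl_indices[:3]) if s else np.zeros(len(schedule)) for s in sig]
    grid = make_grid(schedule, rows, pos=pos)
    called = call_qtl_snps(grid)
    qtls = window_merge(grid, called, half_window=100_000)
    expect = brute_force_union(pos[sig], 100_000)
    assert [(q.start, q.end) for q in qtls] == expect


def test_merge_idempotent_and_monotone(schedule):
    rng = np.random.default_rng(91)
    m = 80
    pos = np.sort(rng.choice(np.arange(1, 8_000_000), size=m, replace=False))
    rows = [
        row(schedule, schedule.hl_indices[:3]) if rng.random() < 0.5
        else np.zeros(len(schedule))
        for _ in range(m)
    ]
    grid = make_grid(schedule, rows, pos=pos)
    called = call_qtl_snps(grid)
    q100 = window_merge(grid, called, half_window=100_000)
    # idempotence: re-sweeping the merged intervals changes nothing
    spans = [(q.start, q.end) for q in q100]
    merged_again = []
    for s, e in spans:
        if merged_again and s <= merged_again[-1][1]:
            merged_again[-1] = (merged_again[-1][0], max(merged_again[-1][1], e))
        else:
            merged_again.append((s, e))
    assert spans == merged_again
    # monotonicity: larger window, no more intervals
    q20 = window_merge(grid, called, half_window=20_000)
    assert len(q100) <= len(q20)


def test_top_snp_is_maximum_with_position_tiebreak(schedule):
    r1 = row(schedule, schedule.hl_indices[:3], value=5.0)
    r2 = row(schedule, schedule.hl_indices[:3], value=5.0)
    grid = make_grid(schedule, [r1, r2], pos=[1_000_000, 1_050_000])
    q = window_merge(grid, call_qtl_snps(grid))[0]
    assert q.top_pos == 1_000_000  # tie broken by smaller position


# ---------------------------------------------------------------------------
# temporal classification


def hl_day_indices(schedule, day):
    return [
        i
        for i, tp in enumerate(schedule)
        if tp.phase == "HL" and schedule.hl_day_index(tp) == day
    ]


@pytest.mark.parametrize(
    "which, expected",
    [
        ("ll", "LL"),
        ("hl_day1", "earlyHL"),
        ("hl_day4", "lateHL"),
        ("hl_span", "persistentHL"),
        ("both", "LL+HL"),
    ],
)
def test_temporal_classes(schedule, which, expected):
    if which == "ll":
        idx = schedule.ll_indices[:3]
    elif which == "hl_day1":
        idx = hl_day_indices(schedule, 1)
    elif which == "hl_day4":
        idx = hl_day_indices(schedule, 4)
    elif which == "hl_span":
        idx = hl_day_indices(schedule, 1)[:2] + hl_day_indices(schedule, 4)[:1]
    else:
        idx = schedule.ll_indices[:3] + hl_day_indices(schedule, 3)
    grid = make_grid(schedule, [row(schedule, idx)])
    qtls = window_merge(grid, call_qtl_snps(grid))
    assert classify_temporal(qtls[0], grid) == expected


def test_unclassifiable_interval_raises(schedule):
    grid = make_grid(schedule, [row(schedule, schedule.hl_indices[:2])])
    from photoacclim.qtl import QtlInterval

    fake = QtlInterval(
        qtl_id=1, chrom="Chr1", start=1, end=2000, top_pos=1000,
        top_neglog10p=5.0,
    )
    with pytest.raises(ValueError, match="recurrence"):
        classify_temporal(fake, grid)


def test_every_called_interval_gets_exactly_one_class(schedule):
    rng = np.random.default_rng(95)
    m = 120
    pos = np.sort(rng.choice(np.arange(1, 10_000_000), size=m, replace=False))
    neglog = rng.exponential(2.5, size=(m, len(schedule)))
    grid = make_grid(schedule, neglog, pos=pos)
    qtls = call_and_classify(grid)
    assert all(q.temporal_class in
               ("LL", "earlyHL", "lateHL", "persistentHL", "LL+HL")
               for q in qtls)
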