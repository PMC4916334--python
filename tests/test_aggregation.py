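"""Bout segmentation, wear-time validation and the summary hierarchy."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gaitpal as gp
from gaitpal.aggregation import (CATEGORIES, cohort_table, find_bouts,
                                 summarize_day, summarize_subject,
                                 wear_time_from_counts)
from gaitpal.errors import NoValidDaysError, ParameterError


def _rle_oracle(labels):
    """Brute-force run-length encoding of walk runs."""
    runs, start = [], None
    for i, lab in enumerate(list(labels) + ["nonwalk"]):
        if lab == "walk" and start is None:
            start = i
        elif lab != "walk" and start is not None:
            runs.append((start, i - start))
            start = None
    return runs


def test_bout_duration_boundary():
    short = find_bouts(["walk"] * 11)   # 55 s
    long = find_bouts(["walk"] * 12)    # 60 s
    assert [b.category for b in short] == ["short"]
    assert [b.category for b in long] == ["long"]
    assert short[0].duration_s == 55.0 and long[0].duration_s == 60.0


def test_no_walk_no_bouts():
    assert find_bouts(["nonwalk", "inactive"] * 5) == []


def test_gap_splits_bouts():
    bouts = find_bouts(["walk", "walk", "nonwalk", "walk"])
    assert [(b.start_epoch, b.n_epochs) for b in bouts] == [(0, 2), (3, 1)]
    assert all(b.category == "short" for b in bouts)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(st.lists(st.sampled_from(["walk", "nonwalk", "inactive"]),
                max_size=60))
def test_bouts_match_rle_oracle(labels):
    bouts = find_bouts(labels)
    assert [(b.start_epoch, b.n_epochs) for b in bouts] == _rle_oracle(labels)


def test_bouts_match_rle_oracle_bulk(rng):
    # high-volume randomized agreement check
    for _ in range(10_000):
        labels = rng.choice(["walk", "nonwalk", "inactive"],
                            size=rng.integers(0, 30))
        bouts = find_bouts(labels)
        assert [(b.start_epoch, b.n_epochs) for b in bouts] == _rle_oracle(labels)


@pytest.mark.parametrize("wear_h,valid", [(9.5, False), (10.0, True)])
def test_wear_time_validity_boundary(wear_h, valid):
    day = summarize_day(["nonwalk"] * 12, np.ones(12), wear_time_h=wear_h)
    assert day.valid is valid


def test_all_inactive_day_is_valid_and_empty():
    day = summarize_day(["inactive"] * 100, np.zeros(100), wear_time_h=12.0)
    assert day.valid
    assert day.activity_time_min == 0.0 and day.activity_counts == 0.0


def test_missing_day_invalid():
    day = summarize_day(["nonwalk"] * 12, np.ones(12), wear_time_h=12.0,
                        missing=True)
    assert not day.valid


def test_duplicate_epochs_rejected():
    with pytest.raises(Exception):
        summarize_day(["walk", "walk"], np.ones(2), wear_time_h=12.0,
                      indices=[3, 3])


def test_conservation_identities(rng):
    labels = rng.choice(["walk", "nonwalk", "inactive"], size=500)
    counts = rng.uniform(0, 2, 500)
    day = summarize_day(labels, counts, wear_time_h=12.0)
    assert day.walking_counts == day.counts["short_walk"] + day.counts["long_walk"]
    assert day.activity_counts == pytest.approx(
        counts[labels != "inactive"].sum(), abs=1e-9)
    assert day.activity_time_min == pytest.approx(
        (labels != "inactive").sum() * 5 / 60, abs=1e-12)
    # classified + inactive epochs tile the recording exactly
    total_min = labels.size * 5 / 60
    inactive_min = (labels == "inactive").sum() * 5 / 60
    assert day.activity_time_min + inactive_min == pytest.approx(total_min)


def test_nonwear_run_detection():
    # 2 h active, 1 h of exact zeros (>= 60 min run), 1 h active
    counts = np.concatenate([np.ones(1440), np.zeros(720), np.ones(720)])
    assert wear_time_from_counts(counts) == pytest.approx(3.0)
    # a 30-min zero run stays wear
    counts = np.concatenate([np.ones(1440), np.zeros(360), np.ones(720)])
    assert wear_time_from_counts(counts) == pytest.approx(3.5)


def _day(walk_kc, wear=12.0, valid=True):
    n = 120
    labels = ["walk"] * n
    counts = np.full(n, walk_kc * 1000.0 / n)
    return summarize_day(labels, counts,
                         wear_time_h=wear if valid else 5.0)


def test_subject_mean_over_valid_days():
    s = summarize_subject([_day(2.0), _day(3.0)], "a")
    assert s.walking_counts == pytest.approx(2500.0)
    assert s.n_valid_days == 2


def test_invalid_days_ignored_and_order_irrelevant():
    days = [_day(2.0), _day(9.0, valid=False), _day(3.0)]
    a = summarize_subject(days, "a")
    b = summarize_subject(days[::-1], "a")
    assert a.walking_counts == b.walking_counts == pytest.approx(2500.0)
    assert a.n_valid_days == 2


def test_zero_time_intensity_reported_missing():
    day = summarize_day(["nonwalk"] * 120, np.ones(120), wear_time_h=12.0)
    s = summarize_subject([day], "a")
    assert s.intensity["short_walk"] is None
    assert s.intensity["nonwalking"] == pytest.approx(1.0 / (5 / 60))


def test_no_valid_days_excludes_subject():
    with pytest.raises(NoValidDaysError):
        summarize_subject([_day(2.0, valid=False)], "a")


def _subject(nonwalk_min, nonwalk_counts, short_min=106.0, short_counts=2100.0,
             long_min=24.0, long_counts=600.0, sid="s"):
    return gp.SubjectSummary(
        subject_id=sid, n_valid_days=7,
        time_min={"nonwalking": nonwalk_min, "short_walk": short_min,
                  "long_walk": long_min},
        counts={"nonwalking": nonwalk_counts, "short_walk": short_counts,
                "long_walk": long_counts},
        intensity={c: None for c in CATEGORIES})


def test_cohort_identical_subjects_zero_sd():
    table = cohort_table([_subject(500.0, 3500.0, sid="a"),
                          _subject(500.0, 3500.0, sid="b")])
    assert table.loc["nonwalking_activity", "time_min_sd"] == 0.0
    assert table.loc["nonwalking_activity", "time_min_mean"] == 500.0
    assert table.loc["nonwalking_activity", "intensity_mean"] == pytest.approx(7.0)


def test_cohort_intensity_is_mean_of_ratios():
    a = _subject(100.0, 1000.0)   # 10 counts/min nonwalking
    b = _subject(100.0, 2000.0)   # 20 counts/min
    table = cohort_table([a, b])
    assert table.loc["nonwalking_activity", "intensity_mean"] == pytest.approx(15.0)


def test_cohort_needs_two_subjects():
    with pytest.raises(ParameterError):
        cohort_table([_subject(500.0, 3500.0)])
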