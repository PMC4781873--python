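"""Behavioral measures: direction coding, hit assignment, cell statistics."""
import numpy as np
import pytest
from scipy import stats as sps

import visuotactile as vt
from visuotactile.metrics import (
    COMPASS_TO_ANGLE,
    DIRECTIONS,
    InvalidDirectionError,
    UndefinedMetricError,
    angular_errors,
    gaze_screen,
)
from visuotactile.synthetic_data import CueEvent, ResponseEvent


# ---------------------------------------------------------------------------
# Signed angular error
# ---------------------------------------------------------------------------

def _brute_force_error(true_dir, resp_dir):
    """Oracle: pick, among all equivalent rotations, the one in (-180, 180]."""
    raw = COMPASS_TO_ANGLE[resp_dir] - COMPASS_TO_ANGLE[true_dir]
    candidates = [raw, raw - 360.0, raw + 360.0]
    return next(c for c in candidates if -180.0 < c <= 180.0)


def test_signed_error_agrees_with_rotation_oracle_on_all_pairs():
    for t in DIRECTIONS:
        for r in DIRECTIONS:
            assert vt.signed_angular_error(t, r) == _brute_force_error(t, r)


@pytest.mark.parametrize(
    "true_dir,resp_dir,expected",
    [("N", "E", 90.0), ("N", "W", -90.0), ("E", "E", 0.0), ("N", "S", 180.0),
     (8, 6, 90.0), (8, 4, -90.0)],
)
def test_signed_error_worked_examples(true_dir, resp_dir, expected):
    """Top cue answered with the right key is +90 deg; the left key, -90."""
    assert vt.signed_angular_error(true_dir, resp_dir) == expected


def test_signed_error_range_and_mirror_antisymmetry():
    """Errors take exactly the values {0, +-45, +-90, +-135, +180}; clockwise
    and counterclockwise deviations of the same size have opposite signs."""
    values = {vt.signed_angular_error(t, r) for t in DIRECTIONS for r in DIRECTIONS}
    assert values == {0.0, 45.0, -45.0, 90.0, -90.0, 135.0, -135.0, 180.0}
    for i, t in enumerate(DIRECTIONS):
        for step in (1, 2, 3):
            cw = vt.signed_angular_error(t, DIRECTIONS[(i + step) % 8])
            ccw = vt.signed_angular_error(t, DIRECTIONS[(i - step) % 8])
            assert cw == -ccw == 45.0 * step
        assert vt.signed_angular_error(t, t) == 0.0


@pytest.mark.parametrize("bad", [5, 0, "X", 10])
def test_signed_error_rejects_non_direction_inputs(bad):
    with pytest.raises(InvalidDirectionError):
        vt.signed_angular_error("N", bad)


# ---------------------------------------------------------------------------
# Hit assignment
# ---------------------------------------------------------------------------

def _cues(*onsets):
    return [CueEvent(t, "N", "VI") for t in onsets]


def _resps(*times):
    return [ResponseEvent(t, 8) for t in times]


def _brute_force_assign(cues, responses, trial_end):
    """Independent interval matcher built on searchsorted."""
    edges = [c.onset_s for c in cues] + [trial_end]
    out = []
    for i in range(len(cues)):
        lo, hi = edges[i], edges[i + 1]
        last = i == len(cues) - 1
        inside = sorted(
            (r for r in responses
             if ((lo <= r.time_s <= hi) if last else (lo <= r.time_s < hi))),
            key=lambda r: r.time_s,
        )
        out.append((cues[i], inside[0] if inside else None))
    return out


@pytest.mark.parametrize(
    "resp_times,expected_hits",
    [((1.4, 2.9), [True, True]),   # one response per window
     ((2.9,), [False, True]),      # empty first window
     ((1.2, 1.9), [True, False])],  # both in window 1: first taken, extra ignored
)
def test_assign_hits_window_rule(resp_times, expected_hits):
    pairs = vt.assign_hits(_cues(1.0, 2.5), _resps(*resp_times), trial_end_s=4.0)
    assert [r is not None for _, r in pairs] == expected_hits


def test_assign_hits_takes_first_response_in_window():
    pairs = vt.assign_hits(_cues(1.0, 2.5), _resps(1.9, 1.2), trial_end_s=4.0)
    assert pairs[0][1].time_s == 1.2


def test_assign_hits_discards_responses_outside_trial():
    pairs = vt.assign_hits(_cues(1.0, 2.5), _resps(0.5, 4.5), trial_end_s=4.0)
    assert all(r is None for _, r in pairs)


def test_assign_hits_requires_sorted_cues():
    with pytest.raises(ValueError, match="sorted"):
        vt.assign_hits(_cues(2.5, 1.0), [], trial_end_s=4.0)


def test_assign_hits_matches_brute_force_on_random_trials(rng):
    for _ in range(200):
        n_cues = int(rng.integers(1, 6))
        onsets = np.sort(rng.uniform(0, 9, n_cues))
        onsets += np.arange(n_cues) * 1.0  # enforce spacing
        cues = _cues(*onsets)
        responses = _resps(*rng.uniform(-1, 14, int(rng.integers(0, 8))))
        expected = _brute_force_assign(cues, responses, 13.0)
        assert vt.assign_hits(cues, responses, 13.0) == expected


# ---------------------------------------------------------------------------
# Cell statistics
# ---------------------------------------------------------------------------

def test_detection_performance_definition():
    pairs = vt.assign_hits(_cues(1.0, 2.5, 4.0, 5.5), _resps(1.1, 2.6, 4.1, 5.6), 7.0)
    assert vt.detection_performance(pairs) == 1.0
    pairs = vt.assign_hits(_cues(*np.arange(1.0, 6.0)), [], 7.0)
    assert vt.detection_performance(pairs) == 0.0
    with pytest.raises(UndefinedMetricError):
        vt.detection_performance([])


def test_detection_unaffected_by_response_direction():
    cues = _cues(1.0, 2.5)
    for key in (8, 2, 4, 6):
        pairs = vt.assign_hits(cues, [ResponseEvent(1.1, key), ResponseEvent(2.6, key)], 4.0)
        assert vt.detection_performance(pairs) == 1.0


def test_localization_accuracy_excludes_misses_from_denominator():
    """4 cues, 2 detected, 1 of those correct: accuracy is 0.5, not 0.25."""
    cues = _cues(1.0, 2.5, 4.0, 5.5)
    responses = [ResponseEvent(1.1, 8), ResponseEvent(2.6, 6)]  # correct, wrong
    pairs = vt.assign_hits(cues, responses, 7.0)
    assert vt.localization_accuracy(pairs) == 0.5
    with pytest.raises(UndefinedMetricError):
        vt.localization_accuracy(vt.assign_hits(cues, [], 7.0))


def test_error_variance_against_two_pass_oracle(rng):
    assert vt.error_variance([0, 0, 0, 0]) == 0.0
    assert vt.error_variance([45, -45]) == 4050.0
    errs = rng.choice([0, 45, -45, 90, -90, 135, -135, 180], size=50)
    mean = sum(errs) / len(errs)
    oracle = sum((e - mean) ** 2 for e in errs) / (len(errs) - 1)
    assert vt.error_variance(errs) == pytest.approx(oracle, rel=1e-12)
    assert vt.error_variance(-errs) == pytest.approx(oracle, rel=1e-12)  # sign flip
    with pytest.raises(UndefinedMetricError):
        vt.error_variance([45.0])


def test_median_search_time_midpoint_and_robustness(rng):
    assert vt.median_search_time([2, 4, 9]) == 4.0
    assert vt.median_search_time([2, 4]) == 3.0
    times = list(rng.lognormal(1.0, 0.4, 30)) + [100.0]
    med = vt.median_search_time(times)
    assert min(times) <= med <= max(times)
    assert vt.median_search_time(times[:-1] + [1000.0]) == med
    with pytest.raises(UndefinedMetricError):
        vt.median_search_time([])


def test_interference_and_reduction_arithmetic():
    assert vt.interference(7.0, 4.0) == 3.0
    assert vt.interference(3.0, 4.0) == -1.0
    assert vt.interference_reduction_pct(0.98, 2.96) == 33
    assert vt.interference_reduction_pct(0.0, 2.0) == 0
    with pytest.raises(UndefinedMetricError):
        vt.interference_reduction_pct(1.0, 0.0)


def test_search_accuracy_definition_and_chance_level(rng):
    assert vt.search_accuracy([True] * 10) == 1.0
    assert vt.search_accuracy([True] * 8 + [False] * 2) == 0.8
    flags = rng.random(1000) < 0.5
    acc = vt.search_accuracy(flags)
    assert abs(acc - 0.5) < 3 * np.sqrt(0.25 / 1000)


def test_gaze_screen_packaging_and_power(rng):
    import pandas as pd
    trials = pd.DataFrame({
        "subject_id": [1] * 4, "condition": ["VS"] * 4,
        "gaze_median_deg": [0.65] * 4,
    })
    out = gaze_screen(trials)
    assert out.loc[0, "mean_gaze_deg"] == pytest.approx(0.65)
    assert out.loc[0, "threshold_deg"] == 1.0
    # power: folded-normal(0.6, 0.1) medians, n=30, reject "gaze >= 1 deg"
    rejections = 0
    for _ in range(500):
        sample = np.abs(rng.normal(0.6, 0.1, 30))
        res = vt.one_sample_t(sample, 1.0)
        rejections += (res.t < 0) and (res.p < 0.05)
    assert rejections / 500 >= 0.99


def test_mean_rt_correct_examples_and_recovery(base_observer, rng):
    cues = _cues(1.0, 3.0)
    responses = [ResponseEvent(1.4, 8), ResponseEvent(3.6, 8)]
    assert vt.mean_rt_correct(vt.assign_hits(cues, responses, 5.0)) == pytest.approx(0.5)
    single = vt.assign_hits(_cues(1.0), [ResponseEvent(1.45, 8)], 3.0)
    assert vt.mean_rt_correct(single) == pytest.approx(0.45)
    with pytest.raises(UndefinedMetricError):
        vt.mean_rt_correct(vt.assign_hits(cues, [ResponseEvent(1.4, 2)], 5.0))
    # generator round trip: mean latency of correct responses recovers rt_mean_s
    import dataclasses
    obs = dataclasses.replace(base_observer, rt_mean_s=0.5, rt_sd_s=0.15)
    rts = []
    while len(rts) < 5000:
        r = vt.simulate_localization_response(CueEvent(0.0, "N", "VI"), obs, False, rng)
        if r is not None and vt.KEY_TO_COMPASS[r.key] == "N":
            rts.append(r.time_s)
    assert abs(np.mean(rts) - 0.5) < 3 * 0.15 / np.sqrt(len(rts))


# ---------------------------------------------------------------------------
# Summary table layout
# ---------------------------------------------------------------------------

def test_summary_leaves_irrelevant_fields_missing(cohort_summary):
    vs = cohort_summary[cohort_summary.condition == "VS"]
    assert vs["detection_performance"].isna().all()
    assert vs["median_search_time_s"].notna().all()
    vi = cohort_summary[cohort_summary.condition == "VI"]
    assert vi["median_search_time_s"].isna().all()
    assert vi["detection_performance"].notna().all()
    fracs = cohort_summary[["search_accuracy", "detection_performance",
                            "localization_accuracy"]].to_numpy(dtype=float)
    finite = fracs[np.isfinite(fracs)]
    assert ((0 <= finite) & (finite <= 1)).all()
    assert (cohort_summary["error_variance_deg2"].dropna() >= 0).all()


def test_summary_statistics_match_bruteforce_recount(cohort_trials, cohort_summary):
    """Cell statistics agree with an independent recomputation from the raw
    event lists for one subject x condition cell."""
    cell = cohort_trials[(cohort_trials.subject_id == 1) & (cohort_trials.condition == "VI")]
    pairs = []
    for _, row in cell.iterrows():
        pairs.extend(_brute_force_assign(row.cues, row.responses, 11.0))
    n_hits = sum(r is not None for _, r in pairs)
    det = n_hits / len(pairs)
    errs = [vt.signed_angular_error(c.direction, r.key) for c, r in pairs if r is not None]
    acc = sum(e == 0 for e in errs) / n_hits
    got = cohort_summary[(cohort_summary.subject_id == 1)
                         & (cohort_summary.condition == "VI")].iloc[0]
    assert got["detection_performance"] == pytest.approx(det)
    assert got["localization_accuracy"] == pytest.approx(acc)
    assert got["error_variance_deg2"] == pytest.approx(np.var(errs, ddof=1))


def test_interference_table_is_dual_minus_single(cohort_summary):
    table = vt.metrics.interference_table(cohort_summary)
    wide = cohort_summary.pivot(index="subject_id", columns="condition",
                                values="median_search_time_s")
    row = table[(table.subject_id == 3) & (table.condition == "TA+VS")].iloc[0]
    assert row["interference_s"] == pytest.approx(
        wide.loc[3, "TA+VS"] - wide.loc[3, "VS"])
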