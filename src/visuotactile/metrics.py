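"""Per-subject, per-condition behavioral measures for the dual-task experiment.

The experiment couples a self-terminated visual search task with a
localization task in which brief location cues (visual, tactile, or congruent
visuotactile) point in one of eight compass directions and the participant
answers on the numeric keypad. This module turns raw trial event streams
(cue onsets, keypress responses) into the derived measures the analysis
consumes: hit assignment, detection performance, localization accuracy,
signed angular error and its variance, median search times, dual-task
interference, search accuracy, gaze screening, and reaction times for
correct localizations.
"""
from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Direction coding: numpad key <-> compass label <-> angle.
# 0 deg = up (N), increasing clockwise. Key layout mirrors the spatial
# arrangement of the numeric keypad (8 = up, 6 = right, 2 = down, 4 = left,
# diagonals on 7/9/1/3).
# ---------------------------------------------------------------------------

KEY_TO_COMPASS = {8: "N", 9: "NE", 6: "E", 3: "SE", 2: "S", 1: "SW", 4: "W", 7: "NW"}
COMPASS_TO_KEY = {v: k for k, v in KEY_TO_COMPASS.items()}
COMPASS_TO_ANGLE = {
    "N": 0.0, "NE": 45.0, "E": 90.0, "SE": 135.0,
    "S": 180.0, "SW": 225.0, "W": 270.0, "NW": 315.0,
}
DIRECTIONS = tuple(COMPASS_TO_ANGLE)  # ordered clockwise from N


class InvalidDirectionError(ValueError):
    """A key or label outside the eight response directions."""


class UndefinedMetricError(ValueError):
    """A metric requested on a cell with no defining observations."""


def direction_angle(direction) -> float:
    """Angle in degrees (0 = up, clockwise) of a compass label or numpad key."""
    if isinstance(direction, str):
        try:
            return COMPASS_TO_ANGLE[direction]
        except KeyError:
            raise InvalidDirectionError(f"unknown compass direction {direction!r}")
    key = int(direction)
    if key not in KEY_TO_COMPASS:
        raise InvalidDirectionError(
            f"key {key} is not one of the eight direction keys {sorted(KEY_TO_COMPASS)}"
        )
    return COMPASS_TO_ANGLE[KEY_TO_COMPASS[key]]


def nearest_direction(angle_deg: float) -> str:
    """Compass label of the 45-degree sector containing ``angle_deg``."""
    idx = int(np.rint((angle_deg % 360.0) / 45.0)) % 8
    return DIRECTIONS[idx]


def signed_angular_error(true_dir, resp_dir) -> float:
    """Signed angular error of a response, clockwise positive.

    Both arguments may be compass labels or numpad keys. The error is
    wrapped to (-180, +180]; exact opposition returns +180 by convention.
    Values are confined to {0, +-45, +-90, +-135, +180} for 8-direction
    responses.
    """
    d = (direction_angle(resp_dir) - direction_angle(true_dir)) % 360.0
    if d > 180.0:
        d -= 360.0
    return d


# ---------------------------------------------------------------------------
# Hit assignment: pairing keypresses with the cue whose response window
# they fall into. A keypress recorded between the onsets of consecutive
# location cues counts as a hit for the earlier cue.
# ---------------------------------------------------------------------------

def assign_hits(cues: Sequence, responses: Sequence, trial_end_s: float) -> list:
    """Pair each cue with the first response in its window, or ``None``.

    The window of cue *i* is [onset_i, onset_{i+1}); the last cue's window
    extends to ``trial_end_s`` (inclusive). Additional responses inside a
    window are ignored; responses before the first onset (or after
    ``trial_end_s``) are discarded with a logged count.

    Parameters
    ----------
    cues : sequence of objects with ``onset_s``, sorted by onset
    responses : sequence of objects with ``time_s``
    trial_end_s : end of the trial's active interval (trial duration for
        localization-only trials, search termination for dual trials)
    """
    cues = list(cues)
    if any(b.onset_s <= a.onset_s for a, b in zip(cues, cues[1:])):
        raise ValueError("cues must be sorted by strictly increasing onset")
    responses = sorted(responses, key=lambda r: r.time_s)
    starts = [c.onset_s for c in cues]
    ends = starts[1:] + [trial_end_s]

    pairs = []
    discarded = sum(1 for r in responses if cues and r.time_s < starts[0])
    discarded += sum(1 for r in responses if r.time_s > trial_end_s)
    for cue, lo, hi in zip(cues, starts, ends):
        if hi == trial_end_s:  # last window: closed on the right
            inside = [r for r in responses if lo <= r.time_s <= hi]
        else:
            inside = [r for r in responses if lo <= r.time_s < hi]
        pairs.append((cue, inside[0] if inside else None))
    if discarded:
        logger.debug("assign_hits: discarded %d response(s) outside all windows", discarded)
    return pairs


def detection_performance(paired: Sequence) -> float:
    """Fraction of cues that drew any response, regardless of direction."""
    paired = list(paired)
    if not paired:
        raise UndefinedMetricError("detection performance undefined with zero cues")
    return sum(1 for _, r in paired if r is not None) / len(paired)


def _hit_pairs(paired):
    return [(c, r) for c, r in paired if r is not None]


def localization_accuracy(paired: Sequence) -> float:
    """Among detected cues, fraction whose response matched the cue direction.

    Misses are excluded from the denominator; zero hits is undefined (raised),
    never reported as 0.
    """
    hits = _hit_pairs(paired)
    if not hits:
        raise UndefinedMetricError("localization accuracy undefined with zero hits")
    correct = sum(1 for c, r in hits if signed_angular_error(c.direction, r.key) == 0.0)
    return correct / len(hits)


def angular_errors(paired: Sequence) -> list:
    """Signed angular errors of all detected cues (correct responses give 0)."""
    return [signed_angular_error(c.direction, r.key) for c, r in _hit_pairs(paired)]


def error_variance(errors: Iterable[float]) -> float:
    """Sample variance (n-1 denominator) of signed angular errors, deg^2."""
    errors = np.asarray(list(errors), dtype=float)
    if errors.size < 2:
        raise UndefinedMetricError("error variance needs >= 2 paired responses")
    return float(np.var(errors, ddof=1))


def median_search_time(times_s: Iterable[float]) -> float:
    """Median search time; even counts use midpoint interpolation."""
    times = np.asarray(list(times_s), dtype=float)
    if times.size == 0:
        raise UndefinedMetricError("median search time undefined on an empty cell")
    return float(np.median(times))


def interference(dual_median_s: float, single_median_s: float) -> float:
    """Dual-task cost on search time: dual minus single-task median (s)."""
    return dual_median_s - single_median_s


def interference_reduction_pct(visual_dual_diff_s: float, overall_interference_s: float) -> int:
    """Percent of the overall interference removed by moving the localization
    task out of the visual modality, rounded to the nearest integer."""
    if overall_interference_s == 0:
        raise UndefinedMetricError("interference reduction undefined for zero overall interference")
    return int(round(100.0 * visual_dual_diff_s / overall_interference_s))


def search_accuracy(correct_flags: Iterable[bool]) -> float:
    """Fraction of search trials with a correct present/absent judgment."""
    flags = list(correct_flags)
    if not flags:
        raise UndefinedMetricError("search accuracy undefined on an empty cell")
    return sum(bool(f) for f in flags) / len(flags)


def mean_rt_correct(paired: Sequence) -> float:
    """Mean reaction time (response time minus cue onset) over correctly
    localized cues only."""
    rts = [
        r.time_s - c.onset_s
        for c, r in _hit_pairs(paired)
        if signed_angular_error(c.direction, r.key) == 0.0
    ]
    if not rts:
        raise UndefinedMetricError("no correctly localized cues in cell")
    return float(np.mean(rts))


def gaze_screen(trials: pd.DataFrame, threshold_deg: float = 1.0,
                conditions: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per subject x condition mean of per-trial median gaze deviations.

    Returns a tidy frame (subject_id, condition, mean_gaze_deg, threshold_deg)
    ready for one-sample t-tests against ``threshold_deg`` (testing whether
    gaze stayed within one visual degree of the screen center).
    """
    if "gaze_median_deg" not in trials.columns:
        logger.warning("gaze_screen: no gaze_median_deg column; skipping")
        return pd.DataFrame(columns=["subject_id", "condition", "mean_gaze_deg", "threshold_deg"])
    df = trials
    if conditions is not None:
        df = df[df["condition"].isin(conditions)]
    out = (
        df.dropna(subset=["gaze_median_deg"])
        .groupby(["subject_id", "condition"], sort=True)["gaze_median_deg"]
        .mean()
        .rename("mean_gaze_deg")
        .reset_index()
    )
    out["threshold_deg"] = threshold_deg
    return out


# ---------------------------------------------------------------------------
# Cell-level summary over a trial table.
# ---------------------------------------------------------------------------

SEARCH_CONDITIONS = ("VS", "VI+VS", "TA+VS", "VITA+VS")
LOCALIZATION_CONDITIONS = ("VI", "TA", "VITA", "VI+VS", "TA+VS", "VITA+VS")


def _trial_pairs(row, trial_duration_s: float) -> list:
    end = row["search_time_s"] if pd.notna(row.get("search_time_s")) else trial_duration_s
    return assign_hits(row["cues"], row["responses"], end)


def summarize(trials: pd.DataFrame, trial_duration_s: float = 11.0) -> pd.DataFrame:
    """Condense a trial table into one row per subject x condition.

    Localization measures pool the cue/response pairs of all trials in the
    cell before computing rates and variances. Fields irrelevant to a
    condition (e.g. search time for a localization-only block) are left
    missing, never zero-filled. Cells whose measures are undefined (e.g.
    fewer than two detected cues for a variance) are flagged missing with a
    logged count.
    """
    rows = []
    n_flagged = 0
    for (subject, condition), cell in trials.groupby(["subject_id", "condition"], sort=True):
        rec = {"subject_id": subject, "condition": condition}
        if condition in SEARCH_CONDITIONS:
            times = cell["search_time_s"].astype(float)
            rec["median_search_time_s"] = median_search_time(times)
            present = cell["target_present"].astype(bool)
            for label, mask in (("present", present), ("absent", ~present)):
                sub = times[mask]
                rec[f"median_search_time_{label}_s"] = (
                    median_search_time(sub) if len(sub) else np.nan
                )
            rec["search_accuracy"] = search_accuracy(cell["search_response_correct"].astype(bool))
        if condition in LOCALIZATION_CONDITIONS:
            pairs = []
            for _, row in cell.iterrows():
                pairs.extend(_trial_pairs(row, trial_duration_s))
            try:
                rec["detection_performance"] = detection_performance(pairs)
            except UndefinedMetricError:
                n_flagged += 1
            try:
                rec["localization_accuracy"] = localization_accuracy(pairs)
                rec["mean_rt_correct_s"] = mean_rt_correct(pairs)
            except UndefinedMetricError:
                n_flagged += 1
            try:
                rec["error_variance_deg2"] = error_variance(angular_errors(pairs))
            except UndefinedMetricError:
                n_flagged += 1
        if "gaze_median_deg" in cell.columns and cell["gaze_median_deg"].notna().any():
            rec["median_gaze_deg"] = float(cell["gaze_median_deg"].mean())
        rows.append(rec)
    if n_flagged:
        logger.info("summarize: %d cell measure(s) undefined and left missing", n_flagged)
    columns = [
        "subject_id", "condition", "median_search_time_s",
        "median_search_time_present_s", "median_search_time_absent_s",
        "search_accuracy", "detection_performance", "localization_accuracy",
        "error_variance_deg2", "mean_rt_correct_s", "median_gaze_deg",
    ]
    return pd.DataFrame(rows).reindex(columns=columns)


def interference_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-subject dual-task interference: dual-condition median search time
    minus the single-task (search-alone) median, for each dual condition."""
    wide = summary.pivot(index="subject_id", columns="condition",
                         values="median_search_time_s")
    if "VS" not in wide.columns:
        raise UndefinedMetricError("interference needs the search-alone (VS) condition")
    rows = []
    for cond in ("VI+VS", "TA+VS", "VITA+VS"):
        if cond not in wide.columns:
            continue
        for subject, row in wide.iterrows():
            rows.append({
                "subject_id": subject,
                "condition": cond,
                "interference_s": interference(row[cond], row["VS"]),
            })
    return pd.DataFrame(rows)
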