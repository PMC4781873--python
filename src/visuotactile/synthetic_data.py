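"""Synthetic observers for the dual-task visuotactile experiment.

Generates experiment-shaped trial tables with the statistical structure the
analysis assumes: 7 conditions (localization alone in the visual, tactile or
visuotactile modality; visual search alone; and the three dual-task
pairings), blocks of trials with a Latin-square-like condition schedule,
location-cue schedules with a minimum inter-onset gap, 8-direction keypad
responses, and a serial self-terminating search process.

Generative model, in the order a trial unfolds:

* Location cues point in one of 8 compass directions; onsets are uniform
  within the trial subject to a minimum gap between onsets, 4-5 cues per
  11 s localization trial (pro rata for longer search intervals, since cues
  continue for as long as the observer is still searching).
* Each cue is detected with a per-modality probability (reduced additively
  under dual-task load). A detected cue draws a response direction from a
  von Mises distribution centered on the true direction, discretized to the
  nearest of the 8 directions, and a lognormal response latency.
* Under the fusion integration mode, the bimodal (visuotactile) von Mises
  concentration is the sum of the unimodal concentrations — the generative
  analogue of reliability-weighted (MLE) cue combination, in which
  precisions add. The ``best_cue`` mode instead pins bimodal precision to
  the better unimodal cue, a non-integrating control.
* Visual search is serial and self-terminating over ``n_search_items``
  items with exponential per-item inspection times; concurrent localization
  adds a per-item slowdown that depends on the localization modality.
* Per-trial gaze deviation summaries are folded-normal draws.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import COMPASS_TO_ANGLE, COMPASS_TO_KEY, DIRECTIONS, nearest_direction

CONDITIONS = ("VI", "TA", "VITA", "VS", "VI+VS", "TA+VS", "VITA+VS")
MODALITIES = ("VI", "TA", "VITA")


def condition_parts(condition: str):
    """Split a condition label into (localization modality or None, has_search)."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition label {condition!r}")
    if condition == "VS":
        return None, True
    if condition.endswith("+VS"):
        return condition[:-3], True
    return condition, False


# ---------------------------------------------------------------------------
# Design and observer parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignSpec:
    """Experimental design parameters.

    Defaults reproduce the reference design: 12 subjects, 21 blocks of 10
    trials covering 7 conditions (each consecutive set of 7 blocks contains
    every condition once, with no condition repeated across adjacent
    blocks), 11 s localization trials carrying 4-5 location cues of 600 ms
    duration separated by at least 1 s, and a 20-item search display with
    the target present on half the trials.
    """

    n_subjects: int = 12
    n_blocks: int = 21
    trials_per_block: int = 10
    conditions: Sequence[str] = CONDITIONS
    trial_duration_s: float = 11.0
    cue_duration_s: float = 0.6
    min_gap_s: float = 1.0
    cues_per_trial: tuple = (4, 5)
    n_search_items: int = 20
    p_target_present: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if sorted(self.conditions) != sorted(CONDITIONS):
            raise ValueError(f"conditions must be a permutation of {CONDITIONS}")
        if self.n_blocks % len(self.conditions) != 0:
            raise ValueError("n_blocks must be a multiple of the number of conditions")
        if not (self.cue_duration_s < self.min_gap_s <= self.trial_duration_s):
            raise ValueError("need cue_duration_s < min_gap_s <= trial_duration_s")
        lo, hi = self.cues_per_trial
        if not (1 <= lo <= hi):
            raise ValueError("cues_per_trial must be an increasing range of counts >= 1")
        if not 0.0 <= self.p_target_present <= 1.0:
            raise ValueError("p_target_present must be a probability")
        for name in ("n_subjects", "n_blocks", "trials_per_block", "n_search_items"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")


def _default_p_detect():
    return {"VI": 0.92, "TA": 0.90, "VITA": 0.95}


def _default_kappa():
    return {"VI": 6.0, "TA": 3.0}


def _default_item_penalty():
    return {"VI": 0.20, "TA": 0.12, "VITA": 0.12}


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one synthetic observer.

    Angular reliability is a von Mises concentration ``kappa`` per modality;
    under the default ``fusion`` mode the visuotactile concentration is
    ``kappa_VI + kappa_TA`` (precision summation — the generative analogue
    of optimal cue combination), while ``best_cue`` pins it to
    ``max(kappa_VI, kappa_TA)`` as a non-integrating control. Dual-task
    load subtracts ``dual_detect_penalty`` from the detection probability
    and multiplies every concentration by ``dual_kappa_factor``.
    """

    p_detect: dict = field(default_factory=_default_p_detect)
    kappa: dict = field(default_factory=_default_kappa)
    dual_detect_penalty: float = 0.18
    dual_kappa_factor: float = 0.7
    base_item_time_s: float = 0.25
    dual_item_penalty_s: dict = field(default_factory=_default_item_penalty)
    p_miss_target: float = 0.10
    rt_mean_s: float = 0.55
    rt_sd_s: float = 0.15
    gaze_sd_deg: float = 0.78
    integration: str = "fusion"

    def __post_init__(self):
        for m in MODALITIES:
            p = self.p_detect.get(m)
            if p is None or not 0.0 <= p <= 1.0:
                raise ValueError(f"p_detect[{m!r}] must be a probability")
        for m in ("VI", "TA"):
            if self.kappa.get(m, -1.0) < 0.0:
                raise ValueError(f"kappa[{m!r}] must be >= 0")
        if not 0.0 <= self.dual_detect_penalty <= 1.0:
            raise ValueError("dual_detect_penalty must be in [0, 1]")
        if not 0.0 < self.dual_kappa_factor <= 1.0:
            raise ValueError("dual_kappa_factor must be in (0, 1]")
        for name in ("base_item_time_s", "rt_mean_s", "rt_sd_s", "gaze_sd_deg"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.p_miss_target <= 1.0:
            raise ValueError("p_miss_target must be a probability")
        if self.integration not in ("fusion", "best_cue"):
            raise ValueError("integration must be 'fusion' or 'best_cue'")

    def effective_kappa(self, modality: str, dual: bool) -> float:
        if modality == "VITA":
            if self.integration == "fusion":
                k = self.kappa["VI"] + self.kappa["TA"]
            else:
                k = max(self.kappa["VI"], self.kappa["TA"])
        else:
            k = self.kappa[modality]
        return k * (self.dual_kappa_factor if dual else 1.0)


# ---------------------------------------------------------------------------
# Event and trial records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CueEvent:
    """One location-cue presentation."""

    onset_s: float
    direction: str  # compass label, one of DIRECTIONS
    modality: str  # VI, TA or VITA
    duration_s: float = 0.6


@dataclass(frozen=True)
class ResponseEvent:
    """One keypad response."""

    time_s: float
    key: int  # numpad key in {1, 2, 3, 4, 6, 7, 8, 9}


@dataclass
class TrialRecord:
    subject_id: int
    block: int
    trial: int
    condition: str
    target_present: Optional[bool]
    search_time_s: Optional[float]
    search_response_correct: Optional[bool]
    cues: list
    responses: list
    gaze_median_deg: float


# ---------------------------------------------------------------------------
# Cue scheduling
# ---------------------------------------------------------------------------

def generate_cue_schedule(design: DesignSpec, active_duration_s: float, rng,
                          *, modality: str = "VI",
                          n_range: Optional[tuple] = None) -> list:
    """Random cue schedule over an active interval.

    Onsets are uniform on the feasible region defined by the minimum gap
    between onsets and the requirement that the last cue end within the
    interval. The cue count is drawn uniformly from ``n_range`` if given;
    otherwise from the design's per-trial range, scaled pro rata when the
    active interval differs from the nominal trial duration (cues keep
    arriving for as long as the observer searches) and capped at what the
    interval can hold.

    Raises ``ValueError`` when an explicitly requested count cannot fit.
    """
    gap, dur = design.min_gap_s, design.cue_duration_s
    if active_duration_s >= dur:
        max_feasible = int(math.floor((active_duration_s - dur) / gap)) + 1
    else:
        max_feasible = 0
    if n_range is not None:
        lo, hi = n_range
        if lo > max_feasible:
            raise ValueError(
                f"cannot fit {lo} cues with gap {gap} s and duration {dur} s "
                f"into {active_duration_s} s"
            )
        hi = min(hi, max_feasible)
    else:
        # pro rata with the nominal trial duration, capped by feasibility
        frac = active_duration_s / design.trial_duration_s
        lo = int(math.floor(design.cues_per_trial[0] * frac))
        hi = int(math.floor(design.cues_per_trial[1] * frac))
        lo, hi = min(lo, max_feasible), min(hi, max_feasible)
    if hi < 1:
        return []
    lo = max(lo, 1)
    n = int(rng.integers(lo, hi + 1))
    slack = active_duration_s - (n - 1) * gap - dur
    onsets = np.sort(rng.uniform(0.0, slack, size=n)) + np.arange(n) * gap
    dirs = rng.integers(0, 8, size=n)
    return [
        CueEvent(float(t), DIRECTIONS[d], modality, dur)
        for t, d in zip(onsets, dirs)
    ]


# ---------------------------------------------------------------------------
# Localization responses
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, sd: float):
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def simulate_localization_response(cue: CueEvent, obs: ObserverParams, dual: bool,
                                   rng) -> Optional[ResponseEvent]:
    """Simulate the keypad response to one location cue, or ``None`` for a miss.

    Detection succeeds with the modality's probability (minus the dual-task
    penalty under load). The response direction is the true direction plus
    von Mises angular noise, binned to the nearest of the 8 directions; the
    latency from cue onset is lognormal.
    """
    p = obs.p_detect[cue.modality] - (obs.dual_detect_penalty if dual else 0.0)
    p = min(max(p, 0.0), 1.0)
    if rng.random() >= p:
        return None
    kappa = obs.effective_kappa(cue.modality, dual)
    if math.isinf(kappa):
        noise_deg = 0.0
    else:
        noise_deg = math.degrees(rng.vonmises(0.0, kappa))
    resp_dir = nearest_direction(COMPASS_TO_ANGLE[cue.direction] + noise_deg)
    mu, sigma = _lognormal_params(obs.rt_mean_s, obs.rt_sd_s)
    latency = float(rng.lognormal(mu, sigma))
    return ResponseEvent(cue.onset_s + latency, COMPASS_TO_KEY[resp_dir])


# ---------------------------------------------------------------------------
# Visual search
# ---------------------------------------------------------------------------

def simulate_search_trial(condition: str, obs: ObserverParams, design: DesignSpec, rng):
    """Serial self-terminating search through the display.

    Items are inspected one at a time with exponential inspection times whose
    mean is ``base_item_time_s`` plus the per-item dual-task penalty of the
    concurrent localization modality (if any). Search stops when the target
    is found (hit) or the display is exhausted (correct rejection when the
    target is absent; miss when a present target was overlooked, which
    happens with probability ``p_miss_target`` at its inspection).

    Returns ``(search_time_s, target_present, search_response_correct)``.
    """
    loc_mod, has_search = condition_parts(condition)
    if not has_search:
        raise ValueError(f"{condition!r} is not a search condition")
    mean_item = obs.base_item_time_s
    if loc_mod is not None:
        mean_item += obs.dual_item_penalty_s[loc_mod]
    times = rng.exponential(mean_item, size=design.n_search_items)
    target_present = bool(rng.random() < design.p_target_present)
    if target_present:
        pos = int(rng.integers(design.n_search_items))
        found = rng.random() >= obs.p_miss_target
        if found:
            return float(times[: pos + 1].sum()), True, True
        return float(times.sum()), True, False  # overlooked -> judged absent
    return float(times.sum()), False, True


# ---------------------------------------------------------------------------
# Block schedule and full experiment
# ---------------------------------------------------------------------------

def block_conditions(design: DesignSpec, rng) -> list:
    """Pseudorandom block order: every consecutive set of 7 blocks contains
    all 7 conditions, and no condition repeats across adjacent blocks."""
    conds = list(design.conditions)
    n_sets = design.n_blocks // len(conds)
    order = []
    for _ in range(n_sets):
        while True:
            perm = [conds[i] for i in rng.permutation(len(conds))]
            if not order or perm[0] != order[-1]:
                order.extend(perm)
                break
    return order


def _simulate_trial(subject_id, block, trial, condition, obs, design, rng):
    loc_mod, has_search = condition_parts(condition)
    target_present = search_time = search_correct = None
    cues, responses = [], []
    if has_search:
        search_time, target_present, search_correct = simulate_search_trial(
            condition, obs, design, rng
        )
    if loc_mod is not None:
        if has_search:
            cues = generate_cue_schedule(design, search_time, rng, modality=loc_mod)
        else:
            cues = generate_cue_schedule(
                design, design.trial_duration_s, rng, modality=loc_mod,
                n_range=design.cues_per_trial,
            )
        for cue in cues:
            resp = simulate_localization_response(cue, obs, has_search, rng)
            if resp is not None:
                responses.append(resp)
    gaze = abs(float(rng.normal(0.0, obs.gaze_sd_deg)))
    return TrialRecord(subject_id, block, trial, condition, target_present,
                       search_time, search_correct, cues, responses, gaze)


def subject_rng(seed: int, subject_index: int):
    """Independent, reproducible per-subject stream from one master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(subject_index,)))


def generate_experiment(design: DesignSpec, observers: Sequence[ObserverParams],
                        seed: Optional[int] = None) -> pd.DataFrame:
    """Simulate the full cohort and return a long-format trial table.

    One row per trial with columns subject_id, block, trial, condition,
    target_present, search_time_s, search_response_correct, cues, responses
    (lists of :class:`CueEvent` / :class:`ResponseEvent`) and
    gaze_median_deg. Deterministic given the seed; subjects use independent
    substreams so any one subject is reproducible in isolation.
    """
    if len(observers) != design.n_subjects:
        raise ValueError(
            f"need one ObserverParams per subject: got {len(observers)} "
            f"for {design.n_subjects} subjects"
        )
    if seed is None:
        seed = design.seed
    records = []
    for s, obs in enumerate(observers):
        rng = subject_rng(seed, s)
        order = block_conditions(design, rng)
        for b, condition in enumerate(order, start=1):
            for t in range(1, design.trials_per_block + 1):
                records.append(_simulate_trial(s + 1, b, t, condition, obs, design, rng))
    return records_to_frame(records)


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records])
    if df.empty:
        df = pd.DataFrame(columns=list(TrialRecord.__annotations__))
    return df


def default_observers(design: DesignSpec, base: Optional[ObserverParams] = None,
                      heterogeneity: float = 0.15,
                      seed: Optional[int] = None) -> list:
    """A cohort of observers jittered around ``base``.

    Multiplicative lognormal jitter (coefficient of variation
    ``heterogeneity``) on the concentrations and item times yields the
    between-subject variability a repeated-measures analysis expects; the
    jitter preserves the integration mode, so fusion cohorts stay fusion
    cohorts.
    """
    base = base or ObserverParams()
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(987654321,)))
    mu, sigma = _lognormal_params(1.0, heterogeneity)
    cohort = []
    for _ in range(design.n_subjects):
        jit = lambda v: float(v * rng.lognormal(mu, sigma))  # noqa: E731
        # iterate keys in sorted order so the draw-to-parameter assignment is
        # independent of dict insertion order (e.g. after a config round trip)
        cohort.append(replace(
            base,
            kappa={m: jit(base.kappa[m]) for m in sorted(base.kappa)},
            base_item_time_s=jit(base.base_item_time_s),
            dual_item_penalty_s={m: jit(base.dual_item_penalty_s[m])
                                 for m in sorted(base.dual_item_penalty_s)},
            rt_mean_s=jit(base.rt_mean_s),
        ))
    return cohort
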