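"""Optimal (maximum-likelihood) cue-integration prediction and assessment.

When two senses provide redundant estimates of the same quantity, the
reliability-weighted (MLE) combination has variance

    sigma2_bimodal = sigma2_v * sigma2_t / (sigma2_v + sigma2_t),

which is below the variance of either unimodal estimate alone. This module
evaluates that prediction and compares it with the observed bimodal
(visuotactile) variance of signed angular localization errors, separately
under single-task and dual-task load: unimodal variances measured under a
given load predict the bimodal variance under the same load.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as vtstats

logger = logging.getLogger(__name__)

#: condition labels supplying (visual, tactile, bimodal) variances per load
LOAD_CONDITIONS = {
    "single": ("VI", "TA", "VITA"),
    "dual": ("VI+VS", "TA+VS", "VITA+VS"),
}


@dataclass(frozen=True)
class CueVarianceTriple:
    """Per-subject variances entering the optimality assessment (deg^2)."""

    subject_id: int
    load: str  # 'single' or 'dual'
    sigma2_visual: float
    sigma2_tactile: float
    sigma2_visuotactile_observed: float

    def __post_init__(self):
        if self.load not in LOAD_CONDITIONS:
            raise ValueError(f"load must be one of {tuple(LOAD_CONDITIONS)}")
        for name in ("sigma2_visual", "sigma2_tactile", "sigma2_visuotactile_observed"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def mle_predicted_variance(sigma2_v: float, sigma2_t: float) -> float:
    """Variance of the optimally fused estimate from two unimodal variances.

    Both inputs in deg^2 (or any common unit); the result is in the same
    unit and satisfies max(a, b)/2 <= prediction <= min(a, b).
    """
    if sigma2_v < 0 or sigma2_t < 0:
        raise ValueError("variances must be non-negative")
    if sigma2_v == 0 and sigma2_t == 0:
        raise ValueError("prediction undefined when both variances are zero")
    return sigma2_v * sigma2_t / (sigma2_v + sigma2_t)


def triples_from_summary(summary: pd.DataFrame) -> list:
    """Extract per-subject variance triples for both load levels from a
    subject x condition summary table. Subjects with any missing variance
    cell are dropped with a logged count."""
    wide = summary.pivot(index="subject_id", columns="condition",
                         values="error_variance_deg2")
    triples = []
    n_dropped = 0
    for load, (c_v, c_t, c_vt) in LOAD_CONDITIONS.items():
        for subject, row in wide.iterrows():
            vals = [row.get(c) for c in (c_v, c_t, c_vt)]
            if any(v is None or np.isnan(v) for v in vals):
                n_dropped += 1
                continue
            triples.append(CueVarianceTriple(subject, load, *map(float, vals)))
    if n_dropped:
        logger.info("triples_from_summary: %d subject-load cell(s) missing, dropped",
                    n_dropped)
    return triples


def optimality_assessment(triples) -> tuple:
    """Compare observed bimodal variance against the MLE prediction, per load.

    Returns ``(per_subject, group)`` frames. ``per_subject`` carries, for
    each subject and load, the unimodal variances, the prediction, the
    observed bimodal variance, the observed/predicted ratio, and the weaker
    qualitative criterion (observed below both unimodal variances).
    ``group`` aggregates each load level: mean predicted and observed
    variance, their ratio of means and mean ratio, the fraction of subjects
    meeting the qualitative criterion, and a paired t-test of observed vs.
    predicted (a formal extension of the usual descriptive comparison).
    """
    rows = []
    for tr in triples:
        pred = mle_predicted_variance(tr.sigma2_visual, tr.sigma2_tactile)
        rows.append({
            "subject_id": tr.subject_id,
            "load": tr.load,
            "sigma2_visual": tr.sigma2_visual,
            "sigma2_tactile": tr.sigma2_tactile,
            "sigma2_predicted": pred,
            "sigma2_observed": tr.sigma2_visuotactile_observed,
            "ratio_obs_pred": tr.sigma2_visuotactile_observed / pred,
            "below_both_unimodal": tr.sigma2_visuotactile_observed
            < min(tr.sigma2_visual, tr.sigma2_tactile),
        })
    per_subject = pd.DataFrame(rows)
    group_rows = []
    for load, sub in per_subject.groupby("load", sort=True):
        obs, pred = sub["sigma2_observed"].to_numpy(), sub["sigma2_predicted"].to_numpy()
        rec = {
            "load": load,
            "n_subjects": len(sub),
            "mean_observed": obs.mean(),
            "mean_predicted": pred.mean(),
            "ratio_of_means": obs.mean() / pred.mean(),
            "mean_ratio": sub["ratio_obs_pred"].mean(),
            "frac_below_both_unimodal": sub["below_both_unimodal"].mean(),
        }
        if len(sub) >= 2 and np.var(obs - pred) > 0:
            t = vtstats.paired_t(obs, pred)
            rec.update(t_obs_vs_pred=t.t, df=t.df, p_obs_vs_pred=t.p)
        group_rows.append(rec)
    return per_subject, pd.DataFrame(group_rows)
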