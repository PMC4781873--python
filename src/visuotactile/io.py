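"""Configuration, trial-table I/O, and the end-to-end analysis pipeline.

The trial table travels as long-format CSV: one row per trial, with the
cue and response event lists serialized as JSON strings in dedicated
columns so the schema stays inspectable with ordinary tabular tools.
Configuration is YAML with strict (unknown-key rejecting) parsing, and a
run writes a manifest carrying the seed and a hash of the canonical config
so identical runs are identical artifacts.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cue_integration, metrics
from . import stats as vtstats
from .synthetic_data import (
    CONDITIONS,
    CueEvent,
    DesignSpec,
    ObserverParams,
    ResponseEvent,
    default_observers,
    generate_experiment,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

TRIAL_COLUMNS = [
    "subject_id", "block", "trial", "condition", "target_present",
    "search_time_s", "search_response_correct", "cues", "responses",
    "gaze_median_deg",
]

#: condition layout of the 2 (task) x 3 (modality) localization analyses,
#: task-major with modality varying fastest
TASK_MODALITY_CELLS = ["VI", "TA", "VITA", "VI+VS", "TA+VS", "VITA+VS"]


# ---------------------------------------------------------------------------
# Trial-table CSV round trip
# ---------------------------------------------------------------------------

def write_trial_table(trials: pd.DataFrame, path) -> None:
    """Write a trial table as CSV with JSON-encoded event columns."""
    df = trials.loc[:, TRIAL_COLUMNS].copy()
    df["cues"] = [json.dumps([dataclasses.asdict(e) for e in evs]) for evs in df["cues"]]
    df["responses"] = [
        json.dumps([dataclasses.asdict(e) for e in evs]) for evs in df["responses"]
    ]
    df.to_csv(path, index=False)


def _parse_bool(value, row: int, column: str):
    if pd.isna(value):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if str(value) in ("True", "False"):
        return str(value) == "True"
    raise ValueError(f"row {row}: column {column!r} has non-boolean value {value!r}")


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV written by :func:`write_trial_table`
    (or user data in the same schema). Schema violations name the offending
    row (1-based, counting the header as row 1)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table is missing required column(s) {missing}")
    if df.empty:
        return df.loc[:, TRIAL_COLUMNS]
    df = df.loc[:, TRIAL_COLUMNS]

    bad = [i + 2 for i, c in enumerate(df["condition"]) if c not in CONDITIONS]
    if bad:
        raise ValueError(f"unknown condition label(s) at row(s) {bad}")

    def _events(cell, row, cls, column):
        if pd.isna(cell) or cell == "":
            return []
        try:
            return [cls(**d) for d in json.loads(cell)]
        except (json.JSONDecodeError, TypeError) as exc:
            raise ValueError(f"row {row}: malformed {column} events: {exc}") from exc

    df["cues"] = [
        _events(c, i + 2, CueEvent, "cues") for i, c in enumerate(df["cues"])
    ]
    df["responses"] = [
        _events(c, i + 2, ResponseEvent, "responses")
        for i, c in enumerate(df["responses"])
    ]
    for col in ("target_present", "search_response_correct"):
        df[col] = [
            _parse_bool(v, i + 2, col) for i, v in enumerate(df[col])
        ]
        df[col] = df[col].astype(object)
    df["search_time_s"] = pd.to_numeric(df["search_time_s"], errors="raise")
    return df


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

def _check_keys(d: dict, allowed, context: str):
    unknown = set(d) - set(allowed)
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {context}")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs: design, observer parameters, analysis options
    and the master seed. Round-trips losslessly through YAML."""

    design: DesignSpec = field(default_factory=DesignSpec)
    observer_defaults: ObserverParams = field(default_factory=ObserverParams)
    heterogeneity: float = 0.15
    per_subject: dict = field(default_factory=dict)
    alpha: float = 0.05
    variance_tolerance: float = 0.10
    gaze_threshold_deg: float = 1.0
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        _check_keys(d, {"design", "observers", "analysis", "seed"}, "config")
        design_d = dict(d.get("design", {}))
        _check_keys(design_d, {f.name for f in dataclasses.fields(DesignSpec)},
                    "config.design")
        for key in ("conditions", "cues_per_trial"):
            if key in design_d:
                design_d[key] = tuple(design_d[key])
        obs_d = dict(d.get("observers", {}))
        _check_keys(obs_d, {"defaults", "heterogeneity", "per_subject"},
                    "config.observers")
        defaults_d = dict(obs_d.get("defaults", {}))
        _check_keys(defaults_d, {f.name for f in dataclasses.fields(ObserverParams)},
                    "config.observers.defaults")
        per_subject = {int(k): dict(v) for k, v in (obs_d.get("per_subject") or {}).items()}
        for sid, over in per_subject.items():
            _check_keys(over, {f.name for f in dataclasses.fields(ObserverParams)},
                        f"config.observers.per_subject[{sid}]")
        ana = dict(d.get("analysis", {}))
        _check_keys(ana, {"alpha", "variance_tolerance", "gaze_threshold_deg"},
                    "config.analysis")
        return cls(
            design=DesignSpec(**design_d),
            observer_defaults=ObserverParams(**defaults_d),
            heterogeneity=float(obs_d.get("heterogeneity", 0.15)),
            per_subject=per_subject,
            alpha=float(ana.get("alpha", 0.05)),
            variance_tolerance=float(ana.get("variance_tolerance", 0.10)),
            gaze_threshold_deg=float(ana.get("gaze_threshold_deg", 1.0)),
            seed=int(d.get("seed", 0)),
        )

    def to_dict(self) -> dict:
        design = dataclasses.asdict(self.design)
        design["conditions"] = list(design["conditions"])
        design["cues_per_trial"] = list(design["cues_per_trial"])
        return {
            "seed": self.seed,
            "design": design,
            "observers": {
                "defaults": dataclasses.asdict(self.observer_defaults),
                "heterogeneity": self.heterogeneity,
                "per_subject": {k: dict(v) for k, v in self.per_subject.items()},
            },
            "analysis": {
                "alpha": self.alpha,
                "variance_tolerance": self.variance_tolerance,
                "gaze_threshold_deg": self.gaze_threshold_deg,
            },
        }

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()

    def observers(self) -> list:
        cohort = default_observers(self.design, self.observer_defaults,
                                   self.heterogeneity, self.seed)
        for sid, over in self.per_subject.items():
            if not 1 <= sid <= len(cohort):
                raise ValueError(f"per_subject override for unknown subject {sid}")
            cohort[sid - 1] = dataclasses.replace(cohort[sid - 1], **over)
        return cohort


# ---------------------------------------------------------------------------
# Analysis stages
# ---------------------------------------------------------------------------

def cell_matrix(summary: pd.DataFrame, value: str, conditions) -> pd.DataFrame:
    """Subjects x conditions matrix of one summary measure, columns in the
    given order; incomplete subjects are reported."""
    wide = summary.pivot(index="subject_id", columns="condition", values=value)
    missing_cols = [c for c in conditions if c not in wide.columns]
    if missing_cols:
        raise ValueError(f"no data for condition(s) {missing_cols} on {value!r}")
    wide = wide.loc[:, list(conditions)]
    bad = list(wide.index[wide.isna().any(axis=1)])
    if bad:
        raise ValueError(f"incomplete {value!r} cells for subject(s) {bad}")
    return wide


def _anova_with_fallback(wide, factors, alpha):
    """rm-ANOVA with the normality gate; if the gate demands a log transform
    but the measure contains zeros (legitimate, e.g. an error-free variance
    cell), analyze untransformed with a logged warning instead of aborting."""
    try:
        return vtstats.rm_anova(wide, factors, alpha=alpha)
    except ValueError as exc:
        if "strictly positive" not in str(exc):
            raise
        logger.warning("log transform not applicable, analyzing untransformed: %s", exc)
        return vtstats.rm_anova(wide, factors, alpha=alpha, apply_normality_gate=False)


def task_modality_anova(summary: pd.DataFrame, value: str, alpha: float = 0.05):
    """The 2 (task: single, dual) x 3 (modality: VI, TA, VITA) within-subject
    ANOVA used for detection, accuracy, variance and reaction-time measures,
    plus Holm-corrected pairwise modality comparisons on task-averaged cells."""
    wide = cell_matrix(summary, value, TASK_MODALITY_CELLS)
    table = _anova_with_fallback(wide, [("task", 2), ("modality", 3)], alpha)
    collapsed = pd.DataFrame({
        m: wide[[m, f"{m}+VS"]].mean(axis=1) for m in ("VI", "TA", "VITA")
    })
    posthoc = vtstats.posthoc_pairwise(collapsed)
    return table, posthoc


def search_time_anova(summary: pd.DataFrame, alpha: float = 0.05):
    """2 (target: present, absent) x 3 (modality) ANOVA on dual-task median
    search times, with modality post-hocs on target-averaged cells."""
    cells = []
    for tgt in ("present", "absent"):
        cells.append(cell_matrix(summary, f"median_search_time_{tgt}_s",
                                 ["VI+VS", "TA+VS", "VITA+VS"]))
    wide = pd.concat(cells, axis=1)
    table = _anova_with_fallback(wide, [("target", 2), ("modality", 3)], alpha)
    collapsed = pd.DataFrame({
        c: wide[c].mean(axis=1) for c in ("VI+VS", "TA+VS", "VITA+VS")
    })
    posthoc = vtstats.posthoc_pairwise(collapsed)
    return table, posthoc


def gaze_tests(summary_gaze: pd.DataFrame, threshold_deg: float = 1.0) -> pd.DataFrame:
    """One-sample t-tests per condition of mean gaze deviation against the
    fixation threshold, Holm-corrected as one family."""
    rows = []
    for cond, sub in summary_gaze.groupby("condition", sort=True):
        res = vtstats.one_sample_t(sub["mean_gaze_deg"].to_numpy(), threshold_deg)
        rows.append({"condition": cond, "mean_gaze_deg": sub["mean_gaze_deg"].mean(),
                     "t": res.t, "df": res.df, "p": res.p})
    out = pd.DataFrame(rows)
    out["p_holm"] = vtstats.holm_bonferroni(out["p"].to_numpy())
    return out


def interference_summary(interference: pd.DataFrame) -> pd.DataFrame:
    """Group-level interference: overall mean (with a one-sample t against
    zero) and the percent reduction gained by moving the localization task
    out of the visual modality."""
    per_cond = interference.groupby("condition")["interference_s"].mean()
    overall = interference.groupby("subject_id")["interference_s"].mean()
    t = vtstats.one_sample_t(overall.to_numpy(), 0.0)
    rows = [{
        "quantity": "overall_interference_s", "value": overall.mean(),
        "t": t.t, "df": t.df, "p": t.p,
    }]
    for cond in ("TA+VS", "VITA+VS"):
        diff = per_cond["VI+VS"] - per_cond[cond]
        rows.append({
            "quantity": f"reduction_pct_vs_{cond}",
            "value": metrics.interference_reduction_pct(diff, overall.mean()),
        })
    return pd.DataFrame(rows)


def make_variance_figure(per_subject: pd.DataFrame, path) -> None:
    """Group-mean angular-error variance per modality and load, observed vs.
    MLE-predicted for the bimodal condition, with SEM error bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 4), sharey=True)
    bars = ["sigma2_visual", "sigma2_tactile", "sigma2_observed", "sigma2_predicted"]
    labels = ["VI", "TA", "VITA obs", "VITA pred"]
    for ax, load in zip(axes, ("single", "dual")):
        sub = per_subject[per_subject["load"] == load]
        means = [sub[b].mean() for b in bars]
        sems = [sub[b].std(ddof=1) / np.sqrt(len(sub)) for b in bars]
        ax.bar(labels, means, yerr=sems, capsize=4,
               color=["C0", "C1", "C2", "C3"])
        ax.set_title(f"{load} task")
        ax.set_ylabel("variance of angular error (deg$^2$)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

def _run_stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def analyze(trials: pd.DataFrame, config: PipelineConfig, out: Path) -> dict:
    """Run every analysis stage on a trial table, writing CSV artifacts."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {}

    def _save(name, df):
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        artifacts[name] = path

    summary = _run_stage("summarize", metrics.summarize, trials,
                         config.design.trial_duration_s)
    _save("summary", summary)

    gaze = _run_stage("gaze_screen", metrics.gaze_screen, trials,
                      config.gaze_threshold_deg, metrics.SEARCH_CONDITIONS)
    _save("gaze_tests", _run_stage("gaze_tests", gaze_tests, gaze,
                                   config.gaze_threshold_deg))
    gaze_wide = _run_stage("gaze_anova", cell_matrix, summary, "median_gaze_deg",
                           metrics.SEARCH_CONDITIONS)
    _save("anova_gaze", _run_stage(
        "gaze_anova", _anova_with_fallback, gaze_wide, [("condition", 4)], config.alpha))
    _save("posthoc_gaze", _run_stage("gaze_posthoc", vtstats.posthoc_pairwise, gaze_wide))

    interference = _run_stage("interference", metrics.interference_table, summary)
    _save("interference", interference)
    _save("interference_summary",
          _run_stage("interference", interference_summary, interference))

    table, posthoc = _run_stage("search_time_anova", search_time_anova,
                                summary, config.alpha)
    _save("anova_search_time", table)
    _save("posthoc_search_time", posthoc)

    acc_wide = _run_stage("search_accuracy_anova", cell_matrix, summary,
                          "search_accuracy", metrics.SEARCH_CONDITIONS)
    _save("anova_search_accuracy", _run_stage(
        "search_accuracy_anova", _anova_with_fallback, acc_wide,
        [("condition", 4)], config.alpha))

    for value, name in (("detection_performance", "detection"),
                        ("localization_accuracy", "localization_accuracy"),
                        ("error_variance_deg2", "error_variance"),
                        ("mean_rt_correct_s", "rt_correct")):
        table, posthoc = _run_stage(f"{name}_anova", task_modality_anova,
                                    summary, value, config.alpha)
        _save(f"anova_{name}", table)
        _save(f"posthoc_{name}", posthoc)

    triples = _run_stage("optimality", cue_integration.triples_from_summary, summary)
    per_subject, group = _run_stage("optimality", cue_integration.optimality_assessment,
                                    triples)
    _save("optimality_subject", per_subject)
    _save("optimality_group", group)

    fig_path = out / "variance_figure.png"
    _run_stage("figure", make_variance_figure, per_subject, fig_path)
    artifacts["variance_figure"] = fig_path
    return artifacts


def run_pipeline(config: PipelineConfig, out) -> dict:
    """Simulate, analyze and report in one deterministic run.

    Writes the trial table, a config echo, every analysis table, the
    variance figure, and a manifest with the seed and config hash. Returns
    the artifact paths. A stage failure aborts with the stage name;
    artifacts already written are preserved.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    trials = _run_stage("simulate", generate_experiment, config.design,
                        config.observers(), config.seed)
    _run_stage("write_trials", write_trial_table, trials, out / "trials.csv")
    config.to_yaml(out / "config_echo.yaml")
    artifacts = {"trials": out / "trials.csv", "config_echo": out / "config_echo.yaml"}
    artifacts.update(analyze(trials, config, out))

    manifest = {
        "seed": config.seed,
        "config_sha256": config.config_hash(),
        "package_version": __version__,
        "n_trials": int(len(trials)),
        "artifacts": sorted(p.name for p in artifacts.values()),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    artifacts["manifest"] = manifest_path
    return artifacts
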