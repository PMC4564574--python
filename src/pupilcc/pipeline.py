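"""End-to-end orchestration: simulate -> preprocess -> epoch -> analyze -> report.

A :class:`RunConfig` carries every tunable parameter of the pipeline with
the study defaults (3-sample artifact padding, 500-ms baseline, 70%
interpolation exclusion, task summary windows, p < 0.001 with >= 6
contiguous samples for waveform clusters, 300-ms RT floor, 3-SD trims).
``analyze_study`` runs the full analysis on an in-memory or on-disk
dataset and returns a :class:`StudyResult`; ``run`` additionally writes
TSV tables, a plain-text report and the resolved config (with its hash) to
an output directory.
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

from . import behavior, indiv, waveform
from .epochs import (
    TASK_WINDOWS,
    WindowSpec,
    apply_exclusion,
    baseline_correct,
    epoch_trace,
    window_means,
)
from .errors import (
    InsufficientDataError,
    MulticollinearityError,
    PupilError,
    UndefinedCellError,
)
from .io import SampleTable, combine_eyes, read_events, read_samples
from .preprocess import interpolate_linear, pad_missing
from .synth import DesignConfig, SimConfig, StudyData, SubjectData, simulate_study

__all__ = ["RunConfig", "StudyResult", "analyze_study", "run", "validate_dataset", "load_study"]

logger = logging.getLogger(__name__)

ALL_TASKS = ("stroop", "2back", "switch")  # fixed administration order


@dataclass
class RunConfig:
    """All numeric pipeline parameters, defaulting to the study's values."""

    tasks: tuple = ALL_TASKS
    pad_samples: int = 3
    span_ms: tuple = (-500.0, 3000.0)
    baseline_ms: tuple = (-500.0, 0.0)
    exclusion_threshold: float = 0.70
    windows_ms: dict = field(
        default_factory=lambda: {
            task: (w.start_ms, w.end_ms) for task, w in TASK_WINDOWS.items()
        }
    )
    cluster_alpha: float = 0.001
    cluster_min_run: int = 6
    rt_floor_ms: float = 300.0
    rt_sd_k: float = 3.0
    subject_outlier_k: float = 3.0
    entry_alpha: float = 0.05
    collinearity_guard_r: float = 0.90
    min_trials: int = 1
    correct_only: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    design: DesignConfig = field(default_factory=DesignConfig)

    def window(self, task: str) -> WindowSpec:
        start, end = self.windows_ms[task]
        return WindowSpec(start, end)

    @property
    def baseline(self) -> WindowSpec:
        return WindowSpec(*self.baseline_ms)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "sim" in data and isinstance(data["sim"], dict):
            data["sim"] = SimConfig(**data["sim"])
        if "design" in data and isinstance(data["design"], dict):
            data["design"] = DesignConfig(**data["design"])
        for key in ("tasks", "span_ms", "baseline_ms"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        if "windows_ms" in data:
            data["windows_ms"] = {k: tuple(v) for k, v in data["windows_ms"].items()}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# per-subject processing

_SCORERS = {
    "2back": behavior.score_2back,
    "stroop": behavior.score_stroop,
    "switch": behavior.score_switch,
}


def preprocess_samples(samples: SampleTable, cfg: RunConfig):
    """Combine eyes, pad artifacts, interpolate."""
    return interpolate_linear(pad_missing(combine_eyes(samples), cfg.pad_samples))


def analyze_subject_task(
    samples: SampleTable, events: pd.DataFrame, task: str, cfg: RunConfig
):
    """Score, preprocess and epoch one subject's recording of one task.

    Returns baseline-corrected, exclusion-flagged epochs whose metadata
    carries the scored trial table plus each trial's summary-window mean
    dilation (NaN for excluded trials).
    """
    trace = preprocess_samples(samples, cfg)
    scored = _SCORERS[task](events)
    scored = behavior.filter_rt_floor(scored, cfg.rt_floor_ms)
    scored = behavior.filter_rt_sd(scored, cfg.rt_sd_k)
    epochs = epoch_trace(trace, scored, cfg.span_ms)
    epochs = baseline_correct(epochs, cfg.baseline)
    epochs = apply_exclusion(
        epochs, cfg.window(task), cfg.exclusion_threshold, cfg.baseline
    )
    epochs.meta["window_mean_mm"] = window_means(epochs, cfg.window(task))
    return epochs


def _mean_or_nan(values: np.ndarray, mask: np.ndarray) -> float:
    vals = values[mask]
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if vals.size else np.nan


def _rt_mean(trials: pd.DataFrame, condition: str | None = None) -> float:
    sub = trials
    if condition is not None:
        sub = sub.loc[sub["condition"] == condition]
    rts = behavior.surviving_correct(sub)["rt_ms"]
    return float(rts.mean()) if len(rts) else np.nan


def _error_pct(trials: pd.DataFrame, condition: str | None = None) -> float:
    sub = trials
    if condition is not None:
        sub = sub.loc[sub["condition"] == condition]
    if len(sub) == 0:
        return np.nan
    correct = sub["correct"].fillna(False).to_numpy(dtype=bool)
    return float(100.0 * (~correct).sum() / len(sub))


def subject_measures(task_epochs: dict) -> dict:
    """Per-subject behavioral and pupillary indices for all analyzed tasks."""
    out: dict[str, float] = {}
    if "2back" in task_epochs:
        meta = task_epochs["2back"].meta
        scorable = meta.loc[meta["scorable"]]
        wm = scorable["window_mean_mm"].to_numpy(dtype=float)
        correct = scorable["correct"].fillna(False).to_numpy(dtype=bool)
        enc = scorable["encoding_ok"]
        out["nback_errors"] = float((~correct).sum())
        out["nback_error_pct"] = _error_pct(scorable)
        out["nback_rt"] = _rt_mean(scorable)
        out["nback_pd_correct"] = _mean_or_nan(wm, correct)
        out["nback_pd_incorrect"] = _mean_or_nan(wm, ~correct)
        enc_ok = enc.fillna(False).to_numpy(dtype=bool)
        enc_bad = (~enc).fillna(False).to_numpy(dtype=bool)
        out["nback_pd_encoding_correct"] = _mean_or_nan(wm, enc_ok)
        out["nback_pd_encoding_incorrect"] = _mean_or_nan(wm, enc_bad)
    if "stroop" in task_epochs:
        meta = task_epochs["stroop"].meta
        wm = meta["window_mean_mm"].to_numpy(dtype=float)
        correct = meta["correct"].fillna(False).to_numpy(dtype=bool)
        cong = meta["condition"].to_numpy() == "congruent"
        out["stroop_error_pct_congruent"] = _error_pct(meta, "congruent")
        out["stroop_error_pct_incongruent"] = _error_pct(meta, "incongruent")
        out["stroop_errors_total"] = float((~correct).sum())
        out["stroop_rt_congruent"] = _rt_mean(meta, "congruent")
        out["stroop_rt_incongruent"] = _rt_mean(meta, "incongruent")
        try:
            rt_eff, err_eff = behavior.stroop_effect(meta)
            out["stroop_effect_rt"] = rt_eff
            out["stroop_effect_errors"] = err_eff
        except UndefinedCellError:
            out["stroop_effect_rt"] = np.nan
            out["stroop_effect_errors"] = np.nan
        out["stroop_pd_correct_congruent"] = _mean_or_nan(wm, correct & cong)
        out["stroop_pd_correct_incongruent"] = _mean_or_nan(wm, correct & ~cong)
        out["stroop_pd_incorrect_incongruent"] = _mean_or_nan(wm, ~correct & ~cong)
        out["stroop_pd_effect"] = (
            out["stroop_pd_correct_incongruent"] - out["stroop_pd_correct_congruent"]
        )
    if "switch" in task_epochs:
        meta = task_epochs["switch"].meta
        scorable = meta.loc[meta["scorable"]]
        wm = scorable["window_mean_mm"].to_numpy(dtype=float)
        correct = scorable["correct"].fillna(False).to_numpy(dtype=bool)
        sw = scorable["condition"].to_numpy() == "switch"
        out["switch_error_pct_switch"] = _error_pct(scorable, "switch")
        out["switch_error_pct_nonswitch"] = _error_pct(scorable, "nonswitch")
        out["switch_errors_total"] = float((~correct).sum())
        out["switch_rt_switch"] = _rt_mean(scorable, "switch")
        out["switch_rt_nonswitch"] = _rt_mean(scorable, "nonswitch")
        try:
            rt_cost, corr_cost = behavior.switch_cost(meta)
            out["switch_cost_rt"] = rt_cost
            out["switch_cost_correct"] = corr_cost
        except UndefinedCellError:
            out["switch_cost_rt"] = np.nan
            out["switch_cost_correct"] = np.nan
        out["switch_pd_correct_switch"] = _mean_or_nan(wm, correct & sw)
        out["switch_pd_correct_nonswitch"] = _mean_or_nan(wm, correct & ~sw)
        out["switch_pd_incorrect_switch"] = _mean_or_nan(wm, ~correct & sw)
        out["switch_pd_effect"] = (
            out["switch_pd_correct_switch"] - out["switch_pd_correct_nonswitch"]
        )
    return out


# ---------------------------------------------------------------------------
# study-level assembly


def _concat_epochs(items: list):
    first = items[0]
    from dataclasses import replace

    return replace(
        first,
        values=np.vstack([e.values for e in items]),
        interpolated=np.vstack([e.interpolated for e in items]),
        meta=pd.concat([e.meta for e in items], ignore_index=True),
    )


_CONTRASTS = {"stroop": ("incongruent", "congruent"), "switch": ("switch", "nonswitch")}

# correlation tables mirror the published per-task layouts
_CORR_COLUMNS = {
    "2back": [
        "nback_errors_sqrt",
        "nback_rt",
        "nback_pd_correct",
        "nback_pd_encoding_correct",
        "nback_pd_incorrect",
        "nback_pd_encoding_incorrect",
    ],
    "stroop": [
        "stroop_effect_rt",
        "stroop_effect_errors",
        "stroop_errors_total",
        "stroop_pd_effect",
        "stroop_pd_correct_congruent",
        "stroop_pd_correct_incongruent",
        "stroop_pd_incorrect_incongruent",
    ],
    "switch": [
        "switch_cost_correct",
        "switch_cost_rt",
        "switch_errors_total",
        "switch_pd_effect",
        "switch_pd_correct_nonswitch",
        "switch_pd_correct_switch",
        "switch_pd_incorrect_switch",
    ],
}


@dataclass
class TaskWaveformAnalysis:
    task: str
    conditions: dict  # label -> SubjectWaveforms
    grand: dict  # label -> (mean, sem)
    rel_time_ms: np.ndarray
    t: np.ndarray | None = None
    p: np.ndarray | None = None
    clusters: waveform.ClusterResult | None = None


@dataclass
class StudyResult:
    measures: pd.DataFrame
    waveforms: dict  # task -> TaskWaveformAnalysis
    correlations: dict  # task -> CorrelationReport
    contrasts: dict  # name -> PairedContrast
    regressions: dict  # name -> StepwiseResult or str note
    retention: pd.DataFrame
    outliers: pd.DataFrame
    config_hash: str


def analyze_study(study: StudyData, cfg: RunConfig | None = None) -> StudyResult:
    """Run the full analysis over all subjects of a study."""
    cfg = cfg or RunConfig()
    per_subject_epochs: list[dict] = []
    measure_rows = []
    retention_rows = []
    for subj in study.subjects:
        task_epochs = {}
        for task in cfg.tasks:
            if task not in subj.samples:
                continue
            try:
                ep = analyze_subject_task(subj.samples[task], subj.events[task], task, cfg)
            except PupilError as exc:
                logger.warning("subject %s task %s skipped: %s", subj.subject_id, task, exc)
                continue
            task_epochs[task] = ep
            inc = ep.meta["included"].to_numpy(dtype=bool)
            for cond, grp in ep.meta.groupby("condition"):
                if cond == "":
                    continue
                retention_rows.append(
                    {
                        "subject_id": subj.subject_id,
                        "task": task,
                        "condition": cond,
                        "n_trials": len(grp),
                        "n_included": int(grp["included"].sum()),
                    }
                )
        per_subject_epochs.append(task_epochs)
        row = {"subject_id": subj.subject_id}
        row.update(subject_measures(task_epochs))
        measure_rows.append(row)
    measures = pd.DataFrame(measure_rows).set_index("subject_id")
    if "nback_errors" in measures.columns:
        measures["nback_errors_sqrt"] = behavior.sqrt_transform(measures["nback_errors"])

    # per-measure between-subject outlier screening
    outlier_flags = {}
    screened = measures.copy()
    for col in measures.columns:
        vals = measures[col]
        if vals.notna().sum() >= 3:
            flags = behavior.subject_outliers(vals, cfg.subject_outlier_k)
            if flags.any():
                screened.loc[flags, col] = np.nan
            outlier_flags[col] = flags
    outliers = pd.DataFrame(outlier_flags)

    # waveform contrasts
    waveforms: dict[str, TaskWaveformAnalysis] = {}
    for task in cfg.tasks:
        stacks = [te[task] for te in per_subject_epochs if task in te]
        if not stacks:
            continue
        all_ep = _concat_epochs(stacks)
        if task in _CONTRASTS:
            hard, easy = _CONTRASTS[task]
            labels = {hard: hard, easy: easy}
        else:
            labels = {"target": ("match", "nonmatch")}
        conds = {}
        for label, sel in labels.items():
            try:
                conds[label] = waveform.subject_waveforms(
                    all_ep, sel, correct_only=cfg.correct_only, min_trials=cfg.min_trials
                )
            except InsufficientDataError:
                continue
        grand = {
            label: waveform.grand_average(wf)
            for label, wf in conds.items()
            if wf.n_subjects >= 2
        }
        analysis = TaskWaveformAnalysis(
            task=task, conditions=conds, grand=grand, rel_time_ms=all_ep.rel_time_ms
        )
        if task in _CONTRASTS:
            hard, easy = _CONTRASTS[task]
            if hard in conds and easy in conds:
                a, b = conds[hard], conds[easy]
                common = sorted(set(a.subjects) & set(b.subjects))
                a = _subset_waveforms(a, common)
                b = _subset_waveforms(b, common)
                if len(common) >= 3:
                    t, p = waveform.samplewise_paired_t(a, b)
                    analysis.t, analysis.p = t, p
                    analysis.clusters = waveform.detect_clusters(
                        p,
                        all_ep.rel_time_ms,
                        alpha=cfg.cluster_alpha,
                        min_run=cfg.cluster_min_run,
                        t=t,
                    )
        waveforms[task] = analysis

    # correlation tables, contrasts, regressions
    correlations = {}
    for task in cfg.tasks:
        cols = [c for c in _CORR_COLUMNS.get(task, []) if c in screened.columns]
        if len(cols) >= 2:
            try:
                correlations[task] = indiv.correlation_matrix(screened[cols])
            except InsufficientDataError as exc:
                logger.warning("correlation table for %s skipped: %s", task, exc)

    contrasts = {}
    contrast_specs = {
        "nback_pd_incorrect_vs_correct": ("nback_pd_incorrect", "nback_pd_correct"),
        "stroop_errors_incongruent_vs_congruent": (
            "stroop_error_pct_incongruent",
            "stroop_error_pct_congruent",
        ),
        "stroop_rt_incongruent_vs_congruent": ("stroop_rt_incongruent", "stroop_rt_congruent"),
        "stroop_pd_incorrect_vs_correct_incongruent": (
            "stroop_pd_incorrect_incongruent",
            "stroop_pd_correct_incongruent",
        ),
        "switch_errors_switch_vs_nonswitch": (
            "switch_error_pct_switch",
            "switch_error_pct_nonswitch",
        ),
        "switch_rt_switch_vs_nonswitch": ("switch_rt_switch", "switch_rt_nonswitch"),
        "switch_pd_incorrect_vs_correct_switch": (
            "switch_pd_incorrect_switch",
            "switch_pd_correct_switch",
        ),
    }
    for name, (a, b) in contrast_specs.items():
        if a in screened.columns and b in screened.columns:
            try:
                contrasts[name] = indiv.paired_contrast(screened[a], screened[b])
            except InsufficientDataError:
                continue

    regressions = {}
    regression_specs = {
        "stroop_effect_rt~pd": (
            "stroop_effect_rt",
            ["stroop_pd_incorrect_incongruent", "stroop_pd_correct_incongruent",
             "stroop_pd_correct_congruent"],
        ),
        "nback_errors~error_pd": ("nback_errors_sqrt", ["nback_pd_incorrect"]),
        "switch_errors~pd": (
            "switch_errors_total",
            ["switch_pd_incorrect_switch", "switch_pd_correct_switch",
             "switch_pd_correct_nonswitch"],
        ),
    }
    for name, (ycol, xcols) in regression_specs.items():
        if ycol not in screened.columns or any(c not in screened.columns for c in xcols):
            continue
        try:
            regressions[name] = indiv.stepwise_forward(
                screened[ycol],
                screened[xcols],
                entry_alpha=cfg.entry_alpha,
                guard_r=cfg.collinearity_guard_r,
            )
        except (MulticollinearityError, InsufficientDataError) as exc:
            regressions[name] = f"not fitted: {exc}"

    retention = pd.DataFrame(
        retention_rows,
        columns=["subject_id", "task", "condition", "n_trials", "n_included"],
    )
    return StudyResult(
        measures=measures,
        waveforms=waveforms,
        correlations=correlations,
        contrasts=contrasts,
        regressions=regressions,
        retention=retention,
        outliers=outliers,
        config_hash=cfg.config_hash(),
    )


def _subset_waveforms(wf, subjects):
    order = {s: i for i, s in enumerate(wf.subjects)}
    idx = [order[s] for s in subjects]
    return waveform.SubjectWaveforms(
        condition=wf.condition,
        subjects=list(subjects),
        rel_time_ms=wf.rel_time_ms,
        data=wf.data[idx],
        n_trials=wf.n_trials[idx],
    )


# ---------------------------------------------------------------------------
# dataset IO, validation, reporting


def load_study(path: str | Path, rate_hz: float = 60.0) -> StudyData:
    """Load a written dataset directory back into memory."""
    path = Path(path)
    subjects: dict[str, SubjectData] = {}
    for f in sorted(path.glob("samples_*.tsv")):
        _, subject_id, task = f.stem.split("_", 2)
        subj = subjects.setdefault(
            subject_id, SubjectData(subject_id=subject_id, truth={}, samples={}, events={})
        )
        subj.samples[task] = read_samples(f, rate_hz=rate_hz)
        subj.events[task] = read_events(path / f"events_{subject_id}_{task}.tsv")
    truth_path = path / "ground_truth.tsv"
    truth = pd.read_csv(truth_path, sep="\t") if truth_path.exists() else pd.DataFrame()
    return StudyData(subjects=list(subjects.values()), truth=truth)


def validate_dataset(path: str | Path, rate_hz: float = 60.0) -> pd.DataFrame:
    """Schema-check every file of a dataset; returns a per-file report."""
    path = Path(path)
    rows = []
    sample_files = sorted(path.glob("samples_*.tsv"))
    if not sample_files:
        rows.append({"file": str(path), "status": "fail", "detail": "no sample files found"})
    for f in sample_files:
        detail = ""
        status = "pass"
        table = None
        try:
            table = read_samples(f, rate_hz=rate_hz)
        except PupilError as exc:
            status, detail = "fail", str(exc)
        rows.append({"file": f.name, "status": status, "detail": detail})
        ev_file = path / f"events_{f.stem.split('_', 1)[1]}.tsv"
        status, detail = "pass", ""
        try:
            events = read_events(ev_file)
            if table is not None:
                out = events.loc[
                    (events["onset_ms"] < table.time_ms[0])
                    | (events["onset_ms"] > table.time_ms[-1])
                ]
                if len(out):
                    status = "warn"
                    detail = f"trial(s) outside trace span: {out['trial_index'].tolist()}"
        except FileNotFoundError:
            status, detail = "fail", "missing event file"
        except PupilError as exc:
            status, detail = "fail", str(exc)
        rows.append({"file": ev_file.name, "status": status, "detail": detail})
    return pd.DataFrame(rows, columns=["file", "status", "detail"])


def _descriptives(measures: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD table over subjects for every measure (Table-1 style)."""
    desc = measures.agg(["mean", "std", "count"]).T
    desc.columns = ["mean", "sd", "n"]
    return desc


def write_report(result: StudyResult, outdir: str | Path, cfg: RunConfig) -> Path:
    """Write TSV tables and the plain-text report; returns the report path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.measures.to_csv(outdir / "measures.tsv", sep="\t")
    _descriptives(result.measures).to_csv(outdir / "descriptives.tsv", sep="\t")
    result.retention.to_csv(outdir / "retention.tsv", sep="\t", index=False)
    cluster_rows = []
    for task, wa in result.waveforms.items():
        frames = []
        for label, (mean, sem) in wa.grand.items():
            frames.append(
                pd.DataFrame(
                    {
                        "condition": label,
                        "rel_time_ms": wa.rel_time_ms,
                        "mean_mm": mean,
                        "sem_mm": sem,
                    }
                )
            )
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(
                outdir / f"waveforms_{task}.tsv", sep="\t", index=False
            )
        if wa.clusters is not None:
            cf = wa.clusters.to_frame()
            cf.insert(0, "contrast", f"{task}:{'-'.join(_CONTRASTS[task])}")
            cluster_rows.append(cf)
    if cluster_rows:
        pd.concat(cluster_rows, ignore_index=True).to_csv(
            outdir / "clusters.tsv", sep="\t", index=False
        )
    for task, rep in result.correlations.items():
        rep.r.to_csv(outdir / f"correlations_{task}.tsv", sep="\t")
    cfg.to_yaml(outdir / "config.yaml")

    lines = [
        "Pupillometry cognitive-control pipeline report",
        f"config hash: {result.config_hash}",
        f"subjects analyzed: {len(result.measures)}",
        "",
        "== Trial retention (included / recorded per condition) ==",
    ]
    if len(result.retention):
        ret = result.retention.groupby(["task", "condition"])[["n_trials", "n_included"]].sum()
        ret["pct_kept"] = 100.0 * ret["n_included"] / ret["n_trials"]
        for (task, cond), row in ret.iterrows():
            lines.append(
                f"  {task:7s} {cond:12s} {int(row.n_included):5d}/{int(row.n_trials):5d}"
                f"  ({row.pct_kept:.1f}%)"
            )
        overall = 100.0 * ret["n_included"].sum() / ret["n_trials"].sum()
        lines.append(f"  overall kept: {overall:.1f}%")
    lines.append("")
    lines.append("== Waveform contrasts (cluster-thresholded paired t) ==")
    for task, wa in result.waveforms.items():
        if wa.clusters is None:
            continue
        name = "-".join(_CONTRASTS[task])
        if len(wa.clusters) == 0:
            lines.append(f"  {task} {name}: no significant clusters")
        for c in wa.clusters.clusters:
            lines.append(
                f"  {task} {name}: {c.start_ms:.0f}-{c.end_ms:.0f} ms "
                f"({c.n_samples} samples, mean t = {c.mean_t:.2f}, min p = {c.min_p:.2g})"
            )
    lines.append("")
    lines.append("== Repeated-measures contrasts ==")
    for name, con in result.contrasts.items():
        lines.append(f"  {name}: {con.summary()}")
    lines.append("")
    lines.append("== Correlations ==")
    for task, rep in result.correlations.items():
        lines.append(f"-- {task} --")
        lines.append(rep.summary())
    lines.append("")
    lines.append("== Stepwise regressions ==")
    for name, reg in result.regressions.items():
        lines.append(f"-- {name} --")
        lines.append(reg if isinstance(reg, str) else reg.summary())
    report_path = outdir / "report.txt"
    report_path.write_text("\n".join(lines) + "\n")
    return report_path


def run(
    cfg: RunConfig,
    outdir: str | Path,
    dataset: str | Path | None = None,
    write_dataset: bool = False,
) -> StudyResult:
    """All-in-one entry point: simulate (or load) a dataset and analyze it."""
    outdir = Path(outdir)
    if dataset is not None:
        study = load_study(dataset, rate_hz=cfg.sim.rate_hz)
    else:
        study = simulate_study(
            cfg.sim,
            cfg.design,
            tasks=tuple(cfg.tasks),
            outdir=(outdir / "dataset") if write_dataset else None,
        )
    result = analyze_study(study, cfg)
    write_report(result, outdir, cfg)
    return result
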