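"""Trial scoring, behavioral filters and performance indices.

Three cognitive-control tasks are scored:

* **2-Back** (updating): a trial is a *match* when its letter equals the
  letter two trials earlier in the same block; the first two trials of a
  block have no comparison stimulus and are non-scorable.  A trial counts
  as *correctly encoded* when the trial two positions later was answered
  correctly.
* **Stroop** (inhibition): congruent vs incongruent colour words; the
  Stroop effect is the incongruent-minus-congruent difference in mean
  correct RT and in error percentage.
* **Number Switch** (set shifting): in the mixed blocks a trial is a
  *switch* trial when its cue colour differs from the previous trial's;
  the first trial of a mixed block has no predecessor and is unlabeled.
  The switch cost is the switch-minus-non-switch difference in mean
  correct RT and in correct-response rate.

Filters follow the same order as the analysis they feed: an RT floor
(2-Back and Number Switch only), a per-cell 3-SD trim of correct-trial RTs
(Stroop and Number Switch only), and per-measure between-subject 3-SD
outlier flags.  Error counts are square-root transformed to reduce right
skew before correlational analyses.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .errors import UndefinedCellError

__all__ = [
    "score_2back",
    "score_stroop",
    "score_switch",
    "filter_rt_floor",
    "filter_rt_sd",
    "subject_outliers",
    "sqrt_transform",
    "stroop_effect",
    "switch_cost",
    "surviving_correct",
]

RT_FLOOR_TASKS = frozenset({"2back", "switch"})
RT_SD_TASKS = frozenset({"stroop", "switch"})


def _require_columns(df: pd.DataFrame, cols: Iterable[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KeyError(f"trial table lacks column(s) {missing}")


def score_2back(trials: pd.DataFrame) -> pd.DataFrame:
    """Derive match labels, scorability and encoding success for 2-Back trials.

    Labels are recomputed from the stimulus letters, not trusted from the
    input: within each block (ordered by ``trial_index``) trial *t* is a
    match iff its letter equals the letter at *t - 2*; the first two trials
    are non-scorable (``condition`` empty, ``scorable`` False).
    ``encoding_ok`` is the correctness of trial *t + 2* and is undefined
    (NA) for the last two trials of a block.
    """
    _require_columns(trials, ["block", "trial_index", "stimulus", "correct"])
    out = trials.copy()
    out["scorable"] = False
    out["condition"] = ""
    out["encoding_ok"] = pd.array([pd.NA] * len(out), dtype="boolean")
    for _, grp in out.groupby("block", sort=False):
        grp = grp.sort_values("trial_index")
        idx = grp.index
        stim = grp["stimulus"].to_numpy()
        match = np.zeros(len(grp), dtype=bool)
        match[2:] = stim[2:] == stim[:-2]
        cond = np.where(match, "match", "nonmatch")
        cond[:2] = ""
        out.loc[idx, "condition"] = cond
        out.loc[idx[2:], "scorable"] = True
        enc = grp["correct"].shift(-2).astype("boolean")
        out.loc[idx, "encoding_ok"] = enc.to_numpy()
    return out


def score_stroop(trials: pd.DataFrame) -> pd.DataFrame:
    """Derive congruency from ``word|ink`` stimulus tokens."""
    _require_columns(trials, ["stimulus"])
    out = trials.copy()
    parts = out["stimulus"].str.split("|", expand=True)
    if parts.shape[1] != 2 or parts.isna().any().any():
        raise ValueError("Stroop stimuli must be 'word|ink' tokens")
    out["condition"] = np.where(parts[0] == parts[1], "congruent", "incongruent")
    out["scorable"] = True
    return out


def score_switch(trials: pd.DataFrame, mixed_blocks: tuple[int, ...] = (3, 4)) -> pd.DataFrame:
    """Derive switch / non-switch labels from ``number|color`` cue tokens.

    Pure (single-rule) blocks are labeled ``pure`` and are not scorable for
    switch costs.  Within each mixed block, a trial is ``switch`` when its
    cue colour differs from the previous trial's colour; the block's first
    trial is unlabeled.
    """
    _require_columns(trials, ["block", "trial_index", "stimulus"])
    out = trials.copy()
    parts = out["stimulus"].str.split("|", expand=True)
    if parts.shape[1] != 2 or parts.isna().any().any():
        raise ValueError("Number Switch stimuli must be 'number|color' tokens")
    color = parts[1]
    out["condition"] = "pure"
    out["scorable"] = False
    for blk, grp in out.groupby("block", sort=False):
        if int(blk) not in mixed_blocks:
            continue
        grp = grp.sort_values("trial_index")
        idx = grp.index
        col = color.loc[idx].to_numpy()
        lab = np.empty(len(grp), dtype=object)
        lab[0] = ""
        lab[1:] = np.where(col[1:] != col[:-1], "switch", "nonswitch")
        out.loc[idx, "condition"] = lab
        out.loc[idx[1:], "scorable"] = True
    return out


def filter_rt_floor(
    trials: pd.DataFrame,
    floor_ms: float = 300.0,
    tasks: frozenset[str] = RT_FLOOR_TASKS,
) -> pd.DataFrame:
    """Flag implausibly fast responses (rt < floor) in the tasks in scope.

    RTs exactly at the floor are kept.  The Stroop task is exempt by
    default.
    """
    _require_columns(trials, ["task", "rt_ms"])
    out = trials.copy()
    rt = out["rt_ms"].to_numpy(dtype=float)
    in_scope = out["task"].isin(tasks).to_numpy()
    out["rt_floor_excluded"] = in_scope & (rt < floor_ms)
    return out


def filter_rt_sd(
    trials: pd.DataFrame,
    k: float = 3.0,
    tasks: frozenset[str] = RT_SD_TASKS,
) -> pd.DataFrame:
    """Flag correct-trial RTs deviating more than ``k`` SD from their cell mean.

    The reference cell is subject x task x condition; mean and SD are taken
    over that cell's correct-trial RTs before any flagging (single pass, no
    iteration).  Cells with fewer than two RTs or zero SD flag nothing.
    """
    _require_columns(trials, ["subject_id", "task", "condition", "correct", "rt_ms"])
    out = trials.copy()
    if "rt_floor_excluded" not in out.columns:
        out["rt_floor_excluded"] = False
    out["rt_sd_excluded"] = False
    eligible = (
        out["task"].isin(tasks).to_numpy()
        & out["correct"].fillna(False).to_numpy(dtype=bool)
        & out["rt_ms"].notna().to_numpy()
        & ~out["rt_floor_excluded"].to_numpy(dtype=bool)
        & (out["condition"].astype(str) != "").to_numpy()
    )
    sub = out.loc[eligible]
    for _, grp in sub.groupby(["subject_id", "task", "condition"], sort=False):
        rt = grp["rt_ms"].to_numpy(dtype=float)
        if rt.size < 2:
            continue
        mean, sd = rt.mean(), rt.std(ddof=1)
        if sd == 0:
            continue
        flag = np.abs(rt - mean) > k * sd
        out.loc[grp.index[flag], "rt_sd_excluded"] = True
    return out


def subject_outliers(values: pd.Series, k: float = 3.0) -> pd.Series:
    """Between-subject outlier flags: |x - mean| > k * SD of the measure.

    Flags are applied per measure only, so a subject extreme on one index
    still contributes to every other analysis.  Missing values are never
    flagged and do not enter the reference mean/SD.
    """
    x = values.astype(float)
    obs = x.dropna()
    if obs.size < 3:
        raise ValueError("subject outlier screening requires >= 3 subjects")
    sd = obs.std(ddof=1)
    flags = pd.Series(False, index=values.index)
    if sd == 0 or not np.isfinite(sd):
        return flags
    flags.loc[obs.index] = (obs - obs.mean()).abs() > k * sd
    return flags


def sqrt_transform(counts) -> np.ndarray:
    """Square-root transform of error counts (variance-stabilising)."""
    arr = np.asarray(counts, dtype=float)
    if np.nanmin(arr) < 0:
        raise ValueError("error counts must be non-negative")
    return np.sqrt(arr)


def surviving_correct(trials: pd.DataFrame) -> pd.DataFrame:
    """Correct trials that survived the RT filters (for RT means)."""
    mask = trials["correct"].fillna(False).to_numpy(dtype=bool)
    for col in ("rt_floor_excluded", "rt_sd_excluded"):
        if col in trials.columns:
            mask &= ~trials[col].to_numpy(dtype=bool)
    mask &= trials["rt_ms"].notna().to_numpy()
    return trials.loc[mask]


def _condition_stats(trials: pd.DataFrame, condition: str) -> tuple[float, float, float]:
    """(mean correct RT, error %, correct-rate) for one condition label."""
    cell = trials.loc[trials["condition"] == condition]
    if len(cell) == 0:
        raise UndefinedCellError(f"no trials in condition {condition!r}")
    correct = cell["correct"].fillna(False).to_numpy(dtype=bool)
    err_pct = 100.0 * (~correct).sum() / len(cell)
    rts = surviving_correct(cell)["rt_ms"]
    if len(rts) == 0:
        raise UndefinedCellError(f"no surviving correct RTs in condition {condition!r}")
    return float(rts.mean()), float(err_pct), float(correct.mean())


def stroop_effect(trials: pd.DataFrame) -> tuple[float, float]:
    """Stroop interference for one subject.

    Returns ``(rt_effect_ms, error_effect)``: mean correct incongruent RT
    minus mean correct congruent RT (on filter-surviving trials), and
    incongruent minus congruent error percentage.
    """
    rt_i, err_i, _ = _condition_stats(trials, "incongruent")
    rt_c, err_c, _ = _condition_stats(trials, "congruent")
    return rt_i - rt_c, err_i - err_c


def switch_cost(trials: pd.DataFrame) -> tuple[float, float]:
    """Switch cost for one subject, computed on the mixed blocks.

    Returns ``(rt_cost_ms, correct_cost)``: mean correct switch RT minus
    mean correct non-switch RT, and the difference in correct-response
    rates (switch minus non-switch; negative when switching hurts
    accuracy).
    """
    scorable = trials.loc[trials.get("scorable", pd.Series(True, index=trials.index))]
    rt_s, _, acc_s = _condition_stats(scorable, "switch")
    rt_n, _, acc_n = _condition_stats(scorable, "nonswitch")
    return rt_s - rt_n, acc_s - acc_n
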