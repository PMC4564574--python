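"""Condition waveforms, sample-wise paired tests and contiguity clusters.

Subject-level mean waveforms (included, correct trials only by default) are
contrasted between conditions with a paired t-test at every sample.  To
control the family of tests across time, an effect is only declared where
the per-sample p-value beats a strict threshold (default p < 0.001) over a
minimum run of consecutive samples (default 6 at 60 Hz, i.e. 100 ms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .epochs import Epochs, WindowSpec
from .errors import AlignmentError, InsufficientDataError, PairingError

__all__ = [
    "SubjectWaveforms",
    "subject_waveforms",
    "grand_average",
    "samplewise_paired_t",
    "Cluster",
    "ClusterResult",
    "detect_clusters",
    "select_window",
]


@dataclass
class SubjectWaveforms:
    """Per-subject mean dilation waveforms for one condition."""

    condition: str
    subjects: list
    rel_time_ms: np.ndarray
    data: np.ndarray  # (n_subjects, n_samples)
    n_trials: np.ndarray  # trials contributing per subject

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]


def subject_waveforms(
    epochs: Epochs,
    condition: str | tuple[str, ...],
    correct_only: bool = True,
    min_trials: int = 1,
) -> SubjectWaveforms:
    """Average included epochs of one or more conditions within each subject.

    Subjects with fewer than ``min_trials`` contributing epochs are left
    out (they cannot enter the paired tests for this condition).  Passing
    a tuple of labels pools them (used for the single-condition 2-Back
    average).
    """
    labels = (condition,) if isinstance(condition, str) else tuple(condition)
    meta = epochs.meta
    mask = meta["condition"].isin(labels).to_numpy()
    if "included" in meta.columns:
        mask &= meta["included"].to_numpy(dtype=bool)
    if correct_only and "correct" in meta.columns:
        mask &= meta["correct"].fillna(False).to_numpy(dtype=bool)
    subjects, data, n_trials = [], [], []
    for subj, grp in meta.loc[mask].groupby("subject_id", sort=True):
        rows = grp.index.to_numpy()
        if rows.size < min_trials:
            continue
        subjects.append(subj)
        data.append(epochs.values[rows].mean(axis=0))
        n_trials.append(rows.size)
    if not subjects:
        raise InsufficientDataError(f"no subject has >= {min_trials} epochs in {condition!r}")
    return SubjectWaveforms(
        condition="+".join(labels),
        subjects=subjects,
        rel_time_ms=epochs.rel_time_ms.copy(),
        data=np.vstack(data),
        n_trials=np.asarray(n_trials),
    )


def grand_average(wf: SubjectWaveforms) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and standard error of the mean across subjects."""
    if wf.n_subjects < 2:
        raise InsufficientDataError("grand average requires >= 2 subjects")
    mean = wf.data.mean(axis=0)
    sem = wf.data.std(axis=0, ddof=1) / np.sqrt(wf.n_subjects)
    return mean, sem


def _align(a: SubjectWaveforms, b: SubjectWaveforms) -> tuple[np.ndarray, np.ndarray]:
    if a.rel_time_ms.shape != b.rel_time_ms.shape or not np.allclose(
        a.rel_time_ms, b.rel_time_ms
    ):
        raise AlignmentError("waveform grids differ between conditions")
    only_a = set(a.subjects) - set(b.subjects)
    only_b = set(b.subjects) - set(a.subjects)
    if only_a or only_b:
        raise PairingError(
            f"subjects present in only one condition: {sorted(only_a | only_b)}"
        )
    order_b = {s: i for i, s in enumerate(b.subjects)}
    idx_b = [order_b[s] for s in a.subjects]
    return a.data, b.data[idx_b]


def samplewise_paired_t(
    a: SubjectWaveforms, b: SubjectWaveforms
) -> tuple[np.ndarray, np.ndarray]:
    """Two-tailed paired t-test at every sample on subject-level means.

    Returns per-sample (t, p) with df = n - 1.  A zero-variance difference
    is degenerate: t is +/-inf and p is reported as 0 when the mean
    difference is non-zero, and t = 0, p = 1 when all differences are zero.
    """
    da, db = _align(a, b)
    n = da.shape[0]
    if n < 3:
        raise InsufficientDataError("paired t-test requires >= 3 subjects")
    d = da - db
    md = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = md / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    zero_var = sd == 0
    signed_inf = np.where(md > 0, np.inf, -np.inf)
    t = np.where(zero_var, np.where(md == 0, 0.0, signed_inf), t)
    p = np.where(zero_var, np.where(md == 0, 1.0, 0.0), p)
    return t, p


@dataclass(frozen=True)
class Cluster:
    start_ms: float
    end_ms: float
    start_idx: int
    end_idx: int  # index of the last member sample (inclusive)
    n_samples: int
    mean_t: float
    min_p: float


@dataclass
class ClusterResult:
    clusters: list
    alpha: float
    min_run: int

    def __len__(self) -> int:
        return len(self.clusters)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "start_ms": c.start_ms,
                    "end_ms": c.end_ms,
                    "n_samples": c.n_samples,
                    "mean_t": c.mean_t,
                    "min_p": c.min_p,
                }
                for c in self.clusters
            ],
            columns=["start_ms", "end_ms", "n_samples", "mean_t", "min_p"],
        )


def detect_clusters(
    p: np.ndarray,
    times_ms: np.ndarray,
    alpha: float = 0.001,
    min_run: int = 6,
    t: np.ndarray | None = None,
) -> ClusterResult:
    """Maximal runs of consecutive samples with p < alpha, length >= min_run.

    Cluster bounds are reported as the times of the first and last member
    samples.  Runs shorter than ``min_run`` are discarded.
    """
    p = np.asarray(p, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    if p.shape != times_ms.shape:
        raise AlignmentError("p-value and time grids differ in length")
    if not np.isfinite(p).all():
        raise ValueError("p-values must be finite")
    sig = p < alpha
    clusters: list[Cluster] = []
    padded = np.concatenate(([False], sig, [False]))
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])  # exclusive
    for s, e in zip(starts, ends):
        if e - s < min_run:
            continue
        tm = float(np.mean(t[s:e])) if t is not None else np.nan
        clusters.append(
            Cluster(
                start_ms=float(times_ms[s]),
                end_ms=float(times_ms[e - 1]),
                start_idx=int(s),
                end_idx=int(e - 1),
                n_samples=int(e - s),
                mean_t=tm,
                min_p=float(p[s:e].min()),
            )
        )
    return ClusterResult(clusters=clusters, alpha=alpha, min_run=min_run)


def select_window(
    curve: np.ndarray,
    times_ms: np.ndarray,
    width_ms: float = 500.0,
    t: np.ndarray | None = None,
    search_start_ms: float = 0.0,
) -> WindowSpec:
    """Choose a summary window by the two reporting criteria.

    Among all ``width_ms``-long windows on the sample grid that contain the
    global peak of ``curve`` (the grand-average dilation, or condition
    difference), return the one maximising the mean |t| when per-sample t
    statistics are given, or the mean of ``curve`` itself otherwise.  Ties
    on the sensitivity criterion fall back to the mean of ``curve``, then
    to the earliest start.  The search is restricted to post-onset times
    (``search_start_ms``).
    """
    curve = np.asarray(curve, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    post = times_ms >= search_start_ms
    if post.sum() == 0:
        raise InsufficientDataError("no samples at or after the search start")
    offset = int(np.flatnonzero(post)[0])
    curve_p = curve[post]
    times_p = times_ms[post]
    crit = np.abs(t[post]) if t is not None else curve_p
    dt = float(np.median(np.diff(times_p))) if times_p.size > 1 else width_ms
    w = int(round(width_ms / dt))
    n = curve_p.size
    if n < w:
        import logging

        logging.getLogger(__name__).warning(
            "grid shorter than the requested window; returning the full span"
        )
        return WindowSpec(float(times_p[0]), float(times_p[0] + width_ms))
    peak = int(np.argmax(curve_p))
    starts = np.arange(0, n - w + 1)
    contains = (starts <= peak) & (peak < starts + w)
    starts = starts[contains]
    primary = np.array([crit[s : s + w].mean() for s in starts])
    secondary = np.array([curve_p[s : s + w].mean() for s in starts])
    cand = np.flatnonzero(primary == primary.max())
    cand = cand[secondary[cand] == secondary[cand].max()]
    best = starts[int(cand[0])]  # remaining ties -> earliest start
    t0 = float(times_p[best])
    return WindowSpec(t0, t0 + width_ms)
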