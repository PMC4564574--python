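"""Per-trial epoching, baseline correction, exclusion and summary windows.

Epochs are cut stimulus-locked on a fixed index grid: the stimulus onset is
mapped to the first sample at or after the onset time, and a constant span
of sample offsets (default -500 ms to +3000 ms at the nominal rate) defines
every epoch, so all epochs of a recording share one relative-time grid.
Dilation is the diameter minus the mean diameter in the 500 ms before
onset.  Trials with more than a threshold fraction of interpolated samples
in the baseline and/or the summary window are excluded.

Interval membership everywhere is start-inclusive, end-exclusive on the
nearest-sample grid: a window ``[a, b)`` in ms maps to sample offsets
``round(a*rate/1000) <= k < round(b*rate/1000)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import EmptyInputError, EmptyIntervalError, ExcludedEpochError
from .preprocess import MonoTrace

__all__ = [
    "WindowSpec",
    "TASK_WINDOWS",
    "BASELINE_WINDOW",
    "DEFAULT_SPAN",
    "Epochs",
    "epoch_trace",
    "baseline_correct",
    "apply_exclusion",
    "window_mean",
    "window_means",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Half-open time window ``[start_ms, end_ms)`` relative to onset."""

    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if not self.end_ms > self.start_ms:
            raise ValueError("end_ms must exceed start_ms")

    @property
    def width_ms(self) -> float:
        return self.end_ms - self.start_ms

    def sample_slice(self, rate_hz: float) -> tuple[int, int]:
        """Window bounds as sample offsets on the nearest-sample grid."""
        k0 = int(round(self.start_ms * rate_hz / 1000.0))
        k1 = int(round(self.end_ms * rate_hz / 1000.0))
        return k0, k1


#: 500-ms summary windows per task, chosen to contain the dilation peak and
#: be maximally sensitive to trial difficulty.
TASK_WINDOWS = {
    "2back": WindowSpec(1100.0, 1600.0),
    "stroop": WindowSpec(1000.0, 1500.0),
    "switch": WindowSpec(1300.0, 1800.0),
}

BASELINE_WINDOW = WindowSpec(-500.0, 0.0)
DEFAULT_SPAN = (-500.0, 3000.0)

@dataclass
class Epochs:
    """A stack of stimulus-locked epochs sharing one relative-time grid.

    ``values`` holds raw diameters before :func:`baseline_correct` and
    baseline-corrected dilation afterwards (``baseline_corrected`` tells
    which).  ``meta`` carries one row per epoch with trial descriptors and,
    after exclusion bookkeeping, the interpolation fractions and the
    ``included`` flag.
    """

    offsets: np.ndarray  # integer sample offsets relative to onset
    values: np.ndarray  # (n_epochs, n_samples)
    interpolated: np.ndarray  # (n_epochs, n_samples) bool
    meta: pd.DataFrame
    rate_hz: float
    baseline_corrected: bool = False

    @property
    def rel_time_ms(self) -> np.ndarray:
        return self.offsets * (1000.0 / self.rate_hz)

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    def window_columns(self, window: WindowSpec) -> np.ndarray:
        k0, k1 = window.sample_slice(self.rate_hz)
        return np.flatnonzero((self.offsets >= k0) & (self.offsets < k1))

    def select(self, mask: np.ndarray) -> "Epochs":
        mask = np.asarray(mask, dtype=bool)
        return replace(
            self,
            values=self.values[mask],
            interpolated=self.interpolated[mask],
            meta=self.meta.loc[mask].reset_index(drop=True),
        )


def epoch_trace(
    trace: MonoTrace,
    events: pd.DataFrame,
    span: tuple[float, float] = DEFAULT_SPAN,
) -> Epochs:
    """Cut one epoch per event row from a preprocessed trace.

    The trace must already be interpolated (no NaN diameters).  Events whose
    span extends beyond the recording are dropped; the count is logged.
    """
    if len(trace) == 0 or len(events) == 0:
        raise EmptyInputError("empty trace or event table")
    if np.isnan(trace.diameter_mm).any():
        raise ValueError("trace contains NaN diameters; interpolate before epoching")
    rate = trace.rate_hz
    k0 = int(round(span[0] * rate / 1000.0))
    k1 = int(round(span[1] * rate / 1000.0))
    offsets = np.arange(k0, k1)
    onset = events["onset_ms"].to_numpy(dtype=float)
    # first sample at or after each onset
    i0 = np.searchsorted(trace.time_ms, onset - 1e-6, side="left")
    idx = i0[:, None] + offsets[None, :]
    in_range = (idx[:, 0] >= 0) & (idx[:, -1] < len(trace))
    n_dropped = int((~in_range).sum())
    if n_dropped:
        logger.info("dropped %d epoch(s) overlapping the recording edges", n_dropped)
    idx = idx[in_range]
    meta = events.loc[in_range].reset_index(drop=True).copy()
    return Epochs(
        offsets=offsets,
        values=trace.diameter_mm[idx],
        interpolated=trace.interpolated[idx],
        meta=meta,
        rate_hz=rate,
    )


def baseline_correct(epochs: Epochs, baseline: WindowSpec = BASELINE_WINDOW) -> Epochs:
    """Subtract each epoch's pre-stimulus mean diameter.

    ``baseline_mm`` is the mean diameter over the baseline window (default
    the 500 ms before onset); dilation is the pointwise difference.  Epochs
    whose baseline window holds no samples are marked excluded with reason
    ``empty_baseline``.
    """
    cols = epochs.window_columns(baseline)
    meta = epochs.meta.copy()
    if cols.size == 0:
        meta["baseline_mm"] = np.nan
        meta["exclusion_reason"] = "empty_baseline"
        return replace(epochs, meta=meta, baseline_corrected=True)
    base = epochs.values[:, cols].mean(axis=1)
    meta["baseline_mm"] = base
    meta["exclusion_reason"] = ""
    return replace(
        epochs,
        values=epochs.values - base[:, None],
        meta=meta,
        baseline_corrected=True,
    )


def apply_exclusion(
    epochs: Epochs,
    window: WindowSpec,
    threshold: float = 0.70,
    baseline: WindowSpec = BASELINE_WINDOW,
) -> Epochs:
    """Flag epochs with excess interpolated data as excluded.

    An epoch is excluded when *more than* ``threshold`` of the samples in
    the baseline interval and/or the summary window were interpolated
    (fractions exactly at the threshold are kept).  A stricter 0.50
    threshold is available via the argument.
    """
    bcols = epochs.window_columns(baseline)
    wcols = epochs.window_columns(window)
    meta = epochs.meta.copy()
    frac_b = epochs.interpolated[:, bcols].mean(axis=1) if bcols.size else np.ones(epochs.n_epochs)
    frac_w = epochs.interpolated[:, wcols].mean(axis=1) if wcols.size else np.ones(epochs.n_epochs)
    meta["frac_interp_baseline"] = frac_b
    meta["frac_interp_window"] = frac_w
    reason = meta.get("exclusion_reason", pd.Series([""] * len(meta))).to_numpy(dtype=object).copy()
    included = ~((frac_b > threshold) | (frac_w > threshold))
    included[reason != ""] = False  # e.g. empty_baseline epochs stay excluded
    reason[~included & (reason == "")] = "interpolated_fraction"
    meta["included"] = included
    meta["exclusion_reason"] = reason
    return replace(epochs, meta=meta)


def window_means(epochs: Epochs, window: WindowSpec) -> np.ndarray:
    """Mean dilation per epoch over a summary window; NaN for excluded epochs."""
    if not epochs.baseline_corrected:
        raise ValueError("baseline-correct epochs before taking window means")
    cols = epochs.window_columns(window)
    if cols.size == 0:
        raise EmptyIntervalError(
            f"window [{window.start_ms}, {window.end_ms}) ms contains no samples"
        )
    out = epochs.values[:, cols].mean(axis=1)
    if "included" in epochs.meta.columns:
        out = np.where(epochs.meta["included"].to_numpy(dtype=bool), out, np.nan)
    return out


def window_mean(epochs: Epochs, index: int, window: WindowSpec) -> float:
    """Mean dilation of one epoch over a summary window.

    Raises :class:`ExcludedEpochError` for an excluded epoch, naming the
    exclusion reason.
    """
    if "included" in epochs.meta.columns and not bool(epochs.meta["included"].iloc[index]):
        reason = epochs.meta["exclusion_reason"].iloc[index] or "excluded"
        raise ExcludedEpochError(f"epoch {index} excluded ({reason})")
    cols = epochs.window_columns(window)
    if cols.size == 0:
        raise EmptyIntervalError(
            f"window [{window.start_ms}, {window.end_ms}) ms contains no samples"
        )
    return float(epochs.values[index, cols].mean())
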