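"""Artifact handling for a single combined pupil trace.

A :class:`MonoTrace` is the one-diameter-per-timestamp signal obtained by
combining the two eyes.  Samples the tracker flagged as missing (blinks,
tracking loss) are padded by a fixed number of neighbouring samples on each
side and then filled by linear interpolation against real timestamps.  The
fraction of interpolated samples inside an interval is the quantity used
downstream to exclude unreliable trials.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import EmptyIntervalError, EmptyInputError, UnrecoverableTraceError

__all__ = [
    "MonoTrace",
    "pad_missing",
    "interpolate_linear",
    "interpolated_fraction",
]

#: tolerance (ms) for inclusive interval boundaries, to absorb float grids
_EDGE_TOL_MS = 1e-6


@dataclass
class MonoTrace:
    """Single combined pupil time series.

    Parameters
    ----------
    time_ms
        Sample timestamps in milliseconds, strictly increasing.
    diameter_mm
        Pupil diameter per sample; NaN where missing and not yet interpolated.
    missing
        True for samples marked missing (after padding: the padded set).
    interpolated
        True for samples whose diameter was filled by interpolation.
    rate_hz
        Nominal sampling rate.
    """

    time_ms: np.ndarray
    diameter_mm: np.ndarray
    missing: np.ndarray
    interpolated: np.ndarray = None  # type: ignore[assignment]
    rate_hz: float = 60.0

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.diameter_mm = np.asarray(self.diameter_mm, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.interpolated is None:
            self.interpolated = np.zeros(self.time_ms.shape, dtype=bool)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)
        n = self.time_ms.size
        if not (self.diameter_mm.size == self.missing.size == self.interpolated.size == n):
            raise ValueError("per-sample sequences of a MonoTrace must have equal length")

    def __len__(self) -> int:
        return self.time_ms.size

    @property
    def n_missing(self) -> int:
        return int(self.missing.sum())


def pad_missing(trace: MonoTrace, pad_samples: int = 3) -> MonoTrace:
    """Extend every missing run by ``pad_samples`` samples on each side.

    Tracker-flagged artifacts are padded because samples adjacent to a blink
    are distorted by the closing/opening lid.  Padding is clipped at the
    trace boundaries; the original missing set is always a subset of the
    result.
    """
    if pad_samples < 0:
        raise ValueError("pad_samples must be >= 0")
    if pad_samples == 0 or len(trace) == 0:
        return replace(trace, missing=trace.missing.copy())
    structure = np.ones(2 * pad_samples + 1, dtype=bool)
    padded = ndimage.binary_dilation(trace.missing, structure=structure)
    diameter = trace.diameter_mm.copy()
    diameter[padded] = np.nan
    return replace(trace, diameter_mm=diameter, missing=padded)


def interpolate_linear(trace: MonoTrace) -> MonoTrace:
    """Fill missing samples by linear interpolation against timestamps.

    Interior missing runs are bridged by the straight line between the two
    bounding valid samples.  Runs touching a trace edge have no anchor on
    one side and are filled by holding the nearest valid value.  Valid
    samples are left bit-identical; the ``interpolated`` flag is set exactly
    on the filled samples.
    """
    if len(trace) == 0:
        raise EmptyInputError("cannot interpolate an empty trace")
    missing = trace.missing
    if missing.all():
        raise UnrecoverableTraceError("all samples missing; trace cannot be recovered")
    valid = ~missing
    diameter = trace.diameter_mm.copy()
    # np.interp holds the edge values outside the anchor range, which is
    # exactly the boundary rule.
    diameter[missing] = np.interp(
        trace.time_ms[missing], trace.time_ms[valid], trace.diameter_mm[valid]
    )
    interpolated = trace.interpolated | missing
    return replace(trace, diameter_mm=diameter, interpolated=interpolated)


def interpolated_fraction(trace: MonoTrace, interval: tuple[float, float]) -> float:
    """Fraction of samples in ``[start, end)`` that were interpolated.

    Membership is start-inclusive, end-exclusive on the sample grid, with a
    microsecond tolerance so that boundaries landing exactly on a sample
    time are classified deterministically on a float grid.
    """
    start, end = float(interval[0]), float(interval[1])
    sel = (trace.time_ms >= start - _EDGE_TOL_MS) & (trace.time_ms < end - _EDGE_TOL_MS)
    n = int(sel.sum())
    if n == 0:
        raise EmptyIntervalError(f"interval [{start}, {end}) ms contains no samples")
    return float(trace.interpolated[sel].sum()) / n
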