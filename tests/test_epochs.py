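"""Epoch cutting, baseline correction, exclusion and summary windows."""

import numpy as np
import pandas as pd
import pytest

from pupilcc.epochs import (
    TASK_WINDOWS,
    WindowSpec,
    apply_exclusion,
    baseline_correct,
    epoch_trace,
    window_mean,
    window_means,
)
from pupilcc.errors import ExcludedEpochError

from conftest import DT, make_trace


def _events(onsets, **extra):
    n = len(onsets)
    base = {
        "subject_id": ["s1"] * n,
        "task": ["stroop"] * n,
        "trial_index": range(n),
        "block": [1] * n,
        "onset_ms": onsets,
        "condition": extra.pop("condition", ["congruent"] * n),
        "correct": extra.pop("correct", [True] * n),
    }
    base.update(extra)
    return pd.DataFrame(base)


def _flat_trace(n=2000, value=4.0):
    return make_trace(np.full(n, value))


class TestEpochTrace:
    def test_first_sample_at_or_after_minus_500(self):
        epochs = epoch_trace(_flat_trace(), _events([10000.0]))
        assert epochs.rel_time_ms[0] >= -500.0 - 1e-9
        assert epochs.rel_time_ms[0] == pytest.approx(-500.0, abs=DT)

    def test_two_events_share_grid_length(self):
        epochs = epoch_trace(_flat_trace(), _events([5000.0, 12000.0]))
        assert epochs.values.shape == (2, 210)

    def test_edge_epochs_dropped(self):
        epochs = epoch_trace(_flat_trace(), _events([100.0, 10000.0]))
        assert epochs.n_epochs == 1

    def test_sample_counts_match_direct_timestamp_filtering(self, rng):
        trace = _flat_trace(4000)
        onsets = np.sort(rng.uniform(2000, 50000, size=12))
        onsets = onsets[np.diff(np.concatenate(([0], onsets))) > 1]
        epochs = epoch_trace(trace, _events(onsets))
        for k, onset in enumerate(onsets):
            direct = np.sum(
                (trace.time_ms >= onset - 500.0 - 1e-6)
                & (trace.time_ms < onset + 3000.0 - 1e-6)
            )
            assert epochs.values.shape[1] == direct, f"epoch {k}"


class TestBaselineCorrect:
    def test_constant_trace_gives_zero_dilation(self):
        epochs = baseline_correct(epoch_trace(_flat_trace(value=4.0), _events([10000.0])))
        assert epochs.meta["baseline_mm"].iloc[0] == pytest.approx(4.0)
        assert np.allclose(epochs.values, 0.0)

    def test_step_trace_dilation_is_post_minus_baseline(self):
        trace = _flat_trace(2000, 4.0)
        onset = 10000.0
        post = trace.time_ms >= onset
        trace.diameter_mm[post] = 4.5
        epochs = baseline_correct(epoch_trace(trace, _events([onset])))
        sel = epochs.rel_time_ms >= 0
        assert np.allclose(epochs.values[0, sel], 0.5)

    def test_baseline_mean_is_zero_invariant(self, rng):
        trace = make_trace(rng.uniform(3, 6, size=3000))
        onsets = np.arange(3, 20) * 2500.0
        epochs = baseline_correct(epoch_trace(trace, _events(onsets)))
        bcols = epochs.window_columns(WindowSpec(-500.0, 0.0))
        assert np.abs(epochs.values[:, bcols].mean(axis=1)).max() < 1e-9

    def test_shift_invariance_of_dilation(self, rng):
        d = rng.uniform(3, 6, size=3000)
        ev = _events([10000.0, 20000.0])
        a = baseline_correct(epoch_trace(make_trace(d), ev))
        b = baseline_correct(epoch_trace(make_trace(d + 1.7), ev))
        assert np.allclose(a.values, b.values, atol=1e-12)


class TestExclusion:
    def _epochs_with_fracs(self, frac_b, frac_w, threshold=0.70):
        """Build one epoch whose interpolated mask hits the given fractions."""
        n = 2000
        trace = _flat_trace(n)
        onset = 10000.0
        i0 = int(np.searchsorted(trace.time_ms, onset - 1e-6))
        interp = np.zeros(n, bool)
        interp[i0 - 30 : i0 - 30 + int(round(frac_b * 30))] = True
        w0, w1 = TASK_WINDOWS["stroop"].sample_slice(60.0)
        interp[i0 + w0 : i0 + w0 + int(round(frac_w * 30))] = True
        trace.interpolated = interp
        epochs = baseline_correct(epoch_trace(trace, _events([onset])))
        return apply_exclusion(epochs, TASK_WINDOWS["stroop"], threshold)

    def test_baseline_over_threshold_excludes_despite_clean_window(self):
        epochs = self._epochs_with_fracs(0.8, 0.0)
        assert not epochs.meta["included"].iloc[0]

    def test_exactly_070_in_both_is_included(self):
        epochs = self._epochs_with_fracs(0.70, 0.70)
        assert epochs.meta["frac_interp_baseline"].iloc[0] == pytest.approx(0.70)
        assert bool(epochs.meta["included"].iloc[0])

    def test_flag_equals_direct_boolean_evaluation(self, rng):
        for _ in range(30):
            fb = float(rng.integers(0, 31)) / 30
            fw = float(rng.integers(0, 31)) / 30
            epochs = self._epochs_with_fracs(fb, fw)
            expect = not (
                epochs.meta["frac_interp_baseline"].iloc[0] > 0.70
                or epochs.meta["frac_interp_window"].iloc[0] > 0.70
            )
            assert bool(epochs.meta["included"].iloc[0]) == expect

    def test_exclusion_rate_monotone_in_threshold(self, rng):
        n = 6000
        d = rng.uniform(3, 6, size=n)
        missing = rng.random(n) < 0.25
        trace = make_trace(d, missing)
        from pupilcc.preprocess import interpolate_linear, pad_missing

        trace = interpolate_linear(pad_missing(trace, 3))
        onsets = np.arange(3, 25) * 3500.0
        epochs = baseline_correct(epoch_trace(trace, _events(onsets)))
        rates = []
        for thr in (0.0, 0.25, 0.5, 0.7, 0.9, 1.0):
            flagged = apply_exclusion(epochs, TASK_WINDOWS["stroop"], thr)
            rates.append((~flagged.meta["included"]).mean())
        assert all(a >= b for a, b in zip(rates, rates[1:]))


class TestWindowMean:
    def _included_epoch(self, values=None):
        trace = _flat_trace(2000) if values is None else make_trace(values)
        epochs = baseline_correct(epoch_trace(trace, _events([10000.0])))
        return apply_exclusion(epochs, TASK_WINDOWS["stroop"], 0.70)

    def test_constant_dilation_recovered(self):
        n = 2000
        d = np.full(n, 4.0)
        t = np.arange(n) * DT
        d[t >= 10000.0] += 0.1
        epochs = self._included_epoch(d)
        assert window_mean(epochs, 0, TASK_WINDOWS["stroop"]) == pytest.approx(0.1)

    def test_linear_ramp_mean_equals_midpoint(self):
        n = 2000
        t = np.arange(n) * DT
        d = np.full(n, 4.0)
        post = t >= 10000.0
        d[post] = 4.0 + 0.0001 * (t[post] - 10000.0)
        epochs = self._included_epoch(d)
        win = TASK_WINDOWS["stroop"]
        cols = epochs.window_columns(win)
        mid = epochs.values[0, cols][[0, -1]].mean()  # midpoint of an even grid
        assert window_mean(epochs, 0, win) == pytest.approx(mid, abs=1e-9)

    def test_excluded_epoch_refuses_with_reason(self):
        epochs = self._included_epoch()
        epochs.meta.loc[0, "included"] = False
        epochs.meta.loc[0, "exclusion_reason"] = "interpolated_fraction"
        with pytest.raises(ExcludedEpochError, match="interpolated_fraction"):
            window_mean(epochs, 0, TASK_WINDOWS["stroop"])
        assert np.isnan(window_means(epochs, TASK_WINDOWS["stroop"])[0])

    def test_window_mean_matches_enumeration(self, rng):
        d = rng.uniform(3, 6, size=2500)
        epochs = self._included_epoch(d)
        win = TASK_WINDOWS["stroop"]
        cols = epochs.window_columns(win)
        rel = epochs.rel_time_ms
        direct = epochs.values[0, (rel >= win.start_ms - 1e-6) & (rel < win.end_ms - 1e-6)]
        assert np.array_equal(epochs.values[0, cols], direct)
        assert window_mean(epochs, 0, win) == pytest.approx(direct.mean())
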