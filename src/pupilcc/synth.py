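"""Synthetic study generator: task designs, pupil traces and behavior.

The generator emulates a Tobii-style 60 Hz binocular recording of the
three cognitive-control tasks.  The continuous pupil signal of a subject
is

    baseline + sum over trials of amplitude * prf(t - onset) + AR(1) noise

where ``prf`` is the stereotyped unit-peak pupil response kernel
``(t/t_max)^n * exp(n * (1 - t/t_max))``.  Trial amplitudes carry a
condition base (calibrated to published group means), an error increment,
a subject effort term theta (which also lowers error probability through a
logistic link — the source of the dilation/performance correlation the
pipeline is meant to recover), an effort-independent subject term, and a
per-subject condition-contrast random effect.  Blinks (short, frequent)
and tracking dropouts (long, rare) mark validity runs invalid in both
eyes.  Behavioral responses are drawn per trial: lognormal RTs with
condition shifts, errors from the logistic link, omissions when the drawn
RT exceeds the response window.

Amplitudes are specified on the scale of the measured summary-window mean:
internally each trial's kernel is scaled by the reciprocal of the kernel's
mean over the task's summary window, so a configured amplitude of 0.152 mm
yields an expected window-mean dilation of 0.152 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .epochs import TASK_WINDOWS
from .errors import DesignConstraintError
from .io import EVENT_COLUMNS, SampleTable, write_events, write_samples

__all__ = [
    "DesignConfig",
    "SimConfig",
    "gen_2back_sequence",
    "gen_stroop_sequence",
    "gen_switch_sequence",
    "prf",
    "render_trace",
    "simulate_subject",
    "simulate_study",
    "SubjectData",
    "StudyData",
]

LETTERS = "BCDFGHJKLMNPQRSTVWXZ"
STROOP_COLORS = ("orange", "blue", "green")
SWITCH_COLORS = ("yellow", "blue")


@dataclass
class DesignConfig:
    """Trial structure of the three tasks (experimental trials only)."""

    nback_blocks: int = 2
    nback_trials_per_block: int = 45
    nback_n_match: int = 34  # total across blocks
    alphabet: str = LETTERS
    stroop_blocks: int = 3
    stroop_congruent_per_block: int = 18
    stroop_incongruent_per_block: int = 18
    switch_pure_blocks: int = 2
    switch_mixed_blocks: int = 2
    switch_trials_per_block: int = 32
    iti_ms: float = 2000.0
    timeout_ms: dict = field(
        default_factory=lambda: {"2back": 1500.0, "stroop": 3000.0, "switch": 3000.0}
    )

    def nback_matches_per_block(self) -> list[int]:
        """Split the total match count over blocks (default 17/17)."""
        base = self.nback_n_match // self.nback_blocks
        rem = self.nback_n_match % self.nback_blocks
        return [base + (1 if b < rem else 0) for b in range(self.nback_blocks)]


@dataclass
class SimConfig:
    """Statistical structure of a simulated study.

    Condition amplitudes (mm, on the summary-window scale) and RT means
    default to the published group descriptives; the effort coupling
    (``amp_effort_gain``, ``err_effort_slope``) is calibrated so the
    generating correlation between 2-Back window dilation and error count
    is about -0.5; blink/dropout rates are tuned so that roughly 73% of
    trials survive the interpolation-based exclusion.
    """

    n_subjects: int = 35
    seed: int = 0
    rate_hz: float = 60.0
    baseline_mean_mm: float = 4.5
    baseline_sd_mm: float = 0.5
    prf_shape: float = 10.1
    prf_tmax_ms: dict = field(
        default_factory=lambda: {"2back": 1350.0, "stroop": 1250.0, "switch": 1550.0}
    )
    amp_mm: dict = field(
        default_factory=lambda: {
            "2back": 0.098,
            "congruent": 0.110,
            "incongruent": 0.152,
            "nonswitch": 0.131,
            "switch": 0.171,
            "pure": 0.110,
        }
    )
    amp_error_increment: float = 0.08
    amp_effort_gain: float = 0.040
    amp_subject_sd: float = 0.069
    contrast_sd: float = 0.02
    ar_phi: float = 0.9
    noise_sd: float = 0.10
    eye_noise_sd: float = 0.02
    blink_rate_hz: float = 0.25
    blink_mean_samples: float = 8.0
    dropout_rate_hz: float = 0.12
    dropout_mean_samples: float = 90.0
    rt_mean_ms: dict = field(
        default_factory=lambda: {
            "2back": 742.0,
            "congruent": 623.0,
            "incongruent": 705.0,
            "nonswitch": 1110.0,
            "switch": 1279.0,
            "pure": 900.0,
        }
    )
    rt_sigma: float = 0.25
    rt_subject_sd: float = 0.10
    # logistic intercepts chosen so the error rate marginalised over the
    # effort distribution matches the published per-condition means
    err_intercept: dict = field(
        default_factory=lambda: {
            "2back": -2.17,
            "congruent": -4.50,
            "incongruent": -3.62,
            "nonswitch": -2.72,
            "switch": -2.57,
            "pure": -3.45,
        }
    )
    err_effort_slope: float = 1.1
    warmup_ms: float = 3000.0
    tail_ms: float = 4000.0
    null_effect: bool = False

    def effective_amp(self, key: str) -> float:
        """Condition amplitude, with contrasts nulled under ``null_effect``."""
        if not self.null_effect:
            return self.amp_mm[key]
        pairs = {
            "congruent": ("congruent", "incongruent"),
            "incongruent": ("congruent", "incongruent"),
            "switch": ("switch", "nonswitch"),
            "nonswitch": ("switch", "nonswitch"),
        }
        if key in pairs:
            a, b = pairs[key]
            return 0.5 * (self.amp_mm[a] + self.amp_mm[b])
        return self.amp_mm[key]


# ---------------------------------------------------------------------------
# task designs


def gen_2back_sequence(design: DesignConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Letter sequence with an exact number of 2-back matches.

    Match positions are sampled per block among trials with an existing
    t - 2 predecessor; match trials repeat the letter from two back,
    non-match trials draw any other letter, so the labeled set equals the
    actual match set with no accidental extras.
    """
    rows = []
    trial = 0
    alphabet = list(design.alphabet)
    if len(alphabet) < 2:
        raise DesignConstraintError("alphabet must contain at least two letters")
    for block, n_match in enumerate(design.nback_matches_per_block(), start=1):
        n = design.nback_trials_per_block
        if n_match > n - 2:
            raise DesignConstraintError(
                f"{n_match} matches infeasible in a block of {n} trials"
            )
        match_pos = set(rng.choice(np.arange(2, n), size=n_match, replace=False).tolist())
        stim: list[str] = []
        for t in range(n):
            if t in match_pos:
                letter = stim[t - 2]
            elif t >= 2:
                letter = rng.choice([c for c in alphabet if c != stim[t - 2]])
            else:
                letter = rng.choice(alphabet)
            stim.append(letter)
            is_match = t >= 2 and letter == stim[t - 2]
            rows.append(
                {
                    "task": "2back",
                    "block": block,
                    "trial_index": trial,
                    "stimulus": letter,
                    "condition": ("match" if is_match else "nonmatch") if t >= 2 else "",
                    "correct_response": "match" if is_match else "nonmatch",
                }
            )
            trial += 1
    return pd.DataFrame(rows)


def gen_stroop_sequence(design: DesignConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Colour-word trials: per block, fixed congruent/incongruent counts."""
    rows = []
    trial = 0
    colors = list(STROOP_COLORS)
    for block in range(1, design.stroop_blocks + 1):
        block_rows = []
        for _ in range(design.stroop_congruent_per_block):
            word = rng.choice(colors)
            block_rows.append((f"{word}|{word}", "congruent", word))
        for _ in range(design.stroop_incongruent_per_block):
            word = rng.choice(colors)
            ink = rng.choice([c for c in colors if c != word])
            block_rows.append((f"{word}|{ink}", "incongruent", ink))
        order = rng.permutation(len(block_rows))
        for i in order:
            stimulus, condition, ink = block_rows[i]
            rows.append(
                {
                    "task": "stroop",
                    "block": block,
                    "trial_index": trial,
                    "stimulus": stimulus,
                    "condition": condition,
                    "correct_response": ink,
                }
            )
            trial += 1
    return pd.DataFrame(rows)


def _switch_correct_response(number: int, color: str) -> str:
    if color == "yellow":
        return "odd" if number % 2 else "even"
    return "gt5" if number > 5 else "le5"


def gen_switch_sequence(
    design: DesignConfig, rng: np.random.Generator, yellow_first: bool = True
) -> pd.DataFrame:
    """Number Switch trials: two pure blocks then two mixed blocks.

    Pure blocks use a single cue colour (order counterbalanced across
    subjects); mixed blocks draw the colour at random per trial.  Switch /
    non-switch labels are derived from colour changes within each mixed
    block; the first trial of a mixed block is unlabeled.
    """
    rows = []
    trial = 0
    pure_order = ["yellow", "blue"] if yellow_first else ["blue", "yellow"]
    n_blocks = design.switch_pure_blocks + design.switch_mixed_blocks
    for block in range(1, n_blocks + 1):
        pure = block <= design.switch_pure_blocks
        prev_color = None
        for _ in range(design.switch_trials_per_block):
            number = int(rng.integers(1, 11))
            if pure:
                color = pure_order[block - 1]
                condition = "pure"
            else:
                color = str(rng.choice(SWITCH_COLORS))
                if prev_color is None:
                    condition = ""
                else:
                    condition = "switch" if color != prev_color else "nonswitch"
                prev_color = color
            rows.append(
                {
                    "task": "switch",
                    "block": block,
                    "trial_index": trial,
                    "stimulus": f"{number}|{color}",
                    "condition": condition,
                    "correct_response": _switch_correct_response(number, color),
                }
            )
            trial += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pupil signal


def prf(t_ms, shape: float = 10.1, t_max_ms: float = 930.0) -> np.ndarray:
    """Unit-peak pupil response kernel ``(t/tmax)^n * exp(n*(1 - t/tmax))``.

    Zero for t <= 0; the peak value is exactly 1 at ``t_max_ms``.
    """
    t = np.asarray(t_ms, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / t_max_ms
    out[pos] = np.exp(shape * (np.log(x) + 1.0 - x))
    return float(out[0]) if scalar else out


def window_kernel_gain(task: str, rate_hz: float, shape: float, t_max_ms: float) -> float:
    """Mean of the kernel over the task's summary window on the sample grid."""
    win = TASK_WINDOWS[task]
    dt = 1000.0 / rate_hz
    k0, k1 = win.sample_slice(rate_hz)
    return float(prf(np.arange(k0, k1) * dt, shape, t_max_ms).mean())


def render_trace(
    n_samples: int,
    onsets_ms: np.ndarray,
    amps_mm: np.ndarray,
    rate_hz: float,
    shape: float,
    t_max_ms: float,
) -> np.ndarray:
    """Noise-free superposition of scaled kernels on a uniform grid.

    Each trial contributes ``amp * prf(t - onset)`` with the onset mapped
    to the first sample at or after it (the same convention epoching
    uses).
    """
    dt = 1000.0 / rate_hz
    time = np.arange(n_samples) * dt
    impulses = np.zeros(n_samples)
    idx = np.searchsorted(time, np.asarray(onsets_ms, dtype=float) - 1e-6, side="left")
    np.add.at(impulses, idx, np.asarray(amps_mm, dtype=float))
    k_len = int(np.ceil(5.0 * t_max_ms / dt))
    kernel = prf(np.arange(k_len) * dt, shape, t_max_ms)
    return np.convolve(impulses, kernel)[:n_samples]


def _ar1_noise(n: int, phi: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - phi * phi), size=n)
    eps[0] = rng.normal(0.0, sd)  # start at the stationary distribution
    return sps.lfilter([1.0], [1.0, -phi], eps)


def _artifact_mask(
    n: int,
    rate_hz: float,
    rate_per_s: float,
    mean_len_samples: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Poisson-onset artifact runs with geometric run lengths."""
    mask = np.zeros(n + 1, dtype=int)
    if rate_per_s <= 0 or n == 0:
        return np.zeros(n, dtype=bool)
    duration_s = n / rate_hz
    k = rng.poisson(rate_per_s * duration_s)
    if k == 0:
        return np.zeros(n, dtype=bool)
    starts = rng.integers(0, n, size=k)
    lengths = rng.geometric(1.0 / mean_len_samples, size=k)
    ends = np.minimum(starts + lengths, n)
    np.add.at(mask, starts, 1)
    np.add.at(mask, ends, -1)
    return np.cumsum(mask[:-1]) > 0


# ---------------------------------------------------------------------------
# subjects and studies


@dataclass
class SubjectData:
    """One simulated subject: per-task raw tables plus generating truth."""

    subject_id: str
    truth: dict
    samples: dict  # task -> SampleTable
    events: dict  # task -> event DataFrame


@dataclass
class StudyData:
    subjects: list
    truth: pd.DataFrame

    def __len__(self) -> int:
        return len(self.subjects)


def _subject_rng(seed: int, subject: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(subject, stream))
    )


_TASK_STREAM = {"2back": 1, "stroop": 2, "switch": 3}


def _amp_key(task: str, condition: str) -> str:
    if task == "2back":
        return "2back"
    if task == "stroop":
        return condition
    if condition in ("switch", "nonswitch", "pure"):
        return condition
    return "switch"  # first mixed-block trial: a rule retrieval like a switch


def simulate_subject(
    design: DesignConfig,
    sim: SimConfig,
    subject_index: int,
    tasks: tuple[str, ...] = ("stroop", "2back", "switch"),
) -> SubjectData:
    """Simulate one subject's sample and event tables for the given tasks."""
    subject_id = f"s{subject_index:03d}"
    srng = _subject_rng(sim.seed, subject_index, 0)
    theta = srng.normal()
    eta = srng.normal()
    baseline = srng.normal(sim.baseline_mean_mm, sim.baseline_sd_mm)
    u_rt = srng.normal(0.0, sim.rt_subject_sd)
    delta_stroop = srng.normal(0.0, sim.contrast_sd)
    delta_switch = srng.normal(0.0, sim.contrast_sd)
    truth = {
        "subject_id": subject_id,
        "theta": theta,
        "amp_subject": eta,
        "baseline_mm": baseline,
        "u_rt": u_rt,
        "delta_stroop": delta_stroop,
        "delta_switch": delta_switch,
    }
    dt = 1000.0 / sim.rate_hz
    samples: dict[str, SampleTable] = {}
    events: dict[str, pd.DataFrame] = {}
    for task in tasks:
        rng = _subject_rng(sim.seed, subject_index, _TASK_STREAM[task])
        if task == "2back":
            seq = gen_2back_sequence(design, rng)
        elif task == "stroop":
            seq = gen_stroop_sequence(design, rng)
        else:
            seq = gen_switch_sequence(design, rng, yellow_first=subject_index % 2 == 0)
        timeout = design.timeout_ms[task]
        n_trials = len(seq)
        keys = [_amp_key(task, c) for c in seq["condition"]]
        p_err = 1.0 / (
            1.0
            + np.exp(
                -(
                    np.array([sim.err_intercept[k] for k in keys])
                    - sim.err_effort_slope * theta
                )
            )
        )
        is_err = rng.random(n_trials) < p_err
        mean_rt = np.array([sim.rt_mean_ms[k] for k in keys])
        mu = (
            np.log(mean_rt)
            - 0.5 * (sim.rt_sigma**2 + sim.rt_subject_sd**2)
            + u_rt
        )
        rt = np.exp(mu + sim.rt_sigma * rng.normal(size=n_trials))
        omission = rt >= timeout
        is_err = is_err | omission
        # responses: correct token, or a wrong token for commission errors
        responses = []
        for i in range(n_trials):
            if omission[i]:
                responses.append("")
            elif not is_err[i]:
                responses.append(seq["correct_response"].iloc[i])
            else:
                responses.append(_wrong_response(task, seq.iloc[i], rng))
        # onsets: stimulus stays until response (or timeout), then the ITI
        hold = np.where(omission, timeout, rt)
        onsets = sim.warmup_ms + np.concatenate(
            ([0.0], np.cumsum(hold[:-1] + design.iti_ms))
        )
        truth_amp = np.array(
            [sim.effective_amp(k) for k in keys]
        ) + sim.amp_error_increment * is_err
        truth_amp = truth_amp + sim.amp_effort_gain * theta + sim.amp_subject_sd * eta
        if task == "stroop":
            sign = np.where(np.array(keys) == "incongruent", 0.5, -0.5)
            truth_amp = truth_amp + sign * delta_stroop
        elif task == "switch":
            sign = np.where(
                np.array(keys) == "switch",
                0.5,
                np.where(np.array(keys) == "nonswitch", -0.5, 0.0),
            )
            truth_amp = truth_amp + sign * delta_switch
        gain = window_kernel_gain(
            task, sim.rate_hz, sim.prf_shape, sim.prf_tmax_ms[task]
        )
        n_samples = int(np.ceil((onsets[-1] + sim.tail_ms) / dt))
        clean = baseline + render_trace(
            n_samples,
            onsets,
            truth_amp / gain,
            sim.rate_hz,
            sim.prf_shape,
            sim.prf_tmax_ms[task],
        )
        noise = _ar1_noise(n_samples, sim.ar_phi, sim.noise_sd, rng)
        trace = clean + noise
        invalid = _artifact_mask(
            n_samples, sim.rate_hz, sim.blink_rate_hz, sim.blink_mean_samples, rng
        ) | _artifact_mask(
            n_samples, sim.rate_hz, sim.dropout_rate_hz, sim.dropout_mean_samples, rng
        )
        left = trace + rng.normal(0.0, sim.eye_noise_sd, size=n_samples)
        right = trace + rng.normal(0.0, sim.eye_noise_sd, size=n_samples)
        left[invalid] = 0.0
        right[invalid] = 0.0
        samples[task] = SampleTable(
            time_ms=np.arange(n_samples) * dt,
            left_mm=left,
            right_mm=right,
            left_valid=~invalid,
            right_valid=~invalid,
            rate_hz=sim.rate_hz,
        )
        ev = seq.copy()
        ev.insert(0, "subject_id", subject_id)
        ev["onset_ms"] = onsets
        ev["response"] = responses
        ev["correct"] = ~is_err
        ev["rt_ms"] = np.where(omission, np.nan, rt)
        events[task] = ev[EVENT_COLUMNS]
        truth[f"mean_amp_{task}"] = float(truth_amp.mean())
    return SubjectData(subject_id=subject_id, truth=truth, samples=samples, events=events)


def _wrong_response(task: str, trial: pd.Series, rng: np.random.Generator) -> str:
    correct = trial["correct_response"]
    if task == "2back":
        return "nonmatch" if correct == "match" else "match"
    if task == "stroop":
        return str(rng.choice([c for c in STROOP_COLORS if c != correct]))
    alternatives = {"odd": "even", "even": "odd", "gt5": "le5", "le5": "gt5"}
    return alternatives[correct]


def simulate_study(
    sim: SimConfig,
    design: DesignConfig | None = None,
    tasks: tuple[str, ...] = ("stroop", "2back", "switch"),
    outdir: str | Path | None = None,
) -> StudyData:
    """Simulate a full study; optionally write it to disk.

    On disk the dataset is one sample TSV and one event TSV per
    subject x task plus ``ground_truth.tsv`` holding the generating
    subject parameters for recovery scoring.
    """
    design = design or DesignConfig()
    subjects = [
        simulate_subject(design, sim, i, tasks=tasks) for i in range(sim.n_subjects)
    ]
    truth = pd.DataFrame([s.truth for s in subjects])
    study = StudyData(subjects=subjects, truth=truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for s in subjects:
            for task in tasks:
                write_samples(s.samples[task], outdir / f"samples_{s.subject_id}_{task}.tsv")
                write_events(s.events[task], outdir / f"events_{s.subject_id}_{task}.tsv")
        truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    return study
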