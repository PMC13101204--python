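"""Synthetic action-observation (AO) EEG sessions.

Forward model for the study conditions the analysis assumes: 32-channel
500 Hz EEG; three AO paradigms (right-hand task-driven RHTD, right-hand
non-task-driven RHNTD, left-hand task-driven LHTD), each with four targets
flickering at 60/N Hz for frame rates N in {13, 11, 8, 9}; 3-s stimulus
epochs carrying

* an occipital steady-state motion visual evoked potential (SSMVEP):
  fundamental plus second harmonic, stimulus-locked phase with small
  per-trial jitter, occipitally weighted scalp spread;
* motion-VEP onset transients (positive P1, negative N2) with Gaussian
  envelopes;
* lateralized sensorimotor alpha/beta event-related desynchronization (ERD)
  at C3/C4 — contralateral deeper than ipsilateral, task-driven deeper than
  non-task-driven — with a post-stimulus event-related synchronization (ERS)
  rebound;
* 1/f-shaped Gaussian background noise on every channel.

All outputs are pure functions of their inputs and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EEGRecording, EpochSet, EVENT_COLUMNS, MONTAGE_32

PARADIGM_IDS = ("RHTD", "RHNTD", "LHTD")
FRAME_RATES = (13, 11, 8, 9)

#: Scalp spread of the occipital response (gain per channel).
OCCIPITAL_GAINS = {
    "O1": 1.0, "Oz": 1.0, "O2": 1.0, "POz": 0.6,
    "P3": 0.3, "P4": 0.3, "P7": 0.3, "P8": 0.3,
}

_RHTD_ACTIONS = ["grasp paper cup", "grasp small ball", "pinch dice", "tap mouse"]
_RHNTD_ACTIONS = ["thumb adduction", "grasp", "pinch thumb-index", "bend index finger"]


@dataclass(frozen=True)
class TargetSpec:
    """One stimulus target: frame rate N gives movement frequency 60/N Hz."""

    index: int
    frame_rate_N: int
    stim_freq: float
    action_label: str
    n_ao: int = 1  # images per action cycle; metadata only

    def __post_init__(self) -> None:
        if not 1 <= self.index <= 4:
            raise ValueError("target index must be 1..4")
        if abs(self.stim_freq - 60.0 / self.frame_rate_N) >= 5e-5:
            raise ValueError("stim_freq must equal 60/N to 4 decimal places")


@dataclass(frozen=True)
class ParadigmSpec:
    paradigm_id: str
    targets: tuple[TargetSpec, ...]
    hand: str
    task_driven: bool

    def __post_init__(self) -> None:
        if self.paradigm_id not in PARADIGM_IDS:
            raise ValueError(f"unknown paradigm {self.paradigm_id!r}")
        if len(self.targets) != 4:
            raise ValueError("a paradigm has exactly 4 targets")
        if len({t.index for t in self.targets}) != 4:
            raise ValueError("target indices must be unique")

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([t.stim_freq for t in self.targets])


def make_paradigms() -> list[ParadigmSpec]:
    """The three AO paradigms with the printed 60/N target frequencies.

    Same-position targets share their frequency across paradigms; LHTD
    mirrors the RHTD actions with the left hand.
    """
    def targets(actions: list[str]) -> tuple[TargetSpec, ...]:
        return tuple(
            TargetSpec(
                index=i + 1,
                frame_rate_N=n,
                stim_freq=round(60.0 / n, 4),
                action_label=a,
            )
            for i, (n, a) in enumerate(zip(FRAME_RATES, actions))
        )

    return [
        ParadigmSpec("RHTD", targets(_RHTD_ACTIONS), hand="right", task_driven=True),
        ParadigmSpec("RHNTD", targets(_RHNTD_ACTIONS), hand="right", task_driven=False),
        ParadigmSpec("LHTD", targets(_RHTD_ACTIONS), hand="left", task_driven=True),
    ]


@dataclass(frozen=True)
class SessionPlan:
    """Ordered runs of a collection session.

    Each run presents every target ``repeats_per_target`` times in random
    order (20 trials per run under the study conditions).
    """

    runs: tuple[tuple[str, str], ...]  # (paradigm_id, feedback)
    trials_per_run: int = 20
    repeats_per_target: int = 5

    def __post_init__(self) -> None:
        if self.trials_per_run != 4 * self.repeats_per_target:
            raise ValueError("trials_per_run must equal 4 x repeats_per_target")
        for _, fb in self.runs:
            if fb not in ("visual", "action"):
                raise ValueError(f"unknown feedback tag {fb!r}")

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def n_trials(self) -> int:
        return self.n_runs * self.trials_per_run


def make_session_plan(stage: str = "full") -> SessionPlan:
    """Session layout: 12 visual-feedback runs (3 paradigms x 4, alternating)
    plus 4 action-feedback runs (RHTD/LHTD x 2), 20 trials each."""
    visual = tuple((p, "visual") for _ in range(4) for p in PARADIGM_IDS)
    action = tuple((p, "action") for _ in range(2) for p in ("RHTD", "LHTD"))
    if stage == "visual":
        return SessionPlan(runs=visual)
    if stage == "action":
        return SessionPlan(runs=action)
    if stage == "full":
        return SessionPlan(runs=visual + action)
    raise ValueError(f"unknown stage {stage!r}; expected visual/action/full")


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the forward model (amplitudes in microvolts, times in s)."""

    fs: float = 500.0
    epoch_window: tuple[float, float] = (-0.8, 4.0)
    channel_names: tuple[str, ...] = tuple(MONTAGE_32)
    ssmvep_amps: tuple[float, float] = (2.0, 0.8)  # harmonic 1 and 2
    mvep: tuple[float, float, float, float] = (0.170, 3.0, 0.245, -4.0)
    mvep_sigma: float = 0.025
    # (C3 depth, C4 depth) per paradigm: contralateral > ipsilateral,
    # task-driven (RHTD) > non-task-driven (RHNTD)
    erd_depth: dict = field(
        default_factory=lambda: {
            "RHTD": (0.55, 0.30),
            "RHNTD": (0.40, 0.22),
            "LHTD": (0.30, 0.55),
        }
    )
    ers_rebound: float = 0.2
    alpha_freq: float = 10.0
    beta_freq: float = 20.0
    alpha_amp: float = 5.0
    beta_amp: float = 3.0
    noise_scale: float = 15.0
    noise_exponent: float = 1.0
    phase_jitter: float = 0.2  # rad, sd of per-trial SSMVEP phase jitter
    stim_duration: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for pid, (d3, d4) in self.erd_depth.items():
            if not (0.0 <= d3 <= 1.0 and 0.0 <= d4 <= 1.0):
                raise ValueError(f"erd_depth for {pid} must lie in [0, 1]")
        fmax = max(2 * 60.0 / min(FRAME_RATES), self.alpha_freq, self.beta_freq)
        if self.fs <= 2 * fmax:
            raise ValueError("fs must exceed twice the highest simulated frequency")

    def replace(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class DomainShift:
    """Instantaneous linear channel shift: x -> gain * mixing @ x + noise."""

    mixing: np.ndarray
    gain: float = 1.0
    extra_noise: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.mixing, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("mixing must be a square matrix")
        object.__setattr__(self, "mixing", m)
        if self.gain <= 0:
            raise ValueError("gain must be positive")


def random_domain_shift(
    n_channels: int,
    strength: float = 0.4,
    gain: float = 1.0,
    extra_noise: float = 0.0,
    seed: int = 0,
) -> DomainShift:
    """Invertible random mixing ``I + strength * G / sqrt(n)``, redrawn until
    comfortably non-singular. Mixing channels preserves frequency content,
    which is the regime least-squares alignment is designed for."""
    for attempt in range(32):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        m = np.eye(n_channels) + strength * rng.standard_normal(
            (n_channels, n_channels)
        ) / np.sqrt(n_channels)
        if np.abs(np.linalg.det(m)) > 1e-6:
            return DomainShift(mixing=m, gain=gain, extra_noise=extra_noise)
    raise RuntimeError("could not draw an invertible mixing matrix")


# ---------------------------------------------------------------------------
# trial-level forward model
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n: int, fs: float, exponent: float) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f^exponent,
    rescaled to unit standard deviation."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    weight = np.zeros_like(f)
    weight[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * weight, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _base_phase(config_seed: int, target_index: int) -> float:
    """Stimulus-locked phase of a target's SSMVEP, fixed across trials."""
    ss = np.random.SeedSequence([config_seed, 977, target_index])
    return float(np.random.default_rng(ss).uniform(0.0, 2.0 * np.pi))


def simulate_trial(
    target: TargetSpec,
    paradigm: ParadigmSpec,
    config: GeneratorConfig,
    seed: int,
) -> np.ndarray:
    """One epoch (channels x samples) over ``config.epoch_window``.

    Deterministic in (target, paradigm, config, seed).
    """
    if paradigm.paradigm_id not in config.erd_depth:
        raise ValueError(f"no erd_depth configured for {paradigm.paradigm_id}")
    fs = config.fs
    t0, t1 = config.epoch_window
    if t0 > -0.8 or t1 < config.stim_duration + 1.0:
        raise ValueError("epoch window must cover at least -0.8 s to stim end + 1 s")
    n = int(round((t1 - t0) * fs))
    t = t0 + np.arange(n) / fs
    names = list(config.channel_names)
    out = np.zeros((len(names), n))

    rng = np.random.default_rng(seed)
    stim = (t >= 0.0) & (t < config.stim_duration)
    post = t >= config.stim_duration

    # occipital SSMVEP: harmonics share a stimulus-locked phase + trial jitter
    phi = _base_phase(config.seed, target.index) + config.phase_jitter * rng.standard_normal()
    ssmvep = np.zeros(n)
    for h, amp in enumerate(config.ssmvep_amps, start=1):
        ssmvep[stim] += amp * np.sin(2 * np.pi * h * target.stim_freq * t[stim] + h * phi)

    # motion-VEP onset transients (Gaussian envelopes)
    p1_lat, p1_amp, n2_lat, n2_amp = config.mvep
    sg = config.mvep_sigma
    mvep = p1_amp * np.exp(-0.5 * ((t - p1_lat) / sg) ** 2)
    mvep += n2_amp * np.exp(-0.5 * ((t - n2_lat) / sg) ** 2)

    occ = ssmvep + mvep
    for ch, gain in OCCIPITAL_GAINS.items():
        if ch in names:
            out[names.index(ch)] += gain * occ

    # sensorimotor alpha/beta with lateralized ERD and post-stimulus ERS
    d3, d4 = config.erd_depth[paradigm.paradigm_id]
    for ch, depth in (("C3", d3), ("C4", d4)):
        if ch not in names:
            continue
        envelope = np.ones(n)
        envelope[stim] = 1.0 - depth
        envelope[post] = 1.0 + config.ers_rebound
        row = names.index(ch)
        for freq, amp in ((config.alpha_freq, config.alpha_amp),
                          (config.beta_freq, config.beta_amp)):
            ph = rng.uniform(0.0, 2.0 * np.pi)
            out[row] += amp * envelope * np.sin(2 * np.pi * freq * t + ph)

    if config.noise_scale > 0:
        for row in range(len(names)):
            out[row] += config.noise_scale * _pink_noise(rng, n, fs, config.noise_exponent)
    return out


# ---------------------------------------------------------------------------
# session-level generation
# ---------------------------------------------------------------------------

def _run_labels(session_seed: int, run_index: int, repeats: int) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([session_seed, 101, run_index]))
    labels = np.repeat(np.arange(1, 5), repeats)
    return rng.permutation(labels)


def _trial_seed(session_seed: int, run_index: int, trial_index: int) -> int:
    ss = np.random.SeedSequence([session_seed, 211, run_index, trial_index])
    return int(ss.generate_state(1)[0])


#: Seconds between consecutive stimulus onsets in the virtual recording
#: (cue 2 s + stimulus 3 s + feedback/rest), and lead-in before the first.
TRIAL_PERIOD = 7.0
LEAD_IN = 1.5


def _plan_events(plan: SessionPlan, seed: int, fs: float) -> pd.DataFrame:
    rows = []
    for r, (pid, fb) in enumerate(plan.runs):
        labels = _run_labels(seed, r, plan.repeats_per_target)
        for k, lab in enumerate(labels):
            global_idx = r * plan.trials_per_run + k
            onset = int(round((LEAD_IN + global_idx * TRIAL_PERIOD) * fs))
            rows.append((r, k, pid, fb, int(lab), onset))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def simulate_session(
    plan: SessionPlan,
    paradigms: list[ParadigmSpec],
    config: GeneratorConfig,
    seed: int,
) -> tuple[EpochSet, pd.DataFrame]:
    """All planned trials as an :class:`EpochSet` plus the event table.

    Per-trial seeds are derived deterministically from the session seed, so
    each epoch is reproducible in isolation via :func:`simulate_trial`.
    """
    by_id = {p.paradigm_id: p for p in paradigms}
    events = _plan_events(plan, seed, config.fs)
    trials = []
    for row in events.itertuples(index=False):
        paradigm = by_id[row.paradigm]
        target = paradigm.targets[row.label - 1]
        ts = _trial_seed(seed, row.run, row.trial)
        trials.append(simulate_trial(target, paradigm, config, ts))
    epochs = EpochSet(
        data=np.stack(trials),
        labels=events["label"].to_numpy(),
        fs=config.fs,
        window=config.epoch_window,
        channel_names=list(config.channel_names),
        run=events["run"].to_numpy(),
        paradigm=events["paradigm"].to_numpy(dtype=object),
        feedback=events["feedback"].to_numpy(dtype=object),
    )
    return epochs, events


def simulate_continuous_session(
    plan: SessionPlan,
    paradigms: list[ParadigmSpec],
    config: GeneratorConfig,
    seed: int,
) -> tuple[EEGRecording, pd.DataFrame]:
    """Continuous recording in which every planned epoch is laid out at its
    event onset (trials spaced :data:`TRIAL_PERIOD` s apart; quiet elsewhere).

    Epoching this recording at the event onsets recovers exactly the arrays
    :func:`simulate_session` returns, which is the round-trip contract the
    EDF writer/reader pair is tested against.
    """
    epochs, events = simulate_session(plan, paradigms, config, seed)
    fs = config.fs
    pre = int(round(-config.epoch_window[0] * fs))
    n_total = int(round((LEAD_IN + plan.n_trials * TRIAL_PERIOD) * fs))
    data = np.zeros((epochs.n_channels, n_total))
    for i, onset in enumerate(events["onset_sample"].to_numpy()):
        start = onset - pre
        data[:, start:start + epochs.n_samples] = epochs.data[i]
    rec = EEGRecording(data=data, fs=fs, channel_names=list(config.channel_names))
    return rec, events


def apply_domain_shift(epochs: EpochSet, shift: DomainShift, seed: int = 0) -> EpochSet:
    """Replace every trial X by ``gain * mixing @ X`` plus white noise of
    standard deviation ``extra_noise``."""
    if shift.mixing.shape[0] != epochs.n_channels:
        raise ValueError("mixing dimension must equal the channel count")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 331]))
    data = shift.gain * np.einsum("ij,tjs->tis", shift.mixing, epochs.data)
    if shift.extra_noise > 0:
        data = data + shift.extra_noise * rng.standard_normal(data.shape)
    out = epochs.subset(np.arange(epochs.n_trials))
    out.data = data
    return out


def write_session(directory: str | Path, epochs: EpochSet, events: pd.DataFrame) -> Path:
    """Persist a session: binary epoch array + JSON sidecar + TSV events."""
    d = epochs.save(directory)
    events.to_csv(Path(d) / "events.tsv", sep="\t", index=False)
    return d
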