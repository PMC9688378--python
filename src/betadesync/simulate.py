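"""Synthetic epoched EEG with controlled beta-band power structure.

Each epoch is 1/f background noise plus a beta-band (default 20 Hz)
sinusoid with randomized phase whose amplitude envelope encodes the effects
the downstream analysis must detect:

* resting beta amplitude is elevated in the older group;
* during motor planning the envelope drops by a stage-, region-,
  hemisphere-, group- and condition-specific depth D (dB of power relative
  to rest, negative = desynchronization), ramping in 0.8 s after the
  planning cue (desynchronization builds up while the movement is being
  prepared, so the earliest planning samples still look like rest);
* at execution onset the envelope drops to the execution depth and stays
  there through the end of the epoch.

Depth defaults follow the qualitative structure of sensorimotor aging
studies: desynchronization is strongest over central electrodes, planning
is left-lateralized, execution is right-lateralized and deeper in older
adults.  A per-participant planning-depth offset (shared across electrodes
and conditions) models stable individual differences in planning
desynchronization; the pipeline couples this latent trait to motor noise so
that deeper planning desynchronization goes with better tracking.

Amplitudes are modulated (depth converted via ``10**(D/20)``); power-domain
checks use ``10*log10`` ratios, keeping the dB bookkeeping exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .task import Condition, Group, TrialTimeline

__all__ = [
    "CHANNELS",
    "REGION",
    "HEMISPHERE",
    "NeuralSimConfig",
    "EEGEpoch",
    "synth_epoch",
    "synth_cohort",
    "iter_cohort_epochs",
    "cohort_truth_table",
    "draw_participants",
]

CHANNELS: tuple[str, ...] = ("F3", "F4", "C3", "C4", "P3", "P4")

REGION = {"F": "frontal", "C": "central", "P": "parietal"}
HEMISPHERE = {"3": "left", "4": "right"}


def electrode_region(ch: str) -> str:
    return REGION[ch[0]]


def electrode_hemisphere(ch: str) -> str:
    # odd 10-20 index -> left hemisphere, even -> right
    return "left" if int(ch[1:]) % 2 == 1 else "right"


# ---------------------------------------------------------------------------
# default depth structure (dB, power change vs rest; negative = MRBD)
# ---------------------------------------------------------------------------

_PLANNING_BASE = {  # (group, region) -> dB
    ("older", "frontal"): -0.73,
    ("older", "central"): -1.12,
    ("older", "parietal"): -1.15,
    ("younger", "frontal"): -0.64,
    ("younger", "central"): -1.41,
    ("younger", "parietal"): -1.04,
}
_PLANNING_HEMI_OFFSET = {  # (region, hemisphere) -> dB, left-dominant planning
    ("frontal", "left"): -0.02,
    ("frontal", "right"): 0.02,
    ("central", "left"): -0.03,
    ("central", "right"): 0.03,
    ("parietal", "left"): -0.12,
    ("parietal", "right"): 0.12,
}
_PLANNING_CONDITION_OFFSET = {  # (hemisphere, condition label) -> dB
    ("left", "1:1"): 0.0,
    ("left", "1:3"): -0.05,
    ("left", "3:1"): -0.16,
    ("right", "1:1"): 0.0,
    ("right", "1:3"): -0.15,
    ("right", "3:1"): 0.0,
}
_EXECUTION_DEPTH = {  # (group, region, hemisphere) -> dB
    ("older", "frontal", "left"): -2.61,
    ("older", "central", "left"): -4.01,
    ("older", "parietal", "left"): -3.91,
    ("older", "frontal", "right"): -3.23,
    ("older", "central", "right"): -4.68,
    ("older", "parietal", "right"): -3.67,
    ("younger", "frontal", "left"): -2.35,
    ("younger", "central", "left"): -3.76,
    ("younger", "parietal", "left"): -2.67,
    ("younger", "frontal", "right"): -2.25,
    ("younger", "central", "right"): -3.82,
    ("younger", "parietal", "right"): -2.88,
}


@dataclass
class NeuralSimConfig:
    """Parameters of the synthetic EEG generator.

    The beta-to-background ratio is deliberately high: the generator's job
    is to embed a known dB depth that the time-frequency pipeline must
    recover, and a strong oscillation keeps the masked dB values faithful
    to the injected depths across the whole beta band.
    """

    fs: float = 256.0
    beta_freq: float = 20.0  # Hz, inside the 13-30 Hz beta band
    one_over_f_exponent: float = 1.0
    background_rms: float = 0.02  # RMS of the 1/f background, arbitrary units
    a_rest: dict[str, float] = field(
        default_factory=lambda: {"younger": 1.0, "older": 1.3}
    )
    planning_base: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(_PLANNING_BASE)
    )
    planning_hemi_offset: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(_PLANNING_HEMI_OFFSET)
    )
    planning_condition_offset: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(_PLANNING_CONDITION_OFFSET)
    )
    execution_depth: dict[tuple[str, str, str], float] = field(
        default_factory=lambda: dict(_EXECUTION_DEPTH)
    )
    planning_onset_s: float = -1.2  # desynchronization onset after the cue
    transition_s: float = 0.1  # envelope ramp duration
    amp_mod_sd: float = 0.2  # slow multiplicative beta-amplitude fluctuation
    amp_mod_cutoff_hz: float = 1.0
    n_per_group: int = 10
    n_trials: int = 12  # trials per condition entering the EEG analysis
    depth_jitter_sd: float = 1.0  # SD of per-participant planning offset, dB
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 4 * self.beta_freq:
            raise ValueError(
                f"fs={self.fs} too low for a {self.beta_freq} Hz oscillation "
                f"(need fs >= {4 * self.beta_freq})"
            )
        if not 13.0 <= self.beta_freq <= 30.0:
            raise ValueError("beta_freq must lie within the 13-30 Hz band")
        if self.a_rest["older"] < self.a_rest["younger"]:
            raise ValueError("resting beta must not be lower in the older group")

    def depth_db(
        self,
        group: str,
        region: str,
        hemisphere: str,
        stage: str,
        condition: str,
    ) -> float:
        """Configured depth D (dB vs rest), before participant offsets."""
        if stage == "planning":
            return (
                self.planning_base[(group, region)]
                + self.planning_hemi_offset[(region, hemisphere)]
                + self.planning_condition_offset[(hemisphere, condition)]
            )
        if stage == "execution":
            return self.execution_depth[(group, region, hemisphere)]
        raise ValueError(f"unknown stage {stage!r}")


@dataclass
class EEGEpoch:
    """Multi-channel epoch on the -3..3.5 s axis, t = 0 = execution onset."""

    channels: tuple[str, ...]
    fs: float
    times: np.ndarray
    data: np.ndarray  # (n_channels, n_times)
    participant: str
    group: str
    condition: str
    trial: int

    def __post_init__(self) -> None:
        if self.data.shape != (len(self.channels), len(self.times)):
            raise ValueError("data shape does not match channels x times")


def epoch_times(fs: float, timeline: TrialTimeline | None = None) -> np.ndarray:
    timeline = timeline or TrialTimeline()
    n = int(round((timeline.epoch_end_s - timeline.epoch_start_s) * fs)) + 1
    return timeline.epoch_start_s + np.arange(n) / fs


def _smoothstep(t: np.ndarray, t0: float, width: float) -> np.ndarray:
    """0 before t0, 1 after t0 + width, raised-cosine in between."""
    if width <= 0:
        return (t >= t0).astype(float)
    x = np.clip((t - t0) / width, 0.0, 1.0)
    return 0.5 * (1 - np.cos(np.pi * x))


def _depth_profile(
    times: np.ndarray,
    d_plan: float,
    d_exec: float,
    onset_s: float,
    transition_s: float,
) -> np.ndarray:
    """dB depth as a function of epoch time (0 during rest)."""
    d = np.zeros_like(times)
    s_plan = _smoothstep(times, onset_s, transition_s)
    s_exec = _smoothstep(times, 0.0, transition_s)
    d = d_plan * s_plan * (1 - s_exec) + d_exec * s_exec
    return d


def _lowpass_noise(
    rng: np.random.Generator, n: int, fs: float, cutoff_hz: float
) -> np.ndarray:
    """Unit-SD Gaussian noise restricted to frequencies below ``cutoff_hz``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1 / fs)
    spec[f > cutoff_hz] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _one_over_f_noise(
    rng: np.random.Generator, n: int, fs: float, exponent: float, rms: float
) -> np.ndarray:
    white = rng.standard_normal(n)
    if rms <= 0:
        return np.zeros(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1 / fs)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = np.maximum(f[nz], 1.0) ** (-exponent / 2)
    shape[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def synth_epoch(
    config: NeuralSimConfig,
    participant: str,
    group: str,
    condition: str,
    trial: int = 0,
    seed: int | np.random.Generator = 0,
    planning_offset_db: float = 0.0,
    timeline: TrialTimeline | None = None,
) -> EEGEpoch:
    """One synthetic epoch for the six electrodes of interest."""
    timeline = timeline or TrialTimeline()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    times = epoch_times(config.fs, timeline)
    a_rest = config.a_rest[group]
    data = np.empty((len(CHANNELS), len(times)))
    for i, ch in enumerate(CHANNELS):
        region = electrode_region(ch)
        hemi = electrode_hemisphere(ch)
        d_plan = (
            config.depth_db(group, region, hemi, "planning", condition)
            + planning_offset_db
        )
        d_exec = config.depth_db(group, region, hemi, "execution", condition)
        depth = _depth_profile(
            times, d_plan, d_exec, config.planning_onset_s, config.transition_s
        )
        envelope = a_rest * 10.0 ** (depth / 20.0)
        if config.amp_mod_sd > 0:
            # slow waxing/waning of beta amplitude (burst-like behavior);
            # multiplicative and stage-independent, so expected dB depths
            # are unchanged while rest-window power acquires realistic
            # temporal variability
            mod = 1.0 + config.amp_mod_sd * _lowpass_noise(
                rng, len(times), config.fs, config.amp_mod_cutoff_hz
            )
            envelope = envelope * np.maximum(mod, 0.05)
        phase = rng.uniform(0, 2 * np.pi)
        beta = envelope * np.sin(2 * np.pi * config.beta_freq * times + phase)
        noise = _one_over_f_noise(
            rng,
            len(times),
            config.fs,
            config.one_over_f_exponent,
            config.background_rms,
        )
        data[i] = beta + noise
    return EEGEpoch(
        channels=CHANNELS,
        fs=config.fs,
        times=times,
        data=data,
        participant=participant,
        group=group,
        condition=condition,
        trial=trial,
    )


def draw_participants(config: NeuralSimConfig) -> pd.DataFrame:
    """Participant roster with the latent planning-depth trait.

    ``latent_z`` is the standard-normal trait behind the participant's
    planning-depth offset (``planning_offset_db = depth_jitter_sd * z``);
    the pipeline reuses it to correlate motor noise with planning MRBD.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 101)))
    rows = []
    for group in ("younger", "older"):
        for k in range(config.n_per_group):
            z = float(rng.standard_normal())
            rows.append(
                {
                    "participant": f"{group[0].upper()}{k:02d}",
                    "group": group,
                    "latent_z": z,
                    "planning_offset_db": config.depth_jitter_sd * z,
                }
            )
    return pd.DataFrame(rows)


def iter_cohort_epochs(
    config: NeuralSimConfig,
    participants: pd.DataFrame | None = None,
    timeline: TrialTimeline | None = None,
) -> Iterator[EEGEpoch]:
    """Yield every epoch of the cohort (participant x condition x trial)."""
    timeline = timeline or TrialTimeline()
    if participants is None:
        participants = draw_participants(config)
    for pi, (_, p) in enumerate(participants.iterrows()):
        for ci, cond in enumerate(Condition):
            for trial in range(config.n_trials):
                ss = np.random.SeedSequence((config.seed, 202, pi, ci, trial))
                yield synth_epoch(
                    config,
                    p["participant"],
                    p["group"],
                    cond.label,
                    trial=trial,
                    seed=np.random.default_rng(ss),
                    planning_offset_db=p["planning_offset_db"],
                    timeline=timeline,
                )


def cohort_truth_table(
    config: NeuralSimConfig, participants: pd.DataFrame
) -> pd.DataFrame:
    """Injected depths per participant x electrode x condition x stage."""
    rows = []
    for _, p in participants.iterrows():
        for ch in CHANNELS:
            region = electrode_region(ch)
            hemi = electrode_hemisphere(ch)
            for cond in Condition:
                for stage in ("planning", "execution"):
                    d = config.depth_db(p["group"], region, hemi, stage, cond.label)
                    if stage == "planning":
                        d += p["planning_offset_db"]
                    rows.append(
                        {
                            "participant": p["participant"],
                            "group": p["group"],
                            "electrode": ch,
                            "region": region,
                            "hemisphere": hemi,
                            "condition": cond.label,
                            "stage": stage,
                            "depth_db": d,
                        }
                    )
    return pd.DataFrame(rows)


def synth_cohort(
    config: NeuralSimConfig, timeline: TrialTimeline | None = None
) -> tuple[list[EEGEpoch], pd.DataFrame, pd.DataFrame]:
    """Materialize the full cohort.

    Returns (epochs, ground-truth depth table, participant roster).  The
    epoch list holds n_groups x n_per_group x 3 conditions x n_trials
    epochs; for large cohorts prefer :func:`iter_cohort_epochs`.
    """
    participants = draw_participants(config)
    epochs = list(iter_cohort_epochs(config, participants, timeline))
    return epochs, cohort_truth_table(config, participants), participants
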