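"""Complex Morlet wavelet time-frequency decomposition and dB baselining.

Power at (f, t) is the squared magnitude of the convolution of the signal
with a unit-energy complex Morlet wavelet of center frequency f and
temporal SD ``cycles / (2 * pi * f)``.  Epoch edges are handled by
reflect-padding with one maximal wavelet half-length.

dB normalization is against the frequency-specific condition-average
baseline: B(f) is the mean, over the baseline window (-2.5 to -2.2 s by
default) and across the per-condition trial-average matrices, of raw
power; dB(f, t) = 10 * log10(P(f, t) / B(f)).  Power ratios use 10*log10,
amplitude ratios 20*log10, everywhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import fft as sp_fft

from .simulate import EEGEpoch
from .task import TrialTimeline

__all__ = [
    "MorletConfig",
    "TFRMatrix",
    "MorletBank",
    "morlet_transform",
    "condition_average",
    "db_normalize",
    "window_columns",
]


@dataclass(frozen=True)
class MorletConfig:
    """Frequency grid and wavelet parameters.

    The wavelet cycle count rises linearly from ``cycles_lo`` at the lowest
    frequency to ``cycles_hi`` at the highest, trading temporal for
    spectral resolution along the grid.  ``decim`` thins the output time
    axis (the downstream mask threshold depends on the grid size, so both
    the frequency count and the decimation are first-class parameters).
    """

    f_min: float = 3.0
    f_max: float = 35.0
    n_freqs: int = 33
    cycles_lo: float = 3.0
    cycles_hi: float = 10.0
    decim: int = 8

    def __post_init__(self) -> None:
        if self.f_min <= 0:
            raise ValueError("f_min must be positive")
        if self.f_max <= self.f_min:
            raise ValueError("frequency grid must be strictly increasing")
        if self.n_freqs < 2:
            raise ValueError("need at least two frequencies")
        if self.cycles_lo < 2:
            raise ValueError("cycles must be >= 2")
        if self.decim < 1:
            raise ValueError("decim must be >= 1")

    @property
    def frequencies(self) -> np.ndarray:
        return np.linspace(self.f_min, self.f_max, self.n_freqs)

    @property
    def cycles(self) -> np.ndarray:
        f = self.frequencies
        return self.cycles_lo + (self.cycles_hi - self.cycles_lo) * (
            (f - self.f_min) / (self.f_max - self.f_min)
        )


@dataclass
class TFRMatrix:
    """Frequency x time power matrix, raw or dB-normalized.

    ``valid`` marks cells free of epoch-edge contamination: a cell is
    invalid when its wavelet (one half-length) reaches past the epoch
    boundary into the reflect-padding.  ``None`` means all cells valid.
    """

    power: np.ndarray  # (n_freqs, n_times)
    freqs: np.ndarray
    times: np.ndarray
    scale: str  # "raw" | "db"
    baseline_window: tuple[float, float] | None = None
    valid: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.power.shape != (len(self.freqs), len(self.times)):
            raise ValueError("power shape does not match freqs x times")
        if self.scale not in ("raw", "db"):
            raise ValueError("scale must be 'raw' or 'db'")
        if self.scale == "raw" and np.any(self.power < 0):
            raise ValueError("raw power must be non-negative")
        if self.valid is not None and self.valid.shape != self.power.shape:
            raise ValueError("valid mask shape does not match power")

    def valid_or_all(self) -> np.ndarray:
        if self.valid is None:
            return np.ones(self.power.shape, dtype=bool)
        return self.valid

    def same_grid(self, other: "TFRMatrix") -> bool:
        return (
            self.power.shape == other.power.shape
            and np.allclose(self.freqs, other.freqs)
            and np.allclose(self.times, other.times)
        )


def window_columns(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Indices of time points in the half-open interval [lo, hi)."""
    lo, hi = window
    return np.nonzero((times >= lo - 1e-9) & (times < hi - 1e-9))[0]


class MorletBank:
    """Precomputed Morlet wavelet spectra for a fixed (fs, n_times) shape.

    Reusing the bank across epochs amortizes the wavelet FFTs, which
    matters when decomposing hundreds of epochs of identical shape.
    """

    def __init__(self, fs: float, n_times: int, config: MorletConfig | None = None):
        self.config = config or MorletConfig()
        if fs < 4 * self.config.f_max:
            raise ValueError(
                f"fs={fs} too low for the {self.config.f_max} Hz grid "
                f"(need fs >= {4 * self.config.f_max})"
            )
        self.fs = fs
        self.n_times = n_times
        freqs = self.config.frequencies
        cycles = self.config.cycles
        sigma_t = cycles / (2 * np.pi * freqs)
        half_lengths = np.ceil(5.0 * sigma_t * fs).astype(int)
        self.pad = int(half_lengths.max())
        n_padded = n_times + 2 * self.pad
        self.n_fft = sp_fft.next_fast_len(n_padded + 2 * self.pad + 1)
        self._halves = half_lengths
        self._wavelet_ffts = np.empty((len(freqs), self.n_fft), dtype=complex)
        for i, (f, st, h) in enumerate(zip(freqs, sigma_t, half_lengths)):
            t = np.arange(-h, h + 1) / fs
            w = np.exp(-(t**2) / (2 * st**2)) * np.exp(2j * np.pi * f * t)
            w /= np.linalg.norm(w)  # unit energy
            self._wavelet_ffts[i] = sp_fft.fft(w, self.n_fft)

    @property
    def freqs(self) -> np.ndarray:
        return self.config.frequencies

    def power(self, data: np.ndarray) -> np.ndarray:
        """Raw power for one or more channels.

        Parameters
        ----------
        data : (n_times,) or (n_channels, n_times)

        Returns
        -------
        (n_freqs, n_out) or (n_channels, n_freqs, n_out) with the time axis
        decimated by ``config.decim``.
        """
        single = data.ndim == 1
        x = np.atleast_2d(np.asarray(data, dtype=float))
        if x.shape[-1] != self.n_times:
            raise ValueError(
                f"expected {self.n_times} time samples, got {x.shape[-1]}"
            )
        padded = np.pad(x, ((0, 0), (self.pad, self.pad)), mode="reflect")
        spec = sp_fft.fft(padded, self.n_fft, axis=-1)
        # (n_channels, n_freqs, n_fft)
        prod = spec[:, None, :] * self._wavelet_ffts[None, :, :]
        conv = sp_fft.ifft(prod, axis=-1)
        n_padded = padded.shape[-1]
        out = np.empty(
            (x.shape[0], len(self.freqs), len(range(0, self.n_times, self.config.decim)))
        )
        for i, h in enumerate(self._halves):
            # 'same'-mode alignment: sample t of the centered convolution
            centered = conv[:, i, h : h + n_padded]
            cropped = centered[:, self.pad : self.pad + self.n_times]
            out[:, i, :] = np.abs(cropped[:, :: self.config.decim]) ** 2
        return out[0] if single else out

    def out_times(self, times: np.ndarray) -> np.ndarray:
        return np.asarray(times)[:: self.config.decim]

    def valid_mask(self) -> np.ndarray:
        """Per-cell edge-validity on the decimated output grid.

        A cell is valid when the wavelet centered there stays at least one
        half-length away from both epoch boundaries.
        """
        sample_idx = np.arange(0, self.n_times, self.config.decim)
        halves = self._halves[:, None]
        return (sample_idx[None, :] >= halves) & (
            sample_idx[None, :] < self.n_times - halves
        )


@lru_cache(maxsize=8)
def _cached_bank(fs: float, n_times: int, config: MorletConfig) -> MorletBank:
    return MorletBank(fs, n_times, config)


def morlet_transform(
    epoch: EEGEpoch, channel: str, config: MorletConfig | None = None
) -> TFRMatrix:
    """Raw-power TFR of one channel of an epoch."""
    config = config or MorletConfig()
    bank = _cached_bank(epoch.fs, len(epoch.times), config)
    idx = epoch.channels.index(channel)
    power = bank.power(epoch.data[idx])
    return TFRMatrix(
        power=power,
        freqs=bank.freqs,
        times=bank.out_times(epoch.times),
        scale="raw",
        valid=bank.valid_mask(),
        meta={
            "participant": epoch.participant,
            "group": epoch.group,
            "condition": epoch.condition,
            "electrode": channel,
        },
    )


def condition_average(tfrs: list[TFRMatrix]) -> TFRMatrix:
    """Cellwise arithmetic mean of raw power across trials."""
    if not tfrs:
        raise ValueError("need at least one TFR")
    first = tfrs[0]
    if first.scale != "raw":
        raise ValueError("condition_average expects raw-power TFRs")
    for t in tfrs[1:]:
        if not first.same_grid(t):
            raise ValueError("TFR grids do not match")
    mean = np.mean([t.power for t in tfrs], axis=0)
    valid = None
    if any(t.valid is not None for t in tfrs):
        valid = np.logical_and.reduce([t.valid_or_all() for t in tfrs])
    meta = dict(first.meta)
    meta["n_trials"] = len(tfrs)
    return TFRMatrix(
        mean, first.freqs.copy(), first.times.copy(), "raw", valid=valid, meta=meta
    )


def db_normalize(
    tfr: TFRMatrix,
    baseline_source: list[TFRMatrix],
    window: tuple[float, float] | None = None,
    timeline: TrialTimeline | None = None,
) -> TFRMatrix:
    """dB-normalize against the frequency-specific condition-average baseline.

    ``baseline_source`` holds the per-condition trial-average raw TFRs of
    the same participant and electrode; the baseline B(f) is their mean
    over the baseline-window time points, common across conditions.
    """
    if tfr.scale != "raw":
        raise ValueError("db_normalize expects a raw-power TFR")
    if window is None:
        window = (timeline or TrialTimeline()).baseline_window
    if not baseline_source:
        raise ValueError("baseline_source must not be empty")
    cols = window_columns(tfr.times, window)
    if len(cols) == 0:
        raise ValueError(f"baseline window {window} not on the TFR time axis")
    for b in baseline_source:
        if not tfr.same_grid(b):
            raise ValueError("baseline TFR grid does not match")
    stack = np.stack([b.power[:, cols] for b in baseline_source])
    baseline = stack.mean(axis=(0, 2))  # (n_freqs,)
    if np.any(baseline <= 0):
        bad = tfr.freqs[baseline <= 0]
        raise ValueError(f"non-positive baseline power at frequencies {bad}")
    db = 10.0 * np.log10(tfr.power / baseline[:, None])
    return TFRMatrix(
        db,
        tfr.freqs.copy(),
        tfr.times.copy(),
        "db",
        baseline_window=window,
        valid=None if tfr.valid is None else tfr.valid.copy(),
        meta=dict(tfr.meta),
    )
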