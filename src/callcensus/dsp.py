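"""Spectrogram computation and low-band noise removal.

All downstream stages (detection, note measurement, spectrogram
cross-correlation) operate on magnitude spectrograms computed at one fixed
analysis resolution: 22,050 Hz audio, 256-sample Hamming window with no
zero-padding, 75% overlap.  The 64-sample hop gives a temporal resolution of
64/22050 s ~= 2.9025 ms and a frequency resolution of 22050/256 ~= 86.13 Hz
per row.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

DEFAULT_SAMPLE_RATE = 22_050
DEFAULT_NFFT = 256
DEFAULT_OVERLAP = 0.75


@dataclass(frozen=True)
class SpectrogramConfig:
    """STFT analysis parameters.

    ``nfft`` is both the window length and transform size (no zero-padding),
    so the hop is ``nfft * (1 - overlap)`` samples.
    """

    sample_rate: float = DEFAULT_SAMPLE_RATE
    nfft: int = DEFAULT_NFFT
    overlap: float = DEFAULT_OVERLAP
    window: str = "hamming"

    @property
    def hop(self) -> int:
        hop = int(round(self.nfft * (1.0 - self.overlap)))
        if hop < 1:
            raise ValueError("overlap too large: hop would be < 1 sample")
        return hop

    @property
    def dt(self) -> float:
        """Seconds per spectrogram column."""
        return self.hop / self.sample_rate

    @property
    def df(self) -> float:
        """Hz per spectrogram row."""
        return self.sample_rate / self.nfft


@dataclass
class Spectrogram:
    """Magnitude time-frequency matrix.

    ``magnitudes`` is (n_freq_rows, n_time_columns), non-negative linear
    magnitude (dB conversion is for display only; correlation and
    measurement use linear magnitude).  ``f0_offset`` is the frequency of
    the first row, non-zero only after rows have been dropped.
    """

    magnitudes: np.ndarray
    dt: float
    df: float
    f0_offset: float = 0.0
    t0: float = 0.0  # centre time of the first column
    window: str = "hamming"
    overlap: float = DEFAULT_OVERLAP

    @property
    def n_freq(self) -> int:
        return self.magnitudes.shape[0]

    @property
    def n_times(self) -> int:
        return self.magnitudes.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        return self.f0_offset + self.df * np.arange(self.n_freq)

    @property
    def times(self) -> np.ndarray:
        """Column centre times."""
        return self.t0 + self.dt * np.arange(self.n_times)

    def time_index(self, t: float) -> int:
        """Index of the column whose centre is nearest time ``t``."""
        return int(round((t - self.t0) / self.dt))

    @property
    def duration(self) -> float:
        return self.n_times * self.dt

    def freq_index(self, hz: float) -> int:
        """Index of the row nearest the given frequency."""
        return int(round((hz - self.f0_offset) / self.df))

    def band(self, fmin: float, fmax: float) -> np.ndarray:
        """View of the rows whose centre frequencies lie in [fmin, fmax]."""
        rows = (self.frequencies >= fmin) & (self.frequencies <= fmax)
        return self.magnitudes[rows, :]

    def slice_time(self, t_start: float, t_end: float) -> "Spectrogram":
        """Copy restricted to columns with centres in [t_start, t_end)."""
        i0 = max(self.time_index(t_start), 0)
        i1 = min(self.time_index(t_end), self.n_times)
        if i1 <= i0:
            raise ValueError("empty time slice")
        return replace(
            self,
            magnitudes=self.magnitudes[:, i0:i1].copy(),
            t0=self.t0 + i0 * self.dt,
        )


def compute_spectrogram(
    audio: np.ndarray, config: SpectrogramConfig | None = None
) -> Spectrogram:
    """Magnitude STFT of mono audio at the fixed analysis resolution.

    Columns are placed every ``hop`` samples; the column count is
    ``floor((N - nfft) / hop) + 1`` (no padding at either end).

    Raises ``ValueError`` for non-mono input or audio shorter than one
    window.
    """
    config = config or SpectrogramConfig()
    audio = np.asarray(audio, dtype=np.float64)
    if audio.ndim != 1:
        raise ValueError("audio must be mono (1-D)")
    if audio.size < config.nfft:
        raise ValueError(
            f"audio length {audio.size} shorter than one window ({config.nfft})"
        )
    hop = config.hop
    n_cols = (audio.size - config.nfft) // hop + 1
    frames = np.lib.stride_tricks.sliding_window_view(audio, config.nfft)[::hop]
    frames = frames[:n_cols]
    if config.window == "hamming":
        win = np.hamming(config.nfft)
    else:
        from scipy.signal import get_window

        win = get_window(config.window, config.nfft)
    mags = np.abs(np.fft.rfft(frames * win, n=config.nfft, axis=1)).T
    return Spectrogram(
        magnitudes=mags,
        dt=config.dt,
        df=config.df,
        f0_offset=0.0,
        t0=config.nfft / (2 * config.sample_rate),
        window=config.window,
        overlap=config.overlap,
    )


def remove_low_band(
    spec: Spectrogram, cutoff: float = 400.0, drop: bool = False
) -> Spectrogram:
    """Remove background noise below ``cutoff`` Hz.

    By default the rows strictly below the cutoff are zeroed so that row
    indices stay aligned across calls (required by the cross-correlation
    stage).  With ``drop=True`` the rows are removed instead and
    ``f0_offset`` records the new first-row frequency.
    """
    nyquist = spec.f0_offset + spec.df * (spec.n_freq - 1)
    if cutoff > nyquist:
        raise ValueError(f"cutoff {cutoff} Hz above highest row {nyquist:.1f} Hz")
    low = spec.frequencies < cutoff
    if drop:
        keep = ~low
        first = int(np.argmax(keep))
        return replace(
            spec,
            magnitudes=spec.magnitudes[keep, :].copy(),
            f0_offset=spec.f0_offset + spec.df * first,
        )
    mags = spec.magnitudes.copy()
    mags[low, :] = 0.0
    return replace(spec, magnitudes=mags)


def to_db(spec: Spectrogram, floor_db: float = -120.0) -> np.ndarray:
    """dB image of a spectrogram, for plotting only."""
    ref = spec.magnitudes.max()
    if ref <= 0:
        return np.full_like(spec.magnitudes, floor_db)
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(spec.magnitudes / ref)
    return np.maximum(db, floor_db)
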