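"""Note segmentation and the 20 temporal/spectral call variables.

One territorial call is a four-note syllable.  For each detected call we
measure, per the field's convention for this call type:

* ``Tdur1..Tdur4`` — note durations (s)
* ``Tint1..Tint3`` — inter-note gap lengths (s)
* ``Ttotal``       — syllable duration, onset of note 1 to offset of note 4
* ``Fpeak1..4``    — frequency of the strongest spectral component per note
* ``Ffoun1..4``    — fundamental frequency per note
* ``Fhar1..4``     — first harmonic (strongest peak near 2 * Ffoun)

Calls that do not segment into exactly four notes are excluded (raising
``MeasurementFailure``) rather than imputed — only clean spectrograms are
measured, as in manual practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .detect import CallDetection, DetectorConfig, band_energy
from .dsp import Spectrogram

VARIABLE_NAMES = (
    "Tdur1", "Tdur2", "Tdur3", "Tdur4",
    "Tint1", "Tint2", "Tint3",
    "Ttotal",
    "Fpeak1", "Fpeak2", "Fpeak3", "Fpeak4",
    "Ffoun1", "Ffoun2", "Ffoun3", "Ffoun4",
    "Fhar1", "Fhar2", "Fhar3", "Fhar4",
)


class MeasurementFailure(ValueError):
    """The call could not be segmented/measured cleanly and is skipped."""


@dataclass
class CallMeasurements:
    call_id: str
    Tdur1: float; Tdur2: float; Tdur3: float; Tdur4: float
    Tint1: float; Tint2: float; Tint3: float
    Ttotal: float
    Fpeak1: float; Fpeak2: float; Fpeak3: float; Fpeak4: float
    Ffoun1: float; Ffoun2: float; Ffoun3: float; Ffoun4: float
    Fhar1: float; Fhar2: float; Fhar3: float; Fhar4: float
    individual_id: str | None = None

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in VARIABLE_NAMES}

    def vector(self, variables=VARIABLE_NAMES) -> np.ndarray:
        return np.array([getattr(self, v) for v in variables], dtype=float)


def segment_notes(
    spec: Spectrogram,
    detection: CallDetection,
    config: DetectorConfig | None = None,
    rel_threshold: float = 0.10,
    n_notes: int = 4,
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Split a detection into 4 note intervals and 3 gap intervals.

    The in-band amplitude envelope (square root of summed band energy,
    robust to the large level differences between emphasised and quiet
    notes) within the detection is thresholded at ``rel_threshold`` of its
    maximum; above-threshold runs are candidate notes.  If more than four
    emerge (e.g., a noise blip inside a gap), the pair separated by the
    shortest gap is merged repeatedly until four remain.  Fewer than four
    raises :class:`MeasurementFailure`.
    """
    config = config or DetectorConfig()
    i0 = spec.time_index(detection.start)
    i1 = spec.time_index(detection.end)
    envelope = np.sqrt(band_energy(spec, config.fmin, config.fmax)[i0:i1])
    if envelope.size == 0 or envelope.max() <= 0:
        raise MeasurementFailure("no in-band energy in detection")
    mask = envelope > rel_threshold * envelope.max()
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    segs = [[int(a), int(b)] for a, b in zip(idx[::2], idx[1::2])]
    if len(segs) < n_notes:
        raise MeasurementFailure(
            f"found {len(segs)} energy segments, need {n_notes}"
        )
    while len(segs) > n_notes:
        gaps = [segs[j + 1][0] - segs[j][1] for j in range(len(segs) - 1)]
        j = int(np.argmin(gaps))
        segs[j][1] = segs[j + 1][1]
        del segs[j + 1]
    t0 = detection.start
    notes = [(t0 + a * spec.dt, t0 + b * spec.dt) for a, b in segs]
    gaps = [(notes[j][1], notes[j + 1][0]) for j in range(n_notes - 1)]
    return notes, gaps


def _note_spectrum(spec: Spectrogram, t0: float, t1: float) -> np.ndarray:
    """Mean magnitude across the note's columns (stabilises peak picking)."""
    i0 = max(spec.time_index(t0), 0)
    i1 = min(spec.time_index(t1), spec.n_times)
    if i1 <= i0:
        raise MeasurementFailure("empty note interval")
    return spec.magnitudes[:, i0:i1].mean(axis=1)


def _frequency_measures(
    spec: Spectrogram, spectrum: np.ndarray, floor_hz: float = 400.0,
    rel_peak: float = 0.10,
) -> tuple[float, float, float]:
    """(Fpeak, Ffoun, Fhar) from one note's mean spectrum.

    Fpeak is the global-maximum frequency.  Ffoun is the lowest local peak
    at or above ``floor_hz`` exceeding ``rel_peak`` of the spectrum
    maximum; Fhar is the strongest peak within 2*Ffoun +/- 1.5*df.  Peak
    frequencies are refined to sub-bin precision by parabolic
    interpolation through the peak bin and its neighbours.
    """
    freqs = spec.frequencies

    def refined(k: int) -> float:
        if 0 < k < spectrum.size - 1:
            y0, y1, y2 = spectrum[k - 1], spectrum[k], spectrum[k + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:  # proper local maximum
                delta = 0.5 * (y0 - y2) / denom
                return float(freqs[k] + np.clip(delta, -0.5, 0.5) * spec.df)
        return float(freqs[k])

    valid = freqs >= floor_hz
    if spectrum[valid].max() <= 0:
        raise MeasurementFailure("no energy above the noise floor")
    fpeak = refined(int(np.flatnonzero(valid)[np.argmax(spectrum[valid])]))
    peaks, _ = find_peaks(spectrum, height=rel_peak * spectrum[valid].max())
    peaks = [p for p in peaks if freqs[p] >= floor_hz]
    if not peaks:
        raise MeasurementFailure("no spectral peak above the floor")
    ffoun = refined(peaks[0])
    lo, hi = 2 * ffoun - 1.5 * spec.df, 2 * ffoun + 1.5 * spec.df
    in_band = [p for p in peaks if lo <= freqs[p] <= hi]
    if in_band:
        fhar = refined(max(in_band, key=lambda p: spectrum[p]))
    else:  # no resolved peak near the octave: take the strongest bin there
        rows = np.flatnonzero((freqs >= lo) & (freqs <= hi))
        if rows.size == 0:
            raise MeasurementFailure("harmonic band outside spectrogram")
        fhar = refined(int(rows[np.argmax(spectrum[rows])]))
    return fpeak, ffoun, fhar


def measure_call(
    spec: Spectrogram,
    note_intervals: list[tuple[float, float]],
    gap_intervals: list[tuple[float, float]] | None = None,
    call_id: str = "call",
    individual_id: str | None = None,
) -> CallMeasurements:
    """Measure the 20 variables given four note intervals.

    Deterministic given the spectrogram and intervals; amplitude scaling of
    the audio leaves every measurement unchanged.
    """
    if len(note_intervals) != 4:
        raise MeasurementFailure("need exactly 4 note intervals")
    if gap_intervals is None:
        gap_intervals = [
            (note_intervals[j][1], note_intervals[j + 1][0]) for j in range(3)
        ]
    vals: dict[str, float] = {}
    for j, (t0, t1) in enumerate(note_intervals, start=1):
        if t1 <= t0:
            raise MeasurementFailure("non-positive note duration")
        vals[f"Tdur{j}"] = t1 - t0
        fpeak, ffoun, fhar = _frequency_measures(spec, _note_spectrum(spec, t0, t1))
        vals[f"Fpeak{j}"] = fpeak
        vals[f"Ffoun{j}"] = ffoun
        vals[f"Fhar{j}"] = fhar
    for j, (g0, g1) in enumerate(gap_intervals, start=1):
        vals[f"Tint{j}"] = g1 - g0
    vals["Ttotal"] = note_intervals[-1][1] - note_intervals[0][0]
    return CallMeasurements(call_id=call_id, individual_id=individual_id, **vals)


def measure_detection(
    spec: Spectrogram,
    detection: CallDetection,
    config: DetectorConfig | None = None,
    call_id: str = "call",
    individual_id: str | None = None,
) -> CallMeasurements:
    """Segment a detection and measure it in one step."""
    notes, gaps = segment_notes(spec, detection, config=config)
    return measure_call(
        spec, notes, gaps, call_id=call_id, individual_id=individual_id
    )
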