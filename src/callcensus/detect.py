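"""Band-limited candidate-call detection and detector evaluation.

The detector mirrors a practitioner's recognizer workflow: gate the
spectrogram to the call's frequency band (850-1650 Hz), find columns whose
in-band energy exceeds an adaptive threshold, merge above-threshold runs
separated by gaps no longer than the maximum syllable interval (0.2 s), and
keep merged candidates whose duration falls in the species' call-length
window (1.0-2.0 s).  Candidates are summarised by low-order 2-D DCT
coefficients of the band-limited sub-spectrogram, clustered, and scored by
the range-normalised reciprocal of the distance to their cluster centre.
Precision is TP/(TP+FP) and recall TP/(TP+FN) against a ground-truth event
log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.fft import dctn
from scipy.ndimage import zoom as nd_zoom
from sklearn.cluster import KMeans

from .dsp import Spectrogram
from .synth import SoundscapeTruth


@dataclass(frozen=True)
class DetectorConfig:
    fmin: float = 850.0
    fmax: float = 1650.0
    min_len: float = 1.0
    max_len: float = 2.0
    max_gap: float = 0.2
    mad_factor: float = 3.0  # noise-floor term: median + mad_factor * MAD
    range_frac: float = 0.02  # dynamic-range term: fraction of (max - median)
    n_dct: int = 24
    dct_shape: tuple[int, int] = (12, 32)  # (freq, time) resample target

    def __post_init__(self):
        if not (self.fmin < self.fmax):
            raise ValueError("fmin must be < fmax")
        if not (self.min_len < self.max_len):
            raise ValueError("min_len must be < max_len")
        if self.max_gap <= 0:
            raise ValueError("max_gap must be positive")


@dataclass
class CallDetection:
    recorder_id: str
    start: float
    end: float
    score: float = np.nan
    label: str = "unverified"  # {"Gallus", "Other", "unverified"}
    features: np.ndarray | None = None

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class DetectionMetrics:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else np.nan

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else np.nan


def band_energy(spec: Spectrogram, fmin: float, fmax: float) -> np.ndarray:
    """Summed squared magnitude per column within [fmin, fmax]."""
    sub = spec.band(fmin, fmax)
    if sub.shape[0] == 0:
        raise ValueError("spectrogram does not cover the requested band")
    return np.sum(sub**2, axis=0)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open [i, j) index pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def detect_candidates(
    spec: Spectrogram,
    config: DetectorConfig | None = None,
    recorder_id: str = "rec",
) -> list[CallDetection]:
    """Adaptive-threshold detection of candidate calls.

    The per-recording threshold is adaptive: the larger of a noise-floor
    term (median + ``mad_factor`` * MAD of in-band column energy) and a
    dynamic-range term (median + ``range_frac`` of the span up to the
    loudest column).  The first tracks varying noise floors; the second
    keeps low-level noise flicker from crossing the threshold when strong
    calls dominate the recording.  Syllable runs separated by gaps <=
    ``max_gap`` are merged into one candidate; candidates outside the
    call-length window are discarded.
    """
    config = config or DetectorConfig()
    energy = band_energy(spec, config.fmin, config.fmax)
    med = np.median(energy)
    mad = np.median(np.abs(energy - med))
    thr = max(
        med + config.mad_factor * mad,
        med + config.range_frac * (energy.max() - med),
    )
    mask = energy > thr
    runs = _runs(mask)
    if not runs:
        return []

    max_gap_cols = int(np.floor(config.max_gap / spec.dt))
    merged = [list(runs[0])]
    for i0, i1 in runs[1:]:
        if i0 - merged[-1][1] <= max_gap_cols:
            merged[-1][1] = i1
        else:
            merged.append([i0, i1])

    out = []
    for i0, i1 in merged:
        dur = (i1 - i0) * spec.dt
        if config.min_len <= dur <= config.max_len:
            out.append(
                CallDetection(
                    recorder_id=recorder_id,
                    start=spec.t0 + i0 * spec.dt,
                    end=spec.t0 + i1 * spec.dt,
                )
            )
    out.sort(key=lambda d: d.start)
    return out


def _zigzag_indices(shape: tuple[int, int]) -> list[tuple[int, int]]:
    order = sorted(
        ((i, j) for i in range(shape[0]) for j in range(shape[1])),
        key=lambda ij: (ij[0] + ij[1], ij[1] if (ij[0] + ij[1]) % 2 else ij[0]),
    )
    return order


def extract_dct_features(
    spec: Spectrogram,
    detection: CallDetection,
    n_dct: int = 24,
    config: DetectorConfig | None = None,
) -> np.ndarray:
    """Low-order 2-D DCT summary of a detection's band-limited patch.

    The in-band sub-spectrogram over the detection's time span is resampled
    to a fixed (freq, time) grid, normalised to unit energy (so features are
    amplitude invariant), transformed with a 2-D DCT-II, and the first
    ``n_dct`` coefficients in zig-zag order are returned.
    """
    config = config or DetectorConfig()
    i0 = spec.time_index(detection.start)
    i1 = spec.time_index(detection.end)
    if i0 < 0 or i1 > spec.n_times or i1 <= i0:
        raise ValueError("detection outside spectrogram extent")
    patch = spec.band(config.fmin, config.fmax)[:, i0:i1]
    target = config.dct_shape
    if n_dct > target[0] * target[1]:
        raise ValueError(f"n_dct={n_dct} exceeds resampled size {target}")
    factors = (target[0] / patch.shape[0], target[1] / patch.shape[1])
    patch = nd_zoom(patch, factors, order=1, grid_mode=True, mode="grid-constant")
    norm = np.linalg.norm(patch)
    if norm > 0:
        patch = patch / norm
    coeffs = dctn(patch, type=2, norm="ortho")
    zz = _zigzag_indices(target)[:n_dct]
    return np.array([coeffs[i, j] for i, j in zz])


def cluster_candidates(
    features: list[np.ndarray] | np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """k-centroid partition of feature vectors (Euclidean, Lloyd updates).

    Returns (assignments, distance of each item to its centre).  The
    distances feed ``score_detections``.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    X = np.asarray(features, dtype=float)
    if X.shape[0] < k:
        raise ValueError("need at least k feature vectors")
    km = KMeans(n_clusters=k, n_init=n_restarts, max_iter=300, random_state=seed)
    labels = km.fit_predict(X)
    dists = np.linalg.norm(X - km.cluster_centers_[labels], axis=1)
    return labels, dists


def score_detections(centre_distances: np.ndarray) -> np.ndarray:
    """Range-normalised reciprocal-distance scores in [0, 1].

    s_i = 1/(d_i + eps), then (s - min)/(max - min); smaller distance to
    the cluster centre means a higher score.  eps is 1e-9 of the median
    distance, so a zero distance never overflows.
    """
    d = np.asarray(centre_distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    med = np.median(d)
    eps = 1e-9 * med if med > 0 else 1e-9
    s = 1.0 / (d + eps)
    if np.ptp(s) == 0:
        warnings.warn("all centre distances equal; scores undefined, returning 1.0")
        return np.ones_like(s)
    return (s - s.min()) / (s.max() - s.min())


def _iou(a0: float, a1: float, b0: float, b1: float) -> float:
    inter = max(0.0, min(a1, b1) - max(a0, b0))
    union = max(a1, b1) - min(a0, b0)
    return inter / union if union > 0 else 0.0


def evaluate_detections(
    detections: list[CallDetection],
    truth: SoundscapeTruth | list[tuple[float, float]],
    iou_threshold: float = 0.5,
    recorder_id: str | None = None,
) -> DetectionMetrics:
    """Greedy one-to-one temporal matching of detections against truth.

    Each detection may claim at most one truth event with interval
    intersection-over-union >= ``iou_threshold``; unmatched detections are
    false positives, unmatched truth events false negatives.
    """
    if isinstance(truth, SoundscapeTruth):
        rec = recorder_id or (detections[0].recorder_id if detections else None)
        intervals = [(on, off) for _, on, off in truth.events_for(rec)] if rec else [
            (on, off) for _, _, on, off in truth.events
        ]
    else:
        intervals = list(truth)

    claimed = [False] * len(intervals)
    tp = 0
    for det in sorted(detections, key=lambda d: d.start):
        best, best_iou = None, iou_threshold
        for j, (t0, t1) in enumerate(intervals):
            if claimed[j]:
                continue
            v = _iou(det.start, det.end, t0, t1)
            if v >= best_iou:
                best, best_iou = j, v
        if best is not None:
            claimed[best] = True
            tp += 1
    fp = len(detections) - tp
    fn = len(intervals) - tp
    return DetectionMetrics(tp=tp, fp=fp, fn=fn)
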