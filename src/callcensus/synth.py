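"""Synthetic junglefowl-like calls, soundscapes, and survey scenarios.

The territorial call modelled here is a single four-note syllable
("ge-ga-ga-ge"): four harmonic-stack notes separated by three short gaps,
with a total duration of roughly 1.1-1.5 s and fundamentals in the
600-1110 Hz band.  Every generated object carries its ground truth
(individual identity, note boundaries, event times), so the detection,
measurement, individuality and clustering stages can all be validated
against known answers.

Individuality is injected the way it is observed in real corpora: each
individual's note durations, gaps and fundamentals are drawn once from an
among-individual distribution, and each call perturbs them by a small
within-individual coefficient of variation.  Peak frequency is made
deliberately *non*-individual by randomising the first-vs-second harmonic
amplitude ratio per call (in the field this ratio is scrambled by
distance-dependent high-frequency attenuation), so the strongest partial
flips between F0 and 2*F0 from call to call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dsp import DEFAULT_SAMPLE_RATE

TOTAL_DURATION_BOUNDS = (1.09, 1.50)  # s, observed range of syllable length
FUNDAMENTAL_BOUNDS = (600.0, 1110.0)  # Hz
MAX_REJECTS = 1000


@dataclass(frozen=True)
class IndividualProfile:
    """Ground-truth acoustic signature of one individual.

    ``harmonic_weights`` are the per-note amplitudes of the second partial
    (2*F0) relative to the first (F0 amplitude is 1).  ``within_cv`` maps
    each parameter group to the per-call coefficient of variation around
    the individual's means.  ``home_center`` is in metres in a local planar
    frame.
    """

    individual_id: str
    note_durations: np.ndarray  # (4,) s
    note_gaps: np.ndarray  # (3,) s
    fundamentals: np.ndarray  # (4,) Hz
    harmonic_weights: np.ndarray  # (4,) unitless
    harmonic3_weights: np.ndarray  # (4,) third-partial amplitude (timbre)
    note_amplitudes: np.ndarray  # (4,) relative note emphasis
    fm_slopes: np.ndarray  # (4,) fractional pitch sweep over each note
    within_cv: dict[str, np.ndarray]
    home_center: tuple[float, float] = (0.0, 0.0)

    @property
    def total_duration(self) -> float:
        return float(self.note_durations.sum() + self.note_gaps.sum())

    def validate(self) -> None:
        if not (1.0 <= self.total_duration <= 2.0):
            raise ValueError(
                f"total duration {self.total_duration:.3f} s outside [1.0, 2.0]"
            )
        lo, hi = FUNDAMENTAL_BOUNDS
        if np.any(self.fundamentals < lo) or np.any(self.fundamentals > hi):
            raise ValueError("fundamentals outside physical bounds")
        for cv in self.within_cv.values():
            if np.any(np.asarray(cv) < 0):
                raise ValueError("within_cv must be >= 0")


# Default within-individual CVs follow the pattern seen in measured pasture
# corpora: temporal and fundamental/harmonic variables are stable within an
# individual (CVw well below the among-individual CV), while the harmonic
# balance — and hence peak frequency — varies strongly call to call.
_DEFAULT_WITHIN_CV = {
    "note_durations": np.array([0.05, 0.04, 0.035, 0.06]),
    "note_gaps": np.array([0.08, 0.10, 0.10]),
    "fundamentals": np.array([0.018, 0.018, 0.018, 0.018]),
    "harmonic_weights": np.array([0.45, 0.45, 0.45, 0.45]),
    "harmonic3_weights": np.array([0.15, 0.15, 0.15, 0.15]),
    "note_amplitudes": np.array([0.06, 0.06, 0.06, 0.06]),
}

_DEFAULT_AMONG_CV = {
    "note_durations": np.array([0.20, 0.23, 0.29, 0.30]),
    "note_gaps": np.array([0.30, 0.40, 0.40]),
    "fundamentals": np.array([0.08, 0.08, 0.08, 0.08]),
    "harmonic_weights": np.array([0.30, 0.30, 0.30, 0.30]),
    "harmonic3_weights": np.array([0.50, 0.50, 0.50, 0.50]),
    "note_amplitudes": np.array([0.30, 0.30, 0.30, 0.30]),
}

# Among-individual CV of the shared pitch factor: one bird sings all four
# notes near its own overall pitch, so individuals separate in frequency as
# wholes rather than note by note.
_DEFAULT_PITCH_AMONG_CV = 0.18

_DEFAULT_MEANS = {
    "note_durations": np.array([0.27, 0.32, 0.32, 0.25]),
    "note_gaps": np.array([0.070, 0.060, 0.070]),
    "fundamentals": np.array([805.0, 830.0, 830.0, 805.0]),
    "harmonic_weights": np.array([1.2, 1.2, 1.2, 1.2]),
    "harmonic3_weights": np.array([0.45, 0.45, 0.45, 0.45]),
    "note_amplitudes": np.array([1.0, 1.0, 1.0, 1.0]),
}

# Per-note fractional pitch sweep (a slight rising or falling contour);
# individual-specific and stable within an individual.
_DEFAULT_FM_AMONG_SD = 0.28
_DEFAULT_FM_WITHIN_SD = 0.015


@dataclass(frozen=True)
class PopulationSpec:
    """Among/within-individual distribution of call parameters.

    Individuals' parameter means are drawn Normal(mean, among_cv * mean)
    per variable, truncated to physical bounds; calls perturb those means
    by ``within_cv``.
    """

    means: dict[str, np.ndarray] = field(
        default_factory=lambda: {k: v.copy() for k, v in _DEFAULT_MEANS.items()}
    )
    among_cv: dict[str, np.ndarray] = field(
        default_factory=lambda: {k: v.copy() for k, v in _DEFAULT_AMONG_CV.items()}
    )
    within_cv: dict[str, np.ndarray] = field(
        default_factory=lambda: {k: v.copy() for k, v in _DEFAULT_WITHIN_CV.items()}
    )
    # CV of a per-individual multiplicative factor applied to all four
    # fundamental means (an individual's overall pitch).
    pitch_among_cv: float = _DEFAULT_PITCH_AMONG_CV
    # SD of the per-individual, per-note fractional pitch sweep
    fm_among_sd: float = _DEFAULT_FM_AMONG_SD
    fm_within_sd: float = _DEFAULT_FM_WITHIN_SD


@dataclass
class SoundscapeTruth:
    """Ground-truth event log for a rendered soundscape."""

    events: list[tuple[str, str, float, float]]  # individual, recorder, on, off
    confounders: list[tuple[float, float, str]]

    def events_for(self, recorder_id: str) -> list[tuple[str, float, float]]:
        return [
            (ind, on, off)
            for ind, rec, on, off in self.events
            if rec == recorder_id
        ]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _draw_profile(spec: PopulationSpec, rng: np.random.Generator) -> dict:
    draw = {}
    for key, mu in spec.means.items():
        sd = spec.among_cv[key] * mu
        draw[key] = rng.normal(mu, sd)
    draw["fundamentals"] = draw["fundamentals"] * rng.normal(
        1.0, spec.pitch_among_cv
    )
    draw["fm_slopes"] = rng.normal(0.0, spec.fm_among_sd, size=4)
    return draw


def _band_visibility_ok(d: dict, lo=800.0, hi=1700.0, min_ratio=0.18) -> bool:
    """Every note must be visible in the detector's analysis band.

    Real territorial calls all carry energy in the 850-1650 Hz band (that
    is how the detection band was chosen from measured calls), so profiles
    whose quietest note has no usable partial there — and would never
    yield a clean detection — are not part of the modelled population.
    """
    vis = []
    for i in range(4):
        f0 = d["fundamentals"][i]
        partials = (
            (1.0, f0),
            (d["harmonic_weights"][i], 2 * f0),
            (abs(d["harmonic3_weights"][i]), 3 * f0),
        )
        strongest = max((a for a, f in partials if lo <= f <= hi), default=0.0)
        vis.append(d["note_amplitudes"][i] * strongest)
    vis = np.asarray(vis)
    return vis.max() > 0 and vis.min() >= min_ratio * vis.max()


def sample_population(
    n_individuals: int,
    population_spec: PopulationSpec | None = None,
    seed=0,
) -> list[IndividualProfile]:
    """Draw ``n_individuals`` independent acoustic profiles.

    Draws violating physical bounds (negative durations/gaps, fundamentals
    outside 600-1110 Hz, total syllable duration outside 1.09-1.50 s) are
    rejected and resampled; more than 1000 consecutive rejects for one
    individual raises, which indicates a spec whose spread is incompatible
    with the bounds.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    spec = population_spec or PopulationSpec()
    rng = _as_rng(seed)
    profiles = []
    for i in range(n_individuals):
        for attempt in range(MAX_REJECTS + 1):
            d = _draw_profile(spec, rng)
            total = d["note_durations"].sum() + d["note_gaps"].sum()
            ok = (
                np.all(d["note_durations"] > 0.02)
                # gaps shorter than ~30 ms cannot be resolved as silences
                # at the fixed spectrogram resolution (11.6 ms window)
                and np.all(d["note_gaps"] > 0.03)
                and np.all(d["fundamentals"] >= FUNDAMENTAL_BOUNDS[0])
                and np.all(d["fundamentals"] <= FUNDAMENTAL_BOUNDS[1])
                and np.all(d["harmonic_weights"] > 0.05)
                and np.all(d["note_amplitudes"] > 0.3)
                and _band_visibility_ok(d)
                and TOTAL_DURATION_BOUNDS[0] <= total <= TOTAL_DURATION_BOUNDS[1]
            )
            if ok:
                break
        else:
            raise RuntimeError(
                f"rejected {MAX_REJECTS} draws for individual {i}: "
                "population spec incompatible with physical bounds"
            )
        profiles.append(
            IndividualProfile(
                individual_id=f"ind{i:03d}",
                note_durations=d["note_durations"],
                note_gaps=d["note_gaps"],
                fundamentals=d["fundamentals"],
                harmonic_weights=d["harmonic_weights"],
                harmonic3_weights=np.abs(d["harmonic3_weights"]),
                note_amplitudes=d["note_amplitudes"],
                fm_slopes=d["fm_slopes"],
                within_cv={k: v.copy() for k, v in spec.within_cv.items()},
            )
        )
    return profiles


def _perturb(mu: np.ndarray, cv: np.ndarray, rng, lo=None, hi=None) -> np.ndarray:
    out = rng.normal(mu, cv * np.abs(mu))
    if lo is not None or hi is not None:
        out = np.clip(out, lo, hi)
    return out


def render_call(
    profile: IndividualProfile,
    snr_db: float = np.inf,
    seed=0,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    pad_s: float = 1.0,
    ramp_s: float = 0.015,
    fm_within_sd: float = _DEFAULT_FM_WITHIN_SD,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Synthesize one call; returns (audio, per-note truth intervals).

    Each note is a two-partial harmonic stack (F0 and 2*F0) with
    raised-cosine onset/offset ramps; per-call parameters are the profile
    means perturbed by the profile's within-individual CVs.  Gaussian
    background noise is added across the whole buffer at ``snr_db``
    relative to the voiced-segment RMS (``snr_db=inf`` -> noiseless).
    ``pad_s`` seconds of background are prepended/appended so the call sits
    in context; truth intervals are in seconds from the buffer start.
    """
    rng = _as_rng(seed)
    cv = profile.within_cv
    durs = _perturb(profile.note_durations, cv["note_durations"], rng, lo=0.02)
    gaps = _perturb(profile.note_gaps, cv["note_gaps"], rng, lo=0.005)
    f0s = _perturb(
        profile.fundamentals, cv["fundamentals"], rng,
        lo=FUNDAMENTAL_BOUNDS[0], hi=FUNDAMENTAL_BOUNDS[1],
    )
    hw = _perturb(profile.harmonic_weights, cv["harmonic_weights"], rng, lo=0.05)
    hw3 = _perturb(profile.harmonic3_weights, cv["harmonic3_weights"], rng, lo=0.0)
    amps = _perturb(profile.note_amplitudes, cv["note_amplitudes"], rng, lo=0.1)
    slopes = profile.fm_slopes + rng.normal(0.0, fm_within_sd, size=4)

    pieces = []
    intervals = []
    t_cursor = pad_s
    pieces.append(np.zeros(int(round(pad_s * sample_rate))))
    for i in range(4):
        n = int(round(durs[i] * sample_rate))
        t = np.arange(n) / sample_rate
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        # linear pitch contour: f(t) = f0 * (1 + slope * (t/d - 1/2))
        d_i = max(n / sample_rate, 1e-6)
        inst = f0s[i] * (1.0 + slopes[i] * (t / d_i - 0.5))
        phase = 2 * np.pi * np.cumsum(inst) / sample_rate
        ph3 = rng.uniform(0, 2 * np.pi)
        tone = (
            np.sin(phase + ph1)
            + hw[i] * np.sin(2.0 * phase + ph2)
            + hw3[i] * np.sin(3.0 * phase + ph3)
        )
        tone *= amps[i]
        n_ramp = min(int(round(ramp_s * sample_rate)), n // 2)
        if n_ramp > 0:
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
            tone[:n_ramp] *= ramp
            tone[-n_ramp:] *= ramp[::-1]
        pieces.append(tone)
        intervals.append((t_cursor, t_cursor + n / sample_rate))
        t_cursor += n / sample_rate
        if i < 3:
            g = int(round(gaps[i] * sample_rate))
            pieces.append(np.zeros(g))
            t_cursor += g / sample_rate
    pieces.append(np.zeros(int(round(pad_s * sample_rate))))
    audio = np.concatenate(pieces)

    if np.isfinite(snr_db):
        voiced = audio[audio != 0]
        sig_rms = np.sqrt(np.mean(voiced**2)) if voiced.size else 1.0
        noise_rms = sig_rms / (10.0 ** (snr_db / 20.0))
        audio = audio + rng.normal(0.0, noise_rms, size=audio.size)
    return audio, intervals


@dataclass(frozen=True)
class Recorder:
    recorder_id: str
    position: tuple[float, float]  # m


@dataclass(frozen=True)
class ScheduleSpec:
    """Poisson call schedule per individual."""

    call_rate_per_min: float = 1.0
    duration_s: float = 120.0
    snr_db: float = 20.0
    detection_radius_m: float = 150.0
    reference_distance_m: float = 10.0  # distance at which gain = 1
    refractory_s: float = 3.0  # a bird cannot overlap its own calls


@dataclass(frozen=True)
class ConfounderSpec:
    """Non-target sounds sharing the band (other species, machinery)."""

    rate_per_min: float = 0.0
    kind: str = "tone"  # "tone" | "chirp"
    freq_hz: float = 1200.0
    duration_s: float = 0.6
    amplitude: float = 0.5


def render_soundscape(
    profiles: list[IndividualProfile],
    recorders: list[Recorder],
    schedule_spec: ScheduleSpec | None = None,
    confounder_spec: ConfounderSpec | None = None,
    seed=0,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> tuple[dict[str, np.ndarray], SoundscapeTruth]:
    """Render per-recorder audio with a complete ground-truth event log.

    Calls are placed at Poisson onsets per individual, attenuated by
    ``reference_distance / distance`` from the home centre to each
    recorder, and only mixed into (and logged for) recorders within the
    detection radius.  Background Gaussian noise of unit reference level
    scaled to the schedule SNR is added per channel.
    """
    if not recorders:
        raise ValueError("recorder list must be non-empty")
    sched = schedule_spec or ScheduleSpec()
    conf = confounder_spec or ConfounderSpec()
    rng = _as_rng(seed)
    n_samp = int(round(sched.duration_s * sample_rate))
    # Noise floor chosen so a call at the reference distance has the
    # schedule's SNR.
    ref_rms = 0.55  # typical voiced RMS of a unit-amplitude 2-partial stack
    noise_rms = ref_rms / (10.0 ** (sched.snr_db / 20.0))
    channels = {
        r.recorder_id: rng.normal(0.0, noise_rms, size=n_samp) for r in recorders
    }
    events: list[tuple[str, str, float, float]] = []
    confounders: list[tuple[float, float, str]] = []

    for prof in profiles:
        n_calls = rng.poisson(sched.call_rate_per_min * sched.duration_s / 60.0)
        onsets = np.sort(rng.uniform(0, sched.duration_s, size=n_calls))
        # thin onsets closer than the refractory interval to the last call
        kept, last = [], -np.inf
        for onset in onsets:
            if onset - last >= sched.refractory_s:
                kept.append(onset)
                last = onset
        for onset in kept:
            call, _ = render_call(
                prof, snr_db=np.inf, seed=rng, sample_rate=sample_rate, pad_s=0.0
            )
            i0 = int(round(onset * sample_rate))
            if i0 + call.size > n_samp:
                continue
            for rec in recorders:
                d = float(np.hypot(
                    prof.home_center[0] - rec.position[0],
                    prof.home_center[1] - rec.position[1],
                ))
                if d > sched.detection_radius_m:
                    continue
                gain = sched.reference_distance_m / max(d, sched.reference_distance_m)
                channels[rec.recorder_id][i0 : i0 + call.size] += gain * call
                events.append(
                    (prof.individual_id, rec.recorder_id, onset,
                     onset + call.size / sample_rate)
                )

    n_conf = rng.poisson(conf.rate_per_min * sched.duration_s / 60.0)
    for onset in np.sort(rng.uniform(0, sched.duration_s, size=n_conf)):
        n = int(round(conf.duration_s * sample_rate))
        i0 = int(round(onset * sample_rate))
        if i0 + n > n_samp:
            continue
        t = np.arange(n) / sample_rate
        if conf.kind == "chirp":
            f = conf.freq_hz * (1 + 0.5 * t / conf.duration_s)
            burst = conf.amplitude * np.sin(2 * np.pi * np.cumsum(f) / sample_rate)
        else:
            burst = conf.amplitude * np.sin(2 * np.pi * conf.freq_hz * t)
        for ch in channels.values():
            ch[i0 : i0 + n] += burst
        confounders.append((onset, onset + conf.duration_s, conf.kind))

    return channels, SoundscapeTruth(events=events, confounders=confounders)


@dataclass
class SurveyScenario:
    recorders: list[Recorder]
    profiles: list[IndividualProfile]
    assignments: dict[str, list[str]]  # recorder_id -> individual_ids in range
    transect_count: int
    survey_area_km2: float
    total_area_km2: float


def simulate_survey(
    n_individuals: int,
    area_km2: float,
    recorder_spacing_m: float = 150.0,
    transect_spec: dict | None = None,
    seed=0,
    detection_radius_m: float = 150.0,
    population_spec: PopulationSpec | None = None,
) -> SurveyScenario:
    """Place a recorder grid and a population over a square study area.

    Individuals are uniform over the area; each individual is assigned to
    every recorder within the detection radius (the same bird heard on
    several nearby recorders is exactly the pseudo-replication a naive
    per-recorder count inflates on).  The transect is a strip of the given
    survey area along one edge; its count is the number of individuals
    whose home centre falls inside the strip.
    """
    if area_km2 <= 0 or recorder_spacing_m <= 0:
        raise ValueError("area and spacing must be positive")
    rng = _as_rng(seed)
    side_m = np.sqrt(area_km2) * 1000.0
    n_per_side = int(side_m // recorder_spacing_m)
    if n_per_side < 1:
        warnings.warn("recorder spacing exceeds area extent; using one recorder")
        coords = [(side_m / 2, side_m / 2)]
    else:
        offs = (side_m - (n_per_side - 1) * recorder_spacing_m) / 2
        coords = [
            (offs + i * recorder_spacing_m, offs + j * recorder_spacing_m)
            for i in range(n_per_side)
            for j in range(n_per_side)
        ]
    recorders = [
        Recorder(recorder_id=f"rec{k:04d}", position=xy)
        for k, xy in enumerate(coords)
    ]

    profiles = sample_population(n_individuals, population_spec, seed=rng)
    homes = rng.uniform(0, side_m, size=(n_individuals, 2))
    profiles = [
        IndividualProfile(
            individual_id=p.individual_id,
            note_durations=p.note_durations,
            note_gaps=p.note_gaps,
            fundamentals=p.fundamentals,
            harmonic_weights=p.harmonic_weights,
            harmonic3_weights=p.harmonic3_weights,
            note_amplitudes=p.note_amplitudes,
            fm_slopes=p.fm_slopes,
            within_cv=p.within_cv,
            home_center=(float(homes[i, 0]), float(homes[i, 1])),
        )
        for i, p in enumerate(profiles)
    ]

    assignments: dict[str, list[str]] = {r.recorder_id: [] for r in recorders}
    for p in profiles:
        for r in recorders:
            d = np.hypot(
                p.home_center[0] - r.position[0], p.home_center[1] - r.position[1]
            )
            if d <= detection_radius_m:
                assignments[r.recorder_id].append(p.individual_id)

    spec = transect_spec or {"survey_area_km2": min(area_km2, 4.62)}
    survey_area = float(spec.get("survey_area_km2", min(area_km2, 4.62)))
    strip_width_m = min(survey_area * 1e6 / side_m, side_m)
    transect_count = int(sum(p.home_center[0] <= strip_width_m for p in profiles))

    return SurveyScenario(
        recorders=recorders,
        profiles=profiles,
        assignments=assignments,
        transect_count=transect_count,
        survey_area_km2=strip_width_m * side_m / 1e6,
        total_area_km2=area_km2,
    )
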