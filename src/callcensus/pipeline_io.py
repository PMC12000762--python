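"""File formats, configuration, and the end-to-end pipeline.

Audio is RIFF WAV, mono 16-bit PCM at 22,050 Hz (other rates are resampled
with a warning; stereo input keeps the left channel).  Tabular artifacts
(measurements, detections, similarity matrices) are plain CSV with fixed
headers so runs round-trip losslessly.  ``run_pipeline`` ties the stages
together on a synthetic scenario and emits a JSON-serialisable report;
a given config + seed always produces the identical report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile
from scipy.signal import resample_poly

from . import cluster as _cluster
from . import individuality as _ind
from . import survey as _survey
from .detect import CallDetection, DetectorConfig, detect_candidates
from .dsp import DEFAULT_SAMPLE_RATE, SpectrogramConfig, compute_spectrogram
from .measure import VARIABLE_NAMES, CallMeasurements, MeasurementFailure, measure_detection
from .synth import PopulationSpec, render_call, sample_population

MEASUREMENT_COLUMNS = ("call_id", "individual_id", *VARIABLE_NAMES)
DETECTION_COLUMNS = ("recorder", "start", "end", "score", "label")


def build_clear_corpus(
    profiles,
    calls_per_individual: int,
    snr_db: float = 20.0,
    seed=0,
    spectrogram_config: SpectrogramConfig | None = None,
    detector_config: DetectorConfig | None = None,
    max_attempts_factor: int = 5,
):
    """Select ``calls_per_individual`` *clear* calls per individual.

    Mirrors manual curation: a call is kept only if the detector finds it
    as exactly one candidate and it segments into four notes cleanly;
    otherwise another call is recorded.  Returns (cut spectrograms,
    measurements, labels), with the spectrograms trimmed to the detected
    syllable for cross-correlation.

    Raises ``RuntimeError`` if an individual cannot produce enough clear
    calls within ``max_attempts_factor * calls_per_individual`` attempts.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    specs, measurements, labels = [], [], []
    for p in profiles:
        kept = 0
        for _ in range(max_attempts_factor * calls_per_individual):
            if kept == calls_per_individual:
                break
            audio, _ = render_call(p, snr_db=snr_db, seed=rng)
            spec = compute_spectrogram(audio, spectrogram_config)
            dets = detect_candidates(spec, detector_config)
            if len(dets) != 1:
                continue
            try:
                m = measure_detection(
                    spec, dets[0], detector_config,
                    call_id=f"{p.individual_id}_c{kept}",
                    individual_id=p.individual_id,
                )
            except MeasurementFailure:
                continue
            specs.append(spec.slice_time(dets[0].start, dets[0].end))
            measurements.append(m)
            labels.append(p.individual_id)
            kept += 1
        else:
            if kept < calls_per_individual:
                raise RuntimeError(
                    f"{p.individual_id}: only {kept} clear calls found"
                )
    return specs, measurements, labels


# ---------------------------------------------------------------- audio I/O

def read_audio(path) -> tuple[np.ndarray, int]:
    """Read a WAV file as float64 in [-1, 1); returns (samples, rate).

    Stereo files keep the left channel.  Files not at 22,050 Hz are
    resampled to it with a warning.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:
        raise ValueError(f"cannot read WAV file {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        audio = data.astype(np.float64) / scale
    else:
        audio = data.astype(np.float64)
    if rate != DEFAULT_SAMPLE_RATE:
        warnings.warn(
            f"{path.name}: resampling {rate} Hz -> {DEFAULT_SAMPLE_RATE} Hz"
        )
        audio = resample_poly(audio, DEFAULT_SAMPLE_RATE, rate)
        rate = DEFAULT_SAMPLE_RATE
    return audio, rate


def write_audio(path, samples: np.ndarray, sample_rate: int = DEFAULT_SAMPLE_RATE):
    """Write mono float samples as 16-bit PCM WAV."""
    samples = np.asarray(samples, dtype=np.float64)
    pcm = np.clip(np.round(samples * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(Path(path), sample_rate, pcm)


# -------------------------------------------------------------- tabular I/O

def write_measurements(path, measurements: list[CallMeasurements]):
    rows = []
    for m in measurements:
        row = {"call_id": m.call_id, "individual_id": m.individual_id}
        row.update(m.as_dict())
        rows.append(row)
    pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS).to_csv(path, index=False)


def read_measurements(path) -> list[CallMeasurements]:
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement CSV missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        ind = row["individual_id"]
        out.append(
            CallMeasurements(
                call_id=str(row["call_id"]),
                individual_id=None if pd.isna(ind) else str(ind),
                **{v: float(row[v]) for v in VARIABLE_NAMES},
            )
        )
    return out


def write_matrix(path, matrix: _cluster.SimilarityMatrix):
    pd.DataFrame(
        matrix.values, index=matrix.call_ids, columns=matrix.call_ids
    ).to_csv(path)


def read_matrix(path) -> _cluster.SimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("matrix CSV header and index disagree")
    return _cluster.SimilarityMatrix(
        values=df.to_numpy(dtype=float), call_ids=[str(c) for c in df.columns]
    )


def write_detections(path, detections: list[CallDetection]):
    rows = [
        {"recorder": d.recorder_id, "start": d.start, "end": d.end,
         "score": d.score, "label": d.label}
        for d in detections
    ]
    pd.DataFrame(rows, columns=DETECTION_COLUMNS).to_csv(path, index=False)


# ------------------------------------------------------------ configuration

_DEFAULT_CONFIG: dict = {
    "seed": 0,
    "corpus": {
        "n_individuals": 5,
        "calls_per_individual": 5,
        "train_calls": 3,
        "snr_db": 20.0,
    },
    "spectrogram": {"nfft": 256, "overlap": 0.75, "sample_rate": 22050},
    "detector": {
        "fmin": 850.0, "fmax": 1650.0,
        "min_len": 1.0, "max_len": 2.0, "max_gap": 0.2,
    },
    "spcc": {"max_freq_shift_hz": 50.0, "band_low": 400.0, "band_high": 3600.0},
    "ap": {"preference": None, "damping": 0.9, "max_iter": 1000, "conv_iter": 100},
    "home_range_ha": 11.0,
    "survey": {
        "counts_per_day": [79, 153],
        "survey_area_km2": 4.62,
        "total_area_km2": 7.05,
        "group_sizes": [],
    },
}


def _merge_checked(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = {}
    unknown = set(overrides) - set(defaults)
    if unknown:
        raise ValueError(f"unknown config keys at '{path or '/'}': {sorted(unknown)}")
    for key, dval in defaults.items():
        oval = overrides.get(key, dval)
        if isinstance(dval, dict) and isinstance(oval, dict):
            out[key] = _merge_checked(dval, oval, f"{path}{key}.")
        else:
            out[key] = oval
    return out


@dataclass
class PipelineConfig:
    """All stage defaults plus the run seed; round-trips through YAML."""

    settings: dict = field(default_factory=lambda: _merge_checked(_DEFAULT_CONFIG, {}))

    @classmethod
    def from_dict(cls, overrides: dict) -> "PipelineConfig":
        return cls(settings=_merge_checked(_DEFAULT_CONFIG, overrides))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.settings, fh, sort_keys=True)

    def __getitem__(self, key):
        return self.settings[key]

    def hash(self) -> str:
        blob = json.dumps(self.settings, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# -------------------------------------------------------------- the pipeline

def run_pipeline(config: PipelineConfig | dict | None = None, out_path=None) -> dict:
    """Run the synthetic end-to-end workflow and return the report.

    Stages: sample a population, render calls, detect them, measure the 20
    variables, compute PIC and select variables, train/test the DFA, build
    the SPCC similarity matrix, test clusterability (Hopkins), cluster with
    affinity propagation, validate clusters spatially, and run the transect
    arithmetic.  The report carries every stage's statistics plus the seed
    and a config hash; rerunning with the same config reproduces it
    byte-identically.
    """
    if config is None:
        config = PipelineConfig()
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    cfg = config.settings
    seed = int(cfg["seed"])
    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(4)
    rng_pop, rng_calls, rng_ap, rng_val = (np.random.default_rng(s) for s in seeds)

    corpus = cfg["corpus"]
    n_ind = int(corpus["n_individuals"])
    n_calls = int(corpus["calls_per_individual"])
    n_train = int(corpus["train_calls"])
    snr = float(corpus["snr_db"])

    sp_cfg = SpectrogramConfig(
        sample_rate=cfg["spectrogram"]["sample_rate"],
        nfft=cfg["spectrogram"]["nfft"],
        overlap=cfg["spectrogram"]["overlap"],
    )
    det_cfg = DetectorConfig(**cfg["detector"])

    # --- synth + detect + measure
    profiles = sample_population(n_ind, PopulationSpec(), seed=rng_pop)
    # spread homes on a coarse grid so spatial validation has structure
    grid = int(np.ceil(np.sqrt(n_ind)))
    profiles = [
        dataclasses.replace(
            p, home_center=(500.0 * (i % grid), 500.0 * (i // grid))
        )
        for i, p in enumerate(profiles)
    ]

    specs, measurements, labels = build_clear_corpus(
        profiles, n_calls, snr_db=snr, seed=rng_calls,
        spectrogram_config=sp_cfg, detector_config=det_cfg,
    )
    homes = {p.individual_id: p.home_center for p in profiles}
    coords = [homes[lab] for lab in labels]

    if len(set(labels)) < 2:
        raise RuntimeError("pipeline stage 'measure': fewer than 2 individuals survived")

    # --- PIC + DFA
    pic_table = _ind.compute_pic(measurements)
    selected = _ind.select_variables(pic_table)
    by_ind: dict[str, list[CallMeasurements]] = {}
    for m in measurements:
        by_ind.setdefault(m.individual_id, []).append(m)
    train, test = [], []
    for ms in by_ind.values():
        train.extend(ms[:n_train])
        test.extend(ms[n_train:])
    dfa_rate = None
    if test and all(len(ms) > n_train for ms in by_ind.values()):
        model = _ind.train_dfa(train, selected)
        _, dfa_rate = _ind.dfa_accuracy(model, test)

    # --- SPCC + Hopkins + AP + validation
    spcc_cfg = cfg["spcc"]
    matrix = _cluster.similarity_matrix(
        specs,
        max_freq_shift_hz=spcc_cfg["max_freq_shift_hz"],
        band=(spcc_cfg["band_low"], spcc_cfg["band_high"]),
        call_ids=[m.call_id for m in measurements],
        coordinates=coords,
    )
    comparison = _cluster.compare_within_between(matrix, labels)
    hopkins = _cluster.hopkins_statistic(matrix, seed=rng_ap) if matrix.n >= 10 else None
    ap_cfg = cfg["ap"]
    ap = _cluster.ap_cluster(
        matrix,
        preference=ap_cfg["preference"],
        damping=ap_cfg["damping"],
        max_iter=int(ap_cfg["max_iter"]),
        conv_iter=int(ap_cfg["conv_iter"]),
        seed=rng_ap,
    )
    _, cluster_acc = _cluster.clustering_accuracy(ap.assignment, labels)
    _, validation_acc = _cluster.validate_wild_clusters(
        ap, matrix, home_range_ha=cfg["home_range_ha"],
        sample_n=matrix.n, seed=rng_val,
    )

    # --- survey arithmetic
    sv = cfg["survey"]
    n_males = _survey.max_over_repeats(sv["counts_per_day"])
    estimate = _survey.estimate_population(
        n_males, sv["survey_area_km2"], sv["total_area_km2"]
    )
    comparison_est = _survey.compare_estimates(ap.n_clusters, estimate.raw)
    groups = (
        _survey.group_statistics(sv["group_sizes"]).__dict__
        if sv["group_sizes"] else None
    )

    report = {
        "seed": seed,
        "config_hash": config.hash(),
        "n_individuals": n_ind,
        "n_calls_measured": len(measurements),
        "pic": {
            v: {k: (None if not np.isfinite(val) else round(float(val), 6))
                if k != "selected" else bool(val)
                for k, val in row.items()}
            for v, row in pic_table.to_dict("index").items()
        },
        "selected_variables": selected,
        "dfa_rate": None if dfa_rate is None else round(float(dfa_rate), 6),
        "similarity": {
            "mean_same": round(comparison.mean_same, 6),
            "sd_same": round(comparison.sd_same, 6),
            "mean_diff": round(comparison.mean_diff, 6),
            "sd_diff": round(comparison.sd_diff, 6),
            "ks_D": round(comparison.ks_D, 6),
            "p_value": float(f"{comparison.p_value:.6g}"),
        },
        "hopkins": None if hopkins is None else round(float(hopkins), 6),
        "ap": {
            "n_clusters": ap.n_clusters,
            "converged": ap.converged,
            "iterations": ap.iterations,
            "clustering_accuracy": round(float(cluster_acc), 6),
            "validation_accuracy": round(float(validation_acc), 6),
        },
        "survey": {
            "n_males_observed": n_males,
            "survey_area_km2": sv["survey_area_km2"],
            "total_area_km2": sv["total_area_km2"],
            "estimate_raw": round(estimate.raw, 4),
            "estimate": estimate.rounded,
            "pct_vs_clustering": round(comparison_est.pct_vs_clustering, 4),
            "pct_vs_transect": round(comparison_est.pct_vs_transect, 4),
            "groups": groups,
        },
    }
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
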