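"""Snore-sound synthesis and synthetic-cohort generation.

The source–filter view of snoring: a low-frequency vibratory source (soft
palate or pharyngeal wall, fundamental ~100 Hz) drives the upper airway,
whose transfer function shapes the radiated spectrum; the resonance in the
450–800 Hz region is what the feature stack later measures as F1.

The default source is a jittered harmonic series rather than a bare
sinusoid: a pure ~100 Hz tone carries no energy near the airway resonance,
so the harmonic content (with a -6 dB/octave rolloff, as for glottal-like
pulse sources) is what actually excites and reveals the resonance.
Cycle-to-cycle jitter emulates the irregularity of real snoring and lets
harmonics sweep across the narrow resonance.

The recording chain is emulated by adding broadband microphone noise and a
5 kHz anti-alias low-pass before 16-bit quantization at fs = 12.5 kHz.

Cohort generation draws anatomy from truncated normal distributions with
the study's means and SDs:
    NC 41.8 ± 2.9 cm, UA-XSA 2.6 ± 0.6 cm², UA-Length 9.1 ± 1.8 cm,
    after-sleep changes ΔNC +0.5 ± 0.3 cm and ΔUA-XSA −0.4 ± 0.3 cm²,
    pitch 102.1 ± 20.6 Hz truncated to [50, 300] Hz,
    AHI 27.6 ± 25.8 events/h truncated at 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.io import wavfile
from scipy.stats import truncnorm

from .acoustic_model import (
    ModelConfig,
    ModelPrediction,
    PhysicalConstants,
    predict_subject,
    _response,
)
from .anatomy import SubjectAnatomy, derive_geometry

__all__ = [
    "SourceSpec",
    "SnoreRecording",
    "CohortDistribution",
    "generate_source",
    "synthesize_snore",
    "generate_cohort",
    "write_wav",
    "read_wav",
]

PEAK_DBFS = -3.0  # peak-normalization target for WAV output
ANTIALIAS_HZ = 5000.0  # recording-chain low-pass cutoff


@dataclass(frozen=True)
class SourceSpec:
    """Parameters of the vibratory snore source.

    ``harmonic_rolloff`` is in dB/octave (amplitude of harmonic k scales as
    k**(rolloff/20/log10(2))); ``jitter_pct`` is the SD of the cycle-to-cycle
    fundamental-period perturbation in percent.
    """

    f0: float = 102.1  # Hz, cohort-mean pitch
    n_harmonics: int = 48
    harmonic_rolloff: float = -6.0  # dB/octave
    jitter_pct: float = 3.0
    noise_snr_db: float = 30.0
    duration_s: float = 2.0
    fs: float = 12500.0

    def __post_init__(self) -> None:
        if not 50.0 <= self.f0 <= 300.0:
            raise ValueError(f"f0 must lie in [50, 300] Hz, got {self.f0}")
        if self.f0 >= self.fs / 2:
            raise ValueError("f0 at or above Nyquist")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.n_harmonics < 1:
            raise ValueError("need at least one harmonic")


@dataclass
class SnoreRecording:
    """A synthesized (or loaded) snore waveform with annotations and truth."""

    samples: np.ndarray
    fs: float
    annotations: list[tuple[float, float, str]] = field(default_factory=list)
    truth: dict | None = None  # ModelPrediction + SourceSpec of the synthesis

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class CohortDistribution:
    """Anatomy sampling distribution (means/SDs in clinical units)."""

    nc_mean: float = 41.8
    nc_sd: float = 2.9
    ua_xsa_mean: float = 2.6
    ua_xsa_sd: float = 0.6
    ua_length_mean: float = 9.1
    ua_length_sd: float = 1.8
    delta_nc_mean: float = 0.5
    delta_nc_sd: float = 0.3
    delta_ua_xsa_mean: float = -0.4
    delta_ua_xsa_sd: float = 0.3
    pitch_mean: float = 102.1
    pitch_sd: float = 20.6
    ahi_mean: float = 27.6
    ahi_sd: float = 25.8


def generate_source(spec: SourceSpec, seed: int | None = 0) -> np.ndarray:
    """Generate the harmonic source waveform (deterministic given seed).

    The fundamental period is perturbed cycle by cycle (jitter); all
    harmonics share the cumulative phase, so the waveform stays pulse-like.
    With ``n_harmonics = 1`` and zero jitter this degenerates to the pure
    sinusoid source.
    """
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration_s * spec.fs))
    dt = 1.0 / spec.fs

    # instantaneous f0 per cycle; expected cycles plus margin
    n_cycles = int(math.ceil(spec.duration_s * spec.f0 * 1.5)) + 2
    jitter = rng.normal(0.0, spec.jitter_pct / 100.0, size=n_cycles)
    cycle_f0 = spec.f0 * np.clip(1.0 + jitter, 0.5, 1.5)

    # cumulative phase phi(t): piecewise-linear, one cycle per unit of phi
    t = np.arange(n) * dt
    cycle_T = 1.0 / cycle_f0
    cycle_edges = np.concatenate([[0.0], np.cumsum(cycle_T)])
    idx = np.clip(np.searchsorted(cycle_edges, t, side="right") - 1, 0, n_cycles - 1)
    phi = idx + (t - cycle_edges[idx]) * cycle_f0[idx]

    nyq = spec.fs / 2.0
    k_max = min(spec.n_harmonics, int(math.floor((nyq - 1e-9) / spec.f0)))
    k_max = max(k_max, 1)
    x = np.zeros(n)
    slope = spec.harmonic_rolloff / (20.0 * math.log10(2.0))  # amp ~ k**slope
    for k in range(1, k_max + 1):
        x += (k**slope) * np.sin(2.0 * math.pi * k * phi)
    peak = np.max(np.abs(x))
    if peak > 0:
        x /= peak
    return x


def _apply_transfer(
    x: np.ndarray,
    fs: float,
    subject: SubjectAnatomy,
    constants: PhysicalConstants,
    config: ModelConfig,
    use_after_sleep: bool = False,
) -> np.ndarray:
    """Filter by H(f): multiplication of the zero-padded spectrum.

    Zero-phase (magnitude-only) equivalent: the acoustic phase does not
    affect any of the extracted spectral features.
    """
    geom = derive_geometry(subject, use_after_sleep=use_after_sleep)
    n = len(x)
    n_fft = int(2 ** math.ceil(math.log2(max(2 * n, 16))))
    X = np.fft.rfft(x, n_fft)
    f = np.fft.rfftfreq(n_fft, 1.0 / fs)
    H = _response(geom, f, constants, config)
    y = np.fft.irfft(X * np.abs(H), n_fft)[:n]
    return y


def synthesize_snore(
    subject: SubjectAnatomy,
    spec: SourceSpec = SourceSpec(),
    constants: PhysicalConstants = PhysicalConstants(),
    seed: int | None = 0,
    config: ModelConfig = ModelConfig(),
    use_after_sleep: bool = False,
) -> SnoreRecording:
    """Synthesize one snore segment through the subject's airway model.

    Pipeline: harmonic source -> multiply spectrum by |H(f)| -> add white
    microphone noise at ``noise_snr_db`` -> 5 kHz anti-alias low-pass ->
    peak-normalize to -3 dBFS.  The returned ``truth`` block records the
    model prediction and source parameters used.
    """
    src_spec = spec
    if subject.pitch_hz is not None and subject.pitch_hz != spec.f0:
        src_spec = SourceSpec(**{**asdict(spec), "f0": subject.pitch_hz})
    rng = np.random.default_rng(seed)
    source = generate_source(src_spec, seed=rng.integers(2**31))
    y = _apply_transfer(source, src_spec.fs, subject, constants, config,
                        use_after_sleep=use_after_sleep)

    if np.any(y != 0.0) and np.isfinite(src_spec.noise_snr_db):
        p_sig = float(np.mean(y**2))
        p_noise = p_sig / (10.0 ** (src_spec.noise_snr_db / 10.0))
        y = y + rng.normal(0.0, math.sqrt(p_noise), size=len(y))

    if ANTIALIAS_HZ < src_spec.fs / 2.0:
        sos = signal.butter(8, ANTIALIAS_HZ, fs=src_spec.fs, output="sos")
        y = signal.sosfiltfilt(sos, y)

    peak = float(np.max(np.abs(y)))
    if peak > 0:
        y = y * (10.0 ** (PEAK_DBFS / 20.0) / peak)

    pred = predict_subject(subject, constants, config, use_after_sleep=use_after_sleep)
    truth = {"prediction": asdict(pred), "source": asdict(src_spec)}
    return SnoreRecording(
        samples=y,
        fs=src_spec.fs,
        annotations=[(0.0, len(y) / src_spec.fs, "snore")],
        truth=truth,
    )


def _trunc_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    n: int,
    seed: int | None = 0,
    dist: CohortDistribution = CohortDistribution(),
) -> list[SubjectAnatomy]:
    """Sample a synthetic cohort with the study's anatomy statistics.

    Truncation bounds: NC > 10 cm, UA-XSA > 0.5 cm², UA-Length > 3 cm,
    after-sleep area > 0.3 cm², pitch in [50, 300] Hz, AHI >= 0; records
    violating N_r > T_r are resampled.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    subjects: list[SubjectAnatomy] = []
    guard = 0
    while len(subjects) < n and guard < 100 * n + 100:
        guard += 1
        nc = float(_trunc_normal(rng, dist.nc_mean, dist.nc_sd, 10.0, np.inf, 1)[0])
        xsa = float(
            _trunc_normal(rng, dist.ua_xsa_mean, dist.ua_xsa_sd, 0.5, np.inf, 1)[0]
        )
        length = float(
            _trunc_normal(rng, dist.ua_length_mean, dist.ua_length_sd, 3.0, np.inf, 1)[0]
        )
        d_nc = float(rng.normal(dist.delta_nc_mean, dist.delta_nc_sd))
        d_xsa = float(rng.normal(dist.delta_ua_xsa_mean, dist.delta_ua_xsa_sd))
        pitch = float(
            _trunc_normal(rng, dist.pitch_mean, dist.pitch_sd, 50.0, 300.0, 1)[0]
        )
        ahi = float(_trunc_normal(rng, dist.ahi_mean, dist.ahi_sd, 0.0, np.inf, 1)[0])
        xsa_after = max(xsa + d_xsa, 0.3)
        try:
            subj = SubjectAnatomy(
                subject_id=f"synth{len(subjects):04d}",
                nc=nc,
                ua_xsa=xsa,
                ua_length=length,
                nc_after=nc + d_nc,
                ua_xsa_after=xsa_after,
                ahi=ahi,
                pitch_hz=pitch,
            )
            derive_geometry(subj)  # reject airway-wider-than-neck draws
            derive_geometry(subj, use_after_sleep=True)
        except ValueError:
            continue
        subjects.append(subj)
    if len(subjects) < n:
        raise RuntimeError("cohort sampling failed to satisfy geometry constraints")
    return subjects


def write_wav(path: str | Path, rec: SnoreRecording) -> None:
    """Write 16-bit PCM mono WAV plus a JSON sidecar (annotations, truth)."""
    path = Path(path)
    x = np.clip(rec.samples, -1.0, 1.0)
    pcm = np.round(x * 32767.0).astype(np.int16)
    wavfile.write(path, int(rec.fs), pcm)
    sidecar = {
        "fs": rec.fs,
        "annotations": [list(a) for a in rec.annotations],
        "truth": rec.truth,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_wav(path: str | Path) -> SnoreRecording:
    """Read a WAV written by :func:`write_wav` (sidecar optional)."""
    path = Path(path)
    fs, pcm = wavfile.read(path)
    if pcm.ndim != 1:
        raise ValueError(f"{path}: expected mono audio")
    if pcm.dtype == np.int16:
        samples = pcm.astype(float) / 32767.0
    else:
        samples = pcm.astype(float)
    rec = SnoreRecording(samples=samples, fs=float(fs))
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        rec.annotations = [tuple(a) for a in meta.get("annotations", [])]
        rec.truth = meta.get("truth")
    return rec
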