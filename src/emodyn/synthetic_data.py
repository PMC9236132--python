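"""Synthetic EEG cohorts with known emotion-dynamics ground truth.

Each recording is a sum of five band-limited oscillations (FIR-filtered
white noise at the rhythm edges), 1/f background noise, and — on the
emotion-related channels — a slow modulation of the theta/alpha
oscillatory amplitude by a latent "emotion state" (the classic coupling
of emotional arousal to low-frequency rhythm power, which spectral-ratio
and complexity features can pick up).  The latent state is a smoothed
Gaussian process whose
correlation length is chosen so its expected zero-crossing rate (Rice's
formula) equals the configured fluctuation rate, giving a tunable,
condition-dependent emotional tempo.

Two conditions mimic a two-arm multimedia-learning study: the higher-load
arm gets relatively more beta power (hence a larger beta/(theta+alpha)
engagement index) and a slower latent state, so a negative association
between trajectory zero-crossing rate and cognitive load is recoverable
by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from .bands import EMOTION_CHANNELS, MONTAGE_15, RHYTHM_EDGES, RHYTHMS
from .preprocess import EEGRecording

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "generate_recording",
    "generate_latent_state",
    "generate_cohort",
    "write_recording_csv",
    "read_recording_csv",
]


class ConfigError(ValueError):
    """Invalid cohort configuration."""


# Default per-condition relative band powers.  The grayscale (higher-load)
# arm has more beta/gamma and more broadband noise; the color-coded arm has
# more theta/alpha.  Engagement index beta/(theta+alpha) of the gains:
# grayscale 1.5/2.0 = 0.75, color 0.7/2.5 = 0.28.
_DEFAULT_BAND_GAINS = {
    "grayscale": {"delta": 0.8, "theta": 1.0, "alpha": 1.0, "beta": 1.5, "gamma": 0.6},
    "color": {"delta": 0.8, "theta": 1.2, "alpha": 1.3, "beta": 0.7, "gamma": 0.4},
}
_DEFAULT_NOISE_GAIN = {"grayscale": 1.0, "color": 0.7}
# latent sign changes per minute: slow under high load, fast under low load
_DEFAULT_EMOTION_RATE = {"grayscale": 3.0, "color": 10.0}


@dataclass
class CohortConfig:
    """Study-design parameters of a two-condition synthetic cohort.

    ``band_gains`` are relative *power* gains per rhythm (oscillation
    amplitudes scale with their square root); ``emotion_rate`` is the
    latent state's expected sign-change rate in crossings per minute;
    ``noise_gain`` scales the 1/f background per condition;
    ``modulation_depth`` sets how strongly the latent state modulates the
    amplitude of the ``modulated_rhythms`` oscillations on the emotion
    channels.
    """

    n_per_condition: int = 19
    duration: float = 300.0
    fs: float = 125.0
    channels: tuple[str, ...] = MONTAGE_15
    band_gains: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(g) for c, g in _DEFAULT_BAND_GAINS.items()}
    )
    noise_gain: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_NOISE_GAIN))
    emotion_rate: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_EMOTION_RATE))
    noise_exponent: float = 1.0
    modulation_depth: float = 0.6
    modulated_rhythms: tuple[str, ...] = ("theta", "alpha")
    emotion_channels: tuple[str, ...] = EMOTION_CHANNELS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_condition < 2:
            raise ConfigError("n_per_condition must be >= 2")
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        if self.fs <= 0:
            raise ConfigError("fs must be positive")
        self.channels = tuple(self.channels)
        self.emotion_channels = tuple(c for c in self.emotion_channels if c in self.channels)
        for cond, gains in self.band_gains.items():
            for rhythm, g in gains.items():
                if rhythm not in RHYTHM_EDGES:
                    raise ConfigError(f"unknown rhythm {rhythm!r} in band_gains[{cond!r}]")
                if g <= 0:
                    raise ConfigError(f"band gain {cond}/{rhythm} must be > 0, got {g}")
        for cond, rate in self.emotion_rate.items():
            if rate <= 0:
                raise ConfigError(f"emotion_rate[{cond!r}] must be > 0")
        missing = set(self.band_gains) - set(self.emotion_rate)
        if missing:
            raise ConfigError(f"emotion_rate missing for conditions {sorted(missing)}")

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.band_gains)

    def engagement_of_gains(self, condition: str) -> float:
        """beta/(theta+alpha) ratio of the configured gains."""
        g = self.band_gains[condition]
        return g.get("beta", 0.0) / (g.get("theta", 0.0) + g.get("alpha", 0.0))


@dataclass
class GroundTruth:
    """What the generator built in, for recovery checks downstream."""

    participants: list[str]             # participant ids, cohort order
    conditions: list[str]               # condition label per participant
    higher_cli_condition: str           # larger configured beta/(theta+alpha)
    higher_emotion_rate_condition: str  # faster latent fluctuation
    modulation_sign: str                # 'negative' or 'positive'

    def as_dict(self) -> dict:
        return {
            "participants": list(self.participants),
            "conditions": list(self.conditions),
            "higher_cli_condition": self.higher_cli_condition,
            "higher_emotion_rate_condition": self.higher_emotion_rate_condition,
            "modulation_sign": self.modulation_sign,
        }


def generate_latent_state(n_samples: int, fs: float, rate_per_minute: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean unit-variance latent state with a target crossing rate.

    White noise is smoothed with a Gaussian kernel; the resulting process
    has squared-exponential autocorrelation, for which Rice's formula gives
    an expected zero-crossing rate of 1 / (pi * sqrt(2) * kernel_sd).
    """
    rate_per_sec = rate_per_minute / 60.0
    sigma_sec = 1.0 / (np.pi * np.sqrt(2.0) * rate_per_sec)
    sigma = sigma_sec * fs
    pad = int(np.ceil(6 * sigma))
    raw = rng.standard_normal(n_samples + 2 * pad)
    smooth = gaussian_filter1d(raw, sigma)[pad:pad + n_samples]
    smooth = smooth - smooth.mean()
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _pink_noise(shape: tuple[int, int], exponent: float,
                rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent noise per row, unit variance."""
    n = shape[1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _band_oscillation(n_ch: int, n: int, lo: float, hi: float, fs: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited noise per channel (FIR band-pass)."""
    taps_n = min(int(np.ceil(3.3 * fs / 1.0)) | 1, max(3, (n // 3) | 1))
    lo_eff = max(lo, 0.4)
    white = rng.standard_normal((n_ch, n))
    taps = signal.firwin(taps_n, [lo_eff, min(hi, fs / 2 * 0.99)],
                         pass_zero=False, fs=fs)
    x = signal.filtfilt(taps, [1.0], white, axis=1,
                        padlen=min(3 * (taps_n - 1), n - 1))
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_recording(config: CohortConfig, condition: str, seed: int) -> EEGRecording:
    """One synthetic participant's recording under ``condition``.

    Deterministic for a fixed (config, condition, seed).  The latent
    emotion state is stored in ``meta['latent_state']`` for ground-truth
    diagnostics; signals are z-scored per channel before return.
    """
    if condition not in config.band_gains:
        raise ConfigError(
            f"unknown condition {condition!r}; configured: {list(config.band_gains)}"
        )
    rng = np.random.default_rng(seed)
    n = int(round(config.duration * config.fs))
    n_ch = len(config.channels)
    gains = config.band_gains[condition]

    latent = generate_latent_state(n, config.fs, config.emotion_rate[condition], rng)
    modulation = 1.0 + config.modulation_depth * np.tanh(latent)
    em_idx = [config.channels.index(c) for c in config.emotion_channels]

    osc = np.zeros((n_ch, n))
    for rhythm in RHYTHMS:
        g = gains.get(rhythm, 0.0)
        if g <= 0:
            continue
        lo, hi = RHYTHM_EDGES[rhythm]
        band = np.sqrt(g) * _band_oscillation(n_ch, n, lo, hi, config.fs, rng)
        if rhythm in config.modulated_rhythms:
            band[em_idx] *= modulation[None, :]
        osc += band

    data = osc
    ng = config.noise_gain.get(condition, 0.0)
    if ng > 0:
        data = data + ng * _pink_noise((n_ch, n), config.noise_exponent, rng)

    sd = data.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    data = (data - data.mean(axis=1, keepdims=True)) / sd

    meta = {
        "condition": condition,
        "seed": int(seed),
        "synthetic": True,
        "latent_state": latent,
        "emotion_rate_per_minute": config.emotion_rate[condition],
    }
    return EEGRecording(data, config.fs, config.channels, meta)


def generate_cohort(config: CohortConfig) -> tuple[list[EEGRecording], GroundTruth]:
    """Generate ``2 * n_per_condition`` labelled recordings plus ground truth.

    Per-participant seeds are ``config.seed + participant_index`` so a
    cohort is reproducible while participants stay independent.
    """
    recordings: list[EEGRecording] = []
    participants: list[str] = []
    conditions: list[str] = []
    idx = 0
    for cond in config.conditions:
        for _ in range(config.n_per_condition):
            rec = generate_recording(config, cond, config.seed + idx)
            pid = f"sub-{idx:03d}"
            rec.meta["participant"] = pid
            recordings.append(rec)
            participants.append(pid)
            conditions.append(cond)
            idx += 1

    eng = {c: config.engagement_of_gains(c) for c in config.conditions}
    rates = config.emotion_rate
    ranked_eng = sorted(eng, key=eng.get)
    ranked_rate = sorted(rates, key=rates.get)
    if len(set(eng.values())) < len(eng):
        raise ConfigError("conditions must differ in configured beta/(theta+alpha)")
    if len(set(rates.values())) < len(rates):
        raise ConfigError("conditions must differ in emotion_rate")
    higher_cli = ranked_eng[-1]
    higher_rate = ranked_rate[-1]
    sign = "negative" if higher_cli != higher_rate else "positive"
    truth = GroundTruth(participants, conditions, higher_cli, higher_rate, sign)
    return recordings, truth


# ------------------------------------------------------------------ writers

def write_recording_csv(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording as CSV (rows = samples, header = channel labels)
    plus a JSON sidecar with fs, condition and seed.  ``.edf`` output is
    not supported (no EDF export backend); use CSV."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        raise NotImplementedError(
            "EDF export is not available; write CSV (+ JSON sidecar) instead"
        )
    header = ",".join(rec.channel_labels)
    np.savetxt(path, rec.data.T, delimiter=",", header=header, comments="")
    sidecar = {
        "fs": rec.fs,
        "channel_labels": list(rec.channel_labels),
        "condition": rec.meta.get("condition"),
        "seed": rec.meta.get("seed"),
        "synthetic": bool(rec.meta.get("synthetic", False)),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_recording_csv(path: str | Path, fs: float | None = None) -> EEGRecording:
    """Read a CSV recording written by :func:`write_recording_csv`.

    ``fs`` is taken from the JSON sidecar when present, else must be given.
    """
    path = Path(path)
    meta: dict = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = meta.get("fs", fs)
    if fs is None:
        raise ConfigError(f"no sampling rate: {sidecar} missing and fs not given")
    with open(path) as fh:
        labels = tuple(fh.readline().strip().split(","))
    data = np.loadtxt(path, delimiter=",", skiprows=1).T
    if data.ndim == 1:
        data = data[None, :]
    return EEGRecording(data, float(fs), labels, meta)
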