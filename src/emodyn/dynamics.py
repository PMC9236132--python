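"""Zero-crossing-rate statistic, cognitive load index, and their regression.

The trajectory Z(n) is passed through a binomial high-pass filter of order
k (equivalently the (k-1)-th backward difference), binarized at zero, and
the symbol changes of the binary series are counted — the ZCR_EC
statistic.  Cognitive load is indexed by the engagement ratio
beta/(theta+alpha) over load-sensitive channel subsets.  Ordinary least
squares across participants fits ZCR_EC = alpha * CLI + beta; a negative
slope means emotional activity slows as cognitive load grows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy import stats

from .bands import CLI_CHANNEL_SETS, EMOTION_CHANNELS
from .preprocess import EEGRecording
from .spectral_hht import BandPowerTable
from .trajectory import EmotionTrajectory

logger = logging.getLogger(__name__)

__all__ = ["ZCRParams", "ZCRResult", "CLIValue", "ModulationFit",
           "binomial_highpass", "binarize", "zcr_ec", "raw_signal_zcr",
           "cognitive_load_index", "fit_modulation"]


@dataclass
class ZCRParams:
    """M binomial high-pass orders to evaluate; order ``report_k`` (default
    1, the plain zero-crossing count) is the reported statistic."""

    M: int = 4
    report_k: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.report_k <= self.M:
            raise ValueError(f"need 1 <= report_k <= M, got {self.report_k}, {self.M}")


@dataclass
class ZCRResult:
    per_k: dict[int, int]   # filter order -> symbol-change count
    zcr_ec: int             # the reported statistic (order report_k)
    n: int                  # series length


@dataclass
class CLIValue:
    per_epoch: np.ndarray           # CLI per retained epoch
    subject_mean: float
    channel_sets: dict[str, tuple[str, ...]]
    excluded_epochs: list[int] = field(default_factory=list)


@dataclass
class ModulationFit:
    """OLS fit of ZCR_EC = alpha * CLI + beta across participants."""

    alpha: float        # slope: modulation of emotional activity by load
    beta: float         # intercept
    n: int
    residual_sd: float
    slope_se: float
    r_value: float
    p_value: float


def binomial_highpass(Z: np.ndarray, k: int, require_zero_mean: bool = True) -> np.ndarray:
    """Order-k binomial high-pass: alternating binomial weights over the
    last k samples, i.e. the (k-1)-th backward difference of Z.

    Output has length N - k + 1 (values defined for n >= k).
    """
    Z = np.asarray(Z, dtype=float)
    if k < 1:
        raise ValueError("filter order k must be >= 1")
    if k > Z.size:
        raise ValueError(f"order k={k} exceeds series length {Z.size}")
    if require_zero_mean:
        sd = Z.std()
        if sd > 0 and abs(Z.mean()) > 1e-9 * sd:
            raise ValueError("input series must be zero-mean (center it first)")
    coeffs = np.array([comb(k - 1, j - 1) * (-1) ** (j - 1) for j in range(1, k + 1)],
                      dtype=float)
    return np.convolve(Z, coeffs, mode="valid")


def binarize(L: np.ndarray) -> np.ndarray:
    """Binary symbol series: 1 where L >= 0, else 0."""
    return (np.asarray(L) >= 0).astype(np.int8)


def _count_symbol_changes(X: np.ndarray) -> int:
    return int((np.diff(X.astype(int)) ** 2).sum())


def zcr_ec(trajectory: EmotionTrajectory, params: ZCRParams | None = None) -> ZCRResult:
    """Zero-crossing-rate statistic of an emotion trajectory.

    For each filter order k = 1..M: binomial high-pass, binarize at zero,
    count symbol changes.  All orders are stored; order ``report_k``
    (default 1) is the reported ZCR_EC.
    """
    params = params or ZCRParams()
    Z = trajectory.values
    if Z.size < 2:
        raise ValueError("trajectory must have at least 2 samples")
    per_k: dict[int, int] = {}
    for k in range(1, params.M + 1):
        if k > Z.size:
            break
        L = binomial_highpass(Z, k, require_zero_mean=trajectory.zero_mean)
        per_k[k] = _count_symbol_changes(binarize(L))
    return ZCRResult(per_k, per_k[params.report_k], Z.size)


def raw_signal_zcr(rec: EEGRecording,
                   channels: tuple[str, ...] = EMOTION_CHANNELS) -> float:
    """Mean zero-crossing count of the zero-meaned raw signal over the
    emotion channel subset (order-1 statistic per channel, averaged)."""
    counts = []
    for ch in channels:
        z = rec.channel(ch)
        z = z - z.mean()
        counts.append(_count_symbol_changes(binarize(z)))
    return float(np.mean(counts))


def cognitive_load_index(
    bands: BandPowerTable,
    channel_sets: dict[str, tuple[str, ...]] | None = None,
) -> CLIValue:
    """Engagement index beta/(theta+alpha) per epoch and its subject mean.

    Band powers are averaged over each band's channel subset before the
    ratio.  Epochs with a non-positive theta+alpha denominator are
    excluded and logged.
    """
    sets = {k: tuple(v) for k, v in (channel_sets or CLI_CHANNEL_SETS).items()}
    for band in ("alpha", "beta", "theta"):
        if band not in sets:
            raise ValueError(f"channel_sets must define {band!r}")
        missing = set(sets[band]) - set(bands.channel_labels)
        if missing:
            raise ValueError(f"{band} channel set has unknown channels {sorted(missing)}")

    def band_mean(band: str) -> np.ndarray:
        idx = [bands.channel_labels.index(c) for c in sets[band]]
        return bands.band(band)[:, idx].mean(axis=1)

    beta = band_mean("beta")
    denom = band_mean("theta") + band_mean("alpha")
    ok = denom > 0
    excluded = list(np.flatnonzero(~ok))
    if excluded:
        logger.warning("excluding %d epoch(s) with zero theta+alpha power", len(excluded))
    if not ok.any():
        raise ValueError("all epochs have zero theta+alpha power; CLI undefined")
    cli = beta[ok] / denom[ok]
    return CLIValue(cli, float(cli.mean()), sets, excluded)


def fit_modulation(cli: np.ndarray, zcr: np.ndarray) -> ModulationFit:
    """Least-squares line through per-subject (CLI, ZCR_EC) points."""
    cli = np.asarray(cli, dtype=float)
    zcr = np.asarray(zcr, dtype=float)
    if cli.shape != zcr.shape or cli.ndim != 1:
        raise ValueError("cli and zcr must be 1-D arrays of equal length")
    if cli.size < 3:
        raise ValueError("need at least 3 participants to fit")
    if np.ptp(cli) == 0:
        raise ValueError("CLI has zero variance; slope undefined")
    res = stats.linregress(cli, zcr)
    resid = zcr - (res.slope * cli + res.intercept)
    dof = max(cli.size - 2, 1)
    return ModulationFit(
        alpha=float(res.slope),
        beta=float(res.intercept),
        n=int(cli.size),
        residual_sd=float(np.sqrt((resid ** 2).sum() / dof)),
        slope_se=float(res.stderr),
        r_value=float(res.rvalue),
        p_value=float(res.pvalue),
    )
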