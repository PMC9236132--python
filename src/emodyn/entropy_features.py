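"""Non-linear complexity estimators and their sliding-window trajectories.

Four estimators quantify the irregularity of an EEG channel:

* approximate entropy (ApEn): log-mean template-match rates at lengths m
  and m+1, self-matches included, Chebyshev distance, tolerance r = F*SD;
* sample entropy (SampEn): same counting without self-matches,
  -ln(A/B) over pooled match counts — length-robust;
* permutation entropy (PEn): Shannon entropy (bits) of ordinal patterns
  of overlapping length-D windows;
* state-space correlation entropy (SSCEn): the series is delay-embedded
  into length-D windows, the correlation (Gram) matrix between every pair
  of windows is formed, and the strict upper triangle is histogrammed into
  K equal-width bins; SSCEn is the Shannon entropy (bits) of the bin
  probabilities.  The series is mean-centered before embedding so the
  statistic is affine-invariant together with the range-relative bins.

Applied over consecutive windows (default 5 s, the approximate cycle of
emotional changes) these produce per-channel feature time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import cdist

from .preprocess import EEGRecording
from .wavelet_features import WAVELET_FEATURE_NAMES, wavelet_feature_vector

__all__ = [
    "EntropyParams",
    "FeatureSeries",
    "approximate_entropy",
    "sample_entropy",
    "permutation_entropy",
    "state_space_correlation_entropy",
    "sliding_feature_series",
    "ESTIMATORS",
]

_R_FLOOR = 1e-12


class UndefinedEntropyError(ValueError):
    """No template matches: the statistic is undefined for this input."""


@dataclass
class EntropyParams:
    """Estimator parameters.

    m : template length for ApEn/SampEn.
    F : tolerance as a multiple of the series SD (r = F * SD).
    D : embedding dimension for PEn/SSCEn.
    K : histogram bin count for SSCEn.
    window, step : sliding-window extent and stride in seconds
        (step defaults to window, i.e. non-overlapping).
    """

    m: int = 2
    F: float = 0.2
    D: int = 3
    K: int = 16
    window: float = 5.0
    step: float | None = None

    def __post_init__(self) -> None:
        if self.m < 1 or self.F <= 0 or self.D < 2 or self.K < 1:
            raise ValueError("need m >= 1, F > 0, D >= 2, K >= 1")
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.step is None:
            self.step = self.window


def _templates(x: np.ndarray, m: int) -> np.ndarray:
    return sliding_window_view(x, m)


@lru_cache(maxsize=8)
def _triu_cached(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def approximate_entropy(x: np.ndarray, m: int = 2, F: float = 0.2) -> float:
    """ApEn = Phi^m - Phi^{m+1} with Phi^m the mean log match rate.

    Match rates C_i count templates within Chebyshev distance r = F*SD of
    template i, self-matches included, normalized by the template count.
    A tolerance floor of 1e-12 guards constant series (ApEn = 0).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= m + 1:
        raise ValueError(f"need n > m+1, got n={n}, m={m}")
    r = max(F * x.std(), _R_FLOOR)

    def phi(mm: int) -> float:
        T = _templates(x, mm)
        d = cdist(T, T, metric="chebyshev")
        C = (d <= r).sum(axis=1) / T.shape[0]
        return float(np.mean(np.log(C)))

    return phi(m) - phi(m + 1)


def sample_entropy(x: np.ndarray, m: int = 2, F: float = 0.2) -> float:
    """SampEn = -ln(A/B), matches pooled over templates, self-matches excluded.

    A counts length-(m+1) template pairs within r, B length-m pairs among
    the same n-m templates.  Raises :class:`UndefinedEntropyError` when no
    length-(m+1) pair matches (the statistic would be infinite).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= m + 1:
        raise ValueError(f"need n > m+1, got n={n}, m={m}")
    r = max(F * x.std(), _R_FLOOR)

    Tm = _templates(x, m)[: n - m]          # n-m templates of length m
    Tm1 = _templates(x, m + 1)              # n-m templates of length m+1
    dB = cdist(Tm, Tm, metric="chebyshev")
    dA = cdist(Tm1, Tm1, metric="chebyshev")
    iu = np.triu_indices(n - m, k=1)
    B = int((dB[iu] <= r).sum())
    A = int((dA[iu] <= r).sum())
    if B == 0 or A == 0:
        raise UndefinedEntropyError("no template matches; SampEn undefined")
    return float(-np.log(A / B))


def permutation_entropy(x: np.ndarray, D: int = 3) -> float:
    """Shannon entropy (bits) of ordinal patterns of length-D windows.

    Overlapping windows (stride 1); ties are broken by order of appearance
    (stable argsort), so e.g. a constant window maps to the identity
    pattern.  A strictly monotone series has a single pattern and PEn = 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size < D + 1:
        raise ValueError(f"need at least D+1={D + 1} samples, got {x.size}")
    W = _templates(x, D)
    patterns = np.argsort(W, axis=1, kind="stable")
    base = D ** np.arange(D)
    codes = patterns @ base
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def state_space_correlation_entropy(x: np.ndarray, D: int = 3, K: int = 16) -> float:
    """Histogram entropy (bits) of pairwise window correlations.

    The mean-centered series is embedded into length-D windows (stride 1);
    the Gram matrix of all window pairs is formed and its strict upper
    triangle histogrammed into K equal-width bins over the observed range.
    Returns 0 when all entries coincide or K = 1.
    """
    x = np.asarray(x, dtype=float)
    if x.size < D + 1:
        raise ValueError(f"need at least D+1={D + 1} samples, got {x.size}")
    if K == 1:
        return 0.0
    xc = x - x.mean()
    W = np.ascontiguousarray(_templates(xc, D))
    G = W @ W.T
    v = G[_triu_cached(G.shape[0])]
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return 0.0
    counts, _ = np.histogram(v, bins=K, range=(lo, hi))
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


# estimator name -> (per-window feature names, callable -> 1-D vector)
ESTIMATORS: dict[str, tuple[tuple[str, ...], Callable[..., np.ndarray]]] = {
    "apen": (("apen",),
             lambda x, fs, p: np.array([approximate_entropy(x, p.m, p.F)])),
    "sampen": (("sampen",),
               lambda x, fs, p: np.array([sample_entropy(x, p.m, p.F)])),
    "pen": (("pen",), lambda x, fs, p: np.array([permutation_entropy(x, p.D)])),
    "sscen": (("sscen",),
              lambda x, fs, p: np.array([state_space_correlation_entropy(x, p.D, p.K)])),
    "wavelet": (WAVELET_FEATURE_NAMES,
                lambda x, fs, p: wavelet_feature_vector(x, fs)),
}

_MIN_SAMPLES = {"apen": 8, "sampen": 8, "pen": 4, "sscen": 4, "wavelet": 32}


@dataclass
class FeatureSeries:
    """Time-indexed per-channel feature values from sliding windows."""

    values: np.ndarray              # (n_windows, n_channels, n_features)
    feature_names: tuple[str, ...]
    timestamps: np.ndarray          # window start times, seconds
    channel_labels: tuple[str, ...]

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (time, channel, feature, value)."""
        rows = []
        for w in range(self.values.shape[0]):
            for c, ch in enumerate(self.channel_labels):
                for f, name in enumerate(self.feature_names):
                    rows.append((self.timestamps[w], ch, name, self.values[w, c, f]))
        return pd.DataFrame(rows, columns=["time", "channel", "feature", "value"])

    def wide(self) -> pd.DataFrame:
        """(n_windows, channel x feature) wide matrix with named columns."""
        n_w = self.values.shape[0]
        flat = self.values.reshape(n_w, -1)
        cols = [f"{ch}__{name}" for ch in self.channel_labels
                for name in self.feature_names]
        return pd.DataFrame(flat, columns=cols, index=self.timestamps)


def sliding_feature_series(
    rec: EEGRecording,
    estimators: Sequence[str] = ("apen",),
    params: EntropyParams | None = None,
    channels: Sequence[str] | None = None,
) -> FeatureSeries:
    """Apply estimators per channel over consecutive windows.

    Windows of ``params.window`` seconds advance by ``params.step``
    (default: non-overlapping); a trailing partial window is dropped.
    """
    params = params or EntropyParams()
    unknown = set(estimators) - set(ESTIMATORS)
    if unknown:
        raise ValueError(f"unknown estimators {sorted(unknown)}; have {sorted(ESTIMATORS)}")
    labels = tuple(channels) if channels is not None else rec.channel_labels
    idx = [rec.channel_labels.index(c) for c in labels]

    L = int(round(params.window * rec.fs))
    step = int(round(params.step * rec.fs))
    min_len = max(_MIN_SAMPLES[e] for e in estimators)
    if L < min_len:
        raise ValueError(f"window of {L} samples below minimum {min_len} "
                         f"for {sorted(estimators)}")
    starts = np.arange(0, rec.n_samples - L + 1, step)
    if starts.size == 0:
        raise ValueError("recording shorter than one window")

    names: list[str] = []
    for est in estimators:
        names.extend(ESTIMATORS[est][0])
    values = np.empty((starts.size, len(labels), len(names)))
    for w, s0 in enumerate(starts):
        for c, ch_i in enumerate(idx):
            seg = rec.data[ch_i, s0:s0 + L]
            col = 0
            for est in estimators:
                feat_names, fn = ESTIMATORS[est]
                values[w, c, col:col + len(feat_names)] = fn(seg, rec.fs, params)
                col += len(feat_names)
    return FeatureSeries(values, tuple(names), starts / rec.fs, labels)
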