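"""Hilbert-Huang spectral analysis and rhythm band powers.

Empirical mode decomposition (EMD) sifts a signal into intrinsic mode
functions (IMFs) a_j(t) so that X(t) = Re sum_j a_j(t) exp(i int w_j dt) +
residual.  The Hilbert transform of each IMF then yields instantaneous
amplitude and frequency, and amplitude^2 binned on a frequency grid gives
the Hilbert spectrum.  Averaging the marginal spectrum inside each rhythm
band produces the per-epoch, per-channel band-power table, whose flattened
form (5 rhythms x 15 channels = 75) is the spectral feature vector.

Sifting uses cubic-spline envelopes through the local extrema, the
standard-deviation stopping criterion (SD < 0.2, at most 10 sifts per IMF,
at most 12 IMFs) and mirror extension of the signal to tame boundary
effects on short epochs.  The envelope inner loops are numba-compiled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.signal import hilbert

from .bands import RHYTHM_EDGES, RHYTHMS
from .preprocess import EpochSet

__all__ = ["IMFSet", "HilbertSpectrum", "BandPowerTable", "emd", "hilbert_spectrum", "band_powers"]


# ---------------------------------------------------------------- numba core

@njit(cache=True)
def _natural_spline(xk, yk, xq):
    """Natural cubic spline through (xk, yk), evaluated at xq (xk ascending)."""
    n = len(xk)
    out = np.empty(len(xq))
    if n == 2:
        slope = (yk[1] - yk[0]) / (xk[1] - xk[0])
        for i in range(len(xq)):
            out[i] = yk[0] + slope * (xq[i] - xk[0])
        return out
    # second derivatives via Thomas algorithm (natural: M[0] = M[n-1] = 0)
    h = np.empty(n - 1)
    for i in range(n - 1):
        h[i] = xk[i + 1] - xk[i]
    a = np.zeros(n)
    b = np.ones(n)
    c = np.zeros(n)
    d = np.zeros(n)
    for i in range(1, n - 1):
        a[i] = h[i - 1]
        b[i] = 2.0 * (h[i - 1] + h[i])
        c[i] = h[i]
        d[i] = 6.0 * ((yk[i + 1] - yk[i]) / h[i] - (yk[i] - yk[i - 1]) / h[i - 1])
    # forward sweep
    for i in range(1, n):
        w = a[i] / b[i - 1]
        b[i] -= w * c[i - 1]
        d[i] -= w * d[i - 1]
    M = np.zeros(n)
    M[n - 1] = d[n - 1] / b[n - 1]
    for i in range(n - 2, -1, -1):
        M[i] = (d[i] - c[i] * M[i + 1]) / b[i]
    # evaluate
    seg = 0
    for i in range(len(xq)):
        x = xq[i]
        while seg < n - 2 and x > xk[seg + 1]:
            seg += 1
        hj = h[seg]
        A = (xk[seg + 1] - x) / hj
        B = (x - xk[seg]) / hj
        out[i] = (
            A * yk[seg]
            + B * yk[seg + 1]
            + ((A * A * A - A) * M[seg] + (B * B * B - B) * M[seg + 1]) * hj * hj / 6.0
        )
    return out


@njit(cache=True)
def _envelope_mean(x):
    """Mean of upper/lower cubic-spline envelopes; also returns extrema count."""
    n = len(x)
    max_i = np.empty(n, dtype=np.int64)
    min_i = np.empty(n, dtype=np.int64)
    nmax = 0
    nmin = 0
    for i in range(1, n - 1):
        if x[i] > x[i - 1] and x[i] >= x[i + 1]:
            max_i[nmax] = i
            nmax += 1
        elif x[i] < x[i - 1] and x[i] <= x[i + 1]:
            min_i[nmin] = i
            nmin += 1
    n_ext = nmax + nmin
    if nmax < 2 or nmin < 2:
        return np.zeros(0), n_ext

    t = np.arange(n).astype(np.float64)
    # endpoint knots clamp the envelopes to the outermost extremum value
    xs = np.empty(nmax + 2)
    ys = np.empty(nmax + 2)
    xs[0] = 0.0
    ys[0] = x[max_i[0]]
    for j in range(nmax):
        xs[j + 1] = max_i[j]
        ys[j + 1] = x[max_i[j]]
    xs[nmax + 1] = n - 1.0
    ys[nmax + 1] = x[max_i[nmax - 1]]
    if xs[1] == 0.0:
        xs = xs[1:]
        ys = ys[1:]
    if xs[-2] == n - 1.0:
        xs = xs[:-1]
        ys = ys[:-1]
    upper = _natural_spline(xs, ys, t)

    xs2 = np.empty(nmin + 2)
    ys2 = np.empty(nmin + 2)
    xs2[0] = 0.0
    ys2[0] = x[min_i[0]]
    for j in range(nmin):
        xs2[j + 1] = min_i[j]
        ys2[j + 1] = x[min_i[j]]
    xs2[nmin + 1] = n - 1.0
    ys2[nmin + 1] = x[min_i[nmin - 1]]
    if xs2[1] == 0.0:
        xs2 = xs2[1:]
        ys2 = ys2[1:]
    if xs2[-2] == n - 1.0:
        xs2 = xs2[:-1]
        ys2 = ys2[:-1]
    lower = _natural_spline(xs2, ys2, t)

    return (upper + lower) * 0.5, n_ext


@njit(cache=True)
def _emd_core(x, max_imf, max_sift, sd_thresh):
    """Sift out up to max_imf IMFs; returns (imf_matrix, count, residual)."""
    n = len(x)
    imfs = np.zeros((max_imf, n))
    r = x.copy()
    k = 0
    while k < max_imf:
        h = r.copy()
        extracted = False
        for _ in range(max_sift):
            m, n_ext = _envelope_mean(h)
            if len(m) == 0:
                break
            h_new = h - m
            extracted = True
            denom = 0.0
            num = 0.0
            for i in range(n):
                num += (h[i] - h_new[i]) ** 2
                denom += h[i] * h[i]
            h = h_new
            if denom > 0.0 and num / denom < sd_thresh:
                break
        if not extracted:
            break
        imfs[k] = h
        r -= h
        k += 1
        # stop when the residual has too few extrema to sift further
        _, n_ext_r = _envelope_mean(r)
        if n_ext_r < 4:
            break
    return imfs, k, r


# ---------------------------------------------------------------- containers

@dataclass
class IMFSet:
    """Ordered intrinsic mode functions plus the monotone-ish residual."""

    imfs: np.ndarray        # (n_imfs, n_samples), high to low frequency
    residual: np.ndarray    # (n_samples,)
    fs: float

    @property
    def n_imfs(self) -> int:
        return self.imfs.shape[0]

    def reconstruct(self) -> np.ndarray:
        """Sum of IMFs and residual; equals the input up to float error."""
        if self.n_imfs == 0:
            return self.residual.copy()
        return self.imfs.sum(axis=0) + self.residual


@dataclass
class HilbertSpectrum:
    """Time x frequency distribution of squared instantaneous amplitude."""

    amplitude: np.ndarray   # (n_times, n_freq_bins), a^2 per bin
    freq_axis: np.ndarray   # bin centers, spanning (0, fs/2]
    time_axis: np.ndarray
    freq_resolution: float

    def marginal(self) -> np.ndarray:
        """Time-integrated power per frequency bin (the marginal spectrum)."""
        return self.amplitude.sum(axis=0)


@dataclass
class BandPowerTable:
    """Per-epoch, per-channel mean spectral power in the five rhythms."""

    power: np.ndarray       # (n_epochs, n_channels, n_rhythms)
    rhythms: tuple[str, ...]
    channel_labels: tuple[str, ...]
    edges: dict[str, tuple[float, float]]

    def feature_vectors(self) -> np.ndarray:
        """(n_epochs, n_rhythms * n_channels) flattened feature matrix."""
        return self.power.reshape(self.power.shape[0], -1)

    def recording_mean(self) -> np.ndarray:
        """(n_channels, n_rhythms) band powers averaged over epochs."""
        return self.power.mean(axis=0)

    def band(self, rhythm: str) -> np.ndarray:
        """(n_epochs, n_channels) power in one rhythm."""
        return self.power[:, :, self.rhythms.index(rhythm)]


# ---------------------------------------------------------------- operations

_MAX_IMF = 12
_MAX_SIFT = 10
_SD_THRESH = 0.2


def emd(x: np.ndarray, fs: float, max_imf: int = _MAX_IMF,
        max_sift: int = _MAX_SIFT, sd_threshold: float = _SD_THRESH) -> IMFSet:
    """Empirical mode decomposition of a 1-D signal.

    The signal is mirror-extended by half its length on each side before
    sifting and the IMFs are cropped back, which suppresses envelope
    end-swings on short epochs.  A signal without interior extrema (e.g. a
    monotone ramp) yields zero IMFs and is returned whole as the residual.
    """
    x = np.ascontiguousarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("emd expects a 1-D series")
    n = x.size
    if n < 8:
        raise ValueError(f"series too short for sifting (n={n} < 8)")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")

    d = np.diff(x)
    if np.all(d >= 0) or np.all(d <= 0):  # monotone: nothing to sift
        return IMFSet(np.zeros((0, n)), x.copy(), fs)

    pad = min(n - 1, n // 2)
    ext = np.concatenate([x[pad:0:-1], x, x[-2:-pad - 2:-1]])
    imfs_ext, k, res_ext = _emd_core(ext, max_imf, max_sift, sd_threshold)
    sl = slice(pad, pad + n)
    imfs = imfs_ext[:k, sl].copy()
    residual = res_ext[sl].copy()
    if k == 0:
        return IMFSet(np.zeros((0, n)), x.copy(), fs)
    # enforce exact reconstruction on the cropped window
    residual = x - imfs.sum(axis=0)
    return IMFSet(imfs, residual, fs)


def _instantaneous(imfs: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Analytic amplitude and instantaneous frequency (Hz) per IMF."""
    analytic = hilbert(imfs, axis=-1)
    amp = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic), axis=-1)
    freq = np.gradient(phase, axis=-1) * fs / (2.0 * np.pi)
    return amp, freq


def hilbert_spectrum(imfset: IMFSet, freq_resolution: float = 0.1) -> HilbertSpectrum:
    """Bin squared IMF amplitudes onto a frequency grid per time sample.

    The grid covers (0, fs/2] at ``freq_resolution``; negative instantaneous
    frequencies (phase-unwrapping glitches) are clipped into the lowest bin.
    Total binned energy equals ``sum_t sum_j a_j(t)^2`` exactly.
    """
    if freq_resolution <= 0:
        raise ValueError("freq_resolution must be positive")
    fs = imfset.fs
    n_bins = max(1, int(round(fs / 2.0 / freq_resolution)))
    n_t = imfset.residual.size
    amp_tf = np.zeros((n_t, n_bins))
    time_axis = np.arange(n_t) / fs
    freq_axis = (np.arange(n_bins) + 0.5) * freq_resolution
    if imfset.n_imfs:
        amp, freq = _instantaneous(imfset.imfs, fs)
        bins = np.clip((freq / freq_resolution).astype(np.int64), 0, n_bins - 1)
        power = amp ** 2
        for j in range(imfset.n_imfs):
            np.add.at(amp_tf, (np.arange(n_t), bins[j]), power[j])
    return HilbertSpectrum(amp_tf, freq_axis, time_axis, freq_resolution)


def _marginal_band_power(x: np.ndarray, fs: float, band_bins: list[np.ndarray],
                         n_bins: int, freq_resolution: float) -> np.ndarray:
    """Mean marginal Hilbert-spectrum power per band for one 1-D signal."""
    imfset = emd(x, fs)
    out = np.zeros(len(band_bins))
    if imfset.n_imfs == 0:
        return out
    amp, freq = _instantaneous(imfset.imfs, fs)
    bins = np.clip((freq / freq_resolution).astype(np.int64), 0, n_bins - 1)
    marg = np.bincount(bins.ravel(), weights=(amp ** 2).ravel(), minlength=n_bins)
    for b, idx in enumerate(band_bins):
        out[b] = marg[idx].mean() if idx.size else 0.0
    return out


def band_powers(
    epochs: EpochSet,
    edges: dict[str, tuple[float, float]] | None = None,
    freq_resolution: float = 0.1,
) -> BandPowerTable:
    """Hilbert-spectrum band powers for every epoch and channel.

    Per epoch and channel the marginal Hilbert spectrum (0.1 Hz grid) is
    averaged inside each rhythm band.  Flattening one epoch's table yields
    the per-participant spectral feature vector (rhythms x channels).
    """
    if edges is None:
        edges = RHYTHM_EDGES
    fs = epochs.fs
    nyq = fs / 2.0
    for name, (lo, hi) in edges.items():
        if not (0 <= lo < hi <= nyq):
            raise ValueError(f"band {name} [{lo}, {hi}] outside (0, {nyq}) Hz")
    n_bins = max(1, int(round(nyq / freq_resolution)))
    centers = (np.arange(n_bins) + 0.5) * freq_resolution
    rhythms = tuple(edges)
    band_bins = [np.flatnonzero((centers >= lo) & (centers < hi))
                 for lo, hi in edges.values()]

    n_ep, n_ch = epochs.n_epochs, len(epochs.channel_labels)
    power = np.zeros((n_ep, n_ch, len(rhythms)))
    for e in range(n_ep):
        for c in range(n_ch):
            power[e, c] = _marginal_band_power(
                epochs.epochs[e, c], fs, band_bins, n_bins, freq_resolution
            )
    return BandPowerTable(power, rhythms, epochs.channel_labels, dict(edges))
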