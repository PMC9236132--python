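"""Wavelet-packet rhythm energies and wavelet entropy.

A 5-level Daubechies-10 wavelet-packet tree splits (0, fs/2] into 32
uniform leaf bands (1.953125 Hz wide at fs = 125 Hz).  Contiguous leaves
are summed into the five rhythms; the energy fractions R_i = E_j/E_total
give the wavelet entropy W_e = -sum R_i ln R_i (nats).

The rhythms cover leaves 1-24 (0-46.9 Hz) while E_total spans all 32
leaves, so sum R_i < 1 for signals with energy above 46.9 Hz and
sum R_i = 1 when the rhythms tile the occupied band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .bands import RHYTHM_WP_LEAVES, RHYTHMS

__all__ = ["RhythmEnergy", "WaveletEntropyResult", "wavelet_rhythm_energies",
           "wavelet_entropy", "wavelet_entropy_of"]

_WAVELET = "db10"
_LEVEL = 5
_N_LEAVES = 2 ** _LEVEL


class UndefinedEntropyError(ValueError):
    """Entropy requested of a zero-energy decomposition."""


@dataclass
class RhythmEnergy:
    E: dict[str, float]                       # rhythm -> energy
    E_total: float                            # energy over all 32 leaves
    leaf_energies: np.ndarray                 # per-leaf, frequency order
    component_map: dict[str, tuple[int, int]]  # rhythm -> 1-based leaf range

    @property
    def leaf_bandwidth(self) -> float:
        """Only meaningful relative to fs: bandwidth = fs/2/32."""
        return 1.0 / _N_LEAVES


def wavelet_rhythm_energies(x: np.ndarray, fs: float) -> RhythmEnergy:
    """Full 5-level db10 wavelet-packet decomposition into rhythm energies.

    The series is zero-padded to a multiple of 32 and decomposed with
    periodization boundaries, so the transform is orthogonal and the 32
    leaf energies sum to the (padded) time-domain energy (Parseval).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D series")
    if x.size < _N_LEAVES:
        raise ValueError(f"series of {x.size} samples shorter than {_N_LEAVES}-leaf support")
    pad = (-x.size) % _N_LEAVES
    if pad:
        x = np.concatenate([x, np.zeros(pad)])

    wp = pywt.WaveletPacket(x, _WAVELET, mode="periodization", maxlevel=_LEVEL)
    leaves = wp.get_level(_LEVEL, order="freq")
    leaf_energy = np.array([float(np.sum(node.data ** 2)) for node in leaves])

    E = {}
    for rhythm in RHYTHMS:
        first, last = RHYTHM_WP_LEAVES[rhythm]
        E[rhythm] = float(leaf_energy[first - 1:last].sum())
    return RhythmEnergy(E, float(leaf_energy.sum()), leaf_energy,
                        dict(RHYTHM_WP_LEAVES))


@dataclass
class WaveletEntropyResult:
    R: dict[str, float]   # rhythm -> energy fraction in [0, 1]
    We: float             # wavelet entropy, nats


def wavelet_entropy(energies: RhythmEnergy) -> WaveletEntropyResult:
    """Energy ratios R_i = E_j / E_total and W_e = -sum R_i ln R_i."""
    if energies.E_total <= 0:
        raise UndefinedEntropyError("total wavelet energy is zero")
    R = {k: v / energies.E_total for k, v in energies.E.items()}
    r = np.array(list(R.values()))
    nz = r[r > 0]
    We = float(-(nz * np.log(nz)).sum())
    return WaveletEntropyResult(R, We)


def wavelet_entropy_of(x: np.ndarray, fs: float) -> float:
    """Convenience: W_e of one series (used as a sliding-window feature)."""
    return wavelet_entropy(wavelet_rhythm_energies(x, fs)).We


WAVELET_FEATURE_NAMES: tuple[str, ...] = ("We",) + tuple(f"R_{r}" for r in RHYTHMS)


def wavelet_feature_vector(x: np.ndarray, fs: float) -> np.ndarray:
    """W_e plus the five rhythm energy ratios, ordered as
    :data:`WAVELET_FEATURE_NAMES` (the frequency-domain feature set)."""
    res = wavelet_entropy(wavelet_rhythm_energies(x, fs))
    return np.array([res.We] + [res.R[r] for r in RHYTHMS])
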