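"""Recording container, temporal filtering, re-referencing and epoching.

The cleaning chain is: band-stop around the mains frequency, FIR high-pass
(removes DC / slow drifts), FIR low-pass (removes high-frequency artifact),
then common-average re-referencing.  All filters are windowed-sinc
(Hamming) FIRs applied forward-backward, so the chain is zero-phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "EEGRecording",
    "EpochSet",
    "preprocess_recording",
    "epoch_signal",
]


class PreprocessError(ValueError):
    """Invalid parameter or degenerate input to a preprocessing step."""


@dataclass
class EEGRecording:
    """A multichannel EEG recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal matrix in microvolts or arbitrary units.
    fs : float
        Sampling rate in Hz.
    channel_labels : sequence of str
        10/20 electrode names, one per row of ``data``.
    meta : dict
        Free-form provenance (condition label, seed, filter settings, ...).
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 2:
            raise PreprocessError("data must be a 2-D channels x samples matrix")
        if self.data.shape[0] != len(self.channel_labels):
            raise PreprocessError(
                f"{self.data.shape[0]} rows but {len(self.channel_labels)} channel labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise PreprocessError("channel labels must be unique")
        if not self.fs > 0:
            raise PreprocessError(f"fs must be positive, got {self.fs}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's samples by 10/20 label."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError as err:
            raise KeyError(f"channel {label!r} not in montage") from err
        return self.data[idx]


@dataclass
class EpochSet:
    """Consecutive non-overlapping fixed-length windows of a recording."""

    epochs: np.ndarray  # (n_epochs, n_channels, epoch_samples)
    epoch_length: float
    fs: float
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.epochs.ndim != 3:
            raise PreprocessError("epochs must be (n_epochs, n_channels, n_samples)")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def _fir_taps_for(transition_hz: float, fs: float) -> int:
    # Hamming window: ~3.3 normalized-width transition for ~53 dB stop-band
    n = int(np.ceil(3.3 * fs / transition_hz))
    return n + 1 if n % 2 == 0 else n  # odd length -> type-I linear phase


def _zero_phase(taps: np.ndarray, x: np.ndarray) -> np.ndarray:
    padlen = min(3 * (len(taps) - 1), x.shape[-1] - 1)
    return signal.filtfilt(taps, [1.0], x, axis=-1, padlen=padlen)


def preprocess_recording(
    rec: EEGRecording,
    line_freq: float | None = 50.0,
    hp: float = 1.0,
    lp: float = 50.0,
    notch_half_width: float = 2.0,
) -> EEGRecording:
    """Filter and average-re-reference a recording.

    Steps, in order: band-stop at ``line_freq`` +/- ``notch_half_width``
    (skipped when ``line_freq`` is None), FIR high-pass at ``hp``, FIR
    low-pass at ``lp``, then subtraction of the instantaneous mean across
    channels.  Filters are applied forward-backward (zero phase).

    Raises
    ------
    PreprocessError
        If ``hp >= lp``, the edges do not fit below Nyquist, or the
        recording has a single channel (average reference would null it).
    """
    nyq = rec.fs / 2.0
    if not 0 < hp < lp:
        raise PreprocessError(f"need 0 < hp < lp, got hp={hp}, lp={lp}")
    if lp >= nyq:
        raise PreprocessError(f"low-pass edge {lp} Hz must be below Nyquist {nyq} Hz")
    if rec.n_channels < 2:
        raise PreprocessError(
            "average re-referencing a single channel would zero the data; "
            "supply >= 2 channels or skip preprocessing"
        )

    x = rec.data

    if line_freq is not None:
        lo, hi = line_freq - notch_half_width, line_freq + notch_half_width
        if not (0 < lo and hi < nyq):
            raise PreprocessError(f"band-stop [{lo}, {hi}] Hz outside (0, {nyq}) Hz")
        taps = signal.firwin(
            _fir_taps_for(1.0, rec.fs), [lo, hi], pass_zero=True, fs=rec.fs
        )
        x = _zero_phase(taps, x)

    hp_taps = signal.firwin(_fir_taps_for(min(hp, 1.0), rec.fs), hp,
                            pass_zero=False, fs=rec.fs)
    x = _zero_phase(hp_taps, x)

    lp_taps = signal.firwin(_fir_taps_for(5.0, rec.fs), lp, pass_zero=True, fs=rec.fs)
    x = _zero_phase(lp_taps, x)

    # common average reference: remove the instantaneous mean over channels
    x = x - x.mean(axis=0, keepdims=True)

    meta = dict(rec.meta)
    meta["preprocess"] = {"line_freq": line_freq, "hp": hp, "lp": lp}
    return EEGRecording(x, rec.fs, rec.channel_labels, meta)


def epoch_signal(rec: EEGRecording, epoch_length: float = 4.0) -> EpochSet:
    """Cut a recording into consecutive non-overlapping epochs.

    Epochs are half-open sample windows ``[k*L, (k+1)*L)`` with
    ``L = round(epoch_length * fs)``; a trailing partial window is dropped.

    Raises
    ------
    PreprocessError
        If the recording is shorter than one epoch.
    """
    if epoch_length <= 0:
        raise PreprocessError("epoch_length must be positive")
    L = int(round(epoch_length * rec.fs))
    n_epochs = rec.n_samples // L
    if n_epochs == 0:
        raise PreprocessError(
            f"recording of {rec.duration:.3f} s shorter than one "
            f"{epoch_length} s epoch"
        )
    trimmed = rec.data[:, : n_epochs * L]
    epochs = trimmed.reshape(rec.n_channels, n_epochs, L).transpose(1, 0, 2)
    return EpochSet(epochs.copy(), epoch_length, rec.fs, rec.channel_labels)
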