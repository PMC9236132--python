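"""Recording readers: CSV (with JSON sidecar) and EDF via MNE."""

from __future__ import annotations

from pathlib import Path

from .bands import MONTAGE_15
from .preprocess import EEGRecording
from .synthetic_data import read_recording_csv, write_recording_csv  # noqa: F401

__all__ = ["load_recording", "read_edf", "read_recording_csv", "write_recording_csv"]


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (requires mne)."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError("EDF reading requires the 'mne' package") from err
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EEGRecording(raw.get_data(), raw.info["sfreq"], tuple(raw.ch_names),
                        {"source": str(path)})


def load_recording(path: str | Path, fs: float | None = None,
                   validate_montage: bool = False) -> EEGRecording:
    """Load a recording by extension (.csv or .edf).

    With ``validate_montage`` the channel labels must all belong to the
    15-site 10/20 montage the pipeline targets.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        rec = read_edf(path)
    elif path.suffix.lower() == ".csv":
        rec = read_recording_csv(path, fs=fs)
    else:
        raise ValueError(f"unsupported recording format: {path.suffix!r}")
    if validate_montage:
        unknown = set(rec.channel_labels) - set(MONTAGE_15)
        if unknown:
            raise ValueError(f"channels outside the 15-site montage: {sorted(unknown)}")
    return rec
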