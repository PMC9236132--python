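"""Canonical EEG rhythm definitions and channel subsets used throughout the pipeline.

The five conventional scalp rhythms are defined on edges that fall on the
1.953125 Hz leaf grid of a 5-level wavelet-packet tree at fs = 125 Hz
(62.5 / 32 Hz per leaf), which is why the printed boundaries are 3.9, 7.8,
13.7, 29.3 and 46.9 Hz rather than the textbook 4/8/13/30 Hz.
"""

from __future__ import annotations

# rhythm -> (low, high) in Hz; half-open intervals [low, high)
RHYTHM_EDGES: dict[str, tuple[float, float]] = {
    "delta": (0.0, 3.9),
    "theta": (3.9, 7.8),
    "alpha": (7.8, 13.7),
    "beta": (13.7, 29.3),
    "gamma": (29.3, 46.9),
}

RHYTHMS: tuple[str, ...] = tuple(RHYTHM_EDGES)

#: 15-channel 10/20 montage of the recordings the pipeline targets.
MONTAGE_15: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "Cz", "T8", "P7", "Pz", "P8", "O1", "O2",
)

#: Channels carrying emotion-related activity; the feature-selection /
#: trajectory stage is restricted to these sites.
EMOTION_CHANNELS: tuple[str, ...] = ("Fp1", "F7", "T7", "Cz", "T8", "P8", "O2")

#: Channel subsets entering the engagement-based cognitive load index
#: beta / (theta + alpha).  Alpha and beta use the sites where the band
#: showed load-related differences; theta uses all sites.
CLI_CHANNEL_SETS: dict[str, tuple[str, ...]] = {
    "alpha": ("Fp1", "Fp2", "F3", "T8", "Cz", "P8", "O1", "O2"),
    "beta": ("Fp1", "F3", "F7", "F8", "Fz", "F4", "T8", "Cz"),
    "theta": MONTAGE_15,
}

#: 5-level wavelet-packet leaf indices (1-based, frequency order) per rhythm.
#: Leaf bandwidth at fs = 125 Hz is 62.5/32 = 1.953125 Hz.
RHYTHM_WP_LEAVES: dict[str, tuple[int, int]] = {
    "delta": (1, 2),
    "theta": (3, 4),
    "alpha": (5, 7),
    "beta": (8, 15),
    "gamma": (16, 24),
}
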