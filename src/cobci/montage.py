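"""16-channel 10-20 montage used throughout the toolkit.

The acquisition setup this package models records 16 scalp electrodes laid
out per the international 10-20 system.  The posterior (parieto-occipital)
subset is where the P300 deflection is strongest and drives both the
synthetic topographies and the strong/weak subject ordering.
"""

from __future__ import annotations

#: Default channel order for all arrays with a channel axis.
CHANNELS_16: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "Fz", "F4",
    "C3", "Cz", "C4", "T7", "T8",
    "P3", "Pz", "P4", "PO7", "PO8", "Oz",
)

#: Parietal / parieto-occipital / occipital labels: the P3 hot zone.
POSTERIOR_LABELS: frozenset[str] = frozenset(
    {"P3", "Pz", "P4", "PO7", "PO8", "Oz"}
)


def posterior_indices(channels=CHANNELS_16) -> list[int]:
    """Indices of parieto-occipital channels within a channel list."""
    idx = [i for i, ch in enumerate(channels) if ch in POSTERIOR_LABELS]
    if not idx:
        raise ValueError("montage contains no parieto-occipital channels")
    return idx
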