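"""Electrode montages (10-20 system) and homologous left-right pairs.

A montage fixes the channel order used everywhere downstream and the list
of homologous electrode pairs over which hemispheric-asymmetry features
are computed. Two montages are built in: the 32-channel Biosemi layout
used by DEAP-style recordings and the 14-channel Emotiv EPOC layout used
by AMIGOS/DREAMER-style recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import EEGAffectError

__all__ = ["Montage", "builtin_montage", "BUILTIN_MONTAGES"]


@dataclass(frozen=True)
class Montage:
    """Named, ordered electrode layout with homologous left/right pairs."""

    name: str
    channels: tuple[str, ...]
    asymmetry_pairs: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        chan_set = set(self.channels)
        if len(chan_set) != len(self.channels):
            raise EEGAffectError(f"montage {self.name!r} has duplicate channels")
        seen: set[frozenset[str]] = set()
        for left, right in self.asymmetry_pairs:
            if left == right:
                raise EEGAffectError(f"degenerate pair ({left}, {right})")
            if left not in chan_set or right not in chan_set:
                raise EEGAffectError(
                    f"pair ({left}, {right}) not contained in montage channels"
                )
            key = frozenset((left, right))
            if key in seen:
                raise EEGAffectError(f"pair ({left}, {right}) repeated")
            seen.add(key)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_pairs(self) -> int:
        return len(self.asymmetry_pairs)

    def index(self, channel: str) -> int:
        return self.channels.index(channel)


# Biosemi ActiveTwo 32-electrode layout (DEAP channel order) with the 14
# homologous left-right 10-20 pairs; midline electrodes (Fz, Cz, Pz, Oz)
# have no homologue and carry no asymmetry feature.
_DEAP32_CHANNELS = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)
_DEAP32_PAIRS = (
    ("Fp1", "Fp2"), ("AF3", "AF4"), ("F3", "F4"), ("F7", "F8"),
    ("FC5", "FC6"), ("FC1", "FC2"), ("C3", "C4"), ("T7", "T8"),
    ("CP5", "CP6"), ("CP1", "CP2"), ("P3", "P4"), ("P7", "P8"),
    ("PO3", "PO4"), ("O1", "O2"),
)

# Emotiv EPOC 14-electrode layout; all channels are lateral, 7 pairs.
_EMOTIV14_CHANNELS = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)
_EMOTIV14_PAIRS = (
    ("AF3", "AF4"), ("F7", "F8"), ("F3", "F4"), ("FC5", "FC6"),
    ("T7", "T8"), ("P7", "P8"), ("O1", "O2"),
)

BUILTIN_MONTAGES: dict[str, Montage] = {
    "deap32": Montage("deap32", _DEAP32_CHANNELS, _DEAP32_PAIRS),
    "emotiv14": Montage("emotiv14", _EMOTIV14_CHANNELS, _EMOTIV14_PAIRS),
}


def builtin_montage(name: str) -> Montage:
    """Return a built-in montage by name (``deap32`` or ``emotiv14``)."""
    try:
        return BUILTIN_MONTAGES[name]
    except KeyError:
        raise EEGAffectError(
            f"unknown montage {name!r}; available: {sorted(BUILTIN_MONTAGES)}"
        ) from None
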