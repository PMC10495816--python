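"""Stable-isotope dimethyl label chemistry.

Dimethyl labeling converts every primary amine of a peptide (the N-terminus
and each lysine epsilon-amine) into a dimethylamino group, adding one
+C2H4-derived mass tag per site. Isotope variants of the reagents
(deuterium for hydrogen, 13C for carbon) generate up to five mass channels:

==========  =======================================  ==============
channel     composition relative to the light tag    tag mass (Da)
==========  =======================================  ==============
delta 0     C2H4 (light)                             28.0313
delta 2     + 2 x (2H - 1H)                          30.0439
delta 4     + 4 x (2H - 1H)                          32.0564
delta 6     + 6 x (2H - 1H)                          34.0690
delta 8     + 2 x (13C - 12C) + 6 x (2H - 1H)        36.0757
==========  =======================================  ==============

With trypsin only channels 0/4/8 keep a 4 Da per-label spacing (3-plex);
Lys-N places both labelable amines on the peptide N-terminus, so every
peptide carries two labels and adjacent channels separate by ~4 Da even at
2 Da per-label spacing, enabling the 5-plex scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

# Standard monoisotopic masses (Da).
MASS_1H = 1.0078250319
MASS_2H = 2.0141017780
MASS_12C = 12.0
MASS_13C = 13.0033548

#: mass gained by swapping one 1H for one 2H
_D = MASS_2H - MASS_1H
#: mass gained by swapping one 12C for one 13C
_C13 = MASS_13C - MASS_12C

#: light dimethyl tag: net +C2H4 per labeled amine
LIGHT_TAG_MASS = 2 * MASS_12C + 4 * MASS_1H

# Heavy-isotope increments per single label, keyed by channel number.
_CHANNEL_DELTA = {
    0: 0.0,
    2: 2 * _D,
    4: 4 * _D,
    6: 6 * _D,
    8: 2 * _C13 + 6 * _D,
}

VALID_CHANNELS = tuple(sorted(_CHANNEL_DELTA))

THREE_PLEX_CHANNELS = (0, 4, 8)
FIVE_PLEX_CHANNELS = (0, 2, 4, 6, 8)

_PROTEASES = ("trypsin", "Lys-C", "Lys-N")


def channel_delta(channel: int) -> float:
    """Per-label monoisotopic mass delta of ``channel`` relative to delta-0."""
    try:
        return _CHANNEL_DELTA[int(channel)]
    except (KeyError, ValueError, TypeError):
        raise ValueError(
            f"unknown channel {channel!r}; valid channels: {list(VALID_CHANNELS)}"
        ) from None


def label_mass(channel: int) -> float:
    """Monoisotopic mass addition (Da) of one dimethyl label for ``channel``."""
    return LIGHT_TAG_MASS + channel_delta(channel)


def label_count(peptide: str, protease: str = "trypsin") -> int:
    """Number of dimethyl-labelable sites of a stripped peptide sequence.

    Every peptide carries one N-terminal label plus one per lysine residue,
    independent of protease (the protease only determines where the lysines
    sit: C-terminal for trypsin/Lys-C, N-terminal for Lys-N).
    """
    if protease not in _PROTEASES:
        raise ValueError(f"unknown protease {protease!r}; expected one of {_PROTEASES}")
    if not peptide:
        raise ValueError("empty peptide sequence")
    return 1 + peptide.upper().count("K")


def precursor_mass_shift(peptide: str, channel: int, protease: str = "trypsin") -> float:
    """Total labeling mass shift of a peptide: label count x per-label mass."""
    return label_count(peptide, protease) * label_mass(channel)


@dataclass(frozen=True)
class LabelScheme:
    """A multiplex design: protease, channel set and per-label masses."""

    name: str
    protease: str
    channels: tuple[int, ...]
    per_label_mass: dict[int, float] = field(default_factory=dict)
    per_label_delta: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.protease not in _PROTEASES:
            raise ValueError(f"unknown protease {self.protease!r}")
        unknown = [c for c in self.channels if c not in _CHANNEL_DELTA]
        if unknown:
            raise ValueError(f"unknown channels {unknown}")
        if not self.per_label_mass:
            object.__setattr__(
                self, "per_label_mass", {c: label_mass(c) for c in self.channels}
            )
        if not self.per_label_delta:
            object.__setattr__(
                self, "per_label_delta", {c: channel_delta(c) for c in self.channels}
            )

    def table(self, example_peptide: str = "PEPTIDEK") -> pd.DataFrame:
        """Per-channel summary: tag mass, delta vs delta-0, example peptide shift."""
        return pd.DataFrame(
            {
                "channel": list(self.channels),
                "label_mass_da": [round(self.per_label_mass[c], 4) for c in self.channels],
                "delta_vs_d0_da": [round(self.per_label_delta[c], 4) for c in self.channels],
                "example_peptide": example_peptide,
                "example_shift_da": [
                    round(precursor_mass_shift(example_peptide, c, self.protease), 4)
                    for c in self.channels
                ],
            }
        )


def three_plex_trypsin() -> LabelScheme:
    """Tryptic 3-plex (channels 0/4/8, 4 Da per-label spacing)."""
    return LabelScheme("3plex-trypsin", "trypsin", THREE_PLEX_CHANNELS)


def five_plex_lysn() -> LabelScheme:
    """Lys-N 5-plex (channels 0/2/4/6/8; two labels per peptide N-terminus)."""
    return LabelScheme("5plex-lysn", "Lys-N", FIVE_PLEX_CHANNELS)


_SCHEMES = {
    "3plex-trypsin": three_plex_trypsin,
    "5plex-lysn": five_plex_lysn,
}


def get_scheme(name: str) -> LabelScheme:
    try:
        return _SCHEMES[name]()
    except KeyError:
        raise ValueError(
            f"unknown label scheme {name!r}; available: {sorted(_SCHEMES)}"
        ) from None


def labeling_efficiency(evidence: pd.DataFrame) -> float:
    """Intensity fraction of fully labeled peptides among all detected peptides.

    ``evidence`` needs columns ``intensity`` (non-negative) and
    ``fully_labeled`` (bool: all labelable sites carry the label). Peptides
    with only a subset of sites labeled count as not fully labeled.
    """
    for col in ("intensity", "fully_labeled"):
        if col not in evidence.columns:
            raise ValueError(f"evidence table is missing column {col!r}")
    if len(evidence) == 0:
        raise ValueError("evidence table is empty")
    inten = evidence["intensity"].astype(float)
    if (inten < 0).any():
        raise ValueError("negative intensities in evidence table")
    total = inten.sum()
    if total == 0:
        raise ValueError("total evidence intensity is zero; efficiency undefined")
    return float(inten[evidence["fully_labeled"].astype(bool)].sum() / total)
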