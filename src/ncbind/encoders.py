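"""Per-residue numeric encodings of peptides: EIIP, INM and AAAF.

Three channels, each mapping a peptide ``S = s1…sn`` to a length-n vector:

* **EIIP** — electron-ion interaction pseudopotential, a physicochemical
  constant per residue (the energy of its delocalised electrons).
* **INM** — integer numerical mapping, a fixed bijection from the 20
  residues to the integers 1–20 (a dense alternative to one-hot).
* **AAAF** — accumulated amino-acid frequency: position j carries the
  frequency of residue s_j among the prefix s1…sj, i.e.
  ``f(s_j) = (1/j) * #{t <= j : s_t == s_j}``.

EIIP and INM are position-wise table lookups; AAAF is prefix-dependent.
``encode_stack`` pads each channel to a fixed length ``L_max`` (post-padding
with 0; 0 is reserved in the INM vocabulary for padding) and stacks the
requested channels into the position × channel matrix the classifier
consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import LengthError
from .peptide_io import ALPHABET, PeptideRecord

#: Channel names in the fixed stacking order.
CHANNELS = ("EIIP", "INM", "AAAF")

#: Default fixed input length: the benchmark's maximum peptide length.
DEFAULT_L_MAX = 15

# EIIP values per residue, stored to the 5 printed decimals.  This table is
# the single source of truth for the package; other published EIIP tables
# are deliberately not consulted.
EIIP_TABLE: dict[str, float] = {
    "A": 0.37100, "R": 0.95930, "N": 0.00359, "D": 0.12630, "C": 0.08292,
    "Q": 0.07606, "E": 0.00580, "G": 0.00499, "H": 0.02415, "I": 0.00000,
    "L": 0.00000, "K": 0.37100, "M": 0.08226, "F": 0.09460, "P": 0.01979,
    "S": 0.08292, "T": 0.09408, "W": 0.05481, "Y": 0.05159, "V": 0.00569,
}

# INM: alphabetical-by-full-name order A..V mapped to 1..20.
INM_TABLE: dict[str, int] = {
    "A": 1, "R": 2, "N": 3, "D": 4, "C": 5, "Q": 6, "E": 7, "G": 8,
    "H": 9, "I": 10, "L": 11, "K": 12, "M": 13, "F": 14, "P": 15,
    "S": 16, "T": 17, "W": 18, "Y": 19, "V": 20,
}

INM_INVERSE: dict[int, str] = {v: k for k, v in INM_TABLE.items()}

assert set(EIIP_TABLE) == set(ALPHABET) == set(INM_TABLE)
assert sorted(INM_TABLE.values()) == list(range(1, 21))


@dataclass(frozen=True)
class EncodingMatrix:
    """Fixed-length position × channel matrix for one peptide.

    Rows beyond ``mask_length`` (the true peptide length) hold the pad value
    in every channel.
    """

    data: np.ndarray
    channels: tuple[str, ...]
    mask_length: int

    def channel(self, name: str) -> np.ndarray:
        """Unpadded single-channel vector (first ``mask_length`` rows)."""
        return self.data[: self.mask_length, self.channels.index(name)].copy()

    def to_frame(self) -> pd.DataFrame:
        """One row per position, one column per channel."""
        return pd.DataFrame(self.data, columns=list(self.channels))


def encode_eiip(peptide: PeptideRecord) -> np.ndarray:
    """EIIP encoding: element t is the EIIP constant of residue s_t."""
    return np.array([EIIP_TABLE[ch] for ch in peptide.sequence], dtype=float)


def encode_inm(peptide: PeptideRecord) -> np.ndarray:
    """INM encoding: element t is the integer code (1–20) of residue s_t."""
    return np.array([INM_TABLE[ch] for ch in peptide.sequence], dtype=int)


def decode_inm(values: Iterable[int]) -> str:
    """Invert an INM vector back to the peptide string (INM is lossless)."""
    return "".join(INM_INVERSE[int(v)] for v in values)


def encode_aaaf(peptide: PeptideRecord) -> np.ndarray:
    """AAAF encoding: prefix frequency of the residue at each position.

    Element j equals (count of s_j among s1…sj) / j, so element 1 is always
    exactly 1 and every element lies in (0, 1].
    """
    seq = peptide.sequence
    counts: dict[str, int] = {}
    out = np.empty(len(seq), dtype=float)
    for j, ch in enumerate(seq, start=1):
        counts[ch] = counts.get(ch, 0) + 1
        out[j - 1] = counts[ch] / j
    return out


_ENCODER_FUNCS = {"EIIP": encode_eiip, "INM": encode_inm, "AAAF": encode_aaaf}


def encode_stack(
    peptide: PeptideRecord,
    channels: Sequence[str] = CHANNELS,
    l_max: int = DEFAULT_L_MAX,
    pad_value: float = 0.0,
) -> EncodingMatrix:
    """Encode, pad to ``l_max`` positions, and stack the requested channels.

    Channels appear column-wise in the requested order; rows beyond the
    peptide length carry ``pad_value``.  Padding never contributes to the
    AAAF frequency counts (AAAF is computed on the unpadded peptide).
    """
    channels = tuple(channels)
    if not channels:
        raise ValueError("at least one channel must be requested")
    unknown = [c for c in channels if c not in _ENCODER_FUNCS]
    if unknown:
        raise ValueError(f"unknown channel(s) {unknown}; choose from {CHANNELS}")
    if peptide.n > l_max:
        raise LengthError(
            f"record {peptide.id!r}: length {peptide.n} exceeds L_max={l_max}"
        )
    data = np.full((l_max, len(channels)), float(pad_value))
    for col, name in enumerate(channels):
        data[: peptide.n, col] = _ENCODER_FUNCS[name](peptide)
    return EncodingMatrix(data=data, channels=channels, mask_length=peptide.n)


def encode_batch(
    peptides: Sequence[PeptideRecord],
    channels: Sequence[str] = CHANNELS,
    l_max: int = DEFAULT_L_MAX,
    pad_value: float = 0.0,
) -> np.ndarray:
    """Stack encodings of many peptides into an (N, L_max, C) array."""
    return np.stack(
        [encode_stack(p, channels, l_max, pad_value).data for p in peptides]
    )
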