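"""Positional information-entropy analysis of peptide sets.

From a set of peptides a position-specific amino-acid matrix ``Z`` (20 × n)
is estimated: ``z[i, j]`` is the probability of amino acid i at position j.
Peptides of mixed length (e.g. 8–15-mers) are left-aligned and 1-based, and
column j is conditioned on the peptides long enough to have a position j —
absence is not treated as a 21st symbol.  Two entropy marginals summarise Z
(both in bits, with the 0·log 0 = 0 convention):

* per-amino-acid entropy ``AP_i = Σ_j −z[i,j]·log2 z[i,j]`` — how spread
  residue i is across positions;
* per-position entropy ``PP_j = Σ_i −z[i,j]·log2 z[i,j]`` — how uncertain
  the residue identity is at position j (0 for a fixed anchor residue, up
  to log2 20 ≈ 4.32 bits for a uniform position).

Low PP at a position marks anchor-like residue preference; binder sets
typically show lower entropy than non-binder sets.  ``entropy_report``
computes both profiles for the positive set, the negative set, and their
union (groups POS / NEG / SUM).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .peptide_io import ALPHABET, PeptideRecord

_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
LOG2_20 = float(np.log2(20.0))


@dataclass(frozen=True)
class PositionAAMatrix:
    """Position-specific amino-acid probabilities with per-column coverage.

    ``z[i, j]`` is conditioned on the ``coverage[j]`` sequences of length
    > j (0-based j); columns with zero coverage are undefined (NaN).
    """

    z: np.ndarray          # (20, n_max)
    coverage: np.ndarray   # (n_max,) number of sequences contributing per column
    alphabet: str = ALPHABET

    @property
    def n_max(self) -> int:
        return self.z.shape[1]

    def covered(self) -> np.ndarray:
        return self.coverage > 0


@dataclass(frozen=True)
class EntropyProfile:
    """AP (per-residue) and PP (per-position) entropies for one group."""

    ap: np.ndarray     # (20,) bits
    pp: np.ndarray     # (n_max,) bits; NaN where the column is uncovered
    group: str         # POS / NEG / SUM
    alphabet: str = ALPHABET


def position_aa_matrix(peptides: Sequence[PeptideRecord], n_max: int
                       ) -> PositionAAMatrix:
    """Estimate Z by counting residues per position over the peptide set."""
    if n_max < 1:
        raise ValueError(f"n_max must be >= 1, got {n_max}")
    if not peptides:
        raise ValueError("peptide list must be non-empty")
    counts = np.zeros((20, n_max))
    coverage = np.zeros(n_max, dtype=int)
    for rec in peptides:
        upto = min(rec.n, n_max)
        coverage[:upto] += 1
        for j in range(upto):
            counts[_AA_INDEX[rec.sequence[j]], j] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        z = counts / coverage
    z[:, coverage == 0] = np.nan
    return PositionAAMatrix(z=z, coverage=coverage)


def _neg_xlog2x(z: np.ndarray) -> np.ndarray:
    """Elementwise −z·log2(z) with 0·log 0 = 0; NaN propagates."""
    return -xlogy(z, z) / np.log(2.0)


def amino_acid_entropy(matrix: PositionAAMatrix) -> np.ndarray:
    """AP: per-residue entropy summed over the covered positions (bits)."""
    terms = _neg_xlog2x(matrix.z[:, matrix.covered()])
    return terms.sum(axis=1)


def positional_entropy(matrix: PositionAAMatrix) -> np.ndarray:
    """PP: Shannon entropy of each position's residue distribution (bits).

    Uncovered columns are NaN (undefined), not 0.
    """
    pp = np.full(matrix.n_max, np.nan)
    cov = matrix.covered()
    pp[cov] = _neg_xlog2x(matrix.z[:, cov]).sum(axis=0)
    return pp


def profile(peptides: Sequence[PeptideRecord], n_max: int, group: str
            ) -> EntropyProfile:
    """Both entropy marginals of one peptide set's Z matrix."""
    matrix = position_aa_matrix(peptides, n_max)
    return EntropyProfile(
        ap=amino_acid_entropy(matrix),
        pp=positional_entropy(matrix),
        group=group,
    )


def entropy_report(positives: Sequence[PeptideRecord],
                   negatives: Sequence[PeptideRecord],
                   n_max: int) -> dict[str, EntropyProfile]:
    """AP and PP profiles for positives (POS), negatives (NEG) and their
    union (SUM)."""
    if not positives or not negatives:
        raise ValueError("both peptide groups must be non-empty")
    return {
        "POS": profile(positives, n_max, "POS"),
        "NEG": profile(negatives, n_max, "NEG"),
        "SUM": profile(list(positives) + list(negatives), n_max, "SUM"),
    }


def report_frame(profiles: dict[str, EntropyProfile]) -> pd.DataFrame:
    """Tidy table: one row per (group, kind, index, value).

    For ``kind == "AP"`` the index column holds the residue letter; for
    ``kind == "PP"`` the 1-based position.
    """
    rows = []
    for group, prof in profiles.items():
        for aa, value in zip(prof.alphabet, prof.ap):
            rows.append({"group": group, "kind": "AP", "index": aa,
                         "value": value})
        for j, value in enumerate(prof.pp, start=1):
            rows.append({"group": group, "kind": "PP", "index": str(j),
                         "value": value})
    return pd.DataFrame(rows)
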