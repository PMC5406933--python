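"""Linear B-cell epitope scanning and position-specific-matrix MHC-II scanning.

B-cell epitopes: a windowed Parker hydrophilicity scan. The Parker scale
assigns each residue an HPLC-derived hydrophilicity value; antibody-
accessible linear epitopes tend to be hydrophilic surface stretches, so
maximal runs of above-threshold window means are reported as predicted
peptides.

T-cell (MHC class II) epitopes: every 9-mer window of the protein is
scored additively against one position-specific scoring matrix per
allele (rows = 20 residues, columns = 9 positions); windows at or above
the per-matrix threshold are binding-peptide hits. Matrices are
user-supplied — pocket-profile and IC50-regression matrices from the
dedicated MHC-II tools are not bundled — so counts depend entirely on
the matrices given.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "PARKER_HYDROPHILICITY",
    "EpitopeProfile",
    "Peptide",
    "MatrixHit",
    "MatrixScanResult",
    "parker_profile",
    "call_bcell_epitopes",
    "matrix_scan",
    "read_matrix",
]

#: Parker, Guo & Hodges HPLC hydrophilicity scale (per-residue propensities).
PARKER_HYDROPHILICITY: dict[str, float] = {
    "A": 2.1, "C": 1.4, "D": 10.0, "E": 7.8, "F": -9.2,
    "G": 5.7, "H": 2.1, "I": -8.0, "K": 5.7, "L": -9.2,
    "M": -4.2, "N": 7.0, "P": 2.1, "Q": 6.0, "R": 4.2,
    "S": 6.5, "T": 5.2, "V": -3.7, "W": -10.0, "Y": -1.9,
}

_RESIDUES = sorted(PARKER_HYDROPHILICITY)  # canonical 20-residue row order


class Peptide(NamedTuple):
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    peptide: str
    mean_score: float


@dataclass
class EpitopeProfile:
    """Per-residue hydrophilicity propensity profile of one sequence."""

    sequence_id: str
    sequence: str
    window: int
    scores: np.ndarray
    threshold: Optional[float] = None
    peptides: list[Peptide] = field(default_factory=list)


def parker_profile(sequence: str, window: int = 7, sequence_id: str = "seq") -> EpitopeProfile:
    """Centered sliding-window mean of the Parker hydrophilicity scale.

    The score at position ``i`` averages the scale values over the window
    centered there; near the termini the window shrinks to what fits
    (never below ``ceil(window/2)`` residues), rather than padding with
    invented residues.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    seq = sequence.upper()
    half = window // 2
    min_len = (window + 1) // 2
    if len(seq) < min_len:
        raise ValueError(f"sequence length {len(seq)} shorter than {min_len} (half window)")
    try:
        vals = np.array([PARKER_HYDROPHILICITY[aa] for aa in seq])
    except KeyError as e:
        raise ValueError(f"residue {e.args[0]!r} not in the 20-residue Parker scale") from None
    cum = np.concatenate([[0.0], np.cumsum(vals)])
    n = len(seq)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    scores = (cum[hi] - cum[lo]) / (hi - lo)
    return EpitopeProfile(sequence_id=sequence_id, sequence=seq, window=window, scores=scores)


def call_bcell_epitopes(
    profile: EpitopeProfile,
    threshold: Union[str, float] = "mean",
    min_len: int = 7,
) -> list[Peptide]:
    """Report maximal runs of strictly above-threshold positions.

    ``threshold="mean"`` uses the sequence-wide mean score (so a flat
    profile yields no peptides — no position is strictly above its own
    mean); a float uses that value directly. Runs shorter than ``min_len``
    are discarded. The returned peptides are disjoint, sorted by start,
    and recorded on the profile.
    """
    thr = float(np.mean(profile.scores)) if threshold == "mean" else float(threshold)
    above = profile.scores > thr
    peptides: list[Peptide] = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if j - i + 1 >= min_len:
                peptides.append(
                    Peptide(
                        start=i + 1,
                        end=j + 1,
                        peptide=profile.sequence[i : j + 1],
                        mean_score=float(np.mean(profile.scores[i : j + 1])),
                    )
                )
            i = j + 1
        else:
            i += 1
    profile.threshold = thr
    profile.peptides = peptides
    return peptides


class MatrixHit(NamedTuple):
    position: int  # 1-based first residue of the 9-mer
    peptide: str
    score: float


@dataclass
class MatrixScanResult:
    sequence_id: str
    allele_id: str
    hits: list[MatrixHit]


def read_matrix(path) -> pd.DataFrame:
    """Read one allele's 20x9 scoring matrix from TSV (rows = residues)."""
    m = pd.read_csv(path, sep="\t", index_col=0)
    return _validate_matrix(m, str(path))


def _validate_matrix(m: pd.DataFrame, name: str) -> pd.DataFrame:
    if m.shape != (20, 9):
        raise ValueError(f"matrix {name}: expected shape (20, 9), got {m.shape}")
    if sorted(str(i).upper() for i in m.index) != _RESIDUES:
        raise ValueError(f"matrix {name}: rows must be the 20 standard residues")
    m = m.copy()
    m.index = [str(i).upper() for i in m.index]
    return m.loc[_RESIDUES].astype(float)


def matrix_scan(
    sequence: str,
    matrices: Mapping[str, pd.DataFrame],
    threshold: Union[float, Mapping[str, float]] = 0.0,
    sequence_id: str = "seq",
) -> tuple[list[MatrixScanResult], dict]:
    """Score every 9-mer against every allele matrix; report threshold hits.

    A 9-mer's score is the sum over positions of the matrix entry for the
    residue at that position; hits have ``score >= threshold`` (per-allele
    thresholds via a mapping). Returns per-allele results in deterministic
    (allele, position) order plus a summary with the total hit count
    (``n_peptides``) and the number of alleles with at least one hit
    (``n_alleles_bound``).
    """
    seq = sequence.upper()
    n_windows = len(seq) - 8
    if n_windows < 1:
        raise ValueError("sequence shorter than 9 residues")
    aa_index = {aa: i for i, aa in enumerate(_RESIDUES)}
    try:
        idx = np.array([aa_index[aa] for aa in seq])
    except KeyError as e:
        raise ValueError(f"residue {e.args[0]!r} is not a standard amino acid") from None

    results: list[MatrixScanResult] = []
    n_peptides = 0
    n_alleles_bound = 0
    for allele in sorted(matrices):
        m = _validate_matrix(matrices[allele], allele).to_numpy()
        thr = threshold[allele] if isinstance(threshold, Mapping) else float(threshold)
        # score all windows: sum_j m[idx[i+j], j]
        windows = np.lib.stride_tricks.sliding_window_view(idx, 9)
        scores = m[windows, np.arange(9)].sum(axis=1)
        hits = [
            MatrixHit(position=i + 1, peptide=seq[i : i + 9], score=float(s))
            for i, s in enumerate(scores)
            if s >= thr
        ]
        results.append(MatrixScanResult(sequence_id=sequence_id, allele_id=allele, hits=hits))
        n_peptides += len(hits)
        n_alleles_bound += bool(hits)

    summary = {
        "sequence_id": sequence_id,
        "n_windows": n_windows,
        "n_peptides": n_peptides,
        "n_alleles_bound": n_alleles_bound,
    }
    return results, summary
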