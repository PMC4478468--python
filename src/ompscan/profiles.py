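"""PSI-BLAST ASCII profile I/O and per-position information features.

A PSI-BLAST run with the ``-Q`` option writes, for every query position, a
row of 20 integer log-odds scores (the PSSM) followed by 20 amino-acid
frequency percentages (the PSFM).  This module parses that dialect into a
:class:`SequenceProfile` and derives the per-residue feature tracks used by
the property predictors: a sigmoid-squashed PSSM, the Shannon entropy of
each PSFM column and a conservation score decreasing in that entropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Amino-acid column order used by PSI-BLAST profile files.
ALPHABET = "ARNDCQEGHILKMFPSTWYV"
_ALPHABET_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: Maximum column entropy (natural log of 20) for a uniform frequency row.
MAX_ENTROPY = math.log(20.0)

#: Residues outside the standard 20 are collapsed to this placeholder.
UNKNOWN_RESIDUE = "X"


class ProfileParseError(ValueError):
    """Raised when a profile file does not follow the expected dialect."""


@dataclass
class SequenceProfile:
    """A protein sequence with its aligned PSSM and PSFM matrices.

    Attributes
    ----------
    sequence:
        Amino-acid string of length L.  Nonstandard residues (B, Z, U, ...)
        are mapped to ``X``; their matrix rows are kept as parsed.
    pssm:
        (L, 20) integer-valued log-odds scores, columns ordered by
        :data:`ALPHABET`.
    psfm:
        (L, 20) frequencies; every row sums to 1.
    """

    sequence: str
    pssm: np.ndarray
    psfm: np.ndarray
    alphabet: str = ALPHABET

    def __post_init__(self) -> None:
        self.pssm = np.asarray(self.pssm, dtype=float)
        self.psfm = np.asarray(self.psfm, dtype=float)
        L = len(self.sequence)
        if self.pssm.shape != (L, 20) or self.psfm.shape != (L, 20):
            raise ValueError(
                f"matrix shapes {self.pssm.shape}/{self.psfm.shape} do not "
                f"match sequence length {L}"
            )
        if L == 0:
            raise ValueError("empty profile")
        sums = self.psfm.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("psfm rows must sum to 1 after normalization")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProfileFeatures:
    """Derived per-residue tracks: squashed PSSM, entropy, conservation."""

    pssm_sig: np.ndarray  # (L, 20) in (0, 1)
    entropy: np.ndarray  # (L,) in [0, ln 20]
    cs: np.ndarray  # (L,) in (0, 1]


def _clean_residue(letter: str) -> str:
    letter = letter.upper()
    return letter if letter in _ALPHABET_INDEX else UNKNOWN_RESIDUE


def _normalize_psfm_row(row: np.ndarray) -> np.ndarray:
    total = row.sum()
    if total <= 0.0:
        # No observations at this position (happens in real PSI-BLAST output
        # when a column gathers no hits): fall back to the uniform vector,
        # the maximally variable state.
        return np.full(20, 0.05)
    return row / total


def parse_psiblast_profile(path) -> SequenceProfile:
    """Read a PSI-BLAST ``-Q`` ASCII profile file.

    Data rows carry: position index, residue letter, 20 log-odds integers,
    20 frequency percentages, and per-position statistics which are ignored.
    Header and trailing statistics lines are skipped.  Frequency percentages
    are divided by 100 and each row renormalized to sum to 1; all-zero rows
    become uniform.

    Raises
    ------
    ProfileParseError
        On a malformed data row (naming the line number) or an empty profile.
    """
    sequence: list[str] = []
    pssm_rows: list[list[int]] = []
    psfm_rows: list[np.ndarray] = []
    expected_index = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if len(fields) < 2:
                continue
            if not fields[0].isdigit() or fields[0] != str(expected_index):
                continue  # header or trailing statistics line
            if not (len(fields[1]) == 1 and fields[1].isalpha()):
                continue
            if len(fields) < 42:
                raise ProfileParseError(
                    f"{path}: line {lineno}: expected at least 42 columns "
                    f"(index, residue, 20 scores, 20 percentages), got "
                    f"{len(fields)}"
                )
            try:
                scores = [int(v) for v in fields[2:22]]
                percents = np.array([float(v) for v in fields[22:42]])
            except ValueError as exc:
                raise ProfileParseError(
                    f"{path}: line {lineno}: non-numeric matrix entry"
                ) from exc
            sequence.append(_clean_residue(fields[1]))
            pssm_rows.append(scores)
            psfm_rows.append(_normalize_psfm_row(percents / 100.0))
            expected_index += 1
    if not sequence:
        raise ProfileParseError(f"{path}: no profile rows found")
    return SequenceProfile(
        sequence="".join(sequence),
        pssm=np.array(pssm_rows, dtype=float),
        psfm=np.vstack(psfm_rows),
    )


def write_psiblast_profile(profile: SequenceProfile, path) -> None:
    """Write a profile in the same ASCII dialect the parser reads.

    Frequencies are stored as integer percentages, as in real PSI-BLAST
    output.  Profiles whose frequency rows are exact multiples of 1% (all
    generated fixtures are) round-trip exactly through parse.
    """
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted "
            "observed percentages rounded down, information per position, "
            "and relative weight of gapless real matches to pseudocounts\n"
        )
        header = " ".join(profile.alphabet)
        fh.write(f"            {header}  {header}\n")
        for i, aa in enumerate(profile.sequence):
            scores = " ".join(f"{int(round(v)):3d}" for v in profile.pssm[i])
            pcts = " ".join(
                f"{int(round(v * 100)):3d}" for v in profile.psfm[i]
            )
            fh.write(f"{i + 1:5d} {aa}  {scores}  {pcts}  0.00 0.00\n")
        fh.write("\n                      K         Lambda\n")
        fh.write("Standard Ungapped    0.1337     0.3177\n")


def sigmoid_normalize(pssm: np.ndarray) -> np.ndarray:
    """Map raw log-odds scores into (0, 1) elementwise via 1/(1+e^-x)."""
    x = np.asarray(pssm, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("pssm entries must be finite")
    return 1.0 / (1.0 + np.exp(-x))


def column_entropy(freqs: np.ndarray) -> float:
    """Shannon entropy (natural log) of one PSFM column, with 0*ln 0 = 0."""
    f = np.asarray(freqs, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequencies must be nonnegative")
    if not math.isclose(f.sum(), 1.0, abs_tol=1e-3):
        raise ValueError("frequencies must sum to 1")
    nz = f[f > 0]
    return float(-(nz * np.log(nz)).sum())


def conservation_score(entropy_value: float) -> float:
    """Conservation score exp(-entropy): 1 when perfectly conserved,
    decreasing to 1/20 at the uniform (maximally variable) limit."""
    if not (-1e-9 <= entropy_value <= MAX_ENTROPY + 1e-9):
        raise ValueError(
            f"entropy {entropy_value} outside [0, ln 20 = {MAX_ENTROPY:.4f}]"
        )
    return float(math.exp(-max(entropy_value, 0.0)))


def compute_features(profile: SequenceProfile) -> ProfileFeatures:
    """Derive all per-residue information tracks for a profile."""
    entropy = np.array([column_entropy(row) for row in profile.psfm])
    cs = np.array([conservation_score(h) for h in entropy])
    return ProfileFeatures(
        pssm_sig=sigmoid_normalize(profile.pssm), entropy=entropy, cs=cs
    )


def write_feature_table(profile: SequenceProfile, features: ProfileFeatures,
                        path) -> None:
    """Write a TSV of position, residue, entropy, CS and normalized PSSM."""
    with open(path, "w") as fh:
        cols = "\t".join(f"pssm_{aa}" for aa in profile.alphabet)
        fh.write(f"position\tresidue\tentropy\tcs\t{cols}\n")
        for i, aa in enumerate(profile.sequence):
            row = "\t".join(f"{v:.6f}" for v in features.pssm_sig[i])
            fh.write(
                f"{i + 1}\t{aa}\t{features.entropy[i]:.6f}\t"
                f"{features.cs[i]:.6f}\t{row}\n"
            )
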