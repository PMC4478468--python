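"""Independent reference implementations used to check the package.

Everything here is deliberately naive — scalar loops and explicit path
enumeration — so that agreement with the vectorized/DP implementations is
meaningful.
"""

from __future__ import annotations

import math

import numpy as np

from ompscan.alignment import AlignedEntry
from ompscan.profiles import ALPHABET, SequenceProfile
from ompscan.struct_props import SS_CLASSES, StructuralFeatures, ss_one_hot


def sigmoid_loop(matrix):
    out = np.empty_like(np.asarray(matrix, dtype=float))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            out[i, j] = 1.0 / (1.0 + math.exp(-matrix[i][j]))
    return out


def entropy_loop(freqs):
    total = 0.0
    for f in freqs:
        if f > 0:
            total -= f * math.log(f)
    return total


def fitness_tally(dataset):
    """Plain dict-of-dicts tally of P(ss class | residue)."""
    counts = {aa: {c: 0 for c in SS_CLASSES} for aa in ALPHABET}
    for seq, ss in dataset:
        for aa, s in zip(seq, ss):
            if aa in counts and s in SS_CLASSES:
                counts[aa][s] += 1
    table = {}
    for aa in ALPHABET:
        total = sum(counts[aa].values())
        if total == 0:
            table[aa] = {c: 1.0 / 3.0 for c in SS_CLASSES}
        else:
            table[aa] = {c: counts[aa][c] / total for c in SS_CLASSES}
    return table


# ----------------------------------------------------------------------
# Brute-force alignment: enumerate every path on the alignment lattice and
# score it with affine gap rules (open once, extend after; switching gap
# direction re-opens).
# ----------------------------------------------------------------------

def oracle_global_score(S: np.ndarray, gap_open: float,
                        gap_extend: float) -> float:
    n, m = S.shape
    best = [-math.inf]

    def rec(i, j, score, last):
        if i == n and j == m:
            if score > best[0]:
                best[0] = score
            return
        if i < n and j < m:
            rec(i + 1, j + 1, score + S[i, j], "M")
        if i < n:
            rec(i + 1, j, score + (gap_extend if last == "X" else gap_open),
                "X")
        if j < m:
            rec(i, j + 1, score + (gap_extend if last == "Y" else gap_open),
                "Y")

    rec(0, 0, 0.0, None)
    return best[0]


def oracle_local_score(S: np.ndarray, gap_open: float,
                       gap_extend: float) -> float:
    """Best over all match-bounded subpaths (0 if none is positive)."""
    n, m = S.shape
    best = 0.0

    def rec(i, j, score, last):
        nonlocal best
        if last == "M" and score > best:
            best = score
        if i < n and j < m:
            rec(i + 1, j + 1, score + S[i, j], "M")
        if i < n:
            rec(i + 1, j, score + (gap_extend if last == "X" else gap_open),
                "X")
        if j < m:
            rec(i, j + 1, score + (gap_extend if last == "Y" else gap_open),
                "Y")

    for i in range(n):
        for j in range(m):
            rec(i + 1, j + 1, float(S[i, j]), "M")
    return best


def random_entry(rng: np.random.Generator, length: int,
                 entry_id: str = "x") -> AlignedEntry:
    """A random feature-complete entry for alignment stress tests."""
    seq = "".join(ALPHABET[k] for k in rng.integers(0, 20, length))
    psfm = rng.dirichlet(np.ones(20), size=length)
    pssm = rng.integers(-6, 9, size=(length, 20)).astype(float)
    ss3 = "".join(SS_CLASSES[k] for k in rng.integers(0, 3, length))
    features = StructuralFeatures(
        ss3=ss3, ss_probs=ss_one_hot(ss3),
        rsa=rng.uniform(0, 1, length), rd=rng.uniform(0, 1, length),
        phi_norm=rng.uniform(0, 1, length),
    )
    return AlignedEntry(
        id=entry_id,
        profile=SequenceProfile(sequence=seq, pssm=pssm, psfm=psfm),
        features=features, ss_ri=rng.uniform(0, 1, length),
    )
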