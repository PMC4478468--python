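"""Normalization of raw structural annotations to [0, 1] training targets.

Raw annotations come from structure-analysis programs run elsewhere (DSSP or
STRIDE for secondary structure and solvent-accessible area, EDTSurf for
residue depth); this module only transforms their plain-table output:

* 7-state secondary structure is reduced to helix/strand/coil,
* absolute solvent-accessible area becomes relative accessibility (RSA)
  by dividing by a per-residue maximum area and capping at 100%,
* absolute residue depth in the EDTSurf range [2.8, 9.8] is min-max
  normalized,
* the Phi backbone torsion angle is remapped from (-180, 180] degrees onto
  [0, 1] by wrapping negatives to (180, 360) and dividing by 360.

It also tallies the amino-acid/secondary-structure fitness table: the
empirical probability of each of the three structure classes given the
residue type.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .profiles import ALPHABET

#: Secondary-structure class order used everywhere in the package.  The
#: network output encoding is H=(0,0,1), E=(0,1,0), C=(1,0,0), i.e. column
#: 0 is coil, column 1 strand, column 2 helix.  With this order a plain
#: first-index argmax breaks ties toward C, then E, then H.
SS_CLASSES = "CEH"

#: EDTSurf absolute residue-depth output range.
RD_MIN, RD_MAX = 2.8, 9.8

_HELIX_STATES = frozenset("HGI")
_STRAND_STATES = frozenset("EB")


@dataclass
class StructuralFeatures:
    """Per-residue structural tracks, all on [0, 1] scales.

    ``ss_probs`` columns follow :data:`SS_CLASSES` (C, E, H); for observed
    (non-predicted) structures the rows are one-hot.
    """

    ss3: str
    ss_probs: np.ndarray  # (L, 3), rows sum to 1
    rsa: np.ndarray  # (L,)
    rd: np.ndarray  # (L,)
    phi_norm: np.ndarray  # (L,)

    def __post_init__(self) -> None:
        L = len(self.ss3)
        for name in ("rsa", "rd", "phi_norm"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if v.shape != (L,):
                raise ValueError(f"{name} length {v.shape} != {L}")
            if np.any(v < -1e-9) or np.any(v > 1 + 1e-9):
                raise ValueError(f"{name} outside [0, 1]")
        self.ss_probs = np.asarray(self.ss_probs, dtype=float)
        if self.ss_probs.shape != (L, 3):
            raise ValueError("ss_probs must be (L, 3)")

    def __len__(self) -> int:
        return len(self.ss3)


@dataclass
class FitnessTable:
    """P(secondary-structure class | residue type), a (20, 3) table.

    Rows follow the profile alphabet, columns :data:`SS_CLASSES`; each row
    sums to 1.  The raw counts are retained for audit.
    """

    ft: np.ndarray  # (20, 3)
    residue_counts: np.ndarray  # (20,) NA_i
    class_counts: np.ndarray  # (20, 3) NS_{j,i}

    def row(self, residue: str) -> np.ndarray:
        return self.ft[ALPHABET.index(residue)]


def ss_one_hot(ss3: str) -> np.ndarray:
    """One-hot (L, 3) encoding of a 3-state string in C/E/H column order."""
    out = np.zeros((len(ss3), 3))
    for i, s in enumerate(ss3):
        out[i, SS_CLASSES.index(s)] = 1.0
    return out


def reduce_ss(seven_state: str) -> str:
    """Collapse 7-state secondary structure to 3 states.

    H, G and I become H (helix); E and B become E (strand); everything
    else — T, S, C, blanks, unknowns — becomes C (coil).  Total: never
    raises, idempotent on 3-state input.
    """
    return "".join(
        "H" if s.upper() in _HELIX_STATES
        else "E" if s.upper() in _STRAND_STATES else "C"
        for s in seven_state
    )


def load_max_asa(path=None) -> dict[str, float]:
    """Load a per-residue maximum accessible-surface-area table (Å²).

    The shipped default is the Tien et al. (2013) theoretical maximum set;
    pass a two-column TSV (residue, max_asa) to substitute another scale.
    """
    if path is None:
        ref = resources.files("ompscan").joinpath("data/max_asa.tsv")
        with ref.open() as fh:
            return _read_max_asa(fh)
    with open(path) as fh:
        return _read_max_asa(fh)


def _read_max_asa(fh) -> dict[str, float]:
    table = {}
    for row in csv.DictReader(fh, delimiter="\t"):
        table[row["residue"].strip().upper()] = float(row["max_asa"])
    missing = set(ALPHABET) - set(table)
    if missing:
        raise ValueError(f"max-ASA table missing residues: {sorted(missing)}")
    return table


def relative_accessibility(asa: float, residue: str,
                           max_area_table: dict[str, float],
                           fallback_area: float | None = None) -> float:
    """RSA = accessible area / maximum area, capped at 1.

    Distorted geometry in real structures can push the ratio above 100%;
    such values are set to exactly 1.
    """
    if asa < 0:
        raise ValueError("accessible surface area must be nonnegative")
    residue = residue.upper()
    max_area = max_area_table.get(residue, fallback_area)
    if max_area is None:
        raise KeyError(
            f"no maximum area for residue {residue!r} and no fallback given"
        )
    return min(asa / max_area, 1.0)


def normalize_rd(dv: float) -> float:
    """Min-max normalize an absolute depth value over [2.8, 9.8], clamped."""
    if not np.isfinite(dv):
        raise ValueError("depth value must be finite")
    return float(np.clip((dv - RD_MIN) / (RD_MAX - RD_MIN), 0.0, 1.0))


def normalize_phi(phi_deg: float) -> float:
    """Map a Phi angle in [-180, 180] degrees onto [0, 1].

    Angles in [0, 180] are kept; negative angles gain 360 so the scale is
    continuous across the helical region; the result is divided by 360.
    Exactly -180 is treated as +180 (one representative of the wrapped
    angle), so the map is a bijection [-180, 180) -> [0, 1).
    """
    if not -180.0 <= phi_deg <= 180.0:
        raise ValueError(f"phi {phi_deg} outside [-180, 180]")
    if phi_deg == -180.0:
        phi_deg = 180.0
    shifted = phi_deg if phi_deg >= 0 else phi_deg + 360.0
    return shifted / 360.0


def compute_fitness(dataset: list[tuple[str, str]]) -> FitnessTable:
    """Tally the fitness of each amino acid in the three structure classes.

    ``dataset`` is a list of (sequence, ss3) pairs of matching lengths.
    For residue type i and class j the table entry is NS_{j,i} / NA_i, the
    fraction of type-i residues observed in class j; rows sum to 1.
    Residue types absent from the dataset get a uniform (1/3, 1/3, 1/3) row
    with a warning.  Nonstandard residues are excluded from the counts.
    """
    counts = np.zeros((20, 3))
    for seq, ss3 in dataset:
        if len(seq) != len(ss3):
            raise ValueError("sequence and ss3 lengths differ")
        for aa, s in zip(seq.upper(), ss3.upper()):
            if aa in ALPHABET and s in SS_CLASSES:
                counts[ALPHABET.index(aa), SS_CLASSES.index(s)] += 1
    residue_counts = counts.sum(axis=1)
    ft = np.full((20, 3), 1.0 / 3.0)
    present = residue_counts > 0
    ft[present] = counts[present] / residue_counts[present, None]
    if not np.all(present):
        absent = [ALPHABET[i] for i in np.flatnonzero(~present)]
        warnings.warn(
            f"residues absent from fitness dataset, rows set uniform: "
            f"{absent}",
            stacklevel=2,
        )
    return FitnessTable(ft=ft, residue_counts=residue_counts,
                        class_counts=counts)


def read_annotation_table(path) -> list[dict]:
    """Read a per-residue annotation TSV.

    Columns: position, residue, ss7, asa, depth, phi_deg — the plain-table
    export of DSSP/STRIDE/EDTSurf runs done outside this package.
    """
    rows = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.append({
                "position": int(row["position"]),
                "residue": row["residue"],
                "ss7": row["ss7"],
                "asa": float(row["asa"]),
                "depth": float(row["depth"]),
                "phi_deg": float(row["phi_deg"]),
            })
    return rows


def annotations_to_features(rows: list[dict],
                            max_area_table: dict[str, float] | None = None,
                            ) -> StructuralFeatures:
    """Normalize a parsed annotation table into StructuralFeatures."""
    if max_area_table is None:
        max_area_table = load_max_asa()
    ss3 = reduce_ss("".join(r["ss7"] for r in rows))
    rsa = np.array([
        relative_accessibility(r["asa"], r["residue"], max_area_table)
        for r in rows
    ])
    rd = np.array([normalize_rd(r["depth"]) for r in rows])
    phi = np.array([normalize_phi(r["phi_deg"]) for r in rows])
    return StructuralFeatures(ss3=ss3, ss_probs=ss_one_hot(ss3), rsa=rsa,
                              rd=rd, phi_norm=phi)


def write_features_table(features: StructuralFeatures, path,
                         sequence: str | None = None) -> None:
    """Write normalized structural tracks as a TSV."""
    with open(path, "w") as fh:
        fh.write("position\tresidue\tss3\tp_C\tp_E\tp_H\trsa\trd\tphi_norm\n")
        for i in range(len(features)):
            aa = sequence[i] if sequence else "-"
            p = features.ss_probs[i]
            fh.write(
                f"{i + 1}\t{aa}\t{features.ss3[i]}\t{p[0]:.6f}\t{p[1]:.6f}\t"
                f"{p[2]:.6f}\t{features.rsa[i]:.6f}\t{features.rd[i]:.6f}\t"
                f"{features.phi_norm[i]:.6f}\n"
            )


def write_fitness_table(table: FitnessTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("residue\tp_C\tp_E\tp_H\tcount\n")
        for i, aa in enumerate(ALPHABET):
            r = table.ft[i]
            # full float precision so serialized bundles predict identically
            fh.write(
                f"{aa}\t{r[0]:.17g}\t{r[1]:.17g}\t{r[2]:.17g}\t"
                f"{int(table.residue_counts[i])}\n"
            )
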