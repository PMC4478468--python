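"""Seeded generators for profile families with ground-truth structure.

Real inputs to this package are PSI-BLAST profiles of protein families and
structure-derived labels.  The generator emulates both so the whole
pipeline can be trained and benchmarked without external databases.  A
family is built structure-first:

* a secondary-structure string is laid down as alternating helix/strand/
  coil segments with geometric lengths;
* each segment gets a positional *exposure field*: strands alternate
  buried/exposed with a per-segment phase (the membrane β-strand pattern),
  helices follow a helical-wheel periodicity with a random phase
  (amphipathic faces), coil is mostly exposed.  The (SS, exposure) pair is
  the family's structure and is what homologs conserve;
* an ancestor sequence is emitted from residue preferences conditioned on
  both the SS class and the exposure state (hydrophobics at buried
  positions), and homologs arise by class- and hydropathy-conserving point
  substitutions, so the positional hydropathy pattern — hence the
  structure — survives sequence divergence;
* the PSFM is the pseudocounted column frequency matrix of the homologs
  and the PSSM its rounded log-odds against a uniform background;
* true RSA is drawn around exposure- and class-dependent means (with a
  weak residue-hydropathy term), residue depth is a noisy decreasing
  function of RSA (negative correlation by construction), and Phi comes
  from class-conditional angle distributions (helical ~ -60 deg, extended
  ~ -120 deg, coil broad with a positive-angle minority).

Everything is a deterministic function of the spec seed.  What this does
not emulate: real barrel topology closure, PSI-BLAST iteration dynamics,
or long-range contacts between sequence-distant residues.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .alignment import AlignedEntry
from .profiles import ALPHABET, SequenceProfile
from .struct_props import SS_CLASSES, StructuralFeatures, normalize_phi, ss_one_hot

#: Uniform background frequency used for the log-odds scores.
BACKGROUND = 0.05
#: PSSM scale: half-bit units, rounded to integers.
LOG_ODDS_SCALE = 2.0

# class-conditional residue preferences (boosted residues per class)
_CLASS_FAVORED = {
    "H": "ALMEQKRH",
    "E": "VIFYWTC",
    "C": "GPSND",
}
_BOOST = 6.0

# mean geometric segment lengths and class draw weights per fold:
# barrels are long membrane strands joined by loops with rare helices;
# globular folds mix all three classes.
_FOLDS = {
    "barrel": {
        "segment_mean": {"H": 5.0, "E": 9.0, "C": 4.0},
        "class_weight": {"H": 0.06, "E": 0.52, "C": 0.42},
        "strand_alternation": True,
    },
    "globular": {
        "segment_mean": {"H": 9.0, "E": 6.0, "C": 5.0},
        "class_weight": {"H": 0.40, "E": 0.25, "C": 0.35},
        "strand_alternation": False,
    },
    # all-β soluble fold: barrel-like class composition (the hard decoys)
    # but a sheet-core exposure pattern instead of membrane alternation
    "beta": {
        "segment_mean": {"H": 5.0, "E": 9.0, "C": 4.0},
        "class_weight": {"H": 0.06, "E": 0.52, "C": 0.42},
        "strand_alternation": False,
    },
}
#: Probability that a non-alternating (globular, sheet-core) strand
#: position is buried.
_GLOBULAR_STRAND_BURIED_P = 0.7

# Kyte-Doolittle hydropathy, rescaled to [0, 1] (1 = most hydrophobic)
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}
_HYDRO = {aa: (v + 4.5) / 9.0 for aa, v in _KD.items()}
_HYDRO_VEC = np.array([_HYDRO[aa] for aa in ALPHABET])

#: Target hydropathy of buried / exposed positions, and the width of the
#: Gaussian pull toward it in the emission and substitution kernels.
_HYDRO_TARGET = {True: 0.75, False: 0.30}  # keyed by "buried"
_HYDRO_SIGMA = 0.20
#: Hydropathy-conservation width of accepted point substitutions.
_SUBST_TAU = 0.15

# true-RSA means: buried positions, and exposed positions per class
_RSA_BURIED = 0.15
_RSA_EXPOSED = {"H": 0.60, "E": 0.50, "C": 0.65}
_RSA_HYDRO_SPAN = 0.10  # weak residual residue-hydropathy effect
_RSA_NOISE = 0.08
_RD_NOISE = 0.06
_COIL_EXPOSED_P = 0.75


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic homolog family."""

    seed: int
    length: int = 80
    n_homologs: int = 50
    mutation_rate: float = 0.30
    pseudocount: float = 1.0
    fold: str = "globular"

    def __post_init__(self) -> None:
        if self.length < 10:
            raise ValueError("length must be at least 10")
        if self.fold not in _FOLDS:
            raise ValueError(f"unknown fold {self.fold!r}")
        if self.n_homologs < 2:
            raise ValueError("need at least 2 homologs")
        if not 0.0 <= self.mutation_rate <= 0.9:
            raise ValueError("mutation_rate must be in [0, 0.9]")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")


def _emission_tables() -> dict[tuple[str, bool], np.ndarray]:
    """P(residue | SS class, buried?) — class preference times a Gaussian
    pull toward the exposure state's target hydropathy."""
    tables = {}
    for cls, favored in _CLASS_FAVORED.items():
        w_cls = np.ones(20)
        for aa in favored:
            w_cls[ALPHABET.index(aa)] = _BOOST
        for buried in (True, False):
            pull = np.exp(-((_HYDRO_VEC - _HYDRO_TARGET[buried]) ** 2)
                          / (2.0 * _HYDRO_SIGMA ** 2))
            w = w_cls * pull
            tables[(cls, buried)] = w / w.sum()
    return tables


_EMISSIONS = _emission_tables()


def _substitution_tables() -> dict[tuple[str, bool], np.ndarray]:
    """20x20 substitution distributions per (class, exposure): the emission
    prior times a hydropathy-conservation kernel around the original
    residue.  This is what keeps burial patterns — hence RSA and RD —
    conserved across a family while the sequence diverges."""
    kernel = np.exp(-((_HYDRO_VEC[:, None] - _HYDRO_VEC[None, :]) ** 2)
                    / (2.0 * _SUBST_TAU ** 2))
    tables = {}
    for key, emission in _EMISSIONS.items():
        w = emission[None, :] * kernel
        tables[key] = w / w.sum(axis=1, keepdims=True)
    return tables


_SUBSTITUTIONS = _substitution_tables()


@dataclass(frozen=True)
class _Structure:
    """What homologs share: the SS string and the exposure field."""

    ss: str
    buried: tuple[bool, ...]

    def __len__(self) -> int:
        return len(self.ss)


def _sample_structure(rng: np.random.Generator, length: int,
                      fold: str = "globular") -> _Structure:
    spec = _FOLDS[fold]
    ss_parts: list[str] = []
    buried: list[bool] = []
    prev = None
    while len(buried) < length:
        choices = [c for c in SS_CLASSES if c != prev]
        weights = np.array([spec["class_weight"][c] for c in choices])
        cls = choices[rng.choice(len(choices), p=weights / weights.sum())]
        seg = int(1 + rng.geometric(1.0 / spec["segment_mean"][cls]))
        if cls == "E":
            if spec["strand_alternation"]:
                # membrane strand: strict in/out alternation, random phase
                phase = int(rng.integers(2))
                pattern = [(k + phase) % 2 == 0 for k in range(seg)]
            else:
                # sheet-core strand: mostly buried, no alternation
                pattern = [rng.random() < _GLOBULAR_STRAND_BURIED_P
                           for _ in range(seg)]
        elif cls == "H":
            # amphipathic helical wheel with a random phase
            phase = float(rng.uniform(0.0, 360.0))
            pattern = [((k * 100.0 + phase) % 360.0) < 180.0
                       for k in range(seg)]
        else:
            pattern = [rng.random() > _COIL_EXPOSED_P for _ in range(seg)]
        ss_parts.append(cls * seg)
        buried.extend(pattern)
        prev = cls
    return _Structure(ss="".join(ss_parts)[:length],
                      buried=tuple(buried[:length]))


def _sample_sequence(rng: np.random.Generator, structure: _Structure) -> str:
    return "".join(
        ALPHABET[rng.choice(20, p=_EMISSIONS[(cls, b)])]
        for cls, b in zip(structure.ss, structure.buried)
    )


def _mutate(rng: np.random.Generator, seq: str, structure: _Structure,
            rate: float) -> str:
    out = list(seq)
    for i, (cls, b) in enumerate(zip(structure.ss, structure.buried)):
        if rng.random() < rate:
            row = _SUBSTITUTIONS[(cls, b)][ALPHABET.index(out[i])]
            out[i] = ALPHABET[rng.choice(20, p=row)]
    return "".join(out)


def _percent_rows(freqs: np.ndarray) -> np.ndarray:
    """Integer percentages per row summing exactly to 100 (largest
    remainder), so profiles round-trip exactly through the ASCII writer."""
    pct = np.zeros_like(freqs, dtype=int)
    for i, row in enumerate(freqs):
        scaled = row * 100.0
        base = np.floor(scaled).astype(int)
        short = 100 - base.sum()
        order = np.argsort(-(scaled - base), kind="stable")
        base[order[:short]] += 1
        pct[i] = base
    return pct


def _profile_from_homologs(homologs: list[str], ancestor: str,
                           pseudocount: float) -> SequenceProfile:
    L = len(ancestor)
    counts = np.zeros((L, 20))
    for seq in homologs:
        for i, aa in enumerate(seq):
            counts[i, ALPHABET.index(aa)] += 1
    smoothed = counts + pseudocount
    freqs = smoothed / smoothed.sum(axis=1, keepdims=True)
    pssm = np.round(LOG_ODDS_SCALE * np.log2(freqs / BACKGROUND))
    pct = _percent_rows(freqs)
    return SequenceProfile(sequence=ancestor, pssm=pssm, psfm=pct / 100.0)


def _sample_labels(rng: np.random.Generator, seq: str,
                   structure: _Structure) -> StructuralFeatures:
    L = len(seq)
    hydro = np.array([_HYDRO[aa] for aa in seq])
    base = np.array([
        _RSA_BURIED if b else _RSA_EXPOSED[cls]
        for cls, b in zip(structure.ss, structure.buried)
    ])
    rsa = base - _RSA_HYDRO_SPAN * (hydro - 0.5) \
        + rng.normal(0.0, _RSA_NOISE, L)
    rsa = np.clip(rsa, 0.0, 1.0)
    rd = np.clip(0.85 - 0.75 * rsa + rng.normal(0.0, _RD_NOISE, L),
                 0.0, 1.0)
    phi_deg = np.empty(L)
    for i, cls in enumerate(structure.ss):
        if cls == "H":
            phi_deg[i] = rng.normal(-60.0, 12.0)
        elif cls == "E":
            phi_deg[i] = rng.normal(-120.0, 20.0)
        elif rng.random() < 0.2:  # coil: glycine-like positive Phi minority
            phi_deg[i] = rng.normal(60.0, 25.0)
        else:
            phi_deg[i] = rng.normal(-75.0, 50.0)
    phi_deg = (phi_deg + 180.0) % 360.0 - 180.0
    phi_norm = np.array([normalize_phi(p) for p in phi_deg])
    return StructuralFeatures(ss3=structure.ss,
                              ss_probs=ss_one_hot(structure.ss), rsa=rsa,
                              rd=rd, phi_norm=phi_norm)


def _build_family(rng: np.random.Generator, spec: FamilySpec,
                  structure: _Structure, ancestor: str
                  ) -> tuple[SequenceProfile, StructuralFeatures]:
    homologs = [ancestor] + [
        _mutate(rng, ancestor, structure, spec.mutation_rate)
        for _ in range(spec.n_homologs - 1)
    ]
    profile = _profile_from_homologs(homologs, ancestor, spec.pseudocount)
    truth = _sample_labels(rng, ancestor, structure)
    return profile, truth


def generate_family(spec: FamilySpec
                    ) -> tuple[SequenceProfile, StructuralFeatures]:
    """Generate one homolog family: its profile and its true labels."""
    rng = np.random.default_rng(spec.seed)
    structure = _sample_structure(rng, spec.length, spec.fold)
    ancestor = _sample_sequence(rng, structure)
    return _build_family(rng, spec, structure, ancestor)


def generate_families(seed: int, n_families: int, fold: str | None = None,
                      **spec_kwargs
                      ) -> list[tuple[SequenceProfile, StructuralFeatures]]:
    """A list of independent families from one master seed.

    ``fold=None`` alternates barrel and globular families so a training
    set covers both structural regimes.
    """
    children = np.random.SeedSequence(seed).spawn(n_families)
    folds = (
        [fold] * n_families if fold is not None
        else ["barrel" if k % 2 else "globular" for k in range(n_families)]
    )
    return [
        generate_family(
            FamilySpec(seed=int(c.generate_state(1)[0] % (2 ** 31)),
                       fold=f, **spec_kwargs)
        )
        for c, f in zip(children, folds)
    ]


def entry_from_truth(entry_id: str, profile: SequenceProfile,
                     truth: StructuralFeatures) -> AlignedEntry:
    """Wrap ground-truth labels as an alignable entry (reliability 1)."""
    return AlignedEntry(id=entry_id, profile=profile, features=truth,
                        ss_ri=np.ones(len(profile)))


def generate_benchmark(seed: int, n_omp_families: int, n_decoys: int,
                       query_divergence: float = 0.60, **spec_kwargs):
    """Build a labeled OMP-identification benchmark.

    Each reference (barrel-fold) family contributes a library entry and
    one positive query: a remote relative whose ancestor is the family
    ancestor mutated at ``query_divergence`` and profiled from its own
    homolog cloud.  The relative shares the family's structure (SS and
    exposure field) — the homology signal — while its sequence has
    diverged.  Decoys are independent globular-fold families, mirroring
    the real benchmark contrast of outer membrane proteins against
    soluble proteins.  Returns ``(library, positives, decoys)``, each
    item a tuple ``(id, SequenceProfile, StructuralFeatures)``.
    """
    if n_omp_families < 1 or n_decoys < 1:
        raise ValueError("need at least one family and one decoy")
    master = np.random.SeedSequence(seed)
    fam_seeds, decoy_seeds = master.spawn(2)
    library, positives, decoys = [], [], []
    for k, child in enumerate(fam_seeds.spawn(n_omp_families)):
        s_lib, s_query = (
            int(c.generate_state(1)[0] % (2 ** 31)) for c in child.spawn(2)
        )
        spec = FamilySpec(seed=s_lib, fold="barrel", **spec_kwargs)
        rng = np.random.default_rng(spec.seed)
        structure = _sample_structure(rng, spec.length, spec.fold)
        ancestor = _sample_sequence(rng, structure)
        lib_profile, lib_truth = _build_family(rng, spec, structure,
                                               ancestor)
        library.append((f"omp{k:03d}", lib_profile, lib_truth))
        # positive query: same structure, diverged sequence, own profile
        q_rng = np.random.default_rng(s_query)
        q_ancestor = _mutate(q_rng, ancestor, structure, query_divergence)
        q_profile, q_truth = _build_family(
            q_rng, replace(spec, seed=s_query), structure, q_ancestor
        )
        positives.append((f"query_omp{k:03d}", q_profile, q_truth))
    for k, child in enumerate(decoy_seeds.spawn(n_decoys)):
        # every other decoy is an all-β soluble protein, the hard negative
        spec = FamilySpec(
            seed=int(child.generate_state(1)[0] % (2 ** 31)),
            fold="beta" if k % 2 else "globular", **spec_kwargs
        )
        d_profile, d_truth = generate_family(spec)
        decoys.append((f"decoy{k:03d}", d_profile, d_truth))
    return library, positives, decoys


def write_labels_table(truth: StructuralFeatures, path,
                       sequence: str | None = None) -> None:
    """Write ground-truth labels as the standard features TSV."""
    from .struct_props import write_features_table

    write_features_table(truth, path, sequence=sequence)
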