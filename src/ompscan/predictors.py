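"""Per-residue encodings and the four structural-property predictors.

Each predictor reads a sequence profile, slides an odd-width window of
per-residue feature tracks over it (squashed PSSM, PSFM, conservation score,
and for secondary structure the amino-acid fitness table), and feeds the
concatenated window through one or two sigmoid networks:

========  ======  ===========  ====================================
property  window  networks     windowed tracks (+ extras)
========  ======  ===========  ====================================
SS        15      2 (stacked)  pssm_sig, psfm, cs, fitness
RD        17      2            pssm_sig, psfm, cs
Phi       17      1            pssm_sig, psfm, cs
RSA       21      2            pssm_sig, psfm, cs  (+ 3 SS probs,
                               target residue only, not windowed)
========  ======  ===========  ====================================

Window positions that fall off either chain terminus contribute zeroed
features plus a raised terminus bit (one extra unit per window position).
The second-stage network smooths the first stage's outputs over a window of
its own, Psipred-style for SS and as a scalar filter for RSA/RD.

Secondary-structure probabilities are ordered (C, E, H) throughout,
matching the output encoding H=(0,0,1), E=(0,1,0), C=(1,0,0); the
per-residue reliability index is the margin between the top two output
nodes, with 0.35 the default confidence cutoff.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .neuralnet import Network, NetworkSpec, init_network, train
from .profiles import ALPHABET, ProfileFeatures, SequenceProfile, compute_features
from .struct_props import SS_CLASSES, FitnessTable, StructuralFeatures, ss_one_hot

TRACK_WIDTHS = {
    "pssm_sig": 20,
    "psfm": 20,
    "cs": 1,
    "fitness": 3,
    "ss_probs": 3,
}

#: SS reliability-index cutoff above which a prediction is called confident.
SS_RI_CONFIDENT = 0.35

PROPERTIES = ("SS", "RSA", "RD", "Phi")


@dataclass(frozen=True)
class EncodingScheme:
    """How to turn per-residue tracks into one input vector per residue.

    ``tracks`` are windowed; ``static_tracks`` are appended once for the
    target residue only (used for the SS probabilities in RSA prediction).
    With the terminus bit on, the vector length is
    ``window * (sum of track widths + 1) + static widths``.
    """

    window: int
    tracks: tuple[str, ...]
    static_tracks: tuple[str, ...] = ()
    terminus_bit: bool = True

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and positive")
        for t in self.tracks + self.static_tracks:
            if t not in TRACK_WIDTHS:
                raise ValueError(f"unknown track {t!r}")

    @property
    def vector_length(self) -> int:
        per_pos = sum(TRACK_WIDTHS[t] for t in self.tracks)
        if self.terminus_bit:
            per_pos += 1
        return self.window * per_pos + sum(
            TRACK_WIDTHS[t] for t in self.static_tracks
        )


def encode_windows(tracks: dict[str, np.ndarray], scheme: EncodingScheme
                   ) -> np.ndarray:
    """Encode every residue of a chain, returning an (L, D) matrix.

    Off-chain window positions get zero features and terminus bit 1.
    """
    lengths = set()
    arrays = []
    for name in scheme.tracks:
        a = np.asarray(tracks[name], dtype=float)
        if a.ndim == 1:
            a = a[:, None]
        if a.shape[1] != TRACK_WIDTHS[name]:
            raise ValueError(f"track {name!r} has width {a.shape[1]}")
        arrays.append(a)
        lengths.add(a.shape[0])
    if len(lengths) != 1:
        raise ValueError("all tracks must share the chain length")
    L = lengths.pop()
    per_res = np.hstack(arrays) if arrays else np.zeros((L, 0))
    if scheme.terminus_bit:
        per_res = np.hstack([per_res, np.zeros((L, 1))])
    width = per_res.shape[1]
    half = scheme.window // 2
    # pad with the off-terminus unit: zero features, terminus bit 1
    pad = np.zeros((half, width))
    if scheme.terminus_bit:
        pad[:, -1] = 1.0
    stacked = np.vstack([pad, per_res, pad])
    windows = np.empty((L, scheme.window * width))
    for i in range(L):
        windows[i] = stacked[i:i + scheme.window].ravel()
    if scheme.static_tracks:
        extras = []
        for name in scheme.static_tracks:
            a = np.asarray(tracks[name], dtype=float)
            if a.ndim == 1:
                a = a[:, None]
            if a.shape != (L, TRACK_WIDTHS[name]):
                raise ValueError(f"static track {name!r} has bad shape")
            extras.append(a)
        windows = np.hstack([windows] + extras)
    return windows


def profile_tracks(profile: SequenceProfile,
                   features: ProfileFeatures | None = None,
                   fitness: FitnessTable | None = None
                   ) -> dict[str, np.ndarray]:
    """Assemble the standard windowable tracks for a profile."""
    if features is None:
        features = compute_features(profile)
    tracks = {
        "pssm_sig": features.pssm_sig,
        "psfm": profile.psfm,
        "cs": features.cs[:, None],
    }
    if fitness is not None:
        rows = np.empty((len(profile), 3))
        for i, aa in enumerate(profile.sequence):
            if aa in ALPHABET:
                rows[i] = fitness.ft[ALPHABET.index(aa)]
            else:
                rows[i] = 1.0 / 3.0  # nonstandard residue: uninformative
        tracks["fitness"] = rows
    return tracks


def ss_reliability(out: np.ndarray) -> float:
    """Reliability index: highest output node minus the second highest."""
    v = np.sort(np.asarray(out, dtype=float))
    return float(v[-1] - v[-2])


@dataclass
class PropertyPredictor:
    """One trained property head: encoding scheme plus its network stack."""

    property: str  # one of PROPERTIES
    scheme: EncodingScheme
    stage1: Network
    stage2: Network | None = None
    stage2_window: int = 0

    def __post_init__(self) -> None:
        if self.property not in PROPERTIES:
            raise ValueError(f"unknown property {self.property!r}")
        want = 3 if self.property == "SS" else 1
        if self.stage1.n_outputs != want:
            raise ValueError("stage-1 output width inconsistent")


def _stage2_scheme(width: int, window: int) -> EncodingScheme:
    name = "ss_probs" if width == 3 else "cs"
    return EncodingScheme(window=window, tracks=(name,))


def predict_ss(profile: SequenceProfile, predictor: PropertyPredictor,
               fitness: FitnessTable,
               features: ProfileFeatures | None = None
               ) -> tuple[np.ndarray, str, np.ndarray]:
    """Two-stage secondary-structure prediction.

    Returns ``(ss_probs, ss3, ss_ri)``: renormalized (L, 3) class
    probabilities in (C, E, H) order, the argmax label string (first-index
    ties resolve C > E > H), and the per-residue reliability index computed
    from the raw second-stage outputs.
    """
    if predictor.property != "SS":
        raise ValueError("predictor is not a secondary-structure predictor")
    if predictor.stage2 is None:
        raise ValueError("SS prediction requires both network stages")
    tracks = profile_tracks(profile, features, fitness)
    X1 = encode_windows(tracks, predictor.scheme)
    raw1 = predictor.stage1.forward_batch(X1)
    X2 = encode_windows(
        {"ss_probs": raw1},
        _stage2_scheme(3, predictor.stage2_window),
    )
    raw2 = predictor.stage2.forward_batch(X2)
    ss_ri = np.array([ss_reliability(row) for row in raw2])
    ss_probs = raw2 / raw2.sum(axis=1, keepdims=True)
    ss3 = "".join(SS_CLASSES[k] for k in np.argmax(ss_probs, axis=1))
    return ss_probs, ss3, ss_ri


def predict_scalar(profile: SequenceProfile, predictor: PropertyPredictor,
                   ss_probs: np.ndarray | None = None,
                   features: ProfileFeatures | None = None,
                   fitness: FitnessTable | None = None) -> np.ndarray:
    """Predict RSA, RD or Phi for every residue, clipped to [0, 1].

    RSA predictors consume the three SS probabilities of the target residue
    (not windowed) and require ``ss_probs``.
    """
    if predictor.property not in ("RSA", "RD", "Phi"):
        raise ValueError("use predict_ss for secondary structure")
    tracks = profile_tracks(profile, features, fitness)
    if "ss_probs" in predictor.scheme.static_tracks:
        if ss_probs is None:
            raise ValueError(
                f"{predictor.property} prediction requires ss_probs"
            )
        tracks["ss_probs"] = np.asarray(ss_probs, dtype=float)
    X1 = encode_windows(tracks, predictor.scheme)
    out = predictor.stage1.forward_batch(X1)[:, 0]
    if predictor.stage2 is not None:
        X2 = encode_windows(
            {"cs": out[:, None]},
            _stage2_scheme(1, predictor.stage2_window),
        )
        out = predictor.stage2.forward_batch(X2)[:, 0]
    return np.clip(out, 0.0, 1.0)


# ----------------------------------------------------------------------
# Training
# ----------------------------------------------------------------------

#: Windowed tracks per property (the SS probabilities consumed by RSA are
#: appended statically, see DEFAULT_SCHEMES).
_PROPERTY_TRACKS = {
    "SS": ("pssm_sig", "psfm", "cs", "fitness"),
    "RD": ("pssm_sig", "psfm", "cs"),
    "Phi": ("pssm_sig", "psfm", "cs"),
    "RSA": ("pssm_sig", "psfm", "cs"),
}

DEFAULT_SCHEMES = {
    "SS": EncodingScheme(window=15, tracks=_PROPERTY_TRACKS["SS"]),
    "RD": EncodingScheme(window=17, tracks=_PROPERTY_TRACKS["RD"]),
    "Phi": EncodingScheme(window=17, tracks=_PROPERTY_TRACKS["Phi"]),
    "RSA": EncodingScheme(window=21, tracks=_PROPERTY_TRACKS["RSA"],
                          static_tracks=("ss_probs",)),
}

#: Which properties carry a second, refining network.
_HAS_STAGE2 = {"SS": True, "RD": True, "RSA": True, "Phi": False}


@dataclass
class TrainingConfig:
    """Desk-scale training budget for one predictor bundle.

    Hidden-layer widths and the stage-2 windows are free architecture
    choices (only the layer counts are fixed: two hidden layers for the
    first SS network, one elsewhere).  The learning rate here is larger
    than the production default of the network module because desk-scale
    training sets are orders of magnitude smaller.
    """

    seed: int = 0
    hidden: dict = field(default_factory=lambda: {
        "SS": (30, 15), "RD": (20,), "Phi": (20,), "RSA": (20,),
    })
    stage2_hidden: dict = field(default_factory=lambda: {
        "SS": (15,), "RD": (10,), "RSA": (10,),
    })
    stage2_window: dict = field(default_factory=lambda: {
        "SS": 15, "RD": 17, "RSA": 21,
    })
    epochs_stage1: int = 40
    epochs_stage2: int = 30
    learning_rate: float = 0.02
    momentum: float = 0.85


def _train_net(X: np.ndarray, Y: np.ndarray, hidden: tuple[int, ...],
               epochs: int, seed: int, lr: float, mom: float) -> Network:
    spec = NetworkSpec(
        layer_sizes=(X.shape[1], *hidden, Y.shape[1]), seed=seed,
        learning_rate=lr, momentum=mom,
    )
    net = init_network(spec)
    return train(net, X, Y, epochs=epochs, shuffle_seed=seed + 1)


def train_property_predictor(
    families: list[tuple[SequenceProfile, StructuralFeatures]],
    prop: str,
    fitness: FitnessTable,
    config: TrainingConfig,
    ss_predictor: PropertyPredictor | None = None,
) -> PropertyPredictor:
    """Train one property head on (profile, true features) pairs.

    For RSA the static SS-probability track is taken from ``ss_predictor``
    when given (the deployment condition) and from the true one-hot labels
    otherwise.
    """
    scheme = DEFAULT_SCHEMES[prop]
    X_parts, Y_parts, per_family = [], [], []
    for profile, truth in families:
        tracks = profile_tracks(profile, fitness=fitness)
        if prop == "RSA":
            if ss_predictor is not None:
                probs, _, _ = predict_ss(profile, ss_predictor, fitness)
            else:
                probs = ss_one_hot(truth.ss3)
            tracks["ss_probs"] = probs
        X = encode_windows(tracks, scheme)
        if prop == "SS":
            Y = ss_one_hot(truth.ss3)
        else:
            track = {"RSA": truth.rsa, "RD": truth.rd,
                     "Phi": truth.phi_norm}[prop]
            Y = np.asarray(track, dtype=float)[:, None]
        X_parts.append(X)
        Y_parts.append(Y)
        per_family.append(len(profile))
    X_all = np.vstack(X_parts)
    Y_all = np.vstack(Y_parts)
    seed = config.seed * 101 + PROPERTIES.index(prop)
    stage1 = _train_net(
        X_all, Y_all, config.hidden[prop], config.epochs_stage1, seed,
        config.learning_rate, config.momentum,
    )
    stage2 = None
    s2_window = 0
    if _HAS_STAGE2[prop]:
        s2_window = config.stage2_window[prop]
        width = 3 if prop == "SS" else 1
        s2_scheme = _stage2_scheme(width, s2_window)
        name = "ss_probs" if width == 3 else "cs"
        X2_parts = []
        start = 0
        for n in per_family:
            raw = stage1.forward_batch(X_all[start:start + n])
            X2_parts.append(encode_windows({name: raw}, s2_scheme))
            start += n
        stage2 = _train_net(
            np.vstack(X2_parts), Y_all, config.stage2_hidden[prop],
            config.epochs_stage2, seed + 7, config.learning_rate,
            config.momentum,
        )
    return PropertyPredictor(property=prop, scheme=scheme, stage1=stage1,
                             stage2=stage2, stage2_window=s2_window)


# ----------------------------------------------------------------------
# Bundles: the full four-property model
# ----------------------------------------------------------------------

@dataclass
class PredictorBundle:
    """All four trained predictors plus the fitness table they share."""

    fitness: FitnessTable
    predictors: dict[str, PropertyPredictor]

    def predict_all(self, profile: SequenceProfile
                    ) -> tuple[StructuralFeatures, np.ndarray]:
        """Predict every structural feature; returns (features, ss_ri)."""
        features = compute_features(profile)
        ss_probs, ss3, ss_ri = predict_ss(
            profile, self.predictors["SS"], self.fitness, features
        )
        rsa = predict_scalar(profile, self.predictors["RSA"],
                             ss_probs=ss_probs, features=features)
        rd = predict_scalar(profile, self.predictors["RD"],
                            features=features)
        phi = predict_scalar(profile, self.predictors["Phi"],
                             features=features)
        return StructuralFeatures(ss3=ss3, ss_probs=ss_probs, rsa=rsa,
                                  rd=rd, phi_norm=phi), ss_ri


def train_bundle(families: list[tuple[SequenceProfile, StructuralFeatures]],
                 config: TrainingConfig | None = None) -> PredictorBundle:
    """Train the whole four-property bundle on labeled families.

    The SS head is trained first; its predictions supply the SS-probability
    inputs for RSA training, matching how the bundle is later applied.
    """
    from .struct_props import compute_fitness

    if config is None:
        config = TrainingConfig()
    fitness = compute_fitness(
        [(p.sequence, t.ss3) for p, t in families]
    )
    ss = train_property_predictor(families, "SS", fitness, config)
    predictors = {"SS": ss}
    for prop in ("RSA", "RD", "Phi"):
        predictors[prop] = train_property_predictor(
            families, prop, fitness, config, ss_predictor=ss,
        )
    return PredictorBundle(fitness=fitness, predictors=predictors)


def save_bundle(bundle: PredictorBundle, directory) -> None:
    """Serialize a bundle to a directory of JSON and TSV files."""
    from .struct_props import write_fitness_table

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_fitness_table(bundle.fitness, directory / "fitness.tsv")
    manifest = {}
    for prop, pred in bundle.predictors.items():
        entry = {
            "scheme": {
                "window": pred.scheme.window,
                "tracks": list(pred.scheme.tracks),
                "static_tracks": list(pred.scheme.static_tracks),
                "terminus_bit": pred.scheme.terminus_bit,
            },
            "stage2_window": pred.stage2_window,
            "stage1": f"{prop}_stage1.json",
            "stage2": f"{prop}_stage2.json" if pred.stage2 else None,
        }
        (directory / entry["stage1"]).write_text(pred.stage1.to_json())
        if pred.stage2 is not None:
            (directory / entry["stage2"]).write_text(pred.stage2.to_json())
        manifest[prop] = entry
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_bundle(directory) -> PredictorBundle:
    import csv

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    ft = np.zeros((20, 3))
    counts = np.zeros(20)
    with open(directory / "fitness.tsv") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            i = ALPHABET.index(row["residue"])
            ft[i] = [float(row["p_C"]), float(row["p_E"]), float(row["p_H"])]
            counts[i] = float(row["count"])
    fitness = FitnessTable(ft=ft, residue_counts=counts,
                           class_counts=ft * counts[:, None])
    predictors = {}
    for prop, entry in manifest.items():
        scheme = EncodingScheme(
            window=entry["scheme"]["window"],
            tracks=tuple(entry["scheme"]["tracks"]),
            static_tracks=tuple(entry["scheme"]["static_tracks"]),
            terminus_bit=entry["scheme"]["terminus_bit"],
        )
        stage1 = Network.from_json(
            (directory / entry["stage1"]).read_text()
        )
        stage2 = None
        if entry["stage2"]:
            stage2 = Network.from_json(
                (directory / entry["stage2"]).read_text()
            )
        predictors[prop] = PropertyPredictor(
            property=prop, scheme=scheme, stage1=stage1, stage2=stage2,
            stage2_window=entry["stage2_window"],
        )
    return PredictorBundle(fitness=fitness, predictors=predictors)


def write_prediction_table(profile: SequenceProfile,
                           features: StructuralFeatures,
                           ss_ri: np.ndarray, path,
                           header_lines: list[str] | None = None) -> None:
    """Write the per-residue prediction product as a TSV."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write(
            "position\tresidue\tss3\tp_C\tp_E\tp_H\tss_ri\trsa\trd\t"
            "phi_norm\n"
        )
        for i, aa in enumerate(profile.sequence):
            p = features.ss_probs[i]
            fh.write(
                f"{i + 1}\t{aa}\t{features.ss3[i]}\t{p[0]:.4f}\t{p[1]:.4f}\t"
                f"{p[2]:.4f}\t{ss_ri[i]:.4f}\t{features.rsa[i]:.4f}\t"
                f"{features.rd[i]:.4f}\t{features.phi_norm[i]:.4f}\n"
            )
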