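import numpy as np
import pytest

from ompscan.neuralnet import Network, NetworkSpec, init_network, train
from ompscan.predictors import (
    DEFAULT_SCHEMES,
    EncodingScheme,
    PredictorBundle,
    PropertyPredictor,
    encode_windows,
    load_bundle,
    predict_scalar,
    predict_ss,
    save_bundle,
    ss_reliability,
)
from ompscan.profiles import ALPHABET
from ompscan.struct_props import SS_CLASSES
from ompscan.synthetic import FamilySpec, generate_family


def test_encoding_vector_lengths_follow_the_track_arithmetic():
    # SS: window 15 x (20 + 20 + 1 + 3 tracks + terminus) = 15 x 45 = 675
    assert DEFAULT_SCHEMES["SS"].vector_length == 675
    # RD: window 17 x (20 + 20 + 1 + terminus) = 17 x 42 = 714
    assert DEFAULT_SCHEMES["RD"].vector_length == 714
    # RSA: window 21 x 42 + 3 static SS probabilities = 885
    assert DEFAULT_SCHEMES["RSA"].vector_length == 885


def test_even_window_is_rejected():
    with pytest.raises(ValueError):
        EncodingScheme(window=4, tracks=("cs",))


def test_terminus_positions_are_zeroed_with_raised_bit():
    L, window = 40, 15
    tracks = {"cs": np.arange(1, L + 1, dtype=float)[:, None]}
    scheme = EncodingScheme(window=window, tracks=("cs",))
    enc = encode_windows(tracks, scheme)
    assert enc.shape == (L, window * 2)
    first = enc[0].reshape(window, 2)
    # residue 1: seven left-flank positions off the N terminus
    assert np.all(first[:7, 0] == 0.0)
    assert np.all(first[:7, 1] == 1.0)
    # center holds the residue's own feature with the bit down
    assert first[7, 0] == 1.0 and first[7, 1] == 0.0
    # interior residue (window fully on-chain) has no raised bits
    mid = enc[20].reshape(window, 2)
    assert np.all(mid[:, 1] == 0.0)
    assert np.allclose(mid[:, 0], np.arange(14, 29))


def test_window_one_is_the_bare_feature_vector():
    tracks = {"cs": np.array([0.2, 0.7, 0.4])[:, None]}
    enc = encode_windows(tracks, EncodingScheme(window=1, tracks=("cs",)))
    assert np.allclose(enc, [[0.2, 0.0], [0.7, 0.0], [0.4, 0.0]])


def test_ss_reliability_margin():
    assert ss_reliability(np.array([0.9, 0.05, 0.05])) == pytest.approx(0.85)
    assert ss_reliability(np.array([0.4, 0.4, 0.4])) == 0.0


def _toy_ss_predictor(window=3, s2_window=3):
    scheme = EncodingScheme(window=window,
                            tracks=("pssm_sig", "psfm", "cs", "fitness"))
    stage1 = init_network(NetworkSpec(
        layer_sizes=(scheme.vector_length, 4, 3), seed=0))
    stage2 = init_network(NetworkSpec(layer_sizes=(s2_window * 4, 4, 3),
                                      seed=1))
    return PropertyPredictor(property="SS", scheme=scheme, stage1=stage1,
                             stage2=stage2, stage2_window=s2_window)


def test_ss_label_order_and_argmax_convention():
    """Probabilities are (C, E, H): index 2 carries helix, matching the
    output encoding H=(0,0,1); ties resolve toward C."""
    assert SS_CLASSES[int(np.argmax([0.1, 0.2, 0.7]))] == "H"
    assert SS_CLASSES[int(np.argmax([0.3, 0.3, 0.3]))] == "C"
    assert SS_CLASSES[int(np.argmax([0.1, 0.4, 0.4]))] == "E"


def test_predict_ss_requires_both_stages_and_normalizes_rows():
    profile, _ = generate_family(FamilySpec(seed=8, length=20))
    pred = _toy_ss_predictor()
    from ompscan.struct_props import compute_fitness
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fitness = compute_fitness([(profile.sequence, "C" * 20)])
    probs, ss3, ss_ri = predict_ss(profile, pred, fitness)
    assert probs.shape == (20, 3)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
    assert len(ss3) == 20 and set(ss3) <= set("HEC")
    assert np.all((ss_ri >= 0) & (ss_ri < 1))
    pred_no2 = PropertyPredictor(property="SS", scheme=pred.scheme,
                                 stage1=pred.stage1, stage2=None,
                                 stage2_window=0)
    with pytest.raises(ValueError):
        predict_ss(profile, pred_no2, fitness)


def test_rsa_prediction_requires_ss_probabilities():
    profile, _ = generate_family(FamilySpec(seed=9, length=20))
    scheme = DEFAULT_SCHEMES["RSA"]
    stage1 = init_network(NetworkSpec(
        layer_sizes=(scheme.vector_length, 3, 1), seed=0))
    pred = PropertyPredictor(property="RSA", scheme=scheme, stage1=stage1)
    with pytest.raises(ValueError):
        predict_scalar(profile, pred)
    out = predict_scalar(profile, pred,
                         ss_probs=np.full((20, 3), 1.0 / 3.0))
    assert out.shape == (20,)
    assert np.all((out >= 0) & (out <= 1))


def test_scalar_predictor_recovers_a_profile_determined_property():
    """When the target is an exact function of one profile column, a
    trained single-stage predictor reaches MAE < 0.05 on held-out
    residues from the same generator."""
    rng = np.random.default_rng(0)
    scheme = EncodingScheme(window=1, tracks=("pssm_sig",))

    def make_set(n_rows, seed):
        r = np.random.default_rng(seed)
        pssm = r.integers(-6, 7, (n_rows, 20)).astype(float)
        target = 1.0 / (1.0 + np.exp(-pssm[:, 0]))
        X = encode_windows({"pssm_sig": 1 / (1 + np.exp(-pssm))}, scheme)
        return X, target[:, None]

    X, Y = make_set(400, 1)
    Xh, Yh = make_set(100, 2)
    net = init_network(NetworkSpec(layer_sizes=(X.shape[1], 8, 1), seed=3,
                                   learning_rate=0.2, momentum=0.85))
    train(net, X, Y, epochs=60)
    mae = float(np.mean(np.abs(net.forward_batch(Xh) - Yh)))
    assert mae < 0.05


def test_bundle_save_load_round_trip_preserves_predictions(
        tmp_path, trained_bundle):
    profile, _ = generate_family(FamilySpec(seed=33, length=40))
    feats_a, ri_a = trained_bundle.predict_all(profile)
    save_bundle(trained_bundle, tmp_path / "bundle")
    restored = load_bundle(tmp_path / "bundle")
    feats_b, ri_b = restored.predict_all(profile)
    assert feats_a.ss3 == feats_b.ss3
    assert np.allclose(feats_a.ss_probs, feats_b.ss_probs, atol=1e-12)
    assert np.allclose(feats_a.rsa, feats_b.rsa, atol=1e-12)
    assert np.allclose(feats_a.rd, feats_b.rd, atol=1e-12)
    assert np.allclose(feats_a.phi_norm, feats_b.phi_norm, atol=1e-12)
    assert np.allclose(ri_a, ri_b, atol=1e-12)


def test_prediction_is_deterministic(trained_bundle):
    profile, _ = generate_family(FamilySpec(seed=34, length=30))
    a, ri1 = trained_bundle.predict_all(profile)
    b, ri2 = trained_bundle.predict_all(profile)
    assert a.ss3 == b.ss3
    assert np.array_equal(a.rsa, b.rsa)
    assert np.array_equal(ri1, ri2)
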