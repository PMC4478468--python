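import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import entropy_loop, sigmoid_loop
from ompscan.profiles import (
    ALPHABET,
    MAX_ENTROPY,
    ProfileParseError,
    SequenceProfile,
    column_entropy,
    compute_features,
    conservation_score,
    parse_psiblast_profile,
    sigmoid_normalize,
    write_psiblast_profile,
)


def make_profile_file(path, rows):
    """Write a minimal PSI-BLAST-dialect file from (aa, scores, pcts)."""
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        fh.write("      " + " ".join(ALPHABET) + "  "
                 + " ".join(ALPHABET) + "\n")
        for k, (aa, scores, pcts) in enumerate(rows, start=1):
            fh.write(
                f"{k:5d} {aa} " + " ".join(str(s) for s in scores) + " "
                + " ".join(str(p) for p in pcts) + " 0.45 0.12\n"
            )
        fh.write("\n                      K         Lambda\n")


def test_parse_known_three_residue_fixture(tmp_path):
    """Hand-written rows parse into the exact matrices, with percentages
    divided by 100 and rows renormalized."""
    path = tmp_path / "tiny.profile"
    scores0 = list(range(-10, 10))
    pct0 = [5] * 20
    pct1 = [100] + [0] * 19
    pct2 = [50, 50] + [0] * 18
    make_profile_file(path, [
        ("A", scores0, pct0), ("R", [0] * 20, pct1), ("X", [1] * 20, pct2),
    ])
    prof = parse_psiblast_profile(path)
    assert prof.sequence == "ARX"
    assert prof.pssm.shape == (3, 20) and prof.psfm.shape == (3, 20)
    assert np.array_equal(prof.pssm[0], np.array(scores0, dtype=float))
    assert np.allclose(prof.psfm[0], 0.05)
    assert prof.psfm[1, 0] == 1.0 and prof.psfm[1, 1:].sum() == 0.0
    assert np.allclose(prof.psfm[2, :2], 0.5)


def test_all_zero_frequency_row_becomes_uniform(tmp_path):
    path = tmp_path / "zero.profile"
    make_profile_file(path, [("A", [0] * 20, [0] * 20),
                             ("G", [0] * 20, [100] + [0] * 19)])
    prof = parse_psiblast_profile(path)
    assert np.allclose(prof.psfm[0], 0.05)


@pytest.mark.parametrize("mutation", [
    "truncate_row", "non_numeric", "empty"
])
def test_malformed_files_raise_parse_errors(tmp_path, mutation):
    path = tmp_path / "bad.profile"
    if mutation == "empty":
        path.write_text("\nno data rows here\n")
    else:
        rows = [("A", [0] * 20, [100] + [0] * 19)]
        make_profile_file(path, rows)
        lines = path.read_text().splitlines()
        idx = next(i for i, ln in enumerate(lines)
                   if ln.strip().startswith("1 "))
        if mutation == "truncate_row":
            lines[idx] = " ".join(lines[idx].split()[:39])
        else:
            parts = lines[idx].split()
            parts[10] = "oops"
            lines[idx] = " ".join(parts)
        path.write_text("\n".join(lines) + "\n")
    with pytest.raises(ProfileParseError):
        parse_psiblast_profile(path)


def test_write_parse_round_trip_is_stable(tmp_path):
    rng = np.random.default_rng(3)
    pct = np.zeros((5, 20), dtype=int)
    pct[:, :4] = 25  # exact-percent rows round-trip bit-identically
    prof = SequenceProfile(
        sequence="ACDEF",
        pssm=rng.integers(-8, 9, (5, 20)).astype(float),
        psfm=pct / 100.0,
    )
    p1 = tmp_path / "a.profile"
    p2 = tmp_path / "b.profile"
    write_psiblast_profile(prof, p1)
    parsed = parse_psiblast_profile(p1)
    write_psiblast_profile(parsed, p2)
    assert p1.read_text() == p2.read_text()
    assert parsed.sequence == prof.sequence
    assert np.array_equal(parsed.pssm, prof.pssm)
    assert np.allclose(parsed.psfm, prof.psfm)


def test_sigmoid_normalize_values_and_monotonicity():
    out = sigmoid_normalize(np.array([[0.0, -7.0, 7.0]]))
    assert out[0, 0] == 0.5
    assert out[0, 1] == pytest.approx(1.0 / (1.0 + math.exp(7)), rel=1e-12)
    x = np.linspace(-12, 12, 100)[None, :]
    y = sigmoid_normalize(x)
    assert np.all(np.diff(y[0]) > 0)
    assert np.all((y > 0) & (y < 1))


def test_column_entropy_anchor_values():
    one_hot = np.zeros(20)
    one_hot[7] = 1.0
    assert column_entropy(one_hot) == 0.0
    assert column_entropy(np.full(20, 0.05)) == pytest.approx(2.996, abs=5e-4)
    two = np.zeros(20)
    two[:2] = 0.5
    assert column_entropy(two) == pytest.approx(math.log(2), rel=1e-12)
    with pytest.raises(ValueError):
        column_entropy(np.array([-0.1] + [0.0] * 18 + [1.1]))


def test_conservation_score_decreasing_from_one():
    assert conservation_score(0.0) == 1.0
    assert conservation_score(math.log(20)) == pytest.approx(0.05, rel=1e-12)
    assert conservation_score(math.log(2)) == pytest.approx(0.5, rel=1e-12)
    with pytest.raises(ValueError):
        conservation_score(MAX_ENTROPY + 1.0)
    with pytest.raises(ValueError):
        conservation_score(-0.5)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.integers(0, 2 ** 32 - 1))
def test_feature_tracks_match_scalar_oracles(seed):
    """Vectorized sigmoid and entropy agree with plain scalar loops, and
    all derived tracks stay in their declared ranges."""
    rng = np.random.default_rng(seed)
    L = int(rng.integers(1, 8))
    psfm = rng.dirichlet(np.ones(20), size=L)
    pssm = rng.integers(-10, 12, (L, 20)).astype(float)
    prof = SequenceProfile(
        sequence="".join(ALPHABET[k] for k in rng.integers(0, 20, L)),
        pssm=pssm, psfm=psfm,
    )
    feats = compute_features(prof)
    assert np.allclose(feats.pssm_sig, sigmoid_loop(pssm), atol=1e-12)
    expected = [entropy_loop(row) for row in psfm]
    assert np.allclose(feats.entropy, expected, atol=1e-12)
    assert np.all((feats.entropy >= 0) & (feats.entropy <= MAX_ENTROPY + 1e-9))
    assert np.all((feats.cs > 0) & (feats.cs <= 1))
    # conservation decreases with entropy
    order = np.argsort(feats.entropy)
    assert np.all(np.diff(feats.cs[order]) <= 1e-12)
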