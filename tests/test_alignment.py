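import numpy as np
import pytest

from _oracles import (
    oracle_global_score,
    oracle_local_score,
    random_entry,
)
from ompscan.alignment import (
    AlignmentParams,
    align,
    format_alignment,
    pair_score,
    profile_score,
    property_delta,
    score_matrix,
    ss_sim,
)
from ompscan.synthetic import FamilySpec, entry_from_truth, generate_family


@pytest.fixture(scope="module")
def entries():
    rng = np.random.default_rng(7)
    return random_entry(rng, 8, "q"), random_entry(rng, 9, "t")


def test_default_parameters_are_the_trained_values():
    p = AlignmentParams()
    assert (p.gap_open, p.gap_extend) == (-7.0, -0.54)
    assert (p.w1, p.w2, p.w3, p.w4, p.shift) == (0.65, 1.0, 1.0, 1.0, 0.76)
    control = p.control()
    assert (control.w2, control.w3, control.w4) == (0.0, 0.0, 0.0)
    assert control.w1 == 0.65 and control.shift == 0.76


def test_params_validation():
    with pytest.raises(ValueError):
        AlignmentParams(gap_open=-0.1, gap_extend=-0.5)
    with pytest.raises(ValueError):
        AlignmentParams(shift=-1.0)
    with pytest.raises(ValueError):
        AlignmentParams(mode="semiglobal")


def test_profile_score_symmetry_and_loop_oracle(entries):
    q, t = entries
    for i, j in [(0, 0), (3, 5), (7, 8)]:
        expected = 0.5 * (
            sum(q.profile.psfm[i, k] * t.profile.pssm[j, k]
                for k in range(20))
            + sum(t.profile.psfm[j, k] * q.profile.pssm[i, k]
                  for k in range(20))
        )
        assert profile_score(q, t, i, j) == pytest.approx(expected,
                                                          abs=1e-12)
        assert profile_score(q, t, i, j) == pytest.approx(
            profile_score(t, q, j, i), abs=1e-12
        )


def test_ss_sim_gating_and_reliability_mean(entries):
    q, t = entries
    same = [(i, j) for i in range(8) for j in range(9)
            if q.features.ss3[i] == t.features.ss3[j]]
    diff = [(i, j) for i in range(8) for j in range(9)
            if q.features.ss3[i] != t.features.ss3[j]]
    i, j = same[0]
    assert ss_sim(q, t, i, j) == pytest.approx(
        0.5 * (q.ss_ri[i] + t.ss_ri[j])
    )
    i, j = diff[0]
    assert ss_sim(q, t, i, j) == 0.0


def test_property_delta_weighted_absolute_differences(entries):
    q, t = entries
    params = AlignmentParams()
    i, j = 2, 4
    expected = (
        abs(q.features.rd[i] - t.features.rd[j])
        + abs(q.features.rsa[i] - t.features.rsa[j])
        + abs(q.features.phi_norm[i] - t.features.phi_norm[j])
    )
    assert property_delta(q, t, i, j, params) == pytest.approx(expected)
    assert property_delta(q, t, i, j, params) == pytest.approx(
        property_delta(t, q, j, i, params)
    )
    half = AlignmentParams(w2=0.5, w3=0.25, w4=2.0)
    assert property_delta(q, t, i, j, half) <= 0.5 + 0.25 + 2.0


def test_pair_score_reduces_to_minus_shift(entries):
    """Zero profile score, differing SS, identical properties: only the
    shift survives."""
    q, _ = entries
    import copy

    a = copy.deepcopy(q)
    b = copy.deepcopy(q)
    a.profile.pssm[:] = 0.0
    b.profile.pssm[:] = 0.0
    b.features.ss3 = ("E" if a.features.ss3[0] != "E" else "H") \
        + a.features.ss3[1:]
    b.features.rsa = a.features.rsa.copy()
    b.features.rd = a.features.rd.copy()
    b.features.phi_norm = a.features.phi_norm.copy()
    assert pair_score(a, b, 0, 0, AlignmentParams()) == pytest.approx(-0.76)


def test_score_matrix_matches_pair_score_loop(entries):
    q, t = entries
    params = AlignmentParams()
    S = score_matrix(q, t, params)
    for i in range(len(q)):
        for j in range(len(t)):
            assert S[i, j] == pytest.approx(
                pair_score(q, t, i, j, params), abs=1e-10
            )


def test_local_alignment_of_all_negative_scores_is_empty():
    rng = np.random.default_rng(11)
    q = random_entry(rng, 5, "q")
    t = random_entry(rng, 5, "t")
    # a huge shift makes every pair score negative
    params = AlignmentParams(shift=1e6)
    res = align(q, t, params)
    assert res.score == 0.0
    assert res.pairs == []


def test_global_self_alignment_pairs_every_position():
    profile, truth = generate_family(FamilySpec(seed=21, length=30))
    e = entry_from_truth("self", profile, truth)
    params = AlignmentParams(mode="global")
    res = align(e, e, params)
    S = score_matrix(e, e, params)
    assert res.pairs == [(i, i) for i in range(30)]
    assert res.score == pytest.approx(np.trace(S))


def test_score_symmetry_both_modes():
    rng = np.random.default_rng(13)
    for mode in ("local", "global"):
        params = AlignmentParams(mode=mode)
        for _ in range(10):
            q = random_entry(rng, int(rng.integers(2, 9)), "q")
            t = random_entry(rng, int(rng.integers(2, 9)), "t")
            assert align(q, t, params).score == pytest.approx(
                align(t, q, params).score, abs=1e-9
            )


def test_local_self_score_at_least_best_single_pair():
    rng = np.random.default_rng(17)
    q = random_entry(rng, 10, "q")
    res = align(q, q, AlignmentParams())
    S = score_matrix(q, q, AlignmentParams())
    if S.max() > 0:
        assert res.score >= S.max() - 1e-9


@pytest.mark.parametrize("mode", ["local", "global"])
def test_dp_equals_bruteforce_enumeration(mode):
    """The affine-gap DP score equals exhaustive path enumeration on the
    alignment lattice for random instances with lengths up to 6."""
    rng = np.random.default_rng(99 if mode == "local" else 100)
    params = AlignmentParams(mode=mode)
    for _ in range(60):
        n = int(rng.integers(1, 7))
        m = int(rng.integers(1, 7))
        q = random_entry(rng, n, "q")
        t = random_entry(rng, m, "t")
        S = score_matrix(q, t, params)
        got = align(q, t, params).score
        if mode == "local":
            want = oracle_local_score(S, params.gap_open, params.gap_extend)
        else:
            want = oracle_global_score(S, params.gap_open,
                                       params.gap_extend)
        assert got == pytest.approx(want, abs=1e-9)


def test_traceback_pairs_are_strictly_increasing():
    rng = np.random.default_rng(23)
    for mode in ("local", "global"):
        params = AlignmentParams(mode=mode)
        q = random_entry(rng, 12, "q")
        t = random_entry(rng, 14, "t")
        res = align(q, t, params)
        for (i1, j1), (i2, j2) in zip(res.pairs, res.pairs[1:]):
            assert i2 > i1 and j2 > j1


def test_alignment_errors_and_formatting():
    rng = np.random.default_rng(29)
    q = random_entry(rng, 4, "q")
    t = random_entry(rng, 4, "t")
    res = align(q, t, AlignmentParams(mode="global"))
    text = format_alignment(res, q, t)
    assert "q vs t" in text and "score" in text
    parsed = __import__("json").loads(res.to_json())
    assert parsed["mode"] == "global"


def test_control_configuration_changes_property_divergent_scores():
    """Zeroing the property weights must change the score of a pair whose
    entries agree in profile and SS but diverge in RSA/RD/Phi."""
    profile, truth = generate_family(FamilySpec(seed=31, length=25))
    a = entry_from_truth("a", profile, truth)
    import copy

    b = copy.deepcopy(a)
    b.features.rsa = 1.0 - b.features.rsa
    b.features.rd = 1.0 - b.features.rd
    full = align(a, b, AlignmentParams()).score
    control = align(a, b, AlignmentParams().control()).score
    assert control > full
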