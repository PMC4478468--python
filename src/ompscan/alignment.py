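"""Profile-to-profile alignment with a structure-aware scoring function.

The score for aligning query position i with template position j combines
four ingredients:

    S(i, j) = w1 * Profile(i, j) + SS_Sim(i, j)
              - [w2*|RD_q(i)-RD_t(j)| + w3*|RSA_q(i)-RSA_t(j)|
                 + w4*|Phi_q(i)-Phi_t(j)|]
              - shift

* ``Profile`` is the symmetric cross dot-product of one profile's
  frequencies with the other's raw log-odds scores, averaged both ways.
* ``SS_Sim`` rewards matching predicted secondary-structure types by the
  mean of the two residues' reliability indices, and is 0 when the types
  differ.
* The property terms penalize disagreement in predicted residue depth,
  solvent accessibility and Phi angle (all on [0, 1] scales).
* ``shift`` is a constant subtracted from every pair so that unrelated
  residue pairs score negative on average, which keeps local alignments
  from extending through noise.

The trained default parameters are gap open -7.0, gap extension -0.54,
w1 = 0.65, w2 = w3 = w4 = 1.0 and shift = 0.76.  Zeroing w2..w4 gives the
profile+SS ablation ("control" configuration).  Alignment itself is
three-state affine-gap dynamic programming with deterministic traceback
(diagonal preferred over a gap in the template, over a gap in the query),
in Smith-Waterman local or Needleman-Wunsch global mode (terminal gaps
penalized, so as many residues as possible are aligned for modeling).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .profiles import SequenceProfile
from .struct_props import StructuralFeatures

NEG_INF = -1e30


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring-function weights and gap penalties (trained defaults)."""

    gap_open: float = -7.0
    gap_extend: float = -0.54
    w1: float = 0.65
    w2: float = 1.0
    w3: float = 1.0
    w4: float = 1.0
    shift: float = 0.76
    mode: str = "local"

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("require gap_open <= gap_extend <= 0")
        if self.shift < 0:
            raise ValueError("shift must be nonnegative")
        if self.mode not in ("local", "global"):
            raise ValueError("mode must be 'local' or 'global'")

    def control(self) -> "AlignmentParams":
        """The profile+SS ablation: property weights zeroed."""
        return replace(self, w2=0.0, w3=0.0, w4=0.0)


@dataclass
class AlignedEntry:
    """A profile bundled with its (predicted) structural feature tracks."""

    id: str
    profile: SequenceProfile
    features: StructuralFeatures
    ss_ri: np.ndarray

    def __post_init__(self) -> None:
        L = len(self.profile)
        self.ss_ri = np.asarray(self.ss_ri, dtype=float)
        if len(self.features) != L or self.ss_ri.shape != (L,):
            raise ValueError("all tracks must share the profile length")

    def __len__(self) -> int:
        return len(self.profile)


@dataclass
class AlignmentResult:
    """A scored alignment: matched position pairs plus explicit gap runs."""

    score: float
    pairs: list[tuple[int, int]]
    gaps: list[tuple[str, int, int]]  # (which sequence gapped, start, length)
    mode: str
    query_id: str = ""
    template_id: str = ""

    def to_json(self) -> str:
        return json.dumps({
            "query": self.query_id, "template": self.template_id,
            "mode": self.mode, "score": self.score,
            "pairs": self.pairs, "gaps": self.gaps,
        })


def profile_score(q: AlignedEntry, t: AlignedEntry, i: int, j: int) -> float:
    """Symmetric profile dot product: query frequencies against template
    log-odds and vice versa, averaged.  Raw (unsquashed) PSSM values are
    used — the trained weight and the decision thresholds live on the
    log-odds scale."""
    if q.profile.alphabet != t.profile.alphabet:
        raise ValueError("profiles use different alphabet orderings")
    return 0.5 * (
        float(q.profile.psfm[i] @ t.profile.pssm[j])
        + float(t.profile.psfm[j] @ q.profile.pssm[i])
    )


def ss_sim(q: AlignedEntry, t: AlignedEntry, i: int, j: int) -> float:
    """Reliability-weighted secondary-structure agreement (0 on mismatch)."""
    if q.features.ss3[i] != t.features.ss3[j]:
        return 0.0
    return 0.5 * (float(q.ss_ri[i]) + float(t.ss_ri[j]))


def property_delta(q: AlignedEntry, t: AlignedEntry, i: int, j: int,
                   params: AlignmentParams) -> float:
    """Weighted absolute differences of the three structural properties."""
    return (
        params.w2 * abs(float(q.features.rd[i]) - float(t.features.rd[j]))
        + params.w3 * abs(float(q.features.rsa[i]) - float(t.features.rsa[j]))
        + params.w4 * abs(float(q.features.phi_norm[i])
                          - float(t.features.phi_norm[j]))
    )


def pair_score(q: AlignedEntry, t: AlignedEntry, i: int, j: int,
               params: AlignmentParams) -> float:
    """The full per-pair score S(i, j)."""
    return (
        params.w1 * profile_score(q, t, i, j)
        + ss_sim(q, t, i, j)
        - property_delta(q, t, i, j, params)
        - params.shift
    )


def score_matrix(q: AlignedEntry, t: AlignedEntry,
                 params: AlignmentParams) -> np.ndarray:
    """Vectorized (Lq, Lt) matrix of pair scores."""
    if q.profile.alphabet != t.profile.alphabet:
        raise ValueError("profiles use different alphabet orderings")
    prof = 0.5 * (
        q.profile.psfm @ t.profile.pssm.T + q.profile.pssm @ t.profile.psfm.T
    )
    ss_q = np.frombuffer(q.features.ss3.encode(), dtype=np.uint8)
    ss_t = np.frombuffer(t.features.ss3.encode(), dtype=np.uint8)
    same = (ss_q[:, None] == ss_t[None, :])
    ss = same * 0.5 * (q.ss_ri[:, None] + t.ss_ri[None, :])
    prop = (
        params.w2 * np.abs(q.features.rd[:, None] - t.features.rd[None, :])
        + params.w3 * np.abs(q.features.rsa[:, None]
                             - t.features.rsa[None, :])
        + params.w4 * np.abs(q.features.phi_norm[:, None]
                             - t.features.phi_norm[None, :])
    )
    return params.w1 * prof + ss - prop - params.shift


# traceback predecessor-state codes
_STOP, _FROM_M, _FROM_X, _FROM_Y = 0, 1, 2, 3


def align(q: AlignedEntry, t: AlignedEntry,
          params: AlignmentParams | None = None) -> AlignmentResult:
    """Affine-gap dynamic programming over the pair-score lattice.

    Three states per cell: match, gap-in-template (query residue consumed)
    and gap-in-query.  Opening a gap costs ``gap_open``; each further
    gapped position ``gap_extend``; switching directly between the two gap
    states re-opens.  Local mode clamps the match state at zero and traces
    back from the best cell (first such cell in row-major order on ties);
    global mode runs end to end with terminal gaps penalized.  Predecessor
    ties prefer match, then gap-in-template, then gap-in-query, making the
    traceback deterministic.
    """
    if params is None:
        params = AlignmentParams()
    n, m = len(q), len(t)
    if n == 0 or m == 0:
        raise ValueError("cannot align an empty entry")
    S = score_matrix(q, t, params)
    go, ge = params.gap_open, params.gap_extend
    local = params.mode == "local"

    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)  # gap in template
    Y = np.full((n + 1, m + 1), NEG_INF)  # gap in query
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    if local:
        M[:, 0] = 0.0
        M[0, :] = 0.0
    else:
        X[1:, 0] = go + np.arange(n) * ge
        ptr_x[1, 0] = _FROM_M
        ptr_x[2:, 0] = _FROM_X
        Y[0, 1:] = go + np.arange(m) * ge
        ptr_y[0, 1] = _FROM_M
        ptr_y[0, 2:] = _FROM_Y

    for i in range(1, n + 1):
        Si = S[i - 1]
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        pm_i, px_i, py_i = ptr_m[i], ptr_x[i], ptr_y[i]
        for j in range(1, m + 1):
            # match: best predecessor state at (i-1, j-1) plus S(i-1, j-1)
            best_prev, code = Mi1[j - 1], _FROM_M
            if Xi1[j - 1] > best_prev:
                best_prev, code = Xi1[j - 1], _FROM_X
            if Yi1[j - 1] > best_prev:
                best_prev, code = Yi1[j - 1], _FROM_Y
            m_val = best_prev + Si[j - 1]
            if local and m_val < 0.0:
                m_val, code = 0.0, _STOP
            Mi[j], pm_i[j] = m_val, code
            # gap in template: consume query residue i-1
            x_val, x_code = Mi1[j] + go, _FROM_M
            if Xi1[j] + ge > x_val:
                x_val, x_code = Xi1[j] + ge, _FROM_X
            if Yi1[j] + go > x_val:
                x_val, x_code = Yi1[j] + go, _FROM_Y
            Xi[j], px_i[j] = x_val, x_code
            # gap in query: consume template residue j-1
            y_val, y_code = Mi[j - 1] + go, _FROM_M
            if Xi[j - 1] + go > y_val:
                y_val, y_code = Xi[j - 1] + go, _FROM_X
            if Yi[j - 1] + ge > y_val:
                y_val, y_code = Yi[j - 1] + ge, _FROM_Y
            Yi[j], py_i[j] = y_val, y_code

    if local:
        best = 0.0
        start_i = start_j = 0
        flat = int(np.argmax(M))
        if M.flat[flat] > 0.0:
            best = float(M.flat[flat])
            start_i, start_j = divmod(flat, m + 1)
        score = best
        state = "M"
    else:
        candidates = (("M", M[n, m]), ("X", X[n, m]), ("Y", Y[n, m]))
        state, score = max(candidates, key=lambda c: c[1])
        for name, val in candidates:  # deterministic tie preference M, X, Y
            if val == score:
                state = name
                break
        start_i, start_j = n, m

    pairs: list[tuple[int, int]] = []
    gaps: list[tuple[str, int, int]] = []
    i, j = start_i, start_j
    while i > 0 or j > 0:
        if state == "M":
            if local and M[i, j] == 0.0:
                break
            code = ptr_m[i, j]
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
            state = {_FROM_M: "M", _FROM_X: "X", _FROM_Y: "Y",
                     _STOP: "M"}[code]
            if code == _STOP:
                break
        elif state == "X":
            code = ptr_x[i, j]
            gaps.append(("template", i - 1, 1))
            i -= 1
            state = {_FROM_M: "M", _FROM_X: "X", _FROM_Y: "Y"}[code]
        else:
            code = ptr_y[i, j]
            gaps.append(("query", j - 1, 1))
            j -= 1
            state = {_FROM_M: "M", _FROM_X: "X", _FROM_Y: "Y"}[code]
    pairs.reverse()
    gaps = _merge_gap_runs(gaps)
    return AlignmentResult(score=float(score), pairs=pairs, gaps=gaps,
                           mode=params.mode, query_id=q.id, template_id=t.id)


def _merge_gap_runs(gaps: list[tuple[str, int, int]]
                    ) -> list[tuple[str, int, int]]:
    """Collapse single gapped positions into (which, start, length) runs."""
    runs: list[tuple[str, int, int]] = []
    for which, pos, _ in sorted(gaps):
        if runs and runs[-1][0] == which and \
                runs[-1][1] + runs[-1][2] == pos:
            runs[-1] = (which, runs[-1][1], runs[-1][2] + 1)
        else:
            runs.append((which, pos, 1))
    return runs


def format_alignment(result: AlignmentResult, q: AlignedEntry,
                     t: AlignedEntry, width: int = 60) -> str:
    """Human-readable pairwise rendering with a match line."""
    if not result.pairs:
        return (
            f"# {result.query_id} vs {result.template_id} "
            f"({result.mode})  score {result.score:.2f}\n(empty alignment)\n"
        )
    qs, ts, mid = [], [], []
    prev_i = prev_j = None
    for i, j in result.pairs:
        if prev_i is not None:
            for k in range(prev_i + 1, i):
                qs.append(q.profile.sequence[k])
                ts.append("-")
                mid.append(" ")
            for k in range(prev_j + 1, j):
                qs.append("-")
                ts.append(t.profile.sequence[k])
                mid.append(" ")
        qa, ta = q.profile.sequence[i], t.profile.sequence[j]
        qs.append(qa)
        ts.append(ta)
        mid.append("|" if qa == ta else ":")
        prev_i, prev_j = i, j
    lines = [
        f"# {result.query_id} vs {result.template_id} ({result.mode})  "
        f"score {result.score:.2f}"
    ]
    for start in range(0, len(qs), width):
        sl = slice(start, start + width)
        lines.append("".join(qs[sl]))
        lines.append("".join(mid[sl]))
        lines.append("".join(ts[sl]))
        lines.append("")
    return "\n".join(lines)
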