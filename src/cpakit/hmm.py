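"""Profile hidden Markov model built from a seed alignment, and glocal
Viterbi alignment of queries against it.

This is a deliberately compact profile HMM: match/insert/delete states per
node, match emissions estimated from seed counts with background pseudocounts,
insert emissions fixed at the background (so insert residues score zero
log-odds), and the seven plan-style transitions M->M/I/D, I->M/I, D->M/D plus
begin/end.  Alignment is *glocal*: the full profile must be traversed
(possibly through delete states) while query residues outside the profile
span are free flanks.  Scores are Viterbi log-odds in bits against the
background distribution; there is no E-value calibration — scores rank
queries, nothing more.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .substitution import AMINO_ACIDS, SubstitutionModel, encode_sequence

NEG_INF = float("-inf")


class EmptyProfileError(ValueError):
    """Raised when no seed column qualifies as a match state."""


@dataclass(frozen=True)
class ProfileHMM:
    """Profile HMM over the 20 amino acids.

    Transition arrays are indexed by source node 0..M (node 0 is Begin, a
    transition out of node M goes to End); insert states exist for nodes
    1..M-1 only.  ``column_map[k]`` is the 0-based seed-MSA column of match
    state k+1 (strictly increasing).
    """

    match_emissions: np.ndarray          # (M, 20)
    background: np.ndarray               # (20,)
    t_mm: np.ndarray                     # (M+1,) M_k -> M_{k+1} (B->M1, M_M->E)
    t_mi: np.ndarray                     # (M+1,) M_k -> I_k
    t_md: np.ndarray                     # (M+1,) M_k -> D_{k+1}
    t_im: np.ndarray                     # (M+1,) I_k -> M_{k+1}
    t_ii: np.ndarray                     # (M+1,) I_k -> I_k
    t_dm: np.ndarray                     # (M+1,) D_k -> M_{k+1} (D_M -> E)
    t_dd: np.ndarray                     # (M+1,) D_k -> D_{k+1}
    column_map: np.ndarray               # (M,) seed columns, 0-based

    @property
    def n_match(self) -> int:
        return self.match_emissions.shape[0]

    def __post_init__(self):
        M = self.n_match
        if M < 1:
            raise EmptyProfileError("profile must have at least one match state")
        if not np.all(np.diff(self.column_map) > 0):
            raise ValueError("column_map must be strictly increasing")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("match emissions must sum to 1")
        for k in range(M + 1):
            out_m = self.t_mm[k] + self.t_mi[k] + self.t_md[k]
            if abs(out_m - 1.0) > 1e-9:
                raise ValueError(f"M-state transitions at node {k} sum to {out_m}")
        object.__setattr__(
            self, "_logodds",
            np.where(self.match_emissions > 0,
                     np.log2(np.maximum(self.match_emissions, 1e-300) / self.background[None, :]),
                     NEG_INF),
        )

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.match_emissions.argmax(axis=1))

    # -- serialisation -------------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "schema": "cpakit-profile-hmm/1",
            "background": self.background.tolist(),
            "match_emissions": self.match_emissions.tolist(),
            "column_map": self.column_map.tolist(),
        }
        for name in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd"):
            payload[name] = getattr(self, name).tolist()
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ProfileHMM":
        data = json.loads(text)
        if data.get("schema") != "cpakit-profile-hmm/1":
            raise ValueError(f"unsupported profile schema: {data.get('schema')!r}")
        kwargs = {k: np.asarray(data[k]) for k in (
            "match_emissions", "background", "t_mm", "t_mi", "t_md",
            "t_im", "t_ii", "t_dm", "t_dd", "column_map")}
        kwargs["column_map"] = kwargs["column_map"].astype(int)
        return cls(**kwargs)


@dataclass(frozen=True)
class AlignmentMap:
    """Bidirectional map between query residues and profile match columns.

    ``col_to_query[k]`` is the 0-based query index aligned to match column
    k+1, or None for a deletion.  ``query_states[i]`` is ("M", col),
    ("I", after_col) or ("F", 0) (flank) for query residue i (cols 1-based).
    """

    col_to_query: tuple
    query_states: tuple

    @property
    def n_match_columns(self) -> int:
        return len(self.col_to_query)

    def query_index_of_column(self, column_1based: int):
        return self.col_to_query[column_1based - 1]

    def column_of_query_index(self, index_0based: int):
        kind, col = self.query_states[index_0based]
        return col if kind == "M" else None

    def to_tsv_rows(self, query_id: str) -> list[str]:
        rows = []
        for i, (kind, col) in enumerate(self.query_states):
            label = str(col) if kind == "M" else ("INS" if kind == "I" else "FLANK")
            rows.append(f"{query_id}\t{i + 1}\t{label}")
        for k, q in enumerate(self.col_to_query):
            if q is None:
                rows.append(f"{query_id}\tDEL\t{k + 1}")
        return rows


def build_profile(
    rows: list[str],
    match_gap_threshold: float = 0.5,
    pseudocount_weight: float = 1.0,
    background: np.ndarray | None = None,
) -> ProfileHMM:
    """Estimate a profile HMM from an aligned seed (equal-length rows).

    Columns whose gap fraction is <= ``match_gap_threshold`` become match
    states.  Match emissions are (residue counts + pseudocount_weight x
    background), normalised; transitions are counted from each row's implied
    state path and Laplace-smoothed (+1 per permitted transition).
    """
    if not rows:
        raise ValueError("seed alignment is empty")
    L = len(rows[0])
    if any(len(r) != L for r in rows):
        raise ValueError("seed alignment rows differ in length")
    if background is None:
        background = SubstitutionModel.lg().frequencies
    cols = np.array([[c for c in row.upper()] for row in rows])
    gap_frac = (cols == "-").mean(axis=0)
    match_cols = np.where(gap_frac <= match_gap_threshold)[0]
    if match_cols.size == 0:
        raise EmptyProfileError("every seed column is gap-rich; no match states")
    M = match_cols.size

    emissions = np.tile(background * pseudocount_weight, (M, 1))
    for k, c in enumerate(match_cols):
        for ch in cols[:, c]:
            idx = AMINO_ACIDS.find(ch)
            if idx >= 0:
                emissions[k, idx] += 1.0
    emissions /= emissions.sum(axis=1, keepdims=True)

    # transition counts, Laplace-smoothed over the permitted moves per node
    c_mm = np.ones(M + 1); c_mi = np.ones(M + 1); c_md = np.ones(M + 1)
    c_im = np.ones(M + 1); c_ii = np.ones(M + 1)
    c_dm = np.ones(M + 1); c_dd = np.ones(M + 1)
    is_match = np.zeros(L, dtype=bool)
    is_match[match_cols] = True
    col_node = np.cumsum(is_match)  # node index of each alignment column
    for row in rows:
        state, node = "M", 0  # begin acts as M_0
        for c in range(L):
            ch = row[c]
            if is_match[c]:
                new = "D" if ch == "-" else "M"
                if state == "M":
                    (c_mm if new == "M" else c_md)[node] += 1
                elif state == "I":
                    if new == "M":
                        c_im[node] += 1
                    # I->D not modelled; absorb as I->M->... skip the count
                else:
                    (c_dm if new == "M" else c_dd)[node] += 1
                state, node = new, col_node[c]
            elif ch != "-":
                if 1 <= node <= M - 1:  # inserts only between match states
                    if state == "M":
                        c_mi[node] += 1
                    elif state == "I":
                        c_ii[node] += 1
                    # D->I not modelled; the residue still moves us to I
                    state = "I"
        # exit to End
        if state == "M":
            c_mm[M] += 1
        elif state == "D":
            c_dm[M] += 1
        else:
            c_im[M] += 1

    # no D1 entry pseudo-structure notes: node M has no M->D / D->D / I states
    c_md[M] = 0.0
    c_dd[M] = 0.0
    c_mi[M] = 0.0
    c_mi[0] = 0.0  # inserts before node 1 are flanks in glocal mode

    tot_m = c_mm + c_mi + c_md
    tot_i = c_im + c_ii
    tot_d = c_dm + c_dd
    hmm = ProfileHMM(
        match_emissions=emissions,
        background=np.asarray(background, dtype=float),
        t_mm=c_mm / tot_m, t_mi=c_mi / tot_m, t_md=c_md / tot_m,
        t_im=c_im / tot_i, t_ii=c_ii / tot_i,
        t_dm=c_dm / tot_d, t_dd=c_dd / tot_d,
        column_map=match_cols,
    )
    return hmm


def _log2(x: float) -> float:
    return math.log2(x) if x > 0 else NEG_INF


def viterbi_align(hmm: ProfileHMM, query: str) -> tuple[AlignmentMap, float]:
    """Best glocal state path of ``query`` through ``hmm``; score in bits.

    Dynamic programme over (node, query-prefix) with free flanking residues:
    entry into node 1 is allowed after any number of unaligned N-terminal
    residues (zero cost), and exit from node M before any number of C-terminal
    residues.  Deterministic: ties resolve in the fixed order M < I < D
    predecessor, earlier entry point first.
    """
    if not query:
        raise ValueError("empty query sequence")
    q = encode_sequence(query)
    L, M = len(q), hmm.n_match
    lo = hmm._logodds  # (M,20)
    lmm = np.log2(np.maximum(hmm.t_mm, 1e-300)); lmm[hmm.t_mm == 0] = NEG_INF
    lmi = np.where(hmm.t_mi > 0, np.log2(np.maximum(hmm.t_mi, 1e-300)), NEG_INF)
    lmd = np.where(hmm.t_md > 0, np.log2(np.maximum(hmm.t_md, 1e-300)), NEG_INF)
    lim = np.where(hmm.t_im > 0, np.log2(np.maximum(hmm.t_im, 1e-300)), NEG_INF)
    lii = np.where(hmm.t_ii > 0, np.log2(np.maximum(hmm.t_ii, 1e-300)), NEG_INF)
    ldm = np.where(hmm.t_dm > 0, np.log2(np.maximum(hmm.t_dm, 1e-300)), NEG_INF)
    ldd = np.where(hmm.t_dd > 0, np.log2(np.maximum(hmm.t_dd, 1e-300)), NEG_INF)

    VM = np.full((M + 1, L + 1), NEG_INF)
    VI = np.full((M + 1, L + 1), NEG_INF)
    VD = np.full((M + 1, L + 1), NEG_INF)
    PM = np.zeros((M + 1, L + 1), dtype=np.int8)  # 0=B/flank,1=M,2=I,3=D
    PD = np.zeros((M + 1, L + 1), dtype=np.int8)
    PI = np.zeros((M + 1, L + 1), dtype=np.int8)

    def em(k: int, code: int) -> float:
        return 0.0 if code < 0 else lo[k - 1, code]

    for j in range(0, L + 1):
        # k = 1
        if j >= 1:
            VM[1, j] = lmm[0] + em(1, q[j - 1])  # from Begin after j-1 flank residues
        VD[1, j] = lmd[0]
        for k in range(2, M + 1):
            if j >= 1:
                cands = (VM[k - 1, j - 1] + lmm[k - 1],
                         VI[k - 1, j - 1] + lim[k - 1],
                         VD[k - 1, j - 1] + ldm[k - 1])
                best = max(cands)
                VM[k, j] = best + em(k, q[j - 1])
                PM[k, j] = 1 + cands.index(best)
            cands = (VM[k - 1, j] + lmd[k - 1], VD[k - 1, j] + ldd[k - 1])
            best = max(cands)
            VD[k, j] = best
            PD[k, j] = (1, 3)[cands.index(best)]
        if j >= 1:
            for k in range(1, M):
                cands = (VM[k, j - 1] + lmi[k], VI[k, j - 1] + lii[k])
                best = max(cands)
                VI[k, j] = best
                PI[k, j] = (1, 2)[cands.index(best)]

    # exit: from M_M or D_M at any consumed prefix j, remaining residues flank
    best_score, best_j, best_state = NEG_INF, None, None
    for j in range(0, L + 1):
        sm = VM[M, j] + lmm[M]
        sd = VD[M, j] + ldm[M]
        if sm > best_score:
            best_score, best_j, best_state = sm, j, 1
        if sd > best_score:
            best_score, best_j, best_state = sd, j, 3
    if best_j is None or best_score == NEG_INF:
        raise RuntimeError("no admissible glocal path (degenerate profile)")

    # traceback (PM/PD default 0 at node 1 = Begin)
    col_to_query: list = [None] * M
    query_states: list = [("F", 0)] * L
    k, j, state = M, best_j, best_state
    while True:
        if state == 1:      # M_k consumed query residue j
            col_to_query[k - 1] = j - 1
            query_states[j - 1] = ("M", k)
            prev = int(PM[k, j])
            k -= 1
            j -= 1
        elif state == 2:    # I_k consumed query residue j, stays at node k
            query_states[j - 1] = ("I", k)
            prev = int(PI[k, j])
            j -= 1
        else:               # D_k consumed nothing
            prev = int(PD[k, j])
            k -= 1
        if k == 0 and prev == 0:
            break
        state = prev
    return AlignmentMap(tuple(col_to_query), tuple(query_states)), float(best_score)


def score_query(hmm: ProfileHMM, query: str) -> float:
    """Viterbi log-odds score (bits) of ``query`` against ``hmm``."""
    return viterbi_align(hmm, query)[1]
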