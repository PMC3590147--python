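"""Independent brute-force oracles for the test suite.

A plain-Python affine-gap Smith-Waterman (BLOSUM62, gap of length g costs
11 + (g-1)) with full traceback, and a literal re-implementation of the
consensus/classification rules that recounts overhang modes exhaustively.
Deliberately naive and loop-based; usable only for tiny fixtures.
"""

from __future__ import annotations

from collections import Counter

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")
OPEN = -11.0   # score of a length-1 gap
EXTEND = -1.0  # each additional gap column

NEG = float("-inf")


def sw_oracle(x: str, y: str):
    """Best local alignment of x vs y.

    Returns (score, q_start, q_end, s_start, s_end, n_ident, aln_len) with
    1-based inclusive coordinates, or None if no positive-scoring alignment
    exists.  aln_len counts all columns including gaps.
    """
    n, m = len(x), len(y)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in y (consumes x)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in x (consumes y)
    # pointers: predecessor state of each cell, or "start" for a fresh
    # local alignment beginning at that match cell
    ptr_m = [[None] * (m + 1) for _ in range(n + 1)]
    ptr_ix = [[None] * (m + 1) for _ in range(n + 1)]
    ptr_iy = [[None] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    best_cell = None
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if M[i - 1][j] + OPEN >= Ix[i - 1][j] + EXTEND:
                Ix[i][j], ptr_ix[i][j] = M[i - 1][j] + OPEN, "M"
            else:
                Ix[i][j], ptr_ix[i][j] = Ix[i - 1][j] + EXTEND, "Ix"
            if M[i][j - 1] + OPEN >= Iy[i][j - 1] + EXTEND:
                Iy[i][j], ptr_iy[i][j] = M[i][j - 1] + OPEN, "M"
            else:
                Iy[i][j], ptr_iy[i][j] = Iy[i][j - 1] + EXTEND, "Iy"
            s = _B62[x[i - 1], y[j - 1]]
            prev, src = max(
                (0.0, "start"), (M[i - 1][j - 1], "M"),
                (Ix[i - 1][j - 1], "Ix"), (Iy[i - 1][j - 1], "Iy"),
                key=lambda t: t[0])
            M[i][j] = prev + s
            ptr_m[i][j] = src
            if M[i][j] > best:
                best = M[i][j]
                best_cell = (i, j)
    if best_cell is None or best <= 0:
        return None
    i, j = best_cell
    q_end, s_end = i, j
    state = "M"
    n_ident = 0
    aln_len = 0
    while True:
        if state == "M":
            aln_len += 1
            if x[i - 1] == y[j - 1]:
                n_ident += 1
            src = ptr_m[i][j]
            i -= 1
            j -= 1
            if src == "start":
                break
            state = src
        elif state == "Ix":
            aln_len += 1
            state = ptr_ix[i][j]
            i -= 1
        else:
            aln_len += 1
            state = ptr_iy[i][j]
            j -= 1
    q_start, s_start = i + 1, j + 1
    return best, q_start, q_end, s_start, s_end, n_ident, aln_len


def classify_oracle(members: list[tuple[str, str]], *, d: float, a: int,
                    b: int, f: int, g: int, min_refs: int,
                    consensus_frac: float = 0.33,
                    bimodal_frac: float = 0.40):
    """Exhaustive recount of the correction decisions for a tiny family.

    ``members`` is a list of (id, residues).  Returns
    {(seq_id, end): (kind, trim, pad)}.  Terminal-X absorption is applied
    to overhang counts exactly as the contract states: paired-off columns
    where either side is X do not count as overhang.
    """
    out = {}
    proposals = {"5prime": [], "3prime": []}
    per_query = {}
    for qid, q in members:
        pairs5 = []
        pairs3 = []
        for rid, r in members:
            if rid == qid:
                continue
            res = sw_oracle(q, r)
            if res is None:
                continue
            score, qs, qe, ss, se, n_ident, aln_len = res
            if n_ident / aln_len < d:
                continue
            q5, r5 = qs - 1, ss - 1
            q3, r3 = len(q) - qe, len(r) - se
            ab5 = min(q5, r5, max(q[:q5].count("X"), r[:r5].count("X")))
            ab3 = min(q3, r3, max(q[len(q) - q3:].count("X"),
                                  r[len(r) - r3:].count("X")))
            pairs5.append((q5 - ab5, r5 - ab5))
            pairs3.append((q3 - ab3, r3 - ab3))
        if len(pairs5) < min_refs:
            per_query[qid] = None
            continue
        per_query[qid] = {}
        for end, pairs, t, s in (("5prime", pairs5, f, a),
                                 ("3prime", pairs3, g, b)):
            n = len(pairs)
            cands = [(p, c) for p, c in Counter(pairs).items()
                     if c / n >= consensus_frac]
            if not cands:
                per_query[qid][end] = ("ok", 0, 0)
                continue

            def implied(pair):
                q_o, r_o = pair
                if q_o >= t and r_o >= t:
                    return ("chimeric", q_o, r_o)
                if q_o >= s:
                    return ("overextended", q_o, 0)
                if r_o >= s:
                    return ("truncated", 0, r_o)
                return ("ok", 0, 0)

            def key(item):
                (q_o, r_o), _c = item
                _k, trim, pad = implied((q_o, r_o))
                return (-(pad - trim), q_o, r_o)

            pair, _c = min(cands, key=key)
            per_query[qid][end] = implied(pair)
    for end in ("5prime", "3prime"):
        decided = [per_query[qid][end] for qid, _ in members
                   if per_query[qid] is not None]
        n = len(decided)
        if n:
            p_trim = sum(1 for k, tr, pa in decided if tr > 0) / n
            p_pad = sum(1 for k, tr, pa in decided if pa > 0) / n
            bimodal = p_trim >= bimodal_frac and p_pad >= bimodal_frac
        else:
            bimodal = False
        for qid, _ in members:
            if per_query[qid] is None:
                out[(qid, end)] = ("uncorrectable", 0, 0)
                continue
            kind, trim, pad = per_query[qid][end]
            if bimodal and kind == "overextended":
                kind, trim, pad = "ok", 0, 0
            out[(qid, end)] = (kind, trim, pad)
    return out
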