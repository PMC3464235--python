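"""Independent brute-force affine-gap local alignment oracle.

Plain O(m*n) Gotoh dynamic programme kept deliberately separate from the
package implementation: no banding, no seeding, score-only.  Used to verify
the built-in aligner's optima.
"""

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -2, -3, -1


def best_local_score(query: str, target: str) -> int:
    """Best Smith-Waterman/Gotoh score; a gap of length k costs 3 + k."""
    m, n = len(query), len(target)
    NEG = float("-inf")
    prev_h = [0.0] * (n + 1)
    prev_f = [NEG] * (n + 1)
    best = 0.0
    for i in range(1, m + 1):
        qi = query[i - 1]
        cur_h = [0.0] * (n + 1)
        cur_e = [NEG] * (n + 1)
        cur_f = [NEG] * (n + 1)
        for j in range(1, n + 1):
            cur_e[j] = max(cur_h[j - 1] + GAP_OPEN + GAP_EXTEND, cur_e[j - 1] + GAP_EXTEND)
            cur_f[j] = max(prev_h[j] + GAP_OPEN + GAP_EXTEND, prev_f[j] + GAP_EXTEND)
            diag = prev_h[j - 1] + (MATCH if qi == target[j - 1] else MISMATCH)
            cur_h[j] = max(0.0, diag, cur_e[j], cur_f[j])
            if cur_h[j] > best:
                best = cur_h[j]
        prev_h, prev_f = cur_h, cur_f
    return int(best)


def score_of_ops(ops: str, query_slice: str, target_slice: str) -> int:
    """Re-score an explicit alignment path (validity cross-check)."""
    score = 0
    qi = ti = 0
    i = 0
    while i < len(ops):
        op = ops[i]
        if op in "=X":
            eq = query_slice[qi] == target_slice[ti]
            assert (op == "=") == eq
            score += MATCH if eq else MISMATCH
            qi += 1
            ti += 1
            i += 1
        else:
            run = 0
            while i < len(ops) and ops[i] == op:
                run += 1
                i += 1
            score += GAP_OPEN + run * GAP_EXTEND
            if op == "I":
                qi += run
            else:
                ti += run
    assert qi == len(query_slice) and ti == len(target_slice)
    return score
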