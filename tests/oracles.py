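"""Independent brute-force oracles used only by the test suite.

These are deliberately naive re-derivations — full O(n*m) Gotoh dynamic
programming in pure Python with explicit state matrices and traceback, and a
triple-loop motif enumerator — kept separate from the package so that
agreement between the two routes is meaningful.
"""

from __future__ import annotations

NEG = float("-inf")

# gap of length k costs open + k*extend (first gapped residue: open+extend)


def _matrices(a, b, score_fn, go, ge, local):
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    ptr = {}
    first = go + ge
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score_fn(a[i - 1], b[j - 1])
            # diagonal predecessors; a fresh start is allowed on the border
            # (semi-global: free leading gap) or anywhere (local)
            cands = [
                ("M", M[i - 1][j - 1]),
                ("X", X[i - 1][j - 1]),
                ("Y", Y[i - 1][j - 1]),
            ]
            if local or i == 1 or j == 1:
                cands.append(("start", 0.0))
            state, val = max(cands, key=lambda kv: kv[1])
            M[i][j] = s + val
            ptr[("M", i, j)] = state
            xc = [("M", M[i - 1][j] - first), ("X", X[i - 1][j] - ge),
                  ("Y", Y[i - 1][j] - first)]
            state, val = max(xc, key=lambda kv: kv[1])
            X[i][j] = val
            ptr[("X", i, j)] = state
            yc = [("M", M[i][j - 1] - first), ("Y", Y[i][j - 1] - ge),
                  ("X", X[i][j - 1] - first)]
            state, val = max(yc, key=lambda kv: kv[1])
            Y[i][j] = val
            ptr[("Y", i, j)] = state
    return M, X, Y, ptr


def _traceback(a, b, M, X, Y, ptr, i, j, state):
    cols = []
    while True:
        if state == "M":
            cols.append((a[i - 1], b[j - 1]))
            prev = ptr[("M", i, j)]
            i, j = i - 1, j - 1
        elif state == "X":
            cols.append((a[i - 1], "-"))
            prev = ptr[("X", i, j)]
            i = i - 1
        else:
            cols.append(("-", b[j - 1]))
            prev = ptr[("Y", i, j)]
            j = j - 1
        if prev == "start":
            break
        state = prev
    cols.reverse()
    return cols


def semiglobal_align(a, b, score_fn, gap_open=10.0, gap_extend=1.0):
    """Optimal free-end-gap global alignment.

    Returns ``(score, columns)`` where columns is the list of aligned
    character pairs between the first and last aligned residues (terminal
    overhangs excluded); columns is empty when the optimum is the
    zero-overlap alignment.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    M, X, Y, ptr = _matrices(a, b, score_fn, gap_open, gap_extend, local=False)
    n, m = len(a), len(b)
    best, where = 0.0, None
    for i in range(1, n + 1):
        for state, mat in (("M", M), ("X", X), ("Y", Y)):
            if mat[i][m] > best:
                best, where = mat[i][m], (i, m, state)
    for j in range(1, m + 1):
        for state, mat in (("M", M), ("X", X), ("Y", Y)):
            if mat[n][j] > best:
                best, where = mat[n][j], (n, j, state)
    if where is None:
        return 0.0, []
    i, j, state = where
    return best, _traceback(a, b, M, X, Y, ptr, i, j, state)


def local_align(a, b, score_fn, gap_open=10.0, gap_extend=1.0):
    """Optimal Smith-Waterman alignment: ``(score, columns)``; score 0 and no
    columns when no positive-scoring cell exists."""
    if not a or not b:
        raise ValueError("empty sequence")
    M, X, Y, ptr = _matrices(a, b, score_fn, gap_open, gap_extend, local=True)
    best, where = 0.0, None
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            if M[i][j] > best:
                best, where = M[i][j], (i, j)
    if where is None:
        return 0.0, []
    i, j = where
    return best, _traceback(a, b, M, X, Y, ptr, i, j, "M")


def identity_from_columns(cols, len_a, len_b):
    """Percent identity with the shorter-sequence floor in the denominator."""
    if not cols:
        return 0.0
    matches = sum(1 for ca, cb in cols if ca == cb and ca != "-" and ca != "X")
    return 100.0 * matches / max(len(cols), min(len_a, len_b))


def blosum62_fn():
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    return lambda x, y: float(mat[x][y])


def enumerate_motifs(sequence, n_range=(2, 5), m_range=(3, 6)):
    """Brute-force enumeration over every (offset, n, m) triple.

    Returns ``(canonical, near_miss)`` as lists of (start, n, m) tuples;
    near-misses match every fixed position except the axial cysteine.
    """
    canonical, near = [], []
    L = len(sequence)
    for start in range(L):
        for n in range(n_range[0], n_range[1] + 1):
            for m in range(m_range[0], m_range[1] + 1):
                end = start + n + m + 4
                if end >= L:
                    continue
                if sequence[start] != "F":
                    continue
                if sequence[start + n + 1] not in "GA":
                    continue
                if sequence[end] != "G":
                    continue
                axial = sequence[start + n + m + 2]
                if axial == "C":
                    canonical.append((start, n, m))
                else:
                    near.append((start, n, m))
    return canonical, near
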