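"""Dynamic-programming alignment kernels shared by the mapper and the
consensus aligner.

Two cost models live here:

* a linear-gap "read mapping" model (mismatch 2, inserted base 3, deleted
  base 3) applied glocally — the read is aligned end-to-end, the reference
  window is local (free leading/trailing reference bases);
* a unit-mismatch affine-gap model (gap = open + extend x length, defaults
  open 2 / extend 1) applied globally, used to align a whole consensus to
  the reference via unique-k-mer anchor decomposition.

Ops are run-length lists over ``=`` (match), ``X`` (mismatch), ``I`` (base
present in the query/read but not the reference) and ``D`` (reference base
absent from the query/read). Inner loops are vectorised per DP row; the
in-row gap recurrence is closed with a min-plus prefix scan.
"""

from __future__ import annotations

import numpy as np

INF = 10 ** 9

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _rle(ops: list[str]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op in ops:
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + 1)
        else:
            out.append((op, 1))
    return out


# ---------------------------------------------------------------------------
# Glocal linear-gap DP (read mapping cost model)
# ---------------------------------------------------------------------------

def glocal_align(read: str, window: str, mismatch: int = 2,
                 ins_cost: int = 3, del_cost: int = 3):
    """Align ``read`` end-to-end against a local stretch of ``window``.

    Returns ``(cost, start, end, ops)`` where ``start``/``end`` are 0-based
    half-open coordinates of the aligned reference stretch within
    ``window`` and ``ops`` is a run-length op list. ``N`` read bases never
    match (they score as mismatches).
    """
    m, n = len(read), len(window)
    x = encode(read)
    y = encode(window)
    D = np.empty((m + 1, n + 1), dtype=np.int32)
    D[0, :] = 0  # free reference prefix
    col = np.arange(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        sub = np.where((y == x[i - 1]) & (x[i - 1] != ord("N")), 0, mismatch).astype(np.int32)
        diag = D[i - 1, :-1] + sub
        up = D[i - 1, 1:] + ins_cost
        nodel = np.minimum(diag, up)
        first = D[i - 1, 0] + ins_cost  # column 0: read base is an insertion
        # min-plus scan for in-row deletions:
        # D[i,j] = min( nodel[j-1..], min_{j'<=j} cand[j'] + del*(j-j') )
        cand = np.concatenate(([first], nodel))
        shifted = cand - del_cost * col
        scanned = np.minimum.accumulate(shifted)
        D[i, :] = scanned + del_cost * col
    cost_row = D[m, :]
    j_end = int(np.argmin(cost_row))  # leftmost minimum
    cost = int(cost_row[j_end])

    # traceback
    ops_rev: list[str] = []
    i, j = m, j_end
    while i > 0:
        here = D[i, j]
        if j > 0:
            match = y[j - 1] == x[i - 1] and x[i - 1] != ord("N")
            sub = 0 if match else mismatch
            if D[i - 1, j - 1] + sub == here:
                ops_rev.append("=" if match else "X")
                i -= 1
                j -= 1
                continue
        if D[i - 1, j] + ins_cost == here:
            ops_rev.append("I")
            i -= 1
            continue
        # must be deletion
        ops_rev.append("D")
        j -= 1
    start = j
    return cost, start, j_end, _rle(ops_rev[::-1])


# ---------------------------------------------------------------------------
# Global affine-gap DP (consensus-to-reference model)
# ---------------------------------------------------------------------------

def affine_global_align(query: str, ref: str, mismatch: int = 1,
                        gap_open: int = 2, gap_extend: int = 1):
    """Needleman-Wunsch with affine gaps (gap cost = open + extend*len).

    Returns ``(cost, ops)``. Intended for segments up to a few kb; longer
    inputs go through :func:`anchored_global_align`.
    """
    m, n = len(query), len(ref)
    if m == 0:
        return (gap_open + gap_extend * n if n else 0), ([("D", n)] if n else [])
    if n == 0:
        return gap_open + gap_extend * m, [("I", m)]
    x = encode(query)
    y = encode(ref)
    ext = gap_extend
    op_ext = gap_open + gap_extend
    col = np.arange(n + 1, dtype=np.int32)

    D = np.empty((m + 1, n + 1), dtype=np.int32)
    P = np.empty((m + 1, n + 1), dtype=np.int32)  # gap in ref (query base, 'I')
    Q = np.empty((m + 1, n + 1), dtype=np.int32)  # gap in query ('D')
    D[0, 0] = 0
    D[0, 1:] = gap_open + ext * col[1:]
    P[0, :] = INF
    Q[0, 0] = INF
    Q[0, 1:] = D[0, 1:]
    for i in range(1, m + 1):
        P[i, :] = np.minimum(D[i - 1, :] + op_ext, P[i - 1, :] + ext)
        sub = np.where(y == x[i - 1], 0, mismatch).astype(np.int32)
        diag = D[i - 1, :-1] + sub
        A = np.empty(n + 1, dtype=np.int32)
        A[0] = gap_open + ext * i  # leading query gap == P state
        A[0] = min(A[0], P[i, 0])
        A[1:] = np.minimum(diag, P[i, 1:])
        # Q[i,j] = min_{j'<j} A[j'] + open + ext*(j-j')
        shifted = A - ext * col
        run = np.minimum.accumulate(shifted)
        Q[i, 0] = INF
        Q[i, 1:] = run[:-1] + ext * col[1:] + gap_open
        D[i, :] = np.minimum(A, Q[i, :])
    cost = int(D[m, n])

    # Gotoh traceback; ties prefer substitution, then 'D', then 'I'
    ops_rev: list[str] = []
    i, j = m, n
    state = "D"
    while i > 0 or j > 0:
        if state == "D":
            here = D[i, j]
            if i > 0 and j > 0:
                match = x[i - 1] == y[j - 1]
                s = 0 if match else mismatch
                if D[i - 1, j - 1] + s == here:
                    ops_rev.append("=" if match else "X")
                    i -= 1
                    j -= 1
                    continue
            if j > 0 and Q[i, j] == here:
                state = "Q"
            else:
                state = "P"
        elif state == "Q":
            ops_rev.append("D")
            if j > 1 and D[i, j - 1] + op_ext != Q[i, j] and Q[i, j - 1] + ext == Q[i, j]:
                state = "Q"
            else:
                state = "D"
            j -= 1
        else:  # P
            ops_rev.append("I")
            if i > 1 and D[i - 1, j] + op_ext != P[i, j] and P[i - 1, j] + ext == P[i, j]:
                state = "P"
            else:
                state = "D"
            i -= 1
    return cost, _rle(ops_rev[::-1])


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    seen: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if km in dup:
            continue
        if km in seen:
            del seen[km]
            dup.add(km)
        else:
            seen[km] = i
    return seen


def _chain_anchors(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest strictly-increasing chain in both coordinates (patience LIS
    on ref position with query positions pre-sorted)."""
    if not pairs:
        return []
    pairs.sort()
    import bisect

    tails: list[int] = []          # ref positions of chain tails
    tail_idx: list[int] = []
    parent = [-1] * len(pairs)
    for i, (_, r) in enumerate(pairs):
        pos = bisect.bisect_left(tails, r)
        if pos == len(tails):
            tails.append(r)
            tail_idx.append(i)
        else:
            tails[pos] = r
            tail_idx[pos] = i
        parent[i] = tail_idx[pos - 1] if pos > 0 else -1
    chain = []
    i = tail_idx[-1]
    while i >= 0:
        chain.append(pairs[i])
        i = parent[i]
    return chain[::-1]


def anchored_global_align(query: str, ref: str, k: int = 20,
                          mismatch: int = 1, gap_open: int = 2,
                          gap_extend: int = 1, max_segment: int = 20000):
    """Global affine alignment of long, mostly-identical sequences.

    Shared k-mers unique in BOTH sequences are chained co-linearly; exact
    affine DP fills the gaps between consecutive anchors. Equivalent to the
    full DP whenever edits are sparse relative to anchor density.
    """
    if max(len(query), len(ref)) <= 1500:
        return affine_global_align(query, ref, mismatch, gap_open, gap_extend)
    uq = _unique_kmers(query, k)
    ur = _unique_kmers(ref, k)
    pairs = [(qi, ur[km]) for km, qi in uq.items() if km in ur]
    chain = _chain_anchors(pairs)
    # keep non-overlapping anchors
    anchors: list[tuple[int, int]] = []
    q_end = r_end = -1
    for q, r in chain:
        if q >= q_end and r >= r_end:
            anchors.append((q, r))
            q_end, r_end = q + k, r + k
        elif anchors and q - anchors[-1][0] == r - anchors[-1][1]:
            q_end, r_end = q + k, r + k  # same diagonal, extend coverage
            anchors[-1] = anchors[-1]
    if not anchors:
        if max(len(query), len(ref)) > max_segment:
            raise ValueError(
                "sequences too divergent for anchored alignment "
                f"(no shared unique {k}-mers)"
            )
        return affine_global_align(query, ref, mismatch, gap_open, gap_extend)

    total = 0
    ops: list[tuple[str, int]] = []

    def extend_ops(new: list[tuple[str, int]]) -> None:
        for op, ln in new:
            if ops and ops[-1][0] == op:
                ops[-1] = (op, ops[-1][1] + ln)
            else:
                ops.append((op, ln))

    qpos = rpos = 0
    segments = [(q, r) for q, r in anchors] + [(len(query), len(ref))]
    for ai, (qa, ra) in enumerate(segments):
        qseg = query[qpos:qa]
        rseg = ref[rpos:ra]
        if len(qseg) > max_segment or len(rseg) > max_segment:
            raise ValueError("inter-anchor segment too large; inputs diverge")
        if qseg or rseg:
            c, o = affine_global_align(qseg, rseg, mismatch, gap_open, gap_extend)
            total += c
            extend_ops(o)
        if ai < len(segments) - 1:
            # consume the anchor itself, then the run shared on its diagonal
            ext = k
            while (qa + ext < len(query) and ra + ext < len(ref)
                   and query[qa + ext] == ref[ra + ext]
                   and (ai + 1 >= len(segments) - 1 or qa + ext < segments[ai + 1][0])):
                ext += 1
            extend_ops([("=", ext)])
            qpos, rpos = qa + ext, ra + ext
    return total, ops
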