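"""Spliced alignment of a full-length CDS to an oriented genomic region.

The gene-model builder aligns the query CDS end-to-end against the region
(query-global, region-local: unaligned region flanks are free) under a
dynamic program with exon states (match/mismatch, affine gaps) and an
intron state. An intron transition is permitted only when the skipped
region segment begins ``GT`` and ends ``AG`` and its length lies within
configured bounds; its cost is a constant, independent of length within
those bounds (canonical splice sites only — the tool's stated limitation).

The DP is exact and unbanded; rows are vectorized with numpy and the
intron window maximum uses a linear-time running filter, so regions up to
~100 kb stay tractable. All scores are integer-valued, so float32 storage
is exact and the traceback can resolve choices by value comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d

NEG = np.float32(-1e9)


@dataclass
class SpliceParams:
    """Scoring of the exon/intron dynamic program."""

    match: int = 5
    mismatch: int = -4
    gap_open: int = -12
    gap_extend: int = -2
    intron_cost: int = -40
    min_intron: int = 50
    max_intron: int | None = None  # None: bounded only by the region


@dataclass(frozen=True)
class ExonSegment:
    """One exon of the alignment, in oriented region coordinates."""

    t_start: int
    t_end: int
    q_start: int
    q_end: int


@dataclass
class SplicedAlignment:
    segments: list[ExonSegment]
    introns: list[tuple[int, int]]  # region intervals skipped as introns
    score: float
    identity: float
    matches: int
    columns: int


def _trailing_window_max(x: np.ndarray, w: int) -> np.ndarray:
    """T[c] = max(x[c-w+1 .. c]), out-of-range treated as -inf."""
    return maximum_filter1d(x, size=w, mode="constant", cval=NEG,
                            origin=(w - 1) // 2)


def spliced_align(cds: str, region: str, params: SpliceParams | None = None) -> SplicedAlignment | None:
    """Optimal spliced alignment of ``cds`` to ``region``; None if score <= 0."""
    params = params or SpliceParams()
    m, n = len(cds), len(region)
    if m == 0 or n == 0:
        return None
    p = params
    max_i = p.max_intron if p.max_intron is not None else n
    q = np.frombuffer(cds.encode(), dtype=np.uint8)
    r = np.frombuffer(region.encode(), dtype=np.uint8)
    G, T, A = ord("G"), ord("T"), ord("A")
    donor_ok = np.zeros(n, dtype=bool)  # j': last exon base before a GT.. intron
    if n >= 3:
        donor_ok[: n - 2] = (r[1 : n - 1] == G) & (r[2:] == T)
    acceptor_ok = np.zeros(n, dtype=bool)  # j: first exon base after an ..AG intron
    if n >= 3:
        acceptor_ok[2:] = (r[:-2] == A) & (r[1:-1] == G)

    go, ge, ic = np.float32(p.gap_open), np.float32(p.gap_extend), np.float32(p.intron_cost)
    M = np.full((m, n), NEG, dtype=np.float32)
    X = np.full((m, n), NEG, dtype=np.float32)
    ptrM = np.zeros((m, n), dtype=np.int8)  # 0 diag, 1 intron, 2 query start
    w = max_i - p.min_intron + 1
    can_intron = w >= 1 and p.min_intron + 2 <= n

    s_row = np.where(r == q[0], np.float32(p.match), np.float32(p.mismatch))
    M[0] = s_row
    ptrM[0] = 2
    X[0] = go
    Yrow = _y_row(np.maximum(M[0], X[0]), go, ge)
    Hprev = np.maximum(np.maximum(M[0], X[0]), Yrow)

    for i in range(1, m):
        s_row = np.where(r == q[i], np.float32(p.match), np.float32(p.mismatch))
        diag = np.empty(n, dtype=np.float32)
        diag[0] = NEG
        diag[1:] = Hprev[:-1]
        if can_intron:
            wsrc = np.where(donor_ok, M[i - 1], NEG)
            tw = _trailing_window_max(wsrc, w)
            intron = np.full(n, NEG, dtype=np.float32)
            lo = p.min_intron + 1
            if lo < n:
                intron[lo:] = tw[: n - lo] + ic
            intron[~acceptor_ok] = NEG
        else:
            intron = np.full(n, NEG, dtype=np.float32)
        best = np.maximum(diag, intron)
        M[i] = s_row + best
        ptrM[i] = (intron > diag).astype(np.int8)
        X[i] = np.maximum(np.maximum(M[i - 1] + go, Yrow + go), X[i - 1] + ge)
        Yrow = _y_row(np.maximum(M[i], X[i]), go, ge)
        Hprev = np.maximum(np.maximum(M[i], X[i]), Yrow)

    final = np.maximum(M[m - 1], X[m - 1])
    j_end = int(np.argmax(final))
    if final[j_end] <= 0:
        return None
    return _traceback(cds, region, params, max_i, M, X, ptrM, donor_ok, j_end)


def _y_row(mx: np.ndarray, go: np.float32, ge: np.float32) -> np.ndarray:
    """Region-gap state for one row: Y[j] = max_{j'<j} MX[j'] + go + ge*(j-1-j')."""
    n = len(mx)
    y = np.full(n, NEG, dtype=np.float32)
    if n < 2:
        return y
    a = mx + go - ge * np.arange(n, dtype=np.float32)
    cm = np.maximum.accumulate(a)
    y[1:] = cm[:-1] + ge * np.arange(0, n - 1, dtype=np.float32)
    return y


def _y_argmax(mx: np.ndarray, go: float, ge: float, j: int) -> int:
    """Rightmost j' < j achieving the Y[i][j] maximum (shortest gap)."""
    js = np.arange(j)
    vals = mx[:j] + go + ge * (j - 1 - js)
    return int(j - 1 - np.argmax(vals[::-1]))


def _traceback(cds, region, p: SpliceParams, max_i, M, X, ptrM, donor_ok, j_end):
    m, n = M.shape
    go, ge = float(p.gap_open), float(p.gap_extend)
    eps = 1e-3
    ops: list[tuple] = []  # backwards
    i, j = m - 1, j_end
    state = "M" if M[i, j] >= X[i, j] else "X"
    score = float(max(M[i, j], X[i, j]))
    y_cache: dict[int, np.ndarray] = {}

    def yrow(row: int) -> np.ndarray:
        if row not in y_cache:
            y_cache[row] = _y_row(np.maximum(M[row], X[row]), np.float32(go), np.float32(ge))
        return y_cache[row]

    while True:
        if state == "M":
            ops.append(("M", i, j))
            if ptrM[i, j] == 2:
                break
            if ptrM[i, j] == 1:
                lo = max(0, j - 1 - max_i)
                hi = j - 1 - p.min_intron
                window = M[i - 1, lo : hi + 1].copy()
                window[~donor_ok[lo : hi + 1]] = NEG
                jp = lo + int(len(window) - 1 - np.argmax(window[::-1]))  # rightmost max
                ops.append(("I", jp + 1, j))
                i, j, state = i - 1, jp, "M"
            else:
                pv = (M[i - 1, j - 1], X[i - 1, j - 1], yrow(i - 1)[j - 1])
                state = "MXY"[int(np.argmax(pv))]
                if state == "Y":
                    i, j = i - 1, j - 1
                    jp = _y_argmax(np.maximum(M[i], X[i]), go, ge, j + 1)
                    ops.append(("Y", jp + 1, j + 1))
                    state = "M" if M[i, jp] >= X[i, jp] else "X"
                    j = jp
                else:
                    i, j = i - 1, j - 1
        elif state == "X":
            ops.append(("X", i))
            if i == 0:
                break
            xv = float(X[i, j])
            if abs(xv - (float(M[i - 1, j]) + go)) < eps:
                state = "M"
            elif abs(xv - (float(X[i - 1, j]) + ge)) < eps:
                state = "X"
            else:
                # from Y: resolve the region gap, then continue from its source
                i -= 1
                jp = _y_argmax(np.maximum(M[i], X[i]), go, ge, j + 1)
                ops.append(("Y", jp + 1, j + 1))
                state = "M" if M[i, jp] >= X[i, jp] else "X"
                j = jp
                continue
            i -= 1
        else:  # pragma: no cover - defensive
            raise AssertionError("unreachable traceback state")

    ops.reverse()
    return _assemble(cds, region, ops, score)


def _assemble(cds, region, ops, score) -> SplicedAlignment:
    segments: list[ExonSegment] = []
    introns: list[tuple[int, int]] = []
    matches = columns = 0
    t_lo = t_hi = q_lo = q_hi = None

    def close():
        nonlocal t_lo, t_hi, q_lo, q_hi
        if t_lo is not None:
            segments.append(ExonSegment(t_lo, t_hi, q_lo, q_hi))
        t_lo = t_hi = q_lo = q_hi = None

    for op in ops:
        if op[0] == "M":
            _, i, j = op
            matches += cds[i] == region[j]
            columns += 1
            t_lo = j if t_lo is None else t_lo
            t_hi = j + 1
            q_lo = i if q_lo is None else q_lo
            q_hi = i + 1
        elif op[0] == "X":
            columns += 1
            if q_lo is None:
                q_lo = op[1]
            q_hi = op[1] + 1
        elif op[0] == "Y":
            _, a, b = op
            columns += b - a
            t_lo = a if t_lo is None else t_lo
            t_hi = b
        elif op[0] == "I":
            close()
            introns.append((op[1], op[2]))
    close()
    identity = matches / columns if columns else 0.0
    return SplicedAlignment(segments=segments, introns=introns, score=score,
                            identity=identity, matches=matches, columns=columns)
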