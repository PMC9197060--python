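"""Numba kernels: banded affine-gap DP, minimizer extraction, anchor chaining.

All kernels operate on uint8 base-code arrays (see :mod:`bacfinish.seq`).
A gap of length L costs ``gap_open + gap_ext * L``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int64(-(10**15))

# traceback pointer bit layout (one uint8 per cell):
#   bits 0-1: H source (0 diag, 1 from E/deletion state, 2 from F/insertion state)
#   bit  2  : E opened from H (else extended from E)
#   bit  3  : F opened from H (else extended from F)


@njit(cache=True, nogil=True)
def gotoh_banded(q, t, dlo, dhi, match, mismatch, gap_open, gap_ext, extend_mode):
    """Banded global (or origin-anchored extension) alignment.

    The band is the diagonal range d = j - i in [dlo, dhi] (i over query,
    j over target, both 0-based DP indices).

    Returns (score, end_i, end_j, ops, touched_edge) where ops is the
    per-column operation array in alignment order (0=M, 1=I/query-only,
    2=D/target-only) and touched_edge reports whether the optimal path hit
    the band boundary (signal to widen).
    """
    n = q.size
    m = t.size
    W = dhi - dlo + 1
    ptr = np.zeros((n + 1, W), dtype=np.uint8)
    h_prev = np.full(W, NEG, dtype=np.int64)
    f_prev = np.full(W, NEG, dtype=np.int64)
    h_cur = np.full(W, NEG, dtype=np.int64)
    e_cur = np.full(W, NEG, dtype=np.int64)
    f_cur = np.full(W, NEG, dtype=np.int64)

    # row i = 0: leading deletions
    for d in range(max(dlo, 0), dhi + 1):
        j = d
        if j > m:
            break
        c = d - dlo
        if j == 0:
            h_prev[c] = 0
        else:
            h_prev[c] = -(gap_open + gap_ext * j)
            ptr[0, c] = 1  # came through E
    best = NEG
    best_i = 0
    best_j = 0
    if extend_mode and 0 >= dlo and 0 <= dhi:
        best = 0
    for i in range(1, n + 1):
        for c in range(W):
            h_cur[c] = NEG
            e_cur[c] = NEG
            f_cur[c] = NEG
        qi = q[i - 1]
        jlo = i + dlo
        if jlo < 0:
            jlo = 0
        jhi = i + dhi
        if jhi > m:
            jhi = m
        for j in range(jlo, jhi + 1):
            d = j - i
            c = d - dlo
            p = np.uint8(0)
            if j == 0:
                diag = NEG
            else:
                hp = h_prev[c] if (c >= 0) else NEG
                if hp <= NEG:
                    diag = NEG
                else:
                    s = match if qi == t[j - 1] else -mismatch
                    diag = hp + s
            # E: gap in query (consume target), from (i, j-1) = column c-1
            e_val = NEG
            if c - 1 >= 0 and j >= 1:
                open_sc = h_cur[c - 1] - (gap_open + gap_ext)
                ext_sc = e_cur[c - 1] - gap_ext
                if open_sc >= ext_sc:
                    e_val = open_sc
                    p |= np.uint8(4)
                else:
                    e_val = ext_sc
            # F: gap in target (consume query), from (i-1, j) = column c+1 of prev row
            f_val = NEG
            if c + 1 < W:
                open_sc = h_prev[c + 1] - (gap_open + gap_ext)
                ext_sc = f_prev[c + 1] - gap_ext
                if open_sc >= ext_sc:
                    f_val = open_sc
                    p |= np.uint8(8)
                else:
                    f_val = ext_sc
            e_cur[c] = e_val
            f_cur[c] = f_val
            h = diag
            src = np.uint8(0)
            if e_val > h:
                h = e_val
                src = np.uint8(1)
            if f_val > h:
                h = f_val
                src = np.uint8(2)
            h_cur[c] = h
            ptr[i, c] = p | src
            if extend_mode and h > best:
                best = h
                best_i = i
                best_j = j
        tmp = h_prev
        h_prev = h_cur
        h_cur = tmp
        tmp = f_prev
        f_prev = f_cur
        f_cur = tmp
    if not extend_mode:
        best_i = n
        best_j = m
        d = m - n
        if d < dlo or d > dhi:
            return NEG, 0, 0, np.zeros(0, dtype=np.uint8), True
        best = h_prev[d - dlo]

    # traceback
    ops = np.empty(n + m + 2, dtype=np.uint8)
    nops = 0
    i = best_i
    j = best_j
    state = 0  # 0=H 1=E 2=F
    touched = False
    while i > 0 or j > 0:
        d = j - i
        if d <= dlo or d >= dhi:
            touched = True
        if i == 0:
            ops[nops] = 2
            nops += 1
            j -= 1
            continue
        if j == 0:
            ops[nops] = 1
            nops += 1
            i -= 1
            continue
        p = ptr[i, d - dlo]
        if state == 0:
            src = p & np.uint8(3)
            if src == 0:
                ops[nops] = 0
                nops += 1
                i -= 1
                j -= 1
            elif src == 1:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[nops] = 2
            nops += 1
            opened = (p & np.uint8(4)) != 0
            j -= 1
            if opened:
                state = 0
        else:
            ops[nops] = 1
            nops += 1
            opened = (p & np.uint8(8)) != 0
            i -= 1
            if opened:
                state = 0
    return best, best_i, best_j, ops[:nops][::-1].copy(), touched


@njit(cache=True, nogil=True)
def stitch_segments(q, t, aq, at, k, band_base, match, mismatch, gap_open, gap_ext):
    """Stitch a chain into one expanded op array: exact k-mer anchors as
    match runs, banded global DP between consecutive anchors.

    Returns (ops, q_end, t_end, low_confidence): ops covers the region from
    the first anchor start to (q_end, t_end); anchors that overlap
    inconsistently with the emitted prefix are dropped.
    """
    cap = q.size + t.size + 32
    out = np.empty(cap, dtype=np.uint8)
    n = 0
    low_conf = False
    q_end = aq[0] + k
    t_end = at[0] + k
    for _ in range(k):
        out[n] = 0
        n += 1
    for i in range(1, aq.size):
        bq = aq[i]
        bt = at[i]
        if bq + k <= q_end or bt + k <= t_end:
            continue
        if (bt - bq) == (t_end - q_end) and bq < q_end:
            ext = bq + k - q_end
            for _ in range(ext):
                out[n] = 0
                n += 1
            q_end += ext
            t_end += ext
            continue
        if bq < q_end or bt < t_end:
            continue
        gqn = bq - q_end
        gtn = bt - t_end
        if gqn == 0 and gtn > 0:
            for _ in range(gtn):
                out[n] = 2
                n += 1
        elif gtn == 0 and gqn > 0:
            for _ in range(gqn):
                out[n] = 1
                n += 1
        elif gqn > 0 and gtn > 0:
            gq = q[q_end:bq]
            gt = t[t_end:bt]
            mx = gqn if gqn > gtn else gtn
            df = gqn - gtn
            if df < 0:
                df = -df
            pad = mx // 4 + 8
            if pad < 16:
                pad = 16
            if pad > band_base:
                pad = band_base
            b = df + pad
            dlo = (gtn - gqn if gtn < gqn else 0) - b
            dhi = (gtn - gqn if gtn > gqn else 0) + b
            sc, ei, ej, seg, touched = gotoh_banded(
                gq, gt, dlo, dhi, match, mismatch, gap_open, gap_ext, False
            )
            if touched and b < mx:
                b2 = 4 * b if 4 * b < mx else mx
                dlo = -gqn
                dhi = gtn
                if b2 < mx:
                    dlo = (gtn - gqn if gtn < gqn else 0) - b2
                    dhi = (gtn - gqn if gtn > gqn else 0) + b2
                sc, ei, ej, seg, touched = gotoh_banded(
                    gq, gt, dlo, dhi, match, mismatch, gap_open, gap_ext, False
                )
                if touched:
                    low_conf = True
            for x in range(seg.size):
                out[n] = seg[x]
                n += 1
        for _ in range(k):
            out[n] = 0
            n += 1
        q_end = bq + k
        t_end = bt + k
    return out[:n].copy(), q_end, t_end, low_conf


@njit(cache=True, nogil=True)
def left_align_path(ops, q, t, q0, t0):
    """Left-align indels in an expanded alignment path (0=M, 1=I, 2=D, 3=S).

    Equivalent-score gap placements (classically ambiguous inside
    homopolymer runs and other repeats) are normalized to their leftmost
    position, so that independent alignments of different reads agree on
    where an indel sits. Score and match statuses are preserved.
    """
    out = ops.copy()
    n = out.size
    changed = True
    passes = 0
    while changed and passes < 4:
        changed = False
        passes += 1
        qi = q0
        ti = t0
        i = 0
        while i < n:
            op = out[i]
            if op == 0:
                qi += 1
                ti += 1
                i += 1
                continue
            if op == 3:
                qi += 1
                i += 1
                continue
            j = i
            while j < n and out[j] == op:
                j += 1
            L = j - i
            shift = 0
            pi = i - 1
            if op == 1:
                a = qi
                while pi >= 0 and out[pi] == 0 and a - 1 >= 0 and q[a - 1] == q[a + L - 1]:
                    pi -= 1
                    a -= 1
                    shift += 1
            else:
                a = ti
                while pi >= 0 and out[pi] == 0 and a - 1 >= 0 and t[a - 1] == t[a + L - 1]:
                    pi -= 1
                    a -= 1
                    shift += 1
            if shift > 0:
                for x in range(L):
                    out[i - shift + x] = op
                for x in range(shift):
                    out[i - shift + L + x] = 0
                changed = True
            if op == 1:
                qi += L
            else:
                ti += L
            i = j
    return out


@njit(cache=True, nogil=True)
def minimizer_scan(codes, k, w):
    """(w,k)-minimizers of a code array with an invertible multiply-shift hash.

    Returns (hashes, positions, strands) where strand 1 means the canonical
    (hash-minimal) orientation of the k-mer is its reverse complement.
    K-mers containing N are skipped.
    """
    n = codes.size
    if n < k:
        return (
            np.zeros(0, dtype=np.uint64),
            np.zeros(0, dtype=np.int64),
            np.zeros(0, dtype=np.uint8),
        )
    nk = n - k + 1
    hashes = np.empty(nk, dtype=np.uint64)
    strands = np.empty(nk, dtype=np.uint8)
    valid = np.empty(nk, dtype=np.uint8)
    mask = np.uint64((1 << (2 * k)) - 1) if 2 * k < 64 else np.uint64(0xFFFFFFFFFFFFFFFF)
    shift = np.uint64(2 * (k - 1))
    fwd = np.uint64(0)
    rev = np.uint64(0)
    last_n = -1
    c1 = np.uint64(0xBF58476D1CE4E5B9)
    c2 = np.uint64(0x94D049BB133111EB)
    for i in range(n):
        b = codes[i]
        if b > 3:
            last_n = i
            fwd = np.uint64(0)
            rev = np.uint64(0)
        else:
            fwd = ((fwd << np.uint64(2)) | np.uint64(b)) & mask
            rev = (rev >> np.uint64(2)) | (np.uint64(3 - b) << shift)
        pos = i - k + 1
        if pos >= 0:
            if last_n >= pos:
                valid[pos] = 0
                hashes[pos] = np.uint64(0xFFFFFFFFFFFFFFFF)
                strands[pos] = 0
            else:
                valid[pos] = 1
                x = fwd
                y = rev
                # splitmix64 finalizer
                x = (x ^ (x >> np.uint64(30))) * c1
                x = (x ^ (x >> np.uint64(27))) * c2
                x = x ^ (x >> np.uint64(31))
                y = (y ^ (y >> np.uint64(30))) * c1
                y = (y ^ (y >> np.uint64(27))) * c2
                y = y ^ (y >> np.uint64(31))
                if x <= y:
                    hashes[pos] = x
                    strands[pos] = 0
                else:
                    hashes[pos] = y
                    strands[pos] = 1
    # window minima
    out_h = np.empty(nk, dtype=np.uint64)
    out_p = np.empty(nk, dtype=np.int64)
    out_s = np.empty(nk, dtype=np.uint8)
    nout = 0
    last_pos = -1
    nwin = nk - w + 1
    if nwin < 1:
        nwin = 1 if nk >= 1 else 0
        w = nk
    for s in range(nwin):
        mpos = -1
        mh = np.uint64(0xFFFFFFFFFFFFFFFF)
        for j in range(s, s + w):
            if valid[j] and hashes[j] < mh:
                mh = hashes[j]
                mpos = j
        if mpos >= 0 and mpos != last_pos:
            out_h[nout] = mh
            out_p[nout] = mpos
            out_s[nout] = strands[mpos]
            nout += 1
            last_pos = mpos
    return out_h[:nout].copy(), out_p[:nout].copy(), out_s[:nout].copy()


@njit(cache=True, nogil=True)
def chain_dp(qpos, tpos, k, max_gap, lookback):
    """Co-linear chaining scores by DP with bounded predecessor lookback.

    Anchors must be sorted by (tpos, qpos). Returns (score, parent) arrays;
    score approximates matched bases minus gap penalties.
    """
    n = qpos.size
    f = np.empty(n, dtype=np.int64)
    parent = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        f[i] = k
        lo = i - lookback
        if lo < 0:
            lo = 0
        for j in range(i - 1, lo - 1, -1):
            qg = qpos[i] - qpos[j]
            tg = tpos[i] - tpos[j]
            if qg <= 0 or tg <= 0:
                continue
            if qg > max_gap or tg > max_gap:
                continue
            dd = qg - tg
            if dd < 0:
                dd = -dd
            mlen = k
            if qg < mlen:
                mlen = qg
            if tg < mlen:
                mlen = tg
            gap_cost = dd // 2 + (1 if dd > 0 else 0)
            sc = f[j] + mlen - gap_cost
            if sc > f[i]:
                f[i] = sc
                parent[i] = j
    return f, parent


@njit(cache=True, nogil=True)
def pileup_accumulate(counts, ops, counts_ops, tstart, qcodes, qstart, weight):
    """Accumulate one alignment into a (5, L) pileup count matrix.

    counts rows: A, C, G, T, deletion. Insertions are handled by the caller.
    Returns nothing; mutates counts in place.
    """
    ti = tstart
    qi = qstart
    for e in range(ops.size):
        op = ops[e]
        ln = counts_ops[e]
        if op == 0:  # M
            for x in range(ln):
                b = qcodes[qi + x]
                if b < 4:
                    counts[b, ti + x] += weight
            ti += ln
            qi += ln
        elif op == 1:  # I (query only)
            qi += ln
        elif op == 2:  # D (target only)
            for x in range(ln):
                counts[4, ti + x] += weight
            ti += ln
        else:  # S
            qi += ln
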