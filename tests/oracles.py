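"""Independent reference implementations used to check the package.

Everything here is deliberately naive (quadratic DP, exhaustive search,
direct definitions) and shares no code with the implementation under test.
"""

from __future__ import annotations

from itertools import combinations

NEG = -(10**9)


def gotoh_score(a: str, b: str, match=1, mismatch=-2, gap_open=-4, gap_ext=-2) -> int:
    """Quadratic affine-gap global alignment score. A gap of length L costs
    |gap_open| + |gap_ext| * L."""
    n, m = len(a), len(b)
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    H[0][0] = 0
    for j in range(1, m + 1):
        E[0][j] = gap_open + gap_ext * j
        H[0][j] = E[0][j]
    for i in range(1, n + 1):
        F[i][0] = gap_open + gap_ext * i
        H[i][0] = F[i][0]
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open + gap_ext, E[i][j - 1] + gap_ext)
            F[i][j] = max(H[i - 1][j] + gap_open + gap_ext, F[i - 1][j] + gap_ext)
            d = H[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            H[i][j] = max(d, E[i][j], F[i][j])
    return H[n][m]


def global_identity(a: str, b: str) -> float:
    """Identity (matches / alignment columns) of an optimal unit-cost
    alignment, by quadratic edit-distance DP with traceback counts."""
    n, m = len(a), len(b)
    # dp over (cost); recover matches greedily via dp of max matches among
    # min-cost alignments
    INF = 10**9
    cost = [[INF] * (m + 1) for _ in range(n + 1)]
    match_cnt = [[-1] * (m + 1) for _ in range(n + 1)]
    cost[0][0] = 0
    match_cnt[0][0] = 0
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            best = (INF, -1)
            if i > 0 and j > 0:
                c = cost[i - 1][j - 1] + (0 if a[i - 1] == b[j - 1] else 1)
                mm = match_cnt[i - 1][j - 1] + (1 if a[i - 1] == b[j - 1] else 0)
                best = min(best, (c, -mm))
            if i > 0:
                best = min(best, (cost[i - 1][j] + 1, -match_cnt[i - 1][j]))
            if j > 0:
                best = min(best, (cost[i][j - 1] + 1, -match_cnt[i][j - 1]))
            cost[i][j] = best[0]
            match_cnt[i][j] = -best[1]
    # columns = matches + mismatches + gaps; reconstruct from cost/matches
    # mismatches + gaps = cost; columns = matches + cost
    matches = match_cnt[n][m]
    return matches / (matches + cost[n][m]) if (matches + cost[n][m]) else 0.0


def window_minimizers(hashes: list[int], w: int) -> set[int]:
    """Positions selected by direct enumeration of window minima."""
    out = set()
    n = len(hashes)
    for s in range(max(1, n - w + 1)):
        win = hashes[s : s + w]
        out.add(s + win.index(min(win)))
    return out


def best_chain_exhaustive(anchors, k: int, max_gap: int):
    """Best co-linear chain by exhaustive subset search (<= 20 anchors).

    Scoring mirrors the implementation: each anchor adds min(k, q-gap,
    t-gap) matched bases; a diagonal difference dd costs dd//2 + 1.
    """
    n = len(anchors)
    best = (0, ())
    for r in range(1, n + 1):
        for sub in combinations(range(n), r):
            pts = [anchors[i] for i in sub]
            ok = True
            score = k
            for (q1, t1), (q2, t2) in zip(pts, pts[1:]):
                qg, tg = q2 - q1, t2 - t1
                if qg <= 0 or tg <= 0 or qg > max_gap or tg > max_gap:
                    ok = False
                    break
                dd = abs(qg - tg)
                score += min(k, qg, tg) - (dd // 2 + (1 if dd else 0))
            if ok and score > best[0]:
                best = (score, sub)
    return best


def n50(lengths) -> int:
    """Direct definition scan: largest L with >= half of all bases in
    reads of length >= L."""
    total = sum(lengths)
    best = 0
    for L in sorted(set(lengths)):
        if sum(x for x in lengths if x >= L) >= total / 2:
            best = max(best, L)
    return best
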