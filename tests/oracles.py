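"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive and kept free of imports from the
package's computational paths (pure python / tiny numpy only).
"""

from __future__ import annotations

import statistics

import numpy as np

NEG = float("-inf")


def sw_affine_oracle(a: str, b: str, match=2, mismatch=-3, gap_open=-5, gap_extend=-2):
    """Plain O(nm) affine-gap Smith-Waterman with traceback.

    A gap of length L costs gap_open + (L-1)*gap_extend. Returns
    (score, identical_positions, span_on_a, span_on_b) for one optimal
    local alignment.
    """
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap consuming a
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap consuming b
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] + gap_open, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + gap_open, F[i][j - 1] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best, bi, bj = H[i][j], i, j
    if best == 0:
        return 0.0, 0, 0, 0
    i, j = bi, bj
    end_i, end_j = bi, bj
    ident = 0
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i][j] == 0:
                break
            s = match if a[i - 1] == b[j - 1] else mismatch
            if H[i][j] == H[i - 1][j - 1] + s:
                if a[i - 1] == b[j - 1]:
                    ident += 1
                i -= 1
                j -= 1
            elif H[i][j] == E[i][j]:
                state = "E"
            elif H[i][j] == F[i][j]:
                state = "F"
            else:
                break
        elif state == "E":
            if E[i][j] == E[i - 1][j] + gap_extend:
                i -= 1
            else:
                i -= 1
                state = "H"
        else:
            if F[i][j] == F[i][j - 1] + gap_extend:
                j -= 1
            else:
                j -= 1
                state = "H"
    return best, ident, end_i - i, end_j - j


def identity_oracle(a: str, b: str) -> tuple[float, float]:
    """(identity, coverage_of_shorter) per the shorter-sequence convention."""
    _, ident, span_a, span_b = sw_affine_oracle(a, b)
    shorter = min(len(a), len(b))
    span = span_a if len(a) <= len(b) else span_b
    return ident / shorter, span / shorter


def greedy_cluster_oracle(sequences: dict[str, str], identity_threshold: float,
                          min_coverage: float) -> list[list[str]]:
    """Independent replay of greedy first-fit clustering using the DP oracle."""
    order = sorted(sequences, key=lambda sid: (-len(sequences[sid]), sid))
    reps: list[str] = []
    clusters: list[list[str]] = []
    for sid in order:
        placed = False
        for idx, rep in enumerate(reps):
            ident, cov = identity_oracle(sequences[sid], sequences[rep])
            if ident >= identity_threshold and cov >= min_coverage:
                clusters[idx].append(sid)
                placed = True
                break
        if not placed:
            reps.append(sid)
            clusters.append([sid])
    return clusters


def modified_zscore_oracle(values):
    """Literal re-derivation of the robust outlier score."""
    xs = list(map(float, values))
    med = statistics.median(xs)
    absdev = [abs(x - med) for x in xs]
    mad = statistics.median(absdev)
    if mad > 0:
        return [0.6745 * (x - med) / mad for x in xs]
    meanad = sum(absdev) / len(absdev)
    if meanad > 0:
        return [(x - med) / (1.253314 * meanad) for x in xs]
    return [0.0 for _ in xs]


def triangle_contains_oracle(px, py, tri) -> bool:
    """Half-plane sign test for a triangle, boundary inclusive."""
    (x1, y1), (x2, y2), (x3, y3) = tri

    def side(ax, ay, bx, by):
        return (bx - ax) * (py - ay) - (by - ay) * (px - ax)

    d1 = side(x1, y1, x2, y2)
    d2 = side(x2, y2, x3, y3)
    d3 = side(x3, y3, x1, y1)
    has_neg = (d1 < 0) or (d2 < 0) or (d3 < 0)
    has_pos = (d1 > 0) or (d2 > 0) or (d3 > 0)
    return not (has_neg and has_pos)


def per_base_mean_depth_oracle(windows, length) -> float:
    """Expand windowed depth to per-base and average over the contig."""
    depth = np.zeros(int(length))
    for start, end, d in windows:
        depth[start:end] += d
    return float(depth.mean())


def gc_fraction_oracle(seq: str) -> float:
    s = seq.upper()
    gc = sum(1 for c in s if c in "GC")
    denom = sum(1 for c in s if c in "ACGT")
    return 100.0 * gc / denom if denom else float("nan")
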