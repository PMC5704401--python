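"""Independent brute-force oracles the tests compare the package against.

Everything here is deliberately naive (double loops, pure-python run-length
scans) and shares no code with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np


def mi_bits_oracle(x, y, edges) -> float:
    """Histogram mutual information in bits, by explicit bin assignment."""
    nb = len(edges) - 1
    joint = np.zeros((nb, nb))

    def bin_of(v: float) -> int:
        for b in range(nb):
            if edges[b] <= v < edges[b + 1]:
                return b
        return nb - 1

    for xi, yi in zip(x, y):
        joint[bin_of(xi), bin_of(yi)] += 1.0
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mi = 0.0
    for a in range(nb):
        for b in range(nb):
            if joint[a, b] > 0:
                mi += joint[a, b] * math.log2(joint[a, b] / (px[a] * py[b]))
    return mi


def ami_profile_oracle(values, max_lag, n_bins) -> np.ndarray:
    lo, hi = float(np.min(values)), float(np.max(values))
    edges = np.linspace(lo, hi, n_bins + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)
    out = []
    n = len(values)
    for tau in range(max_lag + 1):
        out.append(mi_bits_oracle(values[: n - tau], values[tau:], edges))
    return np.array(out)


def embed_oracle(values, m, d) -> np.ndarray:
    n_states = len(values) - (m - 1) * d
    return np.array(
        [[values[i + k * d] for k in range(m)] for i in range(n_states)]
    )


def fnn_fractions_oracle(values, d, max_dim, rtol, atol) -> list[float]:
    """All-pairs false-nearest-neighbor fractions, maximum norm."""
    sigma = float(np.std(values))
    fracs = []
    for m in range(1, max_dim + 1):
        n_lift = len(values) - m * d
        if n_lift < 2:
            break
        emb = embed_oracle(values, m, d)[:n_lift]
        extra = np.array([values[i + m * d] for i in range(n_lift)])
        n_false = 0
        for i in range(n_lift):
            best_j, best_dist = -1, np.inf
            for j in range(n_lift):
                if j == i:
                    continue
                dist = max(abs(emb[i, k] - emb[j, k]) for k in range(m))
                if dist < best_dist:
                    best_dist, best_j = dist, j
            sep = abs(extra[i] - extra[best_j])
            ratio = sep / best_dist if best_dist > 0 else (0.0 if sep == 0 else np.inf)
            lifted = max(best_dist, sep)
            if ratio > rtol or lifted > atol * sigma:
                n_false += 1
        fracs.append(n_false / n_lift)
    return fracs


def _runs(bits) -> dict[int, int]:
    counts: dict[int, int] = {}
    run = 0
    for b in list(bits) + [0]:
        if b:
            run += 1
        elif run:
            counts[run] = counts.get(run, 0) + 1
            run = 0
    return counts


def naive_rqa(states, eps, theiler, lmin=2, vmin=2):
    """Full naive RQA: Θ(ε − d_ij) double loop + run-length scans.

    Returns (rr, det, lam, diag_counts, vert_counts); diagonal lines counted
    once per triangle, verticals over every column, matching the package's
    documented conventions.
    """
    states = np.asarray(states, dtype=float)
    if states.ndim == 1:
        states = states[:, None]
    n = len(states)
    R = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            dist = max(abs(states[i, k] - states[j, k]) for k in range(states.shape[1]))
            R[i, j] = 1 if dist <= eps else 0
    unmasked = [(i, j) for i in range(n) for j in range(n) if abs(i - j) >= theiler]
    points = sum(R[i, j] for i, j in unmasked)
    rr = points / len(unmasked)

    diag_counts: dict[int, int] = {}
    offsets = range(max(theiler, 1), n)
    if theiler == 0:
        for l, c in _runs([R[i, i] for i in range(n)]).items():
            diag_counts[l] = diag_counts.get(l, 0) + c
    for k in offsets:
        line = [R[i, i + k] for i in range(n - k)]
        for l, c in _runs(line).items():
            diag_counts[l] = diag_counts.get(l, 0) + c

    vert_counts: dict[int, int] = {}
    for j in range(n):
        col = [R[i, j] if abs(i - j) >= theiler else 0 for i in range(n)]
        for l, c in _runs(col).items():
            vert_counts[l] = vert_counts.get(l, 0) + c

    def frac(counts, mmin):
        denom = sum(l * c for l, c in counts.items())
        if denom == 0:
            return 0.0
        return sum(l * c for l, c in counts.items() if l >= mmin) / denom

    return rr, frac(diag_counts, lmin), frac(vert_counts, vmin), diag_counts, vert_counts


def rmsd_grid_oracle(ref, mobile, n_grid=24, n_refine=6) -> float:
    """Minimum RMSD over an exhaustive Euler-angle grid with local refinement.

    A coarse zyz-Euler grid is scanned exhaustively, then the grid is zoomed
    around the best angles a few times; converges well below 1e-3 for small
    molecules while staying independent of any SVD-based solution.
    """
    ref = ref - ref.mean(axis=0)
    mobile = mobile - mobile.mean(axis=0)

    def rmsd_at(a, b, c):
        ca, sa = np.cos(a), np.sin(a)
        cb, sb = np.cos(b), np.sin(b)
        cc, sc = np.cos(c), np.sin(c)
        Rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
        Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
        Rz2 = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
        diff = mobile @ (Rz1 @ Ry @ Rz2).T - ref
        return np.sqrt((diff**2).sum() / len(ref))

    centers = (np.pi, np.pi / 2, np.pi)
    spans = (np.pi, np.pi / 2, np.pi)  # half-widths of the search box
    best_val, best_angles = np.inf, centers
    for _ in range(n_refine):
        ca_, cb_, cc_ = best_angles if best_val < np.inf else centers
        sa_, sb_, sc_ = spans
        for a in np.linspace(ca_ - sa_, ca_ + sa_, n_grid):
            for b in np.linspace(cb_ - sb_, cb_ + sb_, n_grid):
                for c in np.linspace(cc_ - sc_, cc_ + sc_, n_grid):
                    val = rmsd_at(a, b, c)
                    if val < best_val:
                        best_val, best_angles = val, (a, b, c)
        spans = tuple(s * 3.0 / n_grid for s in spans)
    return best_val
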