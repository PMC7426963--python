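"""Independent oracle implementations used to cross-check the package.

Everything here is deliberately naive (explicit loops, exhaustive search,
closed-form trigonometry) and shares no code with the implementation under
test.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_rmsd(coords_a, coords_b) -> float:
    """Direct double-loop evaluation of the root-mean-square deviation."""
    n = len(coords_a)
    total = 0.0
    for i in range(n):
        for k in range(3):
            d = coords_a[i][k] - coords_b[i][k]
            total += d * d
    return math.sqrt(total / n)


def brute_force_per_residue_rmsd(coords_a, coords_b, owners) -> dict[int, float]:
    """Per-residue RMSD: atoms grouped by their owner residue index."""
    groups: dict[int, list[int]] = {}
    for pos, owner in enumerate(owners):
        groups.setdefault(owner, []).append(pos)
    out = {}
    for owner, positions in groups.items():
        total = 0.0
        for p in positions:
            for k in range(3):
                d = coords_a[p][k] - coords_b[p][k]
                total += d * d
        out[owner] = math.sqrt(total / len(positions))
    return out


def grid_search_rmsd(mobile, ref, step_deg=1.0, chunk=1500) -> float:
    """Exhaustive rigid-fit RMSD over an axis-angle rotation grid.

    Axes on a (theta, phi) spherical grid with ``step_deg`` spacing and
    rotation angles 0..180 degrees in the same steps; both point sets are
    mean-centred first (the optimal translation superposes the centroids).
    Lower-bounds the true optimum from above within the grid error.
    """
    p = np.asarray(mobile, float)
    q = np.asarray(ref, float)
    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)
    thetas = np.radians(np.arange(0.0, 180.0 + step_deg / 2, step_deg))
    phis = np.radians(np.arange(0.0, 360.0, step_deg))
    alphas = np.radians(np.arange(0.0, 180.0 + step_deg / 2, step_deg))
    tt, pp = np.meshgrid(thetas, phis, indexing="ij")
    axes = np.stack(
        [np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp), np.cos(tt)], axis=-1
    ).reshape(-1, 3)
    ca, sa = np.cos(alphas), np.sin(alphas)
    best = np.inf
    for i in range(0, axes.shape[0], chunk):
        k = axes[i : i + chunk]                          # (m, 3)
        cross = np.cross(k[:, None, :], p[None, :, :])   # (m, n, 3)
        kdp = k @ p.T                                    # (m, n)
        rot = (
            ca[None, :, None, None] * p[None, None, :, :]
            + sa[None, :, None, None] * cross[:, None, :, :]
            + (1 - ca)[None, :, None, None]
            * (k[:, None, None, :] * kdp[:, None, :, None])
        )                                                # (m, a, n, 3)
        d2 = ((rot - q[None, None, :, :]) ** 2).sum(-1).mean(-1)
        best = min(best, float(d2.min()))
    return math.sqrt(best)


def angle_by_law_of_cosines(a, b, c) -> float:
    """Angle at vertex ``b`` in degrees, from the three side lengths only."""
    ab = math.dist(a, b)
    cb = math.dist(c, b)
    ac = math.dist(a, c)
    cosang = (ab * ab + cb * cb - ac * ac) / (2 * ab * cb)
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def enumerate_alignment_identity(a: str, b: str) -> float:
    """Brute-force global alignment identity for short sequences.

    Enumerates every alignment, scores match=1 / mismatch=0 / gap=0,
    keeps the maximum match count and, among those, the fewest columns;
    returns matches / columns.  Exponential — only for len <= ~7.
    """
    best: list[tuple[int, int]] = [(-1, 10**9)]   # (matches, columns)

    def rec(i: int, j: int, matches: int, cols: int) -> None:
        if i == len(a) and j == len(b):
            cand = (matches, cols)
            top = best[0]
            if cand[0] > top[0] or (cand[0] == top[0] and cand[1] < top[1]):
                best[0] = cand
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, matches + (a[i] == b[j]), cols + 1)
        if i < len(a):
            rec(i + 1, j, matches, cols + 1)
        if j < len(b):
            rec(i, j + 1, matches, cols + 1)

    rec(0, 0, 0, 0)
    matches, cols = best[0]
    return matches / cols
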