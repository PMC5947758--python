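"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they verify: the superposition
oracle uses the quaternion characteristic-polynomial method instead of SVD,
and the alignment oracle is a direct Gotoh dynamic program.
"""

from __future__ import annotations

import numpy as np

NEG = float("-inf")


def quaternion_rmsd(fixed: np.ndarray, moving: np.ndarray) -> float:
    """Minimal least-squares r.m.s.d. via the Horn quaternion method."""
    fixed = np.asarray(fixed, float)
    moving = np.asarray(moving, float)
    q = fixed - fixed.mean(axis=0)
    p = moving - moving.mean(axis=0)
    s = p.T @ q
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    g = float(np.sum(p * p) + np.sum(q * q))
    n = len(fixed)
    return float(np.sqrt(max(0.0, g - 2.0 * lam) / n))


def gotoh_identity(a: str, b: str,
                   match: float = 1.0, mismatch: float = 0.0,
                   gap_open: float = -10.0, gap_extend: float = -0.5) -> float:
    """Identity under optimal global affine-gap alignment with free end gaps.

    Cells carry (score, matches) compared lexicographically, so among all
    optimal-score alignments the one with the most identities is reported.
    The first gap character costs ``gap_open``, each further one
    ``gap_extend``.  Identity = matches / len(shorter sequence).
    """
    n, m = len(a), len(b)
    worst = (NEG, 0)

    def plus(cell, ds, dm=0):
        if cell[0] == NEG:
            return worst
        return (cell[0] + ds, cell[1] + dm)

    # M: a[i] aligned to b[j]; X: gap in b (a consumed); Y: gap in a
    M = [[worst] * (m + 1) for _ in range(n + 1)]
    X = [[worst] * (m + 1) for _ in range(n + 1)]
    Y = [[worst] * (m + 1) for _ in range(n + 1)]
    M[0][0] = (0.0, 0)
    for i in range(1, n + 1):
        X[i][0] = (0.0, 0)  # leading end gap in b: free
    for j in range(1, m + 1):
        Y[0][j] = (0.0, 0)  # leading end gap in a: free
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            hit = 1 if a[i - 1] == b[j - 1] else 0
            M[i][j] = max(plus(M[i - 1][j - 1], sub, hit),
                          plus(X[i - 1][j - 1], sub, hit),
                          plus(Y[i - 1][j - 1], sub, hit))
            open_x = gap_open if j < m else 0.0     # trailing end gaps free
            ext_x = gap_extend if j < m else 0.0
            X[i][j] = max(plus(M[i - 1][j], open_x),
                          plus(X[i - 1][j], ext_x),
                          plus(Y[i - 1][j], open_x))
            open_y = gap_open if i < n else 0.0
            ext_y = gap_extend if i < n else 0.0
            Y[i][j] = max(plus(M[i][j - 1], open_y),
                          plus(X[i][j - 1], open_y),
                          plus(Y[i][j - 1], ext_y))
    best = max(M[n][m], X[n][m], Y[n][m])
    return best[1] / min(n, m)


def transitive_closure_clusters(identity_matrix: np.ndarray, threshold: float) -> list[set[int]]:
    """Connected components of the 'identity > threshold' graph (BFS)."""
    n = len(identity_matrix)
    seen = [False] * n
    clusters = []
    for start in range(n):
        if seen[start]:
            continue
        group = {start}
        queue = [start]
        seen[start] = True
        while queue:
            i = queue.pop()
            for j in range(n):
                if not seen[j] and identity_matrix[i][j] > threshold:
                    seen[j] = True
                    group.add(j)
                    queue.append(j)
        clusters.append(group)
    return clusters


def seeded_clusters(items, mid_tol, ext_tol):
    """Exhaustive re-application of the seed-relative clustering rule.

    ``items`` are (id, score, midpoint, extent) tuples; returns a list of
    member-id frozensets in cluster-creation order.
    """
    remaining = sorted(items, key=lambda t: (-t[1], t[0]))
    out = []
    while remaining:
        seed = remaining[0]
        members = [t for t in remaining
                   if abs(t[2] - seed[2]) <= mid_tol and abs(t[3] - seed[3]) <= ext_tol]
        out.append(frozenset(t[0] for t in members))
        chosen = {t[0] for t in members}
        remaining = [t for t in remaining if t[0] not in chosen]
    return out
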