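"""Independent brute-force oracles used to check the metric search paths.

Kept deliberately separate from the package: superpositions are fit on
*every* residue subset of size >= 3 by direct enumeration and the score
is evaluated over all corresponded residues, so the oracle's maximum is
the exact optimum of the subset-superposition family that TM-score and
GDT-TS approximate.
"""
import itertools

import numpy as np


def _kabsch(P, Q):
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return R, qc - R @ pc


def subset_superposition_optima(P, Q, d0, cutoffs=(1.0, 2.0, 4.0, 8.0)):
    """Exact optima of the TM sum and per-cutoff inclusion counts.

    Returns ``(best_tm_sum, {cutoff: best_count})`` over superpositions
    fit on every residue subset of size >= 3.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    m = len(P)
    best_tm = -np.inf
    best_counts = {c: 0 for c in cutoffs}
    for size in range(3, m + 1):
        for subset in itertools.combinations(range(m), size):
            idx = list(subset)
            Ps = P[idx]
            if np.linalg.matrix_rank(Ps - Ps.mean(axis=0), tol=1e-8) < 2:
                continue
            R, t = _kabsch(Ps, Q[idx])
            d = np.linalg.norm(P @ R.T + t - Q, axis=1)
            best_tm = max(best_tm, float(np.sum(1.0 / (1.0 + (d / d0) ** 2))))
            for c in cutoffs:
                n_in = int(np.sum(d < c))
                if n_in > best_counts[c]:
                    best_counts[c] = n_in
    return best_tm, best_counts


def euler_grid_rmsd(P, Q, step_deg, z_only=False):
    """Best RMSD over a rigid-rotation grid (translation optimal per angle).

    Returns ``(best_rmsd, best_rotation)``.  ``z_only`` restricts the grid
    to rotations about the z axis.
    """
    from scipy.spatial.transform import Rotation

    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    if z_only:
        angles = [(a, 0.0, 0.0) for a in np.arange(0.0, 360.0, step_deg)]
    else:
        angles = [
            (a, b, c)
            for a in np.arange(0.0, 360.0, step_deg)
            for b in np.arange(0.0, 180.0 + step_deg, step_deg)
            for c in np.arange(0.0, 360.0, step_deg)
        ]
    best = (np.inf, None)
    for zyz in angles:
        R = Rotation.from_euler("zyz", zyz, degrees=True).as_matrix()
        rmsd = float(np.sqrt(np.mean(np.sum((Pc @ R.T - Qc) ** 2, axis=1))))
        if rmsd < best[0]:
            best = (rmsd, R)
    return best
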