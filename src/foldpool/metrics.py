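"""Structural similarity between CA-trace models of the same target.

Implements least-squares (Kabsch) superposition, TM-score, GDT-TS and a
superposition-free CA-lDDT, plus the pool-wide pairwise similarity matrix
that consensus model ranking consumes.

TM-score and GDT-TS both require maximising a superposition-dependent
objective; exact maximisation is combinatorial, so both use the standard
heuristic of seeding from contiguous fragments and iteratively
re-superposing on the residues currently within a distance cutoff.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .structio import StructureModel

__all__ = [
    "Superposition",
    "InsufficientCorrespondenceError",
    "DegenerateCoordinatesError",
    "correspond",
    "kabsch_superpose",
    "tm_d0",
    "tm_score",
    "gdt_ts",
    "lddt_ca",
    "similarity_matrix",
    "GDT_CUTOFFS",
    "LDDT_THRESHOLDS",
]

GDT_CUTOFFS = (1.0, 2.0, 4.0, 8.0)
LDDT_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)
LDDT_INCLUSION_RADIUS = 15.0
LDDT_MIN_SEPARATION = 2
MAX_REFINE_ROUNDS = 20


class InsufficientCorrespondenceError(ValueError):
    """Fewer than the required number of shared residues between two models."""


class DegenerateCoordinatesError(ValueError):
    """Point set is (near-)collinear; superposition is ill-defined."""


@dataclass(frozen=True)
class Superposition:
    """Rigid transform ``x -> rotation @ x + translation`` with its fit RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation determinant must be +1 (no reflection)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def correspond(
    model_a: StructureModel,
    model_b: StructureModel,
    min_pairs: int = 3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pair residues of two models of the same target by residue number.

    Returns ``(P, Q, residue_numbers)`` where ``P``/``Q`` are the M x 3
    coordinate tables of ``model_a``/``model_b`` over the shared residue
    numbers, in increasing residue-number order.
    """
    if model_a.target_id != model_b.target_id:
        raise ValueError(
            f"models belong to different targets: "
            f"{model_a.target_id!r} vs {model_b.target_id!r}"
        )
    shared = np.intersect1d(model_a.residue_numbers, model_b.residue_numbers)
    if len(shared) < min_pairs:
        raise InsufficientCorrespondenceError(
            f"only {len(shared)} shared residues (need >= {min_pairs})"
        )
    ia = np.searchsorted(model_a.residue_numbers, shared)
    ib = np.searchsorted(model_b.residue_numbers, shared)
    return model_a.ca_coords[ia], model_b.ca_coords[ib], shared


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of P onto Q (reflection excluded)."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must both be M x 3")
    m = len(P)
    if m < 3:
        raise InsufficientCorrespondenceError("need at least 3 point pairs")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    Pc = P - pc
    Qc = Q - qc
    # collinear (rank < 2) point sets leave a rotation axis unconstrained
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2 or np.linalg.matrix_rank(Qc, tol=1e-8) < 2:
        raise DegenerateCoordinatesError("collinear point set")
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((Pc @ R.T - Qc) ** 2, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_pairs=m)


def tm_d0(l_ref: int) -> float:
    """Length-dependent TM-score distance scale, floored at 0.5 A."""
    return float(max(1.24 * np.cbrt(l_ref - 15.0) - 1.8, 0.5))


def _seed_slices(m: int) -> list[tuple[int, int]]:
    """Contiguous seed fragments of lengths {M, M/2, M/4, 4} at all offsets."""
    lengths = {m, m // 2, m // 4, 4}
    lengths = sorted({l for l in lengths if 3 <= l <= m}, reverse=True)
    if not lengths:
        lengths = [m]
    out = []
    for l in lengths:
        for off in range(m - l + 1):
            out.append((off, off + l))
    return out


def _refine_from_seed(P, Q, start, stop, cutoffs, objective):
    """Iterative inclusion refinement from one seed fragment.

    ``objective(distances) -> (value, included_mask)`` evaluates the score of
    the current superposition over all pairs and proposes the next inclusion
    set.  Returns the best objective value reached from this seed.
    """
    best = -np.inf
    for cutoff in cutoffs:
        try:
            sup = kabsch_superpose(P[start:stop], Q[start:stop])
        except DegenerateCoordinatesError:
            continue
        prev: np.ndarray | None = None
        for _ in range(MAX_REFINE_ROUNDS):
            d = np.linalg.norm(sup.apply(P) - Q, axis=1)
            value, _ = objective(d)
            if value > best:
                best = value
            inc = d < cutoff
            widened = cutoff
            while inc.sum() < 3:
                widened += 0.5
                inc = d < widened
            if prev is not None and np.array_equal(inc, prev):
                break
            prev = inc
            try:
                sup = kabsch_superpose(P[inc], Q[inc])
            except DegenerateCoordinatesError:
                break
    return best


# Below this correspondence size the superposition objective is maximised
# exactly by enumerating all residue subsets of size >= 3 (2^M fits); above
# it the fragment-seeded iterative refinement takes over.
EXACT_SEARCH_MAX_PAIRS = 12


def _enumerate_subset_distances(P: np.ndarray, Q: np.ndarray):
    """Distances of all pairs under the superposition fit on every subset."""
    import itertools

    m = len(P)
    for size in range(3, m + 1):
        for subset in itertools.combinations(range(m), size):
            idx = list(subset)
            try:
                sup = kabsch_superpose(P[idx], Q[idx])
            except DegenerateCoordinatesError:
                continue
            yield np.linalg.norm(sup.apply(P) - Q, axis=1)


def _tm_sum_max(P: np.ndarray, Q: np.ndarray, d0: float) -> float:
    """Max over superpositions of sum_i 1/(1+(d_i/d0)^2).

    Exact (subset enumeration) for small correspondences, fragment-seeded
    refinement otherwise.
    """
    if len(P) <= EXACT_SEARCH_MAX_PAIRS:
        return max(
            float(np.sum(1.0 / (1.0 + (d / d0) ** 2)))
            for d in _enumerate_subset_distances(P, Q)
        )
    cutoffs = sorted({max(d0, 0.5), max(1.5 * d0, 1.0), 8.0})

    def objective(d):
        return float(np.sum(1.0 / (1.0 + (d / d0) ** 2))), None

    best = -np.inf
    for start, stop in _seed_slices(len(P)):
        v = _refine_from_seed(P, Q, start, stop, cutoffs, objective)
        if v > best:
            best = v
    return best


def tm_score(
    model: StructureModel,
    reference: StructureModel,
    l_ref: int | None = None,
) -> float:
    """TM-score of ``model`` against ``reference``.

    Normalised by the reference chain length (or an explicit ``l_ref``,
    used by :func:`similarity_matrix` to normalise both orientations by the
    target length).  Values above 0.5 conventionally indicate the correct
    fold.
    """
    P, Q, _ = correspond(model, reference)
    L = reference.n_residues if l_ref is None else int(l_ref)
    d0 = tm_d0(L)
    return float(_tm_sum_max(P, Q, d0) / L)


def gdt_ts(model: StructureModel, reference: StructureModel) -> float:
    """GDT-TS: mean over 1/2/4/8 A cutoffs of the maximal superposable fraction.

    The fraction denominator is the number of corresponded residues; the
    superposition search is the same fragment seeding used by
    :func:`tm_score` with the cutoff itself as the inclusion threshold.
    """
    P, Q, _ = correspond(model, reference)
    m = len(P)
    if m <= EXACT_SEARCH_MAX_PAIRS:
        counts = {c: 0 for c in GDT_CUTOFFS}
        for d in _enumerate_subset_distances(P, Q):
            for c in GDT_CUTOFFS:
                n_in = int(np.sum(d < c))
                if n_in > counts[c]:
                    counts[c] = n_in
        return float(np.mean([counts[c] / m for c in GDT_CUTOFFS]))
    seeds = _seed_slices(m)
    fractions = []
    for cutoff in GDT_CUTOFFS:

        def objective(d, _c=cutoff):
            return int(np.sum(d < _c)), None

        best = 0
        for start, stop in seeds:
            v = _refine_from_seed(P, Q, start, stop, (cutoff,), objective)
            if v > best:
                best = v
        fractions.append(best / m)
    return float(np.mean(fractions))


def lddt_ca(model: StructureModel, reference: StructureModel) -> float:
    """Superposition-free CA-lDDT.

    Over residue pairs with sequence separation >= 2 and reference CA
    distance < 15 A, the fraction whose model-vs-reference distance
    difference falls below each of the 0.5/1/2/4 A thresholds, averaged
    over thresholds.
    """
    P, Q, resnums = correspond(model, reference, min_pairs=2)
    sep = np.abs(resnums[:, None] - resnums[None, :])
    dref = np.linalg.norm(Q[:, None, :] - Q[None, :, :], axis=-1)
    dmod = np.linalg.norm(P[:, None, :] - P[None, :, :], axis=-1)
    iu = np.triu_indices(len(P), k=1)
    mask = (sep[iu] >= LDDT_MIN_SEPARATION) & (dref[iu] < LDDT_INCLUSION_RADIUS)
    if not np.any(mask):
        raise InsufficientCorrespondenceError(
            "no residue pairs qualify for lDDT (separation >= 2, d_ref < 15 A)"
        )
    diff = np.abs(dmod[iu][mask] - dref[iu][mask])
    fracs = [float(np.mean(diff < t)) for t in LDDT_THRESHOLDS]
    return float(np.mean(fracs))


def similarity_matrix(pool, metric: str = "tm_score") -> pd.DataFrame:
    """Symmetric pairwise similarity matrix over a model pool.

    ``pool`` is anything with a ``.models`` sequence of
    :class:`StructureModel` (or such a sequence directly).  Entry (i, j)
    is the mean of the two orientations of the chosen metric; the diagonal
    is 1.  For ``tm_score`` both orientations are normalised by the target
    length (the longest chain in the pool) so the matrix is symmetric by
    construction.
    """
    models: Sequence[StructureModel] = getattr(pool, "models", pool)
    n = len(models)
    if n < 2:
        raise ValueError("similarity matrix needs at least 2 models")
    ids = [m.model_id for m in models]
    mat = np.eye(n)
    if metric == "tm_score":
        l_target = max(m.n_residues for m in models)

        def pair(a, b):
            return 0.5 * (
                tm_score(a, b, l_ref=l_target) + tm_score(b, a, l_ref=l_target)
            )
    elif metric == "gdt_ts":

        def pair(a, b):
            return 0.5 * (gdt_ts(a, b) + gdt_ts(b, a))
    else:
        raise ValueError(f"unknown similarity metric {metric!r}")
    for i in range(n):
        for j in range(i + 1, n):
            v = pair(models[i], models[j])
            mat[i, j] = mat[j, i] = v
    return pd.DataFrame(mat, index=ids, columns=ids)
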