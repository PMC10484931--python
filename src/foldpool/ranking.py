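"""Quality-assessment scores for model pools and their evaluation.

Four complementary scoring schemes rank the models of one target:

* global pLDDT — the predictor's self-estimate (single-model QA);
* APOLLO score — a model's mean pairwise structural similarity to every
  other model in the pool (consensus QA);
* their plain average (pLDDT rescaled to [0, 1]);
* the pLDDT-weighted pairwise similarity
  ``score_j = sum_{i != j} Sim_ij * pLDDT_i / (n - 1)``,
  where the weight is the *other* model's pLDDT.

Also provides the pool-diversity statistic PSS, selector evaluation
(ranking loss, per-target Pearson correlation) and the weighted z-score
combiner used for CASP-style official rankings.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import similarity_matrix
from .structio import global_plddt

__all__ = [
    "apollo_score",
    "apollo_plddt_weight",
    "apollo_plddt_avg",
    "pss",
    "rank_models",
    "ranking_loss",
    "per_target_correlation",
    "zscore_combine",
    "CASP15_GROUPS",
    "compute_qa_scores",
    "UndefinedCorrelationError",
]

# CASP15 official combination: four groups of component z-scores at
# weights 1/16, 1/12 and 1/6.  The component metrics themselves are
# supplied externally.
CASP15_GROUPS: tuple[tuple[float, tuple[str, ...]], ...] = (
    (1.0 / 16.0, ("lddt", "cadaa", "sg", "sidechain")),
    (1.0 / 12.0, ("molprb_clash", "backbone", "dipdiff")),
    (1.0 / 6.0, ("gdt_ha", "ase", "rellg")),
)


class UndefinedCorrelationError(ValueError):
    """Pearson correlation requested on a constant vector."""


def _as_square(sim) -> np.ndarray:
    A = np.asarray(sim, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("similarity table must be square")
    if A.shape[0] < 2:
        raise ValueError("need at least 2 models")
    return A


def apollo_score(sim) -> np.ndarray:
    """Mean pairwise similarity of each model to all other models."""
    A = _as_square(sim)
    n = A.shape[0]
    return (A.sum(axis=1) - np.diag(A)) / (n - 1)


def apollo_plddt_weight(sim, plddt) -> np.ndarray:
    """pLDDT-weighted pairwise similarity, on the 0-100-ish input scale."""
    A = _as_square(sim)
    p = np.asarray(plddt, dtype=float)
    n = A.shape[0]
    if p.shape != (n,):
        raise ValueError("plddt length must match similarity table size")
    return (A @ p - np.diag(A) * p) / (n - 1)


def apollo_plddt_avg(apollo, plddt) -> np.ndarray:
    """Average of APOLLO score and pLDDT/100, both on the [0, 1] scale."""
    a = np.asarray(apollo, dtype=float)
    p = np.asarray(plddt, dtype=float)
    if a.shape != p.shape:
        raise ValueError("apollo and plddt must have equal length")
    return (a + p / 100.0) / 2.0


def pss(sim) -> float:
    """Average pairwise similarity score of a pool (mean off-diagonal entry).

    High PSS means the pool converged on one conformation; low PSS flags
    conformational diversity.
    """
    A = _as_square(sim)
    n = A.shape[0]
    return float((A.sum() - np.trace(A)) / (n * (n - 1)))


def rank_models(scores, model_ids: Sequence[str]) -> list[str]:
    """Model ids in descending score order; ties broken lexicographically."""
    s = np.asarray(scores, dtype=float)
    if len(s) != len(model_ids):
        raise ValueError("scores and model_ids must have equal length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    order = sorted(zip(model_ids, s), key=lambda t: (-t[1], t[0]))
    return [mid for mid, _ in order]


def ranking_loss(true_scores: Mapping[str, float], selected_top1: str) -> float:
    """Quality gap between the pool's best model and the selected top-1.

    ``true_scores`` maps model id to true quality (e.g. GDT-TS against the
    native).  Zero iff the selector picked a true-best model.
    """
    if selected_top1 not in true_scores:
        raise KeyError(f"unknown model id {selected_top1!r}")
    values = np.asarray(list(true_scores.values()), dtype=float)
    return float(values.max() - true_scores[selected_top1])


def per_target_correlation(predicted, true) -> float:
    """Pearson correlation between predicted quality and true scores."""
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(true, dtype=float)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError("inputs must be 1-D of equal length")
    if len(p) < 3:
        raise ValueError("need at least 3 models")
    if np.ptp(p) == 0 or np.ptp(t) == 0:
        raise UndefinedCorrelationError("correlation undefined on constant input")
    return float(stats.pearsonr(p, t).statistic)


def zscore_combine(
    score_table: pd.DataFrame,
    groups: Sequence[tuple[float, Sequence[str]]] = CASP15_GROUPS,
) -> pd.Series:
    """Weighted sum of per-component z-scores across models.

    z-scores use the population (n) standard deviation; a constant
    component contributes z = 0 for every model.
    """
    if score_table.empty:
        raise ValueError("empty score table")
    combined = pd.Series(0.0, index=score_table.index)
    for weight, components in groups:
        for comp in components:
            if comp not in score_table.columns:
                raise KeyError(f"component {comp!r} missing from score table")
            col = score_table[comp].astype(float)
            sd = col.std(ddof=0)
            z = (col - col.mean()) / sd if sd > 0 else col * 0.0
            combined = combined + weight * z
    return combined


def compute_qa_scores(pool, sim: pd.DataFrame | None = None) -> pd.DataFrame:
    """All four QA scores for a pool, indexed by model id.

    Columns: ``plddt_global`` (0-100), ``apollo`` (0-1),
    ``apollo_plddt_avg`` (0-1), ``apollo_plddt_weight`` (0-100-ish).
    """
    models = getattr(pool, "models", pool)
    if sim is None:
        sim = similarity_matrix(models)
    ids = [m.model_id for m in models]
    sim = sim.loc[ids, ids]
    plddt = np.array([global_plddt(m) for m in models])
    apollo = apollo_score(sim.to_numpy())
    return pd.DataFrame(
        {
            "plddt_global": plddt,
            "apollo": apollo,
            "apollo_plddt_avg": apollo_plddt_avg(apollo, plddt),
            "apollo_plddt_weight": apollo_plddt_weight(sim.to_numpy(), plddt),
        },
        index=pd.Index(ids, name="model_id"),
    )
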