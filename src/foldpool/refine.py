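"""Iterative structure-alignment-based model refinement control.

The refinement loop: search the current model against a structure
database, convert the alignments into MSA rows, deepen and
redundancy-filter the MSA, re-fold with the augmented MSA and the
top-ranked hits as templates, and accept the best new model iff its
global pLDDT strictly exceeds the input's.  The loop stops after at most
five iterations or at the first non-improving one; the highest-pLDDT
model generated anywhere in the loop is the output.

The folding and search engines are pluggable callables so the controller
can be exercised offline with deterministic synthetic backends.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol, Sequence

from .msa import Msa
from .structio import StructureModel, global_plddt
from .structsearch import StructureHit, augment_msa, select_templates

logger = logging.getLogger(__name__)

__all__ = [
    "SearchBackend",
    "FoldingBackend",
    "RefinementIteration",
    "RefinementTrace",
    "BackendError",
    "run_refinement",
    "refine_topk",
    "MAX_REFINEMENT_ITERATIONS",
]

MAX_REFINEMENT_ITERATIONS = 5
MODELS_PER_ITERATION = 5


class SearchBackend(Protocol):
    """Structure search: model in, alignment hits out."""

    def __call__(self, model: StructureModel) -> list[StructureHit]: ...


class FoldingBackend(Protocol):
    """Folding engine: (MSA, templates, n_models) in, scored models out."""

    def __call__(
        self, msa: Msa, templates: Sequence[StructureHit], n_models: int
    ) -> list[StructureModel]: ...


class BackendError(RuntimeError):
    """A pluggable backend failed; carries the iteration index as context."""


@dataclass(frozen=True)
class RefinementIteration:
    index: int                       # 1-based
    n_hits: int
    msa_depth_after_filter: int
    best_new_plddt: Optional[float]  # None when no models were generated
    input_plddt: float
    accepted: bool


@dataclass(frozen=True)
class RefinementTrace:
    iterations: tuple[RefinementIteration, ...]
    final_model_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "iterations", tuple(self.iterations))
        if len(self.iterations) > MAX_REFINEMENT_ITERATIONS:
            raise ValueError("trace exceeds the iteration cap")
        accepted_inputs = [
            it.input_plddt for it in self.iterations if it.accepted
        ]
        if any(b <= a for a, b in zip(accepted_inputs, accepted_inputs[1:])):
            raise ValueError("accepted-iteration input pLDDT must strictly increase")


def _best_model(models: Sequence[StructureModel]) -> StructureModel:
    return min(models, key=lambda m: (-global_plddt(m), m.model_id))


def run_refinement(
    initial_model: StructureModel,
    initial_msa: Msa,
    search: SearchBackend,
    fold: FoldingBackend,
    max_iters: int = MAX_REFINEMENT_ITERATIONS,
    models_per_iter: int = MODELS_PER_ITERATION,
) -> tuple[StructureModel, RefinementTrace]:
    """Run the iterative refinement loop from one starting model.

    MSA augmentation is cumulative: each iteration deepens the previous
    iteration's filtered MSA, so structure-alignment rows accumulate
    across accepted iterations.  Each iteration searches with the current
    accepted model, not the original.

    Returns the highest-pLDDT model generated across all iterations
    (tagged ``refined``) and the per-iteration trace.  If the first
    search returns no hits, the initial model is returned unchanged with
    a single non-accepted trace record.
    """
    max_iters = min(max_iters, MAX_REFINEMENT_ITERATIONS)
    current_model = initial_model
    current_msa = initial_msa
    iterations: list[RefinementIteration] = []
    generated: list[StructureModel] = []

    for index in range(1, max_iters + 1):
        input_plddt = global_plddt(current_model)
        try:
            hits = search(current_model)
        except Exception as exc:
            raise BackendError(f"search backend failed at iteration {index}") from exc
        if not hits:
            if index == 1:
                iterations.append(
                    RefinementIteration(
                        index=1,
                        n_hits=0,
                        msa_depth_after_filter=len(current_msa.rows),
                        best_new_plddt=None,
                        input_plddt=input_plddt,
                        accepted=False,
                    )
                )
                trace = RefinementTrace(
                    iterations=tuple(iterations),
                    final_model_id=initial_model.model_id,
                )
                return initial_model, trace
            break

        augmented = augment_msa(current_msa, hits)
        templates = select_templates(hits)
        try:
            models = fold(augmented, templates, models_per_iter)
        except Exception as exc:
            raise BackendError(f"folding backend failed at iteration {index}") from exc
        if not models:
            raise BackendError(f"folding backend returned no models at iteration {index}")
        best = _best_model(models)
        best_plddt = global_plddt(best)
        accepted = best_plddt > input_plddt
        iterations.append(
            RefinementIteration(
                index=index,
                n_hits=len(hits),
                msa_depth_after_filter=len(augmented.rows),
                best_new_plddt=best_plddt,
                input_plddt=input_plddt,
                accepted=accepted,
            )
        )
        generated.extend(models)
        if not accepted:
            break
        current_model = best
        current_msa = augmented

    if generated:
        output = _best_model(generated).with_(source_tag="refined")
    else:
        output = initial_model
    trace = RefinementTrace(
        iterations=tuple(iterations), final_model_id=output.model_id
    )
    return output, trace


def refine_topk(
    top5: Sequence[StructureModel],
    msas: Sequence[Msa],
    search: SearchBackend,
    fold: FoldingBackend,
    **kwargs,
) -> list[StructureModel]:
    """Refine five selected models and keep the best five of the pool of ten.

    Each input is refined independently; the five refined outputs are
    pooled with the five unrefined inputs and the five with the highest
    global pLDDT are returned (ties by model id).  A refinement that
    produced nothing falls back to its unrefined input.
    """
    if len(top5) != 5 or len(msas) != 5:
        raise ValueError("refine_topk requires exactly 5 models with their MSAs")
    pool: dict[str, StructureModel] = {m.model_id: m for m in top5}
    for model, m in zip(top5, msas):
        refined, _ = run_refinement(model, m, search, fold, **kwargs)
        pool.setdefault(refined.model_id, refined)
    ordered = sorted(pool.values(), key=lambda m: (-global_plddt(m), m.model_id))
    return ordered[:5]
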