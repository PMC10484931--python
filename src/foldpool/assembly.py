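"""Integration of assembly-derived monomer models into the model pool.

A monomer target that is a chain of a protein assembly folds in the
context of its interaction partners, so a tertiary model cut out of a
predicted quaternary structure is usually better than one predicted from
the single chain alone.  This module extracts such chains, merges them
into the target's model pool, composes submissions that prefer
assembly-derived models for the top slots, and grafts separately-folded
regions into full-length models of large multi-domain proteins.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import kabsch_superpose
from .structio import StructureModel, read_model

logger = logging.getLogger(__name__)

__all__ = [
    "ModelPool",
    "extract_chain",
    "integrate_pool",
    "compose_submission",
    "graft_region",
    "ASSEMBLY_TAG",
]

ASSEMBLY_TAG = "assembly_extracted"


@dataclass
class ModelPool:
    """All models for one target, with optional cached similarity/QA tables.

    Pools mixing monomer-predictor and assembly-predictor confidences are
    flagged via :attr:`mixed_plddt_provenance`; the scales are not fully
    comparable, and no rescaling is applied.
    """

    target_id: str
    models: list[StructureModel] = field(default_factory=list)
    similarity: Optional[pd.DataFrame] = None
    qa_scores: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        ids = [m.model_id for m in self.models]
        if len(set(ids)) != len(ids):
            raise ValueError("model ids in a pool must be unique")
        for m in self.models:
            if m.target_id != self.target_id:
                raise ValueError(
                    f"model {m.model_id!r} belongs to target {m.target_id!r}, "
                    f"not {self.target_id!r}"
                )

    def __len__(self) -> int:
        return len(self.models)

    @property
    def model_ids(self) -> list[str]:
        return [m.model_id for m in self.models]

    @property
    def mixed_plddt_provenance(self) -> bool:
        tags = {m.source_tag == ASSEMBLY_TAG for m in self.models}
        return tags == {True, False}

    def get(self, model_id: str) -> StructureModel:
        for m in self.models:
            if m.model_id == model_id:
                return m
        raise KeyError(model_id)


def extract_chain(
    assembly_path: str | Path,
    chain_id: str,
    target_id: Optional[str] = None,
    model_id: Optional[str] = None,
) -> StructureModel:
    """Cut one chain out of a multi-chain PDB model.

    Coordinates are kept exactly as they are in the assembly (no
    re-centering); pLDDT comes from the B-factor column.  The result is
    tagged ``assembly_extracted``.
    """
    assembly_path = Path(assembly_path)
    model = read_model(assembly_path, chain=chain_id)
    return model.with_(
        model_id=model_id or f"{assembly_path.stem}_{chain_id}",
        target_id=target_id or model.target_id,
        source_tag=ASSEMBLY_TAG,
    )


def integrate_pool(
    pool: ModelPool,
    assembly_paths: Sequence[str | Path],
    chain_id: str,
) -> ModelPool:
    """Add chain extractions from assembly models to a pool.

    Returns a new pool; similarity/QA caches are invalidated because the
    pool contents changed.  Colliding model ids are an error.
    """
    extracted = [
        extract_chain(p, chain_id, target_id=pool.target_id)
        for p in assembly_paths
    ]
    existing = set(pool.model_ids)
    for m in extracted:
        if m.model_id in existing:
            raise ValueError(f"model id collision: {m.model_id!r}")
        existing.add(m.model_id)
    return ModelPool(target_id=pool.target_id, models=list(pool.models) + extracted)


def compose_submission(
    pool: ModelPool,
    scores,
    n: int = 5,
    assembly_slots: int = 4,
) -> list[StructureModel]:
    """Order a submission of ``n`` models with assembly-derived preference.

    The first ``min(assembly_slots, #assembly-derived)`` slots are filled
    by the top-ranked assembly-derived models, the remaining slots by the
    top-ranked single-chain models.  Assembly-derived models never occupy
    more than ``assembly_slots`` slots, so the submission may be shorter
    than ``n`` when the pool has too few single-chain models.  ``scores``
    maps model id to ranking score (dict or Series).
    """
    if len(pool) == 0:
        raise ValueError("empty pool")
    if isinstance(scores, pd.Series):
        scores = scores.to_dict()
    missing = set(pool.model_ids) - set(scores)
    if missing:
        raise KeyError(f"scores missing for models: {sorted(missing)}")

    def ranked(models):
        return sorted(models, key=lambda m: (-scores[m.model_id], m.model_id))

    assembly = ranked([m for m in pool.models if m.source_tag == ASSEMBLY_TAG])
    single = ranked([m for m in pool.models if m.source_tag != ASSEMBLY_TAG])

    n = min(n, len(pool))
    chosen = assembly[: min(assembly_slots, len(assembly), n)]
    for m in single:
        if len(chosen) >= n:
            break
        chosen.append(m)
    return chosen


def graft_region(
    full_model: StructureModel,
    region_model: StructureModel,
    span: tuple[int, int],
    flank: int = 10,
) -> StructureModel:
    """Replace a residue span of a full-length model with a region model.

    The region model is superposed onto the full model over up to
    ``flank`` residues on each side of the span that exist in both models
    (falling back to superposition over the span itself when no flanks are
    shared), then the span's coordinates and pLDDT are taken from the
    transformed region model.  Residues outside the span are untouched.
    """
    start, end = span
    if start > end:
        raise ValueError("span start must not exceed span end")
    full_nums = full_model.residue_numbers
    region_nums = region_model.residue_numbers
    span_nums = np.arange(start, end + 1)
    span_in_full = np.isin(span_nums, full_nums)
    if not span_in_full.all():
        raise ValueError("span contains residues absent from the full model")
    if not np.isin(span_nums, region_nums).all():
        raise ValueError("region model does not cover the whole span")

    full_set = set(full_nums.tolist())
    region_set = set(region_nums.tolist())
    flank_nums = [
        r for r in list(range(start - flank, start)) + list(range(end + 1, end + flank + 1))
        if r in full_set and r in region_set
    ]
    if len(flank_nums) >= 3:
        anchor = np.array(flank_nums)
    else:
        anchor = span_nums  # no usable flanks: anchor on the span itself

    ra = np.searchsorted(region_nums, anchor)
    fa = np.searchsorted(full_nums, anchor)
    sup = kabsch_superpose(region_model.ca_coords[ra], full_model.ca_coords[fa])
    moved = sup.apply(region_model.ca_coords)

    new_coords = full_model.ca_coords.copy()
    new_plddt = full_model.plddt.copy()
    fi = np.searchsorted(full_nums, span_nums)
    ri = np.searchsorted(region_nums, span_nums)
    new_coords[fi] = moved[ri]
    new_plddt[fi] = region_model.plddt[ri]
    return full_model.with_(
        ca_coords=new_coords, plddt=new_plddt, source_tag="grafted"
    )
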