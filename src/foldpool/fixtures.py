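"""Deterministic synthetic inputs: structures, pools, MSAs, hits, backends.

Everything every other module consumes can be generated here without any
download: ideal helical CA traces with known geometry, Gaussian-perturbed
decoy pools with known ground-truth quality ordering, synthetic A3M
alignments, structure-search hit tables derived from donor models, and a
scripted mock folding backend for exercising the refinement controller.

The confidence proxy ``pLDDT = 100 * exp(-sigma)`` ties a decoy's
self-estimate monotonically to its true perturbation scale so that
QA-recovery tests have an unambiguous ground truth.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .assembly import ModelPool
from .msa import Msa
from .structio import StructureModel, write_model
from .structsearch import (
    StructureHit,
    TemplateRecord,
    write_hits,
    write_templates,
)

__all__ = [
    "make_helix",
    "perturb_model",
    "make_pool",
    "true_sigma",
    "make_msa",
    "make_hits_from_models",
    "MockFoldingSchedule",
    "mock_folding_backend",
    "mock_search_backend",
    "write_toy_workspace",
]

HELIX_RISE = 1.5       # A per residue
HELIX_RADIUS = 2.3     # A
HELIX_TWIST = 100.0    # degrees per residue
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def make_helix(
    n: int,
    seed: Optional[int] = None,
    target_id: str = "toy",
    model_id: str = "native",
) -> StructureModel:
    """Ideal alpha-helical CA trace (poly-alanine, pLDDT 90).

    Rise 1.5 A, radius 2.3 A, 100 degrees of twist per residue, giving the
    canonical ~3.8 A consecutive CA-CA spacing.
    """
    if n < 4:
        raise ValueError("a helix fixture needs at least 4 residues")
    i = np.arange(n)
    theta = np.deg2rad(HELIX_TWIST) * i
    coords = np.column_stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * i]
    )
    return StructureModel(
        model_id=model_id,
        target_id=target_id,
        chain_id="A",
        sequence="A" * n,
        residue_numbers=i + 1,
        ca_coords=coords,
        plddt=np.full(n, 90.0),
    )


def perturb_model(
    model: StructureModel,
    sigma: float,
    seed: int,
    model_id: Optional[str] = None,
    source_tag: Optional[str] = None,
) -> StructureModel:
    """Add iid Gaussian noise (sd = sigma, per coordinate) to a model.

    The per-residue confidence is set to the monotone proxy
    ``100 * exp(-sigma)``.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    coords = model.ca_coords + rng.normal(0.0, sigma, size=model.ca_coords.shape)
    plddt = np.full(model.n_residues, 100.0 * math.exp(-sigma))
    return model.with_(
        model_id=model_id or f"{model.model_id}_s{sigma:g}_r{seed}",
        ca_coords=coords,
        plddt=plddt,
        source_tag=source_tag if source_tag is not None else f"perturb:{sigma:g}",
    )


def true_sigma(model: StructureModel) -> float:
    """Recover the perturbation scale recorded by :func:`perturb_model`."""
    if not model.source_tag.startswith("perturb:"):
        raise ValueError(f"model {model.model_id!r} has no recorded sigma")
    return float(model.source_tag.split(":", 1)[1])


def make_pool(
    native: StructureModel,
    sigmas: Sequence[float],
    seeds: Sequence[int],
) -> ModelPool:
    """Decoy pool: one perturbed model per (sigma, seed) combination.

    Provenance (the true sigma) is recorded in each model's source tag,
    so the ground-truth quality ordering is known.
    """
    if not sigmas:
        raise ValueError("sigmas must be non-empty")
    models = [
        perturb_model(
            native,
            sigma,
            seed,
            model_id=f"m_s{si:02d}_r{seed}",
        )
        for si, sigma in enumerate(sigmas)
        for seed in seeds
    ]
    return ModelPool(target_id=native.target_id, models=models)


def make_msa(
    query_length: int,
    n_rows: int,
    seed: int,
    mutation_rate: float = 0.3,
    query_id: str = "query",
) -> Msa:
    """Synthetic gapless alignment: query plus mutated copies.

    Each non-query row mutates query positions independently with the
    given rate, so expected pairwise identity to the query is
    ``1 - mutation_rate`` (ignoring back-mutations).
    """
    rng = np.random.default_rng(seed)
    query = "".join(rng.choice(list(AMINO_ACIDS), size=query_length))
    rows: list[tuple[str, str]] = [(query_id, query)]
    for k in range(n_rows - 1):
        chars = list(query)
        for i in range(query_length):
            if rng.random() < mutation_rate:
                chars[i] = rng.choice(list(AMINO_ACIDS))
        rows.append((f"seq{k + 1}", "".join(chars)))
    return Msa(query_id=query_id, rows=tuple(rows))


def make_hits_from_models(
    query_model: StructureModel,
    donor_models: Sequence[StructureModel],
) -> list[StructureHit]:
    """Synthesize structure-search output from donor models.

    Each donor yields one full-span gapless alignment over the residues it
    shares with the query; e-values increase with the donor's position in
    the list (callers order donors by perturbation scale to emulate a
    quality-sorted search result).
    """
    hits = []
    q_nums = query_model.residue_numbers
    for rank, donor in enumerate(donor_models):
        shared = np.intersect1d(q_nums, donor.residue_numbers)
        if len(shared) == 0:
            continue
        qi = np.searchsorted(q_nums, shared)
        di = np.searchsorted(donor.residue_numbers, shared)
        qaln = "".join(query_model.sequence[i] for i in qi)
        taln = "".join(donor.sequence[i] for i in di)
        hits.append(
            StructureHit(
                query_id=query_model.target_id,
                hit_id=donor.model_id,
                evalue=1e-10 * 10.0**rank,
                tm=max(0.05, 1.0 - 0.1 * rank) if rank < 10 else 0.05,
                qstart=int(qi[0]) + 1,
                qend=int(qi[-1]) + 1,
                tstart=int(di[0]) + 1,
                tend=int(di[-1]) + 1,
                qaln=qaln,
                taln=taln,
            )
        )
    return hits


@dataclass
class MockFoldingSchedule:
    """Scripted behavior for the mock folding backend.

    ``best_plddts`` gives the best model's global pLDDT per call
    explicitly; alternatively ``start``/``delta`` define the rule
    "call k returns best pLDDT = start + delta * k".  ``sigma`` is the
    coordinate perturbation applied to the hidden native for every
    returned model.
    """

    seed: int
    sigma: float = 1.0
    best_plddts: Optional[Sequence[float]] = None
    start: Optional[float] = None
    delta: Optional[float] = None

    def best_for_call(self, call_index: int) -> float:
        if self.best_plddts is not None:
            idx = min(call_index - 1, len(self.best_plddts) - 1)
            return float(self.best_plddts[idx])
        if self.start is None or self.delta is None:
            raise ValueError("schedule needs best_plddts or start+delta")
        return float(self.start + self.delta * call_index)


def mock_folding_backend(schedule: MockFoldingSchedule, hidden_native: StructureModel):
    """Deterministic folding backend for controller tests.

    Call k returns ``n_models`` perturbations of the hidden native at the
    scheduled sigma; the first model carries the scheduled best global
    pLDDT and each subsequent model one point less (floored at 0).
    Deterministic per (schedule seed, call index).
    """
    state = {"calls": 0}

    def fold(msa: Msa, templates, n_models: int = 5) -> list[StructureModel]:
        state["calls"] += 1
        k = state["calls"]
        best = schedule.best_for_call(k)
        models = []
        for j in range(n_models):
            m = perturb_model(
                hidden_native,
                schedule.sigma,
                seed=schedule.seed * 100_000 + k * 100 + j,
                model_id=f"fold_c{k}_m{j}",
                source_tag="refined",
            )
            value = min(100.0, max(0.0, best - j))
            models.append(m.with_(plddt=np.full(m.n_residues, value)))
        return models

    return fold


def mock_search_backend(donor_models: Sequence[StructureModel]):
    """Search backend returning synthetic hits from a fixed donor set."""

    def search(model: StructureModel) -> list[StructureHit]:
        return make_hits_from_models(model, donor_models)

    return search


def write_toy_workspace(directory: str | Path, seed: int, n_residues: int = 30):
    """Write a complete synthetic workspace: native, decoy pool, MSA, hits, templates.

    Returns a dict of the paths written.  Everything is derived
    deterministically from ``seed``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    native = make_helix(n_residues, target_id="toy")
    native_path = directory / "native.pdb"
    write_model(native, native_path)

    pool_dir = directory / "pool"
    pool_dir.mkdir(exist_ok=True)
    sigmas = [0.3, 0.3, 0.5, 1.0, 2.0]
    pool = make_pool(native, sigmas, seeds=[int(rng.integers(0, 2**20)) for _ in range(2)])
    model_paths = []
    for m in pool.models:
        p = pool_dir / f"{m.model_id}.pdb"
        write_model(m, p)
        model_paths.append(p)

    msa = make_msa(n_residues, n_rows=8, seed=seed + 1)
    msa_path = directory / "query.a3m"
    from .msa import write_a3m

    write_a3m(msa, msa_path)

    donors = [perturb_model(native, s, seed=seed + 10 + i) for i, s in enumerate([0.2, 0.6, 1.2])]
    hits = make_hits_from_models(native, donors)
    hits_path = directory / "hits.tsv"
    write_hits(hits, hits_path)

    templates = [
        TemplateRecord("1abcA", "".join(rng.choice(list(AMINO_ACIDS), size=60)), 2.1, 60),
        TemplateRecord("2defB", "".join(rng.choice(list(AMINO_ACIDS), size=45)), 9.5, 45),
        TemplateRecord("3ghiC", "".join(rng.choice(list(AMINO_ACIDS), size=25)), 1.8, 25),
        TemplateRecord("4jklD", "".join(rng.choice(list(AMINO_ACIDS), size=80)), None, 80, "predicted"),
    ]
    templates_path = directory / "templates.tsv"
    write_templates(templates, templates_path)

    return {
        "native": native_path,
        "pool": model_paths,
        "msa": msa_path,
        "hits": hits_path,
        "templates": templates_path,
    }
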