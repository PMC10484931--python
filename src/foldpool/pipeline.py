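"""Sampling-plan construction, predictor policies and native-based evaluation.

The model-sampling stage pairs each of up to eight MSA variants with a
fixed template database and folds five models per pair (num_ensemble = 8,
num_recycles = 8), for up to 40 models per target; the two
metagenome-derived MSAs are reserved for hard targets and skipped when
the default MSA is already deeper than 200 sequences.  The folding and
search engines themselves sit behind backend contracts — this module
only plans, ranks, selects and evaluates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import ranking as rk
from .assembly import ASSEMBLY_TAG, ModelPool, compose_submission
from .metrics import gdt_ts, lddt_ca, similarity_matrix, tm_score
from .msa import Msa
from .refine import FoldingBackend, SearchBackend, refine_topk
from .structio import StructureModel, global_plddt

logger = logging.getLogger(__name__)

__all__ = [
    "SamplingCombo",
    "SamplingPlan",
    "MSA_TEMPLATE_TABLE",
    "DEEP_MSA_DEPTH_THRESHOLD",
    "build_sampling_plan",
    "PredictorPolicy",
    "POLICIES",
    "get_policy",
    "Backends",
    "rank_and_select",
    "evaluate_against_native",
    "summarize_evaluation",
    "run_toy_pipeline",
    "load_config",
    "DEFAULT_CONFIG",
]

# Each MSA variant is paired with a fixed template database; the *_seq_temp
# variants re-use the same alignment but take templates from the in-house
# curated database instead of pdb70.
MSA_TEMPLATE_TABLE: tuple[tuple[str, str], ...] = (
    ("default", "pdb70"),
    ("default_seq_temp", "PDB_sort90"),
    ("original", "pdb70"),
    ("ori_seq_temp", "PDB_sort90"),
    ("colabfold", "pdb70"),
    ("colab_seq_temp", "PDB_sort90"),
    ("img", "pdb70"),
    ("img_seq_temp", "PDB_sort90"),
)
DEEP_MSA_DEPTH_THRESHOLD = 200
HARD_TARGET_MSA_NAMES = ("img", "img_seq_temp")

NUM_ENSEMBLE = 8
NUM_RECYCLES = 8
MODELS_PER_COMBO = 5

# Search-tool presets recorded as configuration; the searches themselves
# are external backends and never executed here.
DEFAULT_CONFIG: dict = {
    "sampling": {
        "models_per_combo": MODELS_PER_COMBO,
        "num_ensemble": NUM_ENSEMBLE,
        "num_recycles": NUM_RECYCLES,
        "deep_msa_depth_threshold": DEEP_MSA_DEPTH_THRESHOLD,
        "msa_presets": {
            "default": {"tools": ["HHblits", "JackHMMER"],
                        "databases": ["UniRef30 and BFD", "MGnify clusters"]},
            "original": {"tools": ["HHblits", "JackHMMER"],
                         "databases": ["UniRef30", "BFD", "MGnify clusters"]},
            "colabfold": {"tools": ["MMseqs2"], "databases": ["ColabFold DB"]},
            "img": {"tools": ["DeepMSA"],
                    "databases": ["UniRef90", "IMG", "metagenome databases"]},
        },
        "hhblits_params": "-n 3 -e 0.001 -maxseq 1000000 -realign_max 100000 "
                          "-maxfilt 100000 -min_prefilter_hits 1000",
        "jackhmmer_params": "--F1 0.0005 --F2 0.0005 --F3 0.0000005 "
                            "--incE 0.0001 -E 0.0001 -N 1",
        "hard_target_homolog_threshold": 200,
    },
    "ranking": {"similarity_metric": "tm_score"},
    "submission": {"n_models": 5, "assembly_slots": 4},
    "refinement": {"max_iterations": 5, "models_per_iteration": 5,
                   "identity_threshold": 0.90},
}


@dataclass(frozen=True)
class SamplingCombo:
    msa_name: str
    template_db: str
    models_per_combo: int = MODELS_PER_COMBO
    num_ensemble: int = NUM_ENSEMBLE
    num_recycles: int = NUM_RECYCLES

    def __post_init__(self) -> None:
        if self.models_per_combo < 1:
            raise ValueError("models_per_combo must be >= 1")


@dataclass(frozen=True)
class SamplingPlan:
    combos: tuple[SamplingCombo, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "combos", tuple(self.combos))
        names = [c.msa_name for c in self.combos]
        if len(set(names)) != len(names):
            raise ValueError("combo MSA names must be unique")

    @property
    def total_models(self) -> int:
        return sum(c.models_per_combo for c in self.combos)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "msa_name": c.msa_name,
                    "template_db": c.template_db,
                    "models_per_combo": c.models_per_combo,
                    "num_ensemble": c.num_ensemble,
                    "num_recycles": c.num_recycles,
                }
                for c in self.combos
            ]
        )


def build_sampling_plan(
    available_msas: Sequence[str],
    default_msa_depth: int,
    models_per_combo: int = MODELS_PER_COMBO,
) -> SamplingPlan:
    """Plan one folding run per available MSA/template combination.

    The ``img``/``img_seq_temp`` combinations are dropped when the default
    MSA depth is strictly greater than 200 (they exist for hard targets
    with few homologs).  With all eight combinations at five models each,
    the plan schedules 40 models.
    """
    known = {name for name, _ in MSA_TEMPLATE_TABLE}
    unknown = set(available_msas) - known
    if unknown:
        raise KeyError(f"unknown MSA names: {sorted(unknown)}")
    if "default" not in available_msas:
        raise KeyError("'default' MSA must be available")
    combos = []
    for name, template_db in MSA_TEMPLATE_TABLE:
        if name not in available_msas:
            continue
        if name in HARD_TARGET_MSA_NAMES and default_msa_depth > DEEP_MSA_DEPTH_THRESHOLD:
            continue
        combos.append(
            SamplingCombo(
                msa_name=name,
                template_db=template_db,
                models_per_combo=models_per_combo,
            )
        )
    return SamplingPlan(combos=tuple(combos))


@dataclass(frozen=True)
class PredictorPolicy:
    """How one predictor ranks, refines and composes its submission."""

    name: str
    ranking_method: str          # "plddt" | "apollo_plddt_avg"
    refinement_usage: str        # "none" | "top5" | "default_combo"
    assembly_preference: bool = True


POLICIES: dict[str, PredictorPolicy] = {
    "deep": PredictorPolicy("deep", "plddt", "none"),
    "egnn": PredictorPolicy("egnn", "apollo_plddt_avg", "none"),
    "refine": PredictorPolicy("refine", "apollo_plddt_avg", "top5"),
    "qa": PredictorPolicy("qa", "apollo_plddt_avg", "default_combo"),
    # human-predictor alias: consensus/confidence average over a larger pool
    "human": PredictorPolicy("human", "apollo_plddt_avg", "none"),
}


def get_policy(name: str) -> PredictorPolicy:
    try:
        return POLICIES[name]
    except KeyError:
        raise KeyError(f"unknown predictor policy {name!r}") from None


@dataclass
class Backends:
    """Pluggable engines and per-model MSAs for refinement-using policies."""

    search: SearchBackend
    fold: FoldingBackend
    msas: Mapping[str, Msa]


def _policy_scores(pool: ModelPool, policy: PredictorPolicy) -> pd.Series:
    if policy.ranking_method == "plddt":
        return pd.Series(
            {m.model_id: global_plddt(m) for m in pool.models}, name="score"
        )
    qa = rk.compute_qa_scores(pool)
    return qa["apollo_plddt_avg"]


def rank_and_select(
    pool: ModelPool,
    policy: PredictorPolicy | str,
    backends: Optional[Backends] = None,
    n: int = 5,
) -> list[StructureModel]:
    """Apply a predictor policy to a pool and return its ordered selection.

    ``deep`` ranks by global pLDDT; ``egnn`` (and ``human``) by the
    APOLLO/pLDDT average; ``refine`` refines the egnn top five and keeps
    the best five of refined + unrefined; ``qa`` refines only the models
    from the ``default`` sampling combination.  When assembly-derived
    models are present the submission slots prefer them (they are never
    refined — refining a chain outside its assembly context degrades it).
    """
    if isinstance(policy, str):
        policy = get_policy(policy)
    if len(pool) == 0:
        raise ValueError("empty pool")
    scores = _policy_scores(pool, policy)

    has_assembly = any(m.source_tag == ASSEMBLY_TAG for m in pool.models)
    if has_assembly and policy.assembly_preference:
        return compose_submission(pool, scores, n=n)

    if policy.refinement_usage == "none":
        order = rk.rank_models(scores.to_numpy(), list(scores.index))
        return [pool.get(mid) for mid in order[:n]]

    if backends is None:
        raise ValueError(f"policy {policy.name!r} requires backends")

    if policy.refinement_usage == "top5":
        order = rk.rank_models(scores.to_numpy(), list(scores.index))
        chosen = [pool.get(mid) for mid in order[:5]]
    else:  # "default_combo": the five models folded from the default MSA
        chosen = [m for m in pool.models if m.source_tag == "default"][:5]
    if len(chosen) < 5:
        raise ValueError(
            f"policy {policy.name!r} needs 5 candidate models, have {len(chosen)}"
        )
    msas = [backends.msas[m.model_id] for m in chosen]
    return refine_topk(chosen, msas, backends.search, backends.fold)


def evaluate_against_native(pool: ModelPool, native: StructureModel) -> pd.DataFrame:
    """Score every pool model against the native structure.

    Returns a TSV-exportable table indexed by model id with columns
    ``gdt_ts``, ``tm_score`` and ``lddt_ca``.
    """
    if native.target_id != pool.target_id:
        raise ValueError("native belongs to a different target")
    records = {}
    for m in pool.models:
        records[m.model_id] = {
            "gdt_ts": gdt_ts(m, native),
            "tm_score": tm_score(m, native),
            "lddt_ca": lddt_ca(m, native),
        }
    table = pd.DataFrame.from_dict(records, orient="index")
    table.index.name = "model_id"
    return table


def summarize_evaluation(
    table: pd.DataFrame,
    predicted_scores: Optional[pd.Series] = None,
) -> dict:
    """Pool-level summary of a native-based evaluation table.

    Reports best-of-pool and fold-level statistics (correct topology:
    TM-score > 0.5; high accuracy: TM-score > 0.8).  When a selector's
    predicted scores are supplied, also reports its top-1 true GDT-TS,
    ranking loss and per-target Pearson correlation.
    """
    summary = {
        "n_models": int(len(table)),
        "best_gdt_ts": float(table["gdt_ts"].max()),
        "best_tm_score": float(table["tm_score"].max()),
        "correct_topology_fraction": float((table["tm_score"] > 0.5).mean()),
        "high_accuracy_fraction": float((table["tm_score"] > 0.8).mean()),
    }
    if predicted_scores is not None:
        predicted_scores = predicted_scores.loc[table.index]
        top1 = rk.rank_models(
            predicted_scores.to_numpy(), list(predicted_scores.index)
        )[0]
        summary["selected_top1"] = top1
        summary["top1_gdt_ts"] = float(table.loc[top1, "gdt_ts"])
        summary["ranking_loss"] = rk.ranking_loss(table["gdt_ts"].to_dict(), top1)
        try:
            summary["pearson_correlation"] = rk.per_target_correlation(
                predicted_scores.to_numpy(), table["gdt_ts"].to_numpy()
            )
        except (rk.UndefinedCorrelationError, ValueError):
            summary["pearson_correlation"] = None
    return summary


def run_toy_pipeline(workdir: str | Path, seed: int) -> dict:
    """End-to-end demonstration run on a synthetic workspace.

    simulate -> plan -> rank -> refine (mock backends) -> select ->
    evaluate, entirely deterministic under ``seed``.  Returns a plain
    dict of the numbers computed at each stage (JSON-serialisable), used
    by the reproducibility checks and the worked example.
    """
    from . import fixtures as fx
    from .msa import depth as msa_depth, read_a3m
    from .refine import refine_topk
    from .structio import read_model

    paths = fx.write_toy_workspace(workdir, seed=seed)
    native = read_model(paths["native"])
    pool_models = [
        read_model(p).with_(target_id=native.target_id) for p in paths["pool"]
    ]
    pool = ModelPool(target_id=native.target_id, models=pool_models)
    alignment = read_a3m(paths["msa"])

    plan = build_sampling_plan(
        [name for name, _ in MSA_TEMPLATE_TABLE], default_msa_depth=msa_depth(alignment)
    )

    sim = similarity_matrix(pool)
    qa = rk.compute_qa_scores(pool, sim)
    order = rk.rank_models(qa["apollo_plddt_avg"].to_numpy(), list(qa.index))
    top5 = [pool.get(mid) for mid in order[:5]]

    donors = [fx.perturb_model(native, s, seed=seed + 50 + i)
              for i, s in enumerate([0.2, 0.5, 1.0])]
    schedule = fx.MockFoldingSchedule(
        seed=seed + 1, sigma=0.4,
        start=float(max(global_plddt(m) for m in top5)), delta=1.0,
    )
    refined = refine_topk(
        top5,
        [alignment] * 5,
        fx.mock_search_backend(donors),
        fx.mock_folding_backend(schedule, native),
    )

    table = evaluate_against_native(pool, native)
    summary = summarize_evaluation(table, qa["apollo_plddt_avg"])
    return {
        "seed": seed,
        "plan_total_models": plan.total_models,
        "plan_combos": [c.msa_name for c in plan.combos],
        "qa_scores": qa.round(9).to_dict(orient="index"),
        "selected_order": order[:5],
        "refined_ids": [m.model_id for m in refined],
        "refined_plddts": [round(global_plddt(m), 6) for m in refined],
        "pool_pss": round(rk.pss(sim.to_numpy()), 9),
        "evaluation": {k: v for k, v in table.round(9).to_dict(orient="index").items()},
        "summary": {
            k: (round(v, 9) if isinstance(v, float) else v)
            for k, v in summary.items()
        },
    }


def load_config(path: Optional[str | Path] = None) -> dict:
    """Load a YAML run configuration, overlaying the package defaults."""
    config = {k: (v.copy() if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            if isinstance(values, dict) and isinstance(config.get(section), dict):
                config[section].update(values)
            else:
                config[section] = values
    return config
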