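# foldpool

Decision layer for AlphaFold2-era protein tertiary-structure prediction:
given a pool of candidate models for one target, rank them by consensus
and self-confidence, refine the best of them through iterative
structure-alignment-driven MSA augmentation, fold in monomer models cut
out of predicted assemblies, and evaluate everything against a native
structure when one is available.

The heavy engines — the folding network, sequence search, structure
search — are *not* reimplemented here.  They sit behind small backend
contracts (`SearchBackend`, `FoldingBackend`), and deterministic
synthetic stand-ins in `foldpool.fixtures` make the entire decision
layer testable offline.

## Who this is for

Groups running large-scale structure-prediction pipelines (CASP-style
blind prediction, in-house model triage) who need the *plumbing around*
the predictors: model ranking, selection, refinement control, template
curation and evaluation, with reproducible behavior and no hidden state.

## The core methods

**Consensus quality assessment.** For a pool of `n` models of one
target with pairwise structural similarity `Sim_ij` (TM-score by
default) and per-model confidence `pLDDT_i` (0–100), foldpool computes
four ranking scores per model *j*:

- global pLDDT: mean per-residue confidence (single-model QA);
- APOLLO score: `(1/(n−1)) · Σ_{i≠j} Sim_ij` — a model is good if it
  agrees with the rest of the pool;
- their average: `(APOLLO_j + pLDDT_j/100) / 2`;
- the confidence-weighted consensus
  `(1/(n−1)) · Σ_{i≠j} Sim_ij · pLDDT_i`, where the weight is the
  *other* model's confidence.

The pool-level mean pairwise similarity (PSS) measures conformational
diversity; selectors are evaluated by ranking loss (true quality of the
best model minus that of the selected one) and per-target Pearson
correlation.  A weighted z-score combiner
(`1/16 · Σ z` + `1/12 · Σ z` + `1/6 · Σ z` over three component groups)
reproduces CASP-style official ranking arithmetic over externally
supplied component scores.

**Structural similarity.** CA-based TM-score
(`d0 = max(1.24·(L−15)^⅓ − 1.8, 0.5)`), GDT-TS over the 1/2/4/8 Å
cutoffs, and superposition-free CA-lDDT, all built on Kabsch
superposition with residue-number correspondence.  The
superposition-search objective is maximised exactly (subset
enumeration) for small correspondences and by fragment-seeded iterative
refinement at realistic sizes.

**Iterative refinement control.** Search the current model against a
structure database, convert the alignments to A3M rows, deepen the MSA
(HHfilter-style redundancy removal at 90% identity), re-fold with the
augmented MSA plus top hits as templates, and accept only a strict
global-pLDDT improvement — at most five iterations, returning the
highest-confidence model generated anywhere in the loop.

**Sampling plans and assembly integration.** Up to eight MSA variants ×
two template databases × five models (40 models/target; the two
metagenome MSAs are reserved for targets whose default MSA has ≤ 200
sequences), and submission composition that prefers assembly-extracted
models for the top 3–4 slots when the target is a complex subunit.

## Worked example

```python
from pathlib import Path
from foldpool.pipeline import run_toy_pipeline

results = run_toy_pipeline(Path("demo"), seed=7)
print(results["plan_total_models"])   # 40
print(results["pool_pss"])            # 0.531646432
print(results["summary"])
```

This simulates a 30-residue target with a 10-model decoy pool at five
noise levels, plans the sampling, ranks the pool by the four QA scores,
refines the top five with the mock backends, and evaluates against the
hidden native.  The printed summary:

```
{'n_models': 10, 'best_gdt_ts': 1.0, 'best_tm_score': 0.879972566,
 'correct_topology_fraction': 0.6, 'high_accuracy_fraction': 0.4,
 'selected_top1': 'm_s00_r655460', 'top1_gdt_ts': 1.0,
 'ranking_loss': 0.0, 'pearson_correlation': 0.998133177}
```

meaning: the least-perturbed decoy scores GDT-TS 1.0 (all its residues
superpose within 1 Å of the native), 6 of 10 decoys keep the correct
fold (TM-score > 0.5), the consensus/confidence selector picks the true
best model (ranking loss 0), and its scores correlate 0.998 with true
quality.  `pool_pss ≈ 0.53` flags a conformationally diverse pool.

The same steps are exposed as a CLI:

```sh
foldpool --seed 7 simulate demo/
foldpool plan --default-depth 150
foldpool rank demo/pool
foldpool evaluate demo/pool --native demo/native.pdb
```

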