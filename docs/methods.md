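# Methods

This note documents the models and procedures foldpool implements, the
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical choices that affect results.

## Scope and model of the problem

foldpool operates downstream of structure predictors.  Its unit of work
is a *model pool*: a set of candidate CA-trace models for one target,
each with a per-residue confidence (pLDDT, 0–100, carried in the PDB
B-factor column).  Everything the package computes — similarity,
ranking, refinement decisions, evaluation — is CA-based; side chains,
full-atom geometry and mmCIF are out of scope.  Cross-model residue
correspondence is strictly by author residue number; no sequence
alignment is performed between models of the same target.

The folding and search engines are pluggable callables.  A
`FoldingBackend` maps (MSA, templates, n) to n scored models; a
`SearchBackend` maps a model to a list of gapped structure-alignment
hits.  The package ships deterministic synthetic backends only; wiring
in real engines is the caller's concern.

## Structural similarity

**Superposition.** Kabsch least-squares superposition via SVD with the
reflection branch excluded.  Point sets whose centered coordinates have
rank < 2 (collinear) are rejected: the rotation about the line is
unconstrained and any answer would be arbitrary.

**TM-score.** `TM = max over superpositions of (1/L_ref) Σ
1/(1+(d_i/d0)²)` with `d0 = max(1.24·(L_ref−15)^⅓ − 1.8, 0.5)`.  The
0.5 Å floor keeps d0 meaningful for short chains (it engages below
L ≈ 21).  When a model is scored against a designated reference,
`L_ref` is the reference chain length; for pairwise model–model
similarity inside a pool both orientations are normalised by the target
length (the longest chain in the pool) and averaged, which makes the
similarity matrix symmetric by construction.

**GDT-TS.** Mean over the 1/2/4/8 Å cutoffs of the maximal fraction of
corresponded residues placeable within the cutoff under one rigid
superposition.  The denominator is the number of corresponded residues.

**Search strategy.** Exact maximisation of either objective is
combinatorial.  foldpool maximises exactly — enumerating the
superposition fit on every residue subset of size ≥ 3 — whenever the
correspondence has at most 12 pairs (≤ 2¹² subsets, negligible cost),
and otherwise seeds from contiguous fragments of lengths
{M, M/2, M/4, 4} at every offset, iteratively re-superposing on the
residues inside a distance cutoff until the included set stabilises
(≤ 20 rounds; the cutoff widens by 0.5 Å whenever fewer than three
residues qualify).  For TM-score the refinement is run at a small
schedule of cutoffs (d0, 1.5·d0 and 8 Å); for GDT each cutoff is its
own inclusion threshold.  The hybrid exists because the two demands on
the metric — fragment seeding for speed, and exact agreement with a
brute-force subset oracle on small instances — cannot both be met by
the heuristic alone: at small M with heavy noise the optimal
superposition subset is frequently non-contiguous, and the heuristic
can undershoot the optimum by up to ~0.2.  Above 12 pairs the heuristic
is the operative algorithm and its deviation from the exact optimum is
unquantified (as for all tools in this family).

**CA-lDDT.** Superposition-free: over residue pairs with
residue-number separation ≥ 2 and reference CA distance < 15 Å, the
fraction whose model/reference distance difference is below each of
0.5/1/2/4 Å, averaged over thresholds.  Strict inequalities throughout.

## Consensus quality assessment

For similarity matrix `Sim` (unit diagonal, symmetrised) and
confidences `pLDDT` the four scores are

```
plddt_global_j        = mean_i pLDDT_j[i]                      (0–100)
apollo_j              = Σ_{i≠j} Sim_ij / (n−1)                 (0–1)
apollo_plddt_avg_j    = (apollo_j + plddt_global_j/100) / 2    (0–1)
apollo_plddt_weight_j = Σ_{i≠j} Sim_ij · plddt_global_i /(n−1) (0–100 scale)
```

Two scale decisions are deliberate: the average rescales pLDDT by /100
so both addends live in [0, 1]; the weighted score is left on its
natural 0–100-ish scale because only its ordering is consumed.  PSS is
the mean off-diagonal similarity (equivalently the mean APOLLO score).
Pearson correlation on constant vectors raises an error rather than
propagating NaN.  The z-score combiner uses population (n) standard
deviations and maps constant components to z = 0; its default grouping
weights three component groups at 1/16, 1/12 and 1/6.

Consensus ranking assumes the pool's good models outnumber and
out-agree its bad ones; on pools dominated by one wrong conformation it
will confidently pick that conformation.  This is a property of the
method, not of the implementation.

## Alignments

A3M semantics: uppercase/`-` are match states aligned to the query
columns, lowercase are insertions; the query row contains neither gaps
nor insertions.  Pairwise identity is counted over match columns where
both rows carry the same uppercase letter, normalised by the *shorter*
row's residue count — chosen to mirror the `-id` semantics of the usual
MSA filtering tool, which the redundancy filter emulates: greedy scan
in row order, query always kept, a row dropped iff its identity to an
already-kept row strictly exceeds the threshold (default 0.90).

Neff is the inverse-cluster-size sum at 80% identity
(`Σ_i 1/n_i`, `n_i` = rows within the threshold of row i, self
included), without length normalisation.  No standard definition is
universal here; any monotone variant preserves the orderings this
statistic is used for.  A single-sequence alignment has Neff = 1 by
construction.

## Structure-search hits and template curation

Hit tables are tab-separated with a configurable column map (default:
query, target, e-value, TM-score, qstart, qend, tstart, tend, qaln,
taln; 1-based inclusive coordinates).  Rows violating the alignment
invariants are rejected individually with logged reports rather than
aborting the parse.  Conversion to an A3M row places hit residues at
their query columns, lowercases residues opposite query gaps, and pads
uncovered columns with `-`.

Augmentation converts hits in ascending e-value order (capped at 50 per
call to keep a hit flood from dominating the alignment), merges them
after the existing rows with exact-duplicate removal, and re-filters at
90% identity.  Template selection takes the top 4 hits by e-value, ties
broken by descending TM-score then id.

Template-database curation applies three strict filters in order:
resolution > 8 Å removed (records with no resolution — predicted
structures — pass, since the filter targets experimental quality),
length < 30 removed, then a greedy input-order redundancy pass removing
records with > 90% identity to a kept record.  Curation identity uses
global alignment with free end gaps over the shorter sequence, since
template chains are full sequences rather than aligned rows.

## Refinement control

One iteration: search with the current model; augment the *current*
(not original) MSA with the hits — augmentation is cumulative across
iterations, so alignment rows accumulate and the deepening effect
compounds; select templates from the latest search only; fold
`models_per_iter` (default 5) models; accept iff the best new model's
global pLDDT strictly exceeds the input's.  Stop on the first
non-improving iteration or after 5 iterations.  The returned model is
the highest-pLDDT model generated *anywhere* in the loop, tagged
`refined`; if the first search returns no hits the input model is
returned unchanged.  The top-5 pooling rule refines five selected
models independently, pools refined with unrefined, and keeps the five
with the highest global pLDDT (ties by model id).

The controller optimises self-reported confidence, not true quality;
it inherits whatever bias the folding engine's pLDDT carries.

## Assembly integration and grafting

Chains extracted from multi-chain models keep their in-assembly
coordinates and B-factor confidences and are tagged
`assembly_extracted`.  Submission composition fills the first
`assembly_slots` (default 4, configurable 3–4) positions with the
top-ranked assembly-derived models and the rest with single-chain
models; the assembly cap is hard, so a pool with too few single-chain
models yields a shorter submission rather than overfilling with
assembly models.  Pools mixing confidences from different predictors
are flagged (`mixed_plddt_provenance`) but not rescaled — the scales
are not comparable and silently "correcting" them would hide that.

Region grafting superposes the region model onto the full-length model
over up to `flank` (default 10) residues on each side of the span that
exist in both models, falling back to the span itself when no flanks
are shared, then replaces the span's coordinates and confidences.
Superposing on flanks rather than the span preserves the global
placement of the region while replacing its local geometry — the right
behavior when the span is precisely the part of the full-length model
that is badly folded.

## Sampling plans and policies

The plan pairs each available MSA variant with its fixed template
database (default/original/colabfold/img with pdb70; their `_seq_temp`
twins with the curated database), five models per pair, engine
parameters num_ensemble = 8 and num_recycles = 8; eight pairs → 40
models.  The two metagenome-derived variants exist for hard targets and
are excluded when the default MSA depth is strictly greater than 200.

Predictor policies: `deep` ranks by global pLDDT; `egnn` by the
consensus/confidence average; `refine` applies the top-5
refine-and-pool rule to egnn's selection; `qa` refines the five models
from the default sampling combination; `human` is an alias for egnn
ranking over a larger pool (manual re-ranking and learned-QA rankers
are out of scope).  When assembly-derived models are present, all
policies compose the submission with assembly preference and do not
refine the extracted chains: refining a chain outside its assembly
context optimises it toward an isolated-chain conformation.

## Synthetic data and what it shows

`fixtures` generates ideal α-helical CA traces (rise 1.5 Å, radius
2.3 Å, 100°/residue — the canonical ~3.83 Å CA spacing), decoy pools by
iid Gaussian coordinate noise at chosen σ, synthetic A3M alignments by
point mutation, gapless structure-search hits from donor models with
e-values increasing along the donor list, and a scripted folding
backend whose per-call best pLDDT follows an explicit list or a
start + δ·k rule.  Decoy confidence is set to `100·exp(−σ)` so that
self-estimates are perfectly (monotonically) informative about true
quality.

These generators define the study conditions for every test: pools of a
24–30 residue helix, five to seven noise levels between 0.3 and 3.5 Å,
20 replicates where rates are estimated.  The sizes were chosen so the
whole suite runs in minutes on one CPU while each check still exercises
the intended regime (clustered-good-models pools for consensus
recovery, heavy noise at small M for the oracle comparison).

What passing these tests does *not* show: real decoys are not isotropic
Gaussian clouds around the native (errors are correlated along the
chain and concentrated in loops and domain interfaces), real pLDDT is
neither perfectly calibrated nor monotone in error, and real pools mix
conformations rather than noise levels.  The tests validate the
decision logic and the arithmetic, not predictor behavior on real
proteins.

## Numerical choices and degenerate inputs

- Kabsch: reflection excluded via the determinant sign; rank-deficient
  (collinear) inputs are errors.
- Strict inequalities at every printed threshold (depth > 200,
  identity > 0.90, resolution > 8 Å, length < 30, pLDDT improvement >,
  TM > 0.5/0.8) — boundary cases are covered by tests.
- Ranking ties break lexicographically by model id, making every
  selector deterministic.
- PDB writing is fixed-width (coordinates to 3 decimals, B-factors to
  2), so round trips are exact to format precision; insertion codes are
  rejected, first altloc kept, CA-less residues skipped with a warning.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); the toy pipeline is bit-reproducible
  under a fixed seed.

## Known limitations

- Above 12 corresponded residues the TM/GDT search is heuristic with no
  optimality bound.
- lDDT is CA-only; values are not comparable to full-atom lDDT.
- The refinement controller trusts backend pLDDT; no guard against a
  miscalibrated engine.
- Identity and Neff definitions are reasonable stand-ins for the
  conventions of the external tools they emulate, not re-implementations
  of those tools.
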