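# Methods

## Problem setting

`stabscore` operates on de novo designed mini-proteins (< ~80 residues)
whose folding stability ΔG_unfold (kcal/mol; higher = more stable, the sign
opposite of ΔG_fold) has been measured experimentally. Designs come in
groups — *folds* — sharing one backbone, with one sequence per generative
model (tags `TrROS`, `TrMRF`, `ProteinMPNN`, `Joint`). The package scores
sequences and structures with zero-shot confidence/likelihood metrics,
calibrates hybrid combinations of those metrics against measured stability,
compares models within folds, analyzes contact composition, and optimizes
sequences against differentiable surrogate models.

Neural models never run inside the library. Everything that would require
one (pLDDT, masked log-probabilities, inverse-folding logits, distograms,
inter-PAE) enters through the `ScoreBackend` contract; the shipped
`MockBackend` is a deterministic surrogate whose outputs rank-correlate with
a configurable latent stability.

## Score definitions

All logarithms are natural; entropies are reported in nats (no base is
conventional for these scores, and nats make the cross-entropy/perplexity
relation `perplexity = e^CE` direct).

**Pseudo-likelihood (PLL).** For sequence S of length L, with row i of the
input matrix being a masked language model's distribution at position i
given all other positions,

    PLL(S) = (1/L) Σᵢ log P(sᵢ | S_\i).

Uniform rows give ln(1/20) ≈ −2.996; a certain model gives 0.

**Distogram cross-entropy.** The true structure's Cβ–Cβ distances d_ij (Cα
for glycine; an ideal-geometry virtual Cβ is available but off by default)
are digitized into half-open bins B_k = [b_{k−1}, b_k), giving a one-hot
tensor F_ijk, and scored against predicted distogram logits g:

    H(F, g) = Σᵢⱼₖ −F_ijk · LogSoftmax(g_ijk)   (softmax over the bin axis).

Numerical choices: the i = j diagonal is mapped to out-of-range by default
(d_ii = 0 carries no structural information; `include_diagonal=True`
restores the literal sum over all i, j). Distances outside [b_0, b_M) are
excluded through a mask rather than clamped (`clamp=True` assigns them to
the nearest edge bin). The default binning is 2–22 Å at h = 0.5 Å (M = 40),
a conventional distogram range; real models supply their own.

**Sequence cross-entropy.** For one-hot X and per-position logits f(X),

    H(X, f(X)) = Σ_l Σ_a −X_la log f(X)_la,

reported both total and per-residue. The same formula serves conditional
(CCE) and unconditional (UCE) inverse-folding logits; the caller chooses
which logits to pass. The filter threshold `CE < 1.5` is interpreted
per-residue (perplexity e^1.5 ≈ 4.5, the average inverse-folding
perplexity); a total-CE filter is expressible by adjusting the threshold.

**Summed likelihood.** Σᵢ softmax(logitsᵢ)[sᵢ] ∈ [0, L] — the absolute
stability proxy used with inverse-folding decoders.

**Aggregated pLDDT.** The mean of n replicate scalar pLDDT predictions
(0–100) under a masking protocol: `half_mask` hides ⌊mask_frac·L⌋ positions
per replicate (defaults n = 8, mask_frac = 0.5), `masked_msa` fully masks
the MSA input with per-replicate seeds (n = 8), `plain` varies only the
seed. Replicates are averaged as per-structure scalars, not pooled
per-residue. Masks come from a named counter-based seed stream
(`(seed, rep, L)` → child generator), so aggregation is bit-reproducible.
Recycling is passed through as an opaque integer (default 3; 0 reflects the
no-recycle setting that correlates better with stability for adversarial
designs).

## Hybrid scores and calibration

A hybrid score is a convex combination of one sequence-side and one
structure-side metric, with signs orienting both toward stability
(cross-entropies enter negated). Shipped presets reproduce the published
coefficient sets as literal weighted sums of raw columns:
−0.90·CCE + 0.10·half-masked-ESMFold-pLDDT, −0.90·CCE +
0.10·fully-masked-AF2-MSA-pLDDT, and 0.86·PLL +
0.14·half-masked-ESMFold-pLDDT.

`calibrate_weight` reproduces the calibration *procedure*: a seeded 20% row
sample is the training split, the weight sweeps an exhaustive grid
(step 0.01) maximizing Spearman(hybrid, ΔG_unfold) on it, and the final
correlation is reported once on the held-out 80%. Ties break toward 0.5
(then toward the smaller weight, for determinism). Design choices made
where the procedure was genuinely open:

* **Normalization.** Whether the published coefficients were applied to raw
  or standardized columns is not stated. Calibration defaults to z-scoring
  each component on the training split (raw pLDDT spans 0–100 while PLL
  spans ≈ −3..0, so unnormalized weights are scale artifacts);
  `normalization="none"` reproduces literal weighted sums. We make no claim
  of recovering the published 0.90/0.10 or 0.86/0.14 values — only the
  procedure is reproduced.
* **Split.** A uniform row sample without stratification by default; a
  fold-aware split (sampling folds, not rows) is available to avoid leakage
  across same-fold sequences. The split is canonicalized on the key column,
  so results are invariant to input row order.
* Spearman uses average ranks for ties throughout.

## Evaluation statistics

Within-fold deltas difference out the backbone: for each fold carrying both
models, `metric_ref − metric_other` (folds with a missing side are skipped
and counted). `fraction_more_stable` is the percentage of qualifying folds
with a positive ΔG delta; exact ties count as *not* more stable and are
reported separately, so fwd% + rev% + tie% = 100.

Filters are ordered conjunctions of threshold predicates; the keep-set is
order-independent, attrition is logged per predicate, and missing values
never pass a predicate. The monomer rule retains designs with
`inter_pae > 15` (high inter-chain predicted aligned error on a two-copy
prediction means no confident chain–chain packing, i.e. a monomer). The
source text describes the filter both as "filtering based on low inter-PAE"
and as "inter-PAE > 15 indicates a monomer"; we implement retain-if-greater
as the default and expose both the threshold and the direction, since the
two phrasings disagree.

Sequence identity is positional (same-fold designs share a length); an
optional global alignment (match +1 / mismatch 0 / gap −1, identity =
matches / alignment length) handles unequal lengths and is off by default.

## Contact potentials

Contacts: residue pairs separated by more than five positions
(j − i ≥ 6, strict reading of "more than five residues") whose side-chain
heavy atoms (all non-hydrogen atoms beyond Cα, Cβ included, OXT excluded)
come within 5 Å. Glycine can never satisfy the strict rule; `gly_cb=True`
substitutes a (virtual) Cβ.

The pairwise potential is the log-odds
`V(a,b) = ln[P({a,b}|contact) / (P(a)P(b))]` with P({a,b}) the *unordered*
amino-acid-pair probability among contacts (a single K–E contact gives
P({K,E}) = 1, P(K) = P(E) = ½, V = ln 4) and P(a) a background composition:
contact-participant marginal by default, uniform or user-supplied
alternatives (the published analysis does not define P(a); both readings
are offered). A Jeffreys-style pseudocount α = 0.5 per unordered pair
avoids −∞ cells; zero-raw-count cells are additionally NaN-masked in
reports. Cysteine keeps its row/column but is empty for designed sets,
which exclude it to prevent disulfides.

## Straight-through Gumbel optimizer

One step: (1) sample `I_hard = onehot(argmax(I_soft + T·Gumbel))` — the
Gumbel-max trick, so each row is an exact categorical draw from
`softmax(I_soft/T)`; (2) evaluate the model's loss at `I_hard`; (3) update
`I_soft ← I_soft − lr·∇loss(I_hard)` — the straight-through estimator
`stop_gradient(I_hard − I_soft) + I_soft` has identity Jacobian, so the
gradient at the hard point passes through unchanged. Model parameters are
never updated. The loop starts from seeded standard-normal logits and stops
when the best loss has not improved by `tol` for `patience` iterations.

No learning rate, optimizer or convergence tolerance is conventional for
this loop, so the defaults are the simplest faithful reading: plain
gradient descent with lr = 0.1, Gumbel temperature 1.0 (constant — no
annealing is assumed), tol = 1e−4, patience = 50, max_iters = 2000, all
configurable. Joint optimization of two models over one shared sequence is
a `WeightedSumModel` of their losses; with weights (1, 0) it reduces
exactly to single-model optimization. The real joint design loop
(pretrained structure/sequence networks exchanging 6D features) is
represented only by this composition hook; surrogate models
(`ToyPotts`, `FixedTargetCE`) stand in for the networks.

## Synthetic data generator

`simulate_stability_dataset` emulates the *shape* of a four-model stability
comparison, not protein energetics: per fold f, a baseline
`base_f ~ N(μ, σ)`; per model m, `ΔG = base_f + shift_m + ε`,
`ε ~ N(0, ε_sd)`; each metric column is a linear function of the realized
ΔG plus Gaussian noise, clipped where the scale demands it (pLDDT to
[0, 100]) and sign-flipped for cross-entropies so lower CE tracks higher
ΔG. Within a fold the baseline cancels, so the delta between two models is
exactly `N(shift_ref − shift_other, 2·ε_sd²)` and every pass-fraction has a
closed form — the recovery tests check against it.

The `study-like` preset fixes the study-like conditions: 1500 folds × 4
models, Joint shift +0.6 kcal/mol, ε_sd = 0.5 (so ≈ Φ(0.6/√0.5) ≈ 80.2% of
folds favor Joint), baseline N(2.3, 2.0) kcal/mol so the Joint median lands
near 2.9 kcal/mol. Default metric links put rank correlations with ΔG in
the 0.4–0.7 range typical of zero-shot confidence metrics.

What passing on this generator does *not* show: linear links and Gaussian
noise are far kinder than real metric/stability relationships (no
heteroscedasticity, no adversarial high-confidence failures, no fold-level
metric structure); recovering the configured fractions validates the
statistics pipeline, not any claim about real designs.

`generate_helix_structure` is an ideal helical Cα trace (rise 1.5 Å, twist
100°, Cα radius 2.3 Å — consecutive Cα–Cα ≈ 3.8 Å) with backbone N/C placed
a third of a turn away and a CB pseudo-side-chain atom displaced radially;
it exists for geometry and round-trip tests, not as a physical model.
`ToyPotts` is a random-field/coupling Potts energy with analytic gradients
and a guarded exhaustive enumerator (A^L ≤ 10⁶) providing the global
optimum the sampler tests compare against.

## Degenerate inputs and numeric conventions

Residue indexing is 1-based (PDB convention); all pairwise matrices are
0-based over record order. Missing table values stay NaN, are excluded
pairwise in correlations, fail every filter predicate, and are counted —
never imputed. Spearman with fewer than 3 complete pairs is an error; zero
rank variance returns NaN with a warning. Malformed table rows are dropped
with a logged count. Alternate PDB locations resolve to highest occupancy;
insertion codes are rejected by default. The deposited-table schema is not
assumed: loading goes through a `column_map` with a shipped default-guess
map, and two protease-specific ΔG columns are reduced to a consensus
(arithmetic mean by default, recorded in table metadata).

## Problem sizes

The test suite and the acceptance script run entirely on synthetic inputs:
the pipeline checks use the 1500-fold preset (6000 rows), calibration uses
2000 rows, oracle-equivalence checks use 100 randomized small instances per
operation, and the sampler check uses 20 seeds on the 4×4 Potts model
(256-sequence enumeration). These sizes give Monte-Carlo error comfortably
inside the tolerances asserted (binomial s.e. ≈ 1 percentage point at 1500
folds) while the whole suite completes in seconds.

## Known limitations

* Real-model adapters are not included; the backend contract is exercised
  only by the deterministic mock, so agreement with actual AF2/ESMFold/
  ESM-2/ProteinMPNN/ESM-IF outputs is untested here.
* Inter-PAE is consumed as a column, never computed from structures; no
  multi-chain or mmCIF support.
* The calibration reproduces a single 20/80 split, not cross-validation;
  reported test correlations inherit that split's variance.
* The contact analysis has no burial/exposure or secondary-structure
  breakdown, and hydrogen-bond geometry is not detected — contacts are
  purely distance-based.
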