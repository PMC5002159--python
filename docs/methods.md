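# Methods

## Problem and model

The package predicts whether a protein binds DNA from its sequence and
two standard sequence-derived profiles: a PSI-BLAST position-specific
scoring matrix (PSSM, L×20 integer log-odds) and PSIPRED per-residue
secondary-structure probabilities (L×3). It does not run PSI-BLAST or
PSIPRED; it consumes their output files (ASCII `-out_ascii_pssm` dialect
and `.ss2` VFORMAT respectively) and validates them against the FASTA
sequence (row counts, residue columns, probability ranges). Sequences
are restricted to the 20 standard amino acids; ambiguity codes are
rejected rather than imputed, matching the usual curation of DBP
benchmark sets. The 50-residue minimum common in those sets is treated
as a dataset rule, not a parser rule — the `validate` command warns but
does not fail.

## Feature encoding

Each protein becomes a 46-vector with fixed block order
(conservation 20 | motifs 12 | physicochemical 14), every entry in
[0, 1].

**Conservation.** For each amino-acid type the PSSM log-odds of that
type's own column are summed over the positions where the type occurs,
then mapped through the standard logistic 1/(1+e^(−P)). The logistic
(rather than any affine rescaling) is what bounds the block, and gives
the neutral value 0.5 for amino acids absent from the sequence (empty
sum). Only the first 20 file columns (log-odds) are used; the weighted
percentage block is ignored. Output order is the fixed alphabetical
one-letter order `ACDEFGHIKLMNPQRSTVWY`.

**Motifs.** Per-residue labels are the argmax over (H, E, C); ties are
broken by the fixed priority H > E > C (the internal column order makes
`argmax`'s first-maximum rule implement this directly). Labels collapse
into maximal same-type segments, and each window of 3 consecutive
segments falls into one of the 12 ordered triples over {H, E, C} with
distinct adjacent types — the maximal-run construction makes adjacent
equality structurally impossible, so 3·2·2 = 12 categories are
exhaustive. Counts are divided by the window count (max(#segments−2, 1))
so the block is length-free and sums to 1 whenever ≥3 segments exist;
raw counts remain available via `motif_features(..., normalize=False)`.
The `.ss2` file's native column order is (C, H, E); the single remap
constant to the internal (H, E, C) lives in `profile_io`.

**Physicochemical.** Fourteen named property scales; the descriptor is
the per-property mean over the sequence, logistic-squashed with the
other blocks. The shipped table (`physchem_synthetic.py`, version
`synthetic-1.0`) is a synthetic stand-in assembled from the standard
scale families commonly used under each property name; tests pin the
version, not particular values, so a curated table can be swapped in via
`PhysicochemicalTable`. Scale values are z-standardised across the 20
residues at load time (disable with `standardize=False`): scales in
natural units (e.g. accessible surface areas near 150 Å²) would saturate
the logistic at 1.0 and carry no information; standardisation keeps the
sequence means in the map's responsive range without changing the
encoding scheme.

## Binary firefly algorithm

A firefly is a bit string; brightness is the objective value. Per
iteration, firefly *i* performs one inner sweep: for every firefly *j*
currently strictly brighter (ties attract no movement), *i* is attracted
— each bit differing from *j* adopts *j*'s value with probability
β = β₀·e^(−γ_fa·r²), where r is the normalized Hamming **similarity** —
and then mutated, every bit flipping with probability α. With no
brighter neighbour, a firefly mutates only. Brightness is re-evaluated
once per firefly after its full sweep, and updated values are visible to
later fireflies in the same iteration (asynchronous sweep). Using the
similarity (not the distance) in the exponent means dissimilar pairs
take the larger strides, which is what makes the operator converge
quickly on bit masks.

Defaults: 30 fireflies, 500 iterations, γ_fa = 1, β₀ = 1.
α = 0.5 − 0.5·iter/max_iter decays linearly, shifting the search from
exploration to convergence; at the final iteration processed (max−1) it
is near but not exactly 0.

Design choices where the procedure was genuinely open:

* **Elitism.** The best-so-far bit string is archived outside the
  population, so the best individual keeps mutating (diversity) without
  the result ever regressing; the best-so-far trace is monotone.
* **Mutation per movement.** The attract-then-mutate composition applies
  per attraction event. A variant mutating once per sweep was measured
  during development and performed indistinguishably on wrapper
  objectives; the per-movement form was kept.
* **Objective caching.** Evaluations are memoised by bit string;
  correctness-neutral because the objective is deterministic given its
  declared evaluation seed.
* **Fast sweep kernel.** The inner loop runs through `move_firefly`,
  lean XOR arithmetic over a block of pre-drawn uniforms; a unit test
  pins its exact equivalence to the composition of the public
  `attract`/`mutate` operators, so the reference semantics and the fast
  path cannot drift apart.

Runs are bit-reproducible given the config seed (and the objective's
evaluation seed).

## Coupling to the SVM

Firefly layout: t-bit cost field, t-bit kernel-width field, w-bit
feature mask (t = 10 by default, w = feature dimension). Field value
v ∈ [0, 2^t−1] maps log₂-uniformly: exponent = lo + v·(hi−lo)/(2^t−1),
over C ∈ [2⁻⁵, 2¹⁵] and γ ∈ [2⁻¹⁵, 2³] (the standard libsvm grid), so
the all-zero/all-one fields hit the range endpoints exactly.

Fitness is I = ω·MCC + (1−ω)·(1 − n/N) with ω = 0.55, N = w, and MCC
pooled over a seeded stratified **5-fold** cross-validation of the
masked RBF-SVM. Five-fold (rather than leave-one-out) inside the search
is a deliberate protocol choice: LOOCV at every one of hundreds of
thousands of evaluations would be computationally disproportionate, and
leave-one-out is reserved for final-model evaluation. An all-zero mask
gets the hard penalty I = −1; the search space is left intact rather
than repairing degenerate masks. MCC uses the convention 0 when its
denominator vanishes; SN/SP are reported unset when their class is
absent.

Final evaluation protocols: `loocv` (one held-out prediction per
sample, pooled counts), and `repeated_split_protocol` — k seeded
stratified train/test draws (default train fraction 355/455 per class),
a full BFA optimization per draw, mean metrics plus the index of the
median-MCC run (the run whose mask and parameters would seed a deployed
model). ROC-AUC comes from rank-based scoring of the SVM decision
function and is invariant to monotone rescaling. The model artifact is
a self-describing JSON (mask, decoded parameters, layout, property-table
version, training data) from which loading refits deterministically.

## Synthetic data

`gen_protein_triple` emits mutually consistent FASTA/PSSM/ss2 texts:
uniform random sequences, integer PSSM scores in [−10, 10] (realistic
log-odds magnitudes, no claim of evolutionary structure), and random
3-decimal probability rows; an optional label string forces the
per-residue argmax so motif patterns can be planted. These fixtures
exercise parsing, consistency checking and encoding — they do not
emulate real conservation statistics or real secondary-structure run
lengths, so passing tests demonstrate correctness of the machinery, not
biological performance.

`gen_planted_dataset` draws two classes over n_features unit-variance
Gaussians, shifts the informative subset by the standardized effect size
δ_sep (default 2.0, 100 samples per class, 5 informative of 30) and
squashes through the logistic to the [0, 1] feature convention. The
defaults give a strongly separated problem (combined Mahalanobis
separation ≈ 2·√5 σ) with known ground truth for scoring mask recovery.

## Known limitations

* The planted-recovery experiment exposes a real property of the
  sparsity-weighted fitness: with five equally informative, mutually
  redundant features, dropping the fifth costs ≈ 0.01 intensity in MCC
  terms but earns 0.015 in sparsity bonus, so the fitness optimum keeps
  only 3–4 of the 5 planted features. Selected-mask recall therefore
  plateaus near 0.6–0.8 per run (the union over 10 seeded runs recovers
  the full planted set), and on such strongly separated data an
  all-features SVM baseline is already near its ceiling, which masks the
  benefit of feature removal. On real DBP data — where features are
  noisier and redundancy hurts — the sparsity trade-off is the point of
  the method.
* In-search fitness uses one fixed CV partition per run (determinism),
  so selection can overfit that partition; held-out splits are the
  honest estimate.
* The physicochemical table is a documented stand-in (above).
* Reported experiment sizes (12-bit oracle landscapes, 30-feature
  planted datasets, 15×100 search budgets in the recovery experiment)
  are the package's benchmark choices; the search itself has no
  intrinsic size limit beyond evaluation cost.
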