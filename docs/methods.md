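# Methods

This note documents the models, statistics and design choices behind
`coevoscreen`, an analysis pipeline for library-on-library protein
coevolution screens of the Z-domain/affibody kind: two small three-helix
chains displayed as a cleavable single-chain fusion, both interface sides
randomized through degenerate codons, selected over multiple rounds for
non-covalent pairing, and read out by paired next-generation sequencing.

## Library designs

A design is two scaffold chains, a list of 1-based randomized residue
positions per chain, and one degenerate codon per position. Two presets
ship with the package:

* **LL1-style** — Z-A positions 9, 13, 17, 31, 35 with codon `HWW`
  (12 triplets → amino acids {F,H,I,K,L,N,Q,Y} plus the TAA stop), Z-B
  positions 9, 17, 31, 32 with `DTK` (6 triplets → {F,I,L,M,V}).
* **LL2-style** — four positions per chain (9, 13, 17, 31 / 9, 17, 31, 32)
  with codon `NWW` (16 triplets → the 11-amino-acid set
  {D,E,F,H,I,K,N,L,Q,V,Y} plus TAA).

The published alphabets determine these codons only up to choice; `NWW` is
selected because it encodes exactly the 11-amino-acid set and its 16
triplets per position reproduce the theoretical nucleotide diversity
16⁸ = 4,294,967,296 of the expanded library. Stop codons are excluded from
functional alphabets with a warning rather than an error, since real
degenerate sets often tolerate a low stop fraction. The chain-A scaffold
is the 58-residue Z domain; the chain-B scaffold is a synthetic
placeholder (the Z backbone carrying the weak binder's interface residues
L9/V17/I31/F32), as the partner chain's full sequence is configurable and
not bundled.

Nucleotide diversity is the product of codon-expansion sizes over all
randomized positions; functional diversity the product of amino-acid
alphabet sizes. The published figure of 1.91 × 10⁹ "functional diversity"
for the expanded library exceeds 11⁸ ≈ 2.14 × 10⁸ and evidently denotes
transformant-library scale; the package reports the combinatorial value
and does not force agreement.

## Screen simulator

The simulator stands in for the wet-lab platform so every downstream
stage is testable without data downloads. Its model:

* **Affinity landscape.** Each realizable pair gets
  pK_D = pkd0 + scale·(Σᵢ h_A[i,aᵢ] + Σⱼ h_B[j,bⱼ] + Σ_(i,j) ε[i,j,aᵢ,bⱼ]).
  Single-site propensities h are drawn per position as a random linear
  function of the residues' five physicochemical factor scores
  (polarity/hydrophobicity, secondary-structure propensity, size, codon
  composition, charge) plus independent roughness; the `smoothness`
  parameter (default 0.8) is the variance fraction carried by the factor
  term. Smoothness matters: binding energetics of real interfaces vary
  systematically with residue chemistry, and this structure is precisely
  what allows an embedding-based model to generalize to amino acids
  unseen in training. A fully idiosyncratic landscape (smoothness 0)
  makes alphabet transfer impossible in principle, for any model.
* **Planted couplings.** A coupling of magnitude m at position pair (i, j)
  adds m to pK_D when the B-residue is the A-residue's matched partner —
  the most compatible residue under a fixed random bilinear form in
  factor space — and 0 otherwise. Matched and mismatched pairs therefore
  differ by exactly m·scale, and chemically similar residues share
  partners.
* **Selection.** Round-to-round survival is retention =
  clip₀¹(m·(pK_D − p0)) with defaults m = 0.25, p0 = 6, mapping pK_D 6 → 0
  and 10 → 1 across the platform's µM-to-nM range; this is the simplest
  form consistent with the cleavage-capture readout's semilog-linear
  affinity relationship. Each round resamples the cell pool multinomially
  with probability ∝ frequency × retention, then sequencing draws counts
  multinomially at the configured depth (default 10⁵ reads). Clones are
  fixed genotypes: no mutation between rounds. The default cell capture
  per round is 8× the naive diversity, matching the platform's stated
  7–10× capture ratio; lowering it sharply increases drift noise, which
  propagates into label noise for the interaction model.
* **Defaults.** 5 rounds, naive pool of 5000 distinct pairs sampled
  uniformly without replacement from the realizable space, depth 10⁵.
  A noise-free mode replaces sampling with the deterministic recursion
  f ← f·r / Σf·r (largest-remainder integerization) for oracle tests.

What the simulator does *not* emulate: sequencing error, PCR and display
biases, avidity effects, FACS gating geometry, clone dropout from plasmid
loss. Tests passing on simulated screens therefore validate the analysis
machinery and its statistical behavior under the stated model, not
performance on any real screen.

## Pair enrichment

A pair observed k times among N pooled reads with marginal read counts
c_a, c_b is scored by the upper-tail hypergeometric probability
P(X ≥ k), X ~ Hypergeom(N, c_b, c_a) — the probability of co-occurring
that often if partners paired at random. Pairs with p < 0.05 (raw,
uncorrected — the screen convention; Benjamini–Hochberg is available as
an option) form the enriched set. Marginals use read counts rather than
unique-clone counts; both weightings are exposed where downstream
statistics consume frequencies. Counts are pooled by summation across the
named rounds (the analyses here pool the two final rounds, mirroring the
"intermediate enriched library" convention).

## Networks

All variable regions are fixed length, so edit distance is Hamming
distance exactly; the implementation refuses unequal lengths rather than
fall back to indel alignment. The sequence similarity network (SSN) keys
nodes by concatenated Z-A/Z-B variable regions and connects nodes within
the distance threshold (1 for single-round views, 2 for all-round views).
Communities are connected components — the clustering method behind the
published cluster graphs is not specified, and components are the
parameter-free choice; the cluster graph collapses each component to one
weighted node and draws inter-cluster edges at a secondary threshold
(primary + 1 by default, a documented convention of this package). The
specificity similarity network (SpSN) connects Z-A sequences sharing at
least `min_shared` Z-B partners. Cross-reactivity scores are per-Z-A
distinct-partner counts normalized to sum to 1; the chord-diagram export
subsamples pairs by largest-remainder proportional allocation across Z-A
groups (guaranteeing per-group counts within one of exact
proportionality) with seeded within-group sampling.

Mutational pathways are shortest paths in the Hamming-1 graph over
observed sequences (breadth-first search), optionally constrained to
nondecreasing first-appearance rounds. Ties among equal-length shortest
paths are broken deterministically during backward reconstruction:
smallest mean enrichment p-value first, then lexicographic order.
Disconnection is a reported result, not an exception.

## Coupling inference

Frequencies f(Aᵢ), f(Aᵢ, Bⱼ) are computed over all positions of the
concatenated variable regions, count-weighted or unique-pair weighted; an
optional pseudocount λ mixes uniform mass into every table in a way that
preserves marginal consistency. Mutual information is
MI_ij = Σ f(Aᵢ,Bⱼ) ln[f(Aᵢ,Bⱼ)/(f(Aᵢ)f(Bⱼ))] in natural log units (the
log base is a free convention); zero cells contribute zero. MI is applied
to the filtered pair set with unique weighting, direct coupling analysis
to unfiltered count-weighted tables — matching each method's described
input; both weightings are switchable.

The empirical covariance S over one-hot position/amino-acid states has
entries f(Aᵢ,Bⱼ) − f(Aᵢ)f(Bⱼ), with within-position blocks
diag(fᵢ) − fᵢfᵢᵀ. The precision matrix is estimated by the constrained
program

maximize log det θ − ⟨S, θ⟩ subject to Σ|θᵢⱼ| ≤ α, θ ⪰ 0,

solved with ADMM: the θ-step is a closed-form eigendecomposition update,
the Z-step a Euclidean projection onto the L1 ball, with adaptive penalty
balancing. The returned matrix satisfies the budget exactly and is PSD
within tolerance; non-convergence raises with the final residuals. A
ridge (default 10⁻³) is added to the diagonal of S because the one-hot
simplex makes S exactly singular.

**Choice of the budget α.** The constrained program with α = 1 provably
returns an exactly diagonal θ at this problem's scale: frequency
covariances satisfy |Sᵢⱼ| ≤ 0.25, while a unit budget spread over d ≈ 88
states implies a KKT multiplier of order d, far above every off-diagonal
entry — so all coupling scores would be identically zero. The package
therefore defaults to a data-scaled budget, α = 0.1·‖(S + ridge·I)⁻¹‖₁
("auto"): a fixed fraction of the unconstrained precision norm, which
sparsifies without collapsing to the diagonal. Planted-coupling recovery
is insensitive to the fraction across 0.05–0.5. Exact numeric α semantics
remain available for the solver itself.

Position-pair scores aggregate |θ| over each inter-chain amino-acid block
(L1 norm, consistent with the L1-sparse estimator; Frobenius and
APC-corrected variants are available but off by default) and are min-max
normalized to [0, 1]. The score-vs-distance comparison fits ordinary
least squares of score against minimum heavy-atom inter-residue distance
(extracted from a PDB structure when one is supplied) and reports R²;
constant inputs yield an explicit undefined-R² result.

## Interaction model

Dataset assembly follows the screen convention: positives are the
enrichment-filtered pairs of the pooled late rounds, labeled
X_s = (ln(count+100) − ln 2)/(ln(maxcount) − ln 2) with maxcount the
maximum positive count + 100 (so the top positive maps to exactly 1 and
every positive stays separated from naive zeros); negatives are a
size-matched seeded sample of naive pairs absent from those rounds,
labeled 0. The combined set splits 80/20 into train/validation. A
`max_positives` cap (seeded subsample) scales training runs to a single
CPU.

Embedding is a pluggable contract: a deterministic D-vector per full
chain (scaffold with the variant substituted). The built-in embedder maps
each residue to its five physicochemical factor scores, applies a fixed
seeded position-specific projection to D dimensions (default 32), and
mean-pools over the chain. Two properties motivate this over a one-hot
construction: position specificity survives mean-pooling, and residues
unseen in training land near chemically similar training residues — the
shared-embedding-space property that a pre-trained protein language model
supplies at scale and that alphabet transfer fundamentally relies on. An
adapter class accepts any external embedding callable (e.g. a 1280-d mean
last-layer language-model embedding) without changing downstream code.

The pair representation is the outer product V_a ⊗ V_b (D × D, rank 1).
The regressor is a 3-layer 2D CNN — per layer
InstanceNorm(ReLU(Maxpool₂ₓ₂(Conv₅ₓ₅))) — followed by a two-layer fully
connected head and a sigmoid, trained with squared-error loss and Adam,
keeping the checkpoint with minimum validation loss. Published recipe
values (channels [64,128,256], learning rate 10⁻⁴, 100 epochs) are the
`ModelConfig` defaults; CPU-scale experiments use smaller channels
(6,12,24), 25 epochs and learning rate 10⁻³, recorded verbatim in each
output bundle. Convolutions are im2col matrix products in float32 with
hand-derived backpropagation (verified against numerical gradients);
instance normalization has no affine parameters; same-padding preserves
spatial size before pooling; pooling gradients split ties evenly. The
whole training stack is numpy, deterministic for a fixed seed.

Evaluation reports ROC AUC and average precision overall and per
novel-amino-acid bin (count of test residues outside the training
chain's alphabet: 0, 1, 2, 3, 4+), mean predicted score per screening
round, Spearman rank correlation of round means against an external
per-round scalar when given, and a top-K hit table against ground-truth
labels when given. Single-class label sets yield explicitly undefined
metrics rather than a silent number.

**Transfer experiment.** The restricted-alphabet design shares the
expanded design's position geometry; one landscape is drawn over the
per-position alphabet unions so both screens see the same ground truth.
The model trains on the restricted screen (Z-A over 8 amino acids, Z-B
over 5) and classifies enriched-vs-naive pairs of the expanded screen
(11 amino acids per chain), stratified by novel-amino-acid bin. Scaled
problem sizes: 20,000-pair naive training pool, 12,000-pair test pool,
six selection rounds pooling rounds 5–6, 1,200 positives (2,400 training
examples), ~2,000 test pairs per seed. Per-bin AUC declines as more
unseen amino acids enter the test pairs, because a novel residue's
single-site contribution is only partially predictable through its
factor scores (the roughness fraction is irreducible), while in-alphabet
positions continue to carry signal. At these CPU-scale settings the
per-bin decline is clean and monotone, while the overall AUC sits below
what an ideal learner could reach on the same screens: an oracle that
knows the full landscape for training-alphabet residues and only the
factor-predictable part for novel ones scores well above the trained
CNN, so the remaining gap is a capacity/optimization effect of the small
network and linear embedder, not a property of the screens themselves.
Larger channel counts did not close it reliably (their effect varies in
sign across seeds at this training-set size).

## Pipeline

`run_pipeline` executes simulate → filter → network → coupling → train
from one validated configuration; any stage is skippable. One global seed
fans out to per-stage seeds by SHA-256 hashing of the stage name, so
stages rerun independently yet reproducibly. Every text artifact carries
the configuration hash (computed over all settings except the output
location) and seed; the report records a digest over all artifact bytes,
and identical configuration + seed yields an identical digest. The CLI
(`coevoscreen`) mirrors the stages as subcommands plus `run-all`.

## Numerical and testing notes

* Hypergeometric p-values use the scipy survival function; exactness is
  tested against rational-arithmetic enumeration (exhaustive for small
  populations, randomized to N = 200) at 10⁻¹² relative error, and
  calibration against a permuted-pairing null (marginals preserved) in a
  large-count regime where the discrete p-value distribution is close to
  uniform.
* The ADMM graphical lasso is checked three ways: closed forms (1-D,
  diagonal water-filling), a convex duality-gap certificate bounding
  suboptimality at the returned solution, and an independent Frank–Wolfe
  solver with certified gap on small instances.
* The CNN's analytic gradients are verified against central differences;
  training determinism is asserted at byte level on the loss history and
  weights.
* Statistical acceptance checks (planted-coupling recovery, null
  calibration, transfer) run at stated seeds and problem sizes chosen so
  the full suite completes on one CPU; they are frequency claims over
  seeds (e.g. ≥18/20), not per-seed guarantees.

## Known limitations

* The simulator's selection model is a single scalar retention per pair;
  competitive effects enter only through renormalization, not through
  explicit binding competition for shared partners.
* Connected components can chain distinct specificity groups through
  single intermediate sequences at larger thresholds; the published
  analyses' community structure may differ under other clustering rules.
* The built-in embedder is a five-factor linear proxy; it captures
  chemical similarity but none of the contextual epistasis a transformer
  language model encodes. Absolute transfer AUC values at simulator scale
  are not comparable to language-model results on real screens.
* The constrained graphical lasso's default budget is data-scaled; users
  reproducing a fixed-α analysis should pass it explicitly and should
  expect a diagonal estimate when α is far below ‖(S+εI)⁻¹‖₁.
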