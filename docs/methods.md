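# Methods

## Model

`combistate` segments a genome into chromatin states with a **univariate
hidden Markov model over a combinatorial observation alphabet**.  Given an
ordered panel of `n` epigenetic marks (ChIP-seq of a transcription factor,
histone modifications, Pol-II, open chromatin), every fixed-width genomic bin
is reduced to a presence/absence vector over the panel and packed into a
single symbol from the alphabet of `2^n` mark subsets (leftmost bit = first
panel mark).  The hidden chain `Y_t` is first-order and segment-homogeneous;
state `j` emits symbol `O_k` with categorical probability `b_j(O_k)`, so each
state carries a full joint distribution over mark *combinations* rather than
independent per-mark probabilities.  That is the point of the design: a
narrow-binding transcription factor is never averaged away against broad
histone marks, and mark co-occurrence within a state is represented exactly.

Because in practice only a small fraction of the `2^n` subsets occurs, an
optional **compact alphabet** maps the observed bit-codes to consecutive IDs
(ascending bit-code order) and back; model size then scales with the data.

## Preprocessing

* **Binning.** Chromosomes are tiled left to right with fixed-width bins
  (default 750 bp); the final bin of a chromosome is kept even when
  truncated.  Coordinates are 0-based half-open throughout.
* **Read assignment.** Each aligned read contributes its strand-aware 5' end
  (plus/unstranded: `start`; minus: `end - 1`) to exactly one bin.
  Pre-binned count tables are accepted in place of reads.
* **Binarization.** Per mark and cell type, the background rate λ is the
  genome-wide mean count per bin.  A bin with count `c` is called present iff
  `Pr[X ≥ c | Poisson(λ)] < 10⁻⁴` (strict); `c = 0` is never present.  The
  truncated final bin is treated as a full bin for λ — negligible at genome
  scale.  Cell types are binarized independently (their sequencing depths
  differ); each (cell type × chromosome) then becomes one observation
  sequence for a single shared HMM.

## Training

Inference uses the scaled forward–backward recursions: forward vectors are
renormalized at every position and the log-likelihood accumulated from the
normalizers, so no product over the sequence length can underflow; the
backward pass reuses the forward scales, making `α_t ⊙ β_t` the posterior
occupancy directly.  Baum–Welch pools sufficient statistics over all
sequences; the initial distribution update averages the first-position
posteriors across sequences.  After every re-estimation each probability row
is floored at 10⁻⁶ and renormalized (entries below the floor are raised to
exactly the floor and the remaining mass shared proportionally, iterated to a
fixed point).  Training runs a fixed iteration count with no early stopping
(a `tol` parameter exists but is off by default).  Decoding is Viterbi in log
space with ties broken toward the lower state index.

**Model selection** follows a two-stage protocol: five models are trained for
300 iterations from independent random starts and the one with the lowest
BIC is kept, where `BIC = −2 lnL + k ln T_total` and
`k = n(n−1) + n(m−1) + (n−1)` counts the free parameters of the transition,
emission and initial simplices.  The selected model is Viterbi-decoded over
all sequences; states called in fewer bins than 5% of the per-state average
(total bins / n, strict inequality) are removed, each surviving transition
row's mass toward removed states is split **equally** among the surviving
columns (a proportional mode is available behind a flag), removed rows are
dropped, and emission rows are untouched.  The pruned model is retrained for
100 further iterations.  Pruning is applied exactly once.

### Initialization

Initial and emission rows are drawn from a symmetric Dirichlet(1).  The
transition start is `0.9·I + 0.1·Dirichlet(1)` per row (the `transition_bias`
parameter; 0 gives a fully random start).  The diagonal bias matters: genomic
bins are strongly autocorrelated, and with a near-uniform transition start the
early E-steps mix states along the sequence, the emission rows drift toward
blends of the true patterns, and the ensemble converges to optima we measured
at ≈10⁴ nats below the basin reached from a truth-structured start — with
visibly merged or split states.  Seeding the transitions with the model's own
segment-homogeneity assumption removes this failure mode entirely in the
recovery experiments below while leaving the ensemble fully stochastic.

## TF-state calling

The genome is Viterbi-decoded and, because emissions live on combinations,
per-mark probabilities are obtained by **marginalization**: the probability
that state `j` carries mark `i` is the sum of `b_j` over all symbols whose
bit pattern contains bit `i`.  Marginals can be computed from the model
emissions (global) or from the observed symbol frequencies of the bins called
as each state, optionally per cell type — the per-cell-type view uses
observed frequencies under the shared model's calls.  As a fit diagnostic,
the squared Pearson correlation between the flattened emission matrix and the
per-state observed-frequency matrix is reported (empty states excluded).

A mark is *associated* with a state when its marginal exceeds 0.1 (strict);
a state is a **TF-state** when the designated TF mark is associated.  A
configurable YAML rule table attaches functional labels to TF-states from the
associated-mark sets and the state's genomic location profile: promoter-like
(promoter marks, modal location 5'TSS), intragenic enhancer (enhancer marks
plus the elongation mark, majority of bins in gene bodies), distal enhancer
(enhancer marks, majority of bins outside gene bodies and TSSs), and
non-combinatorial TF-state (only the TF associated).  The "majority" and
"modal" operators and the mark sets are data in the rule table, not code.

## Genome annotation

Bin **midpoints** are compared to gene spans (union of each gene's
transcripts).  Region categories and default windows: 5'TSS = TSS ± 2 kb;
5'Proximal = 2–10 kb upstream; 5'Distal = 10–90 kb upstream; Intragenic =
the gene span; 3'Proximal = 0–10 kb downstream of the TES; 3'Distal =
10–90 kb downstream; anything further is GeneDesert.  The 3'Proximal window
starts at 0 (not 2 kb) so the category system has no gap at the gene end —
the TSS window covers the first 2 kb only on the 5' side.  When several genes
disagree the precedence is 5'TSS > Intragenic > 5'Proximal > 3'Proximal >
5'Distal > 3'Distal, then nearest gene, then input order.  All windows are
configurable.

**Metagene profiles** map every gene body linearly onto 100 virtual bins with
90-kb flanks sampled at the native bin width, oriented 5'→3' (minus-strand
genes mirror their sampling coordinates); genes shorter than one native bin
are skipped and counted.  **Expression summaries** use the maximum expression
over a gene's splice variants; each state's average expression weights genes
by the number of the state's bins assigned to them (a bin counts as "near" a
gene when its category is anything but GeneDesert), with optional
log2-with-floor-1 transform and z-scoring across states.  **Interval overlap**
(for repeat tracks and similar) merges bookended/overlapping regions, drops
merged regions shorter than 500 bp, and reports the fraction of each state's
bins whose midpoint falls in a surviving region.

## Synthetic study conditions

The generator emulates the statistical structure the method assumes while
staying independent of how the model is fit: a known HMM produces hidden
paths; given the state, each mark is present by an independent Bernoulli draw
(explicit combination tables are also supported — the fitting code never
assumes per-mark independence); present marks draw Poisson(λ_fg) read counts
and absent marks Poisson(λ_bg).

Standard conditions (fixed once, used by the recovery tests): 4 states ×
5 marks (TF, H3K4me1, H3K27ac, H3K36me3, H3K4me3); a dominant quiescent
background (stationary weight 0.7) plus promoter-like, intragenic-enhancer-
like and distal-enhancer-like states (weight 0.1 each) that all carry the TF;
transitions `0.95·I + 0.05·w` so the weights `w` are exactly the stationary
distribution; four sequences of 50,000 bins (T = 2×10⁵; two cell types × two
chromosomes); λ_fg = 30, λ_bg = 0.25.  These give genome-wide per-mark
presence of roughly 3–21%, matching the sparsity of real ChIP-seq panels, and
an enrichment strong enough that the Poisson binarizer's false-negative rate
is below 1% — as for deeply sequenced marks.  What the generator does **not**
emulate: mappability and duplicate artifacts, copy-number amplification,
fragment-length smearing, replicate structure, and between-mark technical
correlation; passing the recovery tests therefore demonstrates correctness of
the estimation machinery, not robustness to those real-data pathologies.

State identifiability is only up to relabeling, so recovered states are
matched to planted states by exact rectangular assignment
(`linear_sum_assignment`) on a per-state distance between mark-marginal
vectors, defined as the **maximum over marks** of |p − q| (the per-mark
Bernoulli total variation; the marginal vector itself is not a distribution,
so the distributional TV does not apply).  Under the standard conditions the
full pipeline — Poisson counts → binarize → encode → compact → 5×300-iteration
ensemble with a 6-state budget → BIC selection → prune → 100-iteration refine
— recovers all four planted states with worst-case marginal distance ≲ 0.02
in five out of five generator seeds, and surplus states starve below the 5%
pruning threshold as the protocol expects.

## Numerical and degenerate-input choices

* All path computations are in scaled or log space; zero probabilities map
  to −inf in Viterbi without warnings.
* Row-stochasticity is enforced to within 10⁻⁹ by construction; validation
  rejects anything worse.
* Empty sequences, empty sequence sets, symbols outside the alphabet,
  all-zero mark columns, removing every state, and genes without expression
  are rejected or flagged explicitly rather than silently tolerated.
* `floor_normalize` guarantees every entry ≥ floor after renormalization by
  distributing the deficit proportionally over unfloored entries (terminates
  because the floored set grows monotonically).
* Viterbi and assignment tie-breaks are deterministic (lowest index / input
  order), so every pipeline stage is bit-reproducible from its seeds.

## Known limitations

* Per-bin loops in read counting are Python-level; genome-scale read sets are
  better supplied as pre-binned count tables.
* Gene-category assignment loops over genes per chromosome — fine for the
  annotation sizes used here, not tuned for 10⁵ transcripts.
* The BIC parameter count treats all floored entries as free parameters.
* Functional labels are only as good as the rule table; the defaults encode
  the conventional promoter/enhancer mark grammar and nothing else.
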