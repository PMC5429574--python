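# combistate

Chromatin-state segmentation built around a specific transcription factor.

Genome segmentation tools such as multivariate-emission HMMs treat a TF's
ChIP-seq track like any broad histone mark, so narrow TF binding tends to be
averaged into whatever chromatin context surrounds it.  `combistate` takes
the opposite route: the `n` tracks of an epigenetic panel (TF, histone
modifications, Pol-II, DNase) are binarized per genomic bin and packed into a
**single categorical observation** from the combinatorial alphabet of `2^n`
mark subsets.  A univariate hidden Markov model over that alphabet then
assigns every bin a chromatin state whose emission distribution covers mark
*combinations* exactly — including the rare ones that contain the TF — and
states whose marginal TF probability is high are called **TF-states** and
annotated against gene structure and expression (TF promoter, TF intragenic
enhancer, TF distal enhancer, non-combinatorial TF binding).

It is aimed at regulatory genomicists who have binned or aligned ChIP-seq
panels for one or more cell types and want TF-centric chromatin states with
reproducible, scriptable machinery.

## Model in brief

* Observation per bin: symbol `X_t ∈ {0,…,2^n−1}`, bit `i` = presence of
  panel mark `i` (present iff `Pr[X ≥ c | Poisson(λ_mark)] < 10⁻⁴`).
* Hidden chain: first-order, segment-homogeneous; `λ = (A, B, π)` trained by
  scaled Baum–Welch over all (cell type × chromosome) sequences jointly,
  with a 10⁻⁶ probability floor and fixed iteration counts.
* Protocol: five random initializations × 300 iterations → lowest
  `BIC = −2 lnL + k ln T` wins → states called in fewer bins than 5% of the
  per-state average are pruned (transition mass redistributed uniformly) →
  100 more iterations → Viterbi segmentation.
* Per-mark state probabilities by marginalization:
  `P_j(mark i) = Σ_{x : x & bit_i ≠ 0} b_j(x)`; a mark is associated with a
  state when this exceeds 0.1, and TF-states are states whose TF mark is
  associated.

See `docs/methods.md` for the full account, including the synthetic study
conditions and every numerical choice.

## Worked example

Simulate a small genome from a known 4-state model, push it through the full
pipeline, and compare recovered states with the planted ones:

```python
import combistate as cs

spec = cs.default_spec(seq_lengths=(20_000,) * 4)     # 4 sequences, 5 marks
data = cs.sample_generative_model(spec, seed=0)       # truth HMM + calls
seqs = cs.binarized_sequences(data, seed=1)           # counts -> calls -> symbols
amap, compact = cs.compact_alphabet(seqs)             # m = 32 observed symbols

res = cs.fit_two_stage(compact, n_states=6, n_models=3,
                       n_iter=150, n_iter_refine=50, base_seed=0)
marg = cs.emission_mark_marginals(res.model, spec.panel, amap)
print(marg.round(3))
match = cs.match_states(marg.to_numpy(), data.true_mark_marginals())
print(match.pairs, match.distances.round(3))
```

Output:

```
      TF  H3K4me1  H3K27ac  H3K36me3  H3K4me3
0  0.442    0.843    0.741     0.049    0.045
1  0.590    0.099    0.300     0.048    0.901
2  0.020    0.050    0.050     0.049    0.018
3  0.454    0.767    0.701     0.779    0.080
4  0.619    0.801    0.689     0.812    0.127
[(0, 2), (1, 1), (2, 3), (3, 0)] [0.002 0.01  0.046 0.009]
```

One of six trained states was pruned (called in fewer bins than 5% of the
per-state average); the five survivors' mark marginals are shown.  State 2 is
the quiescent background (all marginals ≈ 0.02–0.05), state 1 the
promoter-like state (TF + H3K4me3), state 0 the distal-enhancer-like state
(TF + H3K4me1/H3K27ac without H3K36me3), and states 3/4 split the planted
intragenic-enhancer pattern.  The assignment line matches each planted state
(first index) to its best recovered state (second index) with the worst-mark
marginal difference per pair: every planted state is recovered within 0.05.
On the same run the emission-vs-observed-frequency fit gives R² = 0.993
(`cs.emission_fit_qc`).

The same pipeline is available from the shell:

```bash
combistate simulate --out sim/ --seed 1
combistate binarize --counts sim/counts_cellA.tsv --counts sim/counts_cellB.tsv \
                    --panel sim/panel.yaml --out bin/
combistate train  --symbols bin/symbols.tsv --alphabet-map bin/alphabet_map.tsv \
                  --panel sim/panel.yaml --states 25 --iters 300 --models 5 \
                  --seed 0 --out best.json
combistate refine --model best.json --symbols bin/symbols.tsv --out final.json
combistate call   --model final.json --symbols bin/symbols.tsv --out calls/
combistate annotate --segmentation calls/segmentation.tsv \
                    --genes sim/genes.refflat --expr sim/expression.tsv --out anno/
```

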