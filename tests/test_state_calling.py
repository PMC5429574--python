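import numpy as np
import pandas as pd
import pytest

import combistate as cs
from combistate import (MarkPanel, Segmentation, SymbolSequence,
                        classify_tf_states, decode_genome, emission_fit_qc,
                        emission_mark_marginals, label_functional_states,
                        marginalize_marks, observed_mark_marginals,
                        state_symbol_frequencies)
from combistate.hmm import CombinatorialHMM
from combistate.preprocess import decode_bits
from combistate.state_calling import StateFrequencies


def seq(symbols, m, ct="ct", chrom="chr1"):
    return SymbolSequence(ct, chrom, np.asarray(symbols), "full", m)


def bitwise_marginals_oracle(dist, n_marks):
    """Exhaustive summation: P(mark) = sum over symbols containing its bit."""
    out = np.zeros(n_marks)
    for i in range(n_marks):
        bit = 1 << (n_marks - 1 - i)
        out[i] = sum(p for x, p in enumerate(dist) if x & bit)
    return out


class TestDecodeGenome:
    def test_single_state_model(self):
        model = CombinatorialHMM.from_params([1.0], [[1.0]], [[0.5, 0.5]])
        seg = decode_genome(model, [seq([0, 1, 0], 2)])
        assert seg.paths[0].tolist() == [0, 0, 0]

    def test_private_symbol_toy_mirrors_symbols(self):
        model = CombinatorialHMM.from_params(
            [0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]],
            [[1.0, 0.0], [0.0, 1.0]], floor=0.0, validate=False)
        seg = decode_genome(model, [seq([1, 0, 1], 2), seq([0, 0], 2)])
        assert seg.paths[0].tolist() == [1, 0, 1]
        assert seg.total_bins == 5

    def test_bin_conservation(self):
        model = CombinatorialHMM.from_params([1.0], [[1.0]], [[0.5, 0.5]])
        seqs = [seq(np.zeros(k, dtype=int), 2) for k in (3, 7, 11)]
        assert decode_genome(model, seqs).total_bins == 21


class TestStateSymbolFrequencies:
    def seg_for(self, paths, m):
        return Segmentation(cell_types=["a", "b"][:len(paths)],
                            chroms=["chr1"] * len(paths),
                            paths=[np.asarray(p) for p in paths],
                            n_states=2)

    def test_counting(self):
        seg = self.seg_for([[0, 0, 0, 0]], 8)
        freqs = state_symbol_frequencies(seg, [seq([4, 4, 0, 4], 8, ct="a")])
        assert freqs.freqs[0, 4] == 0.75
        assert freqs.freqs[0, 0] == 0.25
        assert freqs.bin_counts.tolist() == [4, 0]
        assert freqs.empty_states == [1]

    def test_stratified_tables_recombine_to_global(self, rng):
        paths = [rng.integers(0, 2, 40), rng.integers(0, 2, 60)]
        seqs = [seq(rng.integers(0, 4, 40), 4, ct="a"),
                seq(rng.integers(0, 4, 60), 4, ct="b")]
        seg = self.seg_for(paths, 4)
        glob = state_symbol_frequencies(seg, seqs)
        strat = state_symbol_frequencies(seg, seqs, stratify_by_celltype=True)
        for s in range(2):
            num = sum(f.freqs[s] * f.bin_counts[s] for f in strat.values())
            den = sum(f.bin_counts[s] for f in strat.values())
            assert np.allclose(num / max(den, 1), glob.freqs[s])

    def test_misalignment_rejected(self):
        seg = self.seg_for([[0, 1]], 4)
        with pytest.raises(ValueError):
            state_symbol_frequencies(seg, [seq([0, 1, 2], 4, ct="a")])


class TestMarginalization:
    def test_two_mark_worked_example(self):
        panel = MarkPanel(("m1", "m2"), tf="m1")
        dist = np.array([0.0, 0.25, 0.25, 0.5])  # P(00), P(01), P(10), P(11)
        marg = marginalize_marks(dist, panel)
        assert np.allclose(marg, [0.75, 0.75])

    def test_empty_combination_only(self):
        panel = MarkPanel(("m1", "m2", "m3"), tf="m1")
        dist = np.zeros(8)
        dist[0] = 1.0
        assert np.allclose(marginalize_marks(dist, panel), 0.0)

    @pytest.mark.parametrize("n", range(1, 11))
    def test_uniform_distribution_gives_half(self, n):
        panel = MarkPanel(tuple(f"m{i}" for i in range(n)), tf="m0")
        dist = np.full(2 ** n, 1.0 / 2 ** n)
        assert np.allclose(marginalize_marks(dist, panel), 0.5)

    @pytest.mark.parametrize("n", range(1, 11))
    def test_matches_exhaustive_bitwise_summation(self, n, rng):
        panel = MarkPanel(tuple(f"m{i}" for i in range(n)), tf="m0")
        dist = rng.dirichlet(np.ones(2 ** n))
        assert np.allclose(marginalize_marks(dist, panel),
                           bitwise_marginals_oracle(dist, n), atol=1e-12)

    def test_marginal_dominates_any_single_combination(self, rng):
        panel = MarkPanel(("a", "b", "c"), tf="a")
        dist = rng.dirichlet(np.ones(8))
        marg = marginalize_marks(dist, panel)
        for x in range(8):
            bits = decode_bits(np.array([x]), 3)[0]
            for i in range(3):
                if bits[i]:
                    assert marg[i] >= dist[x] - 1e-12

    def test_compact_distribution_requires_map(self):
        panel = MarkPanel(("a", "b"), tf="a")
        with pytest.raises(ValueError):
            marginalize_marks(np.array([0.5, 0.5]), panel)
        amap = cs.AlphabetMap(full_codes=(0, 3), full_size=4)
        marg = marginalize_marks(np.array([0.5, 0.5]), panel, amap)
        assert np.allclose(marg, [0.5, 0.5])


class TestEmissionFitQC:
    def test_perfect_fit_gives_one(self):
        B = np.array([[0.7, 0.3], [0.2, 0.8]])
        model = CombinatorialHMM.from_params([0.5, 0.5],
                                             [[0.5, 0.5], [0.5, 0.5]], B)
        freqs = StateFrequencies(freqs=B.copy(),
                                 bin_counts=np.array([10, 10]))
        assert emission_fit_qc(model, freqs) == pytest.approx(1.0)

    def test_matches_textbook_formula_on_constructed_case(self):
        B = np.array([[0.8, 0.2], [0.4, 0.6]])
        obs = np.array([[0.5, 0.5], [0.9, 0.1]])
        model = CombinatorialHMM.from_params([0.5, 0.5],
                                             [[0.5, 0.5], [0.5, 0.5]], B)
        freqs = StateFrequencies(freqs=obs, bin_counts=np.array([5, 5]))
        a, b = B.ravel(), obs.ravel()
        r = (np.mean(a * b) - a.mean() * b.mean()) / (a.std() * b.std())
        assert emission_fit_qc(model, freqs) == pytest.approx(r ** 2)

    def test_self_generated_data_fits_well(self):
        spec = cs.default_spec(seq_lengths=(20_000,), cell_types=("c",),
                               chroms=("chr1",))
        data = cs.sample_generative_model(spec, seed=9)
        seg = Segmentation(cell_types=["c"], chroms=["chr1"],
                           paths=data.hidden_paths, n_states=4)
        freqs = state_symbol_frequencies(seg, data.sequences)
        assert emission_fit_qc(data.model, freqs) > 0.99

    def test_empty_states_are_excluded(self):
        B = np.array([[0.7, 0.3], [0.5, 0.5]])
        model = CombinatorialHMM.from_params([1.0, 0.0],
                                             [[1.0, 0.0], [0.0, 1.0]], B,
                                             validate=False)
        freqs = StateFrequencies(freqs=np.array([[0.7, 0.3], [0.0, 0.0]]),
                                 bin_counts=np.array([9, 0]))
        assert emission_fit_qc(model, freqs) == pytest.approx(1.0)


class TestClassification:
    def marginals(self, rows, panel):
        return pd.DataFrame(rows, columns=list(panel.marks))

    def test_strict_cutoff(self, nine_mark_panel):
        rows = np.zeros((2, 9))
        rows[0, 0] = 0.15        # TF marginal above cutoff
        rows[1, 0] = 0.10        # exactly at cutoff: not associated
        cls = classify_tf_states(self.marginals(rows, nine_mark_panel),
                                 nine_mark_panel, cutoff=0.1)
        assert cls.frame.loc[0, "is_tf_state"]
        assert not cls.frame.loc[1, "is_tf_state"]
        assert cls.frame.loc[1, "label"] == "quiescent/background"

    def test_invariant_to_state_permutation(self, nine_mark_panel, rng):
        rows = rng.random((5, 9)) * 0.4
        marg = self.marginals(rows, nine_mark_panel)
        perm = rng.permutation(5)
        cls = classify_tf_states(marg, nine_mark_panel)
        cls_p = classify_tf_states(
            self.marginals(rows[perm], nine_mark_panel), nine_mark_panel)
        for new_idx, old_idx in enumerate(perm):
            assert (cls_p.frame.loc[new_idx, "associated_marks"]
                    == cls.frame.loc[old_idx, "associated_marks"])

    def location(self, fractions):
        df = pd.DataFrame(fractions,
                          columns=list(cs.annotation.CATEGORIES))
        df.index.name = "state"
        return df

    def test_functional_labels_from_rules(self, nine_mark_panel):
        panel = nine_mark_panel
        rows = np.zeros((4, 9))
        # state 0: TF + Pol-II + H3K4me3, modal 5'TSS -> promoter
        rows[0, [0, 1, 3]] = [0.3, 0.5, 0.6]
        # state 1: TF + H3K4me1 + H3K27ac + H3K36me3, 76% intragenic
        rows[1, [0, 2, 5, 6]] = [0.3, 0.6, 0.5, 0.4]
        # state 2: TF + enhancer marks, mostly outside gene bodies
        rows[2, [0, 2, 5]] = [0.3, 0.6, 0.5]
        # state 3: TF only -> non-combinatorial
        rows[3, 0] = 0.4
        loc = np.zeros((4, 7))
        loc[0] = [0.60, 0.10, 0.05, 0.15, 0.04, 0.03, 0.03]
        loc[1] = [0.05, 0.05, 0.05, 0.76, 0.04, 0.03, 0.02]
        loc[2] = [0.05, 0.10, 0.40, 0.25, 0.05, 0.10, 0.05]
        loc[3] = [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0]
        cls = classify_tf_states(self.marginals(rows, panel), panel)
        cls = label_functional_states(cls, self.marginals(rows, panel),
                                      self.location(loc), panel)
        assert cls.frame["label"].tolist() == [
            "TF-promoter", "TF-intragenic-enhancer", "TF-distal-enhancer",
            "non-combinatorial TF-state"]

    def test_non_tf_states_pass_through_unlabeled(self, nine_mark_panel):
        rows = np.zeros((1, 9))
        rows[0, 2] = 0.5        # enhancer mark but no TF
        cls = classify_tf_states(self.marginals(rows, nine_mark_panel),
                                 nine_mark_panel)
        cls = label_functional_states(cls, self.marginals(rows, nine_mark_panel),
                                      None, nine_mark_panel)
        assert cls.frame.loc[0, "label"] is None

    def test_planted_tf_state_recovered_from_simulation(self):
        # the generator's TF-sharing states must come out flagged
        spec = cs.default_spec()
        truth = spec.truth_model()
        marg = emission_mark_marginals(truth, spec.panel)
        cls = classify_tf_states(marg, spec.panel)
        assert cls.tf_states() == [1, 2, 3]
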