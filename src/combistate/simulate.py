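"""Ground-truth simulators for every pipeline stage.

A known HMM over a small mark panel generates hidden state paths, per-bin
mark-presence calls (independent per-mark Bernoulli draws given the state),
Poisson read counts (enriched foreground vs. flat background), and toy gene
annotations with log-normal expression.  Everything is reproducible from a
single seed.  The fitting code never assumes the per-mark independence used
here: emissions stay fully combinatorial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .annotation import GeneAnnotation
from .hmm import CombinatorialHMM
from .preprocess import (FULL, BinaryCalls, MarkPanel, SymbolSequence,
                         encode_bits, decode_bits)
from .state_calling import marginalize_marks

DEFAULT_LAMBDA_FG = 30.0
DEFAULT_LAMBDA_BG = 0.25


@dataclass
class GeneratorSpec:
    """Conditions for the synthetic genome generator.

    ``state_mark_probs[k, i]`` is the probability that mark ``i`` is present
    in a bin of state ``k`` (an explicit per-state distribution over full
    symbols may be given instead via ``state_symbol_probs``).  The transition
    matrix is ``self_transition * I + (1 - self_transition) * state_weights``
    row-wise, making ``state_weights`` the stationary distribution.
    """

    panel: MarkPanel
    state_mark_probs: np.ndarray | None = None
    state_symbol_probs: np.ndarray | None = None
    self_transition: float = 0.95
    state_weights: np.ndarray | None = None
    seq_lengths: tuple[int, ...] = (50_000, 50_000, 50_000, 50_000)
    cell_types: tuple[str, ...] | None = None
    chroms: tuple[str, ...] | None = None
    lambda_fg: float = DEFAULT_LAMBDA_FG
    lambda_bg: float = DEFAULT_LAMBDA_BG

    def __post_init__(self):
        if (self.state_mark_probs is None) == (self.state_symbol_probs is None):
            raise ValueError(
                "give exactly one of state_mark_probs / state_symbol_probs")
        if self.state_mark_probs is not None:
            self.state_mark_probs = np.asarray(self.state_mark_probs, dtype=float)
            if self.state_mark_probs.shape[1] != self.panel.n:
                raise ValueError("state_mark_probs columns must match panel")
            if ((self.state_mark_probs < 0) | (self.state_mark_probs > 1)).any():
                raise ValueError("mark probabilities must lie in [0, 1]")
        else:
            self.state_symbol_probs = np.asarray(self.state_symbol_probs, dtype=float)
            if self.state_symbol_probs.shape[1] != self.panel.alphabet_size:
                raise ValueError("state_symbol_probs columns must be 2**n")
        if not 0 <= self.self_transition <= 1:
            raise ValueError("self_transition must lie in [0, 1]")
        if not self.lambda_fg > self.lambda_bg >= 0:
            raise ValueError("need lambda_fg > lambda_bg >= 0")
        if not self.seq_lengths:
            raise ValueError("at least one sequence length required")

    @property
    def n_states(self) -> int:
        probs = (self.state_mark_probs if self.state_mark_probs is not None
                 else self.state_symbol_probs)
        return probs.shape[0]

    def truth_model(self) -> CombinatorialHMM:
        """The generating HMM over the full 2**n alphabet."""
        k, n = self.n_states, self.panel.n
        w = (np.full(k, 1.0 / k) if self.state_weights is None
             else np.asarray(self.state_weights, dtype=float))
        w = w / w.sum()
        A = self.self_transition * np.eye(k) + (1 - self.self_transition) * w
        if self.state_symbol_probs is not None:
            B = self.state_symbol_probs / self.state_symbol_probs.sum(
                axis=1, keepdims=True)
        else:
            bits = decode_bits(np.arange(2 ** n), n)        # (2**n, n)
            p = self.state_mark_probs                       # (k, n)
            B = np.prod(np.where(bits[None], p[:, None, :], 1 - p[:, None, :]),
                        axis=2)
        return CombinatorialHMM.from_params(w, A, B, validate=True)

    def sequence_labels(self) -> list[tuple[str, str]]:
        n = len(self.seq_lengths)
        cts = self.cell_types or tuple(f"cell{i}" for i in range(n))
        chs = self.chroms or tuple(f"chr{i + 1}" for i in range(n))
        if len(cts) != n or len(chs) != n:
            raise ValueError("cell_types/chroms must match seq_lengths")
        return list(zip(cts, chs))


def default_spec(**overrides) -> GeneratorSpec:
    """The standard 4-state, 5-mark study conditions.

    A dominant quiescent background (stationary weight 0.7) plus promoter-,
    intragenic-enhancer- and distal-enhancer-like states sharing the TF,
    with sparse genome-wide mark presence as in real ChIP-seq panels.
    """
    panel = MarkPanel(
        marks=("TF", "H3K4me1", "H3K27ac", "H3K36me3", "H3K4me3"), tf="TF")
    state_mark_probs = np.array([
        [0.02, 0.05, 0.05, 0.05, 0.02],   # quiescent background
        [0.60, 0.10, 0.30, 0.05, 0.90],   # promoter-like (TF + H3K4me3)
        [0.50, 0.80, 0.70, 0.80, 0.10],   # intragenic enhancer-like
        [0.45, 0.85, 0.75, 0.05, 0.05],   # distal enhancer-like
    ])
    kwargs = dict(panel=panel, state_mark_probs=state_mark_probs,
                  state_weights=np.array([0.7, 0.1, 0.1, 0.1]),
                  cell_types=("cellA", "cellA", "cellB", "cellB"),
                  chroms=("chr1", "chr2", "chr1", "chr2"))
    kwargs.update(overrides)
    n_seq = len(kwargs.get("seq_lengths", (0,) * 4))
    for key in ("cell_types", "chroms"):
        if key not in overrides and len(kwargs[key]) != n_seq:
            kwargs[key] = None      # fall back to generated labels
    return GeneratorSpec(**kwargs)


@dataclass
class SimulatedDataset:
    """Everything the generator knows about one synthetic genome."""

    spec: GeneratorSpec
    model: CombinatorialHMM                 # truth, full alphabet
    hidden_paths: list[np.ndarray]
    calls: list[BinaryCalls]                # per-sequence truth presence
    sequences: list[SymbolSequence]         # full-alphabet symbols

    def true_mark_marginals(self) -> np.ndarray:
        """Per-state mark marginals of the generating emissions."""
        return np.vstack([marginalize_marks(b, self.spec.panel)
                          for b in self.model.emissionprob_])


def sample_generative_model(spec: GeneratorSpec, seed: int = 0
                            ) -> SimulatedDataset:
    """Sample hidden paths, mark calls and symbol sequences from the spec."""
    rng = np.random.default_rng(seed)
    model = spec.truth_model()
    k, n = spec.n_states, spec.panel.n
    hidden, calls, seqs = [], [], []
    cum_trans = np.cumsum(model.transmat_, axis=1)
    for (ct, chrom), T in zip(spec.sequence_labels(), spec.seq_lengths):
        path = np.empty(T, dtype=np.int64)
        path[0] = rng.choice(k, p=model.startprob_)
        u = rng.random(T)
        for t in range(1, T):
            path[t] = np.searchsorted(cum_trans[path[t - 1]], u[t])
        if spec.state_mark_probs is not None:
            present = rng.random((T, n)) < spec.state_mark_probs[path]
        else:
            cum_emit = np.cumsum(model.emissionprob_, axis=1)
            symbols = np.array([np.searchsorted(cum_emit[s], v)
                                for s, v in zip(path, rng.random(T))])
            present = decode_bits(symbols, n)
        symbols = encode_bits(present, n)
        hidden.append(path)
        calls.append(BinaryCalls(cell_type=ct, calls=present))
        seqs.append(SymbolSequence(ct, chrom, symbols, FULL, 2 ** n))
    return SimulatedDataset(spec=spec, model=model, hidden_paths=hidden,
                            calls=calls, sequences=seqs)


def sample_counts(calls: BinaryCalls, lambda_fg: float = DEFAULT_LAMBDA_FG,
                  lambda_bg: float = DEFAULT_LAMBDA_BG,
                  seed: int = 0) -> np.ndarray:
    """Poisson read counts: present marks at lambda_fg, absent at lambda_bg."""
    if not lambda_fg > lambda_bg >= 0:
        raise ValueError("need lambda_fg > lambda_bg >= 0")
    rng = np.random.default_rng(seed)
    lam = np.where(calls.calls, lambda_fg, lambda_bg)
    return rng.poisson(lam)


def binarized_sequences(data: SimulatedDataset, seed: int = 0,
                        p_cutoff: float = 1e-4) -> list[SymbolSequence]:
    """Run the count pipeline on a simulated dataset: counts -> calls -> symbols.

    Poisson counts are drawn from the truth presence calls, pooled per cell
    type for background-rate estimation, binarized and re-encoded.  This
    exercises the preprocessing stage end to end with known ground truth.
    """
    from .preprocess import CountMatrix, binarize_counts, encode_symbols

    spec = data.spec
    by_ct: dict[str, list[int]] = {}
    for i, seq in enumerate(data.sequences):
        by_ct.setdefault(seq.cell_type, []).append(i)
    out: list[SymbolSequence] = []
    for k, (ct, idxs) in enumerate(by_ct.items()):
        stacked = np.vstack([data.calls[i].calls for i in idxs])
        counts = sample_counts(BinaryCalls(cell_type=ct, calls=stacked),
                               spec.lambda_fg, spec.lambda_bg, seed=seed + k)
        calls = binarize_counts(CountMatrix(cell_type=ct, counts=counts),
                                p_cutoff=p_cutoff)
        symbols = encode_bits(calls.calls, spec.panel.n)
        pos = 0
        for i in idxs:
            T = len(data.sequences[i])
            out.append(SymbolSequence(ct, data.sequences[i].chrom,
                                      symbols[pos:pos + T], FULL,
                                      spec.panel.alphabet_size))
            pos += T
    return out


def make_toy_annotation(n_genes: int = 10, genome_length: int = 1_000_000,
                        chrom: str = "chr1",
                        gene_length: tuple[int, int] = (5_000, 50_000),
                        max_transcripts: int = 3, minus_fraction: float = 0.5,
                        expr_log_mean: float = 1.0, expr_log_sigma: float = 1.0,
                        seed: int = 0) -> GeneAnnotation:
    """Non-overlapping toy genes with 1..max_transcripts transcripts each.

    Transcripts share the gene 5' end (TSS) and vary at the 3' end, so the
    gene span is the transcript union; expression is log-normal per
    transcript.  Raises if the genes cannot be packed into the genome.
    """
    rng = np.random.default_rng(seed)
    lengths = rng.integers(gene_length[0], gene_length[1] + 1, size=n_genes)
    slack = genome_length - int(lengths.sum())
    if slack < n_genes + 1:
        raise ValueError("genes do not fit on the toy genome")
    gaps = rng.multinomial(slack - (n_genes + 1), np.full(n_genes + 1, 1 / (n_genes + 1)))
    gaps = gaps + 1
    rows = []
    pos = 0
    for i, (length, gap) in enumerate(zip(lengths, gaps[:-1])):
        pos += int(gap)
        start, end = pos, pos + int(length)
        pos = end
        strand = "-" if rng.random() < minus_fraction else "+"
        n_tx = int(rng.integers(1, max_transcripts + 1))
        for j in range(n_tx):
            if n_tx == 1 or j == 0:
                ts, te = start, end
            else:
                # alternative 3' end: shorten the transcript at its 3' side
                cut = int(rng.integers(0, (end - start) // 2))
                ts, te = (start, end - cut) if strand == "+" else (start + cut, end)
            rows.append({
                "gene_id": f"gene{i}", "transcript_id": f"gene{i}.t{j}",
                "chrom": chrom, "strand": strand, "start": ts, "end": te,
                "expression": float(rng.lognormal(expr_log_mean, expr_log_sigma)),
            })
    return GeneAnnotation(transcripts=pd.DataFrame(rows))


@dataclass
class MatchResult:
    """Optimal injective matching of truth states into estimated states."""

    pairs: list[tuple[int, int]]            # (truth_state, estimated_state)
    distances: np.ndarray                   # per matched pair
    unmatched_truth: list[int]
    unmatched_estimated: list[int]

    @property
    def permutation(self) -> np.ndarray:
        """estimated-state index for each truth state (square case)."""
        perm = np.full(max(t for t, _ in self.pairs) + 1, -1, dtype=np.int64)
        for t, e in self.pairs:
            perm[t] = e
        return perm


def marginal_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Distance between two mark-marginal vectors: worst-mark |p - q|.

    Per mark this is the total variation between the two Bernoulli presence
    distributions; the maximum over marks is taken as the state distance.
    """
    return float(np.max(np.abs(np.asarray(p) - np.asarray(q))))


def match_states(estimated_marginals: np.ndarray, truth_marginals: np.ndarray
                 ) -> MatchResult:
    """Optimal one-to-one assignment between truth and estimated states.

    Minimizes the total mark-marginal distance with an exact rectangular
    assignment; with unequal state counts the best injective match is
    returned and leftovers are reported.
    """
    est = np.atleast_2d(np.asarray(estimated_marginals, dtype=float))
    tru = np.atleast_2d(np.asarray(truth_marginals, dtype=float))
    if est.shape[1] != tru.shape[1]:
        raise ValueError("marginal vectors must share the mark panel")
    cost = np.max(np.abs(tru[:, None, :] - est[None, :, :]), axis=2)
    rows, cols = linear_sum_assignment(cost)
    pairs = [(int(r), int(c)) for r, c in zip(rows, cols)]
    distances = cost[rows, cols]
    return MatchResult(
        pairs=pairs, distances=distances,
        unmatched_truth=[t for t in range(tru.shape[0]) if t not in set(rows)],
        unmatched_estimated=[e for e in range(est.shape[0]) if e not in set(cols)])
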