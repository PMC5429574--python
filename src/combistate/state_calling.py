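"""Genome decoding, per-mark marginal probabilities and TF-state calling.

After training, the genome is Viterbi-decoded into chromatin states.  Because
emissions live on the combinatorial alphabet, the probability that a state
carries an individual mark is obtained by marginalization: summing the state's
symbol distribution over every combination whose bit pattern contains that
mark.  A mark is "associated" with a state when its marginal exceeds a cutoff
(default 0.1, strict); states associated with the designated TF mark are
TF-states, and configurable rules attach functional labels (TF promoter,
intragenic/distal enhancer, ...) using the marginals plus the genomic location
profile of each state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import pearsonr

from .hmm import CombinatorialHMM
from .preprocess import AlphabetMap, BinGrid, MarkPanel, SymbolSequence, decode_bits

DEFAULT_MARK_CUTOFF = 0.1


@dataclass
class Segmentation:
    """Bin-aligned Viterbi state calls per (cell type, chromosome)."""

    cell_types: list[str]
    chroms: list[str]
    paths: list[np.ndarray]
    n_states: int
    grid: BinGrid | None = None

    def __post_init__(self):
        if not (len(self.cell_types) == len(self.chroms) == len(self.paths)):
            raise ValueError("cell_types, chroms and paths must align")
        for p in self.paths:
            if p.size and (p.min() < 0 or p.max() >= self.n_states):
                raise ValueError("state call outside model")

    @property
    def total_bins(self) -> int:
        return sum(len(p) for p in self.paths)

    def state_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_states, dtype=np.int64)
        for p in self.paths:
            counts += np.bincount(p, minlength=self.n_states)
        return counts

    def frame(self, bin_width: int | None = None) -> pd.DataFrame:
        """Dense per-bin table (cell_type, chrom, start, end, state)."""
        frames = []
        for ct, chrom, path in zip(self.cell_types, self.chroms, self.paths):
            if self.grid is not None and chrom in self.grid.chroms:
                width = self.grid.bin_width
                length = self.grid.lengths[self.grid.chroms.index(chrom)]
            else:
                width = bin_width or (self.grid.bin_width if self.grid else 1)
                length = width * len(path)
            starts = np.arange(len(path)) * width
            ends = np.minimum(starts + width, length)
            frames.append(pd.DataFrame({
                "cell_type": ct, "chrom": chrom,
                "start": starts, "end": ends, "state": path,
            }))
        return pd.concat(frames, ignore_index=True)

    def to_bed(self, path, cell_type: str, label_prefix: str = "state_"):
        """Write one cell type's calls as dense BED4."""
        df = self.frame()
        df = df[df["cell_type"] == cell_type]
        out = df[["chrom", "start", "end"]].copy()
        out["name"] = label_prefix + df["state"].astype(str)
        out.to_csv(path, sep="\t", header=False, index=False)


def decode_genome(model: CombinatorialHMM, sequences: Sequence[SymbolSequence],
                  grid: BinGrid | None = None) -> Segmentation:
    """Viterbi-decode every sequence into a genome segmentation."""
    paths = [model.predict(seq) for seq in sequences]
    return Segmentation(
        cell_types=[s.cell_type for s in sequences],
        chroms=[s.chrom for s in sequences],
        paths=paths, n_states=model.n_states, grid=grid)


@dataclass
class StateFrequencies:
    """Empirical symbol distribution of the bins called as each state.

    ``freqs`` rows sum to 1 except for empty states (all-zero rows, listed in
    ``empty_states``); ``bin_counts`` holds the per-state call counts.
    """

    freqs: np.ndarray          # (n_states, m)
    bin_counts: np.ndarray     # (n_states,)

    @property
    def empty_states(self) -> list[int]:
        return [int(s) for s in np.nonzero(self.bin_counts == 0)[0]]


def state_symbol_frequencies(seg: Segmentation,
                             sequences: Sequence[SymbolSequence],
                             stratify_by_celltype: bool = False):
    """Observed symbol frequencies under each called state.

    Returns a :class:`StateFrequencies` (global) or a dict keyed by cell type
    when ``stratify_by_celltype`` is set.  Cell-type tables recombine to the
    global table when weighted by per-cell-type bin counts.
    """
    if len(sequences) != len(seg.paths):
        raise ValueError("segmentation and sequences do not align")
    m = max(s.alphabet_size for s in sequences)
    groups: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for seq, path in zip(sequences, seg.paths):
        if len(seq) != len(path):
            raise ValueError(
                f"sequence {seq.cell_type}/{seq.chrom} does not align with calls")
        key = seq.cell_type if stratify_by_celltype else ""
        if key not in groups:
            groups[key] = (np.zeros((seg.n_states, m)), np.zeros(seg.n_states))
        counts, nbins = groups[key]
        np.add.at(counts, (path, seq.symbols), 1.0)
        nbins += np.bincount(path, minlength=seg.n_states)

    def _finish(counts, nbins):
        freqs = np.divide(counts, np.maximum(nbins, 1)[:, None])
        return StateFrequencies(freqs=freqs, bin_counts=nbins.astype(np.int64))

    if stratify_by_celltype:
        return {ct: _finish(*acc) for ct, acc in groups.items()}
    return _finish(*groups[""])


def marginalize_marks(distribution: np.ndarray, panel: MarkPanel,
                      alphabet_map: AlphabetMap | None = None) -> np.ndarray:
    """Per-mark marginal probability of a symbol distribution.

    For each mark the marginal is the total probability of all combinations
    whose bit pattern contains that mark.  ``distribution`` is over the full
    alphabet (length ``2**n``) unless an :class:`AlphabetMap` maps its compact
    indices back to full bit-codes.
    """
    dist = np.asarray(distribution, dtype=float)
    if alphabet_map is not None:
        codes = np.asarray(alphabet_map.full_codes)
        if len(dist) != alphabet_map.m:
            raise ValueError("distribution length does not match alphabet map")
    else:
        if len(dist) != panel.alphabet_size:
            raise ValueError(
                "compact-coded distribution requires an alphabet_map")
        codes = np.arange(panel.alphabet_size)
    bits = decode_bits(codes, panel.n)          # (m, n_marks)
    return dist @ bits


def emission_mark_marginals(model: CombinatorialHMM, panel: MarkPanel,
                            alphabet_map: AlphabetMap | None = None
                            ) -> pd.DataFrame:
    """Mark marginals of every state's emission row (states x marks)."""
    rows = [marginalize_marks(b, panel, alphabet_map)
            for b in model.emissionprob_]
    return pd.DataFrame(rows, columns=list(panel.marks))


def observed_mark_marginals(freqs: StateFrequencies, panel: MarkPanel,
                            alphabet_map: AlphabetMap | None = None
                            ) -> pd.DataFrame:
    """Mark marginals of the observed per-state symbol frequencies."""
    rows = [marginalize_marks(f, panel, alphabet_map) for f in freqs.freqs]
    return pd.DataFrame(rows, columns=list(panel.marks))


def emission_fit_qc(model: CombinatorialHMM, freqs) -> float | dict[str, float]:
    """Squared Pearson correlation between emissions and observed frequencies.

    Flattens the emission matrix and the per-state observed-frequency matrix
    (empty states excluded) and returns R^2; given a dict of per-cell-type
    frequency tables, returns one R^2 per cell type.
    """
    if isinstance(freqs, Mapping):
        return {ct: emission_fit_qc(model, f) for ct, f in freqs.items()}
    occupied = freqs.bin_counts > 0
    if occupied.sum() == 0:
        raise ValueError("no occupied states")
    a = model.emissionprob_[occupied].ravel()
    b = freqs.freqs[occupied].ravel()
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("R^2 undefined: fewer than 2 varying points")
    r, _ = pearsonr(a, b)
    return float(r ** 2)


@dataclass
class StateClassification:
    """Per-state associated marks, TF-state flag and functional label."""

    frame: pd.DataFrame  # columns: state, associated_marks, is_tf_state, label

    def tf_states(self) -> list[int]:
        return self.frame.loc[self.frame["is_tf_state"], "state"].tolist()


def classify_tf_states(marginals: pd.DataFrame, panel: MarkPanel,
                       cutoff: float = DEFAULT_MARK_CUTOFF
                       ) -> StateClassification:
    """Associate marks with states and flag TF-states.

    A mark is associated with a state iff its marginal is strictly greater
    than ``cutoff``; a state is a TF-state iff the designated TF mark is
    associated.  States with no associated marks are labeled
    "quiescent/background".
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    rows = []
    for state, row in marginals.iterrows():
        associated = tuple(m for m in panel.marks if row[m] > cutoff)
        is_tf = panel.tf in associated
        label = None if associated else "quiescent/background"
        rows.append({"state": state, "associated_marks": associated,
                     "is_tf_state": is_tf, "label": label})
    return StateClassification(frame=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# functional labeling rules

# Each rule: a label plus requirements on the associated-mark set and the
# state's location profile.  "TF" resolves to the panel's TF mark.  Location
# conditions: modal (the most frequent category is one of those listed),
# majority (> 0.5 of bins in the listed categories), majority_outside
# (< 0.5 of bins in the listed categories).  First matching rule wins.
DEFAULT_RULES: list[dict] = [
    {"label": "TF-promoter", "requires_tf": True,
     "marks_any": ["H3K4me3", "Pol-II"],
     "location": {"modal": ["5'TSS"]}},
    {"label": "TF-intragenic-enhancer", "requires_tf": True,
     "marks_any": ["H3K4me1", "H3K27ac"], "marks_all": ["H3K36me3"],
     "location": {"majority": ["Intragenic"]}},
    {"label": "TF-distal-enhancer", "requires_tf": True,
     "marks_any": ["H3K4me1", "H3K27ac"],
     "location": {"majority_outside": ["Intragenic", "5'TSS"]}},
    {"label": "non-combinatorial TF-state", "requires_tf": True,
     "marks_only": ["TF"]},
]


def load_rules(path) -> list[dict]:
    """Read a YAML functional-labeling rule table."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data["rules"] if isinstance(data, dict) else data


def _resolve(marks: list[str], panel: MarkPanel) -> list[str]:
    return [panel.tf if m == "TF" else m for m in marks]


def _rule_matches(rule: dict, associated: tuple[str, ...], is_tf: bool,
                  location_row: pd.Series | None, panel: MarkPanel) -> bool:
    if rule.get("requires_tf") and not is_tf:
        return False
    if "marks_only" in rule:
        if set(associated) != set(_resolve(rule["marks_only"], panel)):
            return False
    if "marks_all" in rule:
        if not set(_resolve(rule["marks_all"], panel)) <= set(associated):
            return False
    if "marks_any" in rule:
        if not set(_resolve(rule["marks_any"], panel)) & set(associated):
            return False
    loc = rule.get("location")
    if loc:
        if location_row is None:
            return False
        if "modal" in loc and location_row.idxmax() not in loc["modal"]:
            return False
        if "majority" in loc and location_row[loc["majority"]].sum() <= 0.5:
            return False
        if ("majority_outside" in loc
                and location_row[loc["majority_outside"]].sum() >= 0.5):
            return False
    return True


def label_functional_states(classification: StateClassification,
                            marginals: pd.DataFrame,
                            location: pd.DataFrame | None,
                            panel: MarkPanel,
                            rules: list[dict] | None = None
                            ) -> StateClassification:
    """Attach functional labels to TF-states via the rule table.

    ``location`` gives per-state fractions over the region categories (rows
    indexed by state).  States matched by no rule keep their existing label
    (null for combinatorial states without a rule).
    """
    rules = DEFAULT_RULES if rules is None else rules
    frame = classification.frame.copy()
    labels = []
    for _, row in frame.iterrows():
        state = row["state"]
        loc_row = None
        if location is not None and state in location.index:
            loc_row = location.loc[state]
        label = row["label"]
        for rule in rules:
            if _rule_matches(rule, row["associated_marks"], row["is_tf_state"],
                             loc_row, panel):
                label = rule["label"]
                break
        labels.append(label)
    frame["label"] = labels
    return StateClassification(frame=frame)
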