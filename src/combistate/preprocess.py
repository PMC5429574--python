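"""Data preprocessing: binning, Poisson binarization and the combinatorial alphabet.

Aligned-read 5' ends (or pre-binned counts) are tiled onto fixed-width genomic
bins, each mark is called present/absent against a Poisson background, and every
bin's presence vector over the ``n`` marks is packed into a single observation
symbol from the combinatorial alphabet of ``2**n`` mark subsets.  A compact
alphabet keeps only the symbols actually observed, so downstream model size
scales with the data rather than with ``2**n``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import poisson

logger = logging.getLogger(__name__)

MAX_MARKS = 30


@dataclass(frozen=True)
class MarkPanel:
    """Ordered panel of epigenetic marks with one designated TF mark.

    The panel order fixes the bit order of the combinatorial alphabet: the
    leftmost binary digit of a symbol corresponds to the first mark.
    """

    marks: tuple[str, ...]
    tf: str

    def __post_init__(self):
        marks = tuple(self.marks)
        object.__setattr__(self, "marks", marks)
        if not 1 <= len(marks) <= MAX_MARKS:
            raise ValueError(f"panel must have 1..{MAX_MARKS} marks, got {len(marks)}")
        if len(set(marks)) != len(marks):
            raise ValueError("mark names must be unique")
        if self.tf not in marks:
            raise ValueError(f"TF mark {self.tf!r} not in panel")

    @property
    def n(self) -> int:
        return len(self.marks)

    @property
    def tf_index(self) -> int:
        return self.marks.index(self.tf)

    @property
    def alphabet_size(self) -> int:
        return 2 ** self.n

    def bit_value(self, mark: str) -> int:
        """Binary value of a single mark (leftmost bit = first mark)."""
        return 1 << (self.n - 1 - self.marks.index(mark))


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width tiling of a genome, 0-based half-open coordinates.

    Bins tile each chromosome left to right without gaps; the last bin of a
    chromosome may be truncated.  Global bin indices concatenate chromosomes
    in input order.
    """

    chroms: tuple[str, ...]
    lengths: tuple[int, ...]
    bin_width: int

    def __post_init__(self):
        if len(set(self.chroms)) != len(self.chroms):
            raise ValueError("duplicate chromosome name")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def n_bins_per_chrom(self) -> np.ndarray:
        return -(-np.asarray(self.lengths) // self.bin_width)

    @property
    def offsets(self) -> np.ndarray:
        """Global index of the first bin of each chromosome."""
        n = self.n_bins_per_chrom
        return np.concatenate([[0], np.cumsum(n)[:-1]])

    @property
    def total_bins(self) -> int:
        return int(self.n_bins_per_chrom.sum())

    def chrom_slice(self, chrom: str) -> slice:
        i = self.chroms.index(chrom)
        off = self.offsets
        return slice(int(off[i]), int(off[i] + self.n_bins_per_chrom[i]))

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin index of base-pair position ``pos`` on ``chrom``."""
        i = self.chroms.index(chrom)
        if not 0 <= pos < self.lengths[i]:
            raise ValueError(f"position {pos} outside {chrom}")
        return int(self.offsets[i] + pos // self.bin_width)

    def frame(self) -> pd.DataFrame:
        """Per-bin (chrom, start, end) table in global-index order."""
        rows = []
        for chrom, length in zip(self.chroms, self.lengths):
            starts = np.arange(0, length, self.bin_width)
            ends = np.minimum(starts + self.bin_width, length)
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)


@dataclass
class CountMatrix:
    """Per-bin, per-mark read counts for one cell type (rows follow a BinGrid)."""

    cell_type: str
    counts: np.ndarray  # (total_bins, n_marks) non-negative ints

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (bins x marks)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


@dataclass
class BinaryCalls:
    """Per-bin, per-mark presence/absence calls for one cell type."""

    cell_type: str
    calls: np.ndarray  # (total_bins, n_marks) bool

    def __post_init__(self):
        self.calls = np.asarray(self.calls).astype(bool)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (bins x marks)")


FULL = "full"
COMPACT = "compact"


@dataclass
class SymbolSequence:
    """Encoded observation symbols for one (cell type, chromosome)."""

    cell_type: str
    chrom: str
    symbols: np.ndarray
    alphabet: str = FULL
    alphabet_size: int = 0

    def __post_init__(self):
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        if self.alphabet not in (FULL, COMPACT):
            raise ValueError("alphabet must be 'full' or 'compact'")
        if self.symbols.size and (
            self.symbols.min() < 0 or self.symbols.max() >= self.alphabet_size
        ):
            raise ValueError("symbols outside alphabet")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class AlphabetMap:
    """Bijection between observed full bit-codes and compact consecutive IDs.

    Compact IDs are assigned 0..m-1 in ascending full-code order.
    """

    full_codes: tuple[int, ...]
    full_size: int

    def __post_init__(self):
        codes = tuple(int(c) for c in self.full_codes)
        object.__setattr__(self, "full_codes", codes)
        if list(codes) != sorted(set(codes)):
            raise ValueError("full codes must be strictly ascending and unique")
        if codes and (codes[0] < 0 or codes[-1] >= self.full_size):
            raise ValueError("full code outside alphabet")

    @property
    def m(self) -> int:
        return len(self.full_codes)

    def to_compact(self, full_symbols: np.ndarray) -> np.ndarray:
        codes = np.asarray(self.full_codes)
        idx = np.searchsorted(codes, full_symbols)
        bad = (idx >= len(codes)) | (codes[np.minimum(idx, len(codes) - 1)] != full_symbols)
        if np.any(bad):
            raise ValueError(f"symbol {np.asarray(full_symbols)[bad][0]} not in alphabet map")
        return idx.astype(np.int64)

    def to_full(self, compact_ids: np.ndarray) -> np.ndarray:
        compact_ids = np.asarray(compact_ids)
        if compact_ids.size and (compact_ids.min() < 0 or compact_ids.max() >= self.m):
            raise ValueError("compact ID outside map")
        return np.asarray(self.full_codes, dtype=np.int64)[compact_ids]


# ---------------------------------------------------------------------------
# operations


def make_bin_grid(chrom_sizes: Mapping[str, int] | Iterable[tuple[str, int]],
                  bin_width: int) -> BinGrid:
    """Tile chromosomes into fixed-width bins (last bin may be truncated)."""
    items = list(chrom_sizes.items()) if isinstance(chrom_sizes, Mapping) else list(chrom_sizes)
    return BinGrid(
        chroms=tuple(name for name, _ in items),
        lengths=tuple(int(size) for _, size in items),
        bin_width=int(bin_width),
    )


def five_prime_positions(intervals: pd.DataFrame) -> np.ndarray:
    """Strand-aware 5' coordinate of each read interval.

    Plus-strand (or unstranded) reads map to ``start``; minus-strand reads to
    ``end - 1`` (the last covered base under half-open coordinates).
    """
    start = intervals["start"].to_numpy()
    end = intervals["end"].to_numpy()
    if "strand" in intervals.columns:
        minus = intervals["strand"].to_numpy() == "-"
        return np.where(minus, end - 1, start)
    return start


def count_reads_in_bins(reads: Mapping[str, pd.DataFrame], grid: BinGrid,
                        panel: MarkPanel, cell_type: str = "") -> CountMatrix:
    """Bin strand-aware read 5' ends into a bins x marks count matrix.

    ``reads`` maps each panel mark to an interval table with columns
    ``chrom, start, end`` and optional ``strand``.  Reads on chromosomes
    absent from the grid are skipped (a count is logged).
    """
    missing = [m for m in panel.marks if m not in reads]
    if missing:
        raise ValueError(f"no reads supplied for marks: {missing}")
    counts = np.zeros((grid.total_bins, panel.n), dtype=np.int64)
    offsets = {c: int(o) for c, o in zip(grid.chroms, grid.offsets)}
    nbins = {c: int(n) for c, n in zip(grid.chroms, grid.n_bins_per_chrom)}
    for j, mark in enumerate(panel.marks):
        tab = reads[mark]
        on_grid = tab["chrom"].isin(grid.chroms)
        skipped = int((~on_grid).sum())
        if skipped:
            logger.warning("%s: skipped %d reads on chromosomes absent from grid",
                           mark, skipped)
        tab = tab[on_grid]
        pos = five_prime_positions(tab)
        for chrom, p in zip(tab["chrom"].to_numpy(), pos):
            b = int(p) // grid.bin_width
            if 0 <= b < nbins[chrom]:
                counts[offsets[chrom] + b, j] += 1
            else:
                logger.warning("%s: read 5' end %d outside %s, skipped", mark, p, chrom)
    return CountMatrix(cell_type=cell_type, counts=counts)


def binarize_counts(counts: CountMatrix, p_cutoff: float = 1e-4) -> BinaryCalls:
    """Call mark presence per bin against a Poisson background.

    For each mark the background rate ``lam`` is the genome-wide mean count
    per bin; a bin with observed count ``c`` is called present iff
    ``Pr[X >= c | Poisson(lam)] < p_cutoff`` (strict).  A zero count is never
    present (its tail probability is 1).
    """
    if not 0 < p_cutoff < 1:
        raise ValueError("p_cutoff must be in (0, 1)")
    c = counts.counts
    lam = c.mean(axis=0)
    calls = np.zeros(c.shape, dtype=bool)
    for j in range(c.shape[1]):
        if lam[j] == 0:
            logger.warning("mark column %d has no reads; all bins called absent", j)
            continue
        # Pr[X >= c] = sf(c - 1); strict inequality against the cutoff
        tail = poisson.sf(c[:, j] - 1, lam[j])
        calls[:, j] = (tail < p_cutoff) & (c[:, j] > 0)
    return BinaryCalls(cell_type=counts.cell_type, calls=calls)


def encode_bits(calls: np.ndarray, n_marks: int) -> np.ndarray:
    """Pack presence rows into integers, leftmost bit = first mark column."""
    weights = 1 << np.arange(n_marks - 1, -1, -1, dtype=np.int64)
    return np.asarray(calls, dtype=np.int64) @ weights


def decode_bits(symbols: np.ndarray, n_marks: int) -> np.ndarray:
    """Unpack symbols back to presence rows (inverse of :func:`encode_bits`)."""
    shifts = np.arange(n_marks - 1, -1, -1, dtype=np.int64)
    return ((np.asarray(symbols, dtype=np.int64)[..., None] >> shifts) & 1).astype(bool)


def encode_symbols(calls: BinaryCalls, panel: MarkPanel,
                   grid: BinGrid | None = None) -> list[SymbolSequence]:
    """Encode binary calls to full-alphabet symbol sequences, one per chromosome.

    Without a grid the whole matrix becomes a single sequence named "genome".
    """
    if calls.calls.shape[1] != panel.n:
        raise ValueError(
            f"calls have {calls.calls.shape[1]} columns but panel has {panel.n} marks")
    symbols = encode_bits(calls.calls, panel.n)
    size = panel.alphabet_size
    if grid is None:
        return [SymbolSequence(calls.cell_type, "genome", symbols, FULL, size)]
    if len(symbols) != grid.total_bins:
        raise ValueError("calls rows do not match grid bins")
    return [
        SymbolSequence(calls.cell_type, chrom, symbols[grid.chrom_slice(chrom)], FULL, size)
        for chrom in grid.chroms
    ]


def compact_alphabet(sequences: Sequence[SymbolSequence],
                     ) -> tuple[AlphabetMap, list[SymbolSequence]]:
    """Remap to a compact alphabet of the symbols actually observed.

    Compact IDs follow ascending full-code order; m = number of distinct
    observed symbols.
    """
    if not sequences:
        raise ValueError("no sequences")
    sizes = {s.alphabet_size for s in sequences}
    if len(sizes) != 1 or any(s.alphabet != FULL for s in sequences):
        raise ValueError("sequences must share one full alphabet")
    observed = np.unique(np.concatenate([s.symbols for s in sequences]))
    amap = AlphabetMap(full_codes=tuple(int(x) for x in observed), full_size=sizes.pop())
    remapped = [
        SymbolSequence(s.cell_type, s.chrom, amap.to_compact(s.symbols), COMPACT, amap.m)
        for s in sequences
    ]
    return amap, remapped


def expand_symbols(sequence: SymbolSequence, amap: AlphabetMap) -> SymbolSequence:
    """Map a compact-coded sequence back to full bit-codes."""
    if sequence.alphabet != COMPACT:
        raise ValueError("sequence is not compact-coded")
    return SymbolSequence(sequence.cell_type, sequence.chrom,
                          amap.to_full(sequence.symbols), FULL, amap.full_size)


def stack_sequences(sequences: Sequence[SymbolSequence]) -> tuple[np.ndarray, list[int]]:
    """Concatenate sequences into (X, lengths) for the estimator API."""
    if not sequences:
        raise ValueError("no sequences")
    X = np.concatenate([s.symbols for s in sequences])
    return X, [len(s) for s in sequences]
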