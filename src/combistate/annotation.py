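"""Relating state calls to gene structure and expression.

Each bin midpoint is assigned to a gene-relative region category (5'TSS,
proximal/distal flanks, gene body, gene desert) with a fixed precedence when
several genes disagree.  Per-state location distributions, length-normalized
metagene profiles with fixed flanks, bin-weighted expression summaries and
generic merged-interval overlap fractions are built on top of that assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .state_calling import Segmentation

logger = logging.getLogger(__name__)

CATEGORIES = ("5'TSS", "5'Proximal", "5'Distal", "Intragenic",
              "3'Proximal", "3'Distal", "GeneDesert")
# precedence when several genes give different categories for one bin
PRECEDENCE = ("5'TSS", "Intragenic", "5'Proximal", "3'Proximal",
              "5'Distal", "3'Distal", "GeneDesert")
_PREC_RANK = {cat: r for r, cat in enumerate(PRECEDENCE)}
GENE_DESERT = "GeneDesert"


@dataclass(frozen=True)
class RegionWindows:
    """Extents (bp) of the gene-relative region categories.

    The 5'TSS window spans ``tss_halfwidth`` on both sides of the TSS;
    5'Proximal runs from the TSS window edge out to ``proximal_bp`` upstream,
    5'Distal from there to ``distal_bp``.  Downstream of the TES, 3'Proximal
    covers 0..``proximal_bp`` (no gap at the gene end) and 3'Distal runs out
    to ``distal_bp``.  Beyond ``distal_bp`` on either side is GeneDesert.
    """

    tss_halfwidth: int = 2_000
    proximal_bp: int = 10_000
    distal_bp: int = 90_000

    def __post_init__(self):
        if not 0 < self.tss_halfwidth <= self.proximal_bp <= self.distal_bp:
            raise ValueError("windows must satisfy 0 < tss <= proximal <= distal")


@dataclass
class GeneAnnotation:
    """Transcript table plus derived gene-level spans and expression.

    ``transcripts`` columns: gene_id, transcript_id, chrom, strand, start,
    end and optional expression.  Gene spans are the union of each gene's
    transcripts; gene expression is the maximum over its transcripts
    (splice-variant rule).
    """

    transcripts: pd.DataFrame

    def __post_init__(self):
        t = self.transcripts
        required = {"gene_id", "transcript_id", "chrom", "strand", "start", "end"}
        if missing := required - set(t.columns):
            raise ValueError(f"transcript table missing columns: {sorted(missing)}")
        if (t["end"] <= t["start"]).any():
            raise ValueError("transcript end must exceed start")
        if not t["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")
        if "expression" in t.columns and (t["expression"].dropna() < 0).any():
            raise ValueError("expression must be non-negative")

    @property
    def genes(self) -> pd.DataFrame:
        """Gene-level union spans with max-over-transcript expression."""
        agg = {"chrom": "first", "strand": "first", "start": "min", "end": "max"}
        if "expression" in self.transcripts.columns:
            agg["expression"] = "max"
        genes = (self.transcripts.groupby("gene_id", sort=True)
                 .agg(agg).reset_index())
        return genes

    def set_expression(self, expression: pd.Series) -> "GeneAnnotation":
        """Attach per-transcript expression (indexed by transcript_id)."""
        t = self.transcripts.copy()
        t["expression"] = t["transcript_id"].map(expression)
        return GeneAnnotation(transcripts=t)


def _category_for_gene(mid: np.ndarray, start: int, end: int, strand: str,
                       w: RegionWindows) -> tuple[np.ndarray, np.ndarray]:
    """Category rank (per PRECEDENCE) and distance of midpoints to one gene.

    Distances are 0 inside the gene span, else the distance to the nearest
    span boundary; used only for nearest-gene tie-breaking.
    """
    tss = start if strand == "+" else end
    inside = (mid >= start) & (mid < end)
    in_tss = (mid >= tss - w.tss_halfwidth) & (mid < tss + w.tss_halfwidth)
    if strand == "+":
        du = start - mid          # >0 upstream of the 5' end
        dd = mid - end            # >=0 downstream of the 3' end
    else:
        du = mid - end
        dd = start - mid
    rank = np.full(mid.shape, _PREC_RANK[GENE_DESERT], dtype=np.int64)
    rank[(du > 0) & (du <= w.distal_bp)] = _PREC_RANK["5'Distal"]
    rank[(du > 0) & (du <= w.proximal_bp)] = _PREC_RANK["5'Proximal"]
    rank[(dd >= 0) & (dd <= w.distal_bp) & ~inside] = _PREC_RANK["3'Distal"]
    rank[(dd >= 0) & (dd <= w.proximal_bp) & ~inside] = _PREC_RANK["3'Proximal"]
    rank[inside] = _PREC_RANK["Intragenic"]
    rank[in_tss] = _PREC_RANK["5'TSS"]
    dist = np.where(inside, 0.0,
                    np.minimum(np.abs(mid - start), np.abs(mid - (end - 1))))
    return rank, dist


def assign_bin_categories(midpoints: np.ndarray, chrom: str,
                          genes: pd.DataFrame,
                          windows: RegionWindows | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Assign region categories (and nearest gene) to bin midpoints.

    Returns (categories, gene_index): categories as strings from
    :data:`CATEGORIES`; gene_index as positional indices into ``genes``
    (-1 for GeneDesert).  Conflicting assignments from several genes resolve
    by the category precedence, then smaller distance, then gene order.
    """
    w = windows or RegionWindows()
    mid = np.asarray(midpoints, dtype=float)
    best_rank = np.full(mid.shape, _PREC_RANK[GENE_DESERT], dtype=np.int64)
    best_dist = np.full(mid.shape, np.inf)
    best_gene = np.full(mid.shape, -1, dtype=np.int64)
    on_chrom = genes[genes["chrom"] == chrom]
    if on_chrom.empty and not genes.empty:
        logger.warning("chromosome %s absent from annotation; all bins GeneDesert",
                       chrom)
    for pos, (_, g) in enumerate(on_chrom.iterrows()):
        rank, dist = _category_for_gene(mid, int(g["start"]), int(g["end"]),
                                        g["strand"], w)
        better = (rank < best_rank) | ((rank == best_rank) & (dist < best_dist))
        best_rank[better] = rank[better]
        best_dist[better] = dist[better]
        idx = genes.index.get_loc(on_chrom.index[pos])
        best_gene[better] = idx
    best_gene[best_rank == _PREC_RANK[GENE_DESERT]] = -1
    cats = np.asarray(PRECEDENCE, dtype=object)[best_rank]
    return cats, best_gene


def assign_bin_category(midpoint: float, chrom: str, genes: pd.DataFrame,
                        windows: RegionWindows | None = None) -> str:
    """Region category of a single bin midpoint."""
    cats, _ = assign_bin_categories(np.asarray([midpoint]), chrom, genes, windows)
    return str(cats[0])


def _segmentation_categories(seg: Segmentation, annotation: GeneAnnotation,
                             windows: RegionWindows | None
                             ) -> pd.DataFrame:
    """Per-bin table of state, category and nearest gene across the genome."""
    genes = annotation.genes
    df = seg.frame()
    mids = (df["start"].to_numpy() + df["end"].to_numpy()) / 2.0
    cats = np.empty(len(df), dtype=object)
    gidx = np.empty(len(df), dtype=np.int64)
    for chrom in df["chrom"].unique():
        sel = (df["chrom"] == chrom).to_numpy()
        cats[sel], gidx[sel] = assign_bin_categories(mids[sel], chrom, genes,
                                                     windows)
    df["category"] = cats
    df["gene_index"] = gidx
    return df


def location_distribution(seg: Segmentation, annotation: GeneAnnotation,
                          windows: RegionWindows | None = None
                          ) -> pd.DataFrame:
    """Fraction of each state's bins per region category (rows sum to 1).

    Rows are states, columns the region categories; empty states get a zero
    row.
    """
    df = _segmentation_categories(seg, annotation, windows)
    counts = (df.groupby(["state", "category"], observed=False).size()
              .unstack(fill_value=0)
              .reindex(index=range(seg.n_states), columns=list(CATEGORIES),
                       fill_value=0))
    totals = counts.sum(axis=1)
    fractions = counts.div(totals.where(totals > 0, 1), axis=0)
    fractions.index.name = "state"
    return fractions


@dataclass
class MetageneProfile:
    """Per-state occupancy along a normalized gene axis with fixed flanks.

    ``values[s, p]`` is the fraction of sampled (gene, position) points at
    axis position ``p`` that carry state ``s``; the axis runs 5'->3' through
    ``n_flank_bins`` upstream positions, ``n_body_bins`` virtual body
    positions and ``n_flank_bins`` downstream positions.
    """

    values: np.ndarray
    n_flank_bins: int
    n_body_bins: int
    n_genes_used: int
    n_genes_skipped: int

    @property
    def axis_length(self) -> int:
        return 2 * self.n_flank_bins + self.n_body_bins


def metagene_profile(seg: Segmentation, annotation: GeneAnnotation,
                     flank_bp: int = 90_000, n_body_bins: int = 100
                     ) -> MetageneProfile:
    """Average state occupancy over genes on a normalized 5'->3' axis.

    Every gene body is mapped linearly onto ``n_body_bins`` virtual bins;
    flanks extend ``flank_bp`` on both sides at the native bin width.  Genes
    shorter than one native bin are skipped (counted).  Each cell type's
    segmentation contributes one profile per gene.
    """
    if seg.grid is None:
        raise ValueError("metagene profile requires a segmentation with a grid")
    width = seg.grid.bin_width
    n_flank = flank_bp // width
    genes = annotation.genes
    occ = np.zeros((seg.n_states, 2 * n_flank + n_body_bins))
    total = np.zeros(2 * n_flank + n_body_bins)
    # state lookup per (cell_type, chrom)
    states = {(ct, ch): p for ct, ch, p in
              zip(seg.cell_types, seg.chroms, seg.paths)}
    chrom_len = dict(zip(seg.grid.chroms, seg.grid.lengths))
    used = skipped = 0
    for _, g in genes.iterrows():
        start, end, strand, chrom = int(g["start"]), int(g["end"]), g["strand"], g["chrom"]
        if end - start < width:
            skipped += 1
            continue
        # genomic coordinate sampled at each axis position, 5'->3'
        up = start - flank_bp + (np.arange(n_flank) + 0.5) * width
        body = start + (np.arange(n_body_bins) + 0.5) * (end - start) / n_body_bins
        down = end + (np.arange(n_flank) + 0.5) * width
        coords = np.concatenate([up, body, down])
        if strand == "-":
            # mirror around the gene: axis position p samples (start+end) - c_p,
            # so the 5' flank sits to the genomic right and the axis runs 5'->3'
            coords = (start + end) - coords
        hit_any = False
        for (ct, ch), path in states.items():
            if ch != chrom:
                continue
            hit_any = True
            valid = (coords >= 0) & (coords < chrom_len.get(ch, len(path) * width))
            bins = (coords[valid] / width).astype(np.int64)
            pos = np.nonzero(valid)[0]
            occ[path[bins], pos] += 1
            total[pos] += 1
        if hit_any:
            used += 1
    values = np.divide(occ, np.maximum(total, 1)[None, :])
    if skipped:
        logger.info("metagene: skipped %d genes shorter than one bin", skipped)
    return MetageneProfile(values=values, n_flank_bins=n_flank,
                           n_body_bins=n_body_bins, n_genes_used=used,
                           n_genes_skipped=skipped)


def expression_by_state(seg: Segmentation, annotation: GeneAnnotation,
                        windows: RegionWindows | None = None,
                        log2_floor: bool = False, zscore: bool = False
                        ) -> pd.DataFrame:
    """Bin-weighted average expression of the genes near each state's bins.

    Gene expression is the maximum over the gene's transcripts.  A bin is
    "near" a gene when its region category is anything but GeneDesert; each
    state's average weights genes by how many of the state's bins they
    capture.  With ``log2_floor`` expression values below 1 are floored at 1
    and log2-transformed before averaging; ``zscore`` standardizes the
    averages across states.
    """
    genes = annotation.genes
    if "expression" not in genes.columns:
        raise ValueError("annotation carries no expression values")
    df = _segmentation_categories(seg, annotation, windows)
    near = df[df["gene_index"] >= 0].copy()
    expr = genes["expression"].to_numpy()
    has_expr = ~pd.isna(expr)
    n_excluded = int((~has_expr).sum())
    near = near[has_expr[near["gene_index"].to_numpy()]]
    vals = expr[near["gene_index"].to_numpy()].astype(float)
    if log2_floor:
        vals = np.log2(np.maximum(vals, 1.0))
    near["expr"] = vals
    grouped = near.groupby("state")["expr"]
    out = pd.DataFrame({
        "n_bins": grouped.size().reindex(range(seg.n_states), fill_value=0),
        "mean_expression": grouped.mean().reindex(range(seg.n_states)),
    })
    out.index.name = "state"
    if zscore:
        mu = out["mean_expression"].mean()
        sd = out["mean_expression"].std(ddof=0)
        out["zscore"] = (out["mean_expression"] - mu) / (sd if sd > 0 else 1.0)
    out.attrs["n_genes_without_expression"] = n_excluded
    return out


def merge_intervals(regions: pd.DataFrame, merge_adjacent: bool = True
                    ) -> pd.DataFrame:
    """Merge overlapping (and optionally bookended) intervals per chromosome."""
    if (regions["end"] <= regions["start"]).any():
        bad = regions.index[(regions["end"] <= regions["start"])][0]
        raise ValueError(f"malformed interval at row {bad}: end <= start")
    out = []
    for chrom, grp in regions.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"])
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            joined = s <= cur_e if merge_adjacent else s < cur_e
            if joined:
                cur_e = max(cur_e, int(e))
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def region_overlap_fraction(seg: Segmentation, regions: pd.DataFrame,
                            merge_adjacent: bool = True,
                            min_len: int = 500) -> pd.Series:
    """Fraction of each state's bins with midpoint in a merged, filtered region.

    Regions are merged (bookended intervals join when ``merge_adjacent``),
    regions shorter than ``min_len`` bp are dropped, then each bin midpoint
    is tested for membership.
    """
    merged = merge_intervals(regions, merge_adjacent=merge_adjacent)
    merged = merged[(merged["end"] - merged["start"]) >= min_len]
    df = seg.frame()
    mids = (df["start"].to_numpy() + df["end"].to_numpy()) / 2.0
    inside = np.zeros(len(df), dtype=bool)
    for chrom, grp in merged.groupby("chrom"):
        sel = (df["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        idx = np.searchsorted(starts, mids[sel], side="right") - 1
        ok = idx >= 0
        ok[ok] &= mids[sel][ok] < ends[idx[ok]]
        inside[sel] = ok
    df["inside"] = inside
    frac = (df.groupby("state")["inside"].mean()
            .reindex(range(seg.n_states), fill_value=0.0))
    frac.index.name = "state"
    return frac
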