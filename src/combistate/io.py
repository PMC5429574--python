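"""Readers and writers for the standard text formats.

Coordinates are 0-based half-open (BED convention) throughout.  Models are
serialized to JSON with their mark panel, alphabet map and training trace so
a segmentation run is fully reconstructible from one file.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .hmm import CombinatorialHMM, TrainingTrace
from .preprocess import (AlphabetMap, BinGrid, CountMatrix, MarkPanel,
                         SymbolSequence, make_bin_grid)
from .annotation import GeneAnnotation

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column ``chrom<TAB>length`` text file, input order preserved."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str})
    if df["chrom"].duplicated().any():
        dup = df["chrom"][df["chrom"].duplicated()].iloc[0]
        raise ValueError(f"duplicate chromosome {dup!r} in {path}")
    return dict(zip(df["chrom"], df["length"].astype(int)))


def read_bed(path, min_fields: int = 3) -> pd.DataFrame:
    """BED3+/BED6 intervals; malformed records are rejected with line number."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=BED_COLUMNS[:min_fields])
    if df.shape[1] < min_fields:
        raise ValueError(f"{path}: expected >= {min_fields} BED fields")
    df = df.iloc[:, :min(df.shape[1], 6)]
    df.columns = BED_COLUMNS[:df.shape[1]]
    for col in ("start", "end"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            raise ValueError(f"{path}: malformed {col} at line {bad.idxmax() + 1}")
        df[col] = df[col].astype(int)
    bad = df["end"] <= df["start"]
    if bad.any():
        raise ValueError(f"{path}: end <= start at line {bad.idxmax() + 1}")
    return df


def read_counts_tsv(path, panel: MarkPanel | None = None
                    ) -> tuple[BinGrid, CountMatrix, list[str]]:
    """Pre-binned count matrix: ``chrom start end <mark1> ... <markN>``.

    Bins must tile each chromosome contiguously; the grid is reconstructed
    from the coordinates.  Returns (grid, counts, mark names).
    """
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:3]) != ["chrom", "start", "end"]:
        raise ValueError(f"{path}: header must start with 'chrom start end'")
    marks = list(df.columns[3:])
    if panel is not None:
        if set(panel.marks) - set(marks):
            raise ValueError(f"{path}: missing mark columns for panel")
        marks = list(panel.marks)
    widths = (df["end"] - df["start"]).to_numpy()
    bin_width = int(widths.max())
    sizes = df.groupby("chrom", sort=False)["end"].max()
    grid = make_bin_grid(sizes.to_dict(), bin_width)
    if grid.total_bins != len(df):
        raise ValueError(f"{path}: bins do not tile the chromosomes")
    counts = df[marks].to_numpy(dtype=np.int64)
    if (counts < 0).any():
        raise ValueError(f"{path}: negative counts")
    return grid, CountMatrix(cell_type=Path(path).stem, counts=counts), marks


def write_counts_tsv(path, grid: BinGrid, counts: CountMatrix,
                     marks: Sequence[str]):
    frame = grid.frame()
    for j, mark in enumerate(marks):
        frame[mark] = counts.counts[:, j]
    frame.to_csv(path, sep="\t", index=False)


def write_symbols_tsv(path, sequences: Sequence[SymbolSequence],
                      grid: BinGrid | None = None):
    """Positional symbol table: cell_type chrom start end symbol."""
    frames = []
    for seq in sequences:
        if grid is not None and seq.chrom in grid.chroms:
            width = grid.bin_width
            length = grid.lengths[grid.chroms.index(seq.chrom)]
        else:
            width, length = 1, len(seq)
        starts = np.arange(len(seq)) * width
        frames.append(pd.DataFrame({
            "cell_type": seq.cell_type, "chrom": seq.chrom,
            "start": starts, "end": np.minimum(starts + width, length),
            "symbol": seq.symbols,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_symbols_tsv(path, alphabet: str, alphabet_size: int
                     ) -> list[SymbolSequence]:
    df = pd.read_csv(path, sep="\t")
    seqs = []
    for (ct, chrom), grp in df.groupby(["cell_type", "chrom"], sort=False):
        seqs.append(SymbolSequence(str(ct), str(chrom),
                                   grp["symbol"].to_numpy(), alphabet,
                                   alphabet_size))
    return seqs


def write_alphabet_map(path, amap: AlphabetMap):
    pd.DataFrame({"full_code": amap.full_codes,
                  "compact_id": range(amap.m)}).to_csv(path, sep="\t",
                                                       index=False)


def read_alphabet_map(path, full_size: int) -> AlphabetMap:
    df = pd.read_csv(path, sep="\t")
    order = np.argsort(df["compact_id"].to_numpy())
    return AlphabetMap(full_codes=tuple(df["full_code"].to_numpy()[order]),
                       full_size=full_size)


def save_model(path, model: CombinatorialHMM, panel: MarkPanel | None = None,
               alphabet_map: AlphabetMap | None = None):
    """Serialize a model (with panel / alphabet metadata) to JSON."""
    payload = {
        "n": model.n_states,
        "m": model.n_symbols_,
        "floor": model.floor,
        "pi": model.startprob_.tolist(),
        "A": model.transmat_.tolist(),
        "B": model.emissionprob_.tolist(),
        "marks": list(panel.marks) if panel else None,
        "tf": panel.tf if panel else None,
        "alphabet_map": list(alphabet_map.full_codes) if alphabet_map else None,
        "alphabet_full_size": alphabet_map.full_size if alphabet_map else None,
        "training_trace": getattr(model, "history_",
                                  TrainingTrace()).log_likelihood,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path) -> tuple[CombinatorialHMM, MarkPanel | None,
                              AlphabetMap | None]:
    data = json.loads(Path(path).read_text())
    model = CombinatorialHMM.from_params(
        np.asarray(data["pi"]), np.asarray(data["A"]), np.asarray(data["B"]),
        floor=data.get("floor", 1e-6))
    model.history_ = TrainingTrace(log_likelihood=list(
        data.get("training_trace") or []))
    panel = (MarkPanel(marks=tuple(data["marks"]), tf=data["tf"])
             if data.get("marks") else None)
    amap = (AlphabetMap(full_codes=tuple(data["alphabet_map"]),
                        full_size=data["alphabet_full_size"])
            if data.get("alphabet_map") is not None else None)
    return model, panel, amap


def write_model_tsv(prefix, model: CombinatorialHMM):
    """Spreadsheet-friendly TSV export of the transition and emission matrices."""
    pd.DataFrame(model.transmat_).to_csv(f"{prefix}.transitions.tsv", sep="\t",
                                         index_label="state")
    pd.DataFrame(model.emissionprob_).to_csv(f"{prefix}.emissions.tsv", sep="\t",
                                             index_label="state")


def read_panel_yaml(path) -> MarkPanel:
    """Panel config: ``marks`` in bit order plus the designated ``tf``."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return MarkPanel(marks=tuple(data["marks"]), tf=data["tf"])


def write_panel_yaml(path, panel: MarkPanel):
    Path(path).write_text(yaml.safe_dump(
        {"marks": list(panel.marks), "tf": panel.tf}))


# ---------------------------------------------------------------------------
# gene annotation formats

REFFLAT_COLUMNS = ["gene_id", "transcript_id", "chrom", "strand",
                   "start", "end"]


def read_refflat(path) -> GeneAnnotation:
    """refFlat: geneName name chrom strand txStart txEnd [...]; first 6 used."""
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] < 6:
        raise ValueError(f"{path}: refFlat needs >= 6 columns")
    df = df.iloc[:, :6]
    df.columns = REFFLAT_COLUMNS
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return GeneAnnotation(transcripts=df)


def write_refflat(path, annotation: GeneAnnotation):
    annotation.transcripts[REFFLAT_COLUMNS].to_csv(path, sep="\t",
                                                   header=False, index=False)


def read_bed12_genes(path) -> GeneAnnotation:
    """BED12 transcript spans (blocks ignored; name doubles as gene id)."""
    df = read_bed(path, min_fields=6)
    out = pd.DataFrame({
        "gene_id": df["name"], "transcript_id": df["name"],
        "chrom": df["chrom"], "strand": df["strand"],
        "start": df["start"], "end": df["end"],
    })
    return GeneAnnotation(transcripts=out)


def read_gtf(path) -> GeneAnnotation:
    """GTF transcript records via gffutils (gene_id/transcript_id attributes)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            disable_infer_genes=True,
                            disable_infer_transcripts=True)
    rows = []
    for tx in db.features_of_type("transcript"):
        rows.append({
            "gene_id": tx.attributes["gene_id"][0],
            "transcript_id": tx.attributes["transcript_id"][0],
            "chrom": tx.seqid, "strand": tx.strand,
            "start": tx.start - 1,      # GTF is 1-based inclusive
            "end": tx.end,
        })
    if not rows:
        raise ValueError(f"{path}: no transcript records")
    return GeneAnnotation(transcripts=pd.DataFrame(rows))


def read_expression_tsv(path) -> pd.Series:
    """Per-transcript expression: ``transcript_id<TAB>value`` (with header)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = ["transcript_id", "value"][:df.shape[1]]
    if (df["value"] < 0).any():
        raise ValueError(f"{path}: negative expression values")
    return pd.Series(df["value"].to_numpy(),
                     index=df["transcript_id"].astype(str))
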