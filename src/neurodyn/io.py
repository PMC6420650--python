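"""Readers and writers for the plain-text interchange formats.

All genomic coordinates are 0-based half-open (BED convention). Peak BED
files carry the summit as an offset from ``start`` in the ``thickStart``
slot (column 7) when present; gene BED files carry the transcript length in
the score column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from neurodyn.errors import SchemaError

PEAK_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "summit"]
GENE_COLUMNS = ["chrom", "start", "end", "gene_id", "length", "strand"]


def read_peaks_bed(path: str | Path) -> pd.DataFrame:
    """Read a peak BED file into a DataFrame with a ``summit`` offset.

    Accepts 3+ columns; when column 7 (thickStart, absolute coordinate) is
    present the summit offset is derived from it, otherwise the midpoint is
    used.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise SchemaError(f"{path}: BED needs at least 3 columns")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    if df.shape[1] > 3:
        df = df.rename(columns={3: "name"})
    else:
        df["name"] = [f"peak{i}" for i in range(len(df))]
    if 6 in df.columns:
        df["summit"] = df[6].astype(int) - df["start"].astype(int)
    else:
        df["summit"] = (df["end"].astype(int) - df["start"].astype(int)) // 2
    out = df[["chrom", "start", "end", "name", "summit"]].copy()
    out[["start", "end", "summit"]] = out[["start", "end", "summit"]].astype(int)
    return out


def write_peaks_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    df = peaks.copy()
    if "summit" not in df.columns:
        df["summit"] = (df["end"] - df["start"]) // 2
    if "name" not in df.columns:
        df["name"] = [f"peak{i}" for i in range(len(df))]
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "name": df["name"],
            "score": 0,
            "strand": ".",
            "thickStart": (df["start"] + df["summit"]).astype(int),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed(path: str | Path) -> pd.DataFrame:
    """Read a gene-model BED (name = gene id, score = transcript length).

    Returns a DataFrame with columns chrom, start, end, gene_id, length,
    strand and a derived ``tss`` column (``start`` on + strand, ``end - 1``
    on the - strand).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 6:
        raise SchemaError(f"{path}: gene BED needs 6 columns (incl. strand)")
    df.columns = GENE_COLUMNS[: df.shape[1]] + list(df.columns[len(GENE_COLUMNS):])
    df = df[GENE_COLUMNS].copy()
    df[["start", "end", "length"]] = df[["start", "end", "length"]].astype(int)
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return df


def write_genes_bed(genes: pd.DataFrame, path: str | Path) -> None:
    genes[GENE_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x cells matrix (first column = gene id, header = cells)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise SchemaError(f"{path}: matrix has no cell columns")
    return df


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_table(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{Path(path).name}: {', '.join(missing)}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_pfm(path: str | Path) -> list[tuple[str, np.ndarray]]:
    """Read a position-frequency-matrix file (JASPAR-style blocks).

    Each block is ``>motif_id`` followed by four rows ``A [ n n ... ]`` in
    A, C, G, T order. Returns (motif id, 4 x L count matrix) tuples.
    """
    motifs: list[tuple[str, np.ndarray]] = []
    name = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    motifs.append((name, np.array(rows)))
                name = line[1:].split()[0]
                rows = []
            else:
                payload = line.split("[")[-1].rstrip("]").replace("]", "")
                if line[0] in "ACGT":
                    payload = line[1:].strip().lstrip("[").rstrip("]")
                rows.append([float(x) for x in payload.split()])
    if name is not None:
        motifs.append((name, np.array(rows)))
    for mid, m in motifs:
        if m.shape[0] != 4:
            raise SchemaError(f"motif {mid}: expected 4 rows (A,C,G,T), got {m.shape[0]}")
    return motifs


def write_pfm(motifs: list[tuple[str, np.ndarray]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for mid, mat in motifs:
            fh.write(f">{mid}\n")
            for base, row in zip("ACGT", np.asarray(mat)):
                vals = " ".join(f"{v:g}" for v in row)
                fh.write(f"{base} [ {vals} ]\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
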