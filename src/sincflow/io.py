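"""Readers and writers for the on-disk formats.

Expression matrices are tab-separated, genes in rows (first column) and cells
in columns (header row). Intron annotation is BED6 with the name field
``intron_id|gene_id``. Splice-site sequences are FASTA with record ids
``<intron_id>|5p`` (9 nt) or ``<intron_id>|3p`` (23 nt). Everything a writer
emits, the matching reader accepts (round-trip property).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import (CompartmentMatrix, IntronAnnotation,
                         PseudotimeOrdering, QpcrRecord)

logger = logging.getLogger("sincflow")

FIVE_PRIME_LEN = 9   # exonic 3mer + intronic 6mer around the 5' splice site
THREE_PRIME_LEN = 23  # intronic 20mer + exonic 3mer around the 3' splice site

INTRON_QUANT_COLUMNS = [
    "intron_id", "gene_id", "cell_id", "compartment",
    "fpkm", "intron_cov_frac", "adj_exon_expr", "adj_exon_cov_frac",
]


def read_compartment_matrix(path: str | Path, compartment: str) -> CompartmentMatrix:
    """Read a genes-by-cells TPM matrix from TSV and validate it.

    Raises on duplicate gene/cell identifiers, negative entries, or
    non-numeric cells (the offending row/column is named).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"{path}: non-numeric value at gene {row!r}, cell {col!r}")
        if coerced.isna().any():
            row = df.index[coerced.isna().to_numpy().argmax()]
            raise ValueError(f"{path}: missing value at gene {row!r}, cell {col!r}")
        df[col] = coerced
    mat = CompartmentMatrix(df, compartment)
    sums = df.to_numpy().sum(axis=0)
    logger.info(
        "read %s matrix from %s: %d genes x %d cells; column sums "
        "%.1f..%.1f", compartment, path, *mat.shape, sums.min(), sums.max())
    return mat


def write_compartment_matrix(mat: CompartmentMatrix, path: str | Path) -> None:
    mat.values.to_csv(path, sep="\t", index_label="gene_id")


def read_intron_annotation(path: str | Path,
                           min_length: int = 50) -> list[IntronAnnotation]:
    """Read intron intervals from BED6; drop introns not longer than ``min_length``.

    The BED name field must be ``intron_id|gene_id``. Start/end follow the
    BED convention (0-based half-open).
    """
    introns: list[IntronAnnotation] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED fields, "
                                 f"got {len(fields)}")
            chrom, start, end, name, _score, strand = fields[:6]
            if "|" not in name:
                raise ValueError(
                    f"{path}:{lineno}: name field {name!r} lacks "
                    "'intron_id|gene_id'")
            intron_id, gene_id = name.split("|", 1)
            ann = IntronAnnotation(intron_id=intron_id, gene_id=gene_id,
                                   chrom=chrom, start=int(start), end=int(end),
                                   strand=strand)
            if ann.length_nt <= min_length:
                dropped += 1
                continue
            introns.append(ann)
    logger.info("read %d introns from %s (%d dropped at length <= %d nt)",
                len(introns), path, dropped, min_length)
    ids = [i.intron_id for i in introns]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate intron identifiers")
    return introns


def write_intron_annotation(introns: list[IntronAnnotation],
                            path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in introns:
            fh.write(f"{i.chrom}\t{i.start}\t{i.end}\t"
                     f"{i.intron_id}|{i.gene_id}\t0\t{i.strand}\n")


def read_qpcr(path: str | Path) -> list[QpcrRecord]:
    """Read qPCR records from TSV (cell_id, marker_gene, delta_ct)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"cell_id", "marker_gene", "delta_ct"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: qPCR table needs columns {sorted(required)}")
    return [QpcrRecord(cell=str(r.cell_id), marker_gene=str(r.marker_gene),
                       delta_ct=float(r.delta_ct))
            for r in df.itertuples()]


def write_qpcr(records: list[QpcrRecord], path: str | Path) -> None:
    pd.DataFrame(
        {"cell_id": [r.cell for r in records],
         "marker_gene": [r.marker_gene for r in records],
         "delta_ct": [r.delta_ct for r in records]},
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_pseudotime(path: str | Path) -> PseudotimeOrdering:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if not {"cell_id", "pseudotime"}.issubset(df.columns):
        raise ValueError(f"{path}: pseudotime table needs cell_id, pseudotime")
    return PseudotimeOrdering(cells=[str(c) for c in df["cell_id"]],
                              pseudotime=df["pseudotime"].to_numpy(float))


def write_pseudotime(ordering: PseudotimeOrdering, path: str | Path) -> None:
    ordering.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.17g")


def read_intron_quant(path: str | Path) -> pd.DataFrame:
    """Read the per-intron quantification table (long format TSV)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(INTRON_QUANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: intron quant table missing {sorted(missing)}")
    for col in ("intron_cov_frac", "adj_exon_cov_frac"):
        vals = df[col].to_numpy(float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{path}: {col} outside [0, 1]")
    if (df["fpkm"].to_numpy(float) < 0).any():
        raise ValueError(f"{path}: negative FPKM")
    return df


def write_intron_quant(df: pd.DataFrame, path: str | Path) -> None:
    df[INTRON_QUANT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_splice_sites(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Read splice-site FASTA; returns ({intron_id: 9mer}, {intron_id: 23mer}).

    Record ids are ``<intron_id>|5p`` or ``<intron_id>|3p``; a record of the
    wrong length is an error naming the record.
    """
    five: dict[str, str] = {}
    three: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"splice-site record {rec.id!r} lacks '|5p'/'|3p' suffix")
        intron_id, side = rec.id.rsplit("|", 1)
        seq = str(rec.seq).upper()
        if side == "5p":
            if len(seq) != FIVE_PRIME_LEN:
                raise ValueError(
                    f"record {rec.id!r}: 5' site must be {FIVE_PRIME_LEN} nt, "
                    f"got {len(seq)}")
            five[intron_id] = seq
        elif side == "3p":
            if len(seq) != THREE_PRIME_LEN:
                raise ValueError(
                    f"record {rec.id!r}: 3' site must be {THREE_PRIME_LEN} nt, "
                    f"got {len(seq)}")
            three[intron_id] = seq
        else:
            raise ValueError(f"splice-site record {rec.id!r}: side must be 5p or 3p")
    return five, three


def write_splice_sites(five: dict[str, str], three: dict[str, str],
                       path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=f"{iid}|5p", description="")
               for iid, s in five.items()]
    records += [SeqRecord(Seq(s), id=f"{iid}|3p", description="")
                for iid, s in three.items()]
    SeqIO.write(records, str(path), "fasta")


def read_gene_sets(path: str | Path) -> tuple[list[str], list[str]]:
    """Read cell-cycle phase gene sets from TSV (gene_id, phase in {G1, G2})."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "phase"}.issubset(df.columns):
        raise ValueError(f"{path}: gene-set table needs gene_id, phase")
    bad = ~df["phase"].isin(["G1", "G2"])
    if bad.any():
        raise ValueError(f"{path}: phase must be G1 or G2, "
                         f"got {df.loc[bad, 'phase'].unique().tolist()}")
    g1 = df.loc[df["phase"] == "G1", "gene_id"].astype(str).tolist()
    g2 = df.loc[df["phase"] == "G2", "gene_id"].astype(str).tolist()
    return g1, g2


def write_gene_sets(g1: list[str], g2: list[str], path: str | Path) -> None:
    pd.DataFrame({"gene_id": list(g1) + list(g2),
                  "phase": ["G1"] * len(g1) + ["G2"] * len(g2)}
                 ).to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any result table as TSV (round-trip stable with read_table)."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
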