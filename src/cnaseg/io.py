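"""Readers and writers for the pipeline's flat-file formats.

Tab-delimited tables (intensities, CNA tracks, gene/DE tables, fraction
tables), SEG segment files, BED intervals and FASTA sequences. FASTA goes
through Biopython; coordinates honor each format's convention (SEG 1-based
inclusive, BED 0-based half-open).
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_intensity_tsv",
    "write_intensity_tsv",
    "read_gene_tsv",
    "write_gene_tsv",
    "write_track_tsv",
    "read_track_tsv",
    "read_fasta",
    "write_fasta",
    "sha256_file",
    "write_manifest",
]


def read_intensity_tsv(path: str | Path) -> pd.DataFrame:
    """Intensity table: ``probe_id chrom pos intensity_A:<s> intensity_B:<s> ...``"""
    df = pd.read_csv(path, sep="\t")
    required = {"probe_id", "chrom", "pos"}
    if not required <= set(df.columns):
        raise ValueError(f"intensity table must carry columns {sorted(required)}")
    return df


def write_intensity_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_gene_tsv(path: str | Path) -> pd.DataFrame:
    """Gene/DE table: ``gene_id chrom start end logFC adj_p``."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "start", "end", "logFC", "adj_p"}
    if not required <= set(df.columns):
        raise ValueError(f"gene table must carry columns {sorted(required)}")
    return df


def write_gene_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_track_tsv(track: pd.DataFrame, path: str | Path) -> None:
    """CNA track: ``probe_id chrom pos log2ratio category``."""
    track.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_track_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "log2ratio"}
    if not required <= set(df.columns):
        raise ValueError(f"track must carry columns {sorted(required)}")
    return df


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
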