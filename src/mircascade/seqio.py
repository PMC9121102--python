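"""Sequence and annotation I/O.

Conventions: internal coordinates are 0-based half-open, strands are ``+``/``-``,
sequences are kept uppercase. DNA/RNA alphabets are normalised at the I/O
boundary (files carry T, in-memory RNA work uses U).
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "revcomp",
    "to_rna",
    "to_dna",
    "read_fasta",
    "write_fasta",
    "iter_fastq",
    "write_fastq",
    "write_gff3",
    "read_gff3",
    "sha256_file",
]

_COMP = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA output; U treated as T)."""
    return seq.translate(_COMP)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{full_header_id: sequence}`` dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_fasta_with_desc(path: str | Path) -> list[tuple[str, str, str]]:
    """Read FASTA as ``(id, description, sequence)`` triples."""
    return [
        (rec.id, rec.description, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(title, sequence)`` from FASTQ; raises on malformed records."""
    with open(path) as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            yield title, seq.upper()


def write_fastq(path: str | Path, records: Iterable[tuple[str, str]]) -> int:
    """Write FASTQ with a constant dummy quality (Phred 33 'I'); returns count."""
    n = 0
    with open(path, "w") as fh:
        chunk: list[str] = []
        for title, seq in records:
            chunk.append(f"@{title}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
            if len(chunk) >= 20000:
                fh.write("".join(chunk))
                chunk = []
        fh.write("".join(chunk))
    return n


GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def write_gff3(path: str | Path, rows: Iterable[dict]) -> None:
    """Write GFF3 (1-based inclusive on disk) from dicts with 0-based ``start``."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in rows:
            attrs = r.get("attributes", "")
            if isinstance(attrs, dict):
                attrs = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                "\t".join(
                    [
                        str(r["seqid"]),
                        str(r.get("source", "mircascade")),
                        str(r["type"]),
                        str(int(r["start"]) + 1),
                        str(int(r["end"])),
                        str(r.get("score", ".")),
                        r["strand"],
                        str(r.get("phase", ".")),
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read GFF3 into a DataFrame with 0-based half-open ``start``/``end``."""
    df = pd.read_csv(
        str(path), sep="\t", comment="#", header=None, names=GFF_COLUMNS,
        dtype={"seqid": str},
    )
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    return df


def parse_attributes(attr: str) -> dict[str, str]:
    out = {}
    for field in str(attr).split(";"):
        if "=" in field:
            k, v = field.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()
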