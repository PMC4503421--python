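"""Readers and writers for the sequence-side file formats used by the
pipeline: FASTA, GFF3 (single-contig ORF annotations), FASTQ, per-base depth
TSV (``samtools depth`` 3-column dialect) and a minimal SAM dialect
(mandatory 11 fields, M-only CIGAR).
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome_model import Genome, OrfRecord

# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, circular: bool = True) -> list[Genome]:
    """Read one or more sequences from a FASTA file."""
    genomes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        genomes.append(Genome(id=rec.id, sequence=str(rec.seq).upper(), circular=circular))
    return genomes


def write_fasta(genomes: Iterable[Genome], path: str | Path, wrap: int = 70) -> None:
    """Write genomes as FASTA, wrapped at ``wrap`` columns."""
    records = [SeqRecord(Seq(g.sequence), id=g.id, description="") for g in genomes]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3 (one contig, gene features only; ORF id in ID=, ORFan flag in orfan=)

def write_gff3(orfs: Iterable[OrfRecord], seqid: str, path: str | Path, source: str = "orfanage") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for orf in orfs:
            attrs = f"ID={orf.orf_id}"
            if orf.is_orfan:
                attrs += ";orfan=true"
            fh.write(
                f"{seqid}\t{source}\tgene\t{orf.start}\t{orf.end}\t.\t{orf.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> tuple[str, list[OrfRecord]]:
    """Read a single-contig GFF3 annotation; returns (seqid, ORF records)."""
    seqid = None
    orfs: list[OrfRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            if seqid is None:
                seqid = cols[0]
            elif cols[0] != seqid:
                raise ValueError(f"{path}:{lineno}: multiple contigs not supported")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            orfs.append(
                OrfRecord(
                    orf_id=attrs.get("ID", f"feature_{lineno}"),
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=cols[6] if cols[6] in "+-" else "+",
                    is_orfan=attrs.get("orfan", "false").lower() == "true",
                )
            )
    if seqid is None:
        raise ValueError(f"{path}: no features found")
    return seqid, orfs


# ---------------------------------------------------------------------------
# FASTQ (Phred+33)

def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) tuples; qualities are ignored downstream."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq).upper()


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Write (read_id, sequence, quality-string) records as FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Depth TSV (samtools depth dialect: ref_id <TAB> pos <TAB> depth)

def write_depth_tsv(ref_id: str, depth: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, d in enumerate(depth, 1):
            fh.write(f"{ref_id}\t{i}\t{int(d)}\n")


def read_depth_tsv(path: str | Path) -> tuple[str, np.ndarray]:
    """Read a 3-column depth TSV covering every base of one reference.

    Positions absent from the file (samtools omits zero-depth bases unless
    ``-a`` is used) are filled with zero up to the maximum position seen.
    """
    ref_id = None
    pos: list[int] = []
    dep: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            if ref_id is None:
                ref_id = cols[0]
            elif cols[0] != ref_id:
                raise ValueError(f"{path}:{lineno}: multiple references not supported")
            pos.append(int(cols[1]))
            dep.append(int(cols[2]))
    if ref_id is None:
        raise ValueError(f"{path}: empty depth file")
    depth = np.zeros(max(pos), dtype=np.int64)
    depth[np.asarray(pos) - 1] = dep
    return ref_id, depth


# ---------------------------------------------------------------------------
# Minimal SAM reader (mandatory 11 fields; M-only CIGAR)

def read_sam(path: str | Path):
    """Read alignments from a minimal SAM file.

    Only the 11 mandatory fields are used, the CIGAR must consist of a single
    ``<n>M`` operation (or ``*``), and header lines are skipped.  Returns a
    list of :class:`orfanage.coverage.AlignmentRecord`.
    """
    from .coverage import AlignmentRecord  # local import to avoid a cycle

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("@"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 11:
                raise ValueError(f"{path}:{lineno}: expected >= 11 SAM fields")
            qname, flag, rname, pos, _mapq, cigar = cols[0], int(cols[1]), cols[2], int(cols[3]), cols[4], cols[5]
            seq = cols[9]
            unmapped = bool(flag & 0x4) or rname == "*" or pos == 0
            if unmapped:
                out.append(
                    AlignmentRecord(read_id=qname, ref_id=rname, pos=0, aligned_length=0,
                                    strand="+", n_mismatch=0, mapped=False)
                )
                continue
            if cigar == "*":
                aln_len = len(seq) if seq != "*" else 0
            else:
                if not cigar.endswith("M") or not cigar[:-1].isdigit():
                    raise ValueError(f"{path}:{lineno}: only M-only CIGARs supported, got {cigar!r}")
                aln_len = int(cigar[:-1])
            nm = 0
            for tag in cols[11:]:
                if tag.startswith("NM:i:"):
                    nm = int(tag[5:])
            out.append(
                AlignmentRecord(
                    read_id=qname,
                    ref_id=rname,
                    pos=pos,
                    aligned_length=aln_len,
                    strand="-" if flag & 0x10 else "+",
                    n_mismatch=nm,
                    mapped=True,
                )
            )
    return out


def warn_clipped(n: int) -> None:
    warnings.warn(f"{n} alignment(s) overran the reference end and were clipped", stacklevel=3)
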