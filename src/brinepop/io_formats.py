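"""Readers/writers for the standard formats and the coordinate conventions.

All internal coordinates are 0-based, half-open. Conversion to the 1-based
conventions of SAM and GFF3 happens only inside the functions in this module,
so the rest of the package never sees a 1-based number.

Reverse-strand reads are stored reference-forward (as aligned); allele counts
downstream are therefore taken in reference orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

#: CIGAR operation codes in pysam order: M I D N S H P = X
CONSUMES_QUERY = frozenset("MIS=X")
CONSUMES_REF = frozenset("MDN=X")

_CIGAR_CODE = "MIDNSHP=X"


@dataclass
class Contig:
    """A DNA sequence (assembled contig or reference genome)."""

    id: str
    seq: str
    circular: bool = False
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if len(self.seq) == 0:
            raise ValueError(f"contig {self.id!r} has empty sequence")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"contig {self.id!r} contains characters outside ACGTN: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AlignmentRecord:
    """One read placed on one contig, reference-forward.

    ``cigar`` is a list of ``(op, length)`` with op one of ``MIDNSHP=X``.
    ``start`` is the 0-based leftmost reference position. ``seq`` is the read
    sequence in reference orientation (needed for allele counting).
    """

    read_id: str
    contig_id: str
    start: int
    cigar: list[tuple[str, int]]
    n_mismatch: int
    read_len: int
    mapped: bool = True
    strand: str = "+"
    seq: str = ""

    @property
    def ref_span(self) -> int:
        """Reference bases consumed (M/D/N/=/X)."""
        return sum(n for op, n in self.cigar if op in CONSUMES_REF)

    @property
    def query_aligned(self) -> int:
        """Query bases inside aligned columns (M/I/=/X; soft clips excluded)."""
        return sum(n for op, n in self.cigar if op in "MI=X")

    @property
    def aligned_columns(self) -> int:
        """Alignment columns: matches + mismatches + inserted + deleted bases."""
        return sum(n for op, n in self.cigar if op in "MID=X")

    @property
    def end(self) -> int:
        return self.start + self.ref_span


@dataclass
class GeneRecord:
    """A coding gene on a contig; 0-based half-open, frame 0 on its strand."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id!r}: end < start")

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path, sample_id: str = "") -> list[Contig]:
    """Read a FASTA file into Contig records.

    Lowercase input is uppercased; duplicate ids and characters outside
    ``ACGTN`` raise ``ValueError``. A header ending in ``circular=true``
    (written by :func:`write_fasta`) restores the circular flag.
    """
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate contig id {rec.id!r} in {path}")
        seen.add(rec.id)
        circular = "circular=true" in rec.description
        contigs.append(
            Contig(id=rec.id, seq=str(rec.seq), circular=circular, sample_id=sample_id)
        )
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path) -> None:
    records = []
    for c in contigs:
        desc = "circular=true" if c.circular else ""
        records.append(SeqRecord(Seq(c.seq), id=c.id, description=desc))
    SeqIO.write(records, str(path), "fasta")


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, quality: int = 35) -> None:
    """Write ``(read_id, seq)`` pairs as FASTQ with a constant quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{chr(quality + 33) * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# SAM


def _cigar_from_pysam(cigartuples) -> list[tuple[str, int]]:
    return [(_CIGAR_CODE[op], length) for op, length in cigartuples]


def _nm_from_md(md: str) -> int:
    """Mismatch+deletion count from an MD tag."""
    nm = 0
    i = 0
    while i < len(md):
        ch = md[i]
        if ch.isdigit():
            i += 1
        elif ch == "^":
            i += 1
            while i < len(md) and md[i].isalpha():
                nm += 1
                i += 1
        else:
            nm += 1
            i += 1
    return nm


def read_alignments(path: str | Path, refs: Sequence[Contig]) -> list[AlignmentRecord]:
    """Read a SAM file into AlignmentRecords against known references.

    SAM 1-based POS becomes a 0-based ``start``. Unmapped records are kept but
    flagged ``mapped=False`` (coverage code ignores them). NM is taken from the
    NM tag, or derived from MD+CIGAR when only MD is present.
    """
    ref_lens = {c.id: len(c) for c in refs}
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                out.append(
                    AlignmentRecord(
                        read_id=aln.query_name,
                        contig_id="*",
                        start=0,
                        cigar=[],
                        n_mismatch=0,
                        read_len=aln.query_length or len(aln.query_sequence or ""),
                        mapped=False,
                    )
                )
                continue
            ref = aln.reference_name
            if ref not in ref_lens:
                raise ValueError(f"alignment references unknown contig {ref!r}")
            if aln.has_tag("NM"):
                nm = int(aln.get_tag("NM"))
            elif aln.has_tag("MD"):
                nm = _nm_from_md(str(aln.get_tag("MD"))) + sum(
                    n for op, n in aln.cigartuples if _CIGAR_CODE[op] == "I"
                )
            else:
                raise ValueError(
                    f"record {aln.query_name!r} lacks both NM and MD tags; "
                    "recompute edit distance (e.g. samtools calmd) before import"
                )
            cigar = _cigar_from_pysam(aln.cigartuples)
            rec = AlignmentRecord(
                read_id=aln.query_name,
                contig_id=ref,
                start=aln.reference_start,
                cigar=cigar,
                n_mismatch=nm,
                read_len=aln.query_length,
                mapped=True,
                strand="-" if aln.is_reverse else "+",
                seq=aln.query_sequence or "",
            )
            if rec.end > ref_lens[ref]:
                raise ValueError(
                    f"record {rec.read_id!r} extends past end of contig {ref!r}"
                )
            out.append(rec)
    return out


def write_alignments(
    records: Iterable[AlignmentRecord], refs: Sequence[Contig], path: str | Path
) -> None:
    """Write AlignmentRecords as a minimal SAM (@HD, @SQ, NM tags)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c.id, "LN": len(c)} for c in refs],
    }
    tid = {c.id: i for i, c in enumerate(refs)}
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for rec in records:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = rec.read_id
            if not rec.mapped:
                a.is_unmapped = True
                a.query_sequence = rec.seq or None
                sam.write(a)
                continue
            a.reference_id = tid[rec.contig_id]
            a.reference_start = rec.start
            a.cigartuples = [(_CIGAR_CODE.index(op), n) for op, n in rec.cigar]
            a.query_sequence = rec.seq or None
            a.is_reverse = rec.strand == "-"
            a.mapping_quality = 60
            a.set_tag("NM", rec.n_mismatch)
            sam.write(a)


# ---------------------------------------------------------------------------
# GFF3 (CDS/gene subset)


def read_gff(path: str | Path, refs: Sequence[Contig] | None = None) -> list[GeneRecord]:
    """Read CDS/gene rows of a GFF3 file into GeneRecords.

    GFF 1-based closed intervals become 0-based half-open. CDS rows whose
    length is not a multiple of 3 are excluded with a warning (they cannot be
    read in frame for pN/pS).
    """
    ref_lens = {c.id: len(c) for c in refs} if refs is not None else None
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                continue
            seqid, _source, ftype, start, end, _score, strand, _frame, attrs = fields[:9]
            if ftype not in ("CDS", "gene"):
                continue
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise ValueError(f"GFF row on {seqid}: end {end_i} < start {start_i}")
            gene_id = seqid + ":" + start
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
                    break
            if ref_lens is not None:
                if seqid not in ref_lens:
                    raise ValueError(f"gene {gene_id!r} on unknown contig {seqid!r}")
                if end_i > ref_lens[seqid]:
                    raise ValueError(f"gene {gene_id!r} out of contig bounds")
            length = end_i - (start_i - 1)
            if length % 3 != 0:
                warnings.warn(
                    f"gene {gene_id!r} length {length} not divisible by 3; excluded",
                    stacklevel=2,
                )
                continue
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    contig_id=seqid,
                    start=start_i - 1,
                    end=end_i,
                    strand=strand,
                )
            )
    return genes


def write_gff(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.contig_id,
                        "brinepop",
                        "CDS",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )
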