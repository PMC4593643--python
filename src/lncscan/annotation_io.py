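"""GTF gene models, genome FASTA access, and spliced transcript sequences.

Coordinates follow the GTF convention throughout: 1-based, fully closed
intervals.  A :class:`TranscriptModel` stores its exons sorted by ascending
genomic start regardless of strand; minus-strand mRNA sequences are obtained
by concatenating the exon substrings in genomic order and reverse-complementing
the concatenation once.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")
_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    """A GTF line could not be parsed."""


class TranscriptValidationError(ValueError):
    """Exon records of one transcript violate a structural invariant."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case A/C/G/T/N sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Exon:
    """One exon interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise TranscriptValidationError(
                f"exon start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise TranscriptValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TranscriptModel:
    """A strand-aware, exon-structured transcript.

    Exons are sorted by ascending genomic start on construction; overlapping
    or duplicate exons, or exons disagreeing on chromosome/strand, are
    rejected.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Exon] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise TranscriptValidationError(
                f"transcript {self.transcript_id!r} has no exons"
            )
        for exon in self.exons:
            if exon.chrom != self.chrom or exon.strand != self.strand:
                raise TranscriptValidationError(
                    f"transcript {self.transcript_id!r}: exon on "
                    f"{exon.chrom}{exon.strand} disagrees with transcript "
                    f"{self.chrom}{self.strand}"
                )
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start <= prev.end:
                raise TranscriptValidationError(
                    f"transcript {self.transcript_id!r}: exons "
                    f"{prev.start}-{prev.end} and {cur.start}-{cur.end} "
                    "overlap or duplicate"
                )

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def length(self) -> int:
        return transcript_length(self)


class GenomeSequence:
    """In-memory genome: chromosome name -> upper-case A/C/G/T/N sequence.

    Bases outside the {A,C,G,T,N} alphabet (IUPAC ambiguity codes etc.) are
    mapped to N on load with a logged warning.
    """

    def __init__(self, sequences: dict[str, str]):
        cleaned: dict[str, str] = {}
        for name, seq in sequences.items():
            if name in cleaned:
                raise ValueError(f"duplicate chromosome name {name!r}")
            seq = seq.upper()
            if not _VALID_BASES.issuperset(seq):
                n_bad = sum(1 for c in seq if c not in _VALID_BASES)
                logger.warning(
                    "chromosome %s: %d non-ACGTN characters mapped to N",
                    name,
                    n_bad,
                )
                seq = "".join(c if c in _VALID_BASES else "N" for c in seq)
            cleaned[name] = seq
        self._seqs = cleaned

    @classmethod
    def from_fasta(cls, path) -> "GenomeSequence":
        records = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate chromosome name {rec.id!r} in FASTA")
            records[rec.id] = str(rec.seq)
        return cls(records)

    @property
    def chrom_names(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def sequence(self, chrom: str) -> str:
        try:
            return self._seqs[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome") from None

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Subsequence for a 1-based inclusive interval."""
        seq = self.sequence(chrom)
        if start < 1 or end > len(seq) or start > end:
            raise IndexError(
                f"{chrom}:{start}-{end} out of bounds (chromosome length {len(seq)})"
            )
        return seq[start - 1 : end]


def _parse_attributes(attr_field: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(attr_field))
    if not attrs:
        raise GtfParseError(f"line {lineno}: unparseable attribute field")
    return attrs


def read_gtf(path) -> list[TranscriptModel]:
    """Parse a GTF file into transcript models, in first-appearance order.

    Exon feature lines are grouped by ``transcript_id``; other feature lines
    are ignored, except that a transcript represented only by a
    ``transcript`` line (no exon children) is treated as single-exon spanning
    the transcript interval.  Comment lines starting with ``#`` are skipped.
    """
    exons_by_tx: dict[str, list[Exon]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene_id, chrom, strand)
    tx_span: dict[str, Exon] = {}  # fallback for exon-less transcripts
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr = fields
            if feature not in ("exon", "transcript"):
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(
                    f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            attrs = _parse_attributes(attr, lineno)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise GtfParseError(f"line {lineno}: missing transcript_id attribute")
            gid = attrs.get("gene_id", tid)
            if tid not in meta:
                meta[tid] = (gid, chrom, strand)
                order.append(tid)
            if feature == "exon":
                exons_by_tx.setdefault(tid, []).append(Exon(chrom, start, end, strand))
            else:
                tx_span[tid] = Exon(chrom, start, end, strand)

    models = []
    for tid in order:
        gid, chrom, strand = meta[tid]
        exons = exons_by_tx.get(tid)
        if exons is None:
            exons = [tx_span[tid]]
        models.append(TranscriptModel(tid, gid, chrom, strand, exons))
    return models


def write_gtf(models: list[TranscriptModel], path) -> None:
    """Write exon records for each transcript as 9-column GTF."""
    with open(path, "w") as fh:
        for model in models:
            for exon in model.exons:
                attrs = (
                    f'gene_id "{model.gene_id}"; '
                    f'transcript_id "{model.transcript_id}";'
                )
                fh.write(
                    f"{exon.chrom}\tlncscan\texon\t{exon.start}\t{exon.end}"
                    f"\t.\t{exon.strand}\t.\t{attrs}\n"
                )


def spliced_sequence(model: TranscriptModel, genome: GenomeSequence) -> str:
    """5'->3' mRNA sequence of a transcript.

    Exon substrings are concatenated in ascending genomic order and the
    concatenation is reverse-complemented once for minus-strand transcripts.
    """
    parts = [genome.fetch(exon.chrom, exon.start, exon.end) for exon in model.exons]
    seq = "".join(parts)
    if model.strand == "-":
        seq = reverse_complement(seq)
    return seq


def transcript_length(model: TranscriptModel) -> int:
    """Sum of exon lengths, in nucleotides."""
    return sum(exon.length for exon in model.exons)
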