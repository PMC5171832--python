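"""Genome and annotation I/O, ORF extraction and start/stop-codon validation.

Internal coordinates are 0-based half-open throughout; GenBank and GFF3 are
1-based inclusive and are converted at the file boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

#: Accepted start codons (NTG) on the coding strand.
START_CODONS = frozenset({"ATG", "GTG", "TTG", "CTG"})
#: Accepted stop codons on the coding strand.
STOP_CODONS = frozenset({"TAG", "TGA", "TAA"})


class Validation(str, Enum):
    """Outcome of the ORF start/stop-codon screen."""

    VALID = "valid"
    FAILED_START = "failed_start"
    FAILED_STOP = "failed_stop"
    TOO_SHORT = "too_short"
    UNSET = "unset"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class GenomeFormatError(ValueError):
    """Raised when a sequence record contains characters outside {A,C,G,T,N}."""


class AnnotationError(ValueError):
    """Raised when a feature is inconsistent with its genome (e.g. out of bounds)."""


@dataclass(frozen=True)
class GenomeRecord:
    """A named DNA sequence with a circularity flag.

    The sequence is upper-case over the alphabet {A, C, G, T, N}; construction
    rejects anything else, naming the first offending position.
    """

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 1:
            raise GenomeFormatError(f"record {self.id!r}: empty sequence")
        for i, base in enumerate(seq):
            if base not in VALID_BASES:
                raise GenomeFormatError(
                    f"record {self.id!r}: illegal character {base!r} at position {i + 1}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Return ``sequence[start:end]``, wrapping past the end when circular."""
        n = len(self.sequence)
        if 0 <= start <= end <= n:
            return self.sequence[start:end]
        if not self.circular:
            raise AnnotationError(
                f"interval [{start}, {end}) out of bounds for linear genome "
                f"{self.id!r} of length {n}"
            )
        # circular wrap: spans may cross the origin but not exceed one full turn
        out_len = end - start
        if out_len > n:
            raise AnnotationError(
                f"interval [{start}, {end}) longer than circular genome {self.id!r}"
            )
        start %= n
        doubled = self.sequence + self.sequence
        return doubled[start : start + out_len]


@dataclass
class OrfRecord:
    """An annotated coding region: 0-based half-open genomic interval + strand."""

    gene: str
    start: int
    end: int
    strand: str
    validation: Validation = Validation.UNSET

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise AnnotationError(f"ORF {self.gene!r}: strand must be '+' or '-'")
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"ORF {self.gene!r}: need 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


def read_genome(path: str | Path, format: str = "fasta") -> list[GenomeRecord]:
    """Read all sequence records from a FASTA or GenBank flat file.

    Sequences are upper-cased; circularity is taken from GenBank record
    topology when present, else False. Illegal characters raise
    :class:`GenomeFormatError` naming the record and position.
    """
    if format not in {"fasta", "genbank"}:
        raise ValueError(f"unsupported genome format: {format!r}")
    path = Path(path)
    records: list[GenomeRecord] = []
    for rec in SeqIO.parse(str(path), format):
        circular = False
        if format == "genbank":
            topology = rec.annotations.get("topology", "")
            circular = str(topology).lower() == "circular"
        records.append(GenomeRecord(id=rec.id, sequence=str(rec.seq), circular=circular))
    if not records:
        raise GenomeFormatError(f"no sequence records parsed from {path}")
    return records


def _orf_from_genbank_feature(feature, gene_fallback: str) -> OrfRecord | None:
    loc = feature.location
    if len(loc.parts) > 1:
        logger.warning("skipping compound (join) location for feature %s", gene_fallback)
        return None
    quals = feature.qualifiers
    gene = (quals.get("gene") or quals.get("locus_tag") or [gene_fallback])[0]
    strand = "-" if loc.strand == -1 else "+"
    return OrfRecord(gene=gene, start=int(loc.start), end=int(loc.end), strand=strand)


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attr.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_annotations(path: str | Path, format: str = "gff3") -> list[OrfRecord]:
    """Read CDS features as :class:`OrfRecord` from GFF3 or GenBank.

    File coordinates (1-based inclusive) are converted to 0-based half-open.
    Compound (join) locations are skipped with a warning: the screen has no
    defined treatment for multi-part coding regions. The ``validation`` field
    is left unset; run :func:`validate_orf` on the coding sequence.
    """
    path = Path(path)
    orfs: list[OrfRecord] = []
    if format == "genbank":
        for rec in SeqIO.parse(str(path), "genbank"):
            n_cds = 0
            for feature in rec.features:
                if feature.type != "CDS":
                    continue
                n_cds += 1
                orf = _orf_from_genbank_feature(feature, f"{rec.id}_cds{n_cds}")
                if orf is not None:
                    orfs.append(orf)
    elif format == "gff3":
        with open(path) as fh:
            n = 0
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 8:
                    raise AnnotationError(f"{path}: malformed GFF3 line: {line!r}")
                ftype = fields[2]
                if ftype != "CDS":
                    continue
                n += 1
                attrs = _parse_gff3_attributes(fields[8]) if len(fields) > 8 else {}
                gene = attrs.get("gene") or attrs.get("Name") or attrs.get("ID") or f"cds{n}"
                start1, end1 = int(fields[3]), int(fields[4])
                strand = fields[6] if fields[6] in {"+", "-"} else "+"
                orfs.append(OrfRecord(gene=gene, start=start1 - 1, end=end1, strand=strand))
    else:
        raise ValueError(f"unsupported annotation format: {format!r}")
    return orfs


def write_gff3(orfs: Iterable[OrfRecord], path: str | Path, seqid: str = "chr") -> None:
    """Write ORFs as GFF3 CDS lines (round-trips with :func:`read_annotations`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for orf in orfs:
            fh.write(
                f"{seqid}\ttcrispri\tCDS\t{orf.start + 1}\t{orf.end}\t.\t{orf.strand}\t0"
                f"\tID={orf.gene};gene={orf.gene}\n"
            )


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def coding_sequence(genome: GenomeRecord, orf: OrfRecord) -> str:
    """Return the 5'->3' coding-strand sequence of an ORF.

    Minus-strand features are reverse-complemented. Features extending past the
    sequence end are allowed only on circular genomes (wrap-around).
    """
    if orf.end > len(genome) and not genome.circular:
        raise AnnotationError(
            f"ORF {orf.gene!r} [{orf.start}, {orf.end}) extends past the end of "
            f"linear genome {genome.id!r} (length {len(genome)})"
        )
    seq = genome.fetch(orf.start, orf.end)
    return reverse_complement(seq) if orf.strand == "-" else seq


def validate_orf(coding: str) -> Validation:
    """Screen a coding sequence: NTG start, TAG/TGA/TAA stop.

    Returns ``too_short`` below 6 nt (no room for two codons), ``failed_start``
    when the first codon is not one of ATG/GTG/TTG/CTG (start failure takes
    precedence when both codons fail), ``failed_stop`` when the last codon is
    not a stop, else ``valid``. A codon containing N fails its membership test.
    Frame (length divisible by 3) is reported as a warning only, not a failure.
    """
    coding = coding.upper()
    if len(coding) < 6:
        return Validation.TOO_SHORT
    if len(coding) % 3 != 0:
        logger.warning("coding sequence length %d not divisible by 3", len(coding))
    if coding[:3] not in START_CODONS:
        return Validation.FAILED_START
    if coding[-3:] not in STOP_CODONS:
        return Validation.FAILED_STOP
    return Validation.VALID


def validate_all(genome: GenomeRecord, orfs: Iterable[OrfRecord]) -> list[OrfRecord]:
    """Run :func:`validate_orf` over every ORF, setting ``validation`` in place."""
    out = []
    for orf in orfs:
        orf.validation = validate_orf(coding_sequence(genome, orf))
        out.append(orf)
    return out


def orf_report(orfs: Iterable[OrfRecord], path: str | Path | None = None) -> str:
    """TSV ORF report: gene, start, end, strand, validation. Returns the text."""
    lines = ["gene\tstart\tend\tstrand\tvalidation"]
    for orf in orfs:
        lines.append(f"{orf.gene}\t{orf.start}\t{orf.end}\t{orf.strand}\t{orf.validation}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def count_failed(orfs: Iterable[OrfRecord]) -> int:
    """Aggregate failure count over validated ORFs (everything not ``valid``)."""
    return sum(1 for orf in orfs if orf.validation not in (Validation.VALID, Validation.UNSET))
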