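"""Canonical k-mer counting over a genome.

A canonical k-mer is the lexicographic minimum of a k-mer and its reverse
complement, so both strands of a double-stranded site share one count. The
index scans the forward strand only and canonicalizes each window; a count is
therefore the number of double-stranded genomic sites matching a query on
either strand, with reverse-complement-palindromic k-mers counted once per
site. Windows containing N are skipped. Circular genomes wrap k-1 positions
past the end.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from tcrispri.genome_io import GenomeRecord, reverse_complement

_ACGT = frozenset("ACGT")


def canonicalize(kmer: str) -> str:
    """Return the lexicographically smaller of ``kmer`` and its reverse complement."""
    if not set(kmer) <= _ACGT:
        bad = next(c for c in kmer if c not in _ACGT)
        raise ValueError(f"non-ACGT character {bad!r} in k-mer {kmer!r}")
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class KmerIndex:
    """Canonical k-mer -> count mapping for one genome at one k."""

    k: int
    counts: dict[str, int] = field(default_factory=dict)
    source_length: int = 0

    def count(self, query: str) -> int:
        """Number of double-stranded genomic sites matching ``query`` on either strand."""
        if len(query) != self.k:
            raise ValueError(f"query length {len(query)} != index k {self.k}")
        return self.counts.get(canonicalize(query), 0)

    def dump(self, path: str | Path) -> None:
        """Write the index as a two-column TSV (kmer, count), sorted for determinism."""
        with open(path, "w") as fh:
            fh.write(f"# k={self.k}\tsource_length={self.source_length}\n")
            for kmer in sorted(self.counts):
                fh.write(f"{kmer}\t{self.counts[kmer]}\n")

    @classmethod
    def load(cls, path: str | Path) -> "KmerIndex":
        counts: dict[str, int] = {}
        k = 0
        source_length = 0
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    for part in line[1:].split():
                        key, _, val = part.partition("=")
                        if key == "k":
                            k = int(val)
                        elif key == "source_length":
                            source_length = int(val)
                    continue
                kmer, _, n = line.rstrip("\n").partition("\t")
                counts[kmer] = int(n)
        if k == 0 and counts:
            k = len(next(iter(counts)))
        return cls(k=k, counts=counts, source_length=source_length)


def build_index(genome: GenomeRecord, k: int, circular: bool | None = None) -> KmerIndex:
    """Slide a k-window over the forward strand, canonicalize, count.

    ``circular`` overrides the genome's own flag; when circular, the scan wraps
    k-1 positions past the end so every rotational window is counted once.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    seq = genome.sequence
    wrap = genome.circular if circular is None else circular
    if k > len(seq):
        if not wrap:
            raise ValueError(f"k={k} exceeds linear genome length {len(seq)}")
    scan = seq + seq[: k - 1] if wrap else seq
    counts: Counter[str] = Counter()
    n_windows = len(scan) - k + 1
    for i in range(n_windows):
        window = scan[i : i + k]
        if "N" in window:
            continue
        counts[canonicalize(window)] += 1
    return KmerIndex(k=k, counts=dict(counts), source_length=len(seq))


def count(index: KmerIndex, query: str) -> int:
    """Functional alias for :meth:`KmerIndex.count`."""
    return index.count(query)
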