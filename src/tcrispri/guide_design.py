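"""Candidate sgRNA enumeration, tiered off-target profiling, filtering, ranking.

All matching is done in the genomic CC-prefixed frame: a candidate site is the
23-mer 5'-CC-N-[20-nt protospacer]-3' as read on the scanned strand (the
reverse-complement view of the N-G-G PAM). Region I is the PAM-proximal 7 nt
of the protospacer, regions I+II its PAM-proximal 12 nt, so the three screen
lengths decompose as 10 = CC + N + 7, 15 = CC + N + 12, 23 = CC + N + 20.

"Mismatches outside the PAM" means mismatches confined to the 20-nt
protospacer: the leading dinucleotide must be CC (or the weak CT/TC variants)
exactly, and the PAM N at position 3 is a free position never counted as a
mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tcrispri.genome_io import (
    AnnotationError,
    GenomeRecord,
    OrfRecord,
    Validation,
    coding_sequence,
    reverse_complement,
    validate_orf,
)
from tcrispri.kmer_index import KmerIndex, build_index

PAM_PREFIX = "CC"
NEAR_PAM_PREFIXES = ("CT", "TC")


@dataclass(frozen=True)
class DesignParams:
    """Tunable knobs of the candidate screen.

    window_nt bounds the offset of a site's first (CC) base from the A of the
    start codon, 0-based on the coding strand. The defaults reproduce the
    whole-genome screen: 150-nt window, CC PAM prefix with CT/TC near-PAM
    variants, 10/15/23-mer abundance tiers, removal on any exact / 1-mismatch /
    2-mismatch genomic match outside the PAM, and 3-/4-mismatch reporting
    tiers over the full 20-nt protospacer.
    """

    window_nt: int = 150
    region1_len: int = 7
    region12_len: int = 12
    pam_prefix: str = PAM_PREFIX
    near_pam_prefixes: tuple[str, ...] = NEAR_PAM_PREFIXES
    site_len: int = 23
    kmer_lens: tuple[int, ...] = (10, 15, 23)
    max_outside_pam_mm: int = 2
    deep_mm_tiers: tuple[int, ...] = (3, 4)
    scan_both_strands: bool = False

    def __post_init__(self) -> None:
        if not (self.region1_len < self.region12_len < self.site_len - 3):
            raise ValueError("need region1_len < region12_len < protospacer length")


@dataclass(frozen=True)
class GuideCandidate:
    """One CC-prefixed 23-mer site within an ORF window.

    offset_nt is the 0-based coding-strand distance of the site's first (CC)
    base from the start codon. genome_start/genome_strand give the site's
    leftmost forward-strand coordinate and the genome strand it reads on.
    """

    gene: str
    offset_nt: int
    site23: str
    genome_start: int
    genome_strand: str
    scanned_strand: str = "coding"

    def __post_init__(self) -> None:
        if len(self.site23) != 23:
            raise ValueError(f"site must be 23 nt, got {len(self.site23)}")
        if not self.site23.startswith(PAM_PREFIX):
            raise ValueError(f"site must start with CC: {self.site23!r}")
        if self.offset_nt < 0:
            raise ValueError("offset_nt must be >= 0")

    @property
    def pam3(self) -> str:
        return self.site23[:3]

    @property
    def region1(self) -> str:
        """PAM-proximal 7 nt of the protospacer (site positions 4-10)."""
        return self.site23[3:10]

    @property
    def region2(self) -> str:
        """Next 5 nt (site positions 11-15)."""
        return self.site23[10:15]

    @property
    def protospacer20(self) -> str:
        return self.site23[3:23]

    @property
    def region1_site10(self) -> str:
        """The CC-prefixed 10-mer (CC + N + region I) used for abundance ranking."""
        return self.site23[:10]

    def spacer_for_cassette(self, emit_reverse_complement: bool = True) -> str:
        """20-mer handed to the oligo builder.

        Default is the reverse complement of the protospacer (the strand that
        base-pairs as the sgRNA spacer in the N-G-G frame); cassette
        orientation is strain-specific, so the verbatim protospacer is
        available by flag.
        """
        return (
            reverse_complement(self.protospacer20)
            if emit_reverse_complement
            else self.protospacer20
        )


@dataclass
class OffTargetProfile:
    """Genome-wide match counts for one candidate across the screen tiers.

    Exact tiers are canonical k-mer counts of the site's 10/15/23-mer with the
    leading dinucleotide substituted by CC or by the CT/TC near-PAM variants.
    Mismatch tiers count 23-nt windows on either genome strand whose prefix is
    in {CC, CT, TC} and whose 20-nt protospacer differs from the candidate's
    at exactly 1-4 positions; the candidate's own site (distance 0) lands in
    n_exact23, never in a mismatch tier.
    """

    n_region1_cc: int = 0
    n_region1_nearpam: int = 0
    n_region12_cc: int = 0
    n_region12_nearpam: int = 0
    n_exact23: int = 0
    n_mm1: int = 0
    n_mm2: int = 0
    n_mm3: int = 0
    n_mm4: int = 0

    @property
    def region1_total(self) -> int:
        """Ranking key: total region-I abundance over CC and CT/TC prefixes."""
        return self.n_region1_cc + self.n_region1_nearpam

    def as_dict(self) -> dict[str, int]:
        return {
            "n_region1_cc": self.n_region1_cc,
            "n_region1_nearpam": self.n_region1_nearpam,
            "n_region12_cc": self.n_region12_cc,
            "n_region12_nearpam": self.n_region12_nearpam,
            "n_exact23": self.n_exact23,
            "n_mm1": self.n_mm1,
            "n_mm2": self.n_mm2,
            "n_mm3": self.n_mm3,
            "n_mm4": self.n_mm4,
        }


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def _site_on_coding_strand(
    genome: GenomeRecord, orf: OrfRecord, c: int
) -> tuple[str, int] | None:
    """23-mer starting at coding offset c on the coding strand, or None if it
    does not fit. Returns (site, leftmost forward coordinate)."""
    n = len(genome)
    if orf.strand == "+":
        g = orf.start + c
        if g + 23 > n and not genome.circular:
            return None
        return genome.fetch(g, g + 23), g % n
    g = orf.end - 1 - c
    if g - 22 < 0 and not genome.circular:
        return None
    return reverse_complement(genome.fetch(g - 22, g + 1)), (g - 22) % n


def _site_on_template_strand(
    genome: GenomeRecord, orf: OrfRecord, c: int
) -> tuple[str, int] | None:
    """23-mer whose first base sits opposite coding offset c, reading 5'->3'
    on the template strand (anti-coding direction)."""
    n = len(genome)
    if orf.strand == "+":
        g = orf.start + c
        if g - 22 < 0 and not genome.circular:
            return None
        return reverse_complement(genome.fetch(g - 22, g + 1)), (g - 22) % n
    g = orf.end - 1 - c
    if g + 23 > n and not genome.circular:
        return None
    return genome.fetch(g, g + 23), g % n


def enumerate_candidates(
    genome: GenomeRecord, orf: OrfRecord, params: DesignParams | None = None
) -> list[GuideCandidate]:
    """Enumerate CC-prefixed 23-mer sites within the ORF's start-codon window.

    The coding strand is scanned by default (template strand too when
    ``params.scan_both_strands``); a site qualifies when its CC lies within
    the ORF at offset <= window_nt and the full 23-mer fits in the genome
    (crossing the ORF boundary away from the start codon is allowed).
    Candidates are returned in increasing offset order, coding strand first
    at equal offsets.
    """
    params = params or DesignParams()
    if orf.validation != Validation.VALID:
        raise ValueError(
            f"ORF {orf.gene!r} has validation {orf.validation}; "
            "only validated ORFs are scanned"
        )
    L = len(orf)
    out: list[GuideCandidate] = []
    max_c = min(params.window_nt, L - 1)
    for c in range(0, max_c + 1):
        hit = _site_on_coding_strand(genome, orf, c) if c <= L - 2 else None
        if hit is None:
            site, gstart = "", -1
        else:
            site, gstart = hit
        if site and site.startswith(params.pam_prefix) and "N" not in site:
            gstrand = orf.strand
            out.append(
                GuideCandidate(
                    gene=orf.gene,
                    offset_nt=c,
                    site23=site,
                    genome_start=gstart,
                    genome_strand=gstrand,
                    scanned_strand="coding",
                )
            )
        if params.scan_both_strands and c >= 1 and c <= min(params.window_nt, L - 1):
            hit_t = _site_on_template_strand(genome, orf, c)
            if hit_t is None:
                continue
            site_t, gstart_t = hit_t
            if site_t.startswith(params.pam_prefix) and "N" not in site_t:
                gstrand_t = "-" if orf.strand == "+" else "+"
                out.append(
                    GuideCandidate(
                        gene=orf.gene,
                        offset_nt=c,
                        site23=site_t,
                        genome_start=gstart_t,
                        genome_strand=gstrand_t,
                        scanned_strand="template",
                    )
                )
    out.sort(key=lambda cand: (cand.offset_nt, cand.scanned_strand))
    return out


_BASE = {"A": 65, "C": 67, "G": 71, "T": 84, "N": 78}


def _strand_scan_strings(genome: GenomeRecord) -> list[str]:
    """Both genome strands as linear scan strings, wrapped 22 nt when circular."""
    fwd = genome.sequence
    rev = reverse_complement(fwd)
    if genome.circular:
        fwd = fwd + fwd[:22]
        rev = rev + rev[:22]
    return [fwd, rev]


def _mismatch_tier_counts(genome: GenomeRecord, protospacer20: str) -> dict[int, int]:
    """Count PAM-prefixed 23-nt windows at protospacer Hamming distance 1-4.

    Vectorized scan of both strands: windows whose leading dinucleotide is in
    {CC, CT, TC}, whose third position is free, and whose trailing 20 nt sit
    at the given distance from the protospacer. Windows containing N are
    skipped. Distance-0 windows (exact matches, including the candidate's own
    site) are excluded by construction.
    """
    proto = np.frombuffer(protospacer20.encode(), dtype=np.uint8)
    tiers = {1: 0, 2: 0, 3: 0, 4: 0}
    C, T, N = _BASE["C"], _BASE["T"], _BASE["N"]
    for strand_seq in _strand_scan_strings(genome):
        if len(strand_seq) < 23:
            continue
        arr = np.frombuffer(strand_seq.encode(), dtype=np.uint8)
        w = np.lib.stride_tricks.sliding_window_view(arr, 23)
        prefix_ok = ((w[:, 0] == C) & ((w[:, 1] == C) | (w[:, 1] == T))) | (
            (w[:, 0] == T) & (w[:, 1] == C)
        )
        no_n = ~(w == N).any(axis=1)
        sel = w[prefix_ok & no_n]
        if sel.shape[0] == 0:
            continue
        d = (sel[:, 3:] != proto).sum(axis=1)
        for m in tiers:
            tiers[m] += int((d == m).sum())
    return tiers


def off_target_profile(
    candidate: GuideCandidate,
    genome: GenomeRecord,
    indices: dict[int, KmerIndex],
    params: DesignParams | None = None,
) -> OffTargetProfile:
    """Compute the full tiered off-target profile for one candidate.

    Requires canonical k-mer indices at k = 10, 15, 23 built from the same
    genome. Exact tiers are index lookups with the leading dinucleotide
    substituted; mismatch tiers are windowed scans of both strands (the
    canonical index cannot answer Hamming-ball queries).
    """
    params = params or DesignParams()
    for k in (10, 15, 23):
        if k not in indices:
            raise ValueError(f"missing k-mer index for k={k}")
    site = candidate.site23
    core10, core15 = site[2:10], site[2:15]

    prof = OffTargetProfile()
    prof.n_region1_cc = indices[10].count(params.pam_prefix + core10)
    prof.n_region1_nearpam = sum(
        indices[10].count(p + core10) for p in params.near_pam_prefixes
    )
    prof.n_region12_cc = indices[15].count(params.pam_prefix + core15)
    prof.n_region12_nearpam = sum(
        indices[15].count(p + core15) for p in params.near_pam_prefixes
    )
    prof.n_exact23 = indices[23].count(site)

    tiers = _mismatch_tier_counts(genome, candidate.protospacer20)
    prof.n_mm1, prof.n_mm2, prof.n_mm3, prof.n_mm4 = (
        tiers[1],
        tiers[2],
        tiers[3],
        tiers[4],
    )
    return prof


def filter_and_rank(
    candidates: list[GuideCandidate], profiles: list[OffTargetProfile]
) -> list[tuple[GuideCandidate, OffTargetProfile]]:
    """Remove non-specific candidates, rank survivors by region-I abundance.

    A candidate is removed when its site has any exact genomic match beyond
    itself (n_exact23 > 1) or any 1- or 2-mismatch match outside the PAM.
    Survivors are sorted by ascending total region-I abundance (CC + CT/TC),
    ties broken by ascending offset; the order is deterministic and invariant
    under input permutation.
    """
    if len(candidates) != len(profiles):
        raise ValueError(
            f"candidates ({len(candidates)}) and profiles ({len(profiles)}) misaligned"
        )
    kept = [
        (c, p)
        for c, p in zip(candidates, profiles)
        if p.n_exact23 <= 1 and p.n_mm1 == 0 and p.n_mm2 == 0
    ]
    kept.sort(key=lambda cp: (cp[1].region1_total, cp[0].offset_nt, cp[0].site23))
    return kept


def least_abundant_region1(
    candidates: list[GuideCandidate], profiles: list[OffTargetProfile]
) -> tuple[str, int] | None:
    """The candidate 10-mer (CC + N + region I) of minimal region-I abundance.

    Ties break to the smaller offset. Returns None for an empty candidate
    list (reported as absent, not an error).
    """
    if len(candidates) != len(profiles):
        raise ValueError("candidates and profiles misaligned")
    if not candidates:
        return None
    best = min(zip(candidates, profiles), key=lambda cp: (cp[1].region1_total, cp[0].offset_nt))
    return best[0].region1_site10, best[1].region1_total


def design_genome(
    genome: GenomeRecord,
    annotations: list[OrfRecord],
    params: DesignParams | None = None,
    indices: dict[int, KmerIndex] | None = None,
) -> pd.DataFrame:
    """Run the full screen over every annotated ORF.

    Pipeline per ORF: validate start/stop codons -> enumerate CC-prefixed
    sites in the window -> profile each against the genome -> filter and
    rank. Returns one row per ORF with the validation outcome, candidate
    counts, the top-ranked guide (site, offset, cassette spacer, profile) and
    the least-abundant region-I sequence. Deterministic for fixed inputs.
    """
    params = params or DesignParams()
    if indices is None:
        indices = {k: build_index(genome, k) for k in params.kmer_lens}

    rows: list[dict] = []
    for orf in annotations:
        orf.validation = validate_orf(coding_sequence(genome, orf))
        row: dict = {
            "gene": orf.gene,
            "start": orf.start,
            "end": orf.end,
            "strand": orf.strand,
            "validation": str(orf.validation),
            "n_candidates": 0,
            "n_retained": 0,
            "status": "",
            "selected_site23": "",
            "selected_offset": pd.NA,
            "spacer": "",
            "least_region1_site10": "",
            "least_region1_count": pd.NA,
        }
        for key in OffTargetProfile().as_dict():
            row[key] = pd.NA
        if orf.validation != Validation.VALID:
            row["status"] = str(orf.validation)
            rows.append(row)
            continue
        cands = enumerate_candidates(genome, orf, params)
        profs = [off_target_profile(c, genome, indices, params) for c in cands]
        ranked = filter_and_rank(cands, profs)
        row["n_candidates"] = len(cands)
        row["n_retained"] = len(ranked)
        least = least_abundant_region1(cands, profs)
        if least is not None:
            row["least_region1_site10"], row["least_region1_count"] = least
        if not cands:
            row["status"] = "no_candidates"
        elif not ranked:
            row["status"] = "no qualifying sgRNA"
        else:
            best_c, best_p = ranked[0]
            row["status"] = "ok"
            row["selected_site23"] = best_c.site23
            row["selected_offset"] = best_c.offset_nt
            row["spacer"] = best_c.spacer_for_cassette()
            row.update(best_p.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
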