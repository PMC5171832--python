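"""Seeded synthetic fixtures for every input class the toolkit consumes.

These generators stand in for a real annotated bacterial genome and its
RNA-Seq expression tables, so the whole pipeline is testable without
downloads: genomes with annotated ORFs (NTG starts, TAG/TGA/TAA stops, a
controllable number of deliberately invalid ones), planted CC/CT/TC-prefixed
guide sites with exact mismatch structure, expression tables with a single
knocked-down target under multiplicative log-normal noise, and dose-response
curves from the rising logistic.

All randomness flows from one integer seed per call through
``numpy.random.default_rng``; identical seeds give byte-identical outputs.
No attempt is made to mimic real codon usage, GC content or operon
structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tcrispri.genome_io import (
    START_CODONS,
    STOP_CODONS,
    GenomeRecord,
    OrfRecord,
    reverse_complement,
    write_gff3,
)
from tcrispri.offtarget_expression import attach_fold_change

_BASES = np.array(list("ACGT"))


class GenerationError(RuntimeError):
    """Raised when a fixture spec cannot be packed into the genome."""


@dataclass(frozen=True)
class PlantedSite:
    """One guide site to embed: prefix + N + (spacer with n_mismatches).

    positions are 0-based indices into the 20-mer protospacer (hence always
    outside the PAM); drawn from the seed when not given. host_gene is an
    ORF index (the site lands on that gene's coding strand inside the design
    window) or None for an intergenic placement on the forward strand.
    """

    spacer: str
    prefix: str = "CC"
    n_mismatches: int = 0
    positions: tuple[int, ...] | None = None
    host_gene: int | None = None
    n_base: str | None = None  # fix the free PAM N; drawn from the seed when None

    def __post_init__(self) -> None:
        if len(self.spacer) != 20:
            raise ValueError("spacer must be 20 nt")
        if self.prefix not in {"CC", "CT", "TC"}:
            raise ValueError(f"prefix must be CC, CT or TC, got {self.prefix!r}")
        if not 0 <= self.n_mismatches <= 4:
            raise ValueError("n_mismatches must be 0..4")
        if self.positions is not None and len(self.positions) != self.n_mismatches:
            raise ValueError("positions must match n_mismatches")


@dataclass(frozen=True)
class FixtureSpec:
    """Layout of a synthetic annotated genome."""

    seed: int
    genome_length: int = 6000
    n_orfs: int = 6
    n_invalid_orfs: int = 0
    orf_length: int = 300
    intergenic_length: int = 150
    planted_sites: tuple[PlantedSite, ...] = ()
    circular: bool = False


def random_spacer(rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=20))


def _mutate(spacer: str, positions: tuple[int, ...], rng: np.random.Generator) -> str:
    out = list(spacer)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(out)


def make_genome(
    spec: FixtureSpec,
) -> tuple[GenomeRecord, list[OrfRecord], pd.DataFrame]:
    """Generate (genome, annotations, truth table) from a fixture spec.

    ORFs are laid out left to right on alternating strands, separated by
    intergenic spacers; the first ``n_invalid_orfs`` violate exactly one
    screen rule (alternating bad start / bad stop). Planted sites are
    embedded with exactly the requested mismatch structure relative to their
    spacer; the truth table lists every planted site's coordinates, strand,
    realised 23-mer and mismatch tier.
    """
    rng = np.random.default_rng(spec.seed)
    unit = spec.orf_length + spec.intergenic_length
    needed = spec.n_orfs * unit + spec.intergenic_length
    if needed > spec.genome_length:
        raise GenerationError(
            f"cannot pack {spec.n_orfs} ORFs of {spec.orf_length} nt plus spacers "
            f"into {spec.genome_length} nt (need {needed})"
        )
    if spec.orf_length < 29 or spec.orf_length % 3 != 0:
        raise GenerationError("orf_length must be a multiple of 3 and >= 29")

    seq = list(rng.choice(_BASES, size=spec.genome_length))

    start_list = sorted(START_CODONS)
    stop_list = sorted(STOP_CODONS)
    orfs: list[OrfRecord] = []
    for i in range(spec.n_orfs):
        start = spec.intergenic_length + i * unit
        end = start + spec.orf_length
        strand = "+" if i % 2 == 0 else "-"
        coding = list("".join(rng.choice(_BASES, size=spec.orf_length)))
        coding[:3] = start_list[int(rng.integers(len(start_list)))]
        coding[-3:] = stop_list[int(rng.integers(len(stop_list)))]
        if i < spec.n_invalid_orfs:
            if i % 2 == 0:
                coding[:3] = "AAA"  # failed_start
            else:
                coding[-3:] = "AAA"  # failed_stop
        text = "".join(coding)
        if strand == "-":
            text = reverse_complement(text)
        seq[start:end] = list(text)
        orfs.append(OrfRecord(gene=f"gene{i:03d}", start=start, end=end, strand=strand))

    # plant sites: in-gene placements go on the host's coding strand inside
    # the design window; intergenic placements use forward-strand gap slots
    truth_rows = []
    used_in_gene: dict[int, list[tuple[int, int]]] = {}
    next_gap_slot = [spec.intergenic_length // 4]  # offset inside each gap
    gap_cursor = 0
    for site_no, planted in enumerate(spec.planted_sites):
        positions = planted.positions
        if positions is None:
            positions = tuple(
                sorted(int(p) for p in rng.choice(20, size=planted.n_mismatches, replace=False))
            )
        mutated = _mutate(planted.spacer, positions, rng) if positions else planted.spacer
        n_base = planted.n_base or str(rng.choice(_BASES))
        site23 = planted.prefix + n_base + mutated

        if planted.host_gene is not None:
            gi = planted.host_gene
            if gi >= spec.n_orfs:
                raise GenerationError(f"host_gene {gi} out of range")
            orf = orfs[gi]
            lo, hi = 3, spec.orf_length - 26  # keep start/stop codons intact
            taken = used_in_gene.setdefault(gi, [])
            offset = None
            for _ in range(200):
                cand = int(rng.integers(lo, hi + 1))
                if all(cand + 23 <= a or cand >= b for a, b in taken):
                    offset = cand
                    break
            if offset is None:
                raise GenerationError(f"no room for planted site in gene {gi}")
            taken.append((offset, offset + 23))
            if orf.strand == "+":
                g0 = orf.start + offset
                seq[g0 : g0 + 23] = list(site23)
                strand = "+"
            else:
                g_first = orf.end - 1 - offset
                g0 = g_first - 22
                seq[g0 : g0 + 23] = list(reverse_complement(site23))
                strand = "-"
            host = orfs[gi].gene
        else:
            # walk gaps between ORFs left to right
            while True:
                gap_start = gap_cursor * unit
                slot = next_gap_slot[0]
                g0 = gap_start + slot
                if g0 + 23 <= gap_start + spec.intergenic_length:
                    next_gap_slot[0] = slot + 30
                    break
                gap_cursor += 1
                next_gap_slot[0] = 4
                if gap_cursor > spec.n_orfs:
                    raise GenerationError("ran out of intergenic room for planted sites")
            seq[g0 : g0 + 23] = list(site23)
            strand = "+"
            host = ""
        truth_rows.append(
            {
                "site_no": site_no,
                "spacer": planted.spacer,
                "prefix": planted.prefix,
                "n_mismatches": planted.n_mismatches,
                "positions": ",".join(str(p) for p in positions),
                "site23": site23,
                "genome_start": g0,
                "strand": strand,
                "host_gene": host,
            }
        )

    genome = GenomeRecord(id=f"synthfix_{spec.seed}", sequence="".join(seq), circular=spec.circular)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "site_no",
            "spacer",
            "prefix",
            "n_mismatches",
            "positions",
            "site23",
            "genome_start",
            "strand",
            "host_gene",
        ],
    )
    return genome, orfs, truth


def write_fixture(
    genome: GenomeRecord, orfs: list[OrfRecord], truth: pd.DataFrame, prefix: str | Path
) -> tuple[Path, Path, Path]:
    """Write FASTA + GFF3 + truth TSV with deterministic bytes."""
    prefix = Path(prefix)
    fasta = prefix.with_suffix(".fasta")
    gff = prefix.with_suffix(".gff3")
    tsv = prefix.with_suffix(".truth.tsv")
    with open(fasta, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, len(genome.sequence), 70):
            fh.write(genome.sequence[i : i + 70] + "\n")
    write_gff3(orfs, gff, seqid=genome.id)
    truth.to_csv(tsv, sep="\t", index=False)
    return fasta, gff, tsv


def make_expression(
    n_genes: int = 4000,
    target_gene: str = "gene0000",
    knockdown_fold: float = 32.0,
    noise_cv: float = 0.2,
    seed: int = 0,
    baseline_median: float = 100.0,
    baseline_sigma: float = 1.0,
) -> pd.DataFrame:
    """Expression table with one knocked-down target under multiplicative noise.

    Baseline abundances are log-normal across genes; the induced abundance is
    the uninduced one times unit-mean log-normal noise of the given CV, with
    the target additionally divided by ``knockdown_fold`` (32, matching a
    strong chromosomal knockdown; fold 1 makes the target a null gene).
    """
    if knockdown_fold < 1:
        raise ValueError("knockdown_fold must be >= 1")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:04d}" for i in range(n_genes)]
    if target_gene not in genes:
        raise ValueError(f"target {target_gene!r} not among generated genes")
    uninduced = rng.lognormal(mean=np.log(baseline_median), sigma=baseline_sigma, size=n_genes)
    sigma_n = np.sqrt(np.log1p(noise_cv**2))
    noise = rng.lognormal(mean=-sigma_n**2 / 2, sigma=sigma_n, size=n_genes)
    induced = uninduced * noise
    induced[genes.index(target_gene)] /= knockdown_fold
    table = pd.DataFrame(
        {"gene": genes, "abundance_uninduced": uninduced, "abundance_induced": induced}
    )
    return attach_fold_change(table)


def make_dose_response(
    f_max: float = 100.0,
    x_half: float = 0.03,
    gamma_rate: float = 0.01,
    n_points: int = 12,
    noise_cv: float = 0.0,
    seed: int = 0,
    x_min: float = 0.001,
    x_max: float = 0.1,
) -> pd.DataFrame:
    """Dose-response points from the rising logistic plus multiplicative noise.

    Concentrations span two decades (default 0.001-0.1 % w/v inducer, the
    linear operating range of the promoter). Zero noise puts the points
    exactly on the closed form.
    """
    if min(f_max, gamma_rate, n_points) <= 0 or x_min <= 0 or x_max <= x_min:
        raise ValueError("parameters must be positive with x_max > x_min")
    rng = np.random.default_rng(seed)
    x = np.geomspace(x_min, x_max, n_points)
    y = f_max / (1.0 + np.exp(-(x - x_half) / gamma_rate))
    if noise_cv > 0:
        sigma_n = np.sqrt(np.log1p(noise_cv**2))
        y = y * rng.lognormal(mean=-sigma_n**2 / 2, sigma=sigma_n, size=n_points)
    return pd.DataFrame({"concentration": x, "signal": y})
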