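# tcrispri

Guide design, genome-wide specificity screening and recombineering-oligo
construction for **tunable, plasmid-free CRISPRi (tCRISPRi)** in bacteria,
plus the off-target audit and descriptive model fits that accompany such a
screen.

In a tCRISPRi strain, dCas9 sits on the chromosome under an
arabinose-tunable P_BAD promoter, and converting the generic strain into a
gene-specific knockdown strain takes a single 90-nt oligo recombined into an
sgRNA cassette. Designing that oligo for a gene requires (i) a validated open
reading frame, (ii) a 20-nt spacer near the start codon whose genomic site is
unique enough to avoid off-target silencing, and (iii) the oligo sequence
itself. This package implements that computation end to end for anyone
building single knockdown strains or whole sgRNA libraries.

## What it computes

**ORF screen.** Every annotated coding region is checked for a canonical
start codon (NTG: ATG/GTG/TTG/CTG) and stop codon (TAG/TGA/TAA) on its
coding strand; failures are classified and counted.

**Candidate enumeration.** For SpCas9 the PAM is N-G-G on the non-target
strand, which reads as a CC-prefixed site 5'-CC-N-[20-nt protospacer]-3' on
the scanned strand. Candidates are all CC-prefixed 23-mers whose first base
lies within 150 nt of the start codon (configurable; both-strand scanning
optional).

**Tiered off-target profile.** Binding specificity is dominated by the
PAM-proximal end of the spacer, so each candidate is scored at three exact
lengths via canonical k-mer counts of the genome — the 10-mer (CC + N +
region I, the PAM-proximal 7 nt), the 15-mer (CC + N + regions I+II, 12 nt)
and the full 23-mer — each also queried with the weak near-PAM prefixes CT
and TC. A windowed scan of both genome strands then counts sites at exactly
1, 2, 3 or 4 mismatches over the 20-mer ("outside the PAM": the leading
dinucleotide must match {CC, CT, TC} exactly and the free N is never a
mismatch). A canonical k-mer is min(k-mer, reverse complement), so one count
covers both strands of a double-stranded site.

**Filter and rank.** Candidates with any exact genomic duplicate or any
1-/2-mismatch match are removed; survivors are ranked by ascending total
region-I abundance (ties: smaller offset). The least-abundant region-I
sequence per gene is reported alongside.

**Oligo construction.** `homology5 (35 nt) + spacer (20 nt) + homology3
(35 nt)` = 90 nt, one oligo per qualifying gene. The arms are
cassette-specific and must be supplied.

**Expression audit.** Given per-gene uninduced/induced abundances
(RPKM-like), the package rebuilds candidate off-target gene subsets from the
genome (region-I exact; regions I+II with ≤2 mismatches; exactly 3 or 4
mismatches over the 20-mer), compares each subset's log2 fold-change
distribution to the global one (two-sample Kolmogorov–Smirnov), ranks the
on-target gene within its subset, and tests for a Hamming-distance /
repression relationship (Spearman).

**Model fits.** Dose-response curves are fitted with the rising logistic
f(x) = f_max / (1 + exp(−(x − x_half)/γ)); per-cell fluorescence
distributions with a maximum-likelihood two-parameter gamma (predicted
CV = 1/√shape); post-washout dilution with a log-linear exponential decay.

## Worked example

Generate a small seeded fixture genome, design guides, build oligos:

```
$ tcrispri fixtures genome --seed 11 --out demo --n-orfs 4 --n-invalid 1 --genome-length 4000
wrote demo.fasta, demo.gff3, demo.truth.tsv

$ tcrispri design --genome demo.fasta --annotations demo.gff3 --out design.tsv
ORFs: 4 read, 3 valid, 3 with a qualifying sgRNA
```

`design.tsv` has one row per gene (provenance header elided):

```
gene     start end  strand validation   n_candidates n_retained status       selected_site23          selected_offset spacer               least_region1_site10 ...
gene000  150   450  +      failed_start 0            0          failed_start
gene001  600   900  -      valid        14           14         ok           CCGCGAACTTAACTGGGCATATT  28              AATATGCCCAGTTAAGTTCG CCGCGAACTT           ...
```

gene000 failed the start-codon screen (planted by the fixture); gene001's
selected guide is the CC-prefixed 23-mer at offset 28 from its start codon,
with its profile counts (region-I/II abundances, exact and mismatch tiers)
in the remaining columns. The `spacer` column is the reverse complement of
the protospacer, the orientation handed to the oligo builder:

```
$ tcrispri oligos --design design.tsv --arms arms.fasta --out oligos.fasta
wrote 3 oligos to oligos.fasta

$ head -2 oligos.fasta
>gene001_tCRISPRi_oligo
AAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAATATGCCCAGTTAAGTTCGTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTT
```

(placeholder A/T arms; real arms are the 35-nt flanks of your cassette
locus). Every oligo is exactly 90 nt with the spacer at positions 36–55.

The same library surface is importable directly
(`from tcrispri import design_genome, off_target_profile, ...`); the CLI
subcommands `index`, `profile`, `rnaseq-audit`, `fit` and `fixtures` cover
k-mer index dumps, single-site profiling, the expression audit and the model
fits.

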