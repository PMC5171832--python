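# Methods

This note records the models and procedures the package implements, the
conventions adopted where more than one was defensible, and what the
synthetic fixtures do and do not establish about real data.

## ORF validation

A coding sequence passes the screen when its first codon is one of
ATG/GTG/TTG/CTG (the NTG starts used by bacterial ribosomes) and its last
codon is TAG/TGA/TAA. Nothing else is required: in particular a length not
divisible by 3 is logged as a warning, not a failure, since frame errors are
an annotation-quality signal distinct from the screen's question. Sequences
under 6 nt are `too_short`; when both ends fail, `failed_start` is reported
(the aggregate "failed" count is unaffected by this precedence). A codon
containing N fails its membership test — conservative, since an ambiguous
base cannot be confirmed. Compound (`join`) locations are skipped with a
warning: a multi-part CDS has no single coding-strand window to scan.

Internally all coordinates are 0-based half-open; GenBank and GFF3 (1-based
inclusive) are converted at the file boundary. Circular genomes allow
features and scan windows to wrap the origin.

## Site frame and region arithmetic

All matching is done in the genomic CC-prefixed frame: a site is the 23-mer
5'-CC-N-[20-nt protospacer]-3' on the scanned strand (the reverse-complement
view of the N-G-G PAM). Region I is the PAM-proximal 7 nt of the
protospacer and regions I+II its PAM-proximal 12 nt, which makes the three
screen lengths 10 = 2+1+7, 15 = 2+1+12 and 23 = 2+1+20 — the only
decomposition under which the three k-mer lengths are prefixes of one
another in a single coordinate frame.

"Mismatches outside the PAM" means: positions 1–2 must be CC (or the weak
variants CT/TC), position 3 (the PAM N) is free and never counted, and
mismatches are counted over the 20-nt protospacer only.

The candidate's own genomic site is included in the exact-23 count (a unique
guide has `n_exact23 = 1`) and is excluded from mismatch tiers by
construction (its distance is 0). The removal rule is therefore
`n_exact23 > 1 or n_mm1 > 0 or n_mm2 > 0`. The 10/15-mer near-PAM abundances
are reported and used for ranking, not removal: ranking is by ascending
total region-I abundance (CC + CT/TC), ties broken by ascending offset, so
the output order is a total order independent of input order.

## Enumeration window

The 150-nt positional limit (default `window_nt`) bounds the 0-based
coding-strand offset of the site's first (CC) base from the A of the start
codon. The site may run past the ORF's 3' end into downstream sequence — the
window constrains where repression initiates, not where the site ends. The
default scans the coding strand only; `scan_both_strands` adds the template
strand (CRISPRi efficacy is strand-dependent, so the choice is recorded in
output metadata). Sites containing N are skipped.

## Canonical k-mer counting

The index slides a window over the forward strand (wrapping k−1 positions on
circular genomes), skips windows containing N, and counts the lexicographic
minimum of each window and its reverse complement. A count is therefore the
number of double-stranded genomic sites matching the query on either strand,
with reverse-complement palindromes counted once per site. Exact tiers are
index lookups; mismatch tiers are vectorised scans of both strands, since a
canonical hash cannot answer Hamming-ball queries. The scan cost is
O(genome × candidates); at the bacterial-genome scale used here this is the
dominant cost of `design_genome`, and whole-genome runs on multi-megabase
references should pre-build indices once (`indices=` argument, `index` CLI).

## Expression audit

Fold change is log2(induced/uninduced), defined only when both abundances
are positive; the pseudocount default is 0 so zero-abundance genes are
flagged and excluded rather than silently offset. A gene joins an off-target
tier if any 23-nt window within its annotated extent, on either strand,
meets the tier's prefix + mismatch condition; tiers are not mutually
exclusive, gene flanks/promoters are not searched, and each membership keeps
the minimum-distance site. The subset-vs-global comparison is a two-sided
two-sample Kolmogorov–Smirnov test on log2 fold changes with no
multiple-testing correction (Mann–Whitney available as an option); the
distribution-comparison test is a package design choice among standard
options. On-target rank sorts the subset by ascending fold change with ties
sharing the better rank. The distance/repression association is a Spearman
rank correlation over members with defined fold change, reported as
not-testable below 3 members or for constant inputs.

## Model fits

Dose-response: f(x) = f_max / (1 + exp(−(x − x_half)/γ)), fitted by
Levenberg–Marquardt least squares. Initialisation is data-driven
(f_max = max signal, x_half = concentration nearest half-max, γ = a tenth of
the concentration span) and deterministic. The two sign conventions of the
exponent differ only by γ → −γ; fits are normalised to γ > 0 in the declared
convention, and a falling variant is available by flag. An all-zero signal
short-circuits to f_max = 0. Units: x in % w/v inducer, f in arbitrary
signal units, γ in concentration units.

Per-cell fluorescence: two-parameter gamma by maximum likelihood with
location fixed at 0 (scipy's MLE), requiring ≥ 50 strictly positive values
with non-zero variance; the predicted coefficient of variation is 1/√shape
(shape 25 ⇒ CV 0.2, the regime of a well-behaved graded promoter).

Dilution decay: least-squares slope of log signal vs time;
half-time = ln 2 / rate, infinite for a flat signal. With growth-limited
dilution the half-time equals the culture doubling time.

## Synthetic fixtures

`make_genome` lays ORFs left to right on alternating strands with random
ACGT background, canonical start/stop codons, a controllable number of
deliberately invalid ORFs (violating exactly one rule each), and planted
guide sites with exact mismatch structure (mismatch positions are indices
into the 20-mer, hence always outside the PAM; the free N can be pinned for
exact-duplicate planting). `make_expression` draws log-normal baselines
(median 100, log-sd 1.0 — a realistic RPKM spread), applies unit-mean
log-normal noise of CV 0.2 to the induced channel, and divides the target by
the knockdown fold (default 32, a strong chromosomal knockdown).
`make_dose_response` spans 0.001–0.1 % inducer, two decades, the graded
operating range of the tunable promoter. All randomness flows from one
explicit seed per call; identical seeds give byte-identical files. Callers
planting sites should draw spacers from a stream independent of the genome
seed, since the background replays the generator's stream.

What the fixtures do **not** emulate: real codon usage, GC content, operon
structure and co-regulation (so expression noise is independent across
genes, unlike a real regulon), repeat families, or annotation errors other
than the planted codon violations. Passing tests establish the correctness
of the counting, filtering, statistics and fits under the stated model — not
knockdown efficacy or the biological specificity of any particular guide.

## Problem sizes and numerical choices

Tests and the acceptance script run on genomes of 0.2–6 kb, 4–9 ORFs, 4000
gene expression tables, 1000-replicate null calibrations and 200-replicate
rank simulations — sizes at which the brute-force oracles (naive
double-strand scans, position-by-position k-mer counting) are exact and
cheap, so every tier count can be checked for equality rather than
approximately. Filtering, ranking and tie-breaks are exact integer
comparisons with no tolerances; the only numerical tolerances in the package
are those of the least-squares and MLE fits.

## Known limitations

No on-target efficacy scoring (thermodynamics or learned models), no
CRISPRi polarity/operon modelling, no ambiguity-aware (IUPAC) matching, no
multi-guide pooling. The mismatch scan is linear per candidate rather than
indexed. GFF3 parsing covers single-line CDS features with standard
attributes; richly structured GFF3 (phases across joined parts, feature
hierarchies) is out of scope.
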