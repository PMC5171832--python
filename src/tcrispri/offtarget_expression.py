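"""Expression-table audit of potential off-target genes.

Given a per-gene expression table from paired uninduced/induced cultures
(RPKM-like units) and an sgRNA spacer, this module rebuilds the candidate
off-target gene subsets directly from the genome — tiered by PAM-proximal
match stringency — and asks whether their fold-change distributions differ
from the global distribution, where the on-target gene ranks among them, and
whether mismatch count predicts repression.

Tiers, from most to least stringent evidence of binding:

- ``region1_exact``: genes carrying a PAM dinucleotide (CC, or the weak
  CT/TC variants) followed by an exact match to the PAM-proximal 7 nt
  (region I) of the sgRNA;
- ``region12_le2mm``: same PAM dinucleotides with at most 2 mismatches over
  the PAM-proximal 12 nt (regions I + II);
- ``mm3`` / ``mm4``: PAM-prefixed sites with exactly 3 or 4 mismatches over
  the entire 20-nt protospacer.

Tiers are not mutually exclusive; each membership records the matched site
and its Hamming distance to the spacer over the 20-mer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from tcrispri.genome_io import GenomeRecord, OrfRecord, reverse_complement
from tcrispri.guide_design import DesignParams, hamming

TIERS = ("region1_exact", "region12_le2mm", "mm3", "mm4")

_PAM_SET = ("CC", "CT", "TC")


class ExpressionFormatError(ValueError):
    """Raised on malformed expression tables (e.g. duplicate genes)."""


def load_expression(path: str | Path) -> pd.DataFrame:
    """Load a TSV of (gene, abundance_uninduced, abundance_induced).

    Adds a ``log2_fc`` column, defined only where both abundances are > 0;
    zero-abundance genes are retained with log2_fc = NaN and flagged in the
    boolean ``fc_defined`` column. Duplicate gene names are rejected.
    """
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] < 3:
        raise ExpressionFormatError("expected columns: gene, uninduced, induced")
    table = table.rename(
        columns=dict(zip(table.columns[:3], ["gene", "abundance_uninduced", "abundance_induced"]))
    )
    if table["gene"].duplicated().any():
        dupes = table.loc[table["gene"].duplicated(), "gene"].tolist()
        raise ExpressionFormatError(f"duplicate gene names: {dupes}")
    return attach_fold_change(table)


def attach_fold_change(table: pd.DataFrame, pseudocount: float = 0.0) -> pd.DataFrame:
    """Compute log2 fold change induced/uninduced with an optional pseudocount.

    With the default pseudocount of 0, genes with a zero abundance get an
    undefined (NaN) fold change and are excluded from the statistics rather
    than silently offset.
    """
    table = table.copy()
    u = table["abundance_uninduced"].to_numpy(dtype=float) + pseudocount
    i = table["abundance_induced"].to_numpy(dtype=float) + pseudocount
    defined = (u > 0) & (i > 0)
    fc = np.full(len(table), np.nan)
    fc[defined] = np.log2(i[defined] / u[defined])
    table["log2_fc"] = fc
    table["fc_defined"] = defined
    return table


@dataclass
class SubsetMember:
    gene: str
    site23: str
    strand: str
    distance20: int  # Hamming distance of the site's 20-mer to the spacer


def _gene_windows(genome: GenomeRecord, orf: OrfRecord):
    """Yield (site23, strand) for every 23-nt window of both strands whose
    footprint lies within the gene's annotated extent."""
    span = genome.fetch(orf.start, orf.end)
    for i in range(len(span) - 22):
        w = span[i : i + 23]
        if "N" not in w:
            yield w, "+"
        wr = reverse_complement(w)
        if "N" not in wr:
            yield wr, "-"


def build_subsets(
    spacer: str,
    genome: GenomeRecord,
    annotations: list[OrfRecord],
    params: DesignParams | None = None,
) -> dict[str, list[SubsetMember]]:
    """Assign genes to off-target candidate tiers for one 20-nt spacer.

    A gene joins a tier if any 23-nt window within its annotated extent, on
    either strand, starts with a PAM dinucleotide in {CC, CT, TC} and meets
    the tier's mismatch condition against the spacer. Each gene appears at
    most once per tier, recording its best (minimum-distance) matching site.
    """
    if len(spacer) != 20:
        raise ValueError(f"spacer must be 20 nt, got {len(spacer)}")
    params = params or DesignParams()
    r1, r12 = params.region1_len, params.region12_len
    subsets: dict[str, dict[str, SubsetMember]] = {t: {} for t in TIERS}
    for orf in annotations:
        for site, strand in _gene_windows(genome, orf):
            if site[:2] not in _PAM_SET:
                continue
            proto = site[3:]
            d20 = hamming(proto, spacer)
            hits = []
            if proto[:r1] == spacer[:r1]:
                hits.append("region1_exact")
            if hamming(proto[:r12], spacer[:r12]) <= params.max_outside_pam_mm:
                hits.append("region12_le2mm")
            if d20 == 3:
                hits.append("mm3")
            if d20 == 4:
                hits.append("mm4")
            for tier in hits:
                prev = subsets[tier].get(orf.gene)
                if prev is None or d20 < prev.distance20:
                    subsets[tier][orf.gene] = SubsetMember(
                        gene=orf.gene, site23=site, strand=strand, distance20=d20
                    )
    return {t: list(members.values()) for t, members in subsets.items()}


def compare_to_global(
    table: pd.DataFrame, subset: list[str], test: str = "ks"
) -> tuple[float, float] | None:
    """Two-sample test of subset log2 fold changes against all genes.

    Kolmogorov-Smirnov by default (``test="mannwhitney"`` for the rank-sum
    alternative), two-sided, no multiple-testing correction. Genes with
    undefined fold change are excluded. Returns (statistic, p_value), or
    None when the subset has no testable members.
    """
    defined = table[table["fc_defined"]]
    global_fc = defined["log2_fc"].to_numpy()
    sub_fc = defined.loc[defined["gene"].isin(set(subset)), "log2_fc"].to_numpy()
    if sub_fc.size == 0:
        return None
    if test == "ks":
        res = stats.ks_2samp(sub_fc, global_fc, alternative="two-sided")
    elif test == "mannwhitney":
        res = stats.mannwhitneyu(sub_fc, global_fc, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def on_target_rank(table: pd.DataFrame, subset: list[str], target_gene: str) -> int:
    """Rank of the target among subset genes sorted by ascending log2 FC.

    Rank 1 = most repressed. Ties share the better (smaller) rank: the rank
    is 1 plus the number of subset genes strictly more repressed.
    """
    if target_gene not in set(subset):
        raise ValueError(f"target gene {target_gene!r} not in subset")
    sub = table[table["gene"].isin(set(subset)) & table["fc_defined"]]
    target_rows = sub[sub["gene"] == target_gene]
    if target_rows.empty:
        raise ValueError(f"target gene {target_gene!r} has undefined fold change")
    target_fc = float(target_rows["log2_fc"].iloc[0])
    return 1 + int((sub["log2_fc"] < target_fc).sum())


def hamming_vs_repression(
    table: pd.DataFrame, members: list[SubsetMember]
) -> tuple[float, float] | None:
    """Spearman correlation between match distance and repression.

    Correlates each member gene's minimal Hamming distance (over the 20-mer)
    with its log2 fold change. Returns (rho, p_value); None when fewer than
    3 members have a defined fold change or the inputs are degenerate
    (constant fold change or constant distance).
    """
    by_gene = {m.gene: m.distance20 for m in members}
    sub = table[table["gene"].isin(by_gene) & table["fc_defined"]]
    if len(sub) < 3:
        return None
    distances = sub["gene"].map(by_gene).to_numpy(dtype=float)
    fcs = sub["log2_fc"].to_numpy()
    if np.ptp(fcs) == 0 or np.ptp(distances) == 0:
        return None
    rho, p = stats.spearmanr(distances, fcs)
    if np.isnan(rho):
        return None
    return float(rho), float(p)


def audit_report(
    spacer: str,
    target_gene: str | None,
    table: pd.DataFrame,
    subsets: dict[str, list[SubsetMember]],
) -> pd.DataFrame:
    """Summary statistics per tier: size, KS statistic and p, on-target rank."""
    rows = []
    for tier in TIERS:
        members = subsets[tier]
        genes = [m.gene for m in members]
        row: dict = {"tier": tier, "n_members": len(genes)}
        result = compare_to_global(table, genes) if genes else None
        row["ks_statistic"], row["ks_p"] = result if result else (np.nan, np.nan)
        if target_gene is not None and target_gene in genes:
            row["on_target_rank"] = on_target_rank(table, genes, target_gene)
        else:
            row["on_target_rank"] = pd.NA
        rows.append(row)
    return pd.DataFrame(rows)
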