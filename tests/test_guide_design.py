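"""Candidate enumeration, tiered off-target profiling, filtering and ranking."""

import numpy as np
import pytest

from _oracles import oracle_profile, rc
from conftest import random_seq
from tcrispri import (
    DesignParams,
    GenomeRecord,
    GuideCandidate,
    OffTargetProfile,
    OrfRecord,
    Validation,
    build_index,
    design_genome,
    enumerate_candidates,
    filter_and_rank,
    hamming,
    least_abundant_region1,
    off_target_profile,
)
from tcrispri.synthetic import FixtureSpec, PlantedSite, make_genome, random_spacer


def indices_for(genome):
    return {k: build_index(genome, k) for k in (10, 15, 23)}


class TestHamming:
    @pytest.mark.parametrize(
        "a,b,d", [("AAAA", "AAAT", 1), ("ACGT", "ACGT", 0), ("AAAA", "TTTT", 4)]
    )
    def test_examples(self, a, b, d):
        assert hamming(a, b) == d

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            hamming("AAA", "AAAA")


def _orf_with_cc_at(offsets, length=63, flank=40):
    """A genome whose single + ORF has CC exactly at the given coding offsets."""
    coding = list("A" * length)
    coding[:3] = "ATG"
    coding[-3:] = "TAA"
    for off in offsets:
        coding[off : off + 2] = "CC"
    genome = GenomeRecord("g", "".join(coding) + "G" * flank)
    orf = OrfRecord("g1", 0, length, "+", Validation.VALID)
    return genome, orf


class TestEnumerateCandidates:
    def test_finds_exactly_the_cc_offsets(self):
        genome, orf = _orf_with_cc_at([5, 40])
        cands = enumerate_candidates(genome, orf)
        assert [c.offset_nt for c in cands] == [5, 40]
        assert all(c.site23.startswith("CC") for c in cands)
        assert all(c.site23 == genome.sequence[c.offset_nt : c.offset_nt + 23] for c in cands)

    def test_positional_window_limit_excludes(self):
        genome, orf = _orf_with_cc_at([5, 40])
        cands = enumerate_candidates(genome, orf, DesignParams(window_nt=30))
        assert [c.offset_nt for c in cands] == [5]

    def test_no_cc_gives_empty_list(self):
        genome, orf = _orf_with_cc_at([])
        assert enumerate_candidates(genome, orf) == []

    def test_unvalidated_orf_rejected(self):
        genome, orf = _orf_with_cc_at([5])
        orf.validation = Validation.UNSET
        with pytest.raises(ValueError):
            enumerate_candidates(genome, orf)

    def test_site_may_cross_orf_3prime_boundary(self):
        # CC at offset 55 of a 63-nt ORF: the 23-mer runs past the stop codon
        genome, orf = _orf_with_cc_at([55])
        cands = enumerate_candidates(genome, orf)
        assert [c.offset_nt for c in cands] == [55]
        assert cands[0].site23 == genome.sequence[55:78]

    def test_site_not_fitting_in_linear_genome_skipped(self):
        genome, orf = _orf_with_cc_at([55], flank=10)  # 63+10 < 55+23
        assert enumerate_candidates(genome, orf) == []

    def test_minus_strand_orf_scanned_on_coding_strand(self):
        coding = list("A" * 63)
        coding[:3] = "ATG"
        coding[-3:] = "TAA"
        coding[10:12] = "CC"
        fwd = "T" * 40 + rc("".join(coding)) + "T" * 5
        genome = GenomeRecord("g", fwd)
        orf = OrfRecord("g1", 40, 40 + 63, "-", Validation.VALID)
        cands = enumerate_candidates(genome, orf)
        assert [c.offset_nt for c in cands] == [10]
        assert cands[0].site23.startswith("CC")
        assert cands[0].genome_strand == "-"
        # the site reads on the reverse strand of the stored genome
        left = cands[0].genome_start
        assert rc(genome.sequence[left : left + 23]) == cands[0].site23

    def test_region_decomposition(self):
        genome, orf = _orf_with_cc_at([5])
        (cand,) = enumerate_candidates(genome, orf)
        assert cand.pam3 == cand.site23[:3]
        assert cand.region1 + cand.region2 == cand.protospacer20[:12]
        assert len(cand.region1) == 7 and len(cand.region2) == 5
        assert cand.region1_site10 == cand.site23[:10]
        assert cand.spacer_for_cassette() == rc(cand.protospacer20)
        assert cand.spacer_for_cassette(emit_reverse_complement=False) == cand.protospacer20


class TestOffTargetProfile:
    def test_planted_exact_duplicate_doubles_exact_count(self, rng):
        spacer = random_spacer(rng)
        spec = FixtureSpec(
            seed=42,
            planted_sites=(
                PlantedSite(spacer, "CC", 0, host_gene=0, n_base="G"),
                PlantedSite(spacer, "CC", 0, host_gene=None, n_base="G"),
            ),
        )
        genome, orfs, truth = make_genome(spec)
        from tcrispri.genome_io import validate_all

        validate_all(genome, orfs)
        cands = enumerate_candidates(genome, orfs[0], DesignParams(window_nt=300))
        cand = next(c for c in cands if c.site23 in set(truth["site23"]))
        prof = off_target_profile(cand, genome, indices_for(genome))
        assert prof.n_exact23 == 2

    def test_single_mismatch_lands_in_tier_one(self, rng):
        spacer = random_spacer(rng)
        spec = FixtureSpec(
            seed=43,
            planted_sites=(
                PlantedSite(spacer, "CC", 0, host_gene=0),
                PlantedSite(spacer, "CC", 1, positions=(9,), host_gene=None),
            ),
        )
        genome, orfs, truth = make_genome(spec)
        cand = GuideCandidate(
            gene="gene000",
            offset_nt=0,
            site23=truth.loc[0, "site23"],
            genome_start=int(truth.loc[0, "genome_start"]),
            genome_strand=truth.loc[0, "strand"],
        )
        prof = off_target_profile(cand, genome, indices_for(genome))
        assert prof.n_mm1 == 1
        assert prof.n_mm2 == 0

    def test_ct_prefixed_region1_match_counts_as_near_pam(self, rng):
        spacer = random_spacer(rng)
        spec = FixtureSpec(
            seed=44,
            planted_sites=(
                PlantedSite(spacer, "CC", 0, host_gene=0, n_base="G"),
                PlantedSite(spacer, "CT", 0, host_gene=None, n_base="G"),
            ),
        )
        genome, orfs, truth = make_genome(spec)
        cand = GuideCandidate(
            gene="gene000",
            offset_nt=0,
            site23=truth.loc[0, "site23"],
            genome_start=int(truth.loc[0, "genome_start"]),
            genome_strand=truth.loc[0, "strand"],
        )
        prof = off_target_profile(cand, genome, indices_for(genome))
        oracle = oracle_profile(cand.site23, genome.sequence)
        assert prof.n_region1_nearpam == oracle["n_region1_nearpam"] >= 1

    def test_missing_index_rejected(self, rng):
        genome, orf = _orf_with_cc_at([5])
        (cand,) = enumerate_candidates(genome, orf)
        with pytest.raises(ValueError):
            off_target_profile(cand, genome, {10: build_index(genome, 10)})

    def test_matches_brute_force_oracle_on_random_genomes(self, rng):
        for trial in range(5):
            seq = random_seq(rng, 1500)
            genome = GenomeRecord(f"g{trial}", seq)
            indices = indices_for(genome)
            # take real CC sites from the genome as candidates
            cc_positions = [i for i in range(len(seq) - 23) if seq[i : i + 2] == "CC"][:4]
            for pos in cc_positions:
                cand = GuideCandidate(
                    gene="x", offset_nt=0, site23=seq[pos : pos + 23],
                    genome_start=pos, genome_strand="+",
                )
                prof = off_target_profile(cand, genome, indices)
                assert prof.as_dict() == oracle_profile(cand.site23, seq)

    def test_prefix_nesting_invariant(self, rng):
        seq = random_seq(rng, 2000)
        genome = GenomeRecord("g", seq)
        indices = indices_for(genome)
        for pos in [i for i in range(len(seq) - 23) if seq[i : i + 2] == "CC"][:8]:
            cand = GuideCandidate(
                gene="x", offset_nt=0, site23=seq[pos : pos + 23],
                genome_start=pos, genome_strand="+",
            )
            prof = off_target_profile(cand, genome, indices)
            assert prof.n_region1_cc >= prof.n_region12_cc >= prof.n_exact23 >= 1


def _cand(offset, site23=None):
    site = site23 or ("CCA" + "A" * 20)
    return GuideCandidate(
        gene="g", offset_nt=offset, site23=site, genome_start=offset, genome_strand="+"
    )


def _prof(**kw):
    prof = OffTargetProfile(n_exact23=1)
    for key, value in kw.items():
        setattr(prof, key, value)
    return prof


class TestFilterAndRank:
    def test_exact_duplicate_removed(self):
        out = filter_and_rank([_cand(0)], [_prof(n_exact23=2)])
        assert out == []

    @pytest.mark.parametrize("field", ["n_mm1", "n_mm2"])
    def test_near_matches_removed(self, field):
        assert filter_and_rank([_cand(0)], [_prof(**{field: 1})]) == []

    def test_sorted_by_region1_total_ascending(self):
        cands = [_cand(0), _cand(10)]
        profs = [_prof(n_region1_cc=3), _prof(n_region1_cc=1)]
        out = filter_and_rank(cands, profs)
        assert [c.offset_nt for c, _ in out] == [10, 0]

    def test_near_pam_counts_included_in_rank_key(self):
        cands = [_cand(0), _cand(10)]
        profs = [_prof(n_region1_cc=1, n_region1_nearpam=5), _prof(n_region1_cc=2)]
        out = filter_and_rank(cands, profs)
        assert [c.offset_nt for c, _ in out] == [10, 0]

    def test_tie_broken_by_offset(self):
        cands = [_cand(20), _cand(5)]
        profs = [_prof(n_region1_cc=2), _prof(n_region1_cc=2)]
        out = filter_and_rank(cands, profs)
        assert [c.offset_nt for c, _ in out] == [5, 20]

    def test_order_invariant_under_permutation(self):
        cands = [_cand(o) for o in (3, 17, 8, 29)]
        profs = [_prof(n_region1_cc=n) for n in (4, 1, 4, 2)]
        ref = filter_and_rank(cands, profs)
        perm = [2, 0, 3, 1]
        out = filter_and_rank([cands[i] for i in perm], [profs[i] for i in perm])
        assert [c.offset_nt for c, _ in out] == [c.offset_nt for c, _ in ref]

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            filter_and_rank([_cand(0)], [])


class TestLeastAbundantRegion1:
    def test_minimum_selected(self):
        cands = [_cand(0), _cand(5), _cand(9)]
        profs = [_prof(n_region1_cc=4), _prof(n_region1_cc=2), _prof(n_region1_cc=9)]
        site10, count = least_abundant_region1(cands, profs)
        assert count == 2
        assert site10 == cands[1].region1_site10

    def test_single_candidate(self):
        site10, count = least_abundant_region1([_cand(0)], [_prof(n_region1_cc=7)])
        assert count == 7

    def test_tie_smaller_offset_wins(self):
        cands = [_cand(12), _cand(3)]
        profs = [_prof(n_region1_cc=2), _prof(n_region1_cc=2)]
        site10, _ = least_abundant_region1(cands, profs)
        assert site10 == cands[1].region1_site10

    def test_empty_reported_absent(self):
        assert least_abundant_region1([], []) is None


class TestDesignGenome:
    def test_failed_orfs_flagged_in_table(self):
        genome, orfs, _ = make_genome(
            FixtureSpec(seed=5, n_orfs=4, n_invalid_orfs=1, genome_length=4000)
        )
        table = design_genome(genome, orfs)
        assert len(table) == 4
        assert (table["validation"] != "valid").sum() == 1
        failed = table[table["validation"] != "valid"].iloc[0]
        assert failed["status"] == "failed_start"

    def test_gene_with_only_duplicated_candidate_flagged(self):
        # a short gene whose single CC site also exists verbatim elsewhere
        site = "CCG" + "GATAGATAGATAGATAGATA"  # no internal CC
        coding = list("ATG" + "A" * 57)
        coding[-3:] = "TAA"
        coding[5 : 5 + 23] = site
        genome = GenomeRecord("g", "".join(coding) + "T" * 40 + site + "T" * 10)
        orf = OrfRecord("solo", 0, 60, "+")
        table = design_genome(genome, [orf])
        assert table.loc[0, "status"] == "no qualifying sgRNA"
        assert table.loc[0, "n_candidates"] >= 1
        assert table.loc[0, "n_retained"] == 0

    def test_two_runs_identical(self):
        genome, orfs, _ = make_genome(FixtureSpec(seed=6, n_orfs=4, genome_length=4000))
        t1 = design_genome(genome, orfs)
        t2 = design_genome(genome, orfs)
        assert t1.to_csv() == t2.to_csv()


def test_appending_exact_copy_removes_retained_candidate(rng):
    """Monotone filtering: duplicating a retained site forces its removal."""
    genome, orfs, _ = make_genome(FixtureSpec(seed=9, n_orfs=3, genome_length=3500))
    table = design_genome(genome, orfs)
    ok = table[table["status"] == "ok"]
    assert not ok.empty
    row = ok.iloc[0]
    extended = GenomeRecord("g2", genome.sequence + "T" * 30 + row["selected_site23"] + "T" * 5)
    table2 = design_genome(extended, orfs)
    row2 = table2[table2["gene"] == row["gene"]].iloc[0]
    assert row2["selected_site23"] != row["selected_site23"]
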