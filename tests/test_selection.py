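"""Degenerate-base selection: profiles, optimality, soundness."""

import numpy as np
import pytest

from croma.selection import (
    build_mismatch_profile,
    best_design_for_site,
    design_option_candidate,
    exhaustive_coverage,
    select_degenerate_bases,
    verify_coverage,
)
from croma.fixtures import random_site_alignment
from croma.probe_model import DegenerateBase, ProbeDesignOption, ProbeType

from conftest import make_site

T2F = ProbeDesignOption(ProbeType.II, "+")
T2R = ProbeDesignOption(ProbeType.II, "-")


class TestMismatchProfile:
    def test_all_identical_species_all_feasible(self):
        sa = make_site("ACGTACGTAA", {"a": "ACGTACGTAA", "b": "ACGTACGTAA"})
        prof = build_mismatch_profile(sa, M=3)
        assert prof.feasible == {"a", "b"}
        assert not prof.position_multiset

    def test_single_substitution_counts_one_mismatch(self):
        sa = make_site("ACGTACGTAA", {"a": "ACTTACGTAA"})
        prof = build_mismatch_profile(sa, M=3)
        assert prof.feasible == {"a"}
        assert prof.mismatches["a"] == [(2, "T")]
        assert prof.position_multiset == {2: 1}

    def test_gap_column_makes_species_infeasible(self):
        # no substitution-only degenerate set can cover a gapped species
        sa = make_site("ACGTACGTAA", {"a": "AC-TACGTAA"})
        prof = build_mismatch_profile(sa, M=3)
        assert prof.feasible == set()
        assert prof.infeasible_reason["a"] == "gap_or_unaligned"

    def test_unaligned_and_insertion_and_lost_cpg_are_infeasible(self):
        sa = make_site(
            "ACGTACGTAA",
            {"u": ".CGTACGTAA", "i": "ACGTACGTAA", "c": "ACGTACGTAATG"},
            insertion={"i": True})
        prof = build_mismatch_profile(sa, M=3)
        assert prof.feasible == set()
        assert prof.infeasible_reason == {
            "u": "gap_or_unaligned", "i": "insertion", "c": "cpg_not_conserved"}

    def test_too_many_mismatches_excluded_by_budget(self):
        sa = make_site("AAAAAAAAAA", {"a": "TTAAAAAAAA"})
        assert "a" in build_mismatch_profile(sa, M=2).feasible
        assert "a" not in build_mismatch_profile(sa, M=1).feasible

    def test_bisulfite_collapsed_mode_forgives_non_cpg_c_t(self):
        # reference C at offset 0 (not CpG) vs species T: identical after
        # conversion, a real mismatch in strict genomic space
        sa = make_site("CAAAACGTAA", {"a": "TAAAACGTAA"})
        strict = build_mismatch_profile(sa, M=0, comparison="strict")
        collapsed = build_mismatch_profile(sa, M=0,
                                           comparison="bisulfite_collapsed")
        assert "a" not in strict.feasible
        assert "a" in collapsed.feasible


class TestSelection:
    def test_empty_multiset_covers_all_feasible(self):
        sa = make_site("ACGTACGTAA", {"a": "ACGTACGTAA", "b": "ACGTACGTAA"})
        prof = build_mismatch_profile(sa, M=2)
        deg, cov = select_degenerate_bases(prof, 2)
        assert deg == ()
        assert cov == {"ref", "a", "b"}

    def test_shared_mismatch_is_preferred_five_species_case(self):
        # A exact; B and C share offset 2 -> T; D mismatches offset 4;
        # E lacks the CpG.  With M=1 the shared mismatch wins.
        ref = "ACGAACGTAA"
        sa = make_site(ref, {
            "A": ref,
            "B": "ACTAACGTAA",
            "C": "ACTAACGTAA",
            "D": "ACGATCGTAA",
            "E": ref + "CA",
        })
        prof = build_mismatch_profile(sa, M=1)
        deg, cov = select_degenerate_bases(prof, 1)
        assert deg == (DegenerateBase(2, "T"),)
        assert cov == {"ref", "A", "B", "C"}
        # brute force over all single (offset, alternate) choices agrees
        _, best = exhaustive_coverage(prof, 1)
        assert len(best) == 4

    def test_budget_two_covers_both_mismatch_groups(self):
        ref = "ACGAACGTAA"
        sa = make_site(ref, {
            "A": ref,
            "B": "ACTAACGTAA",
            "C": "ACTAACGTAA",
            "D": "ACGATCGTAA",
            "E": ref + "CA",
        })
        prof = build_mismatch_profile(sa, M=2)
        deg, cov = select_degenerate_bases(prof, 2)
        assert set(deg) == {DegenerateBase(2, "T"), DegenerateBase(4, "T")}
        assert cov == {"ref", "A", "B", "C", "D"}
        _, best = exhaustive_coverage(prof, 2)
        assert len(cov) == len(best) == 5

    def test_top_k_alternates_ranked_by_species_count(self):
        # offset 0 carries T in two species and G in one; with one slot
        # at that offset the T alternate must win
        ref = "AAAAACGTAA"
        sa = make_site(ref, {
            "x": "TAAAACGTAA",
            "y": "TAAAACGTAA",
            "z": "GAAAACGTAA",
        })
        prof = build_mismatch_profile(sa, M=1)
        deg, cov = select_degenerate_bases(prof, 1)
        assert deg == (DegenerateBase(0, "T"),)
        assert cov == {"ref", "x", "y"}

    def test_multiplicity_selects_multiple_alternates_at_one_offset(self):
        ref = "AAAAACGTAA"
        sa = make_site(ref, {
            "x": "TAAAACGTAA",
            "y": "GAAAACGTAA",
        })
        prof = build_mismatch_profile(sa, M=2)
        deg, cov = select_degenerate_bases(prof, 2)
        assert set(deg) == {DegenerateBase(0, "G"), DegenerateBase(0, "T")}
        assert cov == {"ref", "x", "y"}


class TestRandomInstances:
    def test_never_beats_exhaustive_and_mostly_matches(self):
        rng = np.random.default_rng(11)
        equal = 0
        n = 200
        for _ in range(n):
            sa = random_site_alignment(rng)
            for M in (1, 2):
                prof = build_mismatch_profile(sa, M)
                deg, cov = select_degenerate_bases(prof, M)
                _, best = exhaustive_coverage(prof, M)
                assert len(cov) <= len(best)
                assert verify_coverage(prof, deg, cov)
            prof = build_mismatch_profile(sa, 2)
            _, cov = select_degenerate_bases(prof, 2)
            _, best = exhaustive_coverage(prof, 2)
            if len(cov) == len(best):
                equal += 1
        assert equal / n >= 0.95

    def test_equality_guaranteed_with_single_alternate_per_offset(self):
        rng = np.random.default_rng(13)
        checked = 0
        for _ in range(300):
            sa = random_site_alignment(rng, n_species=6)
            prof = build_mismatch_profile(sa, 2)
            alts_per_offset = {}
            for s in prof.feasible:
                for off, base in prof.mismatches[s]:
                    alts_per_offset.setdefault(off, set()).add(base)
            if any(len(v) > 1 for v in alts_per_offset.values()):
                continue
            checked += 1
            _, cov = select_degenerate_bases(prof, 2)
            _, best = exhaustive_coverage(prof, 2)
            assert len(cov) == len(best)
        assert checked > 20  # the guarantee was actually exercised

    def test_coverage_monotone_in_budget(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            sa = random_site_alignment(rng)
            prev = -1
            for M in range(4):
                prof = build_mismatch_profile(sa, M)
                _, cov = select_degenerate_bases(prof, M)
                assert len(cov) >= prev
                prev = len(cov)

    def test_selection_is_deterministic(self):
        rng = np.random.default_rng(19)
        for _ in range(50):
            sa = random_site_alignment(rng)
            prof1 = build_mismatch_profile(sa, 2)
            prof2 = build_mismatch_profile(sa, 2)
            assert select_degenerate_bases(prof1, 2) == \
                select_degenerate_bases(prof2, 2)


class TestBestDesignForSite:
    def _candidate(self, option, coverage):
        from croma.selection import ProbeCandidate
        return ProbeCandidate(
            chrom="chrT", site=100, option=option, degenerate_set=(),
            covered_species=frozenset(f"s{i}" for i in range(coverage)),
            budget_M=3)

    def test_higher_coverage_strand_retained(self):
        cands = {T2F: self._candidate(T2F, 9), T2R: self._candidate(T2R, 12)}
        retained = best_design_for_site(cands)
        assert retained[ProbeType.II].option == T2R

    def test_tie_goes_to_forward(self):
        cands = {T2F: self._candidate(T2F, 7), T2R: self._candidate(T2R, 7)}
        retained = best_design_for_site(cands)
        assert retained[ProbeType.II].option == T2F

    def test_empty_input_gives_empty_result(self):
        assert best_design_for_site({}) == {}

    def test_fixture_truth_exhaustive_coverage_reproduced(self, bundle):
        """The full pipeline's coverages equal the brute-force optima
        recorded in the fixture sidecar at generation time."""
        from croma.alignment_io import (ReferenceGenome,
                                        extract_site_alignment, read_maf)
        genome = ReferenceGenome.from_fasta(bundle["paths"]["reference"])
        blocks = list(read_maf(bundle["paths"]["maf"],
                               bundle["reference_species"]))
        for rec in bundle["design_truth"][:40]:
            option = ProbeDesignOption(ProbeType(rec["probe_type"]),
                                       rec["strand"])
            sa = extract_site_alignment(
                blocks, genome, bundle["chrom"], rec["site"], option,
                reference_species=bundle["reference_species"],
                all_species=bundle["species"])
            cand = design_option_candidate(sa)
            assert cand.budget_M == rec["M"]
            assert cand.coverage == rec["optimal_coverage"]
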