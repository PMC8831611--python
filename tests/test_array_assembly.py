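"""Selection pipeline: S1-S4 steps, mappability filter, biomarker merge."""

import numpy as np
import pandas as pd
import pytest

from croma.array_assembly import (
    AssemblyConfig,
    apply_mappability_filter,
    assemble,
    final_probe_ids,
    format_degenerate,
    manifest_summary,
    merge_biomarkers,
    parse_degenerate,
)
from croma.probe_model import DegenerateBase


def _candidate_row(site, ptype, strand, coverage, species):
    return {
        "chrom": "chr1", "site": site, "probe_type": ptype, "strand": strand,
        "coverage": coverage, "covered_species": ";".join(species),
        "degenerate": "", "budget_M": 3, "sequence": "A" * 50,
    }


@pytest.fixture()
def toy_candidates():
    """20 CpG sites with hand-assigned coverages.

    Sites 0..4 (x100) have Type II probes covering 'mouse'; sites 5..19
    do not.  Type II coverages descend from site 19 down; every site
    also has a Type I candidate with coverage site_index % 7 + 1.
    """
    rows = []
    for i in range(20):
        site = (i + 1) * 100
        species = [f"sp{j}" for j in range(3 + i % 5)]
        if i < 5:
            species.append("mouse")
        rows.append(_candidate_row(site, "II", "+", 30 - i, species))
        rows.append(_candidate_row(site, "II", "-", 30 - i - (i % 2),
                                   species))
        rows.append(_candidate_row(site, "I", "+", i % 7 + 1, species))
    return pd.DataFrame(rows)


class TestAssemble:
    def test_hand_enumerated_manifest(self, toy_candidates):
        """Manual execution of the four steps on the toy table.

        S1: sites 100..500 (cover mouse).  S2: top-up to 10 by Type II
        coverage -> sites 600..1000 (coverages 25..21).  S3: EPIC lists
        sites 1100 (Type II '+') and 1200 (Type I '+'), neither chosen
        yet -> both taken.  S4: two remaining sites with the highest
        Type I coverage; sites 1300..2000 have Type I coverages
        (12%7)+1=6, 6, 1..7 -> best are 1900 (cov 5? no: check) —
        computed below from first principles instead of prose.
        """
        epic = pd.DataFrame([
            {"cpg_id": "cgE1", "chrom": "chr1", "position": 1101,
             "probe_type": "II", "strand": "+"},
            {"cpg_id": "cgE2", "chrom": "chr1", "position": 1201,
             "probe_type": "I", "strand": "+"},
        ])
        config = AssemblyConfig(model_species="mouse", total_after_topup=10,
                                n_epic=2, n_typeI=2)
        manifest = assemble(toy_candidates, config, epic_metadata=epic)

        s1 = manifest[manifest["provenance_step"] == "S1_model_species"]
        assert sorted(s1["position"]) == [101, 201, 301, 401, 501]
        s2 = manifest[manifest["provenance_step"] == "S2_topup"]
        assert sorted(s2["position"]) == [601, 701, 801, 901, 1001]
        s3 = manifest[manifest["provenance_step"] == "S3_epic"]
        assert sorted(s3["position"]) == [1101, 1201]
        assert set(s3["probe_id"]) == {"cgE1", "cgE2"}
        assert list(s3["probe_type"]) == ["II", "I"] or \
            sorted(s3["probe_type"]) == ["I", "II"]
        s4 = manifest[manifest["provenance_step"] == "S4_typeI"]
        # remaining sites 1300..2000; Type I coverage = idx % 7 + 1,
        # idx 12..19 -> 6,7,1,2,3,4,5,6; best two: idx 13 (cov 7) then
        # idx 12 (cov 6, earlier coordinate than idx 19's 6)
        assert list(s4["position"]) == [1401, 1301]
        # a site appears at most once across all steps
        assert manifest["position"].is_unique

    def test_strand_winner_ties_to_forward(self, toy_candidates):
        # even indices have equal coverage on both strands
        config = AssemblyConfig(model_species="mouse", total_after_topup=5)
        manifest = assemble(toy_candidates, config)
        s1 = manifest[manifest["provenance_step"] == "S1_model_species"]
        even = s1[s1["position"].isin([101, 301, 501])]
        assert set(even["strand"]) == {"+"}

    def test_no_model_species_coverage_gives_empty_s1(self, toy_candidates):
        config = AssemblyConfig(model_species="unicorn", total_after_topup=4)
        manifest = assemble(toy_candidates, config)
        assert (manifest["provenance_step"] == "S2_topup").all()
        assert len(manifest) == 4

    def test_epic_site_already_selected_keeps_s1_provenance(self, toy_candidates):
        epic = pd.DataFrame([{"cpg_id": "cgE9", "chrom": "chr1",
                              "position": 101, "probe_type": "II",
                              "strand": "+"}])
        config = AssemblyConfig(model_species="mouse", total_after_topup=5,
                                n_epic=1)
        manifest = assemble(toy_candidates, config, epic_metadata=epic)
        row = manifest[manifest["position"] == 101]
        assert list(row["provenance_step"]) == ["S1_model_species"]
        assert len(manifest[manifest["position"] == 101]) == 1

    def test_epic_without_metadata_errors(self, toy_candidates):
        config = AssemblyConfig(model_species="mouse", total_after_topup=5,
                                n_epic=3)
        with pytest.raises(ValueError, match="EPIC metadata"):
            assemble(toy_candidates, config)

    def test_epic_row_without_strand_skipped(self, toy_candidates):
        epic = pd.DataFrame([{"cpg_id": "cgE1", "chrom": "chr1",
                              "position": 1101, "probe_type": "II",
                              "strand": None}])
        config = AssemblyConfig(model_species="mouse", total_after_topup=5,
                                n_epic=1)
        with pytest.warns(UserWarning, match="lacks strand"):
            manifest = assemble(toy_candidates, config, epic_metadata=epic)
        assert not (manifest["provenance_step"] == "S3_epic").any()

    def test_s1_plus_s2_equals_topup_total(self, toy_candidates):
        config = AssemblyConfig(model_species="mouse", total_after_topup=12)
        manifest = assemble(toy_candidates, config)
        n12 = manifest["provenance_step"].isin(
            ["S1_model_species", "S2_topup"]).sum()
        assert n12 == 12

    def test_rerun_is_identical(self, toy_candidates):
        config = AssemblyConfig(model_species="mouse", total_after_topup=10,
                                n_typeI=3)
        m1 = assemble(toy_candidates, config)
        m2 = assemble(toy_candidates, config)
        pd.testing.assert_frame_equal(m1, m2)


class TestMappabilityFilter:
    def _manifest(self, rows):
        df = pd.DataFrame(rows)
        df["duplicate_suffix"] = ""
        return df

    def _case(self, pid, coverage, n_targeted, n_unique, panel_size=16):
        """One constructed decision case: a probe targeting n_targeted of
        the panel genomes, unique in n_unique of them."""
        covered = [f"g{j}" for j in range(n_targeted)] + \
            [f"x{j}" for j in range(max(0, coverage - n_targeted))]
        uniq = {f"g{j}": j < n_unique for j in range(panel_size)}
        row = {"probe_id": pid, "chrom": "chr1", "position": 1,
               "probe_type": "II", "strand": "+", "sequence": "A" * 50,
               "degenerate": "", "coverage": coverage,
               "covered_species": ";".join(covered),
               "provenance_step": "S1_model_species"}
        return row, uniq

    def test_eighty_percent_and_rescue_rule_table(self):
        """20 constructed cases spanning the 80% / >=40-species rule."""
        panel = [f"g{j}" for j in range(16)]
        cases = []
        # (coverage, targeted, unique, expected_keep)
        grid = [
            (16, 16, 13, True),    # 13/16 = 0.8125 >= 0.8
            (45, 16, 7, True),     # fails fraction, rescued by coverage 45
            (20, 16, 12, False),   # 12/16 = 0.75 < 0.8
            (16, 16, 16, True),
            (16, 16, 0, False),
            (40, 16, 0, True),     # rescue boundary: exactly 40
            (39, 16, 0, False),    # just below rescue
            (10, 10, 8, True),     # 8/10 = 0.8 exactly
            (10, 10, 7, False),    # 7/10 = 0.7
            (5, 5, 4, True),       # 4/5 = 0.8
            (5, 5, 3, False),
            (12, 12, 10, True),    # 10/12 = 0.833
            (12, 12, 9, False),    # 0.75
            (8, 4, 4, True),       # targets only 4 panel genomes, all unique
            (8, 4, 2, False),      # 2/4 = 0.5
            (41, 2, 0, True),      # rescued
            (30, 15, 12, True),    # 0.8 exactly
            (30, 15, 11, False),
            (16, 16, 14, True),
            (2, 1, 0, False),
        ]
        rows, uniq_rows, expected = [], [], []
        for i, (cov, targ, uni, keep) in enumerate(grid):
            row, uniq = self._case(f"p{i:02d}", cov, targ, uni)
            rows.append(row)
            uniq_rows.append(pd.Series(uniq, name=f"p{i:02d}"))
            expected.append(keep)
        manifest = self._manifest(rows)
        uniqueness = pd.DataFrame(uniq_rows).fillna(False)
        config = AssemblyConfig(model_species="mouse", total_after_topup=0,
                                panel_genomes=tuple(panel))
        out = apply_mappability_filter(manifest, uniqueness, config)
        kept = set(out["probe_id"])
        for (row, keep) in zip(rows, expected):
            assert (row["probe_id"] in kept) == keep, row["probe_id"]

    def test_filter_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        rows, uniq_rows = [], []
        for i in range(30):
            cov = int(rng.integers(2, 20))
            targ = int(rng.integers(1, 17))
            uni = int(rng.integers(0, targ + 1))
            row, uniq = self._case(f"p{i:02d}", cov, targ, uni)
            rows.append(row)
            uniq_rows.append(pd.Series(uniq, name=f"p{i:02d}"))
        manifest = self._manifest(rows)
        uniqueness = pd.DataFrame(uniq_rows).fillna(False)
        prev = None
        for thr in (0.2, 0.5, 0.8, 1.0):
            config = AssemblyConfig(
                model_species="m", total_after_topup=0,
                mappability_fraction_threshold=thr,
                panel_genomes=tuple(f"g{j}" for j in range(16)))
            kept = set(apply_mappability_filter(
                manifest, uniqueness, config)["probe_id"])
            if prev is not None:
                assert kept <= prev
            prev = kept

    def test_missing_probe_in_report_errors(self):
        row, uniq = self._case("p00", 5, 5, 5)
        manifest = self._manifest([row])
        uniqueness = pd.DataFrame([pd.Series(uniq, name="other")])
        config = AssemblyConfig(model_species="m", total_after_topup=0)
        with pytest.raises(KeyError, match="absent from uniqueness"):
            apply_mappability_filter(manifest, uniqueness, config)


class TestBiomarkerMerge:
    def _design_manifest(self):
        return pd.DataFrame([{
            "probe_id": "cg00000001", "chrom": "chr1", "position": 500,
            "probe_type": "II", "strand": "+", "sequence": "A" * 50,
            "degenerate": "", "coverage": 10, "covered_species": "a;b",
            "provenance_step": "S1_model_species", "duplicate_suffix": "",
        }])

    def test_empty_biomarker_list_is_noop(self):
        m = self._design_manifest()
        out = merge_biomarkers(m, pd.DataFrame())
        pd.testing.assert_frame_equal(out, m)

    def test_collision_keeps_both_rows_with_suffixes(self):
        bio = pd.DataFrame([{
            "probe_id": "cg00000001", "chrom": "chr1", "position": 500,
            "probe_type": "I", "strand": "-", "sequence": "C" * 50,
        }])
        out = merge_biomarkers(self._design_manifest(), bio)
        assert len(out) == 2
        ids = sorted(final_probe_ids(out))
        assert ids == ["cg00000001.1", "cg00000001.2"]
        assert list(out["provenance_step"]) == ["S1_model_species", "biomarker"]

    def test_ch_probe_accepted_without_cpg_validation(self):
        bio = pd.DataFrame([{
            "probe_id": "ch.1.123", "chrom": "chr1", "position": 999,
            "probe_type": "II", "strand": "+", "sequence": "G" * 50,
        }])
        out = merge_biomarkers(self._design_manifest(), bio)
        assert "ch.1.123" in set(out["probe_id"])

    def test_malformed_row_names_the_row(self):
        bio = pd.DataFrame([{
            "probe_id": "rs123", "chrom": "chr1", "position": 999,
            "probe_type": "II", "strand": "+", "sequence": None,
        }])
        with pytest.raises(ValueError, match="rs123.*missing|missing.*sequence"):
            merge_biomarkers(self._design_manifest(), bio)


class TestManifestHelpers:
    def test_degenerate_round_trip(self):
        deg = (DegenerateBase(3, "T"), DegenerateBase(40, "A"))
        assert parse_degenerate(format_degenerate(deg)) == deg
        assert parse_degenerate("") == ()

    def test_summary_counts_on_synthetic_manifest(self):
        # 3 probe sets over 2 unique cytosines; expansions 1 + 2 + 4
        m = pd.DataFrame([
            {"chrom": "chr1", "position": 10, "sequence": "ACGT"},
            {"chrom": "chr1", "position": 10, "sequence": "ARGT"},
            {"chrom": "chr2", "position": 20, "sequence": "RRAA"},
        ])
        s = manifest_summary(m)
        assert s == {"unique_cytosines": 2, "probe_sets": 3,
                     "expanded_sequences": 7}
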