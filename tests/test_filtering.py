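"""The two published filtering pipelines, QC metrics and Mendelian checks."""

import numpy as np
import pytest

from pinegbs.calling import call_genotypes
from pinegbs.filtering import (
    FilterConfig,
    filter_final49K,
    filter_pilot80K,
    haploid_het_site_fraction,
    mendelian_check,
    qc_report,
)

from conftest import make_matrix, make_sheet, make_table


def sheet_with_megas(n_megas: int, n_diploids: int = 3):
    rows = [{"sample_id": f"d{i}"} for i in range(n_diploids)]
    rows += [
        {"sample_id": f"m{i}", "ploidy": 1, "role": "megagametophyte", "mother_id": "d0"}
        for i in range(n_megas)
    ]
    return rows


class TestPilot80K:
    def test_polymorphic_haploid_probe_removed_entirely(self):
        # 2 of 20 megagametophytes (10% > 5%) heterozygous at one SNP of a
        # 2-SNP probe: the whole probe goes
        rows = sheet_with_megas(20)
        sheet = make_sheet(rows)
        het = {f"m{i}": [15, 14] for i in range(2)}
        hom = {f"m{i}": [20, 0] for i in range(2, 20)}
        dip = {f"d{i}": [15, 14] for i in range(3)}
        specs = [
            {"depths": {**het, **hom, **dip}, "probe": "pX", "site_id": "bad"},
            {"depths": {**{f"m{i}": [20, 0] for i in range(20)}, **dip}, "probe": "pX", "site_id": "guilt"},
            {"depths": {**{f"m{i}": [20, 0] for i in range(20)}, **dip}, "probe": "pY", "site_id": "clean"},
        ]
        table = make_table([r["sample_id"] for r in rows], specs)
        out, report = filter_pilot80K(table, sheet)
        assert out.site_ids == ["clean"]  # by-association removal of "guilt"
        assert report.to_frame()["n_snps"].tolist()[:2] == [3, 1]

    def test_quality_and_depth_and_triallelic_stages(self):
        rows = sheet_with_megas(0, n_diploids=4)
        sheet = make_sheet(rows)
        good = {f"d{i}": [15, 14] for i in range(4)}
        specs = [
            {"depths": good, "qual": 9.9, "site_id": "lowq"},
            {"depths": {f"d{i}": [3, 1] for i in range(4)}, "site_id": "shallow"},  # mean 4 < 5
            {"depths": {f"d{i}": [10, 8, 7] for i in range(4)}, "alleles": ("A", "C", "G"), "site_id": "tri"},
            {"depths": good, "qual": 50, "site_id": "keep"},
            {"depths": {f"d{i}": [28, 2] for i in range(4)}, "site_id": "skewed"},  # pop ratio 1/15
        ]
        table = make_table([r["sample_id"] for r in rows], specs)
        out, report = filter_pilot80K(table, sheet)
        assert out.site_ids == ["keep"]
        f = report.to_frame()
        assert f["stage"].tolist() == [
            "None", "Polymorphic haploids", "Quality", "Read depth per SNP", "Biallelic", "Allele ratio",
        ]
        assert f["n_snps"].tolist() == [5, 5, 4, 3, 2, 1]

    def test_report_monotone_on_simulation(self, small_sim):
        _, table, sheet, _ = small_sim
        _, report = filter_pilot80K(table, sheet)
        assert report.is_monotone()


class TestFinal49K:
    def test_mean_depth_stage_boundary(self):
        sheet = make_sheet(sheet_with_megas(0, 2))
        specs = [
            {"depths": {"d0": [5, 5], "d1": [5, 4]}, "site_id": "under"},  # mean 9.5
            {"depths": {"d0": [5, 5], "d1": [5, 5]}, "site_id": "exact"},  # mean 10 survives
        ]
        table = make_table(["d0", "d1"], specs)
        out, _, _ = filter_final49K(table, sheet)
        assert "under" not in out.site_ids

    def test_triallelic_routing_by_extra_allele_depth(self):
        sheet = make_sheet(sheet_with_megas(0, 2))
        specs = [
            # third allele seen at 12 reads in one individual: true triallelic
            {"depths": {"d0": [10, 9, 12], "d1": [12, 10, 0]}, "alleles": ("A", "C", "G"), "site_id": "true_tri"},
            # third allele at most 3 reads: dropped, reclassified biallelic
            {"depths": {"d0": [10, 9, 3], "d1": [12, 10, 0]}, "alleles": ("A", "C", "G"), "site_id": "resolved"},
            # boundary: exactly 10 reads is treated as weak (dropped)
            {"depths": {"d0": [10, 9, 10], "d1": [12, 10, 0]}, "alleles": ("A", "C", "G"), "site_id": "boundary"},
        ]
        table = make_table(["d0", "d1"], specs)
        out, tri, _ = filter_final49K(table, sheet)
        assert tri is not None and tri.site_ids == ["true_tri"]
        kept = out.sites.set_index("site_id")
        for sid in ("resolved", "boundary"):
            assert kept.loc[sid, "n_alleles"] == 2
            assert len(kept.loc[sid, "alleles"]) == 2

    def test_individual_masking_counts_reported(self):
        sheet = make_sheet(sheet_with_megas(0, 3))
        specs = [
            {"depths": {"d0": [6, 3], "d1": [30, 28], "d2": [58, 2]}, "site_id": "s"},
            {"depths": {"d0": [20, 19], "d1": [30, 28], "d2": [15, 14]}, "site_id": "t"},
        ]
        table = make_table(["d0", "d1", "d2"], specs)
        out, _, report = filter_final49K(table, sheet)
        f = report.to_frame().set_index("stage")
        assert f.loc["Read depth per individual", "n_datapoints_masked"] == 1  # d0 at s
        assert f.loc["Allele ratio", "n_datapoints_masked"] == 1  # d2 at s (2/60)
        # masked points do not change site counts (the published report shape)
        assert f.loc["Read depth per individual", "n_snps"] == f.loc["Biallelic", "n_snps"]

    def test_maf_floor_over_reference_cohort(self):
        # 20 unrelated: one SNP with a single het (MAF 0.025 < 0.03), one
        # common SNP
        samples = [f"d{i}" for i in range(20)]
        sheet = make_sheet([{"sample_id": s} for s in samples])
        rare = {s: ([30, 28] if s == "d0" else [30, 0]) for s in samples}
        common = {s: ([30, 28] if i < 10 else [30, 0]) for i, s in enumerate(samples)}
        table = make_table(samples, [
            {"depths": rare, "site_id": "rare"},
            {"depths": common, "site_id": "common"},
        ])
        out, _, _ = filter_final49K(table, sheet)
        assert out.site_ids == ["common"]

    def test_post_conditions_on_simulation(self, small_sim):
        cfg, table, sheet, truth = small_sim
        out, tri, report = filter_final49K(table, sheet)
        assert report.is_monotone()
        assert (out.sites["n_alleles"] == 2).all()
        assert (haploid_het_site_fraction(out, sheet) <= 0.05).all()
        from pinegbs.filtering import cohort_maf

        m = call_genotypes(out, sheet, low_ratio_action="missing")
        maf = cohort_maf(m, sheet.unrelated_cohort)
        assert (maf >= 0.03).all()

    def test_idempotence_of_site_level_stages(self, small_sim):
        _, table, sheet, _ = small_sim
        out1, _, _ = filter_final49K(table, sheet)
        out2, tri2, rep2 = filter_final49K(out1, sheet)
        f = rep2.to_frame().set_index("stage")["n_snps"]
        # stages 1-5 remove nothing on a second pass; only the genotype
        # stages (monomorphic/MAF) may act after masking reclassification
        assert f.loc["Polymorphic haploids"] == f.loc["None"]
        assert tri2 is None
        assert set(out2.site_ids) <= set(out1.site_ids)

    def test_error_free_pipeline_removes_only_monomorphic_and_rare(self, clean_sim):
        _, table, sheet, truth = clean_sim
        out, tri, report = filter_final49K(table, sheet)
        f = report.to_frame().set_index("stage")["n_snps"]
        assert tri is None
        # depth is ample and there are no artifacts: the site-level QC
        # stages remove nothing
        assert f.loc["Polymorphic haploids"] == f.loc["None"]


class TestQCReport:
    def test_call_rates_and_concordance(self):
        samples = ["a", "a_rep", "b"]
        genos = {
            "a": [(0, 1)] * 99 + [(0, 0)],
            "a_rep": [(0, 1)] * 99 + [(1, 1)],  # one differing call of 100
            "b": [(0, 0)] * 90 + [None] * 10,
        }
        matrix = make_matrix(samples, genos)
        sheet = make_sheet(
            [
                {"sample_id": "a", "replicate_group": "ra"},
                {"sample_id": "a_rep", "role": "replicate", "replicate_group": "ra"},
                {"sample_id": "b"},
            ]
        )
        table = make_table(samples, [{"depths": {s: [15, 15] for s in samples}, "site_id": f"S{j}"} for j in range(100)])
        rep = qc_report(matrix, table, sheet)
        assert rep.call_rate_per_sample["b"] == pytest.approx(0.9)
        assert rep.replicate_concordance.iloc[0]["concordance"] == pytest.approx(0.99)
        assert rep.snps_per_probe.sum() == table.sites["probe_id"].nunique()

    def test_identical_replicates_fully_concordant(self):
        samples = ["a", "a_rep"]
        genos = {"a": [(0, 1), (1, 1), (0, 0)], "a_rep": [(0, 1), (1, 1), (0, 0)]}
        matrix = make_matrix(samples, genos)
        sheet = make_sheet(
            [
                {"sample_id": "a", "replicate_group": "g"},
                {"sample_id": "a_rep", "role": "replicate", "replicate_group": "g"},
            ]
        )
        table = make_table(samples, [{"depths": {s: [15, 15] for s in samples}} for _ in range(3)])
        rep = qc_report(matrix, table, sheet)
        assert rep.replicate_concordance["concordance"].iloc[0] == 1.0

    def test_simulated_replicates_highly_concordant(self, clean_sim):
        _, table, sheet, _ = clean_sim
        m = call_genotypes(table, sheet)
        rep = qc_report(m, table, sheet)
        assert (rep.replicate_concordance["concordance"] > 0.99).all()


class TestMendelianCheck:
    def test_constructed_inconsistencies(self):
        samples = ["mom", "dad", "kid", "mega"]
        genos = {
            "mom": [(0, 0), (0, 1)],
            "dad": [(0, 0), (0, 1)],
            "kid": [(1, 1), (0, 1)],  # site 0 impossible from AA x AA
            "mega": [1, 0],  # site 0 allele absent from mom (AA)
        }
        matrix = make_matrix(samples, genos, ploidy=[2, 2, 2, 1])
        sheet = make_sheet(
            [
                {"sample_id": "mom", "role": "parent"},
                {"sample_id": "dad", "role": "parent"},
                {"sample_id": "kid", "role": "offspring", "family_id": "f",
                 "mother_id": "mom", "father_id": "dad"},
                {"sample_id": "mega", "ploidy": 1, "role": "megagametophyte", "mother_id": "mom"},
            ]
        )
        trios, duos = mendelian_check(matrix, sheet)
        assert trios.iloc[0]["n_inconsistent"] == 1
        assert duos.iloc[0]["n_inconsistent"] == 1

    def test_error_free_simulation_is_consistent(self, clean_sim):
        _, _, sheet, truth = clean_sim
        trios, duos = mendelian_check(truth.to_matrix(), sheet)
        assert (trios["n_inconsistent"] == 0).all()
        assert (duos["n_inconsistent"] == 0).all()

    def test_requires_relationships(self):
        matrix = make_matrix(["a"], {"a": [(0, 0)]})
        sheet = make_sheet([{"sample_id": "a"}])
        with pytest.raises(ValueError):
            mendelian_check(matrix, sheet)
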