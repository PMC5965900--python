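"""QC filters and qualifying-variant logic against independent truth tables."""

import numpy as np
import pytest

from pvnhkit import (
    MissingAnnotationError,
    SiteGenotype,
    TrioGenotypes,
    is_qualifying_biallelic_site,
    is_qualifying_dominant,
    list_trio_biallelic_genotypes,
    qc_pass_collapsing,
    qc_pass_denovo,
)
from pvnhkit.variants import GeneAnnotation, PROBABLY_DAMAGING_HUMDIV

from conftest import make_variant


class TestDenovoQC:
    @pytest.mark.parametrize(
        "qc_override,is_indel,expected",
        [
            ({"QD": 1.9}, False, False),
            ({"MQ": 39.9}, False, False),
            ({"FS": 60.1}, False, False),
            ({"HS": 13.1}, False, False),
            ({"MQRS": -12.6}, False, False),
            ({"RPRS": -8.1}, False, False),
            # boundary semantics: thresholds themselves pass (strict inequalities)
            ({"QD": 2.0, "MQ": 40.0, "FS": 60.0, "HS": 13.0, "MQRS": -12.5, "RPRS": -8.0}, False, True),
            ({"FS": 200.0}, True, True),
            ({"FS": 200.1}, True, False),
            ({"RPRS": -20.1}, True, False),
            ({"RPRS": -19.9, "FS": 100.0, "HS": 99.0, "MQ": 1.0}, True, True),
        ],
    )
    def test_thresholds(self, qc_override, is_indel, expected):
        v = make_variant(qc=qc_override, is_indel=is_indel)
        assert qc_pass_denovo(v) is expected

    def test_missing_metric_raises_unless_declared_absent(self):
        qc = {k: v for k, v in make_variant().qc.items() if k != "HS"}
        v = make_variant(qc={})
        object.__setattr__(v, "qc", qc)
        with pytest.raises(MissingAnnotationError):
            qc_pass_denovo(v)
        assert qc_pass_denovo(v, absent_fields=("HS",)) is True

    def test_agrees_with_truth_table_oracle_on_random_variants(self):
        """Filter decisions match an independently coded oracle on 1,000 draws."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            qc = {
                "QD": float(rng.uniform(0, 5)),
                "MQ": float(rng.uniform(30, 70)),
                "FS": float(rng.uniform(0, 250)),
                "HS": float(rng.uniform(0, 20)),
                "MQRS": float(rng.uniform(-25, 5)),
                "RPRS": float(rng.uniform(-25, 5)),
            }
            is_indel = bool(rng.random() < 0.3)
            v = make_variant(qc=qc, is_indel=is_indel)
            if is_indel:
                oracle = not (qc["QD"] < 2 or qc["RPRS"] < -20 or qc["FS"] > 200)
            else:
                oracle = not (
                    qc["QD"] < 2
                    or qc["MQ"] < 40
                    or qc["FS"] > 60
                    or qc["HS"] > 13
                    or qc["MQRS"] < -12.5
                    or qc["RPRS"] < -8
                )
            assert qc_pass_denovo(v) is oracle


class TestCollapsingQC:
    def test_het_allele_ratio_below_quarter_fails(self):
        v = make_variant(qc={"depth": 40, "alt_depth": 9})
        assert qc_pass_collapsing(v, "het") is False
        assert qc_pass_collapsing(v, "hom_alt") is True

    def test_low_coverage_fails(self):
        v = make_variant(qc={"depth": 4, "alt_depth": 2})
        assert qc_pass_collapsing(v, "het") is False

    def test_clean_hom_alt_passes(self):
        assert qc_pass_collapsing(make_variant(), "hom_alt") is True

    def test_blacklist_and_vqsr(self):
        v = make_variant()
        assert qc_pass_collapsing(v, "het", blacklist=frozenset({v.key})) is False
        v2 = make_variant(qc={"vqsr_pass": False})
        assert qc_pass_collapsing(v2, "het") is False

    def test_pure_predicate_idempotent(self):
        v = make_variant()
        assert qc_pass_collapsing(v, "het") == qc_pass_collapsing(v, "het")


class TestQualifyingDominant:
    def test_lof_with_four_copies_qualifies(self):
        v = make_variant(effect="lof", cohort_allele_count=4)
        assert is_qualifying_dominant(v, "lof_only")

    def test_five_copies_disqualifies(self):
        v = make_variant(effect="lof", cohort_allele_count=5)
        assert not is_qualifying_dominant(v, "lof_only")

    def test_synonymous_never_qualifies(self):
        v = make_variant(effect="synonymous")
        assert not is_qualifying_dominant(v, "lof_plus_probably_damaging")

    def test_population_presence_disqualifies(self):
        v = make_variant(effect="lof", pop_freq={"EVS": 0.001, "ExAC": 0.0})
        assert not is_qualifying_dominant(v, "lof_only")

    def test_probably_damaging_cut(self):
        damaging = make_variant(polyphen_humdiv=PROBABLY_DAMAGING_HUMDIV)
        benign = make_variant(polyphen_humdiv=0.5)
        assert is_qualifying_dominant(damaging, "lof_plus_probably_damaging")
        assert not is_qualifying_dominant(benign, "lof_plus_probably_damaging")
        assert not is_qualifying_dominant(damaging, "lof_only")

    def test_unknown_model_errors(self):
        with pytest.raises(ValueError):
            is_qualifying_dominant(make_variant(), "recessive")

    def test_lof_only_is_subset_of_combined_model(self):
        """Any lof_only-qualifying variant also qualifies under the wider model."""
        rng = np.random.default_rng(7)
        for _ in range(500):
            v = make_variant(
                effect=str(rng.choice(["lof", "missense", "synonymous"])),
                polyphen_humdiv=float(rng.random()),
                cohort_allele_count=int(rng.integers(0, 8)),
                pop_freq={"EVS": float(rng.choice([0.0, 1e-4])), "ExAC": 0.0},
            )
            if is_qualifying_dominant(v, "lof_only"):
                assert is_qualifying_dominant(v, "lof_plus_probably_damaging")


class TestQualifyingBiallelic:
    def test_maf_boundary(self):
        ok = make_variant(effect="lof", pop_freq={"EVS": 0.0, "ExAC": 0.0009})
        assert is_qualifying_biallelic_site(ok)
        too_common = make_variant(effect="lof", cohort_maf=0.002)
        assert not is_qualifying_biallelic_site(too_common)

    def test_benign_missense_does_not_qualify(self):
        v = make_variant(polyphen_humdiv=0.2)
        assert not is_qualifying_biallelic_site(v)


class TestTrioBiallelicListing:
    def _trio(self, sites, sex="female"):
        return TrioGenotypes(sites, proband_sex=sex)

    def test_compound_het_from_both_parents(self):
        va = make_variant(effect="lof", pos=100)
        vb = make_variant(effect="lof", pos=200)
        trio = self._trio(
            [
                SiteGenotype("het", "het", "hom_ref"),
                SiteGenotype("het", "hom_ref", "het"),
            ]
        )
        records = list_trio_biallelic_genotypes(trio, [va, vb])
        assert len(records) == 1
        rec = records[0]
        assert rec.kind == "comphet" and not rec.same_parent and not rec.inconsistent

    def test_same_parent_configuration_flagged(self):
        va = make_variant(effect="lof", pos=100)
        vb = make_variant(effect="lof", pos=200)
        trio = self._trio(
            [
                SiteGenotype("het", "het", "hom_ref"),
                SiteGenotype("het", "het", "hom_ref"),
            ]
        )
        (rec,) = list_trio_biallelic_genotypes(trio, [va, vb])
        assert rec.same_parent

    def test_common_contributing_variant_excluded(self):
        common = make_variant(effect="lof", pos=100, pop_freq={"EVS": 0.015, "ExAC": 0.0})
        other = make_variant(effect="lof", pos=200)
        trio = self._trio(
            [
                SiteGenotype("het", "het", "hom_ref"),
                SiteGenotype("het", "hom_ref", "het"),
            ]
        )
        assert list_trio_biallelic_genotypes(trio, [common, other]) == []

    def test_parent_hom_ref_needs_coverage(self):
        v = make_variant(effect="lof")
        trio = self._trio([SiteGenotype("hom_alt", "het", "hom_ref", father_depth=8)])
        assert list_trio_biallelic_genotypes(trio, [v]) == []
        trio_ok = self._trio([SiteGenotype("hom_alt", "het", "het")])
        (rec,) = list_trio_biallelic_genotypes(trio_ok, [v])
        assert rec.kind == "hom" and not rec.inconsistent

    def test_inconsistent_inheritance_flagged_not_dropped(self):
        v = make_variant(effect="lof")
        trio = self._trio([SiteGenotype("hom_alt", "het", "hom_ref")])
        (rec,) = list_trio_biallelic_genotypes(trio, [v])
        assert rec.inconsistent

    def test_hemizygous_male_x_only(self):
        v = make_variant(effect="lof", chrom="X")
        site = SiteGenotype("hemi", "het", "hom_ref")
        male = self._trio([site], sex="male")
        female = self._trio([site], sex="female")
        assert [r.kind for r in list_trio_biallelic_genotypes(male, [v])] == ["hemi"]
        assert list_trio_biallelic_genotypes(female, [v]) == []

    def test_known_hom_site_excluded(self):
        v = make_variant(effect="lof")
        trio = self._trio([SiteGenotype("hom_alt", "het", "het")])
        known = frozenset({(v.chrom, v.pos, v.alt)})
        assert list_trio_biallelic_genotypes(trio, [v], known_hom_sites=known) == []


def test_gene_annotation_intolerance_cut():
    assert GeneAnnotation("A", 0.25).intolerant
    assert not GeneAnnotation("B", 0.2501).intolerant
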