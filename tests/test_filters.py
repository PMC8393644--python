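"""The selection cascade: filter predicates, co-segregation, and the funnel."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famvar import (
    Consequence,
    FilterConfig,
    Genotype,
    MutationTasterCall,
    Pedigree,
    PhenotypeStatus,
    PolyphenCall,
    SiftCall,
    cosegregates,
    flag_cadd,
    passes_consequence,
    passes_maf,
    passes_pathogenicity,
    passes_quality,
    run_control_selection,
    run_family_cascade,
)
from famvar.filters import FAMILY_STAGES, SampleMismatchError

from conftest import make_record

CFG = FilterConfig()


class TestSiteFilters:
    @pytest.mark.parametrize(
        "quality, expected",
        [(19.9, False), (20.0, True), (None, False)],
    )
    def test_quality_threshold_inclusive_and_unscored_untrusted(self, quality, expected):
        assert passes_quality(make_record(site_quality=quality), CFG) is expected

    @pytest.mark.parametrize(
        "consequence, expected",
        [
            (Consequence.MISSENSE, True),
            (Consequence.NONSENSE, True),
            (Consequence.FRAMESHIFT, True),
            (Consequence.INFRAME_INDEL, True),
            (Consequence.SPLICE_SITE, True),
            (Consequence.SYNONYMOUS, False),
            (Consequence.INTRONIC, False),
            (Consequence.OTHER, False),
        ],
    )
    def test_retained_consequence_classes(self, consequence, expected):
        assert passes_consequence(make_record(consequence=consequence), CFG) is expected

    @pytest.mark.parametrize(
        "maf, expected",
        [(0.002821, True), (None, True), (0.05, False), (0.049999, True)],
    )
    def test_maf_strictly_below_threshold_and_unknown_passes(self, maf, expected):
        assert passes_maf(make_record(maf=maf), CFG) is expected

    def test_single_deleterious_call_suffices(self):
        rec = make_record(
            sift_call=SiftCall.DELETERIOUS,
            polyphen_call=PolyphenCall.BENIGN,
            mutation_taster_call=MutationTasterCall.POLYMORPHISM,
        )
        assert passes_pathogenicity(rec, CFG)

    def test_missense_without_any_call_fails(self):
        rec = make_record(sift_call=None, polyphen_call=None, mutation_taster_call=None)
        assert not passes_pathogenicity(rec, CFG)

    @pytest.mark.parametrize("csq", [Consequence.NONSENSE, Consequence.FRAMESHIFT])
    def test_loss_of_function_bypasses_predictors(self, csq):
        rec = make_record(
            consequence=csq, sift_call=None, polyphen_call=None, mutation_taster_call=None
        )
        assert passes_pathogenicity(rec, CFG)

    def test_stricter_consensus_configurable(self):
        cfg = FilterConfig(min_predictor_calls=2)
        rec = make_record(
            sift_call=SiftCall.DELETERIOUS,
            polyphen_call=PolyphenCall.BENIGN,
            mutation_taster_call=None,
        )
        assert not passes_pathogenicity(rec, cfg)

    @pytest.mark.parametrize("cadd, expected", [(28.9, True), (19.99, False), (None, False)])
    def test_cadd_is_a_flag_not_a_filter(self, cadd, expected, trio_pedigree):
        rec = make_record(cadd_phred=cadd)
        assert flag_cadd(rec, CFG) is expected
        # low CADD must never remove a variant from the funnel
        result = run_family_cascade([rec], trio_pedigree, CFG)
        assert [c.cadd_ge_threshold for c in result.survivors] == [expected]


class TestCosegregation:
    def test_het_in_affected_absent_in_unaffected(self, trio_pedigree):
        assert cosegregates(make_record(), trio_pedigree)

    def test_hom_alt_affected_fails(self, trio_pedigree):
        rec = make_record(genotypes={"P1": Genotype.HET, "P2": Genotype.HOM_ALT, "C1": Genotype.HOM_REF})
        assert not cosegregates(rec, trio_pedigree)

    def test_carrier_unaffected_fails(self, trio_pedigree):
        rec = make_record(genotypes={"P1": Genotype.HET, "P2": Genotype.HET, "C1": Genotype.HET})
        assert not cosegregates(rec, trio_pedigree)

    def test_missing_genotype_is_not_a_demonstrated_het(self, trio_pedigree):
        rec = make_record(genotypes={"P1": Genotype.HET, "P2": Genotype.MISSING, "C1": Genotype.HOM_REF})
        assert not cosegregates(rec, trio_pedigree)

    def test_unknown_status_member_is_ignored(self):
        ped = Pedigree(
            "F",
            (
                ("P1", PhenotypeStatus.AFFECTED),
                ("P2", PhenotypeStatus.AFFECTED),
                ("X1", PhenotypeStatus.UNKNOWN),
            ),
        )
        rec = make_record(genotypes={"P1": Genotype.HET, "P2": Genotype.HET, "X1": Genotype.HOM_ALT})
        assert cosegregates(rec, ped)

    def test_pedigree_member_without_genotype_is_mismatch_error(self, trio_pedigree):
        rec = make_record(genotypes={"P1": Genotype.HET, "C1": Genotype.HOM_REF})
        with pytest.raises(SampleMismatchError, match="P2"):
            cosegregates(rec, trio_pedigree)


class TestFamilyCascade:
    def test_zero_records_zero_counts(self, trio_pedigree):
        result = run_family_cascade([], trio_pedigree, CFG)
        assert result.gene_set == set()
        assert all(v == 0 for v in result.stage_counts.values())

    def test_counts_weakly_decreasing(self, trio_pedigree):
        records = [
            make_record(pos=1000 + 10 * i, gene_symbol=f"G{i}", maf=0.2 if i % 2 else 0.001)
            for i in range(20)
        ]
        counts = list(run_family_cascade(records, trio_pedigree, CFG).stage_counts.values())
        assert counts == sorted(counts, reverse=True)

    def test_planted_gene_recovered_from_noise(self, trio_pedigree):
        planted = make_record(gene_symbol="TARGET")
        noise = []
        for i in range(50):
            noise.append(
                make_record(
                    pos=2000 + 10 * i,
                    gene_symbol=f"BG{i}",
                    maf=0.3,  # every background record violates the MAF filter
                )
            )
        result = run_family_cascade([planted] + noise, trio_pedigree, CFG)
        assert result.gene_set == {"TARGET"}

    def test_collapse_conservation(self, trio_pedigree):
        records = [make_record(pos=1000 + 10 * i, gene_symbol="SAME") for i in range(3)]
        records += [make_record(pos=5000, gene_symbol="OTHER")]
        result = run_family_cascade(records, trio_pedigree, CFG)
        assert len(result.gene_set) <= len(result.survivors)
        assert result.gene_set == {"SAME", "OTHER"}
        assert len(result.genes["SAME"]) == 3

    def test_truncated_stage_list_for_pre_maf_inspection(self, trio_pedigree):
        common = make_record(maf=0.08)
        stages = FAMILY_STAGES[:3]  # quality, consequence, cosegregation
        result = run_family_cascade([common], trio_pedigree, CFG, stages=stages)
        assert result.gene_set == {"GENE1"}
        full = run_family_cascade([common], trio_pedigree, CFG)
        assert full.gene_set == set()


SITE_STAGES = ("quality", "consequence", "maf", "pathogenicity")

_records = st.builds(
    make_record,
    site_quality=st.one_of(st.none(), st.floats(0, 100, allow_nan=False)),
    consequence=st.sampled_from(list(Consequence)),
    maf=st.one_of(st.none(), st.floats(0, 1, allow_nan=False)),
    sift_call=st.one_of(st.none(), st.sampled_from(list(SiftCall))),
    polyphen_call=st.one_of(st.none(), st.sampled_from(list(PolyphenCall))),
    mutation_taster_call=st.one_of(st.none(), st.sampled_from(list(MutationTasterCall))),
)


@settings(max_examples=60, derandomize=True)
@given(
    records=st.lists(_records, max_size=12),
    order=st.permutations(SITE_STAGES),
)
def test_commuting_site_filters_are_order_robust(records, order):
    """Any order of the site-level filters yields the same survivor set."""
    preds = {
        "quality": passes_quality,
        "consequence": passes_consequence,
        "maf": passes_maf,
        "pathogenicity": passes_pathogenicity,
    }
    stated = [r for r in records if all(preds[s](r, CFG) for s in SITE_STAGES)]
    permuted = records
    for stage in order:
        permuted = [r for r in permuted if preds[stage](r, CFG)]
    assert permuted == stated


@settings(max_examples=40, derandomize=True)
@given(records=st.lists(_records, max_size=12))
def test_cascade_stages_are_subsets_of_their_input(records):
    ped = Pedigree(
        "F",
        (
            ("P1", PhenotypeStatus.AFFECTED),
            ("P2", PhenotypeStatus.AFFECTED),
            ("C1", PhenotypeStatus.UNAFFECTED),
        ),
    )
    counts = list(run_family_cascade(records, ped).stage_counts.values())
    assert counts == sorted(counts, reverse=True)


class TestControlSelection:
    def test_het_variants_collapse_to_genes(self):
        recs = [
            make_record(pos=1000, gene_symbol="A", genotypes={"I1": Genotype.HET}),
            make_record(pos=2000, gene_symbol="B", genotypes={"I1": Genotype.HET}),
        ]
        result = run_control_selection(recs, "I1", CFG)
        assert result.gene_set == {"A", "B"}

    def test_hom_alt_excluded_under_het_only_policy(self):
        rec = make_record(genotypes={"I1": Genotype.HOM_ALT})
        assert run_control_selection([rec], "I1", CFG).gene_set == set()

    def test_hom_alt_kept_under_nonref_policy(self):
        cfg = FilterConfig(control_zygosity="nonref")
        rec = make_record(genotypes={"I1": Genotype.HOM_ALT})
        assert run_control_selection([rec], "I1", cfg).gene_set == {"GENE1"}

    def test_cohort_union_over_individuals(self):
        from famvar import CandidateGeneSet

        cohort = CandidateGeneSet("CONTROL")
        for ind, genes in [("I1", ["A"]), ("I2", ["A", "B"]), ("I3", ["C"])]:
            recs = [
                make_record(pos=1000 + 10 * i, gene_symbol=g, genotypes={ind: Genotype.HET})
                for i, g in enumerate(genes)
            ]
            cohort.add(run_control_selection(recs, ind, CFG))
        assert cohort.genes == {"A", "B", "C"}
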