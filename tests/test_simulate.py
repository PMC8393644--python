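"""The synthetic cohort generator: determinism, ground truth, and tags."""

from __future__ import annotations

import filecmp

import pytest

from famvar import (
    RecurrentVariantPlan,
    SimulationConfig,
    find_recurrent_variants,
    read_ped,
    read_vcf,
    run_family_cascade,
    simulate_cohort,
)
from famvar.filters import DEFAULT_FILTER_CONFIG, FAMILY_STAGES, rejection_stage
from famvar.simulate import SimulationPlanError

from conftest import SMALL_SIM


def _tiny(**overrides):
    cfg = dict(SMALL_SIM)
    cfg.update(overrides)
    return SimulationConfig(**cfg)


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        a = simulate_cohort(_tiny(), tmp_path / "a")
        b = simulate_cohort(_tiny(), tmp_path / "b")
        for name in [p.name for p in a.out_dir.iterdir()]:
            assert filecmp.cmp(a.out_dir / name, b.out_dir / name, shallow=False), name

    def test_different_seed_differs(self, tmp_path):
        a = simulate_cohort(_tiny(seed=1), tmp_path / "a")
        b = simulate_cohort(_tiny(seed=2), tmp_path / "b")
        assert a.truth.family_planted != b.truth.family_planted


class TestGroundTruth:
    def test_noise_free_cohort_recovered_exactly(self, tmp_path):
        cfg = _tiny(
            num_families=2,
            num_controls=0,
            planted_genes_per_family=1,
            background_variants_per_sample=0,
            recurrent_pairs=0,
            panel_family_overlap=2,
            panel_control_overlap=0,
            panel_shared_overlap=0,
        )
        cohort = simulate_cohort(cfg, tmp_path)
        peds = {p.family_id: p for p in read_ped(cohort.ped_path)}
        for fam, path in cohort.family_vcfs.items():
            result = run_family_cascade(read_vcf(path), peds[fam])
            assert result.gene_set == cohort.truth.family_planted[fam]
            assert len(cohort.truth.family_planted[fam]) == 1

    def test_planted_variants_pass_and_background_fail(self, small_cohort):
        peds = {p.family_id: p for p in read_ped(small_cohort.ped_path)}
        for fam, path in small_cohort.family_vcfs.items():
            tags = small_cohort.truth.background_tags[fam]
            for rec in read_vcf(path):
                stage = rejection_stage(rec, DEFAULT_FILTER_CONFIG, fam=peds[fam])
                key = f"{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alt}"
                if key in tags:
                    assert stage is not None  # every background variant fails somewhere
                else:
                    assert stage is None  # every planted variant survives everything

    def test_recurrent_plan_realized_in_emitted_vcfs(self, small_cohort):
        peds = {p.family_id: p for p in read_ped(small_cohort.ped_path)}
        survivors = {
            fam: run_family_cascade(read_vcf(path), peds[fam]).survivors
            for fam, path in small_cohort.family_vcfs.items()
        }
        report = find_recurrent_variants(survivors)
        expected = {
            (gene, rsid): frozenset(fams)
            for gene, rsid, fams in small_cohort.truth.recurrent_variants
        }
        assert dict(report.variant_level) == expected

    def test_panel_overlap_plan_is_exact(self, small_cohort):
        truth = small_cohort.truth
        family_genes = set().union(*truth.family_planted.values())
        control_genes = set().union(*truth.control_planted.values())
        assert family_genes & truth.panel_genes == truth.panel_family_overlap
        assert control_genes & truth.panel_genes == truth.panel_control_overlap
        assert truth.panel_family_overlap & truth.panel_control_overlap == truth.panel_shared_overlap

    def test_planted_term_contains_panel_family_genes(self, small_cohort):
        term_genes = small_cohort.library.terms[small_cohort.truth.planted_term]
        assert small_cohort.truth.panel_family_overlap <= term_genes

    def test_sidecar_roundtrip(self, small_cohort):
        from famvar import GroundTruth

        loaded = GroundTruth.from_json(small_cohort.truth_path.read_text())
        assert loaded == small_cohort.truth


class TestPlanValidation:
    def test_recurrent_plan_with_unknown_family_rejected(self, tmp_path):
        plan = (RecurrentVariantPlan("GENE00001", "rsS000001", ("F01", "F99")),)
        with pytest.raises(SimulationPlanError, match="nonexistent"):
            simulate_cohort(_tiny(recurrent_variant_plan=plan), tmp_path)

    def test_recurrent_plan_needs_two_families(self):
        with pytest.raises(SimulationPlanError):
            RecurrentVariantPlan("G", "rs1", ("F01",))

    def test_inconsistent_panel_plan_rejected(self, tmp_path):
        with pytest.raises(SimulationPlanError):
            simulate_cohort(
                _tiny(panel_shared_overlap=50, panel_family_overlap=10), tmp_path
            )

    def test_stage_mix_must_sum_to_one(self, tmp_path):
        with pytest.raises(SimulationPlanError, match="sum to 1"):
            simulate_cohort(
                _tiny(background_stage_mix=(("maf", 0.5),)), tmp_path
            )


class TestAuditTags:
    def test_family_funnel_counts_monotone(self, small_cohort):
        peds = {p.family_id: p for p in read_ped(small_cohort.ped_path)}
        for fam, path in small_cohort.family_vcfs.items():
            counts = run_family_cascade(read_vcf(path), peds[fam]).stage_counts
            assert list(counts) == ["input", *FAMILY_STAGES]
            values = list(counts.values())
            assert values == sorted(values, reverse=True)

    def test_rejection_stage_matches_generator_tag(self, small_cohort):
        """Site-tagged background fails exactly its tagged stage; only the
        HWE-genotyped co-segregation class may shift stage, and rarely."""
        peds = {p.family_id: p for p in read_ped(small_cohort.ped_path)}
        total = matched = 0
        for fam, path in small_cohort.family_vcfs.items():
            tags = small_cohort.truth.background_tags[fam]
            for rec in read_vcf(path):
                key = f"{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alt}"
                if key not in tags:
                    continue
                total += 1
                stage = rejection_stage(rec, DEFAULT_FILTER_CONFIG, fam=peds[fam])
                if stage == tags[key]:
                    matched += 1
                else:
                    assert tags[key] == "cosegregation"  # only HWE draws may shift
        assert total > 0
        assert matched / total >= 0.95  # small cohort; acceptance checks >= 0.99 at scale
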