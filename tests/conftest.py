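"""Shared fixtures: record factories, a tiny pedigree, and a small simulated cohort."""

from __future__ import annotations

import pytest

from famvar import (
    Consequence,
    Genotype,
    MutationTasterCall,
    Pedigree,
    PhenotypeStatus,
    PolyphenCall,
    SiftCall,
    SimulationConfig,
    VariantRecord,
    simulate_cohort,
)


def make_record(**overrides) -> VariantRecord:
    """A variant that passes every cascade filter unless overridden."""
    fields = dict(
        chrom="chr1",
        pos=1000,
        ref="A",
        alt="G",
        rsid="rs1",
        site_quality=50.0,
        gene_symbol="GENE1",
        consequence=Consequence.MISSENSE,
        maf=0.001,
        sift_call=SiftCall.DELETERIOUS,
        polyphen_call=PolyphenCall.DAMAGING,
        mutation_taster_call=MutationTasterCall.DISEASE_CAUSING,
        cadd_phred=25.0,
        genotypes={"P1": Genotype.HET, "P2": Genotype.HET, "C1": Genotype.HOM_REF},
    )
    fields.update(overrides)
    return VariantRecord(**fields)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def trio_pedigree() -> Pedigree:
    """Two affected siblings and one unaffected relative."""
    return Pedigree(
        "FAM1",
        (
            ("P1", PhenotypeStatus.AFFECTED),
            ("P2", PhenotypeStatus.AFFECTED),
            ("C1", PhenotypeStatus.UNAFFECTED),
        ),
    )


SMALL_SIM = dict(
    num_families=4,
    num_controls=3,
    num_genes=1500,
    planted_genes_per_family=6,
    planted_genes_per_control=8,
    background_variants_per_sample=25,
    recurrent_pairs=3,
    panel_size=60,
    panel_family_overlap=10,
    panel_control_overlap=12,
    panel_shared_overlap=5,
    library_terms=20,
    library_term_size=12,
    seed=42,
)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A down-scaled cohort shared by read-only tests."""
    out = tmp_path_factory.mktemp("cohort")
    return simulate_cohort(SimulationConfig(**SMALL_SIM), out)
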