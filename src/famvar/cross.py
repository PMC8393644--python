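"""Recurrence across families, panel intersection, and Venn partition.

Recurrence is reported at two levels: genes carrying any qualifying
variant in at least ``min_families`` independent families, and identical
variants (same dbSNP id, or same coordinates when unnamed) observed in
two or more families.  Candidate gene sets are intersected with a
host-pathogen interactome panel, and the two cohorts' panel overlaps are
partitioned into cohort-private and shared genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Set, Tuple

from .filters import CandidateVariant
from .io import GenePanel


@dataclass(frozen=True)
class RecurrenceReport:
    """Families sharing genes (gene level) and identical variants (variant level).

    ``variant_level`` keys are ``(gene_symbol, variant_label)`` where the
    label is the rsid when present, else ``chrom:pos:ref:alt``.
    """

    gene_level: Mapping[str, FrozenSet[str]]
    variant_level: Mapping[Tuple[str, str], FrozenSet[str]]


@dataclass(frozen=True)
class CrossResult:
    """Overlap of one cohort's candidate genes with an interactome panel."""

    cohort_label: str
    candidate_genes: FrozenSet[str]
    panel_name: str
    overlap: FrozenSet[str]
    proportion: Optional[float]  # raw fraction; None when no candidates

    @property
    def proportion_percent(self) -> Optional[float]:
        """Percentage to one decimal, rounded half away from zero; None if undefined."""
        if self.proportion is None:
            return None
        return round_half_away(100.0 * self.proportion, 1)


@dataclass(frozen=True)
class VennPartition:
    """Two-set partition: private to each input, and shared."""

    only_a: FrozenSet[str]
    shared: FrozenSet[str]
    only_b: FrozenSet[str]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (so 9.15 -> 9.2), unlike banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def find_recurrent_genes(
    gene_sets_by_family: Mapping[str, Set[str]],
    min_families: int = 2,
) -> RecurrenceReport:
    """Genes whose family set reaches ``min_families``, with the exact sets."""
    if min_families < 2:
        raise ValueError("min_families must be >= 2")
    families_by_gene: Dict[str, Set[str]] = {}
    for family, genes in gene_sets_by_family.items():
        for gene in genes:
            families_by_gene.setdefault(gene.upper(), set()).add(family)
    gene_level = {
        gene: frozenset(fams)
        for gene, fams in families_by_gene.items()
        if len(fams) >= min_families
    }
    return RecurrenceReport(gene_level=gene_level, variant_level={})


def _variant_label(record) -> str:
    if record.rsid is not None:
        return record.rsid
    return f"{record.chrom}:{record.pos}:{record.ref}:{record.alt}"


def find_recurrent_variants(
    candidate_variants_by_family: Mapping[str, Iterable[CandidateVariant]],
) -> RecurrenceReport:
    """Identical variants observed in >= 2 families, plus gene-level recurrence.

    Variant identity uses the rsid when present, else the
    ``(chrom, pos, ref, alt)`` tuple.  The gene-level map in the returned
    report is restricted to genes qualifying in >= 2 families, so the
    variant-level family sets are always subsets of their gene's set.
    """
    fams_by_variant: Dict[Tuple[str, tuple, str], Set[str]] = {}
    fams_by_gene: Dict[str, Set[str]] = {}
    for family, cands in candidate_variants_by_family.items():
        for cand in cands:
            rec = cand.record
            key = (rec.gene_symbol, rec.variant_id, _variant_label(rec))
            fams_by_variant.setdefault(key, set()).add(family)
            fams_by_gene.setdefault(rec.gene_symbol, set()).add(family)
    variant_level = {
        (gene, label): frozenset(fams)
        for (gene, _vid, label), fams in fams_by_variant.items()
        if len(fams) >= 2
    }
    gene_level = {
        gene: frozenset(fams) for gene, fams in fams_by_gene.items() if len(fams) >= 2
    }
    return RecurrenceReport(gene_level=gene_level, variant_level=variant_level)


def intersect_panel(
    candidate_genes: Iterable[str],
    panel: GenePanel,
    cohort_label: str = "",
) -> CrossResult:
    """Intersect a cohort's candidate genes with an interactome panel.

    The proportion is ``|overlap| / |candidates|`` (undefined — ``None``,
    not zero — for an empty candidate set).
    """
    candidates = frozenset(g.upper() for g in candidate_genes)
    overlap = candidates & panel.genes
    proportion = len(overlap) / len(candidates) if candidates else None
    return CrossResult(
        cohort_label=cohort_label,
        candidate_genes=candidates,
        panel_name=panel.name,
        overlap=overlap,
        proportion=proportion,
    )


def venn_partition(overlap_a: Iterable[str], overlap_b: Iterable[str]) -> VennPartition:
    """Partition two gene sets into private and shared components."""
    a = frozenset(g.upper() for g in overlap_a)
    b = frozenset(g.upper() for g in overlap_b)
    return VennPartition(only_a=a - b, shared=a & b, only_b=b - a)
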