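"""Core domain types for annotated variant records.

A :class:`VariantRecord` is one bi-allelic variant site together with its
per-sample genotypes, population frequency, and in-silico pathogenicity
annotations.  Multi-allelic VCF sites are split into one record per
alternate allele at read time, so every record carries exactly one ALT.

Annotations distinguish *absent* (``None``) from numeric zero: a variant
with no recorded minor allele frequency is unknown-frequency, not
frequency zero, and downstream frequency filtering treats the two
differently.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional


class Genotype(enum.Enum):
    """Diploid genotype of one sample with respect to the record's ALT."""

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


class Consequence(enum.Enum):
    """Collapsed functional consequence class of a coding variant."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_SITE = "splice_site"
    SYNONYMOUS = "synonymous"
    INTRONIC = "intronic"
    OTHER = "other"


#: Loss-of-function classes that bypass the missense predictor consensus.
LOSS_OF_FUNCTION = frozenset({Consequence.NONSENSE, Consequence.FRAMESHIFT})


class SiftCall(enum.Enum):
    DELETERIOUS = "deleterious"
    TOLERATED = "tolerated"


class PolyphenCall(enum.Enum):
    DAMAGING = "damaging"
    BENIGN = "benign"


class MutationTasterCall(enum.Enum):
    DISEASE_CAUSING = "disease_causing"
    POLYMORPHISM = "polymorphism"


class VariantValidationError(ValueError):
    """A record violates a structural invariant (coordinates, alleles, MAF)."""


@dataclass
class VariantRecord:
    """One annotated bi-allelic variant site.

    Parameters
    ----------
    chrom, pos, ref, alt
        1-based, fully closed VCF coordinates; ``ref != alt`` and exactly
        one alternate allele per record.
    rsid
        dbSNP identifier, or ``None`` when the site is unnamed.
    site_quality
        Non-negative site quality score (VCF ``QUAL``); ``None`` when the
        caller did not score the site.
    gene_symbol
        HGNC-style symbol, uppercased on construction.
    consequence
        Collapsed consequence class (one pre-resolved class per record).
    maf
        Minor allele frequency in ``[0, 1]``, or ``None`` when unknown.
    sift_call, polyphen_call, mutation_taster_call
        Categorical predictor calls; ``None`` means the predictor did not
        score the variant.
    cadd_phred
        Scaled CADD deleteriousness score, or ``None``.
    genotypes
        Mapping ``sample_id -> Genotype``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_symbol: str
    consequence: Consequence
    rsid: Optional[str] = None
    site_quality: Optional[float] = None
    maf: Optional[float] = None
    sift_call: Optional[SiftCall] = None
    polyphen_call: Optional[PolyphenCall] = None
    mutation_taster_call: Optional[MutationTasterCall] = None
    cadd_phred: Optional[float] = None
    genotypes: Mapping[str, Genotype] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantValidationError(
                f"{self.chrom}:{self.pos} position must be >= 1"
            )
        if self.ref == self.alt:
            raise VariantValidationError(
                f"{self.chrom}:{self.pos} REF and ALT are identical ({self.ref})"
            )
        if self.maf is not None and not 0.0 <= self.maf <= 1.0:
            raise VariantValidationError(
                f"{self.chrom}:{self.pos} MAF {self.maf} outside [0, 1]"
            )
        if self.site_quality is not None and self.site_quality < 0:
            raise VariantValidationError(
                f"{self.chrom}:{self.pos} negative site quality"
            )
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise VariantValidationError(
                f"{self.chrom}:{self.pos} negative CADD score"
            )
        self.gene_symbol = self.gene_symbol.upper()
        self.genotypes = dict(self.genotypes)

    @property
    def site_key(self) -> tuple:
        """``(chrom, pos, ref, alt)`` coordinate identity of the record."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def variant_id(self) -> tuple:
        """Identity used for cross-family recurrence.

        The rsid when present, else the coordinate tuple — recurrent
        variants are reported by dbSNP name where one exists.
        """
        if self.rsid is not None:
            return ("rsid", self.rsid)
        return ("site",) + self.site_key

    def genotype_of(self, sample_id: str) -> Genotype:
        try:
            return self.genotypes[sample_id]
        except KeyError:
            raise KeyError(
                f"sample {sample_id!r} has no genotype at "
                f"{self.chrom}:{self.pos} {self.ref}>{self.alt}"
            ) from None
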