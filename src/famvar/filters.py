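"""The variant prioritization cascade for dominant familial disease.

The selection model assumes autosomal dominant transmission: a causal
variant is heterozygous in every affected member of a family and absent
(homozygous reference) from intrafamilial healthy relatives.  Candidate
variants must additionally be rare (MAF < 0.05 or unknown), fall in a
retained coding/splice consequence class, pass site quality control, and
carry in-silico pathogenicity support (a disjunctive consensus over
SIFT, PolyPhen-2 and MutationTaster, with loss-of-function classes
passing unconditionally).

CADD is an annotation flag, never a filter: candidates are flagged when
their scaled CADD score reaches the threshold, but low-CADD variants are
retained.

Stage order (the funnel reported in per-stage survivor counts)::

    quality -> consequence -> cosegregation -> maf -> pathogenicity

Control individuals run the same cascade with the co-segregation stage
replaced by a single-sample zygosity restriction (heterozygous-only by
default, mirroring the family arm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .io import Pedigree
from .variants import (
    LOSS_OF_FUNCTION,
    Consequence,
    Genotype,
    MutationTasterCall,
    PolyphenCall,
    SiftCall,
    VariantRecord,
)


class SampleMismatchError(KeyError):
    """A pedigree member has no genotype in a record (sample/pedigree mismatch)."""


DEFAULT_RETAINED_CONSEQUENCES = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT,
        Consequence.INFRAME_INDEL,
        Consequence.SPLICE_SITE,
    }
)

#: Family-arm cascade stages, in application order.
FAMILY_STAGES: Tuple[str, ...] = (
    "quality",
    "consequence",
    "cosegregation",
    "maf",
    "pathogenicity",
)

#: Control-arm stages: no family to segregate in, zygosity instead.
CONTROL_STAGES: Tuple[str, ...] = (
    "quality",
    "consequence",
    "zygosity",
    "maf",
    "pathogenicity",
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the selection cascade.

    maf_threshold
        Strict upper bound on minor allele frequency (default 0.05);
        unknown frequency passes.
    min_site_quality
        Minimum trusted site quality score (default 20, inclusive);
        unscored sites fail.
    retained_consequences
        Consequence classes kept by the coding/splice filter.
    min_predictor_calls
        Deleterious calls required among SIFT / PolyPhen-2 /
        MutationTaster (default 1: an "and/or" disjunction).
    cadd_flag_threshold
        Scaled CADD score at or above which a surviving candidate is
        flagged as high-deleteriousness (default 20); a flag, not a
        filter.
    control_zygosity
        ``"het"`` (default) restricts the control arm to heterozygous
        genotypes, mirroring the family arm; ``"nonref"`` accepts any
        non-reference genotype.
    """

    maf_threshold: float = 0.05
    min_site_quality: float = 20.0
    retained_consequences: frozenset = DEFAULT_RETAINED_CONSEQUENCES
    min_predictor_calls: int = 1
    cadd_flag_threshold: float = 20.0
    control_zygosity: str = "het"

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_threshold <= 1.0:
            raise ValueError("maf_threshold must lie in (0, 1]")
        if self.min_predictor_calls < 1:
            raise ValueError("min_predictor_calls must be >= 1")
        if self.control_zygosity not in ("het", "nonref"):
            raise ValueError("control_zygosity must be 'het' or 'nonref'")
        object.__setattr__(
            self, "retained_consequences", frozenset(self.retained_consequences)
        )


DEFAULT_FILTER_CONFIG = FilterConfig()


# ---------------------------------------------------------------------------
# individual filter predicates


def passes_quality(v: VariantRecord, cfg: FilterConfig = DEFAULT_FILTER_CONFIG) -> bool:
    """Site quality at or above the threshold; unscored sites are not trusted."""
    return v.site_quality is not None and v.site_quality >= cfg.min_site_quality


def passes_consequence(v: VariantRecord, cfg: FilterConfig = DEFAULT_FILTER_CONFIG) -> bool:
    return v.consequence in cfg.retained_consequences


def cosegregates(v: VariantRecord, fam: Pedigree) -> bool:
    """Heterozygous in every affected member, absent from every unaffected one.

    Unknown-status members are ignored.  A missing genotype in an
    affected member is not a demonstrated heterozygote and fails the
    test; a pedigree member absent from the record's genotype map
    raises :class:`SampleMismatchError`.
    """
    fam.require_family_mode()
    for sample in fam.affected:
        try:
            gt = v.genotypes[sample]
        except KeyError:
            raise SampleMismatchError(
                f"affected member {sample!r} of family {fam.family_id} has no "
                f"genotype at {v.chrom}:{v.pos}"
            ) from None
        if gt is not Genotype.HET:
            return False
    for sample in fam.unaffected:
        try:
            gt = v.genotypes[sample]
        except KeyError:
            raise SampleMismatchError(
                f"unaffected member {sample!r} of family {fam.family_id} has no "
                f"genotype at {v.chrom}:{v.pos}"
            ) from None
        if gt is not Genotype.HOM_REF:
            return False
    return True


def passes_maf(v: VariantRecord, cfg: FilterConfig = DEFAULT_FILTER_CONFIG) -> bool:
    """Strictly below the frequency threshold, or frequency unknown.

    Unknown frequency passes: rare variants are often absent from
    population databases, and discarding them would bias against exactly
    the novel alleles the cascade is built to find.
    """
    return v.maf is None or v.maf < cfg.maf_threshold


def _deleterious_calls(v: VariantRecord) -> int:
    return (
        (v.sift_call is SiftCall.DELETERIOUS)
        + (v.polyphen_call is PolyphenCall.DAMAGING)
        + (v.mutation_taster_call is MutationTasterCall.DISEASE_CAUSING)
    )


def passes_pathogenicity(v: VariantRecord, cfg: FilterConfig = DEFAULT_FILTER_CONFIG) -> bool:
    """Disjunctive predictor consensus, with a loss-of-function bypass.

    Nonsense and frameshift variants pass unconditionally — the missense
    predictors do not score protein truncation, and truncating alleles
    are deleterious on first principles.
    """
    if v.consequence in LOSS_OF_FUNCTION:
        return True
    return _deleterious_calls(v) >= cfg.min_predictor_calls


def flag_cadd(v: VariantRecord, cfg: FilterConfig = DEFAULT_FILTER_CONFIG) -> bool:
    """Annotation flag: CADD present and at or above the threshold.

    Never removes a variant; low-CADD candidates survive the cascade and
    simply carry ``cadd_ge_threshold=False``.
    """
    return v.cadd_phred is not None and v.cadd_phred >= cfg.cadd_flag_threshold


def _zygosity_ok(v: VariantRecord, individual_id: str, cfg: FilterConfig) -> bool:
    gt = v.genotypes.get(individual_id, Genotype.MISSING)
    if cfg.control_zygosity == "het":
        return gt is Genotype.HET
    return gt in (Genotype.HET, Genotype.HOM_ALT)


# ---------------------------------------------------------------------------
# cascade results


@dataclass(frozen=True)
class CandidateVariant:
    """A variant surviving the cascade in one family or control individual."""

    record: VariantRecord
    unit_id: str
    filters_passed: Tuple[str, ...]
    cadd_ge_threshold: bool

    @property
    def gene_symbol(self) -> str:
        return self.record.gene_symbol


@dataclass
class CascadeResult:
    """Survivors and the per-stage audit funnel for one family/individual."""

    unit_id: str
    stages: Tuple[str, ...]
    stage_counts: Dict[str, int]
    survivors: List[CandidateVariant]

    @property
    def genes(self) -> Dict[str, List[CandidateVariant]]:
        out: Dict[str, List[CandidateVariant]] = {}
        for cand in self.survivors:
            out.setdefault(cand.gene_symbol, []).append(cand)
        return out

    @property
    def gene_set(self) -> Set[str]:
        return set(c.gene_symbol for c in self.survivors)


@dataclass
class CandidateGeneSet:
    """Candidate genes per unit (family or individual) for one cohort."""

    cohort_label: str
    unit_genes: Dict[str, Set[str]] = field(default_factory=dict)
    supporting: Dict[str, List[CandidateVariant]] = field(default_factory=dict)

    def add(self, result: CascadeResult) -> None:
        self.unit_genes[result.unit_id] = result.gene_set
        for gene, cands in result.genes.items():
            self.supporting.setdefault(gene, []).extend(cands)

    @property
    def genes(self) -> Set[str]:
        """Union of candidate genes over all units in the cohort."""
        out: Set[str] = set()
        for genes in self.unit_genes.values():
            out |= genes
        return out


def _stage_predicate(stage: str, cfg: FilterConfig, fam: Optional[Pedigree], individual_id: Optional[str]):
    if stage == "quality":
        return lambda v: passes_quality(v, cfg)
    if stage == "consequence":
        return lambda v: passes_consequence(v, cfg)
    if stage == "cosegregation":
        return lambda v: cosegregates(v, fam)
    if stage == "zygosity":
        return lambda v: _zygosity_ok(v, individual_id, cfg)
    if stage == "maf":
        return lambda v: passes_maf(v, cfg)
    if stage == "pathogenicity":
        return lambda v: passes_pathogenicity(v, cfg)
    raise ValueError(f"unknown cascade stage {stage!r}")


def _run_cascade(
    records: Iterable[VariantRecord],
    stages: Sequence[str],
    cfg: FilterConfig,
    unit_id: str,
    fam: Optional[Pedigree] = None,
    individual_id: Optional[str] = None,
) -> CascadeResult:
    surviving = list(records)
    counts: Dict[str, int] = {"input": len(surviving)}
    for stage in stages:
        pred = _stage_predicate(stage, cfg, fam, individual_id)
        surviving = [v for v in surviving if pred(v)]
        counts[stage] = len(surviving)
    candidates = [
        CandidateVariant(
            record=v,
            unit_id=unit_id,
            filters_passed=tuple(stages),
            cadd_ge_threshold=flag_cadd(v, cfg),
        )
        for v in surviving
    ]
    return CascadeResult(unit_id, tuple(stages), counts, candidates)


def run_family_cascade(
    records: Iterable[VariantRecord],
    fam: Pedigree,
    cfg: FilterConfig = DEFAULT_FILTER_CONFIG,
    stages: Sequence[str] = FAMILY_STAGES,
) -> CascadeResult:
    """Apply the family selection funnel and collapse survivors to genes.

    Returns survivors plus the count after each stage (monotone
    non-increasing).  ``stages`` may be truncated (e.g. everything up to
    co-segregation) to inspect recurrence before frequency filtering.
    """
    fam.require_family_mode()
    unknown = [s for s in stages if s not in FAMILY_STAGES]
    if unknown:
        raise ValueError(f"unknown family stage(s): {unknown}")
    return _run_cascade(records, stages, cfg, unit_id=fam.family_id, fam=fam)


def run_control_selection(
    records: Iterable[VariantRecord],
    individual_id: str,
    cfg: FilterConfig = DEFAULT_FILTER_CONFIG,
) -> CascadeResult:
    """Apply the control-arm funnel (no segregation; zygosity-restricted)."""
    return _run_cascade(
        records, CONTROL_STAGES, cfg, unit_id=individual_id, individual_id=individual_id
    )


def rejection_stage(
    v: VariantRecord,
    cfg: FilterConfig,
    fam: Optional[Pedigree] = None,
    individual_id: Optional[str] = None,
) -> Optional[str]:
    """First cascade stage that rejects ``v``, or ``None`` if it survives.

    Used by the cascade audit to compare each background variant's
    observed rejection stage with its generator tag.
    """
    stages = FAMILY_STAGES if fam is not None else CONTROL_STAGES
    for stage in stages:
        pred = _stage_predicate(stage, cfg, fam, individual_id)
        if not pred(v):
            return stage
    return None
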