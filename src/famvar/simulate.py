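"""Synthetic cohort generator with known ground truth.

Emulates the data layout of a family-based exome study of a dominant
trait: 13 multiplex families (two or three affected first-degree
relatives plus one or two unaffected members), each carrying planted
heterozygous rare deleterious coding variants shared by all affected and
absent from unaffected members, over a background of variants that each
violate at least one cascade filter by construction; plus a series of
independent control individuals with their own rare deleterious
variants.  A host-pathogen interactome panel and a gene-set library with
a planted enriched term are emitted alongside, so every pipeline stage
is testable without access to real exomes.

Every background variant carries a generator tag (VCF INFO key
``SIMTAG``) naming the cascade stage it was built to fail.  Variant
classes tagged with a site-level stage carry a segregation-consistent
genotype pattern so the tagged stage is genuinely the first failure;
the co-segregation-tagged class draws genotypes under Hardy–Weinberg
equilibrium at a common allele frequency, which makes accidental
perfect co-segregation possible but rare (such draws carry a common
frequency and benign annotations, so they can shift the rejection
stage but can never produce a false-positive candidate gene).

Outputs are deterministic given the seed: one VCF per family, one per
control individual, a cohort PED file, a panel file, a GMT library, and
a machine-readable ground-truth sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .io import (
    GenePanel,
    GeneSetLibrary,
    Pedigree,
    PhenotypeStatus,
    write_gene_panel,
    write_gmt,
    write_vcf,
)
from .variants import (
    Consequence,
    Genotype,
    MutationTasterCall,
    PolyphenCall,
    SiftCall,
    VariantRecord,
)


class SimulationPlanError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class RecurrentVariantPlan:
    """Plant one identical variant (same gene, rsid, site) in several families."""

    gene: str
    rsid: str
    families: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.families) < 2:
            raise SimulationPlanError(
                f"recurrent variant {self.rsid} needs >= 2 families"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic cohort.

    Defaults mirror the emulated study design: 13 multiplex families
    with 2–3 affected and 1–2 unaffected members, 100 control
    individuals, a 20,000-gene symbol universe, a 332-gene interactome
    panel overlapping 30 family-planted / 95 control-planted / 15 shared
    genes, seven planted recurrent variant pairs, roughly 30 planted
    genes per family and 50 per control (the per-unit candidate yield of
    a dominant-model exome screen), and 60 background variants per
    sample.
    """

    num_families: int = 13
    affected_choices: Tuple[int, ...] = (2, 3)
    unaffected_choices: Tuple[int, ...] = (1, 2)
    num_controls: int = 100
    num_genes: int = 20000
    planted_genes_per_family: int = 30
    planted_genes_per_control: int = 50
    background_variants_per_sample: int = 60
    background_stage_mix: Tuple[Tuple[str, float], ...] = (
        ("quality", 0.10),
        ("consequence", 0.20),
        ("cosegregation", 0.10),
        ("maf", 0.40),
        ("pathogenicity", 0.20),
    )
    recurrent_pairs: int = 7
    recurrent_variant_plan: Optional[Tuple[RecurrentVariantPlan, ...]] = None
    panel_size: int = 332
    panel_family_overlap: int = 30
    panel_control_overlap: int = 95
    panel_shared_overlap: int = 15
    library_terms: int = 100
    library_term_size: int = 50
    planted_term_name: str = "PLANTED_PATHWAY"
    unknown_maf_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.num_families < 1:
            raise SimulationPlanError("need at least one family")
        if any(a < 2 for a in self.affected_choices):
            raise SimulationPlanError("families need >= 2 affected members")
        if any(u < 1 for u in self.unaffected_choices):
            raise SimulationPlanError("families need >= 1 unaffected member")
        if self.panel_shared_overlap > min(
            self.panel_family_overlap, self.panel_control_overlap
        ):
            raise SimulationPlanError("shared panel overlap exceeds a cohort overlap")
        if self.panel_family_overlap > self.num_families * self.planted_genes_per_family:
            raise SimulationPlanError("panel family overlap exceeds planted genes")
        if self.panel_size < self.panel_family_overlap + (
            self.panel_control_overlap - self.panel_shared_overlap
        ):
            raise SimulationPlanError("panel too small for the requested overlaps")
        if self.num_controls > 0:
            capacity = self.num_controls * self.planted_genes_per_control
            if self.panel_control_overlap > capacity:
                raise SimulationPlanError(
                    "control panel overlap exceeds control planting capacity"
                )
        weights = dict(self.background_stage_mix)
        allowed = {"quality", "consequence", "cosegregation", "maf", "pathogenicity"}
        if set(weights) - allowed:
            raise SimulationPlanError(f"unknown background stage tag in mix: {set(weights) - allowed}")
        if abs(sum(weights.values()) - 1.0) > 1e-9:
            raise SimulationPlanError("background stage mix must sum to 1")


@dataclass
class GroundTruth:
    """Everything the generator planted, for test harnesses."""

    family_planted: Dict[str, Set[str]]
    control_planted: Dict[str, Set[str]]
    recurrent_variants: List[Tuple[str, str, Tuple[str, ...]]]
    panel_genes: Set[str]
    panel_family_overlap: Set[str]
    panel_control_overlap: Set[str]
    panel_shared_overlap: Set[str]
    planted_term: str
    background_tags: Dict[str, Dict[str, str]]

    def to_json(self) -> str:
        def _sets(d):
            return {k: sorted(v) for k, v in d.items()}

        return json.dumps(
            {
                "family_planted": _sets(self.family_planted),
                "control_planted": _sets(self.control_planted),
                "recurrent_variants": [
                    [g, r, list(f)] for g, r, f in self.recurrent_variants
                ],
                "panel_genes": sorted(self.panel_genes),
                "panel_family_overlap": sorted(self.panel_family_overlap),
                "panel_control_overlap": sorted(self.panel_control_overlap),
                "panel_shared_overlap": sorted(self.panel_shared_overlap),
                "planted_term": self.planted_term,
                "background_tags": self.background_tags,
            },
            indent=1,
            sort_keys=True,
        )

    @staticmethod
    def from_json(text: str) -> "GroundTruth":
        d = json.loads(text)
        return GroundTruth(
            family_planted={k: set(v) for k, v in d["family_planted"].items()},
            control_planted={k: set(v) for k, v in d["control_planted"].items()},
            recurrent_variants=[
                (g, r, tuple(f)) for g, r, f in d["recurrent_variants"]
            ],
            panel_genes=set(d["panel_genes"]),
            panel_family_overlap=set(d["panel_family_overlap"]),
            panel_control_overlap=set(d["panel_control_overlap"]),
            panel_shared_overlap=set(d["panel_shared_overlap"]),
            planted_term=d["planted_term"],
            background_tags=d["background_tags"],
        )


@dataclass
class SimulatedCohort:
    """Paths and in-memory objects of one simulated cohort."""

    out_dir: Path
    config: SimulationConfig
    pedigrees: List[Pedigree]
    family_vcfs: Dict[str, Path]
    control_vcfs: Dict[str, Path]
    ped_path: Path
    panel_path: Path
    gmt_path: Path
    truth_path: Path
    panel: GenePanel
    library: GeneSetLibrary
    truth: GroundTruth


# ---------------------------------------------------------------------------
# internals


def _gene_symbols(n: int) -> List[str]:
    return [f"GENE{i:05d}" for i in range(1, n + 1)]


_BASES = ("A", "C", "G", "T")


class _SiteFactory:
    """Deterministic coordinates: one locus block per gene, unique positions."""

    def __init__(self, gene_index: Mapping[str, int], rng: np.random.Generator):
        self._index = gene_index
        self._rng = rng
        self._counters: Dict[str, int] = {}

    def new_site(self, gene: str) -> Tuple[str, int, str, str]:
        gidx = self._index[gene]
        chrom = f"chr{(gidx % 22) + 1}"
        base = 100_000 + (gidx // 22) * 50_000
        count = self._counters.get(gene, 0)
        self._counters[gene] = count + 1
        ref, alt = self._rng.choice(4, size=2, replace=False)
        return chrom, base + count * 10, _BASES[ref], _BASES[alt]


def _planted_annotations(rng: np.random.Generator, unknown_maf_fraction: float):
    """Profile satisfying every cascade filter: rare, coding, deleterious."""
    consequence = Consequence(
        str(
            rng.choice(
                ["missense", "missense", "missense", "inframe_indel", "splice_site", "nonsense", "frameshift"],
            )
        )
    )
    if consequence in (Consequence.NONSENSE, Consequence.FRAMESHIFT):
        sift = polyphen = mtaster = None  # loss-of-function bypass
    else:
        sift = SiftCall.DELETERIOUS if rng.random() < 0.8 else None
        polyphen = PolyphenCall.DAMAGING if rng.random() < 0.6 else PolyphenCall.BENIGN
        mtaster = MutationTasterCall.DISEASE_CAUSING if rng.random() < 0.6 else None
        if sift is None and polyphen is not PolyphenCall.DAMAGING and mtaster is None:
            sift = SiftCall.DELETERIOUS
    maf = None if rng.random() < unknown_maf_fraction else float(rng.uniform(0.0005, 0.049))
    return dict(
        site_quality=float(rng.uniform(40, 90)),
        consequence=consequence,
        maf=maf,
        sift_call=sift,
        polyphen_call=polyphen,
        mutation_taster_call=mtaster,
        cadd_phred=float(rng.uniform(20, 35)),
    )


def _benign_predictors(rng: np.random.Generator):
    return dict(
        sift_call=SiftCall.TOLERATED if rng.random() < 0.7 else None,
        polyphen_call=PolyphenCall.BENIGN if rng.random() < 0.7 else None,
        mutation_taster_call=MutationTasterCall.POLYMORPHISM if rng.random() < 0.5 else None,
    )


def _deleterious_predictors(rng: np.random.Generator):
    preds = dict(
        sift_call=SiftCall.DELETERIOUS if rng.random() < 0.7 else None,
        polyphen_call=PolyphenCall.DAMAGING if rng.random() < 0.5 else None,
        mutation_taster_call=None,
    )
    if preds["sift_call"] is None and preds["polyphen_call"] is None:
        preds["sift_call"] = SiftCall.DELETERIOUS
    return preds


def _coseg_genotypes(affected: Sequence[str], unaffected: Sequence[str]) -> Dict[str, Genotype]:
    gts = {s: Genotype.HET for s in affected}
    gts.update({s: Genotype.HOM_REF for s in unaffected})
    return gts


def _hwe_genotypes(samples: Sequence[str], p: float, rng: np.random.Generator) -> Dict[str, Genotype]:
    q = 1.0 - p
    cut_rr, cut_het = q * q, q * q + 2 * p * q
    out = {}
    for s in samples:
        u = rng.random()
        out[s] = (
            Genotype.HOM_REF if u < cut_rr else Genotype.HET if u < cut_het else Genotype.HOM_ALT
        )
    return out


def _background_variant(
    tag: str,
    gene: str,
    sites: _SiteFactory,
    rng: np.random.Generator,
    rsid: str,
    affected: Sequence[str] = (),
    unaffected: Sequence[str] = (),
    control_id: Optional[str] = None,
) -> VariantRecord:
    """One background variant built to fail exactly the tagged stage first."""
    chrom, pos, ref, alt = sites.new_site(gene)
    samples = list(affected) + list(unaffected) if control_id is None else [control_id]
    fields: dict = dict(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        rsid=rsid,
        gene_symbol=gene,
        site_quality=float(rng.uniform(30, 90)),
        consequence=Consequence.MISSENSE,
        maf=float(rng.uniform(0.05, 0.5)) if rng.random() < 0.8 else float(rng.uniform(0.001, 0.049)),
        cadd_phred=float(rng.uniform(0, 19)),
    )
    fields.update(_benign_predictors(rng))
    if control_id is None:
        fields["genotypes"] = _coseg_genotypes(affected, unaffected)
    else:
        fields["genotypes"] = {control_id: Genotype.HET}

    if tag == "quality":
        fields["site_quality"] = float(rng.uniform(2, 19.5))
    elif tag == "consequence":
        fields["consequence"] = Consequence(str(rng.choice(["synonymous", "intronic", "other"])))
    elif tag == "cosegregation":
        maf = float(rng.uniform(0.05, 0.5))
        fields["maf"] = maf  # common + benign backstop: can never survive
        fields["genotypes"] = _hwe_genotypes(samples, maf, rng)
    elif tag == "zygosity":
        maf = float(rng.uniform(0.05, 0.5))
        fields["maf"] = maf
        fields["genotypes"] = {control_id: Genotype.HOM_ALT if rng.random() < 0.5 else Genotype.HOM_REF}
    elif tag == "maf":
        fields["maf"] = float(rng.uniform(0.05, 0.5))
        fields.update(_deleterious_predictors(rng))
    elif tag == "pathogenicity":
        fields["maf"] = float(rng.uniform(0.001, 0.049))
        fields["sift_call"] = SiftCall.TOLERATED
        fields["polyphen_call"] = PolyphenCall.BENIGN if rng.random() < 0.8 else None
        fields["mutation_taster_call"] = None
    else:
        raise SimulationPlanError(f"unknown background tag {tag!r}")
    return VariantRecord(**fields)


# ---------------------------------------------------------------------------
# public operations


def simulate_cohort(cfg: SimulationConfig, out_dir) -> SimulatedCohort:
    """Generate the full synthetic cohort and write it under ``out_dir``.

    Emits one VCF per family and per control individual, a cohort PED
    file, the interactome panel, the gene-set library (GMT), and a
    ground-truth JSON sidecar.  Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_symbols(cfg.num_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    sites = _SiteFactory(gene_index, rng)
    rs_counter = iter(range(1, 10_000_000))

    def next_rsid() -> str:
        return f"rsS{next(rs_counter):06d}"

    # -- pedigrees ---------------------------------------------------------
    pedigrees: List[Pedigree] = []
    for f in range(1, cfg.num_families + 1):
        fam_id = f"F{f:02d}"
        n_aff = int(rng.choice(cfg.affected_choices))
        n_un = int(rng.choice(cfg.unaffected_choices))
        members = [(f"{fam_id}A{i}", PhenotypeStatus.AFFECTED) for i in range(1, n_aff + 1)]
        members += [(f"{fam_id}U{i}", PhenotypeStatus.UNAFFECTED) for i in range(1, n_un + 1)]
        pedigrees.append(Pedigree(fam_id, tuple(members)))
    family_ids = [p.family_id for p in pedigrees]
    control_ids = [f"C{c:03d}" for c in range(1, cfg.num_controls + 1)]

    # -- recurrent variant plan -------------------------------------------
    free_genes = list(genes)
    rng.shuffle(free_genes)
    free_iter = iter(free_genes)

    if cfg.recurrent_variant_plan is not None:
        plan = list(cfg.recurrent_variant_plan)
        for item in plan:
            unknown = [f for f in item.families if f not in family_ids]
            if unknown:
                raise SimulationPlanError(
                    f"recurrent plan references nonexistent families: {unknown}"
                )
        planned_genes = {item.gene for item in plan}
        free_iter = iter([g for g in free_genes if g not in planned_genes])
    else:
        plan = []
        if cfg.num_families >= 2:
            for _ in range(cfg.recurrent_pairs):
                pair = rng.choice(len(family_ids), size=2, replace=False)
                plan.append(
                    RecurrentVariantPlan(
                        gene=next(free_iter),
                        rsid=next_rsid(),
                        families=tuple(family_ids[i] for i in sorted(pair)),
                    )
                )

    # -- planted gene assignment ------------------------------------------
    family_planted: Dict[str, Set[str]] = {f: set() for f in family_ids}
    for item in plan:
        for fam in item.families:
            family_planted[fam].add(item.gene)
    for fam in family_ids:
        while len(family_planted[fam]) < cfg.planted_genes_per_family:
            family_planted[fam].add(next(free_iter))
    family_pool = sorted(set().union(*family_planted.values())) if family_ids else []

    # -- panel construction ------------------------------------------------
    panel_family = sorted(
        rng.choice(family_pool, size=min(cfg.panel_family_overlap, len(family_pool)), replace=False).tolist()
    )
    panel_shared = sorted(
        rng.choice(panel_family, size=min(cfg.panel_shared_overlap, len(panel_family)), replace=False).tolist()
    )
    n_control_only = cfg.panel_control_overlap - len(panel_shared)
    panel_control_only = [next(free_iter) for _ in range(n_control_only)]
    n_filler = cfg.panel_size - len(panel_family) - len(panel_control_only)
    panel_filler = [next(free_iter) for _ in range(n_filler)]
    panel = GenePanel.from_symbols(
        "interactome_panel", panel_family + panel_control_only + panel_filler
    )
    panel_control = sorted(panel_shared + panel_control_only)

    # -- control planted genes --------------------------------------------
    control_planted: Dict[str, Set[str]] = {c: set() for c in control_ids}
    if control_ids:
        for gene in panel_control:
            control_planted[control_ids[int(rng.integers(len(control_ids)))]].add(gene)
        for cid in control_ids:
            while len(control_planted[cid]) < cfg.planted_genes_per_control:
                control_planted[cid].add(next(free_iter))

    # -- gene-set library ---------------------------------------------------
    planted_term_genes = list(panel_family)
    pad_pool = [g for g in family_pool if g not in set(panel_family)]
    while len(planted_term_genes) < cfg.library_term_size and pad_pool:
        planted_term_genes.append(pad_pool.pop(0))
    terms: Dict[str, frozenset] = {cfg.planted_term_name: frozenset(planted_term_genes)}
    for t in range(1, cfg.library_terms):
        members = rng.choice(cfg.num_genes, size=cfg.library_term_size, replace=False)
        terms[f"TERM{t:04d}"] = frozenset(genes[i] for i in members)
    library = GeneSetLibrary("simulated_library", terms, background_size=cfg.num_genes)

    # -- variants -----------------------------------------------------------
    stage_names = [s for s, _ in cfg.background_stage_mix]
    stage_weights = np.array([w for _, w in cfg.background_stage_mix])
    background_pool = [
        g for g in genes if g not in set(family_pool) and g not in panel.genes
    ]
    recurrent_records: Dict[Tuple[str, str], VariantRecord] = {}
    truth_tags: Dict[str, Dict[str, str]] = {}

    family_vcfs: Dict[str, Path] = {}
    for ped in pedigrees:
        fam = ped.family_id
        records: List[VariantRecord] = []
        extra_info: Dict[tuple, Dict[str, str]] = {}
        tags: Dict[str, str] = {}
        planted_here = sorted(family_planted[fam])
        recurrent_here = {item.gene: item for item in plan if fam in item.families}
        for gene in planted_here:
            if gene in recurrent_here:
                item = recurrent_here[gene]
                proto = recurrent_records.get((item.gene, item.rsid))
                if proto is None:
                    chrom, pos, ref, alt = sites.new_site(gene)
                    proto = VariantRecord(
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        rsid=item.rsid,
                        gene_symbol=gene,
                        genotypes={},
                        **_planted_annotations(rng, cfg.unknown_maf_fraction),
                    )
                    recurrent_records[(item.gene, item.rsid)] = proto
                rec = VariantRecord(
                    chrom=proto.chrom,
                    pos=proto.pos,
                    ref=proto.ref,
                    alt=proto.alt,
                    rsid=proto.rsid,
                    gene_symbol=proto.gene_symbol,
                    site_quality=proto.site_quality,
                    consequence=proto.consequence,
                    maf=proto.maf,
                    sift_call=proto.sift_call,
                    polyphen_call=proto.polyphen_call,
                    mutation_taster_call=proto.mutation_taster_call,
                    cadd_phred=proto.cadd_phred,
                    genotypes=_coseg_genotypes(ped.affected, ped.unaffected),
                )
            else:
                chrom, pos, ref, alt = sites.new_site(gene)
                rec = VariantRecord(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    rsid=next_rsid(),
                    gene_symbol=gene,
                    genotypes=_coseg_genotypes(ped.affected, ped.unaffected),
                    **_planted_annotations(rng, cfg.unknown_maf_fraction),
                )
            records.append(rec)
        for _ in range(cfg.background_variants_per_sample):
            tag = stage_names[int(rng.choice(len(stage_names), p=stage_weights))]
            gene = background_pool[int(rng.integers(len(background_pool)))]
            rec = _background_variant(
                tag,
                gene,
                sites,
                rng,
                rsid=next_rsid(),
                affected=ped.affected,
                unaffected=ped.unaffected,
            )
            records.append(rec)
            extra_info[rec.site_key] = {"SIMTAG": tag}
            tags[f"{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alt}"] = tag
        path = out_dir / f"family_{fam}.vcf"
        write_vcf(records, path, sample_ids=list(ped.sample_ids), extra_info=extra_info)
        family_vcfs[fam] = path
        truth_tags[fam] = tags

    control_vcfs: Dict[str, Path] = {}
    for cid in control_ids:
        records = []
        extra_info = {}
        tags = {}
        for gene in sorted(control_planted[cid]):
            chrom, pos, ref, alt = sites.new_site(gene)
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    rsid=next_rsid(),
                    gene_symbol=gene,
                    genotypes={cid: Genotype.HET},
                    **_planted_annotations(rng, cfg.unknown_maf_fraction),
                )
            )
        for _ in range(cfg.background_variants_per_sample):
            tag = stage_names[int(rng.choice(len(stage_names), p=stage_weights))]
            tag = "zygosity" if tag == "cosegregation" else tag
            gene = background_pool[int(rng.integers(len(background_pool)))]
            rec = _background_variant(
                tag, gene, sites, rng, rsid=next_rsid(), control_id=cid
            )
            records.append(rec)
            extra_info[rec.site_key] = {"SIMTAG": tag}
            tags[f"{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alt}"] = tag
        path = out_dir / f"control_{cid}.vcf"
        write_vcf(records, path, sample_ids=[cid], extra_info=extra_info)
        control_vcfs[cid] = path
        truth_tags[cid] = tags

    # -- sidecar files ------------------------------------------------------
    ped_path = out_dir / "cohort.ped"
    with open(ped_path, "w") as fh:
        for ped in pedigrees:
            for sample, status in ped.members:
                code = {"affected": "2", "unaffected": "1", "unknown": "0"}[status.value]
                fh.write(f"{ped.family_id}\t{sample}\t0\t0\t0\t{code}\n")
    panel_path = out_dir / "panel.txt"
    write_gene_panel(panel, panel_path)
    gmt_path = out_dir / "library.gmt"
    write_gmt(library, gmt_path)

    truth = GroundTruth(
        family_planted=family_planted,
        control_planted=control_planted,
        recurrent_variants=[(i.gene, i.rsid, i.families) for i in plan],
        panel_genes=set(panel.genes),
        panel_family_overlap=set(panel_family),
        panel_control_overlap=set(panel_control),
        panel_shared_overlap=set(panel_shared),
        planted_term=cfg.planted_term_name,
        background_tags=truth_tags,
    )
    truth_path = out_dir / "ground_truth.json"
    truth_path.write_text(truth.to_json())

    return SimulatedCohort(
        out_dir=out_dir,
        config=cfg,
        pedigrees=pedigrees,
        family_vcfs=family_vcfs,
        control_vcfs=control_vcfs,
        ped_path=ped_path,
        panel_path=panel_path,
        gmt_path=gmt_path,
        truth_path=truth_path,
        panel=panel,
        library=library,
        truth=truth,
    )


def simulate_null_query(library: GeneSetLibrary, list_size: int, seed: int) -> List[str]:
    """Uniform random gene list (without replacement) from the library universe."""
    universe = sorted(library.universe)
    if list_size > len(universe):
        raise SimulationPlanError(
            f"list_size {list_size} exceeds the {len(universe)}-gene universe"
        )
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(universe), size=list_size, replace=False)
    return [universe[i] for i in picks]


def build_exchangeable_library(
    num_terms: int,
    term_size: int,
    universe_size: int,
    seed: int,
    name: str = "exchangeable_library",
) -> GeneSetLibrary:
    """Library of identically-sized, exchangeable (i.i.d. random) terms.

    Used for null calibration studies: every term is a uniform random
    ``term_size``-gene subset of the same universe, so all terms share
    one null rank distribution by symmetry.  The background size equals
    the universe size.
    """
    genes = _gene_symbols(universe_size)
    rng = np.random.default_rng(seed)
    terms = {}
    for t in range(num_terms):
        members = rng.choice(universe_size, size=term_size, replace=False)
        terms[f"XTERM{t:04d}"] = frozenset(genes[i] for i in members)
    # all universe genes must be coverable by the background
    return GeneSetLibrary(name, terms, background_size=universe_size)
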