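"""Readers and writers for the pipeline's plain-text formats.

VCF parsing is backed by :mod:`cyvcf2`; pedigrees (6-column PED), gene
panels (one symbol per line), GMT gene-set libraries, the packaged
interactome panel table, and TSV result tables are small line formats
read and written directly.

Annotations are read from the VCF INFO field under configurable key
names (see :class:`InfoKeys`).  A missing key maps to ``None`` —
"absent" is semantically distinct from zero, because a variant with
unknown frequency must still pass the frequency filter.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .variants import (
    Consequence,
    Genotype,
    MutationTasterCall,
    PolyphenCall,
    SiftCall,
    VariantRecord,
)


class VcfParseError(ValueError):
    """The VCF could not be parsed or carries inconsistent annotations."""


class ConfigurationError(ValueError):
    """A requested sample or option does not match the input files."""


class PedigreeError(ValueError):
    """A PED file violates pedigree invariants."""


class LibraryError(ValueError):
    """A gene-set library violates container invariants."""


class PanelTableError(ValueError):
    """The interactome panel annotation table is malformed."""


# ---------------------------------------------------------------------------
# pedigrees


class PhenotypeStatus(enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Pedigree:
    """One family: sample ids with affected/unaffected status.

    Unknown-status members are retained in ``members`` but belong to
    neither the affected nor the unaffected set, so they are ignored by
    co-segregation logic.
    """

    family_id: str
    members: Tuple[Tuple[str, PhenotypeStatus], ...]

    def __post_init__(self) -> None:
        seen: Set[str] = set()
        for sample_id, _ in self.members:
            if sample_id in seen:
                raise PedigreeError(
                    f"family {self.family_id}: duplicate sample {sample_id!r}"
                )
            seen.add(sample_id)

    @property
    def affected(self) -> Tuple[str, ...]:
        return tuple(s for s, st in self.members if st is PhenotypeStatus.AFFECTED)

    @property
    def unaffected(self) -> Tuple[str, ...]:
        return tuple(s for s, st in self.members if st is PhenotypeStatus.UNAFFECTED)

    @property
    def sample_ids(self) -> Tuple[str, ...]:
        return tuple(s for s, _ in self.members)

    def require_family_mode(self) -> None:
        """Validate the >= 2 affected members precondition of family mode."""
        if len(self.affected) < 2:
            raise PedigreeError(
                f"family {self.family_id} has {len(self.affected)} affected "
                "member(s); family mode requires at least two"
            )


_PED_PHENOTYPES = {
    "2": PhenotypeStatus.AFFECTED,
    "1": PhenotypeStatus.UNAFFECTED,
    "0": PhenotypeStatus.UNKNOWN,
    "-9": PhenotypeStatus.UNKNOWN,
}


def read_ped(path) -> List[Pedigree]:
    """Read a 6-column whitespace-delimited PED file into pedigrees.

    Column layout: family, individual, father, mother, sex, phenotype
    (2 = affected, 1 = unaffected, 0 or -9 = unknown).
    """
    members: Dict[str, List[Tuple[str, PhenotypeStatus]]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < 6:
            raise PedigreeError(f"{path}:{lineno}: expected 6 PED columns, got {len(cols)}")
        fam, sample = cols[0], cols[1]
        pheno = cols[5]
        if pheno not in _PED_PHENOTYPES:
            raise PedigreeError(f"{path}:{lineno}: unrecognized phenotype code {pheno!r}")
        members.setdefault(fam, []).append((sample, _PED_PHENOTYPES[pheno]))
    return [Pedigree(fam, tuple(mem)) for fam, mem in members.items()]


# ---------------------------------------------------------------------------
# gene panels


@dataclass(frozen=True)
class GenePanel:
    """A named set of gene symbols (uppercased, deduplicated)."""

    name: str
    genes: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise LibraryError(f"panel {self.name!r} is empty")
        if any(not g for g in self.genes):
            raise LibraryError(f"panel {self.name!r} contains an empty symbol")

    @staticmethod
    def from_symbols(name: str, symbols: Iterable[str]) -> "GenePanel":
        return GenePanel(name, frozenset(s.strip().upper() for s in symbols if s.strip()))


def read_gene_panel(path, name: Optional[str] = None) -> GenePanel:
    """Read a plain-text panel: one symbol per line, ``#`` comments allowed."""
    path = Path(path)
    symbols = []
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            symbols.append(line)
    return GenePanel.from_symbols(name or path.stem, symbols)


def write_gene_panel(panel: GenePanel, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(panel.genes)))


# ---------------------------------------------------------------------------
# gene-set libraries (GMT)


@dataclass(frozen=True)
class GeneSetLibrary:
    """Named terms mapping to gene sets over a stated background universe.

    ``background_size`` is the universe size N used in the Fisher
    contingency table; it must cover at least the union of all term gene
    sets.
    """

    name: str
    terms: Mapping[str, FrozenSet[str]]
    background_size: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", dict(self.terms))
        if not self.terms:
            raise LibraryError(f"library {self.name!r} has no terms")
        for term, genes in self.terms.items():
            if not genes:
                raise LibraryError(f"library {self.name!r}: term {term!r} has no genes")
        if self.background_size < len(self.universe):
            raise LibraryError(
                f"library {self.name!r}: background_size {self.background_size} "
                f"smaller than the {len(self.universe)}-gene union of its terms"
            )

    @property
    def universe(self) -> FrozenSet[str]:
        out: Set[str] = set()
        for genes in self.terms.values():
            out |= genes
        return frozenset(out)


def read_gmt(path, background_size: int, name: Optional[str] = None) -> GeneSetLibrary:
    """Read a tab-delimited GMT library (term, description, genes...).

    Gene symbols are uppercased and deduplicated within a term; a term
    with zero genes or a duplicated term name is an error.
    """
    path = Path(path)
    terms: Dict[str, FrozenSet[str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) < 3:
            raise LibraryError(f"{path}:{lineno}: GMT line needs term, description, genes")
        term = cols[0].strip()
        if term in terms:
            raise LibraryError(f"{path}:{lineno}: duplicate term {term!r} (ambiguous library)")
        genes = frozenset(g.strip().upper() for g in cols[2:] if g.strip())
        if not genes:
            raise LibraryError(f"{path}:{lineno}: term {term!r} has zero genes")
        terms[term] = genes
    return GeneSetLibrary(name or path.stem, terms, background_size)


def write_gmt(library: GeneSetLibrary, path) -> None:
    with open(path, "w") as fh:
        for term in library.terms:
            genes = "\t".join(sorted(library.terms[term]))
            fh.write(f"{term}\tna\t{genes}\n")


# ---------------------------------------------------------------------------
# interactome panel annotation table


class Cohort(enum.Enum):
    F_SARC = "F-SARC"
    CONTROL = "Control"


@dataclass(frozen=True)
class PanelGeneAnnotation:
    """One interactome panel gene: symbol, viral bait protein, cohorts."""

    gene_symbol: str
    viral_bait: str
    cohorts: FrozenSet[Cohort]

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise PanelTableError(f"{self.gene_symbol}: empty cohort set")


_COHORT_FLAGS = {
    "F-SARC + Control": frozenset({Cohort.F_SARC, Cohort.CONTROL}),
    "F-SARC": frozenset({Cohort.F_SARC}),
    "CTRL": frozenset({Cohort.CONTROL}),
}

#: Symbol spelling harmonisation applied on panel-table ingest.  TYSND1
#: circulates under a transposed spelling in some published gene lists,
#: so matching must be normalization-tolerant.
SYMBOL_ALIASES = {"TYSDN1": "TYSND1"}


def read_panel_table(path) -> List[PanelGeneAnnotation]:
    """Read a tab-separated panel annotation table (gene, bait, cohort flag).

    Cohort flags: ``F-SARC + Control``, ``F-SARC``, or ``CTRL``; anything
    else is an error.  Symbols are uppercased and alias-normalized.
    """
    rows: List[PanelGeneAnnotation] = []
    seen: Set[str] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 3:
            raise PanelTableError(f"{path}:{lineno}: expected 3 columns, got {len(cols)}")
        gene, bait, flag = (c.strip() for c in cols)
        gene = gene.upper()
        gene = SYMBOL_ALIASES.get(gene, gene)
        if flag not in _COHORT_FLAGS:
            raise PanelTableError(f"{path}:{lineno}: unrecognized cohort flag {flag!r}")
        if gene in seen:
            raise PanelTableError(f"{path}:{lineno}: duplicate panel gene {gene!r}")
        seen.add(gene)
        rows.append(PanelGeneAnnotation(gene, bait, _COHORT_FLAGS[flag]))
    return rows


# ---------------------------------------------------------------------------
# VCF


@dataclass(frozen=True)
class InfoKeys:
    """INFO key names under which annotations are stored in the VCF."""

    gene: str = "GENE"
    consequence: str = "CSQCLASS"
    maf: str = "MAF"
    sift: str = "SIFT"
    polyphen: str = "POLYPHEN"
    mutation_taster: str = "MTASTER"
    cadd: str = "CADD"


DEFAULT_INFO_KEYS = InfoKeys()

_CONSEQUENCE_BY_VALUE = {c.value: c for c in Consequence}
_SIFT_BY_VALUE = {c.value: c for c in SiftCall}
_POLYPHEN_BY_VALUE = {c.value: c for c in PolyphenCall}
_MTASTER_BY_VALUE = {c.value: c for c in MutationTasterCall}


def _decode(value):
    if isinstance(value, bytes):
        return value.decode()
    return value


def _parse_call(value, table, path, what):
    if value is None:
        return None
    value = str(_decode(value))
    try:
        return table[value]
    except KeyError:
        raise VcfParseError(f"{path}: unrecognized {what} call {value!r}") from None


def read_vcf(
    path,
    sample_ids: Optional[Sequence[str]] = None,
    info_keys: InfoKeys = DEFAULT_INFO_KEYS,
) -> List[VariantRecord]:
    """Read an annotated VCF into :class:`VariantRecord` objects.

    Multi-allelic sites are emitted as one record per alternate allele;
    each sample's genotype is classified with respect to that allele
    (phasing is discarded, so ``0|1`` and ``0/1`` both map to het).
    Absent annotation keys map to ``None``, never to zero.

    Parameters
    ----------
    sample_ids
        Optional subset of samples to load; a requested sample missing
        from the VCF header is a :class:`ConfigurationError`.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path, gts012=False, strict_gt=False)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad files
        raise VcfParseError(f"{path}: cannot open VCF: {exc}") from exc
    try:
        if sample_ids is not None:
            missing = [s for s in sample_ids if s not in vcf.samples]
            if missing:
                raise ConfigurationError(
                    f"{path}: requested sample(s) absent from VCF header: "
                    + ", ".join(missing)
                )
            vcf.set_samples(list(sample_ids))
        samples = list(vcf.samples)
        records: List[VariantRecord] = []
        for var in vcf:
            records.extend(_split_site(var, samples, info_keys, path))
        return records
    except (VcfParseError, ConfigurationError):
        raise
    except Exception as exc:
        raise VcfParseError(f"{path}: malformed VCF record: {exc}") from exc
    finally:
        vcf.close()


def _split_site(var, samples, info_keys: InfoKeys, path: str) -> List[VariantRecord]:
    info = var.INFO
    gene = info.get(info_keys.gene)
    if gene is None:
        raise VcfParseError(
            f"{path}: {var.CHROM}:{var.POS} lacks the {info_keys.gene} INFO key"
        )
    csq_raw = info.get(info_keys.consequence)
    if csq_raw is None:
        consequence = Consequence.OTHER
    else:
        csq_raw = str(_decode(csq_raw))
        if csq_raw not in _CONSEQUENCE_BY_VALUE:
            raise VcfParseError(
                f"{path}: {var.CHROM}:{var.POS} unrecognized consequence {csq_raw!r}"
            )
        consequence = _CONSEQUENCE_BY_VALUE[csq_raw]
    maf = info.get(info_keys.maf)
    cadd = info.get(info_keys.cadd)
    sift = _parse_call(info.get(info_keys.sift), _SIFT_BY_VALUE, path, "SIFT")
    polyphen = _parse_call(info.get(info_keys.polyphen), _POLYPHEN_BY_VALUE, path, "PolyPhen")
    mtaster = _parse_call(
        info.get(info_keys.mutation_taster), _MTASTER_BY_VALUE, path, "MutationTaster"
    )
    rsid = var.ID if var.ID not in (None, ".", "") else None
    qual = var.QUAL  # None when '.'
    genotype_rows = var.genotypes  # [[a0, a1, phased], ...]

    out = []
    for alt_index, alt in enumerate(var.ALT, start=1):
        genotypes: Dict[str, Genotype] = {}
        for sample, row in zip(samples, genotype_rows):
            alleles = [a for a in row[:-1]]
            if any(a < 0 for a in alleles) or not alleles:
                genotypes[sample] = Genotype.MISSING
                continue
            dose = sum(1 for a in alleles if a == alt_index)
            if dose == 0:
                genotypes[sample] = Genotype.HOM_REF
            elif dose == len(alleles):
                genotypes[sample] = Genotype.HOM_ALT
            else:
                genotypes[sample] = Genotype.HET
        out.append(
            VariantRecord(
                chrom=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alt=alt,
                rsid=rsid,
                site_quality=float(qual) if qual is not None else None,
                gene_symbol=str(gene),
                consequence=consequence,
                maf=float(maf) if maf is not None else None,
                sift_call=sift,
                polyphen_call=polyphen,
                mutation_taster_call=mtaster,
                cadd_phred=float(cadd) if cadd is not None else None,
                genotypes=genotypes,
            )
        )
    return out


_VCF_GT = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}

_VCF_HEADER_TEMPLATE = """\
##fileformat=VCFv4.2
##INFO=<ID={gene},Number=1,Type=String,Description="Gene symbol">
##INFO=<ID={consequence},Number=1,Type=String,Description="Collapsed consequence class">
##INFO=<ID={maf},Number=1,Type=Float,Description="Minor allele frequency">
##INFO=<ID={sift},Number=1,Type=String,Description="SIFT call">
##INFO=<ID={polyphen},Number=1,Type=String,Description="PolyPhen-2 call">
##INFO=<ID={mutation_taster},Number=1,Type=String,Description="MutationTaster call">
##INFO=<ID={cadd},Number=1,Type=Float,Description="CADD PHRED score">
##INFO=<ID=SIMTAG,Number=1,Type=String,Description="Synthetic generator tag: cascade filter violated by construction">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_KNOWN_CONTIGS = tuple(f"chr{i}" for i in range(1, 23)) + tuple(str(i) for i in range(1, 23)) + ("chrX", "chrY", "X", "Y")


def write_vcf(
    records: Sequence[VariantRecord],
    path,
    sample_ids: Optional[Sequence[str]] = None,
    info_keys: InfoKeys = DEFAULT_INFO_KEYS,
    extra_info: Optional[Mapping[tuple, Mapping[str, str]]] = None,
) -> None:
    """Write records as an uncompressed VCF v4.2 file.

    All records must carry genotypes for the same sample set; the sample
    column order is ``sample_ids`` when given, else sorted.  Records are
    written in coordinate order.  ``extra_info`` may attach additional
    INFO entries (e.g. generator tags) keyed by record ``site_key``.
    """
    if sample_ids is None:
        all_samples: Set[str] = set()
        for rec in records:
            all_samples.update(rec.genotypes)
        sample_ids = sorted(all_samples)
    def _chrom_rank(chrom: str):
        stem = chrom[3:] if chrom.startswith("chr") else chrom
        return (0, int(stem)) if stem.isdigit() else (1, stem)

    lines = [_VCF_HEADER_TEMPLATE.format(**vars(info_keys))]
    contigs = sorted({r.chrom for r in records} | set(_KNOWN_CONTIGS), key=_chrom_rank)
    lines.extend(f"##contig=<ID={c}>\n" for c in contigs)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids) + "\n")

    for rec in sorted(records, key=lambda r: (_chrom_rank(r.chrom), r.pos, r.ref, r.alt)):
        info_parts = [f"{info_keys.gene}={rec.gene_symbol}"]
        info_parts.append(f"{info_keys.consequence}={rec.consequence.value}")
        if rec.maf is not None:
            info_parts.append(f"{info_keys.maf}={rec.maf:.6g}")
        if rec.sift_call is not None:
            info_parts.append(f"{info_keys.sift}={rec.sift_call.value}")
        if rec.polyphen_call is not None:
            info_parts.append(f"{info_keys.polyphen}={rec.polyphen_call.value}")
        if rec.mutation_taster_call is not None:
            info_parts.append(f"{info_keys.mutation_taster}={rec.mutation_taster_call.value}")
        if rec.cadd_phred is not None:
            info_parts.append(f"{info_keys.cadd}={rec.cadd_phred:.6g}")
        if extra_info and rec.site_key in extra_info:
            for key, value in extra_info[rec.site_key].items():
                info_parts.append(f"{key}={value}")
        gts = "\t".join(_VCF_GT[rec.genotypes.get(s, Genotype.MISSING)] for s in sample_ids)
        qual = f"{rec.site_quality:.6g}" if rec.site_quality is not None else "."
        lines.append(
            f"{rec.chrom}\t{rec.pos}\t{rec.rsid or '.'}\t{rec.ref}\t{rec.alt}\t"
            f"{qual}\t.\t{';'.join(info_parts)}\tGT\t{gts}\n"
        )
    Path(path).write_text("".join(lines))


# ---------------------------------------------------------------------------
# result tables

#: Stable column order for enrichment result tables.
RESULT_COLUMNS = (
    "term",
    "k",
    "n",
    "K",
    "N",
    "p_fisher",
    "observed_rank",
    "z",
    "combined_score",
    "p_adjusted",
    "genes",
)


def write_results(results, path) -> None:
    """Write enrichment results as a TSV with a stable column order.

    Rows are ordered by combined score descending, ties broken
    alphabetically by term name; floats carry 9 significant digits.
    """
    rows = sorted(results, key=lambda r: (-r.combined_score, r.term))
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.term,
                        str(r.k),
                        str(r.n),
                        str(r.K),
                        str(r.N),
                        f"{r.p_fisher:.9g}",
                        f"{r.observed_rank:.9g}",
                        f"{r.z:.9g}",
                        f"{r.combined_score:.9g}",
                        f"{r.p_adjusted:.9g}",
                        ",".join(r.overlap_genes),
                    ]
                )
                + "\n"
            )
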