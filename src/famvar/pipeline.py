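"""Orchestration: simulate -> filter -> cross -> enrich as one reproducible run.

A run is driven by a single config mapping (usually loaded from YAML)
with per-stage blocks; every reported number in the summary is
recomputable from the manifest's recorded inputs, config snapshot and
seeds.  Partial outputs are retained on failure, with the failing stage
named in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from . import __version__
from .cross import (
    find_recurrent_genes,
    find_recurrent_variants,
    intersect_panel,
    venn_partition,
)
from .enrich import calibrate_ranks, enrich
from .filters import (
    FAMILY_STAGES,
    CandidateGeneSet,
    CascadeResult,
    FilterConfig,
    run_control_selection,
    run_family_cascade,
)
from .io import (
    Cohort,
    GenePanel,
    GeneSetLibrary,
    PanelGeneAnnotation,
    Pedigree,
    read_gene_panel,
    read_gmt,
    read_panel_table,
    read_ped,
    read_vcf,
    write_results,
)
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

_FIXTURE_NAME = "fsarc_cov_panel.tsv"
_FIXTURE_ROWS = 31


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is recorded in the manifest."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


class FixtureError(RuntimeError):
    """The packaged panel annotation fixture is corrupted."""


def load_panel_annotations() -> List[PanelGeneAnnotation]:
    """Load the packaged interactome cohort panel annotation table.

    The table lists, for each host-interactome gene observed in the
    familial or control cohort, the SARS-CoV-2 bait protein and the
    cohort(s) it was identified in.
    """
    ref = resources.files("famvar.data").joinpath(_FIXTURE_NAME)
    with resources.as_file(ref) as path:
        rows = read_panel_table(path)
    if len(rows) != _FIXTURE_ROWS:
        raise FixtureError(
            f"panel fixture has {len(rows)} rows, expected {_FIXTURE_ROWS}"
        )
    return rows


def cohort_genes(rows: Sequence[PanelGeneAnnotation], cohort: Cohort) -> Set[str]:
    """Panel genes annotated to one cohort."""
    return {r.gene_symbol for r in rows if cohort in r.cohorts}


def bait_genes(rows: Sequence[PanelGeneAnnotation], bait: str) -> Set[str]:
    """Panel genes whose product is bound by the given viral bait protein."""
    return {r.gene_symbol for r in rows if r.viral_bait.upper() == bait.upper()}


# ---------------------------------------------------------------------------
# manifest


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    version: str
    seed: Optional[int]
    config: dict
    input_digests: Dict[str, str] = field(default_factory=dict)
    stage_status: Dict[str, str] = field(default_factory=dict)
    stage_counts: Dict[str, Dict[str, int]] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    outputs: Dict[str, str] = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def match_pedigree(samples: Sequence[str], pedigrees: Sequence[Pedigree]) -> Pedigree:
    """Find the pedigree whose members are exactly the VCF's samples."""
    sset = set(samples)
    for ped in pedigrees:
        if set(ped.sample_ids) <= sset:
            return ped
    raise PipelineError(
        "filter", f"no pedigree matches VCF samples {sorted(sset)[:5]}..."
    )


# ---------------------------------------------------------------------------
# run_all


def run_all(config: Mapping, out_dir, seed: Optional[int] = None) -> RunManifest:
    """Execute the full chain described by ``config`` and write reports.

    Config blocks (all optional except one of ``simulate``/``inputs``)::

        simulate: {...}            # SimulationConfig fields
        inputs:
          family_vcfs: [...]
          ped: cohort.ped
          control_vcfs: [...]
          panel: panel.txt
          library: {gmt: library.gmt, background_size: 20000}
        filters: {...}             # FilterConfig fields
        cross: {min_families: 2, pre_maf_recurrence: false}
        enrich: {permutations: 1000, top_n: 10}

    ``seed`` overrides ``simulate.seed`` and seeds the rank calibration.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = dict(config)
    manifest = RunManifest(version=__version__, seed=seed, config=_jsonable(config))
    manifest_path = out_dir / "manifest.json"
    try:
        _run_stages(config, out_dir, seed, manifest)
    except PipelineError as exc:
        manifest.stage_status[exc.stage] = "failed"
        manifest.write(manifest_path)
        raise
    manifest.write(manifest_path)
    manifest.outputs["manifest"] = str(manifest_path)
    return manifest


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _run_stages(config, out_dir, seed, manifest: RunManifest) -> None:
    # ---- stage: simulate -------------------------------------------------
    if "simulate" in config:
        try:
            sim_kwargs = dict(config["simulate"])
            if seed is not None:
                sim_kwargs["seed"] = seed
            sim_cfg = SimulationConfig(**sim_kwargs)
            cohort = simulate_cohort(sim_cfg, out_dir / "simulated")
        except Exception as exc:
            raise PipelineError("simulate", str(exc)) from exc
        manifest.stage_status["simulate"] = "ok"
        family_vcfs = list(cohort.family_vcfs.values())
        ped_path = cohort.ped_path
        control_vcfs = list(cohort.control_vcfs.values())
        panel_path = cohort.panel_path
        library_spec = {"gmt": cohort.gmt_path, "background_size": sim_cfg.num_genes}
    else:
        manifest.stage_status["simulate"] = "skipped"
        inputs = config.get("inputs", {})
        family_vcfs = [Path(p) for p in inputs.get("family_vcfs", [])]
        ped_path = inputs.get("ped")
        control_vcfs = [Path(p) for p in inputs.get("control_vcfs", [])]
        panel_path = inputs.get("panel")
        library_spec = inputs.get("library")
        if not family_vcfs or ped_path is None:
            raise PipelineError("filter", "no family VCFs/PED given and no simulate block")

    for p in [*family_vcfs, ped_path, *control_vcfs]:
        if p is not None:
            manifest.input_digests[Path(p).name] = _sha256(p)
    if panel_path is not None:
        manifest.input_digests[Path(panel_path).name] = _sha256(panel_path)

    # ---- stage: filter ---------------------------------------------------
    try:
        fcfg = FilterConfig(**config.get("filters", {}))
        pedigrees = read_ped(ped_path)
        fam_results: Dict[str, CascadeResult] = {}
        fam_records: Dict[str, list] = {}
        fsarc = CandidateGeneSet("F-SARC")
        for vcf_path in family_vcfs:
            records = read_vcf(vcf_path)
            samples = set()
            for r in records:
                samples.update(r.genotypes)
            ped = match_pedigree(sorted(samples), pedigrees)
            fam_records[ped.family_id] = records
            result = run_family_cascade(records, ped, fcfg)
            fam_results[ped.family_id] = result
            fsarc.add(result)
            manifest.stage_counts[ped.family_id] = dict(result.stage_counts)
            logger.info("family %s funnel: %s", ped.family_id, result.stage_counts)
        control = CandidateGeneSet("CONTROL")
        ctrl_results: Dict[str, CascadeResult] = {}
        for vcf_path in control_vcfs:
            records = read_vcf(vcf_path)
            cid = sorted({s for r in records for s in r.genotypes})[0]
            result = run_control_selection(records, cid, fcfg)
            ctrl_results[cid] = result
            control.add(result)
            manifest.stage_counts[cid] = dict(result.stage_counts)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("filter", str(exc)) from exc
    manifest.stage_status["filter"] = "ok"
    _write_candidates(fsarc, out_dir / "candidates_fsarc.tsv", manifest)
    if control_vcfs:
        _write_candidates(control, out_dir / "candidates_control.tsv", manifest)
    manifest.summary["fsarc_candidate_genes"] = len(fsarc.genes)
    manifest.summary["control_candidate_genes"] = len(control.genes)

    # ---- stage: cross ----------------------------------------------------
    try:
        ccfg = dict(config.get("cross", {}))
        min_families = int(ccfg.get("min_families", 2))
        if ccfg.get("pre_maf_recurrence", False):
            # recurrence inspected before frequency thresholding
            pre_stages = FAMILY_STAGES[: FAMILY_STAGES.index("maf")]
            rec_source = {
                fam: run_family_cascade(
                    fam_records[fam], _ped_of(pedigrees, fam), fcfg, stages=pre_stages
                ).survivors
                for fam in fam_results
            }
        else:
            rec_source = {fam: res.survivors for fam, res in fam_results.items()}
        recurrence = find_recurrent_variants(rec_source)
        gene_recurrence = find_recurrent_genes(
            {fam: res.gene_set for fam, res in fam_results.items()},
            min_families=min_families,
        )
        _write_recurrence(gene_recurrence, recurrence, out_dir, manifest)
        manifest.summary["recurrent_genes"] = len(gene_recurrence.gene_level)
        manifest.summary["recurrent_variants"] = len(recurrence.variant_level)
        if panel_path is not None:
            panel = read_gene_panel(panel_path)
            cross_f = intersect_panel(fsarc.genes, panel, "F-SARC")
            cross_c = intersect_panel(control.genes, panel, "CONTROL")
            venn = venn_partition(cross_f.overlap, cross_c.overlap)
            _write_cross(cross_f, cross_c, venn, out_dir, manifest)
            manifest.summary["fsarc_panel_overlap"] = len(cross_f.overlap)
            manifest.summary["control_panel_overlap"] = len(cross_c.overlap)
            manifest.summary["venn_shared"] = len(venn.shared)
        manifest.stage_status["cross"] = "ok"
    except Exception as exc:
        raise PipelineError("cross", str(exc)) from exc

    # ---- stage: enrich ---------------------------------------------------
    if not library_spec:
        manifest.stage_status["enrich"] = "skipped"
        logger.info("no enrichment library configured; stopping after cross")
        return
    try:
        ecfg = dict(config.get("enrich", {}))
        library = read_gmt(
            library_spec["gmt"], background_size=int(library_spec["background_size"])
        )
        manifest.input_digests[Path(library_spec["gmt"]).name] = _sha256(library_spec["gmt"])
        permutations = int(ecfg.get("permutations", 1000))
        top_n = int(ecfg.get("top_n", 10))
        cal_seed = seed if seed is not None else int(ecfg.get("seed", 0))
        for label, geneset in (("fsarc", fsarc), ("control", control)):
            query = geneset.genes & library.universe or geneset.genes
            if not query:
                continue
            cal = calibrate_ranks(
                library, list_size=len(query), num_permutations=permutations, seed=cal_seed
            )
            results = enrich(query, library, cal, top_n=top_n)
            path = out_dir / f"enrichment_{label}.tsv"
            write_results(results, path)
            manifest.outputs[f"enrichment_{label}"] = str(path)
            manifest.summary[f"top_term_{label}"] = results[0].term if results else None
        manifest.stage_status["enrich"] = "ok"
    except Exception as exc:
        raise PipelineError("enrich", str(exc)) from exc


def _ped_of(pedigrees: Sequence[Pedigree], family_id: str) -> Pedigree:
    for ped in pedigrees:
        if ped.family_id == family_id:
            return ped
    raise KeyError(family_id)


def _write_candidates(geneset: CandidateGeneSet, path: Path, manifest: RunManifest) -> None:
    with open(path, "w") as fh:
        fh.write("unit\tgene\tchrom\tpos\tref\talt\trsid\tmaf\tcadd\tcadd_ge_threshold\n")
        for gene in sorted(geneset.supporting):
            for cand in geneset.supporting[gene]:
                r = cand.record
                fh.write(
                    f"{cand.unit_id}\t{gene}\t{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t"
                    f"{r.rsid or '.'}\t{'' if r.maf is None else f'{r.maf:.6g}'}\t"
                    f"{'' if r.cadd_phred is None else f'{r.cadd_phred:.6g}'}\t"
                    f"{int(cand.cadd_ge_threshold)}\n"
                )
    manifest.outputs[path.stem] = str(path)


def _write_recurrence(gene_rec, var_rec, out_dir: Path, manifest: RunManifest) -> None:
    path = out_dir / "recurrence_genes.tsv"
    with open(path, "w") as fh:
        fh.write("gene\tn_families\tfamilies\n")
        for gene in sorted(gene_rec.gene_level):
            fams = sorted(gene_rec.gene_level[gene])
            fh.write(f"{gene}\t{len(fams)}\t{','.join(fams)}\n")
    manifest.outputs["recurrence_genes"] = str(path)
    path = out_dir / "recurrence_variants.tsv"
    with open(path, "w") as fh:
        fh.write("gene\tvariant\tn_families\tfamilies\n")
        for gene, label in sorted(var_rec.variant_level):
            fams = sorted(var_rec.variant_level[(gene, label)])
            fh.write(f"{gene}\t{label}\t{len(fams)}\t{','.join(fams)}\n")
    manifest.outputs["recurrence_variants"] = str(path)


def _write_cross(cross_f, cross_c, venn, out_dir: Path, manifest: RunManifest) -> None:
    path = out_dir / "cross.tsv"
    with open(path, "w") as fh:
        fh.write("cohort\tn_candidates\tn_overlap\tpercent\toverlap_genes\n")
        for cr in (cross_f, cross_c):
            pct = "NA" if cr.proportion_percent is None else f"{cr.proportion_percent:.1f}"
            fh.write(
                f"{cr.cohort_label}\t{len(cr.candidate_genes)}\t{len(cr.overlap)}\t"
                f"{pct}\t{','.join(sorted(cr.overlap))}\n"
            )
    manifest.outputs["cross"] = str(path)
    path = out_dir / "venn.tsv"
    with open(path, "w") as fh:
        fh.write("partition\tn\tgenes\n")
        for name, genes in (
            ("fsarc_only", venn.only_a),
            ("shared", venn.shared),
            ("control_only", venn.only_b),
        ):
            fh.write(f"{name}\t{len(genes)}\t{','.join(sorted(genes))}\n")
    manifest.outputs["venn"] = str(path)
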