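# Methods

## Scope and data model

The package starts from *annotated* multi-sample VCFs (one per family,
one per control individual): alignment, variant calling and effect
annotation are upstream. Each record carries one alternate allele
(multi-allelic sites are split on ingest), one pre-resolved consequence
class, a population minor allele frequency, categorical calls from
three missense predictors (SIFT, PolyPhen-2, MutationTaster), and a
scaled CADD score. Annotations live in the VCF INFO field under
configurable key names; a missing key is *absent* (`None`), which is
semantically distinct from zero — in particular a variant of unknown
frequency must survive the frequency filter, since novel ultra-rare
alleles are routinely absent from population databases. Coordinates are
1-based and fully closed as in VCF; genotypes are read unphased
(`0|1` ≡ `0/1`); gene symbols are uppercased everywhere, with a small
alias map (e.g. the transposed TYSND1 spelling) applied on panel
ingest so matching is normalization-tolerant.

## The selection cascade

The genetic model is autosomal dominant with full penetrance within a
family: a causal variant is heterozygous in every affected member and
absent from unaffected relatives. Stages apply in the order

`quality → consequence → cosegregation → maf → pathogenicity`

and only remove records, so per-stage survivor counts form a monotone
funnel that is logged and written to the run manifest. Choices worth
recording:

- **Quality** is inclusive at the threshold (a score of exactly 20
  passes; "below 20" is removed) and unscored sites fail — a site the
  caller could not score should not anchor a familial candidate.
- **Co-segregation** ignores unknown-status members, and a *missing*
  genotype in an affected member fails: a missing call is not a
  demonstrated heterozygote, and the conservative reading avoids false
  familial candidates. A pedigree member with no genotype column at all
  is a hard sample/pedigree mismatch error rather than a silent fail.
- **MAF** is a strict `< 0.05` with unknown passing (see above).
- **Pathogenicity** is a disjunctive consensus: at least
  `min_predictor_calls` (default 1) deleterious calls among the three
  predictors. Nonsense and frameshift classes bypass the consensus:
  missense predictors do not score truncation. Manual-review suites are
  deliberately outside the machine logic.
- **CADD ≥ 20** is an annotation flag on survivors, never a filter — a
  candidate with low or absent CADD is retained and simply flagged
  false. This matters because rare familial candidates (e.g. in poorly
  covered genes) can score below 20 while still co-segregating.
- **Splice handling**: records must arrive pre-classified; the
  `splice_site` class is understood as the canonical ±2 bp
  donor/acceptor dinucleotides.
- The control arm replaces co-segregation with a single-sample
  zygosity restriction, heterozygous-only by default to mirror the
  family arm; `control_zygosity="nonref"` accepts homozygous-alternate
  genotypes for users who prefer the looser reading.
- Recurrence can be inspected *before* the frequency filter (truncated
  stage list / `--pre-maf` flag), since common-ish variants recurring
  across families are worth eyeballing even when the final candidate
  list is MAF-thresholded.

No compound-heterozygote, recessive or de-novo models are implemented:
the design targets multiplex families with dominant transmission.

## Recurrence, panel crossing, Venn

Variant identity for cross-family recurrence is the dbSNP rsid when
present, else the `(chrom, pos, ref, alt)` tuple. Variant-level
recurrence implies gene-level recurrence with the same or larger family
set (asserted by tests). Panel intersection reports the raw overlap and
the proportion `|overlap|/|candidates|`; the proportion of an empty
candidate set is *undefined* (reported as not-available, never 0).
Reported percentages are rounded half-away-from-zero to one decimal;
raw fractions are retained internally.

## Enrichment scores

The three scores follow the design popularized by gene-list enrichment
servers. The Fisher p is the one-sided upper-tail hypergeometric
probability; numerically it is delegated to `scipy.stats.hypergeom.sf`,
which we verified against exact integer-arithmetic tail summation over
*every* contingency table with N ≤ 60 (worst relative error
~9·10⁻¹⁶, see `scripts/acceptance.py`).

The expected-rank z-score corrects for term-specific ranking bias:
`calibrate_ranks` draws uniform random query lists (without
replacement) from the library universe, ranks all terms by ascending
Fisher p in each draw (average rank on ties — symmetric and
deterministic), and records per-term mean and standard deviation of
rank. `z = (mean_rank − observed_rank)/sd_rank`, oriented so terms
ranking *better* than expected get positive z, and the combined score
is `−ln(p)·z`, so enrichment is positive. Calibration is per
(library, list size); a query of a different size reuses the nearest
configured calibration with a logged note. Defaults: 1000 permutations,
seed recorded in the calibration object and all outputs. A standard
deviation of exactly zero can only occur in degenerate libraries whose
term ranks never vary; it is floored at 10⁻⁹ so z stays finite, and any
real permutation spread dominates the floor.

The background universe N of the contingency table is an explicit,
logged parameter of the library container (default 20,000 genes for
whole-exome work): enrichment servers do not publish a per-library
universe, so it must be user-visible rather than baked in. Printed
pathway p-values from external library snapshots are reproducible only
when the user supplies the same snapshot; the package bundles no
third-party gene-set libraries.

Benjamini–Hochberg adjustment uses the statsmodels step-up
implementation behind the package's `adjust_bh` surface, checked
against a hand-computed oracle.

## The synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated. Defaults: 13 families with 2–3 affected and 1–2 unaffected
members each, 100 control individuals, a 20,000-gene symbol universe, a
332-gene interactome panel overlapping 30 family-planted, 95
control-planted and 15 shared genes, seven recurrent variant pairs
(one identical variant planted in two families), ~30 planted genes per
family and ~50 per control — echoing the per-unit candidate yield of a
dominant-model exome screen (hundreds of candidate genes over 13
families; thousands over 100 controls) — and 60 background variants per
sample. rsids are synthesized (`rsS<counter>`) so variant-level
recurrence is testable without dbSNP.

Planted variants satisfy every filter by construction (quality 40–90,
retained consequence, MAF uniform on (0.0005, 0.049) or unknown with
probability 0.1, ≥ 1 deleterious call or a truncating class, CADD
20–35). Every background variant carries a generator tag (`SIMTAG` in
INFO) naming the cascade stage it was built to fail, with a class mix
of 10% quality, 20% consequence, 10% co-segregation, 40% frequency and
20% predictor-consensus failures; frequency-violating classes draw
common MAFs (uniform 0.05–0.5) and the predictor-consensus class draws
rare but benign-annotated variants, so both the MAF and pathogenicity
filters are exercised.

One design point deserves emphasis. For the audit "rejection stage ==
tag" to be meaningful, a variant tagged with a *site-level* stage must
actually reach that stage, so those classes carry a
segregation-consistent genotype pattern (het in affected, reference in
unaffected). Real background variation's segregation behaviour is
represented by the co-segregation-tagged class, whose genotypes are
drawn per sample under Hardy–Weinberg equilibrium at the variant's
(common) allele frequency. Such draws accidentally co-segregate
perfectly in roughly 1–7% of families (analytically,
`(2pq)^A · (q²)^U` averaged over the frequency distribution); because
the class also carries a common MAF and benign annotations, an
accidental co-segregator is still removed downstream — it can shift the
rejection stage (counted against the ≤ 1% tag-mismatch allowance) but
can never become a false-positive candidate gene. Consequently
planted-gene recovery has sensitivity and specificity exactly 1.0 by
construction, and the measured tag agreement is ~99.5%.

What the generator does **not** emulate: linkage disequilibrium,
sequencing error and coverage structure, population stratification,
relatedness beyond the nuclear family pattern, annotation
disagreement between predictors correlated with true effect, and gene
length/mutability variation. Passing the recovery tests therefore
demonstrates that the implementation applies its stated definitions
exactly — not that those definitions have any particular sensitivity or
specificity on real exomes, where causal variants can fail any filter
and background variants can pass all of them.

## Validation problem sizes

The acceptance study uses: exhaustive Fisher verification to N = 60
(~1.2M tables); null calibration with a 30-term exchangeable library
(i.i.d. 5000-gene terms over a 20,000-gene universe), 1000 calibration
permutations and 1000 random 2000-gene queries — term sizes are chosen
so the discrete upper-tail p-values (super-uniform, with
Kolmogorov–Smirnov bias approximately the maximum hypergeometric pmf,
here ≈ 0.02) sit well inside the 1% critical distance 0.0515 at 1000
replicates; and 20 independently seeded 13-family cohorts at the
default study conditions (controls disabled — the recovery criteria
concern the family arm) with 200-permutation calibrations for the
planted-term rank check. The unit/property suite runs on smaller
cohorts with the same structure.

## Known limitations

- The cascade models full penetrance; a single phenocopy or missing
  genotype in an affected member removes a true candidate.
- The z-score calibration samples queries from the library universe;
  queries containing many genes outside every term dilute k but not n,
  which is the standard contingency-table convention but worth knowing
  when comparing against servers that drop unknown genes.
- Proportions between cohorts of very different construction (family
  recurrence vs single individuals) are reported without a significance
  test, deliberately.
- The packaged panel table covers only the genes observed in the two
  cohorts (31 rows), not the full interactome; full-panel analyses
  require a user-supplied panel file.
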