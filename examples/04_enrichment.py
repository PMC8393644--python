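"""Rank-calibrated gene-set enrichment on a simulated candidate list.

Every term gets a one-sided Fisher exact p, an expected-rank z-score
(how much better the term ranks than it does for random queries of the
same size), and the combined score -ln(p) * z used for ordering.
"""

import tempfile

from famvar import (
    SimulationConfig,
    calibrate_ranks,
    enrich,
    read_ped,
    read_vcf,
    run_family_cascade,
    simulate_cohort,
)

cohort = simulate_cohort(
    SimulationConfig(num_families=6, num_controls=0, num_genes=5000,
                     planted_genes_per_family=10, library_terms=40,
                     library_term_size=25, panel_family_overlap=15,
                     panel_control_overlap=15, panel_shared_overlap=5, seed=9),
    tempfile.mkdtemp(),
)
peds = {p.family_id: p for p in read_ped(cohort.ped_path)}
query = set()
for fam, path in cohort.family_vcfs.items():
    query |= run_family_cascade(read_vcf(path), peds[fam]).gene_set

cal = calibrate_ranks(cohort.library, list_size=len(query), num_permutations=300, seed=1)
results = enrich(query, cohort.library, cal, top_n=5)

print(f"query: {len(query)} candidate genes; library: {len(cohort.library.terms)} terms\n")
print(f"{'term':<18}{'k/K':>8}{'p':>12}{'z':>8}{'combined':>10}{'p_adj':>12}")
for r in results:
    print(f"{r.term:<18}{f'{r.k}/{r.K}':>8}{r.p_fisher:>12.3g}{r.z:>8.2f}"
          f"{r.combined_score:>10.1f}{r.p_adjusted:>12.3g}")
print(
    f"\nThe planted term ({cohort.truth.planted_term}) collects the panel-overlap"
    " genes, so it tops the ranking by a wide margin; the other terms overlap"
    " the query only by chance."
)
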