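"""Screen genes for prognostic value across three cohorts, then ask which
functional module is consistently over-represented in the hit lists.

The catalog holds the true cell-cycle module plus two random decoys; when
proliferation drives hazard, the cell-cycle module should rank first by the
(number of significant cohorts, mean p) rule, and be each cohort's top hit.
"""
import numpy as np

import ccpmeta as cm

specs = [cm.CohortSpec(n_samples=200, n_genes=300, beta_prolif=1.0,
                       beta_indep=0.3, baseline_hazard=0.1, censor_max=20.0,
                       seed=7 + i) for i in range(3)]
cohorts = cm.generate_multi_cohort(specs)

rng = np.random.default_rng(0)
tables = []
for co in cohorts:
    m = cm.znormalize(cm.collapse_probes(co.expression))
    universe = list(m.values.index)
    catalog = cm.ModuleCatalog({
        "cell_cycle": tuple(co.truth.genes_of_class("ccp")),
        "decoy_metabolism": tuple(rng.choice(universe, 40, replace=False)),
        "decoy_immune": tuple(rng.choice(universe, 40, replace=False)),
    })
    hits = cm.gene_screen(m, co.clinical, alpha=0.01).hits
    print(f"{co.cohort_id}: {len(hits)} genes prognostic at P<0.01")
    tables.append(cm.overrepresentation(hits, universe, catalog,
                                        cohort_id=co.cohort_id))

ranking = cm.rank_modules(tables, fdr_cut=0.20)
print("\nmodule ranking (cohorts significant at FDR<20%, then mean p):")
print(ranking[["module_id", "n_cohorts_significant", "mean_p"]].to_string(index=False))
for t in tables:
    print(f"top hit in {t.cohort_id}: {cm.top_hit(tables, t.cohort_id)}")
# The top-ranked module is the biological process most consistently tied to
# outcome across cohorts -- the meta-analytic signal a single cohort misses.
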