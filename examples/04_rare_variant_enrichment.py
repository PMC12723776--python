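"""Quantify rare-variant enrichment among dosage outliers.

Simulates a cohort where planted outlier cells carry a rare splice-donor
variant 80% of the time (baseline 10%), joins outlier calls to the carrier
table, and reports the relative risk by significance threshold.
"""

import pandas as pd

from asevar import (
    SimConfig,
    build_pairs,
    dot_cohort,
    enrichment_by_significance,
    simulate_population,
    simulate_variant_table,
)

cfg = SimConfig(
    seed=4,
    n_genes=400,
    n_individuals=50,
    sd_g_law=("fixed", 0.15),
    coverage_law=("loguniform", 100, 2000),
    outlier_fraction=0.05,
    outlier_effect="monoallelic",
    variant_classes={"splice_donor": (0.1, 0.8)},
)
counts, truth = simulate_population(cfg)
reference = pd.DataFrame({"gene_id": counts.gene_ids, "sd_g": 0.15})
results, _ = dot_cohort(counts, reference, set(counts.gene_ids))
variants = simulate_variant_table(truth, cfg)

pairs = build_pairs(results, variants)
table = enrichment_by_significance(pairs, [0.01, 0.05])

cols = ["threshold", "stratum", "a", "b", "c", "d", "rr", "ci_low", "ci_high"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# rr is the ratio of rare-variant carrier rates between outlier and
# non-outlier (individual, gene) pairs with a Katz 95% CI; with an 80% vs
# 10% planted carrier rate it sits far above 1.
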