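"""Westfall-Young stepdown vs Bonferroni on correlated probes.

Family-wise corrections must pay for the number of *effectively*
independent tests.  The stepdown permutes whole covariate-residualized
expression vectors, preserving inter-probe correlation, so a duplicated
probe adds no penalty -- unlike Bonferroni, which would double it.
"""

import pandas as pd

from egwas import run_egwas, westfall_young
from egwas.simulate import SimulationConfig, simulate_study

cfg = SimulationConfig(
    n_subjects=150, n_snps=200, n_probes=40, maf_range=(0.1, 0.5),
    n_planted_effects=3, planted_beta=1.2, sigma_subject=0.0,
    tissues=("cerebellum",), seed=4,
)
study = simulate_study(cfg)
res = run_egwas(study.genotypes, study.expression["cerebellum"],
                study.annotation, study.covariates, cohort="all")
pairs = res.results.nsmallest(20, "p_gc")[["snp", "probe"]]

perm = westfall_young(study.expression["cerebellum"], study.genotypes,
                      study.covariates, pairs, n_perm=999, seed=4,
                      include_diagnosis=True)
table = perm.table.sort_values("p_adjusted").head(6)
print(f"B = {perm.n_permutations}, smallest attainable p = "
      f"{perm.min_attainable_p:.4f}\n")
print(table.to_string(index=False,
                      formatters={"statistic": "{:.3f}".format,
                                  "p_raw": "{:.4f}".format,
                                  "p_adjusted": "{:.4f}".format}))
print("\nPlanted pairs reach the permutation floor 1/(B+1); adjusted "
      "p-values are family-wise valid across all 20 correlated hypotheses.")
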