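"""Are significant cisSNPs enriched among disease/trait-associated SNPs?

Builds a disease catalog with a planted 2.4-fold excess of significant
SNPs, filters it to single-rs entries, joins by rs number, and tests the
unique-SNP overlap against a null that redraws SNP sets matched to the
significant set's minor-allele-frequency profile (ten bins of width 0.05).
"""

import numpy as np
import pandas as pd

from egwas import enrichment_test, filter_catalog, link_significant
from egwas.simulate import simulate_catalog

rng = np.random.default_rng(5)
n_universe, n_sig = 20_000, 400
universe = pd.DataFrame(
    {"chrom": "1", "pos": np.arange(n_universe) + 1, "a1": "A", "a2": "G",
     "maf": rng.uniform(0.005, 0.5, n_universe)},
    index=pd.Index([f"rs{i}" for i in range(n_universe)], name="snp"))
sig_snps = rng.choice(universe.index.to_numpy(), size=n_sig, replace=False)

raw = simulate_catalog(universe, sig_snps, enrichment_factor=2.4,
                       n_catalog=500, seed=5)
filtered = filter_catalog(raw)
print(f"catalog: {filtered.n_input} raw rows -> {filtered.n_kept} single-rs "
      f"rows ({filtered.n_unique_snps} SNPs, {filtered.n_unique_traits} traits)")

overlap = link_significant(sig_snps, filtered.table)
print(f"overlap: {overlap.n_rows} SNP-trait rows, "
      f"{overlap.n_unique_snps} unique SNPs")

res = enrichment_test(sig_snps, filtered.table["SNPs"].unique(), universe,
                      n_sim=1_000_000, seed=5)
print(f"\nMAF-matched null over {res.n_sim:,} simulations: "
      f"mean overlap = {res.null_mean:.2f}")
print(f"fold enrichment = {res.fold_enrichment:.2f}, "
      f"empirical p = {res.empirical_p:.2e}")
print("\nThe fold estimate should recover the planted 2.4x excess; an "
      "empirical p at the 1/(n_sim+1) floor means no null draw matched the "
      "observed overlap.")
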