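"""Instrument selection: genome-wide filtering, LD pruning, overlap
exclusion, variance explained and power.

Mirrors the construction of the waist/hip instrument sets: select SNPs at
p < 5e-8, prune pairs with r^2 >= 0.05 keeping the smaller p-value, exclude
variants shared between the two traits' sets, then summarize instrument
strength (variance explained) and the power of the downstream MR test.
"""

import numpy as np

from adipomr import (
    InstrumentSet,
    LDInfo,
    SimulationConfig,
    exclude_overlap,
    filter_genomewide,
    ld_prune,
    mr_power,
    simulate_two_sample,
    variance_explained,
)

waist = simulate_two_sample(SimulationConfig(k_snps=64, beta_true=-0.27, seed=3)).exposure
waist.trait_name = "waist"

candidates = filter_genomewide(waist, threshold=5e-8)
print(f"{len(candidates)} of {len(waist)} SNPs reach p < 5e-8")

# pairwise r^2 would normally come from a reference-panel pairs file
rng = np.random.default_rng(0)
ids = candidates.snp_ids
ld = LDInfo({(ids[i], ids[i + 1]): 0.8 for i in range(0, len(ids) - 1, 6)})
pruned = ld_prune(candidates, waist, ld, r2_threshold=0.05)
print(f"{len(pruned)} remain after LD pruning at r^2 < 0.05")

hip_ids = pruned.snp_ids[:4] + [f"hip_rs{i}" for i in range(40)]
reduced, hip_set, shared = exclude_overlap(pruned, InstrumentSet("hip", hip_ids))
print(f"{len(shared)} variants shared with the hip set excluded -> "
      f"{len(reduced)} waist instruments")

r2 = variance_explained(reduced, waist)
print(f"\nvariance explained by the waist instruments: {100 * r2:.2f}%")
power = mr_power(r2=r2, n_outcome=29_347, true_beta=0.27, alpha=0.05)
print(f"power to detect |beta| = 0.27 with an outcome GWAS of n = 29 347: "
      f"{100 * power:.1f}%")
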