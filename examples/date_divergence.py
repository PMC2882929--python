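"""Date a species split from ortholog Ks values.

Builds CDS pairs evolved to a known synonymous divergence, measures each
pair with codon-aware alignment + NG86, and converts the median Ks to a
divergence time with the grass synonymous clock T = Ks / (2 * 6.5e-9).
"""

import numpy as np

from polysynt.kaks_divergence import estimate_divergence, kaks_pair
from polysynt.synthetic_data import simulate_ortholog_pairs

pairs = simulate_ortholog_pairs(100, target_ks=0.10, seed=7)
ks = [kaks_pair(a, b, check_reliability=False).Ks for a, b in pairs]
est = estimate_divergence(ks)

print(f"measured Ks over {est.n_pairs} ortholog pairs: median {est.median_ks:.3f}")
print(f"clock rate: {est.rate:g} synonymous substitutions/site/year")
print(f"estimated divergence time: {est.time_mya} million years")
print()
print("A median Ks near 0.10 corresponds to ~7.7 MYa under the grass clock,")
print("the age of the sugarcane-sorghum split this pipeline was built to date.")
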