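"""Which vertices drive identification: uniqueness and differential power.

Builds the paired cohort tensor (subject i's target map against subject j's
base map) and derives the two vertex-contribution statistics: uniqueness,
the OLS residual of inter-individual over intra-individual variability, and
differential power, the negative log probability that a cross-subject match
beats the self-match.
"""

import numpy as np

from lgmfp import make_icosphere
from lgmfp.contribution import differential_power, uniqueness_map
from lgmfp.fingerprint import LgmSet, build_lcm_tensor
from lgmfp.synthetic import CohortSpec, simulate_lgm_cohort

mesh = make_icosphere(3)
cohort = simulate_lgm_cohort(CohortSpec(master_seed=0))
targets = LgmSet(cohort.lgm_set_entries("S1"), "target")
bases = LgmSet(cohort.lgm_set_entries("S2"), "base")
tensor = build_lcm_tensor(targets, bases, mesh, np.arange(mesh.n_vertices), r=1)

dp_subject, dp_population = differential_power(tensor)
uniq = uniqueness_map(tensor)

n = len(cohort.subjects)
cap = -np.log(0.5 / (2 * (n - 1)))
print(f"population DP: mean {dp_population.mean():.2f}, "
      f"max {dp_population.max():.2f} (per-subject cap {cap:.2f})")
print(f"uniqueness fit: alpha = {uniq.alpha:.3f}, beta = {uniq.beta:.3f}")
print(f"uniqueness residual range: [{uniq.u.min():.3f}, {uniq.u.max():.3f}]")
print(
    "High-DP and high-uniqueness vertices are those whose local boundary "
    "pattern is stable within a subject but differs between subjects — the "
    "functional fingerprint's most informative locations."
)
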