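"""Predict cognitive scores from boundary features of LGMs.

Simulates 140 scans whose scores are linearly coupled (population R^2 =
0.36) to two known causal region boundaries, then runs the full prediction
procedure: dilated boundary-band features, per-fold p < 0.01 directional
selection, two-dimensional sum features, and a 20-tree random forest under
10 iterations of 10-fold cross-validation, followed by the
leave-one-network-out importance profile.
"""

import numpy as np

from lgmfp import make_icosphere
from lgmfp.prediction import feature_table, leave_one_network_out, rf_cv_predict
from lgmfp.synthetic import (
    CohortSpec,
    design_prediction_study,
    simulate_lgm_cohort,
    simulate_scores,
)

mesh = make_icosphere(3)
cohort = simulate_lgm_cohort(CohortSpec(n_subjects=70, n_parcels=12, master_seed=5))
atlas, causal_pos, causal_neg = design_prediction_study(cohort.base_labels, mesh)
scores, truth = simulate_scores(
    cohort, atlas, causal_pos, causal_neg, effect=40.0, seed=17, target_r2=0.36
)
table = feature_table([m for _, _, m in cohort.scans()], scores, atlas)

cv = rf_cv_predict(table, seed=23)
print(f"cross-validated r over {len(table.features)} scans: {cv.r_value:.3f}")
sel = np.mean([causal_pos[0] in rec.positive for rec in cv.folds])
print(f"causal positive boundary {causal_pos[0]} selected in {sel:.0%} of folds")
for net in atlas.networks:
    r = leave_one_network_out(table, atlas, net, seed=23)
    tag = " <- causal network" if net == 0 else ""
    print(f"leave-out network {net}: r = {r:.3f}{tag}")
print(
    "Removing the network holding the causal boundaries collapses the "
    "prediction; removing any other network leaves it near the full model."
)
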