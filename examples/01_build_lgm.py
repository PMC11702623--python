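"""Build a local gradient map from parcel-structured BOLD signal.

Constructs a noiseless six-parcel signal on a level-3 icosphere (642
vertices), runs the full pipeline (RSFC -> Fisher z -> second-order
correlation -> per-row gradient + watershed -> mean boundary map) and shows
that the resulting LGM concentrates on the true parcel borders.
"""

import numpy as np

from lgmfp import BoldMatrix, compute_lgm, make_icosphere
from lgmfp.mesh import hop_distances
from lgmfp.synthetic import simulate_parcellation

mesh = make_icosphere(3)
parcels = simulate_parcellation(mesh, k=6, seed=1)
latent = np.random.default_rng(2).standard_normal((6, 100))
bold = BoldMatrix(latent[parcels], subject_id="demo", session_id="S1")

lgm = compute_lgm(bold, mesh)

border = np.array(
    [any(parcels[u] != parcels[v] for u in mesh.neighbor_rings[v])
     for v in range(mesh.n_vertices)]
)
interior = hop_distances(mesh, np.flatnonzero(border)) >= 2

print(f"mean LGM on true parcel borders: {lgm.values[border].mean():.3f}")
print(f"mean LGM two hops inside parcels: {lgm.values[interior].mean():.5f}")
print(
    "High values on borders and near-zero inside parcels mean the watershed "
    "boundary maps consistently localize the connectivity transitions."
)
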