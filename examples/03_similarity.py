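"""Compare snapshot potentials with Hodgkin-index electrostatic distances.

Distances D = sqrt(2 - 2*SI) are evaluated over a 'skin' of solvent
voxels just outside the molecular surface, restricted to a sphere around
the probe phosphate - the region where headgroup electrostatics differ.
"""

import numpy as np

from memesp import (
    GridSpec,
    SkinMaskSpec,
    SyntheticBilayerSpec,
    distance_autocorrelation,
    distance_stats,
    generate_bilayer,
    pairwise_matrix,
    perturb_ensemble,
    skin_mask,
)

spec = SyntheticBilayerSpec(lipids_per_leaflet=36, seed=4)
bilayer = generate_bilayer(spec)
grid_spec = GridSpec.centered(bilayer.role_position("P1"), (33, 33, 33), 1.0)
ensemble = perturb_ensemble(bilayer, 25, spec, grid_spec)

mask = skin_mask(bilayer, grid_spec, SkinMaskSpec(sphere_radius=14.0))
print(f"skin region: {mask.size} voxels within 14 A of P1")

matrix = pairwise_matrix(list(ensemble.grids()), mask=mask,
                         timestamps=ensemble.timestamps)
stats = distance_stats(matrix)
print(f"snapshot-to-snapshot distances ({stats['n_pairs']} pairs):")
print(f"  mean D = {stats['mean']:.3f}, sd = {stats['sd']:.3f}")

lags, acf = distance_autocorrelation(matrix)
print("similarity autocorrelation (1 = identical, ~0 = uncorrelated):")
for tau in (1, 2, 5):
    print(f"  lag {lags[tau]:.1f} ns: {acf[tau]:+.3f}")
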