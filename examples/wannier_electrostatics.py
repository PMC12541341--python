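"""Wannier centroids, charge bookkeeping and Gaussian-charge electrostatics.

Builds a water molecule with four Wannier centers around its oxygen,
collapses them into a -8 e centroid, checks the fragment charge bookkeeping,
and evaluates the periodic interaction energy of Gaussian charges both in
reciprocal space and with the real-space image-sum oracle.
"""

import math

import numpy as np

from calcipair import (
    ChargedSiteSet,
    ChargeTable,
    Frame,
    SimulationBox,
    assign_centroids,
    build_charged_sites,
    direct_sum_oracle,
    fragment_net_charge,
    gaussian_ewald_energy,
    lr_tail_from_charges,
)

# -- one water molecule with slightly displaced Wannier centers -------------
box = SimulationBox.cubic(12.0)
o = np.array([6.0, 6.0, 6.0])
tet = 0.35 / math.sqrt(3) * np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]])
shift = np.array([0.05, 0.03, 0.0])  # electron cloud pulled toward the H side
frame = Frame(
    ("O", "H", "H") + ("WC",) * 4,
    np.vstack([o, o + [0.76, 0.59, 0.0], o + [-0.76, 0.59, 0.0], o + tet + shift]),
    box,
)
table = ChargeTable()
assignment = assign_centroids(frame, table)
sites = build_charged_sites(frame, assignment, table)

print(f"centroid displacement from O: {np.round(assignment.displacements[0], 3)} A")
print(f"water net charge            : {sites.net_charge:+.1f} e")
for name in ("water", "hydroxide", "carbonate", "bicarbonate", "Ca"):
    from calcipair.wannier import FRAGMENTS

    print(f"  {name:12s} fragment charge: {fragment_net_charge(FRAGMENTS[name], table):+.1f} e")

# -- periodic Gaussian-charge energy vs the real-space oracle ----------------
rng = np.random.default_rng(1)
edge = 10.0
random_sites = ChargedSiteSet(
    rng.uniform(0, edge, (8, 3)), np.repeat([1.0, -1.0], 4),
    SimulationBox.cubic(edge), spread=0.3,
)
e_k, forces = gaussian_ewald_energy(random_sites)
e_r = direct_sum_oracle(random_sites)
print()
print(f"reciprocal-space energy : {e_k:12.6f} kJ/mol")
print(f"direct-sum oracle       : {e_r:12.6f} kJ/mol  (|diff| = {abs(e_k - e_r):.2e})")

tail = lr_tail_from_charges(table, ("Ca", "carbonate"), epsilon=102.0, r=14.0)
print(f"screened Ca/CO3 tail at 14 A, eps = 102: {tail:7.3f} kJ/mol")
print()
print("The -8 e centroids place the electronic charge where the Wannier")
print("functions localise it, so molecular fragments carry their formal")
print("charges; the reciprocal-space energy of the smeared charges agrees")
print("with an independent image-sum to ~1e-5 kJ/mol, and the screened tail")
print("is what the long-range pairing analysis aligns W(r) against.")
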