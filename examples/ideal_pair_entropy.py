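"""The 4 pi r^2 entropy of an ideal pair, removed exactly.

A non-interacting pair in 3D has radial free energy G(r) = -kBT ln(4 pi r^2)
+ const; after the entropy correction W(r) = G(r) + kBT ln(4 pi r^2) the
potential of mean force must be flat.  This is the null experiment that
validates the radial pipeline before any real potential is analysed.
"""

from calcipair.workflows import ideal_pair_null

null = ideal_pair_null(seeds=(1, 2), n_steps=300_000)
sampled = null.well_sampled

print(f"well-sampled bins (> 100 counts): {int(sampled.sum())}")
print(f"max |W - mean W| over those bins: {null.max_deviation:6.3f} kJ/mol")
print()
print("r [A]   W - <W> [kJ/mol]")
for r, w in list(zip(null.pmf.r[sampled], null.pmf.w[sampled] - null.pmf.w[sampled].mean()))[::6]:
    print(f"{r:5.2f}   {w:+7.3f}")
print()
print("Flat within a fraction of kBT (2.74 kJ/mol at 330 K): the sampling,")
print("histogramming and entropy correction introduce no radial artefact.")
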