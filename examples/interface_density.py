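"""Interfacial electron-density profile from layered synthetic frames.

Builds frames that mimic a mineral-water interface (a Ca layer as the
surface, two ordered water-oxygen layers above it) and computes the electron
density as a weighted sum of per-species nuclei histograms (O 8 e, H 1 e,
C 6 e, Ca 20 e), with the topmost Ca layer as the height origin.
"""

import numpy as np

from calcipair import electron_density_profile, layered_interface_frames

traj = layered_interface_frames(
    layers=[
        (0.0, "Ca", 16, 0.05),   # surface calcium layer (origin)
        (2.3, "O", 32, 0.15),    # first, highly localised water layer
        (3.5, "O", 32, 0.45),    # second, more diffuse layer
    ],
    lateral_box=(20.0, 20.0),
    n_frames=50,
    seed=7,
)
profile = electron_density_profile(traj, bin_width=0.2, smoothing=0.1)

print(f"origin (mean z of topmost Ca layer): {profile.origin:6.2f} A")
print(f"total electrons (conserved exactly): {profile.total_electrons:8.1f} e")
print()
print("  z [A]   rho_e [e/A^3]")
sel = (profile.z_centers > -1.0) & (profile.z_centers < 5.5)
for z, v in zip(profile.z_centers[sel][::3], profile.values[sel][::3]):
    bar = "#" * int(v * 120)
    print(f"{z:7.2f}   {v:8.4f}  {bar}")
print()
print("The first water layer shows as a sharp peak ~2.3 A above the Ca")
print("plane, the second as a broader shoulder — the fingerprint compared")
print("against surface X-ray profiles of the mineral-water interface.")
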