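"""Simulate a Shack-Hartmann spot-array frame.

Builds the reference sensor (16x16 lenslets, f = 6.5 mm, 20x20 px windows
of 10 um pixels, lambda = 500 nm), draws a random turbulence-weighted
wavefront of 1.5 waves RMS, and renders the noiseless detector frame.
The printed displacement statistics show how far each lenslet's focal spot
moved from its calibrated reference position — the raw signal every
Shack-Hartmann reconstruction starts from.
"""

import numpy as np

import shwfs

geometry = shwfs.build_geometry()
print(f"sensor: {geometry.config.grid_shape}x{geometry.config.grid_shape} lenslets, "
      f"{geometry.k_effective} effective, frame {geometry.frame_shape} px")

coeffs = shwfs.sample_coefficients(rng=42, n_modes=15, target_rms=1.5)
frame, truth = shwfs.render_frame(coeffs, geometry)

disp = truth.true_centers - geometry.reference_centers
print(f"wavefront RMS: {coeffs.rms():.3f} waves")
print(f"spot displacements: mean {np.linalg.norm(disp, axis=1).mean():.3f} px, "
      f"max {np.linalg.norm(disp, axis=1).max():.3f} px")
print(f"frame total flux: {frame.intensity.sum():.3f} "
      f"(= one unit per effective lenslet, minus clipped tails)")

# persist the frame and the generating coefficients
from shwfs import io

io.save_frame("frame.tiff", frame)
with open("coefficients.json", "w") as f:
    f.write(coeffs.to_json())
print("wrote frame.tiff and coefficients.json")
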