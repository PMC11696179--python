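"""Detect single particles in a TIRF-like field, quantify their total
intensities, and colocalize two channels.

Builds a sparse field of diffraction-limited spots, detects them with the
LoG detector, measures background-subtracted integrated intensities, and
matches the field against a half-pixel-shifted copy of itself.
"""

import numpy as np

from cophase import particles, synthetic

image, truth = synthetic.make_particle_field(
    12, intensity_mean=4000.0, psf_sigma=1.5, image_size=128,
    seed=3, background=20.0, noise_sd=3.0,
)
spots = particles.detect_spots(image, sigma_expected=1.5)
print(f"true spots: {len(truth)}, detected: {len(spots)}")
spots = particles.quantify_spots(image, spots)
print(f"quantified (border-clipped spots excluded): {len(spots)}")
print(f"mean true total intensity:     {truth['total_intensity'].mean():.0f}")
print(f"mean measured total intensity: {np.mean([s.total_intensity for s in spots]):.0f}")

shifted = [particles.Spot(x=s.x + 0.5, y=s.y, sigma=s.sigma) for s in spots]
pairs, fraction = particles.colocalize_channels(spots, shifted, radius_px=2.0)
print(f"colocalized fraction against the shifted copy: {fraction:.2f}")
# Detection should be complete at this signal-to-noise, measured intensities
# unbiased within a few percent, and the shifted copy fully matched.
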