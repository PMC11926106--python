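"""Membrane fluidity from a hyperspectral stack via spectral phasors.

Simulates one vesicle cross-section whose membrane mixes a gel-like and a
fluid-like spectral species at a known fraction, phasor-transforms the
stack, projects pixels onto the gel-to-fluid trajectory and summarises the
fraction histogram by its centre of mass.  The printed CM is the per-image
fluidity statistic (0 = most gel-like, 1 = most fluid); it should recover
the simulated mixing fraction to within photon noise.
"""

from memwet import (
    PhasorConfig,
    center_of_mass,
    compute_phasor,
    histogram_fractions,
    project_fraction,
    simulate_hsi_vesicle,
)
from memwet.pipeline import default_axis

TRUE_FRACTION = 0.35

stack, truth = simulate_hsi_vesicle(f=TRUE_FRACTION, photons_per_pixel=1e4, seed=11)
field = compute_phasor(stack, PhasorConfig(intensity_threshold=100.0))
fractions = project_fraction(field, default_axis())
hist = histogram_fractions(fractions[field.mask], n_bins=100)
cm = center_of_mass(hist)

print(f"membrane pixels analysed : {field.n_included}")
print(f"true fluid fraction      : {TRUE_FRACTION:.3f}")
print(f"histogram centre of mass : {cm:.3f}")
print("CM tracks the fluid fraction: higher CM = looser lipid packing.")
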