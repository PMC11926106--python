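# memwet

Quantitative analysis of how membrane lipid packing controls the wetting of
membranes by biomolecular condensates. The package implements the three
measurement chains such a study rests on, each paired with a synthetic-data
generator so the whole pipeline is verifiable by parameter recovery:

1. **Membrane fluidity from hyperspectral imaging.** Solvatochromic membrane
   dyes (LAURDAN-type) red-shift their emission as lipid packing loosens and
   interfacial hydration grows. Each pixel's spectrum I(λ), acquired over
   [λ_min, λ_max], is mapped to spectral-phasor coordinates

   G = Σ_k I(λ_k) cos(2πn(λ_k − λ_min)/(λ_max − λ_min)) / Σ_k I(λ_k),
   S = Σ_k I(λ_k) sin(2πn(λ_k − λ_min)/(λ_max − λ_min)) / Σ_k I(λ_k),

   with harmonic n = 1. Mixtures of two spectral species fall on the straight
   segment between the pure-species phasors, so projecting pixels onto a
   gel-to-fluid trajectory yields a per-pixel *fluidity fraction* in [0, 1];
   an image is summarised by the centre of mass CM = Σ F_i·i / Σ F_i of the
   fraction histogram.

2. **Fluid-elastic wetting parameters from cross-section geometry.** In the
   equatorial cross-section of a vesicle–condensate couple, the three
   interfaces (membrane–buffer *ie*, membrane–condensate *ic*, condensate–
   buffer *ce*) are circular arcs meeting at two contact points where the
   tensions Σ_ce, Σ_ie, Σ_ic close a force triangle. From circle fits
   (Taubin) the apparent contact angles θ_i + θ_e + θ_c = 360° are measured,
   giving the geometric factor

   Φ = (sin θ_e − sin θ_c) / sin θ_i ∈ [−1, 1],  Φ = cos θ_e^in,

   the intrinsic contact angle θ_e^in, the affinity contrast W = Φ·Σ_ce
   (bounded by ±Σ_ce; Φ = +1 dewetting, Φ = −1 complete wetting) and the
   membrane segment tensions Σ_ie = Σ_ce sin θ_c / sin θ_i,
   Σ_ic = Σ_ce sin θ_e / sin θ_i.

3. **Condensate ζ-potential from microelectrophoresis.** The drift velocity
   ν of a condensate in a DC field E (least-squares slope of the field-axis
   projection of its trajectory) converts to ζ via the liquid-droplet
   modification of the Smoluchowski relation,

   ζ = 3 η_c ν / (ε₀ ε_r E) · 1/(3 η_e + κR),

   with condensate viscosity η_c, external viscosity η_e, inverse Debye
   length κ and droplet radius R.

The intended users are membrane-biophysics labs analysing hyperspectral
confocal stacks, vesicle–condensate contour tracings and condensate
trajectories — from Python, or through the thin `memwet` CLI.

## Worked example

`python examples/wetting_parameters.py` builds a noisy synthetic
vesicle–condensate cross-section with known affinity contrast
W = −6 µN/m (glycinin-like Σ_ce = 15.7 µN/m), then runs the full
measurement chain:

```
apparent angles (deg)  : theta_i=137.09 theta_e=132.33 theta_c=90.58 (sum 360.00)
geometric factor Phi   : -0.3829   (truth -0.3822)
intrinsic angle (deg)  : 112.51
affinity contrast W    : -6.01 uN/m  (truth -6.00)
segment tensions       : Sigma_ie=23.06  Sigma_ic=17.05 uN/m
geometry checks passed : True
```

The negative Φ says this membrane prefers the condensate over the buffer;
W recovers the simulated −6 µN/m from rendered contours with 0.5-pixel
noise. The other examples do the same for the fluidity fraction
(`fluidity_fraction.py`: CM 0.350 at true fraction 0.35) and the
ζ-potential (`zeta_potential.py`: +10.03 mV at true 10 mV), and
`full_pipeline.py` runs the config-driven simulate→analyze→report chain,
printing a per-condition truth-vs-estimate table.

The same pipeline is available from a shell:

```
memwet run --seed 1 --out demo        # simulate + analyze + report
memwet wetting --contours arcs.csv --sigma-ce 15.7 --out results
memwet show-config                    # all defaults as YAML
```

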