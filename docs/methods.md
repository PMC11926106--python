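# Methods

This note documents the models, conventions and numerical choices behind
memwet, and what the synthetic generators do and do not emulate.

## Spectral phasor analysis

**Model.** A pixel's emission spectrum I(λ), sampled at channel centres
λ_k within the acquisition range [λ_min, λ_max], is represented by its
first-harmonic Fourier coefficients (G, S) normalised by total intensity.
The integrals are discretised as sums over channel centres with uniform
channel weights, matching acquisition with equal-bandwidth channels (the
default metadata is 416–728 nm in 32 channels of 9.75 nm). For any
non-negative spectrum G² + S² ≤ 1, and the transform is linear in
intensity: a mixture a·I₁ + b·I₂ sits on the segment between the component
phasors at the fractional integrated intensity a·ΣI₁/(a·ΣI₁ + b·ΣI₂).
The harmonic defaults to n = 1; higher harmonics are passed through but not
otherwise used.

**Background masking.** Inclusion requires per-pixel summed intensity above
a threshold. The default is Otsu's threshold on the total-intensity image
(with a fall-back to "any signal" for degenerate images); a fixed count
threshold can be supplied instead. Masked pixels carry NaN coordinates.

**Two-cursor fraction.** The fluidity fraction is the scalar projection of
(G, S) onto the segment between two endpoint phasors, divided by the
segment length and clamped to [0, 1]; the component orthogonal to the axis
is discarded. Endpoint 1 is the high-fluidity end, so the fraction
increases toward fluid membranes. Endpoint placement is an analysis
convention (the defaults anchor at the phasors of the built-in gel/fluid
reference spectra); fractions are comparable across images only under a
fixed axis. Histograms default to 100 equal-width bins on [0, 1]; the
centre of mass CM = Σ F_i·i / Σ F_i uses bin-centre positions and is stable
to < 0.01 against bin-count changes (tested from 50 to 400 bins). CM is
invariant under uniform intensity rescaling. Cursor classification uses
first-cursor-wins ordering for overlapping cursors, making multi-cursor
label images deterministic.

## Wetting geometry

**Circle fitting.** Interface arcs are fit with the algebraic Taubin
method (SVD form), which is nearly unbiased on partial arcs; an optional
independent geometric (Levenberg) refit serves as a cross-check in the
tests. A fitted curvature below 1/(1000 × the arc's bounding-box diagonal)
triggers a total-least-squares line fall-back for flat membrane–condensate
interfaces. The threshold is deliberately conservative: replacing an arc of
radius r and half-chord a by its chord biases the endpoint tangent by
asin(a/r), so flattening is reserved for arcs where that bias is
negligible (< 0.03°). Callers that know the imaging field size can pass a
coarser threshold (e.g. one tenth of the field of view).

**Contact angles.** The two contact points are computed as the
intersections of the vesicle (ie) and condensate (ce) circles; the ic model
must pass within a tolerance (default 5% of the condensate radius) of both,
otherwise the geometry is rejected as inconsistent. At each contact point
the into-arc tangent ray of each interface is selected by which side of the
other circles the arc continues on (the ie arc leaves the condensate disc,
the ce arc leaves the vesicle disc, the ic arc runs under the condensate);
the three rays partition the neighbourhood into the interior, exterior and
condensate sectors, and each apparent angle is the sector between its two
bounding rays that does not contain the third ray. This assignment uses
only the fitted centres, needs no pixel-region labelling, is independent of
image chirality, and makes θ_i + θ_e + θ_c = 360° hold exactly at each
point. Angles from both contact points are averaged; a left/right
disagreement above 5° (symptomatic of a mis-aligned projection plane)
raises an error rather than silently averaging. Angles are degrees in the
API, radians internally.

**Fluid-elastic parameters.** From the closed tension triangle, the law of
sines gives Σ_ie = Σ_ce sin θ_c / sin θ_i and Σ_ic = Σ_ce sin θ_e / sin θ_i;
the geometric factor Φ = (sin θ_e − sin θ_c)/sin θ_i equals both the
rescaled affinity contrast W/Σ_ce and cos θ_e^in. Φ is undefined at
θ_i ∈ {0°, 180°} (raised as an error); values outside [−1, 1] by more than
1e−9 are rejected, smaller excursions clamped before arccos. Σ_ce is a
supplied material constant per condensate system (15.7 µN/m for glycinin
under the reference buffer conditions); it is not estimated here. The
common membrane tension Σ and the individual adhesion parameters W_ic, W_ie
enter only through Σ_ie = Σ + W_ie and Σ_ic = Σ + W_ic and are not
identifiable from angles plus Σ_ce; only W = W_ic − W_ie is reported.
On the valid domain, at fixed θ_i, Φ = −2 cos((360° − θ_i)/2) ·
sin((θ_c − θ_e)/2) / sin θ_i is strictly increasing in θ_c − θ_e, with
θ_c → 0 at complete wetting (Φ = −1) and θ_e → 0 at dewetting (Φ = +1).

**Consistency report.** `validate_geometry` reports the angle-sum deviation
from 360° (tolerance 1° for experimental input; the synthetic noiseless
contract is 1e−6°), the Φ range check, and the closure residual of the
tension triangle (unit vectors laid head-to-tail with exterior turns equal
to the apparent angles). Noisy inputs produce bounded deviations and flags,
never exceptions.

## Electrokinetics

Drift velocity is the least-squares slope of the trajectory projected onto
the field axis (robust to superimposed Brownian motion, unlike endpoint
displacement); the fit's standard error and R² are reported. The
ζ-conversion implements the liquid-droplet-modified Smoluchowski relation
ζ = 3η_c ν/(ε₀ε_r E) · 1/(3η_e + κR) exactly as conventionally written.
The bracketed sum adds the numeric SI value of a viscosity (Pa·s) to the
dimensionless product κR and is therefore dimensionally heterogeneous as a
formula; the implementation fixes the convention — all inputs in SI units
(Pa·s, 1/m, m, F/m, V/m, m/s) — and the forward and inverse maps share it,
so simulated tracks round-trip exactly. The electrode geometry is not
modelled; the field magnitude E is taken as given per experiment.

## Synthetic data

The generators define the study conditions for every recovery test; all are
deterministic given (parameters, seed).

* **Hyperspectral vesicles.** Pure-component spectra are single Gaussians
  sampled on the channel grid and unit-normalised — defaults: gel-like
  440 nm / σ 25 nm, fluid-like 490 nm / σ 35 nm, a 50 nm centre separation
  matching the packing-driven spectral shift between the most ordered and
  most fluid bilayers. (The centre-of-mass separation of the discretised
  spectra is ~44 nm because the acquisition window truncates the gel
  spectrum's blue tail.) Membrane pixels form a ring (default 64 × 64 image,
  radius 20 px, half-width 2 px); each mixes the references at fraction f
  scaled to a photon budget (default 10⁴ photons/pixel) with Poisson noise
  per channel. Detector read noise is omitted: shot noise dominates at
  confocal photon budgets and keeps recovery tolerances derivable from
  binomial statistics. No optical PSF, no 3-D stack.
* **Wetting geometry.** A tension triple (Σ_ce, Σ_mean ∓ W/2) fixes the
  apparent angles through the law of cosines on the tension triangle
  (apparent = 180° − interior, so the triple sums to 360° exactly); three
  arcs are constructed meeting at (±a, 0) with exactly those sector angles,
  the vesicle arc at its prescribed radius (default 10 µm, 0.1 µm/pixel).
  The one remaining shape degree of freedom, the contact-ring ratio
  c = a/R, defaults to sin(clip(θ_e/2, 5°, 65°)), keeping the condensate
  cap well conditioned over the whole valid angle domain; `flat_ic=True`
  instead picks c = sin θ_i (θ_i > 90°), the geometry whose ic interface is
  exactly flat. Points are sampled uniformly in arc angle (default
  200/arc) in continuous coordinates (x right, y down, 0-based pixel
  centres) with isotropic Gaussian noise in pixel units. Projection
  misalignment and segmentation are not simulated — contours are inputs.
* **Drift tracks.** Uniform drift at the ζ-implied velocity plus Gaussian
  Brownian increments of variance 2D·dt per coordinate (defaults
  D = 0.05 µm²/s, 1000 s at 1 Hz, E = 1 kV/m). Default medium: η_c = 3 Pa·s
  (protein-condensate scale), η_e = 1 mPa·s, κ = 1.27·10⁹ m⁻¹ (150 mM 1:1
  electrolyte), R = 5 µm, ε_r = 78.4. Electroosmotic flow and droplet
  deformation are not modelled.

Because the generators share the analytic structure the analyses assume
(exact tension-triangle geometry, exact two-component mixing, ideal
Brownian drift), passing recovery tests demonstrate the correctness and
noise robustness of the inference chain — not segmentation quality,
spectral calibration, or optical artefacts in real microscopy data.

## Pipeline

`RunConfig` (pydantic-validated YAML/JSON) drives simulate → phasor /
wetting / zeta → report. Per-condition aggregation is mean ± SD across
images; group-comparison statistics are intentionally out of scope. Outputs
are CSV tables plus a JSON run log recording package versions, the master
seed and per-stage messages; a fixed (config, seed) reproduces results
bit-for-bit. Stage failures raise errors naming the stage.

## Problem sizes and tolerances in the test suite

Recovery tests use 20 vesicle images per fraction at 10⁴ photons/pixel
(|CM − f| ≤ 0.05), 500 random tension triples (Φ within 1e−3 noiseless,
0.05 at 0.5-pixel contour noise; angle sums within 1e−6°/1°), and 100
seeded 1000-s tracks (ensemble-mean ζ within 2%). Random triples are drawn
with |W| ≤ 0.85 Σ_ce and Σ_mean ∈ [0.75, 2] Σ_ce, resampled until all
apparent angles lie in [15°, 165°]: outside that band sin θ_i → 0 and the
geometric factor is undefined by its own formula, so such couples are not
measurable by this method in the first place.

## Known limitations

* The fraction axis and cursor positions are conventions; CM values are
  comparable only within a fixed axis choice.
* Apparent-angle extraction assumes the projection plane contains the
  symmetry axis; misalignment surfaces as left/right asymmetry (> 5° is an
  error) but is not corrected.
* Σ, W_ic and W_ie are not individually identifiable (see above).
* The ζ relation inherits the printed form's unit convention; comparisons
  across tools must use the same convention.
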