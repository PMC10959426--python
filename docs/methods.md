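# Methods

This note documents the models behind `bolusdose`, the defaults and why they
were chosen, and what the package's tests do and do not establish about real
beams.

## Material model

A material is a set of elemental mass fractions `w_i` plus a mass density ρ
(g/cm³).  Nine materials are bundled (five boluses: water, polystyrene, PLA,
glycerol, silica-gel; four tissues: skin, soft tissue, muscle, lung at
0.5000 g/cm³ — the inflated-lung density, configurable over the physiological
0.345–0.746 g/cm³ range).  Derived quantities are pure functions of
(composition, ρ):

* **Electron density** ρₑ = ρ Σ wᵢZᵢ/Aᵢ, reported in units of N_A per cm³.
* **Effective atomic number** Z_eff = (Σ αᵢZᵢ^m)^{1/m} with the fractional
  electron contributions αᵢ = (wᵢZᵢ/Aᵢ)/Σⱼ(wⱼZⱼ/Aⱼ) as weights and m = 3.4
  by default (the photoelectric-regime exponent used for tissue-equivalence
  work).  Electron-fraction weighting — not mass-fraction weighting —
  reproduces the published derived columns for all nine materials within
  ±0.001 (ρₑ) and ±0.05 (Z_eff); the residuals (~3 × 10⁻⁴ relative) are the
  footprint of whichever atomic-weight table the original derivation used,
  which is not stated anywhere we could check.
* **Mean excitation energy** via Bragg ln-additivity over electron fractions
  with ICRU-37 elemental (gas-phase) I-values; no condensed-phase
  adjustment.  This yields I(water) ≈ 69 eV instead of the condensed-phase
  75–78 eV — a known, documented bias of order 1 % on stopping power.
* **Collision stopping power**: Berger–Seltzer/Møller form.  The
  density-effect correction is omitted; below 10 MeV in unit-density media
  this biases S_col high by a few percent.  Both simplifications are why the
  engine is a structural stand-in, not a reference dosimetry code.
* **Radiative stopping power**: high-energy asymptote S_rad = (E + mₑc²)/X₀,
  used only to ledger bremsstrahlung losses.
* **Radiation length** by inverse additivity 1/X₀ = Σ wᵢ/X₀ᵢ (PDG elemental
  values); **CSDA range** as the quadrature of 1/S_col from a 0.01 MeV floor.
  Collision-only CSDA for water at 6 MeV comes out 2.94 g/cm², within 4 % of
  the published 3.05 g/cm².

The elemental table (Z, standard atomic weight, ICRU-37 I, PDG X₀) ships as
a versioned constants module covering H–Ca plus Fe.

## Treatment models and scoring

Both families are 30 × 30 cm slab stacks at 100 cm source-to-surface
distance, with the beam entering the bolus (layer 1) and depth 0 at the bolus
top.  Skin is fixed at 0.3 cm; layer 4 is 30 cm of soft tissue (S-T) or lung
(P-B).  The bundled scenario table pairs layer-3 thickness 0.5/1.0/1.5 cm
with 6/6/9 MeV beams and 1.0/0.5/1.0 cm boluses.  Dose is scored in
1.0 × 1.0 × 0.1 cm voxels along the central axis; layer thicknesses must be
commensurate with the 0.1 cm bin (all bundled scenarios are), so no partial
voxels exist.  Voxel material is taken at the bin center; voxel mass is
ρ × 0.1 g.  Changing the bolus material never changes the geometry — only
layer-1 voxel materials and masses.

## Transport engine

Class-I condensed history, electrons only:

* **Source**: point source at 100 cm, positions uniform over the 10 × 10 cm
  field footprint, directions through the sampled point, energy
  Normal(E₀, σ_E) truncated positive (σ_E = 0 by default).  This is a
  parameterized stand-in for an accelerator phase-space file.
* **Stepping**: path limited by min(0.05 cm, distance to the next 0.1 cm
  depth plane, 5 % of the residual CSDA range).  Because every layer
  interface lies on the 0.1 cm grid, each step sees one material and the
  midpoint bins into the correct voxel.  Energy loss per step is
  S_col·ρ·s, optionally perturbed by Bohr-variance Gaussian straggling
  (on by default), clamped to [0, E]; radiative loss S_rad·ρ·s is removed
  from the electron and ledgered, never deposited.
* **Scattering**: Highland plane-projected σ_θ = (13.6 MeV/βpc)·√(x/X₀)·
  (1 + 0.038 ln(x/X₀)), the log factor clamped at 0.1 for very short steps;
  space deflection sampled from two independent projected Gaussians with a
  uniform azimuth.
* **Termination**: electrons below 0.2 MeV (≈ 0.5–1 mm residual range in
  water, mirroring a millimetre-scale production cutoff) deposit locally;
  electrons leaving the slab deposit their kinetic energy in the escape
  ledger.
* **Variance reduction**: concentric lateral importance regions — beyond the
  field margin (weight 1), near environment (10), on-axis column ±1 cm
  (100), the 1 × 1 cm scoring column (1000).  Crossing inward splits a track
  into ⌊r⌋ (+1 with probability frac r) copies of weight w/r; crossing
  outward survives with probability r at weight w/r.  Expected weight is
  conserved exactly; roulette makes the realized ledger stochastic, which is
  why energy conservation is exact in analog mode and a ~3σ statement under
  splitting.  The region geometry is an interpretation: the published
  weights are named per region but without coordinates.
* **Uncertainties**: histories are split into ≥ 2 batches (default 10) with
  independent, deterministically derived substreams; the per-voxel relative
  error is the standard error of batch means.  Dose unit: MeV/g per source
  electron.

Known limitations: no δ rays, no photon transport (the bremsstrahlung tail
of real beams is absent — deep-tail doses here decay to ~0), no density
effect, Gaussian small-angle scattering only.  Consequently the engine
reproduces *structure* (conservation, ranges, material ordering,
falloff shape) and is not expected to reproduce published absolute RD
extrema, which require full condensed-history physics and the vendor beam
model.

**Problem sizes.**  The bundled tests run 2–15 × 10⁴ histories per
simulation, a size at which the structural claims resolve clearly (the
lung-dose ordering across boluses separates by ≥ 2 combined standard errors
at 1.5 × 10⁵ histories); production-scale runs of the original study design
used ~10⁹ events.  History counts, batches and seeds are configurable.

## Analytic curve generator

The water-beam shape is

    PDD(d) = 100 · b(d) · F(d) / max + t(d),

with a quintic-smoothstep build-up b from the surface fraction (default
80 %) to 1 at d_max, a Gaussian-CDF falloff F(d) = ½ erfc((d − R50)/√2 σ_f),
and a pedestal t(d) = t₀ e^{−μd} (t₀ = 0.6 % of max, μ = 0.05 cm⁻¹ —
a photon-contamination level and attenuation typical of 6–9 MeV beams).
Empirical parameter rules: Rp = 0.521 E − 0.376 cm, R50 = E/2.33 cm,
d_max = 0.46 E^0.67 cm for 4–20 MeV.  Two shape choices deserve comment:

* The falloff is an error function, not a logistic.  Range straggling makes
  the log-slope of a real electron falloff steepen with depth; a logistic's
  exponential tail saturates instead, which would make RD ratios plateau
  mid-falloff and park the detected extrema at unrealistically high water-PDD
  levels.  With the erfc form the extrema land where the water PDD is ~1–8 %,
  matching where published extrema sit (1.0–3.5 %).
* σ_f = falloff_gradient × (Rp − R50) with falloff_gradient = 2.0 by
  default, chosen to reproduce clinical falloff slopes (~60 %/cm at 6 MeV,
  ~45 %/cm at 9 MeV); the empirical Rp and R50 rules above are individually
  standard but their difference is too narrow to set the falloff width
  directly.
* The build-up uses a quintic smoothstep so the curve is C² at the peak;
  a clipped trigonometric build-up has a curvature kink there that biases
  sub-voxel peak refinement by ~5 × 10⁻³ cm — enough to leak ~1 % errors
  through the steep falloff after alignment.

Material dependence enters in two ways.  Depth is remapped to
water-equivalent depth through the slab stack using electron-density ratios,
so a denser-electron bolus pulls the whole curve shallower (an all-water
stack is the exact identity).  Separately, a clearly phenomenological tail
multiplier, linear in the bolus Z_eff excess over water
(tail_z_coeff = 0.1 per Z unit in the study generator), emulates the
observed high-Z pedestal enhancement; its size was set so the synthetic S-T
effect magnitudes (extrema roughly −20 % to +40 %) match the published ones.
The generator is *not* a beam model: it exists so the analysis chain can be
tested against exact ground truth (true curves, true d_max, true shifts are
stored alongside every curve).

Noise is multiplicative Gaussian with a piecewise-linear relative sigma vs
depth — 0.5 % through the falloff (anchors at 3.1–4.6 cm) rising to 1 % in
the deep tail (9.5–16 cm), the error envelope of the full-scale Monte Carlo
runs this emulates — and the recorded `rel_err` column always equals the
generating sigma, so no analysis is ever tested against noise it is not told
about.  What passing these tests shows about real data: that the pipeline
recovers shifts, extrema and orderings from curves with the *stated* shape
and noise structure; real beams add spectral effects, photon tails and
off-axis physics the generator deliberately omits.

## Relative-dose analysis

* PDD conventions: max-normalized (S-T) or reference-voxel-normalized at the
  deepest muscle voxel (P-B).  Conversions are pure functions; switching
  conventions never mutates raw curves.
* d_max: discrete argmax (ties to the shallower depth) refined by a local
  cubic-spline maximization (derivative roots), exact on polynomial peaks.
  A least-squares quadratic refinement was evaluated for noisy curves and
  rejected: its window bias on the asymmetric peak exceeded the spline's
  noise jitter.
* Alignment (S-T only): each curve is shifted rigidly by
  Δ = d_max(water) − d_max(M) and linearly interpolated onto the water grid
  (the 0.1 cm grid is fine relative to curve curvature).  A rigid shift
  cannot be exact when the water-equivalent offset differs between layers
  (skin vs soft tissue); the residual is ≲ 0.01 cm and is part of the
  method, not a defect.
* RD = PDD_M/PDD_water × 100 beyond the reference depth; points with water
  PDD < 0.01 % are masked, not divided.
* Extremum: the point maximizing |RD − 100| inside the falloff region,
  defined as water PDD ∈ [1 %, 90 %] (configurable); ties break shallow.
  The stabilization region is water PDD < 1 %; its summary is the mean RD
  and a materials ranking.  Under measurement noise the detected extremum is
  a random variable — the acceptance tests therefore assert its location
  band on the median over noise replications and its value against 3× the
  replication spread, on the P-B family where the generator plants
  pronounced physics-driven minima; noisy S-T extrema are dominated by
  d_max-alignment jitter through the steep falloff, a real property of the
  alignment convention.
* The practical-range helper extrapolates the steepest tangent of a lightly
  smoothed curve to the tail level; with no transported photons the tail
  level is ~0.

## Workflow and formats

Curves are CSV with `#key: value` metadata lines, a fixed header
(`depth_cm,dose_per_history_MeV_per_g,rel_err`) and %.6g numbers (bit-stable
after one write/read cycle); configs and manifests are JSON.  The study
runner enumerates 2 families × 3 rows × 5 materials = 30 curves and 24
report rows, derives per-curve seeds deterministically from the study seed,
continues past per-scenario failures, and writes a manifest (config, seed,
package version, failures) sufficient to regenerate every artifact.  The
`bolusdose` CLI is a thin layer over these functions.
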