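# bolusdose

Electron-beam bolus dosimetry in layered slab phantoms: how does the choice
of bolus material change the dose deposited in deep tissue?

A bolus is a tissue-equivalent slab placed on the skin during electron-beam
radiotherapy to pull the dose build-up region toward the surface so that
superficial targets receive full dose.  Clinics use several bolus materials —
water, polylactic acid (PLA), polystyrene, silica-gel, glycerol — and these
differ radiologically (electron density, effective atomic number), so the
dose reaching the normal tissue *behind* the target differs too.  This
package implements a desk-scale comparative study of that effect:

* **materials** — elemental mixtures with derived radiological properties:
  electron density ρₑ = ρ Σᵢ wᵢZᵢ/Aᵢ (in units of N_A/cm³), effective atomic
  number Z_eff = (Σᵢ αᵢZᵢ^m)^{1/m} with electron-fraction weights αᵢ and
  m = 3.4, mean excitation energy (Bragg ln-additivity), Berger–Seltzer
  collision stopping power, radiation length, CSDA range.
* **phantoms** — two four-layer treatment-model families on a 0.1 cm
  central-axis scoring grid: the superficial-tumor model
  (bolus / 0.3 cm skin / soft tissue / 30 cm soft tissue, "S-T") and the
  postoperative-breast model (bolus / skin / muscle / 30 cm lung, "P-B"),
  with three bundled geometry rows pairing layer-3 thickness
  {0.5, 1.0, 1.5 cm} with beam energy {6, 6, 9 MeV} and bolus thickness
  {1.0, 0.5, 1.0 cm}.
* **transport** — a simplified class-I condensed-history electron Monte
  Carlo engine (continuous collision loss, Highland multiple scattering,
  optional Bohr straggling, ledgered radiative losses) with geometric
  importance splitting (region weights 1/10/100/1000 from the periphery to
  the scoring voxels) and batch-based uncertainties.
* **synthetic** — an analytic depth-dose generator (build-up, Gaussian-CDF
  falloff through R50, bremsstrahlung pedestal) with electron-density depth
  scaling and a labelled phenomenological Z_eff tail knob, plus a noise model
  matching the Monte Carlo error envelope, so the analysis chain is testable
  against exact ground truth.
* **analysis** — the comparison statistic itself.  Curves are normalized to
  percentage depth dose (PDD) either at the depth of maximum dose d_max
  (S-T convention, with d_max alignment across materials) or at the deepest
  muscle voxel (P-B convention), and each material M is compared with the
  water bolus through the relative dose

      RD(d) = PDD_M(d) / PDD_water(d) × 100 %

  for depths beyond the reference.  The report gives, per scenario and
  material, the extremum of |RD − 100| inside the falloff region (water PDD
  between 1 % and 90 %), its depth, the co-located water PDD, and the mean
  RD over the stabilization region (water PDD < 1 %).

## Worked example

Material characterization from the command line:

```
$ bolusdose materials show glycerol
material: glycerol
composition (mass %): H 8.8, C 39.1, O 52.1
density: 1.2613 g/cm^3
electron density: 0.6851 N_A/cm^3
effective atomic number (m=3.4): 6.9342
mean excitation energy: 68.44 eV
radiation length: 38.806 g/cm^2
CSDA range at 6 MeV: 3.003 g/cm^2 (2.381 cm)
CSDA range at 9 MeV: 4.417 g/cm^2 (3.502 cm)
```

The electron density (0.6851 N_A/cm³ ≈ 4.13 × 10²³ electrons/cm³) is the
highest of the five bolus materials — which is why glycerol shields the lung
best in the P-B model below.

Running the full study grid (2 families × 3 geometry rows × 5 materials)
with the analytic engine:

```python
import bolusdose as bd

result = bd.run_study(bd.StudyConfig(seed=7))
row = result.report.query(
    "scenario == 'PB_L3-0.5cm_E6MeV_bolus1cm' and material == 'glycerol'"
).iloc[0]
print(row[["extremum_rd_pct", "extremum_depth_cm_from_skin",
           "water_pdd_at_extremum_pct", "tail_mean_rd_pct"]])
```

prints

```
extremum_rd_pct                28.125141
extremum_depth_cm_from_skin         3.35
water_pdd_at_extremum_pct       6.954081
tail_mean_rd_pct               96.212355
```

Read: with a 1 cm glycerol bolus and a 6 MeV beam, the dose in lung falls to
28 % of what a water bolus would deliver at the same depth, with the minimum
reached 3.35 cm behind the skin surface where the water-bolus PDD has already
dropped to ~7 %; in the deep stabilization region the two boluses converge to
within a few percent.  The ordering across materials (glycerol lowest, then
silica-gel, PLA, polystyrene) follows the bolus electron density.

The same grid can be driven by the Monte Carlo engine
(`StudyConfig(engine="transport", histories=...)`) or from the shell:

```bash
bolusdose run-study --engine synthetic --seed 7 --out out/
bolusdose simulate --scenario scenario.json --histories 100000 --seed 1 --out curve.csv
bolusdose analyze --curves out/curves --family PB
```

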