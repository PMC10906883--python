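# pemscat

Monte Carlo toolkit for studying **crystal-scatter effects in a dual-panel
positron emission mammography (PEM) scanner**.

Dedicated breast-PET scanners read out 511 keV annihilation photons in two
parallel LYSO panels a few centimetres apart. Inside the scintillator a
photon rarely deposits its energy in one spot: about two thirds of
interactions are Compton scatterings, so most detected photons leave a
*chain* of energy deposits. The detector assigns the photon the
energy-weighted centroid of that chain (EWP), while the physically correct
line-of-response endpoint is the *first* interaction position (FHP). The
distance between the two,

```
Δr_xy = sqrt((X_EW − X_FH)² + (Y_EW − Y_FH)²),
```

is the in-plane positioning error, and its effect propagates through
list-mode reconstruction into lost image contrast. `pemscat` simulates the
whole chain — photon transport, digitization, coincidence sorting,
interaction-chain classification, limited-angle list-mode OS-MLEM
reconstruction and Derenzo-phantom image-quality metrics — for two panel
configurations: monolithic 57.4×57.4×10 mm³ crystals and pixelated
40×40 arrays of 1.35×1.35×10 mm³ crystals at 1.44 mm pitch.

## What is inside

| module | role |
|---|---|
| `pemscat.geometry` | dual-panel scanner spatial model (blocks, pixels, gaps, element lookup) |
| `pemscat.physics` | LYSO attenuation coefficients (mixture rule over embedded Lu/Y/Si/O tables), Klein-Nishina sampling |
| `pemscat.sources` | cuboid / miniDerenzo / planar back-to-back pair emitters with Poisson timing |
| `pemscat.transport` | Woodcock delta-tracking of photon chains (photoelectric + Compton only) |
| `pemscat.digitizer` | energy-weighted singles, 13% energy blur, 6 µs block dead time, 350–750 keV window, 6 ns coincidence sorter |
| `pemscat.classify` | SI/MI coincidence classes, chain statistics, positioning-error histograms, spectra |
| `pemscat.recon` | virtual-crystal LOR conversion, Siddon projector, planar-source sensitivity, list-mode OSEM, Gaussian post-filter |
| `pemscat.metrics` | peak-to-valley ratios, per-rod 2D Gaussian FWHM, resolvability index RI = FWHM/d |

## Worked example

Simulate a uniform 15×10×6 cm³ source between monolithic panels and look
at how coincidences decompose:

```python
import pemscat as pm

run = pm.run_study("monolithic", "cuboid", 500_000, seed=1)
stats = pm.classify_coincidences(run.singles, run.coincidences)
errs = pm.positioning_errors(run.singles, run.coincidences)
print({k: round(100 * v, 1) for k, v in stats.class_fractions.items()})
print(round(errs.mean, 2), round(errs.percentile(80), 2))
```

prints (seed 1):

```
{'SI-SI': 19.6, 'MI-SI': 49.7, 'MI-MI': 30.7}
1.76 2.78
```

i.e. only ~20% of registered coincidences are "clean" single-interaction
pairs; the rest involve at least one scattered chain, and the typical
assigned-vs-true position discrepancy over those events is ~1.7 mm with
80% of events inside 2.8 mm.

A full image-quality study — miniDerenzo phantom, planar-source
normalization, 2 iterations × 28 subsets, reconstructed once with
first-hit and once with energy-weighted LOR endpoints:

```python
run, images = pm.derenzo_pipeline("monolithic", seed=1)
rep_fhp = pm.analyze_sector(images["fhp"], run.phantom.rods, 2.0)
rep_ewp = pm.analyze_sector(images["ewp"], run.phantom.rods, 2.0)
print(round(rep_fhp.pvr_mean, 1), round(rep_ewp.pvr_mean, 1))
```

Typical output is a 2 mm-rod peak-to-valley ratio of order 70–90 for
first-hit positioning versus 6–9 for energy-weighted positioning: crystal
scatter costs roughly an order of magnitude in hot-rod contrast while the
rods themselves stay resolved in both images.

There is also a thin CLI:

```bash
pemscat geometry --mode pixelated --dump
pemscat simulate --mode monolithic --phantom derenzo --events 2e6 --seed 7 --out run.h5
pemscat classify run.h5 --report report.json
pemscat recon run.h5 --norm norm.h5 --position-mode fhp --out img.nii
pemscat metrics img.nii --sector 2.0
```

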