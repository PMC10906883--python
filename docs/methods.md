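# Methods

`pemscat` is a self-contained Monte Carlo model of a dual-panel PEM
scanner built to quantify what intra-crystal Compton scattering does to
event positioning and reconstructed image quality. This note records the
model, its parameters and defaults, the numerical choices, and what the
simulation does and does not capture.

## Scanner model

Two parallel panels face each other across a 60 mm gap (a moderate breast
compression); the panel-separation axis is z, images are formed in the
(x, y) plane. Each panel is a 3×3 array of LYSO blocks, 10 mm thick, with
inner crystal faces at z = ±30 mm:

* **monolithic** — one 57.4×57.4×10 mm³ crystal per block; sensitive
  panel span 172.2 mm;
* **pixelated** — 40×40 crystals of 1.35×1.35×10 mm³ at 1.44 mm pitch per
  block. The pitch-derived footprint (57.6 mm) is taken as the block
  size, so the panel spans 172.8 mm and every crystal sits strictly
  inside its block with a 45 µm half-reflector margin. The ~90 µm
  specular-reflector gaps are modeled as vacuum: at 511 keV the polymer
  is optically decisive but radiologically negligible, and treating it as
  dead-but-transparent isolates the effect under study (gaps alter photon
  tracks and remove sensitive volume).

The light guide, silicone coupling and SiPM array behind the crystals are
not modeled as attenuating volumes; only crystals interact. The total
LYSO volume ratio monolithic/pixelated is 1.13, which is what drives the
~20% sensitivity advantage of the monolithic panels.

Coordinate conventions: element boundaries are half-open and
lower-edge-inclusive on every axis, which makes point location
deterministic on boundaries.

## Photon physics

Only photoelectric absorption and Compton scattering are modeled — the
processes that dominate 511 keV transport in LYSO. Rayleigh scattering,
Doppler broadening, fluorescence X-rays and secondary-electron transport
are excluded; energy is deposited exactly at each interaction point.
Compton angles follow the free-electron Klein-Nishina distribution
(sampled by rejection under the forward-scatter bound, which is exactly 2
in units of the unnormalized density for every energy).

Attenuation coefficients come from the mixture rule
µ = ρ Σᵢ wᵢ (µ/ρ)ᵢ over elemental tables for Lu, Y, Si and O shipped with
the package (LYSO as Lu₂₍₁₋ₓ₎Y₂ₓSiO₅, x ≈ 0.1, ρ = 7.4 g/cm³; mass
fractions Lu 0.714, Y 0.040, Si 0.064, O 0.181). The incoherent columns
are exact free-electron Klein-Nishina totals (so the sampler and the
cross section are mutually consistent); the photoelectric columns use a
smooth two-parameter log-log shape anchored at 511 keV with K-edge jumps
for Lu (63.3 keV) and Y (17.0 keV) and an E⁻³ continuation below
100 keV. The anchor reproduces the standard XCOM-scale partition for
LYSO at 511 keV: µ_tot ≈ 0.82 cm⁻¹ with a 67% Compton share. Below
~60 keV the tables are deliberately crude (no L-edges); photons there
have sub-0.1 mm mean free paths and terminate immediately, so no studied
observable is sensitive to that region. Tables are interpolated log-log
and cached on a 0.25 keV grid for O(1) lookup in the tracking kernel.

## Transport

Each back-to-back pair is two 511 keV photons with isotropic common axis.
A photon is tracked only inside the panel slab its direction points at,
using Woodcock delta-tracking with the LYSO total attenuation as
majorant: tentative collisions in reflector gaps or outside the block
span are virtual, which reproduces segment-wise exponential attenuation
exactly without ray-tracing crystal boundaries. At a real collision the
process is photoelectric with probability µ_pe/µ_tot (deposit all
remaining energy, terminate) or Compton (deposit E − E′, rotate, continue).
A chain ends at photoelectric absorption or when the photon exits the
slab; a back-scattered photon heading to the opposite panel is treated as
escaped (cross-panel chains are vanishingly rare and have no consistent
single-panel centroid). Hit times include the flight path at c.

## Digitizer and coincidence chain

Per photon, hits merge into a *single*: energy-weighted centroid (EWP)
over all of the photon's hits in the panel, first-hit position (FHP),
summed energy, chain label. The energy is blurred once per single with a
Gaussian of FWHM(E) = 0.13·√(511·E) keV (13% at 511 keV, 1/√E scaling).
Dead time is non-paralyzable, 6 µs per detector block, applied to the
time-ordered singles stream before the energy window. Singles inside
350–750 keV are then grouped into clusters whose consecutive gaps are
≤ 6 ns; clusters of exactly two singles in opposite panels become
coincidences, larger clusters are discarded. A coincidence is *random*
when its two singles come from different decays.

At the cuboid study's nominal activity (3.7 kBq/ml over 900 ml =
3.33 MBq) this parameter set is internally strained: the 6 µs
block dead time removes about half the singles and randoms reach ~2.5% of
coincidences. The classification fractions and positioning-error
statistics are insensitive to both effects (dead time is chain-agnostic),
and at the Derenzo/planar activities (tens of kBq) both are negligible.

The classification is hit-based: a photon with one hit is a single
interaction (SI) — a photoelectric absorption or a single Compton that
escapes — and a photon with two or more hits is a multiple interaction
(MI), even when all hits share one crystal element. Coincidences are
SI-SI, MI-SI or MI-MI accordingly.

### Positioning errors

For every MI-SI and MI-MI coincidence both photons contribute an in-plane
EWP-FHP distance; the SI partner of an MI-SI pair contributes an exact
zero, and SI-SI coincidences (identically zero on both sides) are
excluded. This per-coincidence-photon population is what the reported
mean and the cumulative "fraction of events within Δr" curve use; a
`mi_only` switch restricts the population to the scattered photons
themselves (whose mean is correspondingly ~40% larger).

## Reconstruction

Dual-panel geometry is limited-angle, so images come from list-mode OSEM.
LOR endpoints are the chosen per-photon position (FHP or EWP) snapped
in-plane to the center of a 1.44 mm virtual-crystal cell within its block
and placed axially on the inner crystal face (z = ±30 mm). The 1.44 mm
virtual pitch mirrors the pixelated crystal grid, which makes the two
crystal modes directly comparable; it is configurable. The projector is
exact Siddon ray tracing on a 174×174×24 grid of 1×1×2.5 mm³ voxels.

The sensitivity image is the Siddon backprojection of a simulated planar
normalization acquisition (back-to-back source at z = 0 covering the
FOV), rescaled to unit mean over traversed voxels. OSEM uses round-robin
subset assignment in list order, 2 iterations × 28 subsets by default;
voxels never traversed by normalization LORs stay zero, and events whose
forward projection vanishes are skipped and counted. An optional
post-reconstruction filter is a separable 3D Gaussian (1.5 mm FWHM
default) with per-axis sigma in voxel units.

Default study sizes: 13.6×10⁶ Derenzo emissions and 8×10⁶ planar
normalization emissions per crystal mode (the Derenzo count is the
study's nominal acquisition size; the normalization count keeps sensitivity
noise well below the image noise); the cuboid interaction study uses
5×10⁵ emissions, which puts ~1 percentage-point statistics on the class
fractions. A full Derenzo pipeline runs in about two minutes on one CPU.

## Image-quality metrics

Analysis uses the mean of reconstructed slices 11–14 (1-based), the slab
the phantom occupies. For a rod sector, intensity profiles run through
each lattice row of rod centers (linear interpolation at 0.05 mm steps);
a rod's peak is the profile maximum within ±d/4 of its center, the valley
is the minimum between adjacent peaks, and each adjacent pair contributes
PVR = mean(two peaks)/valley (+∞ is reported and flagged when a valley is
exactly zero). Per-rod axis-aligned 2D Gaussians with constant offset are
least-squares fitted in a 1.5·d square window (d = 2×diameter is the
center spacing); rods within 2 mm of another sector's rods are excluded
from fits, and degenerate fits (r² < 0.5) are dropped from sector
summaries. The resolvability index is RI = FWHM/d; RI < 1 means the rods
are distinguishable.

## Synthetic phantoms

* **Cuboid**: 15×10×6 cm³, uniform, 3.7 kBq/ml — a breast-sized
  background volume.
* **miniDerenzo**: ⌀50 mm × 20 mm cylinder with hot rods of 1, 1.5, 2,
  3, 4, 5 mm in six 60° sectors, center spacing twice the diameter,
  3 kBq/ml in the rods only. Rod placement is a per-sector triangular
  lattice growing from the center with a 2 mm rim margin and a one-
  diameter clearance to sector boundaries (74/32/17/6/3/3 rods for the
  six sizes).
* **Planar**: zero-thickness 172.2×172.2 mm sheet at z = 0 for
  normalization.

All phantoms are air-like: no attenuation or scatter in the phantom body,
no positron range, no photon non-collinearity. This isolates crystal
scatter — it also means the absolute sensitivity and the sharpness of the
reconstructions are upper bounds on what a physical system would show.
The detector positioning is ideal (no scintillation-light transport), so
the positioning-error histograms have an unphysically sharp core, and
first-hit reconstructions resolve rods more sharply than any real readout
would.

## Numerical choices and degenerate inputs

* Boundaries half-open lower-inclusive everywhere; virtual-cell snapping
  clamps out-of-span positions to edge cells.
* The Woodcock majorant is re-evaluated after every energy change; energy
  lookups clamp to the 10–750 keV table.
* Chains are capped at 64 recorded hits (never reached in practice).
* Siddon accumulates exact parametric crossings; the chord-length sum is
  conserved to machine precision and degenerate (grid-missing) LORs yield
  empty rows.
* OSEM keeps images non-negative by construction; likelihood monotonicity
  holds for the 1-subset (pure MLEM) case.
* The 2D Gaussian rod fit bounds centers to the window and reports
  non-converged fits as unfit rather than raising.
* All stochastic stages take explicit seeds; study drivers derive
  sub-seeds with `numpy.random.SeedSequence`, and transport processes
  emissions in fixed 2×10⁶-pair chunks so results are reproducible and
  memory-bounded.

## Known limitations

* Free-electron Klein-Nishina (no incoherent scattering function) and the
  parametrized photoelectric shape shift interaction-chain length
  statistics at the few-percent level relative to condensed-history codes.
* No fluorescence or electron transport: deposits are point-like, which
  sharpens both positioning-error histograms and reconstructions.
* The pixelated-mode positioning-error tail is shorter than a physical
  system with optical readout would show; gap-induced track lengthening
  alone extends it only mildly.
* The nominal digitizer parameters are kept verbatim even where they are
  mutually strained at the cuboid activity (see the dead-time/randoms
  remark above).
* Peak-to-valley ratios of first-hit reconstructions are intrinsically
  high-variance: their valleys approach zero, so sector means fluctuate
  strongly between seeds even at the full acquisition size.
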