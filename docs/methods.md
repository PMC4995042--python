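# Methods

This package is a forward-modelling study of a thresholding artifact in OCT
angiography (OCTA) of the choriocapillaris (CC) under drusen. It compares two
acquisition presets — a spectral-domain instrument at ~840 nm (`SD840`) and a
swept-source instrument at ~1050 nm (`SS1050`) — on a common synthetic macula,
and grades the resulting en face CC slabs the way a reading-center workflow
would. Everything below is implemented in `src/drusenshadow/` and exercised by
the test suite; no empirical claim in this note goes beyond what the tests and
`scripts/acceptance.py` themselves compute.

## The digital macular phantom (`phantom`)

A 3 × 3 mm lateral field with depth `z` in µm increasing away from the
instrument (`z = 0` is the zero-delay of the vitreoretinal protocol). Layers,
top down: vitreous, neurosensory retina, a 30-µm RPE band, druse material
(inside footprints), Bruch's membrane (BM, a flat plane), a 60-µm
choriocapillaris flow layer immediately below BM, and choroid. Default
surfaces: ILM at 150 µm, BM at 460 µm. The 30-µm "RPE band" is the reflective
RPE–Bruch complex as seen on OCT, not the 10-µm cellular monolayer.

Drusen are paraboloid domes `h(r) = h·max(0, 1 − (2r/d)²)` sitting on BM and
lifting the RPE band (a Gaussian profile is available via config). The dome
volume has the closed form `π·h·d²/8` (half base-area × height), which the
rasterised elevation map must reproduce to < 2 % — the geometry oracle in the
tests. Only drusen with lateral diameter ≥ 165 µm are analysis-eligible, the
study's inclusion rule for large soft drusen. The paper gives no druse
heights; the defaults use a dome aspect `height ≈ 0.45 × diameter` (90–225 µm
over the default 200–500 µm cohort), at the tall end of large soft
drusen/early drusenoid elevations. That choice is deliberate: the artifact
under study is driven by the optical thickness of the dome, and the default
cohort is meant to span the transition from "no visible shadow" to "shadow
deep enough to cross the OCTA display threshold".

A lateral flow map assigns erythrocyte speed (default uniform 3 mm/s, a
plausible CC transit speed) to the CC layer only. Zero-speed regions are true
flow voids — the ground truth that makes "false-positive flow impairment"
well defined. Scenarios: `uniform` (no true pathology anywhere),
`voids_under_drusen`, `voids_elsewhere`.

Per-tissue optics (reflectivity; attenuation in mm⁻¹ at 840/1050 nm):
vitreous 0 (0/0), retina 0.2 (1.0/0.8), RPE 1.0 (8.0/3.0), druse 0.4
(4.0/1.5), CC 0.6 (2.0/1.5), choroid 0.5 (2.0/1.5). The numeric values are
design choices — the literature constrains only the ordering (RPE and druse
attenuate 840 nm markedly more than 1050 nm) — and all are configurable. They
put the round-trip excess attenuation of a 225-µm druse dome at ~12 dB for
840 nm but ~3 dB at 1050 nm.

## The OCT forward model (`oct_simulator`)

Per voxel, the noise-free mean amplitude is

    A(x, y, z) = reflectivity(tissue) · exp(−2 ∫₀ᶻ µ(λ, s) ds) · S(z)

with round-trip Beer–Lambert attenuation computed analytically from the
piecewise-constant layer model, and a sensitivity roll-off
`S(z) = exp(−ln 2 · (z/z₆dB)²)` normalised to 1 at the zero-delay and ½ at
the 6-dB depth. `SD840` uses `z₆dB = 600 µm` (spectrometer detection);
`SS1050` uses `z₆dB = ∞` (swept-source detection is modelled as roll-off
free). Device presets carry the published acquisition parameters: SD840 —
70 kHz, 2 repeats × 304 × 304, Δt ≈ 5 ms, ~5 µm axial resolution; SS1050 —
400 kHz, 5 repeats × 500 × 500, Δt ≈ 1.5 ms, ~8.5 µm axial resolution.

Speckle is fully developed: each voxel's repeat amplitude is the modulus of a
circular complex Gaussian field scaled so its mean equals `A`. Flow
decorrelates the field between consecutive repeats by first-order mixing
`g_{n+1} = ρ g_n + √(1−ρ²) w` with complex correlation
`ρ = exp(−(vΔt/L_c)²)` and decorrelation length `L_c = 10 µm` — a smooth,
monotone, saturating law chosen for convenience, not claimed to match any
device. Because intensity correlation of jointly circular Gaussian fields
equals |ρ|², the mixed-in ρ is recoverable from simulated amplitudes, which
is how the Monte-Carlo test validates the construction (ρ = e⁻¹ recovered to
±0.02 over ~8 × 10⁴ voxels). Detection noise is an independent circular
complex Gaussian of scale σₙ added to every repeat, so a signal-free voxel
(vitreous) has exactly Rayleigh(σₙ) amplitude and signal voxels are Rician.

σₙ defaults to 0.03 for both presets. This sets the OCT amplitude SNR of the
unshadowed CC slab to ≈ 4–5 on SD840 — typical of clinical CC imaging — and
places the masking threshold (below) inside the dynamic range that druse
shadows actually traverse. With a much smaller noise floor the simulated
instrument would be cleaner than any clinical device and the thresholding
artifact this study is about could not occur at any plausible druse height.

Acquisition time and eye motion are not simulated; grids default to a
desk-scale 192 × 192 × 320 (axial pitch 3 µm) so a full two-device study runs
in well under a minute; the full device grids are available via
`use_device_grid`.

## Angiography and thresholding (`octa_engine`)

The angiogram is an unsplit, intensity-based pairwise decorrelation over
consecutive repeats:

    D = 1 − (1/(R−1)) Σₙ AₙAₙ₊₁ / (½(Aₙ² + Aₙ₊₁²)) ∈ [0, 1].

Identical repeats give D = 0; a pair with both amplitudes exactly zero
contributes 0 (an empty signal must not fabricate flow). The same unsplit
formula is deliberately applied to both simulated devices: the commercial SD
instrument's spectrum-split variant is proprietary, and using one statistic
isolates wavelength and roll-off as the only differences between presets.
Amplitude (not intensity) enters the formula.

Thresholding follows the clinical recipe exactly: the mean and standard
deviation of the noise are estimated from a signal-free region — by default
all vitreous voxels, eroded by 2 voxels — of the mean-over-repeats amplitude,
the threshold is `T = µ_noise + 2σ_noise`, and every voxel with OCT signal
below `T` has its decorrelation set to zero (strict comparison; a value
exactly at `T` is retained; masking is idempotent). The mean over repeats is
used as the per-voxel OCT signal because it is the stable amplitude proxy;
the choice is a convention, not from the source device. This masking is the
crux: a masked voxel with true flow is output-identical to a voxel with no
flow, which is asserted directly in the tests.

## En face CC slabs (`slab_projection`)

Volumes are flattened to the segmented BM and mean-projected 30–60 µm below
it — the standard CC slab. Index convention (fixed for bit-reproducibility):
BM pixel by floor, offsets by ceil, half-open window
`[floor(bm/pitch)+ceil(30/pitch), floor(bm/pitch)+ceil(60/pitch))`, at least
one sample; at the default 3-µm pitch this is exactly 10 samples. Projection
runs along the flattened axis, so flattening and projection commute.

Segmentation modes: `ground_truth_bm` (default in tests — removes
segmentation error as a confounder) reads the phantom's BM; `estimated_bm`
emulates the clinical automatic segmentation by taking the brightest
reflector of each axially smoothed A-scan as the RPE-band top, placing BM one
band thickness (30 µm) below, and median-filtering the surface laterally over
5 pixels. The estimated mode reproduces the documented clinical failure mode:
under a druse it follows the lifted RPE rather than the flat membrane — the
reason the original workflow needed manual slab adjustment — and it raises an
error on a pure-noise volume ("no RPE peak"). Manual adjustment itself is out
of scope; the lateral median filter is its only stand-in.

## Automated grading (`classification`)

Human readers judged the *presence* of low signal under each druse. The
automatic reader makes that judgment explicit with two parameters: a slab
pixel is **low** when its value is below `k ×` the median of the background
(all slab pixels outside every druse footprint, eroded 2 px), and an ROI
(the druse footprint disc) is flagged when at least a fraction `f` of its
pixels are low. Defaults `k = 0.6`, `f = 0.35`, calibrated once on a
development simulation and frozen:

* `f = 0.35` because a paraboloid dome always leaves half its footprint below
  half the apex height, so demanding a majority-area shadow would require
  implausibly tall drusen before anything is ever flagged; `f = 0.35`
  corresponds to a dark patch covering the central ~60 % of the footprint
  radius — a reasonable automation of "presence of a low-signal area".
* `k = 0.6` so that the reader's OCT-low cutoff `k × median(background)`
  sits at (slightly above) the masking threshold `T`: with the default optics
  the background CC slab is ~1.7× `T`, and a cutoff below `T` would
  systematically misread threshold-masked areas as "OCT preserved".

Per device: loss = low OCTA; **ambiguous** = low OCTA ∧ low OCT;
**unambiguous** = low OCTA ∧ OCT preserved. **False-positive flow
impairment** on one device = ambiguous loss there ∧ no OCTA loss on the other
device. Cohort tallies report losses out of all drusen and the
ambiguous/unambiguous/false-positive splits out of that device's losses,
with percentages rounded half-up to one decimal.

Interreader agreement is percent agreement plus Cohen's κ with chance
agreement from the product of marginal label frequencies; perfect observed
agreement is defined as κ = 1 even when the marginals are degenerate (the
`sklearn` implementation, used as a cross-check oracle on generic data,
returns NaN there). The published κ = 0.957 cannot be recomputed because the
underlying marginals were never released; the statistic is instead exercised
on the printed worked example (45 matches of 46 → 97.8 %) and on Monte-Carlo
nulls. The third-reader arbitration workflow is not modelled.

## The reference cohort

The published study-level tallies (23 drusen; SD: 17 losses, 14 ambiguous, 3
unambiguous, 10 false-positive; SS: 7 losses, all unambiguous, 0
false-positive) admit consistent per-druse assignments; one such table is
fixed and shipped as `data/cohort23_synthetic.csv` (synthetic — it is a
reconstruction, not patient data): rows 1–10 SD-ambiguous with clear SS
(the false positives), rows 11–14 SD-ambiguous with SS-unambiguous, rows
15–17 unambiguous on both, rows 18–23 clear on both. Re-classifying and
aggregating this table with the package's own rules reproduces every printed
percentage, which is the exact worked-example check in the acceptance suite.

## What the synthetic data does and does not show

The generator reproduces the *mechanism*: wavelength-dependent attenuation by
RPE/druse material, SD sensitivity roll-off under the vitreoretinal protocol,
speckle decorrelation by flow, and OCT-signal thresholding. Under uniform
true flow the pipeline yields false-positive flow impairment on the SD preset
only; with attenuation disabled a true void is read as unambiguous loss on
both presets. It does **not** emulate: real retinal sublayers, overlying
retinal vessels and their projection artifacts, eye motion or motion
correction, the commercial device's split-spectrum statistic or display
processing, foveal geometry, or reader-to-reader perceptual variability.
Passing tests therefore demonstrate internal consistency of the mechanism at
the stated parameters, not quantitative agreement with any particular
hardware; the clinical percentages are reproduced through the reference
cohort, not through simulation.

## Numerical choices and degenerate inputs

float32 volumes with float64 accumulation in the decorrelation; one
`numpy` `default_rng` per simulation, seeds split per device from the root
seed; bit-identical reruns for fixed (config, seed). Intervals are half-open,
pixel indices 0-based, pixel/voxel centres at half-integer coordinates.
Degenerate inputs fail loudly: fewer than 2 repeats, negative amplitudes or
optics, empty noise region or ROI or background, slab windows leaving the
volume (error names the pixel), drusen whose footprint leaves the field,
out-of-field queries, all-noise volumes in estimated segmentation.

## Problem sizes

Default experiments use the 192 × 192 × 320 desk-scale grid (uniform-flow and
true-void studies, both devices: ≈ 1 minute together); simulation-heavy unit
tests use 64 × 64 × 320 with the same axial geometry. These sizes were chosen
so the whole suite and the acceptance script run comfortably on a single CPU
while keeping ≥ 10⁴ CC voxels for every Monte-Carlo assertion.
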