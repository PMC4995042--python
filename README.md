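# drusenshadow

Synthetic dual-wavelength OCT angiography (OCTA) of the choriocapillaris
under drusen.

In eyes with age-related macular degeneration, drusen attenuate the OCT beam
and cast shadows on the choriocapillaris (CC), the capillary layer just below
Bruch's membrane. OCTA displays are thresholded on the OCT signal — voxels
whose OCT signal falls below `T = µ_noise + 2σ_noise` are set to zero — so a
shadowed but perfectly perfused CC appears as a black "flow void". Whether a
dark patch of angiogram means absent flow or just absent signal can only be
decided by consulting the co-registered OCT: **ambiguous** signal loss (dark
OCTA *and* dark OCT) versus **unambiguous** loss (dark OCTA with preserved
OCT). A **false-positive flow impairment** is an ambiguous loss on one device
with no loss at all on the other — an artifact, not pathology. Shorter-
wavelength (~840 nm) spectral-domain systems are hit twice: the RPE and druse
material attenuate 840 nm more than 1050 nm, and spectrometer detection adds
sensitivity roll-off with depth. This package rebuilds that comparison as a
fully synthetic, end-to-end pipeline for anyone studying OCTA thresholding
artifacts:

* `phantom` — digital 3 × 3 mm macula: layered tissue, paraboloid drusen
  (analysis-eligible at diameter ≥ 165 µm), a CC flow layer with optional
  true flow voids, per-tissue per-wavelength optics;
* `oct_simulator` — repeated-B-scan amplitude simulation for the SD-840
  (70 kHz, 2 repeats, Δt ≈ 5 ms, roll-off) and SS-1050 (400 kHz, 5 repeats,
  Δt ≈ 1.5 ms, roll-off free) presets: Beer–Lambert attenuation
  `exp(−2∫µ dz)`, Gaussian roll-off, circular-Gaussian speckle with flow
  decorrelation `ρ = exp(−(vΔt/L_c)²)`, Rayleigh noise floor;
* `octa_engine` — unsplit pairwise decorrelation
  `D = 1 − ⟨AₙAₙ₊₁ / ½(Aₙ²+Aₙ₊₁²)⟩` and OCT-signal thresholding at
  `µ_noise + 2σ_noise`;
* `slab_projection` — flattening to Bruch's membrane and mean-projected en
  face CC slabs 30–60 µm below it;
* `classification` — automated two-reader grading
  (ambiguous/unambiguous/false-positive), cohort tallies, percent agreement
  and Cohen's κ;
* `cli` / `analysis/` — a `drusenshadow` command-line pipeline and numbered
  analysis drivers.

See `docs/methods.md` for the model, parameter defaults, and limitations.

## Worked example

Run the numbered drivers from the repository root:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_grade_uniform_flow.py
```

The first simulates the default cohort — four drusen of 200/300/400/500 µm
diameter over a *uniformly flowing* CC — on both devices and prints, among
other lines:

```
SD840: threshold 0.0654 (noise mean 0.0376); 58.1% of voxels below threshold
SS1050: threshold 0.0552 (noise mean 0.0376); 23.5% of voxels below threshold
```

The second grades the en face slabs:

```
drusen analyzed: 4
SD840: 3/4 (75.0%) OCTA signal loss; ambiguous 2 (66.7%), unambiguous 1 (33.3%), false-positive flow impairment 2 (66.7%)
SS1050: 0/4 (0.0%) OCTA signal loss; ambiguous 0 (-%), unambiguous 0 (-%), false-positive flow impairment 0 (-%)

finding: the shorter-wavelength SD device fabricates 2 false-positive flow impairment(s) under drusen; the longer-wavelength SS device fabricates none.
```

Since the simulated CC flows everywhere, every graded loss here is an imaging
artifact: the two largest drusen shadow the 840-nm beam below the display
threshold (dark OCTA *and* dark OCT → ambiguous), while the 1050-nm device
keeps the CC above threshold under every druse — hence SD-only false-positive
flow impairment. `analysis/03_true_void_control.py` shows the converse
control (attenuation off, a genuine void under one druse → unambiguous loss
on *both* devices), `analysis/04_reference_cohort_tallies.py` tallies the
packaged 23-druse reference cohort, and `analysis/05_reader_agreement.py`
computes interreader agreement between two parameterized readers.

The same pipeline is scriptable stage by stage:

```sh
drusenshadow simulate --seed 1 --outdir results/run
drusenshadow angiography --outdir results/run
drusenshadow slabs --outdir results/run
drusenshadow grade --outdir results/run
drusenshadow report --outdir results/run
drusenshadow fixture-check
```

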