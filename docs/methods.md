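# Methods

This note documents the models behind `lcphantom`, the defaults they use,
and what the synthetic data can and cannot say about real fluoroscopy
systems.

## Spectral model

Spectra are generated by an analytic tungsten-anode model. Bremsstrahlung
follows the Kramers thick-target form integrated over electron penetration
depth: a photon of energy `E` can be produced while the electron energy `T`
exceeds `E`; production at mass depth `(E0² − T²)/C_TW` (Thomson–Whiddington
relation, `C_TW = 8.0e5 keV²·cm²/g`) escapes through that depth divided by
the sine of the anode take-off angle (default 12°) of tungsten. This
Birch–Marshall-style self-filtration is what distinguishes the model from
bare Kramers: it preferentially removes the soft end of the spectrum the way
a real reflection target does. Above the K edge (69.525 keV) the four W K
fluorescence lines are added with a yield that grows as
`(1 − E_K/E0)^1.5`, scaled to 0.35 of the bremsstrahlung output at the
asymptote — a standard magnitude for the K-series fraction at 100 kVp. An
Elwert-corrected Bethe–Heitler thin-target kernel was evaluated as an
alternative and rejected: without screening corrections its Born logarithm
over-weights soft photons and degrades the agreement of computed HVLs with
clinical values.

The generated spectrum is filtered by the inherent aluminium-equivalent
filtration (default **3.0 mm Al**; configurable) and the added copper of the
beam quality. The bundled beam set Q1–Q3 is 65/80/100 kVp with 0.3/0.6/0.9 mm
Cu at 1000 mm focus-detector distance. Inverse-square and distance effects
cancel in every fluence ratio, so FDD is carried only for simulator
calibration.

Numerical choices: photon energies on a uniform 0.5-keV grid from 10 keV to
the tube potential (halving the bin width changes integrals by <0.1%);
attenuation coefficients are NIST values interpolated log-log (error ~1%
away from edges; tungsten carries a two-sided K-edge point, and its L edges
below 12.1 keV are unresolved because all supported beams are filtered far
past them). PLA (C₃H₄O₂, 1.24 g/cm³ at 100% infill) is built from elemental
H/C/O tables by the mixture rule; PMMA (1.19 g/cm³) is tabulated directly.

**Subject contrast** of a hole of depth `d` in a plate of thickness `t` is
the relative difference of transmitted fluence integrals between the
`t − d` and `t` paths, in percent. On a single-bin spectrum this reduces
exactly to `100·(e^{μd} − 1)`, which the tests use as a closed-form oracle.

**HVL** is defined on air kerma (fluence × energy × (μ_en/ρ)_air), matching
what a clinical multimeter measures; a fluence-weighted variant is available
behind a flag. The halving thickness is found by bracketing root search to
10⁻³ mm. With the 3.0 mm Al default the simulated HVLs are 5.04/7.65/9.92 mm
Al for Q1/Q2/Q3. Measured values on a clinical unit run a few percent to
~10% higher at the soft end; the unit's true inherent filtration is the
dominant uncertainty here, is not publicly reported, and a 1-mm change in
aluminium equivalence moves the Q1 HVL by roughly 0.3 mm. Exact reproduction
of measured HVLs is therefore not expected; the package reports what the
stated filtration implies.

## Phantom geometry

Plate modules are discs of 10-mm PLA with 10-mm-diameter flat-bottom holes
on a single ring (radius 0.35 × outer diameter, equal angular spacing,
ordered by increasing depth). The central module (plate A, 114.3-mm disc for
the 4.5″ field of view) carries depths 0.2–2.2 mm in 0.2-mm steps — 11
holes, honouring the stated range; the quoted "ten targets" is satisfied by
plates B and C (0.3–2.1 mm, offset 0.1 mm from plate A). The reference
phantom is modelled as the 8-mm-diameter column only: ten PMMA cells at
15-mm pitch with depths 0.3–2.5 mm covering the comparison range; the full
15×15 contrast-detail matrix is out of scope. Exact ring radii and angular
offsets of the printed device are not published; the defaults are package
choices, configurable per build.

Rasterization point-samples pixel centres ((i+0.5)·pitch offsets, row 0 at
top): hole pixels carry `plate_thickness − depth`, in-disc pixels the full
thickness. STL export builds a watertight mesh without any triangulation
engine by partitioning the top face into convex cells (angular sectors for
ring layouts, horizontal bands for the column), each zip-triangulated to its
hole rim; rim sampling includes the four cardinal angles so the mesh
bounding box equals the nominal diameter exactly.

## Frame simulator

The signal chain per pixel: expected detected quanta
`q = k · T(path length)`, where `T` is the spectrum-weighted transmission
and `k` normalizes the open-beam pixel to
`air_kerma_rate × exposure_time × quanta_per_kerma_pixel`; a seeded Poisson
draw; Gaussian PSF blur (default σ = 0.3 mm); affine gain/offset (defaults
8.0, 50.0); additive Gaussian electronic noise (default SD 2.0); clipping
and quantization to 12 bits. Frames are 0.25 mm/pixel, at least 512², and
are bit-identical for a fixed seed. Saturation of more than 1% of in-field
pixels raises a warning rather than failing silently.

Defaults encode the reference acquisition conditions: air kerma rates
73/78/66 µGy/min for Q1/Q2/Q3 at 1 s exposure. `quanta_per_kerma_pixel = 95`
is a calibration knob, not a physical claim: it is fixed so the default Q1
acquisition yields background CNR ≈ 1 at the 1.0-mm hole of the central
module (measured 1.07 ± 0.07), which places simulated thresholds in the same
CNR ≈ 1 regime as visual thresholds on clinical units.

Not modelled: scatter, anti-scatter grids, automatic exposure control,
vendor denoising, image-intensifier distortion, multi-frame sequences, and
anatomical/structured noise (the phantoms are uniform). Their aggregate
effect is folded into the gain/noise knobs. Consequently, passing tests
demonstrate the *methodology* — linear CNR-depth behaviour, calibration
recovery, protocol statistics — not the absolute performance of any
particular detector.

## CNR protocol

`CNR = (MPV_hole − MPV_bg)/STD_bg` with two hole-MPV samples and five
background regions; the five background ROIs supply both the MPVs and the
(population) SDs, all averaged before the single CNR evaluation. The
"800-pixel ROI" is realized as a circle of radius `pitch·√(800/π)` fully
inscribed in the hole; on the 8-mm reference holes the radius is capped at
the hole radius minus one pixel of jitter clearance. The two hole samples
are concentric placements jittered ±1 pixel — a stand-in for the two-sample
protocol on a single physical hole. Background ROIs sit at fixed angles on
a ring at half the hole-ring radius (ring layouts) or alternate laterally
beside the column (column layout), and every placement is validated for
hole clearance before use. CNR is exactly invariant under positive affine
pixel maps, which the tests assert to 10⁻¹².

## Calibration chain

Ordinary least squares with intercept throughout (no weighting,
no errors-in-variables). The SC-CNR fit regresses theoretical SC% of the
reference phantom on its measured CNR; the cross-phantom fit regresses
printed-phantom CNR on reference CNR paired by *exact* depth equality over
the configured series (no interpolation; the default series share
0.4/0.6/0.8/1.0/1.6/2.0 mm). The SC-equivalent map is the algebraic
composition `SC = a·(CNR_lc − d)/c + b`, exposed both as the composition and
as sequential application (identical to 10⁻¹²). Threshold depths convert
through the phantom's fitted CNR-depth line rather than nearest-hole lookup,
because observer means fall between discrete depths.

## Observer statistics

Group summaries use the sample SD and a t-distribution 95% CI
(`mean ± t₀.₀₂₅,n−1·SD/√n`), the standard choice for n = 5 readings;
bootstrap CIs could be swapped in. The paired Wilcoxon signed-rank test
drops zero differences, mid-ranks ties in |d|, and enumerates all
`2^n_effective` sign assignments exactly (dynamic programming over doubled
ranks; no normal approximation or continuity correction), reporting the
smaller signed-rank sum and the two-sided tail probability. With five
observers the attainable p-values are multiples of 1/16.

The simulated-observer mode reads the threshold off the fitted CNR-depth
line at a visibility criterion (default CNR = 1.2, the centre of the
threshold-CNR range observed in clinical visual scoring), adds per-observer
Gaussian jitter (SD 0.15 mm) and snaps to the nearest discrete hole depth.
It is labelled a synthetic stand-in for human scoring: it reproduces the
statistical machinery, not psychophysics.

## Problem sizes and reproducibility

Default study runs use one 512²–720² frame per phantom-beam pair;
stochastic checks use 20 seeded replicates and report medians. A master
seed expands deterministically to per-frame seeds; every output artifact
(manifest, CSVs, calibration files) embeds the config hash and master seed,
and DICOM UIDs derive from frame metadata so reruns are bit-identical.

## Known limitations

- The spectral model is semi-empirical; absolute fluence is relative, and
  HVL agreement with any specific clinical unit is limited by that unit's
  unreported inherent filtration (see above).
- Holes are modelled one per reference cell; the possibility that the
  two-sample MPV protocol refers to the two holes of a physical
  contrast-detail cell (centre + corner) is noted but not modelled.
- Printed-phantom SC is computed from nominal PLA composition and density;
  infill, moisture and pigment variations in real filament are not
  represented.
- Composite SC-CNR coefficients published for specific clinical units are
  not reproducible from synthetic data and are used only as magnitude
  anchors in the tests.
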