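# lcphantom

A validation toolkit for 3D-printed low-contrast fluoroscopy phantoms.

Low-contrast detectability is a core image-quality parameter in fluoroscopy
quality control: the shallowest hole an observer can still see in a uniform
plate measures how well the imaging chain renders structures that differ
from their background by only a few percent in transmitted X-ray fluence.
Commercial contrast-detail phantoms (the CDRAD family) are the reference for
this test but are expensive; a printed PLA plate with a ring of
calibrated-depth holes can stand in for them — *if* its readings can be made
traceable to the reference. `lcphantom` implements that traceability chain
end-to-end on synthetic data, so the whole methodology can be exercised,
tested and extended without access to a fluoroscopy unit:

1. **Spectral model** — analytic tungsten-anode spectra (Kramers thick-target
   emission with Birch–Marshall anode self-filtration and W K lines) for
   Cu-hardened beams Q1–Q3 (65/80/100 kVp with 0.3/0.6/0.9 mm Cu), giving
   subject contrast
   `SC% = 100 · (Ψ_hole − Ψ_background) / Ψ_background`,
   air kerma and the aluminium half-value layer (HVL).
2. **Phantom geometry** — parametric plate modules (10-mm PLA plates with
   10-mm holes, depth series 0.2–2.2 mm / 0.3–2.1 mm) and the 8-mm-diameter
   column of the PMMA reference phantom; rasterization to thickness maps and
   watertight binary STL export.
3. **Frame simulator** — Poisson quantum noise, Gaussian PSF and electronic
   noise over the spectrum-weighted transmission map; frames written as
   uncompressed grayscale DICOM.
4. **CNR measurement** — `CNR = (MPV_hole − MPV_bg) / STD_bg` with the
   two-hole-ROI / five-background-ROI averaging protocol and fully inscribed
   800-pixel circular ROIs.
5. **Calibration chain** — OLS fits `SC% = a·CNR_ref + b` (reference phantom)
   and `CNR_lc = c·CNR_ref + d` (paired by common hole depth), composed into
   the SC-equivalent mapping `SC% = a·(CNR_lc − d)/c + b`.
6. **Observer statistics** — threshold summaries (mean, SD, t-based 95% CI),
   an exact paired Wilcoxon signed-rank test (enumeration with mid-ranked
   ties), and depth→CNR→SC threshold conversion; a simulated-observer mode
   runs the full loop with zero human input.

## Worked example

The one-command workflow simulates DICOM frames for both phantoms under all
three beams, measures CNR-depth profiles, fits the calibration chain and
reports simulated-observer thresholds:

```sh
$ lcphantom run-all --seed 1 --output demo_run
unit beam      phantom  mean_depth_mm  sd_depth_mm  ...  cnr_mean  sc_mean_percent  sc_sd_percent
 SIM   Q1 cdrad_column           1.04     0.250998  ...  1.191011         3.027115       0.501652
 SIM   Q1      plate_a           1.12     0.178885  ...  1.299729         3.249059       0.425886
 SIM   Q2 cdrad_column           1.30     0.212132  ...  1.240965         2.609395       0.450194
 SIM   Q2      plate_a           1.04     0.167332  ...  1.097838         2.259652       0.455541
 SIM   Q3 cdrad_column           1.36     0.250998  ...  1.242251         3.193558       0.464802
 SIM   Q3      plate_a           1.24     0.089443  ...  1.152411         2.987286       0.209127
```

Each row is one observer group: the mean limiting hole depth (mm) with its
interobserver SD, the CNR at that depth from the fitted CNR-depth line, and
the reference-traceable SC-equivalent threshold. All thresholds fall in the
2–4% band that international QC protocols quote for low-contrast
acceptability, at threshold depths near 1 mm. The per-beam calibration fits
echo the printed-figure format:

```sh
$ lcphantom calibrate --seed 1 --output demo_run
Q1: y = 2.741x -0.450 (R2 = 0.977); inset y = 1.343x -0.512 (R2 = 0.968)
Q2: y = 2.730x -0.245 (R2 = 0.964); inset y = 1.117x +0.073 (R2 = 0.949)
Q3: y = 2.680x -0.270 (R2 = 0.940); inset y = 1.167x -0.266 (R2 = 0.976)
```

Library-level quantities:

```python
>>> from lcphantom import DEFAULT_BEAMS, generate_spectrum, hvl_al, subject_contrast, get_material
>>> s = generate_spectrum(DEFAULT_BEAMS["Q1"])
>>> round(hvl_al(s), 2)              # mm Al, kerma-halving definition
5.04
>>> pmma = get_material("pmma")
>>> round(subject_contrast(DEFAULT_BEAMS["Q1"], pmma, 10.0, 1.0), 2)  # SC%
2.69
```

A 1.0-mm hole in a 10-mm PMMA plate offers 2.69% subject contrast under Q1,
falling to 2.26% under the harder Q3 beam — the expected loss of subject
contrast with beam hardening.

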