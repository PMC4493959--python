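# Methods

This note documents the physical model, the numerical methods and the
deliberate design choices behind `utecine`.  Units: seconds, millimeters,
millimolar, and µmol Fe / kg body weight unless stated otherwise.

## 1. Acquisition geometry

**Trajectory.**  Each half-projection (spoke) starts at the k-space
center and reads outward to `k_max = matrix/2` cycles/FOV with
`2 × matrix/2` samples (2x readout oversampling), so the first sample of
every FID is the DC sample.  Spoke directions follow a generalized
(pole-to-pole) spiral: for `n` spokes the polar coordinate is uniform and
endpoint-inclusive, `z_i = 1 − 2i/(n−1)`, and the azimuth advances by
`Δφ_i = c / sqrt(n (1 − z_i²))` with `c = 3.6` (zero advance at the
poles).  This gives near-uniform area density on the sphere at any `n`.

**Gating and block-of-4 encoding.**  With prospective ECG gating, each
R-R interval acquires one *block* of 4 distinct projections, repeated
once per cine frame within the beat.  The number of HSR frames is
`n_hsr = floor(rr / (block · tr))` (10 for rr = 150 ms, tr = 3.5 ms);
any remaining time before the next trigger idles.  A scan of `n_total`
projections therefore takes `(n_total / 4) · rr` seconds gated and
`n_total · tr` ungated.

**HSR/HTR binning.**  HSR frame `f` collects all `n_total` projections
acquired at frame slot `f` — full angular sampling at `n_hsr` time
points.  HTR re-bins the identical raw data into `4·n_hsr` frames: HTR
frame `4f + s` contains the slot-`s` projection of every block, i.e.
`n_total/4` projections.  The four HTR children of an HSR frame
partition its projection set exactly (a tested invariant).  The HTR
frame count is fixed at `4 × n_hsr` — one frame per TR inside the block.

**Protocol presets** (`utecine.cli_io.PRESETS`):

| preset        | TR (ms) | TE (µs) | FOV (mm) | matrix | projections | gated | coils | scan time | voxel |
|---------------|--------:|--------:|---------:|-------:|------------:|:-----:|------:|----------:|------:|
| static        |     4.5 |      31 |       30 |    128 |      51 360 |  no   |     1 |  231.12 s | 234 µm |
| midres_cine   |     3.5 |      31 |       20 |    128 |      18 144 |  yes  |     4 |   680.4 s | 156 µm |
| highres_cine  |     3.5 |      31 |       20 |    192 |      52 540 |  yes  |     4 |  1970.25 s | 104 µm |

Flip angle 15°, R-R interval 150 ms throughout.

## 2. Signal model

Spoiled gradient-echo steady state with mono-exponential T2\* decay:

    S = M0 sinα (1 − E1)/(1 − E1 cosα) · exp(−TE/T2*),  E1 = exp(−TR/T1).

**Relaxivity.**  The USPIO agent shortens blood relaxation linearly in
concentration `C` (mM Fe): `R1 = R1,0 + r1·C`, `R2* = R2*,0 + κ·r2·C`.
Saline relaxivities per field (s⁻¹ mM⁻¹):

| field (T) | r1   | r2    |
|----------:|-----:|------:|
| 4.7       | 1.14 | 36.46 |
| 7.0       | 1.13 | 65.21 |
| 9.4       | 1.14 | 86.23 |

Dose converts to blood concentration via a mouse blood volume of
77 mL/kg: `C (mM) = dose (µmol/kg) / 77 (mL/kg)`, so 200 µmol Fe/kg ≈
2.6 mM.

**Blood R2\* enhancement factor κ = 5.** In vivo, intravascular iron is
compartmentalized; static dephasing around red cells and vessels makes
the effective R2\* relaxivity several-fold larger than the saline r2
measured in a well-mixed tube.  With the saline r2 alone, the simulated
post-contrast blood signal at TE = 3 ms would still exceed the
pre-contrast signal, contradicting the defining behaviour of the method
(positive enhancement only at ultra-short TE).  κ = 5 applied to blood
only reproduces the observed regime: at 7 T and 200 µmol/kg the blood
post/pre signal ratio is 5.66 at TE = 31 µs and 0.46 at TE = 3 ms.

**Tissue table** (M0 relative; T1 in s at 4.7 / 7.0 / 9.4 T; T2\* in ms;
uptake = fraction of blood concentration seen by the tissue):

| tissue     | M0   | T1            | T2\*        | uptake |
|------------|-----:|---------------|-------------|-------:|
| blood      | 1.00 | 1.8 / 2.2 / 2.4 | 30 / 20 / 15 | 1.0 |
| myocardium | 0.85 | 1.4 / 1.6 / 1.8 | 15 / 10 / 8  | 0.0 |
| muscle     | 0.80 | 1.2 / 1.4 / 1.6 | 12 / 8 / 6   | 0.0 |
| liver      | 0.90 | 0.9 / 1.0 / 1.1 | 10 / 7 / 5   | 0.5 |

## 3. Phantom

The beating thorax phantom is a list of analytic primitives (ellipsoids
and one z-aligned cylinder) drawn in order, later primitives overwriting
earlier ones: a muscle body, a liver lobe (hepatic USPIO uptake), a
myocardial shell, LV and RV blood cavities, and an aortic tube.  Cavity
and shell semi-axes interpolate cosinusoidally between end-diastole
(trigger, t = 0) and end-systole at 35 % of the R-R interval.
End-systolic cavity axes are the end-diastolic axes scaled by
`(1 − EF)^(1/3)`, so the configured ejection fraction is exact for the
analytic ground-truth volumes (default LVEF 64.1 %, RVEF 61.8 %; LV EDV
≈ 41 µL at the default geometry).  Rasterization uses the voxel-center
rule on an FFT-centered grid (object center at array index `matrix/2`);
optional supersampling block-averages a finer label grid for
partial-volume antialiasing.

What the phantom does **not** emulate: respiratory motion, flow and
inflow enhancement, B0 inhomogeneity and off-resonance blurring,
chemical shift, trigger jitter, relaxation during the readout, and
anatomical detail beyond the primitive set.

## 4. Forward simulation

For each HSR frame window the phantom is rasterized at the window
mid-time, multiplied by each coil sensitivity and transformed to the
scheduled k-space samples with a type-2 NUFFT.  Coil models: 1 coil =
uniform volume coil; 4 coils = 2×2 Gaussian-profile surface array on the
+z face (transverse σ = 0.35·matrix, depth decay 0.8·matrix, +0.02
floor so the sum-of-squares sensitivity is positive everywhere).  Noise
is i.i.d. complex Gaussian with `noise_sigma` the per-component standard
deviation; the `run` pipeline sets `noise_sigma = 3 × 10⁻⁴ ×` (sum of
the end-diastolic signal map), which lands blood apparent SNR in the
tens-to-hundred range typical of these scans.  Raw data, trajectory,
schedule and metadata round-trip through HDF5 (`save_raw`/`load_raw`).

## 5. Reconstruction

Gridding (adjoint NUFFT) per frame and coil:

1. **Density compensation**: analytic spherical-shell weights
   `w(r) ∝ (r+Δ/2)³ − max(0, r−Δ/2)³` for radial sample spacing Δ; the
   DC sample gets the innermost-shell volume.  Weights are normalized by
   `n_projections · matrix³`.
2. **Gridding**: width-4 Kaiser-Bessel kernel on a 2x-oversampled grid,
   β from the Beatty formula (β ≈ 8.996).  Spread and interpolation use
   the identical kernel evaluation, so they are exact numerical adjoints
   (tested to 1e-10); the forward/adjoint NUFFTs match a direct-summation
   DFT oracle to <1 % on 16³ problems.
3. **FFT**: centered convention `fftshift(FFT(ifftshift(·)))`, DC at
   array index `M/2`.
4. **Deapodization** by the analytic kernel transform, cropping to
   `matrix³`, magnitude, and sum-of-squares coil combination.

HSR reconstruction uses all projections per frame; HTR uses the
`n_total/4` slot projections of each HTR frame (4x fewer, visibly higher
streak energy — a tested property).

## 6. Metrics

* **Apparent SNR** = mean(ROI) / std(noise ROI); **CNR** =
  SNR(blood) − SNR(reference tissue).  Standard deviations use the
  sample (n−1) convention.  The noise ROI is a 10³ corner cube.
* **Homogeneity** = standard deviation across cine frames of the
  per-frame blood-ROI mean (the ROI is the end-systolic blood region, a
  subset of the blood pool at every phase); reported in noise-std units
  where comparability across noise levels matters.
* **Volumetry**: the LV cavity is segmented in every frame by a
  threshold at 50 % of a common blood reference intensity (brightest
  seed-neighborhood mean over frames) followed by 6-connected component
  selection around the seed.  ED/ES are the frames of maximal/minimal
  segmented volume; EDV/ESV/SV/EF follow from the voxel volume.

## 7. Desk-scale study sizes

The acceptance studies run at 64³ with 3000 projections (static
contrast) and 4096 projections (cine EF recovery) — small enough for
minutes-scale runtimes on one core, large enough that the reconstruction
is fully sampled at the object scale.  These sizes are a package choice;
the presets above carry the full-scale protocol parameters.
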