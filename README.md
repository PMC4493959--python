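# utecine

Simulation and reconstruction toolkit for **USPIO-enhanced 3D ultra-short
echo time (UTE) radial cine MRI of the mouse heart**.

Imaging murine cardiac function at high field is hard: the heart beats at
~400 bpm, blood T2\* is short, and iron-oxide (USPIO) blood-pool agents
destroy the blood signal at conventional echo times.  A 3D radial
center-out ("koosh-ball") acquisition with TE of a few tens of
microseconds samples the free-induction decay before the iron-induced
dephasing takes hold, so USPIO T1-shortening makes blood *bright* instead
of black.  Combined with prospective ECG gating and a block-of-4 FID
encoding scheme, one scan yields both a fully-sampled cine (high spatial
resolution, HSR) and a 4x-finer temporal re-binning of the same data
(high temporal resolution, HTR).

This package provides a desk-scale digital twin of that experiment:

* **trajectory** — generalized-spiral (pole-to-pole) half-projection
  distribution on the sphere, center-out radial readouts;
* **schedule** — prospective gating with block-of-4 FID encoding, HSR/HTR
  frame binning, scan-time prediction;
* **phantom** — beating mouse-thorax phantom (myocardium, LV/RV cavities,
  liver, muscle, aorta) with field- and dose-dependent SPGR signal from a
  USPIO relaxivity model;
* **forward_sim** — NUFFT-based k-space simulation with coil maps and
  complex Gaussian noise, HDF5 raw-data I/O;
* **recon** — Kaiser-Bessel gridding reconstruction (density compensation,
  oversampled FFT, deapodization, sum-of-squares coil combination);
* **metrics** — apparent SNR/CNR, cardiac-cycle signal homogeneity,
  threshold volumetry (EDV/ESV/SV/EF);
* **cli** — `utecine` command-line interface and NIfTI export.

## Model summary

Spoiled gradient-echo steady state with mono-exponential T2\* decay:

    S = M0 · sin(α) · (1 − E1) / (1 − E1 · cos(α)) · exp(−TE/T2*),   E1 = exp(−TR/T1)

USPIO shortens relaxation times linearly in blood iron concentration
`C` (mM): `1/T1 = 1/T1,0 + r1·C` and `1/T2* = 1/T2*,0 + κ·r2·C`, where
`r1`, `r2` are the field-dependent saline relaxivities and `κ` accounts
for the stronger in-vivo R2\* effect of compartmentalized iron (see
`docs/methods.md`).  The reconstruction grids the radial samples with a
width-4 Kaiser-Bessel kernel on a 2x-oversampled grid, weights them by
analytic spherical-shell density compensation, and combines coils by
sum of squares.

## Worked example

Protocol bookkeeping is instant:

```console
$ utecine schedule --n-proj 18144
{
  "scan_time_s": 680.4,
  "n_heartbeats": 4536,
  "hsr_frames": 10,
  "htr_frames": 40,
  "projections_per_htr_frame": 4536
}
```

A full simulate-acquire-reconstruct-analyze experiment (here the mid-res
cine preset scaled down to a 64^3 matrix and 4096 projections; ~2 min on
one CPU core):

```console
$ utecine run --preset midres_cine --seed 0 --outdir demo --matrix 64 --n-proj 4096
```

which writes `raw.h5` (k-space), `cine.nii.gz` (10-frame HSR cine),
`run.log` and `metrics.json`:

```json
{
  "voxel_size_um": 312.5,
  "n_frames": 10,
  "snr_blood": 91.19,
  "snr_myocardium": 18.68,
  "cnr_blood_myocardium": 72.51,
  "lv_function": {
    "EDV_uL": 39.79, "ESV_uL": 14.98, "SV_uL": 24.81,
    "EF_percent": 62.35, "ED_frame": 0, "ES_frame": 3
  }
}
```

The phantom in this run was configured with LVEF 64.1 %; threshold
volumetry on the reconstructed cine recovers 62.3 %.  The same raw file
can be re-binned at 4x temporal resolution with
`utecine recon --raw demo/raw.h5 --mode htr --out demo/htr.nii.gz`.

The same pipeline from Python:

```python
from utecine.study import static_contrast_study, echo_time_comparison

echo_time_comparison(field=7.0, dose=200.0)
# blood post/pre contrast: 5.66x at TE 31 us, 0.46x at TE 3 ms

static_contrast_study(7.0, doses=(0.0, 200.0, 500.0), seed=123)
# CNR(blood, myocardium): -1.96 pre-contrast, +32.8 at 200, +36.5 at 500 umol Fe/kg
```

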