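# opmkit

Processing toolkit for **single-objective oblique-plane light-sheet
microscopy** (OPM) with dual-sided illumination and stabilized stage
scanning. It implements the computational chain such an instrument needs
between the camera and a quantitative time-lapse dataset, together with a
synthetic forward model that generates every kind of test input with known
ground truth.

## Who this is for

Builders and users of oblique-plane / single-objective light-sheet
microscopes who need a tested, self-contained reference for:

- **Deskewing** — resampling the stack of tilted camera frames, indexed
  (scan *s*, row *y*, column *x′*), onto the coverslip-aligned (*x, y, z*)
  grid. A camera sample maps to world coordinates as
  *x = s·Δs + σ·x′·p·cos θ*, *y = y·p*, *z = x′·p·sin θ*, with sheet angle
  *θ* (45° by default), scan step Δs, sample-space pixel *p*, and σ = ±1 for
  the two illumination sides.
- **Dehazing** — white top-hat removal of large-scale background from
  scattered and out-of-focus light.
- **Multi-scale warp registration** — the second view is registered onto the
  first by iteratively splitting both volumes into chunks (2, 4, 8, … per
  axis, minimum 32³), estimating one translation per chunk pair by phase
  correlation with subvoxel parabolic refinement, and warping with the
  spline-interpolated displacement field.
- **Content-aware fusion** — per-voxel blending of the two views driven by
  the smoothed Sobel-gradient magnitude, so each region comes from the view
  whose illumination path was less obstructed.
- **Illumination correction** — dividing out the Gaussian intensity profile
  of the light sheet along *y*.
- **Temporal stabilization** — pairwise phase-correlation shifts to 2·*n*
  temporal neighbours (*n* = 7) assembled into the band system **R = M A**
  and inverted for the absolute trajectory **A** with L1-robust (IRLS)
  regression, which tolerates grossly wrong shift measurements where plain
  least squares does not.
- **PSF characterization** — bead detection, estimation of the PSF tilt from
  the intensity second-moment tensor, rotation so the long axis z″ aligns
  with z, and 1D Gaussian fits along x″, y, z″
  (FWHM = 2·√(2 ln 2)·σ).
- **Scan-timing simulation (LS³)** — light-sheet stabilized stage scanning:
  the galvo translates the sheet at the stage speed during each exposure so
  no motion blur accrues, and flies back during readout; the simulator
  reproduces the waveforms, the residual blur |v_stage − v_galvo|·t_exp,
  and the acquisition throughput.

## Worked example

```bash
python examples/psf_characterization.py
```

```
12 beads characterized
FWHM x'':   479.2 +/-   4.4 nm   (generated: 480 nm)
FWHM y  :   378.1 +/-   4.1 nm   (generated: 379 nm)
FWHM z'':  1861.8 +/-   9.9 nm   (generated: 1865 nm)
tilt of z'' from z: 20.03 deg (generated: 20.0 deg)
```

The script builds a bead volume whose anisotropic Gaussian PSF is tilted by
20° in the xz plane, runs the full detection → rotation → 1D-fit chain at
shot-noise SNR ≈ 20, and recovers the generated widths within a fraction of
a percent — the same procedure a real bead calibration uses.

Other examples: `examples/deskew_roundtrip.py` (forward model vs deskew,
sub-0.01-voxel bead centroids), `examples/two_view_fusion.py` (occluded
regions filled from the complementary view),
`examples/drift_stabilization.py` (L1 vs least-squares trajectory inversion
under 10% gross outliers), `examples/ls3_timing.py` (scan waveforms and
throughput).

A thin command-line interface wraps the same functions:

```bash
opmkit simulate beads beads.tif --n-beads 10
opmkit deskew raw.tif deskewed.tif
opmkit psf beads.tif records.csv --threshold 100
opmkit ls3 --scan-range-um 2000 --stage-speed 180.6
opmkit run pipeline.yaml
```

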