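# echopatch

Simulation, image-formation and analysis toolkit for a **conformal
wearable cardiac ultrasound imager**: a stretchable 32-element, 3 MHz
phased array worn on the chest that images the left ventricle
continuously and tracks cardiac performance over time.

The package is aimed at ultrasound-systems and biomedical-imaging
researchers who want a desk-reproducible model of the whole chain:

1. **Geometry** — flat, orthogonal (Mills-cross) and curved arrays;
   nominal element positions mapped onto a measured chest-surface
   profile so that phase distortion from device bending can be
   corrected in beamforming.
2. **Transmit** — plane-wave, mono-focus and wide-beam (diverging-wave)
   delay laws; the default compounding sequence is 97 steered
   transmissions spanning −37.5°…+37.5°.
3. **Acoustics** — Born single-scattering simulation of RF channel data
   for point-scatterer phantoms, and RMS transmitted-pressure field
   maps, x_RMS = sqrt((x₁² + … + x_n²)/n).
4. **Imaging** — delay-and-sum receive beamforming with dynamic
   focusing, coherent compounding, envelope detection, log compression
   I_new = 20·log₁₀(I_old), sector scan conversion with pixel spacings
   Δy = depth/(N_vertical − 1) and Δx = width/(N_lateral − 1), and
   B-mode/M-mode assembly.
5. **Phantoms** — seeded wire grids, speckle phantoms with cylindrical
   contrast inclusions, and a beating-left-ventricle generator with
   exact ground-truth volumes.
6. **Metrics** — FWHM resolutions, location accuracy
   (1 − |computed/truth − 1|), dynamic range by linear grey-vs-contrast
   extrapolation to grey 0 and 255, CNR = |μ_in − μ_out|/√(σ_in² + σ_out²),
   SNR vs depth, 6-dB penetration depth, −6 dB fractional bandwidth,
   insertion loss, relative resistance R/R₀.
7. **Cardiac** — M-mode interface tracking, LVIDd/LVIDs and fractional
   shortening (LVIDd − LVIDs)/LVIDd, Simpson's method-of-disks LV volume
   from segmentation masks, per-cycle EDV/ESV/SV/EF/HR/CO, and
   Bland–Altman limits of agreement.

## Worked example

```python
import numpy as np
import echopatch as ep

a = ep.make_linear_array()                      # 32 el, 0.4 mm pitch, 3 MHz
print(round(ep.pitch_in_wavelengths(a.pitch, a.centre_frequency), 2))

seq = ep.make_compounding_sequence(a)           # 97 wide-beam transmissions
ph = ep.Phantom(positions=[[0.0, 0.0, 50e-3]], reflectivity=[1.0])
ch = ep.simulate_channel_data(ph, a, seq)
grid = ep.PixelGrid(imaging_depth=6e-3, imaging_width=8e-3,
                    n_vertical=121, n_lateral=161, z_start=47e-3)
bmode = ep.envelope_logcompress(ep.beamform_sequence(ch, grid))
res = ep.resolution_set(bmode, ph).iloc[0]
print(f"axial {res.axial_fwhm_mm:.2f} mm, lateral {res.lateral_fwhm_mm:.2f} mm")

span, _ = ep.dynamic_range([-15, 15], [38.7, 159.8])
print(f"dynamic range {span:.1f} dB")

lv = ep.beating_lv(ep.BeatingLVSpec())          # EDV 120, ESV 50, HR 75
wf = ep.volume_waveform(lv.masks, lv.pixel_size_m, lv.frame_dt)
idx = ep.indices_from_waveform(wf.time_s.to_numpy(), wf.volume_ml.to_numpy())
print(idx[["edv_ml", "esv_ml", "sv_ml", "ef_pct", "hr_bpm"]].round(1).iloc[0].to_dict())
```

prints

```
0.78
axial 0.42 mm, lateral 2.17 mm
dynamic range 63.2 dB
{'edv_ml': 120.6, 'esv_ml': 49.8, 'sv_ml': 70.8, 'ef_pct': 58.7, 'hr_bpm': 75.0}
```

The pitch is 0.78 ultrasonic wavelengths (grating-lobe-safe for a phased
array); the 97-angle compound image of a 50 mm wire has a
pulse-length-limited axial width of 0.42 mm and a diffraction-limited
lateral width of 2.17 mm; the display dynamic range obtained by fitting
mean grey value against inclusion contrast and extrapolating to grey 0
and 255 is 63.2 dB; and the mask-driven cardiac pipeline recovers the
generator's EDV 120 ml / ESV 50 ml / HR 75 bpm to within a fraction of a
millilitre (ejection fraction 58.7% vs the exact 58.33%).

There is also a CLI for the end-to-end demo pipeline:

```sh
echopatch run --out demo_out --n-angles 21 --seed 1
```

which writes the phantom, RF data, B-mode HDF5 + PNG, a PSF metrics CSV
and the per-cycle cardiac indices CSV.

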