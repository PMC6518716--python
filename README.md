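# vesselcam

Vision-based measurement of pulsating vessel-wall motion from multi-camera
silhouette imaging.

Elastic models of abdominal aortic aneurysms (AAA), driven by a pulsatile
pump at physiological rates, can be imaged by a ring of cameras: each camera
sees a bright vessel silhouette on a dark background, and the change of that
silhouette's area over the cardiac cycle encodes the wall deformation at the
camera's viewing angle. `vesselcam` implements the complete offline analysis
chain for such data, plus a synthetic phantom generator with exact ground
truth so the chain can be validated end to end without hardware.

## The measurement

For camera *c*, every frame *i* is rectified (pinhole model with
Brown–Conrady radial/tangential distortion), binarised with Otsu's
threshold, and reduced to the pixel area *F<sub>ic</sub>* of its largest
bright object. The **shape deformation factor**

&nbsp;&nbsp;&nbsp;&nbsp;*n<sub>i</sub>* = *F<sub>ic</sub>* / *F<sub>c</sub>*

compares each frame to the reference area *F<sub>c</sub>* of the first,
motionless frame of the same camera. The factor is converted to a radial
wall displacement via the equivalent-circle radius of the reference
silhouette, Δ*r<sub>i</sub>* = √(*F<sub>c</sub>*/π) · s · (√*n<sub>i</sub>* − 1),
with *s* the millimetre-per-pixel scale of the object plane, and summarised
as per-cycle amplitudes (max − min per pulse period) and per-position
averages (anterior / left / posterior / right).

Supporting modules provide:

- **phantom** — synthetic rendering of a pulsating vessel cross-section
  (Fourier-perturbed radius, angle-dependent amplitude, 72 min⁻¹ pulse,
  30 fps, seeded noise and illumination gradient) and of the two
  verification squares, with analytic shoelace areas as ground truth;
- **optics** — projection, undistortion (fixed-point inversion),
  bilinear rectification, and plane-based camera calibration with
  nonlinear refinement;
- **segmentation** — Otsu thresholding (smallest-maximiser tie-break),
  8-connected largest component, Moore boundary following, caliper width;
- **verification** — the two-square accuracy protocol: squares of 0.05 m
  and 0.10 m imaged in sequence must yield a factor of 4;
- **agreement** — Bland–Altman bias and limits of agreement, pooled
  Student's t test, Spearman rank correlation, and a packaged reference
  dataset of paired wall-deformation measurements (vision system vs
  speckle-tracking echocardiography, 4 subjects × 4 positions × 4 probes);
- **pipeline / cli** — batch orchestration, PNG/CSV/YAML I/O, and a
  deterministic simulation of the producer–consumer acquisition queues
  (lossless saving queue, size-1 lossy preview queue).

## Worked example

```python
import numpy as np
from vesselcam import (RigGeometry, PhantomSpec, PixelScale,
                       render_phantom_sequence, segment_frame,
                       deformation_factors, factor_to_displacement,
                       cycle_amplitudes, run_square_protocol)

rig = RigGeometry(image_size=(480, 270), object_distance=0.30)

# two-square verification: the recovered ratio must be 4
r = run_square_protocol(rig, distances=(0.30,), replicates=5, seed=1)[0]
print(f"square ratio: {r.mean:.5f} +/- {r.sd:.5f}  (expected {r.expected}, "
      f"accuracy {r.accuracy_pct:.2f}%)")

# pulsating phantom, 3 cycles at 72 min^-1, 30 fps, 4 mm radial amplitude
spec = PhantomSpec(radius_fourier=(), pulsation_amplitude_mm=4.0, n_cycles=3)
seq, truth = render_phantom_sequence(spec, rig, camera_index=1, seed=1)
areas = [segment_frame(f).area_px for f in seq.frames]
series = deformation_factors(areas)
disp = factor_to_displacement(series, PixelScale(truth.mm_per_pixel))
amps = cycle_amplitudes(disp, frame_rate=30.0, pulse_rate=72.0)
print(f"peak deformation factor n_i: {series.factors.max():.4f}")
print(f"cycle amplitudes (mm): {np.round(amps, 3)}")
```

prints

```
square ratio: 4.00000 +/- 0.00000  (expected 4.0, accuracy 100.00%)
peak deformation factor n_i: 1.1939
cycle amplitudes (mm): [3.985 3.985 3.985]
```

The square ratio is exact because at this resolution both squares rasterise
to integer pixel sides. The peak factor ≈ (47/43)² = 1.195 is the area ratio
of the inflated vs resting cross-section, and the recovered per-cycle
amplitudes sit within 0.4% of the 3.985 mm ground truth (30 fps does not
sample the exact peak of a 1.2 Hz pulse, so the truth is slightly below the
4 mm generating amplitude).

A command-line interface mirrors the library: `vesselcam synth-phantom`,
`synth-squares`, `calibrate`, `run`, `verify-squares`, `agreement`.

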