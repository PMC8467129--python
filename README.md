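# sfdikit

Spatial frequency domain imaging (SFDI) maps the absorption coefficient μa
and the reduced scattering coefficient μs′ of turbid media — fruit tissue,
liquid phantoms, skin — over a wide field, without contact. A projector
casts sinusoidal fringe patterns at several spatial frequencies fx; a camera
records the diffusely reflected light; the per-pixel modulation amplitude,
normalised against a reference whiteboard, gives the frequency-dependent
diffuse reflectance Rd(fx); and fitting a diffusion-theory model to Rd(fx)
recovers (μa, μs′) per pixel. Because damage to fruit raises μa and lowers
μs′, the recovered coefficient maps separate surface-damage classes that
ordinary planar (unmodulated) imaging confuses.

`sfdikit` implements the full computational chain for a projector–camera
SFDI rig, including the calibrations a commercial projector needs:

- **Forward model** — diffusion-approximation reflectance
  Rd(fx) = 3Aμs′/μtr / ((μ′eff/μtr + 1)(μ′eff/μtr + 3A)), with
  μtr = μa + μs′, μeff = √(3μa μtr), μ′eff = √(μeff² + (2πfx)²), and the
  boundary constant A = (1−Reff)/(2(1+Reff)) from the effective reflection
  coefficient Reff(n).
- **Keystone correction** — pinhole-projector geometry with pitch/yaw
  rotations; inverse-perspective pre-distortion of patterns so tilted
  projection lands as straight fringes; a per-column fringe-uniformity error
  ep and a grid sweep that localises the true mounting angles.
- **Frequency calibration** — fringe-period estimation from averaged
  reflectance profiles (sub-pixel minima spacing), the checkerboard scale
  chain Tr = Tc·Xr/Xc̄ and period ratio rrp = Tp/Tr, and a two-step
  per-frequency recalibration that removes multiplicative period bias in
  one update.
- **Demodulation** — three-phase amplitude envelope
  Mac = (2/3)√((I1−I2)² + (I2−I3)² + (I1−I3)²) and whiteboard calibration
  Rd = (Mac/Mac,ref)·Rd,ref; planar (fx = 0) channel via the direct ratio.
- **Inversion** — bounded nonlinear least squares of the forward model to
  the multi-frequency reflectance spectrum, per pixel or per superpixel,
  plus the phantom-based linear correction k = mean(ref/measured).
- **Phantom references** — Beer–Lambert μa = −ln(T)/d for ink and Mie-theory
  μs′ for TiO2 suspensions (in-package Mie series, Wiscombe truncation),
  over the two nine-sample calibration series.
- **Simulator** — renders whiteboard and sample phase stacks with
  configurable noise from ground-truth coefficient maps, plus parametric
  damage scenes (bruise / scratch / abrasion), so every stage is testable
  without hardware.
- **Classification** — ROI-mean features from the coefficient maps and
  stratified 5-fold cross-validated linear discriminant analysis, comparing
  the SFDI feature set (μa, μs′) against planar-light reflectance.

## Worked example

Simulate a homogeneous sample (μa = 0.02 mm⁻¹, μs′ = 1.2 mm⁻¹) at four
spatial frequencies with 1% camera noise, demodulate, calibrate against the
simulated whiteboard, and invert:

```python
import numpy as np
from sfdikit import OpticalProperties, diffuse_reflectance
from sfdikit.synthetic import SceneSpec, simulate_stack
from sfdikit.demodulation import demodulate_stack, planar_reflectance
from sfdikit.inversion import invert_point, ReflectanceSpectrum

truth = OpticalProperties(mua=0.02, musp=1.2)
scene = SceneSpec(mua_map=np.full((32, 32), truth.mua),
                  musp_map=np.full((32, 32), truth.musp),
                  fx_list=(0.0, 0.042, 0.084, 0.14),
                  noise_sigma=0.01, seed=7)
acq = simulate_stack(scene)

fx = [0.0]
rd = [np.nanmean(planar_reflectance(acq.sample_planar, acq.reference_planar).rd)]
for f in acq.ac_frequencies:
    img = demodulate_stack(acq.sample_stacks[f], acq.reference_stacks[f])
    fx.append(f); rd.append(np.nanmean(img.rd))
    
res = invert_point(ReflectanceSpectrum(fx=np.array(fx), rd=np.array(rd)))
```

This prints (via the loop shown in the docstrings):

```
fx = 0.000 mm^-1   Rd = 0.5617   (model: 0.5624)
fx = 0.042 mm^-1   Rd = 0.4683   (model: 0.4685)
fx = 0.084 mm^-1   Rd = 0.3394   (model: 0.3401)
fx = 0.140 mm^-1   Rd = 0.2277   (model: 0.2272)
recovered mua  = 0.02010 mm^-1  (truth 0.02000)
recovered mus' = 1.20035 mm^-1  (truth 1.20000)
```

The measured reflectance follows the model at every frequency (reflectance
falls as the fringe frequency rises — high-frequency modulation probes
shallower, more scatter-dominated light paths), and the two coefficients
come back within 0.5% despite the image noise.

The same stages are scriptable from the shell:

```sh
sfdi simulate --out acq/ --seed 3 --label B     # bruised-pear scene
sfdi invert --manifest acq/manifest.yaml --out maps/ --bin 8
sfdi freqcal --bias 1.02                        # two-step frequency calibration
sfdi keystone --alpha 20 --beta 0.5             # angle sweep on a tilted rig
sfdi phantoms --out phantom_refs.csv            # reference (mua, mus') table
sfdi classify --seed 1                          # cohort + LDA accuracies
```

For instance `sfdi freqcal --bias 1.02` reports

```
{"step1_mean_error_pct": 2.009, "step2_mean_error_pct": 0.047, "n_frequencies": 10}
```

— a 2% projector period bias leaves ~2% period error after the first
calibration pass and under 0.05% after the per-frequency ratio update.

## Layout

```
src/sfdikit/
  forward_model.py   diffusion reflectance model and boundary constants
  demodulation.py    three-phase amplitude + whiteboard calibration
  inversion.py       multi-frequency fitting, linear correction
  keystone.py        projector geometry, pattern correction, angle sweep
  freqcal.py         period estimation and two-step frequency calibration
  phantoms.py        Beer-Lambert / Mie phantom reference properties
  synthetic.py       acquisition and damage-scene simulator
  classify.py        feature extraction and LDA cross-validation
  io.py, cli.py      TIFF/YAML manifests, pipeline driver, `sfdi` CLI
docs/methods.md      model assumptions, parameter choices, limitations
```
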