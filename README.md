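# mlcmargins

Auto-adaptive tracking margins for MLC-tracked radiotherapy.

When a multileaf collimator (MLC) tracks a moving target (liver, lung,
pancreas breathing motion), system latencies and the electromechanic
response of the leaves leave a residual geometric error between the
aperture and the target. Those errors smear the delivered dose and
underdose the field shoulders. This package implements an on-line margin
generator that measures the tracking-error statistics *during* delivery,
translates them through a convolution dose model into per-side, per-axis
aperture margins at a chosen coverage level, and applies them to the
segment by raster dilation and leaf fitting — plus a virtual-MLC delivery
simulator that stands in for linac, motion stage and film so the whole
closed loop can be exercised and scored on a desk.

It is aimed at medical-physics researchers working on MLC tracking and
real-time adaptive delivery.

## The model

Per control cycle (40 ms), the tracking error per principal BEV axis is

    eps(t) = p_MLC(t) - p_target(t),

evaluated causally as `eps(t' - dT_sense) = p_MLC(t' - dT_sense) -
p_sense(t')` because the sensed position lags the target by the sensing
latency `dT_sense`. A cyclic FIFO of N = 500 errors (20 s of history) feeds
a Gaussian kernel density estimator with rule-of-thumb bandwidth
`sigma = s (4/3N)^(1/5)`, giving a continuous error density `p_eps`. The
density degrades the reference dose by convolution,

    D_dyn(x) = (D_ref * p_eps)(x),

where `D_ref` is an ideal block field blurred by the penumbra-generating
kernel (PGK), itself recovered from a static measurement by
waterlevel-regularized Fourier deconvolution. The margin per side is found
by solving

    D_ref(x) = D_dyn(x + m) = D_hat

at the confidence level `D_hat` (default 0.9): the distance between the
`D_hat` crossings of the reference and the degraded profile. The four
margins `(m_x+, m_x-, m_y+, m_y-)` dilate the rasterized segment (0.25 mm
grid, separable morphologic dilation), the outline is re-contoured, and
leaves/jaws are fitted by sub-leaf averaging.

Coverage is scored with dose-area histograms: `A90` is the fraction of a
region receiving more than 90% of the reference dose, evaluated in the
reference shoulder (0.9 < D < 0.97) and plateau (D > 0.9) regions.

See `docs/methods.md` for assumptions, parameters and numerical choices.

## Worked example

```python
import numpy as np
from mlcmargins import (RunConfig, run_loop, build_dilation_kernel,
                        ideal_block, apply_pgk, gaussian_kernel_profile,
                        estimate_pgk)

# 1. penumbra kernel from a (synthetic) 10x10 cm^2 block measurement
ideal = ideal_block(100.0, grid=0.25)
measured = apply_pgk(ideal, gaussian_kernel_profile(3.0, 0.25))
pgk = estimate_pgk(measured, ideal, waterlevel=1e-3)
print(f"PGK sd: {pgk.sd():.3f} mm")

# 2. dilation kernel for margins (-4 mm, 2 mm) at the 0.25 mm raster
print("dilation kernel (n-, center, n+):", build_dilation_kernel((4.0, 2.0), 0.25))

# 3. closed-loop tracked delivery, irregular breathing, 300 ms latency
result = run_loop(RunConfig(preset="v2", duration=40.0, seed=1))
last = result.cycle_log.iloc[-1]
print(f"final margins (mm): x+={last.m_x_plus_mm:.2f} x-={last.m_x_minus_mm:.2f} "
      f"y+={last.m_y_plus_mm:.2f} y-={last.m_y_minus_mm:.2f}")
sh = result.a90["shoulder"]
print(f"shoulder A90: untracked={sh['untracked']:.3f} tracked={sh['tracked']:.3f} "
      f"with margins={sh['margin']:.3f}")
```

prints

```
PGK sd: 3.000 mm
dilation kernel (n-, center, n+): (16, 1, 8)
final margins (mm): x+=5.44 x-=5.49 y+=1.12 y-=1.12
shoulder A90: untracked=0.007 tracked=0.059 with margins=0.803
```

Reading it: the deconvolution recovers the 3 mm penumbra kernel exactly; a
(-4, 2) mm margin prescription at 0.25 mm resolution becomes a 25-element
dilation kernel (16 negative, 1 center, 8 positive); and after 40 s of
irregular breathing through a 300 ms-latency loop the controller asks for
~5.5 mm margins along the (dominant) leaf-travel axis and ~1.1 mm
perpendicular to it, lifting the shoulder-region A90 from 0.059
(uncompensated tracking) to 0.803. Longer deliveries (200 s) reach ~0.9.

## Command line

```sh
mlcmargins simulate --preset v2 --duration 200 --seed 1 --out trace.csv
mlcmargins estimate-pgk --measured profile.csv --out pgk.csv
mlcmargins compute-margin --density density.csv --pgk pgk.csv --out margins.json
mlcmargins run-loop --preset v1 --outdir run1/
mlcmargins analyze --dose-map run1/dose_margin.csv --out dah.csv
```

File formats: motion traces `t_s,x_mm,y_mm`; dose profiles `x_mm,dose_rel`;
PGK `offset_mm,weight`; dose maps as CSV grids; DAH `level,area_fraction` —
each with a JSON sidecar carrying roles, grids, normalization and
provenance (package version, seed, config hash).

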