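# Methods

`mlcmargins` implements an on-line, auto-adaptive margin generator for
MLC-tracked radiotherapy, together with a virtual delivery loop that takes
the place of a linac, a motion stage and film dosimetry. This note records
the model, the numerical choices, and what the built-in simulator does and
does not emulate.

## Tracking-error model

All geometry lives in the beam's-eye view (BEV), in isocenter-centered
millimetres, with `x` the leaf-travel axis and `y` the jaw axis. Three
signals circulate in the loop:

- `p_target(t)` — the true target position,
- `p_sense(t)` — the delayed feedback variable, `p_target(t - dT_sense)`,
- `p_MLC(t)` — the aperture's center-of-gravity read-out.

The tracking error is `eps(t) = p_MLC(t) - p_target(t)`, per axis. Because
the target position only becomes known a sensing latency later, the
controller evaluates it causally at each cycle `t'` as

    eps(t' - dT_sense) = p_MLC(t' - dT_sense) - p_sense(t'),

interpolating the MLC read-out linearly at the look-back time and never
touching samples beyond `t'`. `dT_sense` is constant per run (300 ms by
default, emulating a realistic imaging chain); the API accepts an arbitrary
value per call so dynamically timed look-backs remain possible.

Errors are kept per axis in a cyclic FIFO of `N = 500` samples; at the
40 ms control cycle that is a 20 s sliding history — long enough to average
several breathing cycles, short enough to follow drifting machine/patient
behaviour.

## Error statistics

The buffered errors are turned into a continuous density with a Gaussian
kernel density estimator,

    p_eps(x) = (1/N) sum_n phi_sigma(x - eps_n),

with the 1-D normal-reference rule-of-thumb bandwidth
`sigma = s (4 / 3N)^(1/5)` (sample SD, ddof = 1). The SD variant was chosen
over robust IQR-based alternatives for determinism and simplicity. The raw
kernel sum is normalized to unit integral so that degrading a dose profile
with the density conserves the dose scale (a delta density must leave the
reference dose unchanged). Degenerate buffers (fewer than two samples, or
zero spread) fall back to a bandwidth of 0.25 mm, one raster cell.

The density is evaluated on a grid spanning `[min eps - 4 sigma,
max eps + 4 sigma]` at 0.05 mm — five times finer than the aperture raster,
so interpolation error in the margin solve is far below the 0.25 mm
quantization. Margin generation is suspended (zero margins) until 50 errors
are buffered; the warm-up threshold is a design choice, as start-up
behaviour is otherwise unspecified.

## Dose model and margin extraction

Collimators do not cut the field off sharply; the penumbra is modelled by a
shift-invariant, symmetric penumbra-generating kernel (PGK) with
`D_static,real = PGK * D_static,ideal`. The PGK is recovered from a static
measurement of a 10 x 10 cm^2 block field by Fourier deconvolution with
waterlevel regularization: the ideal field's spectrum is clipped from below
at `waterlevel x max|spectrum|` (default 1e-3) before division.

Three clean-up steps make the estimate robust:

1. **Noise-aware waterlevel.** The measurement noise is estimated from the
   plateau scatter and the waterlevel floor is lifted to three times the
   implied noise spectrum if needed, so the division never amplifies noise.
2. **Compact support.** The kernel cannot be wider than the edge roll-off
   it produces, so its support is bounded by the measured profile's
   0.95 -> 0.05 edge width (a noise-insensitive read-out) with a 25% safety
   factor. This removes the long-range ripple left by the suppressed
   spectral bins.
3. **Tail denoising.** If the outer region of the raw kernel shows a noise
   floor, a 1 mm moving average plus a 1.5-sigma hard threshold suppress it
   before the non-negativity clip; otherwise the clip would rectify
   zero-mean noise into spurious tail mass and inflate the kernel's second
   moment.

Finally the kernel is clipped to non-negative values, symmetrized by
averaging with its mirror, and renormalized to unit integral.

Tracking errors degrade the reference dose by convolution,

    D_dyn(x) = (D_ref * p_eps)(x),

oriented so that a pure aperture displacement `+s` relative to the target
moves dose to `+s`. The per-side margin at confidence level `D_hat`
(default 0.9) is the outward distance between the `D_hat` crossings of the
reference and degraded profiles on that side, clamped to `>= 0`: dose
*gained* on a side never erodes the aperture. The crossing is the
*outermost* one (conservative for multi-modal error densities) and is
located by linear interpolation on the evaluation grid, accurate to well
under 0.05 mm for penumbra-scale shoulders. If the degraded profile never
reaches `D_hat` the margin saturates at the configured maximum (20 mm) with
an explicit flag. Margins are solved independently per axis and per side
from the same degraded profile, giving the four-component prescription
`(m_x+, m_x-, m_y+, m_y-)`.

For Gaussian-shouldered references (penumbra SD `sigma_p`) and zero-mean
Gaussian errors (`sigma_e`) the solve reproduces the closed form
`m = PhiInv(D_hat) (sqrt(sigma_p^2 + sigma_e^2) - sigma_p)` to within the
grid tolerance; this closed form is the main numerical oracle in the test
suite.

## Aperture forming

The planned segment is shifted to the prescribed position, rasterized at
0.25 mm (a cell is occupied iff its center lies inside the polygon,
even-odd rule), and expanded by separable morphologic dilation. The 1-D
structuring element per axis has `round(m/resolution)` cells on each side
plus a center cell — half-up rounding, so margins of (-4 mm, 2 mm) at
0.25 mm give 16 + 1 + 8 = 25 elements. Margins are clamped to
[0, 20 mm]; the generator only ever expands apertures.

The dilated raster's outline is traced along cell edges (largest
4-connected component; holes discarded), which makes the
rasterize/contour round trip exact away from the one-cell boundary band.
Leaf fitting subdivides each leaf into 10 sub-leaves (0.5 mm effective
resolution for 5 mm leaves); each sub-leaf row contributes the min/max `x`
of its center line's intersection with the polygon, and the pair's
positions are the means over contributing rows. Rows crossing the polygon
more than twice take the global extents. Pairs without intersection park
closed at the aperture centroid's `x` (shielded by the jaws); no park rule
is standard, this one keeps closed pairs near the field. Jaws follow the
(undilated, shifted) polygon's `y` extrema plus the `y` margins.

## Virtual delivery

The simulator closes the loop without hardware:

- **Motion.** A breathing surrogate `s = A_i (2 sin^4(pi phi) - 1)` with an
  exhale rest phase; per-cycle amplitude `A_i` and period `T_i` vary with a
  configurable fractional SD, plus linear drift and a small cardiac ripple.
  Two presets emulate the qualitative classes of free-breathing volunteer
  liver-dome traces: `v1` (regular, sleep-like: 12 mm amplitude, 4 s
  period, 5% variability) and `v2` (irregular: 10 mm, 3.2 s, 30%
  variability, 1 mm/min drift, stronger cardiac component). Amplitudes
  match reported diaphragm excursions. The surrogate is generated at the
  native 10 Hz of fast 2-D imaging and linearly upsampled to the 40 ms
  control cycle; the dominant axis is mapped mostly onto leaf travel, as a
  tracking system would orient the collimator.
- **Machine.** The MLC's center-of-gravity response is a first-order lag
  (60 ms time constant) plus a 25 mm/s rate limit and 0.25 mm quantization.
  The real response is more complex (over- and undershoots), so the model
  is configurable and its exact form is not a validation surface; what
  matters is that it produces realistic, non-constant-lag residual errors.
- **Dose.** Dose accumulates cycle-exactly in the target's frame: each
  40 ms cycle deposits the delivered aperture's area-exact rectangle
  fluence (per leaf pair, clipped by the jaws) displaced by the
  instantaneous error, weighted by the cycle duration. Sub-cycle motion is
  ignored, consistent with the control-system granularity. The 2-D penumbra
  blur is applied once after summation (convolution commutes with the sum)
  as the separable product `K1(x) K1(y)` of the 1-D PGK with itself. The
  separable form is used rather than a rotation of the 1-D kernel because
  its axis marginals are exactly the 1-D kernel, so the 1-D margin model
  and the 2-D simulation agree by construction; for near-Gaussian kernels
  the two constructions coincide.
- **Scoring.** Maps are normalized to the mean of a 15 x 15 mm^2 central
  plateau region of the static exposure. Coverage is scored by dose-area
  histograms; `A90` is the fraction of a region receiving more than 0.9 of
  the reference dose. Regions of interest are the reference shoulder
  (0.9 < D < 0.97) and plateau (D > 0.9). The principal motion axis comes
  from a PCA of the target trace.

A closed-loop run produces four exposures (static, untracked, tracked,
tracked with margins), mirroring a four-film tracking experiment, plus a
per-cycle log of positions, errors, bandwidths and margins.

The default run length is 200 s (5000 cycles), which gives stable A90 and
model-comparison statistics while keeping a full two-preset study at a few
minutes of compute; all sizes are configurable.

## What the simulator does and does not show

The built-in model validates the *method*: that on-line KDE error
statistics pushed through the convolution dose model produce margins that
restore a chosen coverage level, and that the dose model predicts the
simulated dose loss (the simulator-vs-model equivalence is itself a tested
invariant, and is non-trivial because the simulator deposits 2-D leaf-fitted
fluence while the model is a 1-D convolution). It does not reproduce film
dosimetry numbers: output-factor changes with aperture position, head
scatter, depth-dependent penumbra, film calibration and 3-D dose deposition
are all outside the model, so measured A90 values from a physical
experiment are comparable only in direction, not in magnitude. Leaf
discretization leaves small residual mismatches near aperture vertices at
45 degrees to the axes — visible as a sub-2% area of the reference 90%
isodose that the compensated delivery misses.

## Known limitations

- BEV-only: a third motion component is accepted in input and ignored.
- Constant sensing latency; jitter is not modelled.
- The PGK is depth-independent.
- No vendor constraints (leaf speed per leaf, interdigitation) or collimator
  rotation in the leaf fitter; the closed-pair park rule is a convention.
- Margins react within one control cycle, but the error statistics lag by
  the 20 s buffer by design; abrupt changes in breathing are only absorbed
  after the buffer turns over.
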