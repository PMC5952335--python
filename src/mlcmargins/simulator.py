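"""Virtual delivery: breathing-like motion, MLC response, dose accumulation.

Replaces linac and radiosensitive film with a cycle-exact simulation. Target
motion emulates liver-dome traces of free-breathing volunteers (a
cycle-varying sinusoid with an exhale rest phase, slow drift and a small
cardiac ripple, generated at the native 10 Hz sampling of fast 2-D imaging
and linearly upsampled to the 40 ms control cycle). The virtual MLC applies
the sensing latency, a first-order electromechanic lag, a leaf-speed rate
limit and position quantization. Dose is accumulated in the moving target's
frame as per-cycle aperture fluence convolved with the 2-D penumbra kernel,
and coverage is scored with dose-area histograms (A90) plus a PCA principal
motion axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .error_stats import CYCLE_PERIOD, MotionTrace
from .dose_model import PGK
from .geometry import LeafBank

logger = logging.getLogger(__name__)

#: Side length of the central plateau region used for dose normalization, mm.
NORMALIZATION_BOX = 15.0


class SimulatorError(ValueError):
    """Invalid simulator input."""


# ---------------------------------------------------------------------------
# motion generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BreathingParams:
    """Parameters of the synthetic breathing surrogate.

    ``amplitude_cc`` is the half peak-to-peak excursion (mm) of the dominant
    axis; ``variability`` the fractional SD of per-cycle amplitude and
    period; ``axis_mix`` maps the 1-D surrogate onto (x, y) in BEV (the
    dominant axis is kept parallel to leaf travel, as a tracking system
    would orient the collimator).
    """

    amplitude_cc: float = 12.0
    period: float = 4.0
    variability: float = 0.05
    drift: float = 0.0              # mm/min
    cardiac_amplitude: float = 0.8  # mm
    cardiac_rate: float = 1.1       # Hz
    axis_mix: tuple[float, float] = (1.0, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period <= 0 or self.cardiac_rate <= 0:
            raise SimulatorError("period and cardiac rate must be positive")
        if self.amplitude_cc < 0 or self.variability < 0 or self.cardiac_amplitude < 0:
            raise SimulatorError("amplitudes and variability must be >= 0")


def v1_like(seed: int = 0) -> BreathingParams:
    """Regular, sleep-like breathing (low cycle-to-cycle variability)."""
    return BreathingParams(amplitude_cc=12.0, period=4.0, variability=0.05,
                           drift=0.0, cardiac_amplitude=0.8, cardiac_rate=1.1,
                           axis_mix=(1.0, 0.3), seed=seed)


def v2_like(seed: int = 0) -> BreathingParams:
    """Irregular breathing: strong amplitude/frequency variation plus drift."""
    return BreathingParams(amplitude_cc=10.0, period=3.2, variability=0.30,
                           drift=1.0, cardiac_amplitude=1.2, cardiac_rate=1.25,
                           axis_mix=(1.0, 0.4), seed=seed)


PRESETS = {"v1": v1_like, "v2": v2_like}


@dataclass(frozen=True)
class MachineParams:
    """Timing and electromechanic parameters of the virtual tracking chain."""

    cycle: float = CYCLE_PERIOD      # s, control-system cycle
    delta_T_sense: float = 0.300     # s, imposed sensing latency
    mlc_lag: float = 0.06            # s, first-order response time constant
    rate_limit: float = 25.0         # mm/s, COG slew limit (leaf speed)
    quantization: float = 0.25       # mm, position quantization (0 disables)

    def __post_init__(self) -> None:
        for name in ("cycle", "delta_T_sense", "mlc_lag", "rate_limit", "quantization"):
            if getattr(self, name) < 0:
                raise SimulatorError(f"{name} must be >= 0")
        if self.cycle == 0:
            raise SimulatorError("cycle must be positive")


def draw_breathing_cycles(params: BreathingParams, duration: float,
                          rng: np.random.Generator
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-cycle (period, amplitude) pairs covering ``duration``.

    Periods and amplitudes vary independently around their nominal values
    with fractional SD ``params.variability`` (periods floored at 30% of
    nominal, amplitudes at zero).
    """
    periods, amplitudes = [], []
    total = 0.0
    while total < duration:
        T_i = params.period * max(0.3, 1.0 + params.variability * rng.standard_normal())
        A_i = params.amplitude_cc * max(0.0, 1.0 + params.variability * rng.standard_normal())
        periods.append(T_i)
        amplitudes.append(A_i)
        total += T_i
    return np.asarray(periods), np.asarray(amplitudes)


def generate_trace(params: BreathingParams, duration: float,
                   native_dt: float = 0.1,
                   cycle: float = CYCLE_PERIOD) -> MotionTrace:
    """Synthesize a 2-D target trace and upsample it to the control cycle.

    The surrogate is a per-cycle sinusoid-with-rest-phase,
    s = A_i (2 sin^4(pi phi) - 1), phi the phase within breathing cycle i,
    whose amplitude A_i and period T_i are drawn per cycle with fractional
    SD ``variability``; drift and cardiac ripple are added on top. The
    native-rate samples are linearly interpolated to ``cycle`` spacing,
    mirroring an imaging chain that delivers ~10 Hz positions to a 40 ms
    controller. Reproducible given ``params.seed``.
    """
    if duration <= 0 or native_dt <= 0:
        raise SimulatorError("duration and native_dt must be positive")
    rng = np.random.default_rng(params.seed)
    t_native = np.arange(0.0, duration + native_dt, native_dt)
    periods, amplitudes = draw_breathing_cycles(params, duration + native_dt, rng)
    phase = np.empty_like(t_native)
    amp = np.empty_like(t_native)
    t_cycle_start = 0.0
    for T_i, A_i in zip(periods, amplitudes):
        in_cycle = (t_native >= t_cycle_start) & (t_native < t_cycle_start + T_i)
        phase[in_cycle] = (t_native[in_cycle] - t_cycle_start) / T_i
        amp[in_cycle] = A_i
        t_cycle_start += T_i
    breathing = amp * (2.0 * np.sin(np.pi * phase) ** 4 - 1.0)
    cardiac_phase = rng.uniform(0.0, 2.0 * np.pi)
    surrogate = (breathing
                 + params.drift * t_native / 60.0
                 + params.cardiac_amplitude
                 * np.sin(2.0 * np.pi * params.cardiac_rate * t_native + cardiac_phase))
    t = np.arange(0.0, duration, cycle)
    x = np.interp(t, t_native, params.axis_mix[0] * surrogate)
    y = np.interp(t, t_native, params.axis_mix[1] * surrogate)
    return MotionTrace(t, x, y, role="target")


def delayed_trace(target: MotionTrace, delay: float, role: str = "sensed"
                  ) -> MotionTrace:
    """Delayed copy: value at t is the target's position at t - delay.

    Before the first sample becomes available the first position is held
    (the sensing chain reports its last known value).
    """
    if delay < 0:
        raise SimulatorError("delay must be >= 0")
    t = target.t
    x = np.interp(t - delay, t, target.x, left=target.x[0])
    y = np.interp(t - delay, t, target.y, left=target.y[0])
    return MotionTrace(t, x, y, role=role, delta_T_sense=delay)


def respond(prescribed: MotionTrace, machine: MachineParams) -> MotionTrace:
    """Virtual MLC COG response: first-order lag, rate limit, quantization.

    The continuous (pre-quantization) state is integrated so quantization
    does not dead-band the loop; the emitted positions are quantized. For
    vanishing lag and unbounded rate the response equals the input.
    """
    dt = machine.cycle
    steps = np.diff(prescribed.t)
    if steps.size and not np.allclose(steps, dt, rtol=1e-6):
        raise SimulatorError("prescribed trace must be sampled at the machine cycle")
    alpha = 1.0 if machine.mlc_lag == 0 else 1.0 - np.exp(-dt / machine.mlc_lag)
    max_step = machine.rate_limit * dt if machine.rate_limit > 0 else np.inf
    out = np.empty((prescribed.t.size, 2))
    state = np.array([prescribed.x[0], prescribed.y[0]])
    for k in range(prescribed.t.size):
        u = np.array([prescribed.x[k], prescribed.y[k]])
        step = alpha * (u - state)
        step = np.clip(step, -max_step, max_step)
        state = state + step
        out[k] = state
    if machine.quantization > 0:
        out = np.round(out / machine.quantization) * machine.quantization
    return MotionTrace(prescribed.t, out[:, 0], out[:, 1], role="mlc")


# ---------------------------------------------------------------------------
# dose accumulation and scoring
# ---------------------------------------------------------------------------

@dataclass
class DoseMap2D:
    """Accumulated relative dose on a uniform 2-D grid in the target frame."""

    x: np.ndarray
    y: np.ndarray
    dose: np.ndarray  # [iy, ix]
    n_cycles: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != (self.y.size, self.x.size):
            raise SimulatorError("dose shape must be (len(y), len(x))")
        if np.any(self.dose < 0):
            raise SimulatorError("dose must be non-negative")

    @property
    def spacing(self) -> float:
        return float(self.x[1] - self.x[0])

    def central_plateau_mean(self, box: float = NORMALIZATION_BOX) -> float:
        """Mean dose in the central box x box mm^2 region."""
        mx = np.abs(self.x) <= box / 2.0
        my = np.abs(self.y) <= box / 2.0
        return float(self.dose[np.ix_(my, mx)].mean())

    def normalized(self, reference_value: float | None = None) -> "DoseMap2D":
        """Scale so the reference value (default: own central plateau) is 1."""
        ref = self.central_plateau_mean() if reference_value is None else reference_value
        if ref <= 0:
            raise SimulatorError("non-positive normalization value")
        return DoseMap2D(self.x.copy(), self.y.copy(), self.dose / ref, self.n_cycles)

    def profile_x(self, y0: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        iy = int(np.argmin(np.abs(self.y - y0)))
        return self.x.copy(), self.dose[iy].copy()

    def profile_y(self, x0: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        ix = int(np.argmin(np.abs(self.x - x0)))
        return self.y.copy(), self.dose[:, ix].copy()


def make_grid(half_span: float = 60.0, resolution: float = 0.5
              ) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric uniform grid coordinates for dose maps."""
    n = int(np.ceil(half_span / resolution))
    c = np.arange(-n, n + 1) * resolution
    return c, c.copy()


def _interval_coverage(coords: np.ndarray, h: float, a: float, b: float
                       ) -> np.ndarray:
    """Fraction of each cell [c - h/2, c + h/2] covered by [a, b]."""
    lo = np.maximum(a, coords - h / 2.0)
    hi = np.minimum(b, coords + h / 2.0)
    return np.clip((hi - lo) / h, 0.0, 1.0)


def _deposit_bank(fluence: np.ndarray, xs: np.ndarray, ys: np.ndarray,
                  bank: LeafBank, dx: float, dy: float, weight: float) -> None:
    """Add one cycle's aperture fluence, bank translated by (dx, dy)."""
    h = float(xs[1] - xs[0])
    jm = bank.jaw_y_minus + dy
    jp = bank.jaw_y_plus + dy
    geo = bank.geometry
    for k in range(geo.n_pairs):
        if bank.right[k] - bank.left[k] <= 0:
            continue
        lo, hi = geo.pair_edges(k)
        ylo = max(lo + dy, jm)
        yhi = min(hi + dy, jp)
        if yhi <= ylo:
            continue
        cov_x = _interval_coverage(xs, h, bank.left[k] + dx, bank.right[k] + dx)
        cov_y = _interval_coverage(ys, h, ylo, yhi)
        if cov_x.any() and cov_y.any():
            fluence += weight * cov_y[:, None] * cov_x[None, :]


def _pgk_taps(pgk: PGK, h: float) -> np.ndarray:
    """Resample the 1-D PGK to grid spacing h, unit discrete sum."""
    half_n = int(np.ceil(pgk.offsets[-1] / h))
    off = np.arange(-half_n, half_n + 1) * h
    w = np.interp(off, pgk.offsets, pgk.weights, left=0.0, right=0.0)
    s = w.sum()
    if s <= 0:
        raise SimulatorError("PGK resampling lost all mass")
    return w / s


def accumulate(target: MotionTrace, mlc_cog: MotionTrace,
               aperture_series, pgk: PGK,
               grid: tuple[np.ndarray, np.ndarray],
               prescribed: MotionTrace | None = None,
               cycle: float = CYCLE_PERIOD) -> DoseMap2D:
    """Accumulate dose in the target frame over a cycle-exact delivery.

    ``aperture_series`` is a :class:`LeafBank` or a per-cycle sequence of
    banks positioned at the *prescribed* COG; the delivered aperture each
    cycle is the bank translated by the machine's residual
    ``p_MLC - p_prescribed`` (if ``prescribed`` is None the banks are taken
    as already delivered). Each cycle deposits the aperture's area-exact
    rectangle fluence displaced by ``-p_target`` (so the instantaneous
    displacement relative to the target is the tracking error), weighted by
    the cycle duration. The 2-D penumbra blur — the separable product of the
    1-D PGK with itself, whose axis marginals are exactly the 1-D kernel —
    is applied once after summation (convolution commutes with the sum).
    """
    xs, ys = grid
    if not np.allclose(target.t, mlc_cog.t, rtol=0, atol=1e-9):
        raise SimulatorError("target and MLC traces must share timestamps")
    if prescribed is not None and not np.allclose(target.t, prescribed.t,
                                                  rtol=0, atol=1e-9):
        raise SimulatorError("prescribed trace timestamps misaligned")
    n = target.t.size
    banks = aperture_series if not isinstance(aperture_series, LeafBank) \
        else [aperture_series] * n
    if len(banks) != n:
        raise SimulatorError("aperture series length must match trace length")
    fluence = np.zeros((ys.size, xs.size))
    for k in range(n):
        if prescribed is not None:
            dx = mlc_cog.x[k] - prescribed.x[k] - target.x[k]
            dy = mlc_cog.y[k] - prescribed.y[k] - target.y[k]
        else:
            dx, dy = -target.x[k], -target.y[k]
        _deposit_bank(fluence, xs, ys, banks[k], dx, dy, cycle)
    taps = _pgk_taps(pgk, float(xs[1] - xs[0]))
    dose = ndimage.convolve1d(fluence, taps, axis=0, mode="constant")
    dose = ndimage.convolve1d(dose, taps, axis=1, mode="constant")
    return DoseMap2D(xs, ys, np.clip(dose, 0.0, None), n_cycles=n)


@dataclass
class DAHResult:
    """Dose-area histogram over a region: area fraction >= each dose level."""

    levels: np.ndarray
    area_fraction: np.ndarray
    a90: float

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.area_fraction = np.asarray(self.area_fraction, dtype=float)
        if np.any(np.diff(self.levels) <= 0):
            raise SimulatorError("levels must be strictly increasing")
        if np.any(np.diff(self.area_fraction) > 1e-12):
            raise SimulatorError("area fraction must be non-increasing in level")


def dah(dose_map: DoseMap2D, region: np.ndarray,
        levels: np.ndarray | None = None) -> DAHResult:
    """Dose-area histogram of a (normalized) map within a region mask.

    ``a90`` is the fraction of the region receiving more than 0.9 of the
    reference dose.
    """
    region = np.asarray(region, dtype=bool)
    if region.shape != dose_map.dose.shape:
        raise SimulatorError("region mask shape mismatch")
    if not region.any():
        raise SimulatorError("empty region")
    if levels is None:
        levels = np.linspace(0.0, 1.2, 121)
    vals = dose_map.dose[region]
    frac = np.array([(vals >= lv).mean() for lv in np.asarray(levels, dtype=float)])
    a90 = float((vals > 0.9).mean())
    return DAHResult(levels, frac, a90)


def shoulder_region(reference: DoseMap2D, d_hat: float = 0.9,
                    upper: float = 0.97) -> np.ndarray:
    """Shoulder of the reference distribution: d_hat < D < upper."""
    return (reference.dose > d_hat) & (reference.dose < upper)


def plateau_region(reference: DoseMap2D, d_hat: float = 0.9) -> np.ndarray:
    """Region of the reference distribution with D > d_hat."""
    return reference.dose > d_hat


def principal_axis(points: np.ndarray) -> np.ndarray:
    """First principal direction of 2-D motion samples (unit vector).

    The sign is fixed to the positive-x half-plane. Isotropic or degenerate
    clouds are flagged and default to the x axis.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise SimulatorError("need >= 2 two-dimensional samples")
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0 or np.isclose(evals[0], evals[-1], rtol=1e-9):
        logger.warning("degenerate/isotropic motion: principal axis defaults to x")
        return np.array([1.0, 0.0])
    v = evecs[:, -1]
    if v[0] < 0 or (v[0] == 0 and v[1] < 0):
        v = -v
    return v
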