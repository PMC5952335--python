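"""On-line tracking-error quantification and kernel-density statistics.

The tracking error is the displacement between the actual aperture center of
gravity and the true target position in BEV,

    eps(t) = p_MLC(t) - p_target(t).

Because the sensed position is a delayed copy of the target,
``p_target(t) = p_sense(t + dT_sense)``, the error is only known a sensing
latency later: at wall-clock time t' the controller evaluates

    eps(t' - dT_sense) = p_MLC(t' - dT_sense) - p_sense(t'),

i.e. the freshest sensed sample is compared against a *look-back* MLC
position. Errors are collected per axis in a cyclic FIFO buffer (N = 500 at
the 40 ms control cycle spans 20 s) and turned into a continuous density
with a Gaussian kernel density estimator whose bandwidth follows the 1-D
normal-reference rule of thumb.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Control-system cycle of the MLC, seconds.
CYCLE_PERIOD = 0.040
#: Default FIFO depth; 500 samples at 40 ms give a 20 s history.
BUFFER_CAPACITY = 500
#: Margin generation is suspended until this many errors are buffered.
WARMUP_COUNT = 50
#: Fallback bandwidth (mm) when the sample spread is degenerate; equals the
#: raster resolution.
FALLBACK_BANDWIDTH = 0.25
#: Evaluation grid spacing of the density, mm (5x finer than the raster).
DENSITY_GRID_STEP = 0.05


class TraceError(ValueError):
    """Invalid motion-trace input."""


@dataclass
class MotionTrace:
    """Time-stamped 2-D BEV positions of one signal in the tracking chain.

    ``role`` tags the signal as ``target`` (true position), ``sensed``
    (delayed feedback variable) or ``mlc`` (aperture COG read-out). A third
    spatial component, if supplied, is dropped with a warning: tracking and
    margin generation operate in the 2-D beam's-eye view.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    role: str = "target"
    delta_T_sense: float = 0.0
    delta_T_mlc: float = 0.0
    z: "np.ndarray | None" = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.x.shape or self.t.shape != self.y.shape:
            raise TraceError("t, x, y must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.x))
                and np.all(np.isfinite(self.y))):
            raise TraceError("trace samples must be finite")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise TraceError("timestamps must be strictly increasing")
        if self.role not in ("target", "sensed", "mlc"):
            raise TraceError(f"unknown trace role {self.role!r}")
        if self.z is not None:
            logger.warning("z component ignored: tracking operates in BEV only")
            self.z = None

    def __len__(self) -> int:
        return self.t.size

    def position(self, when: float) -> tuple[float, float]:
        """Linear interpolation at ``when`` (must lie inside the trace)."""
        if when < self.t[0] or when > self.t[-1]:
            raise TraceError(f"time {when} outside trace span")
        return (float(np.interp(when, self.t, self.x)),
                float(np.interp(when, self.t, self.y)))


def compute_tracking_error(mlc: MotionTrace, sensed: MotionTrace,
                           delta_T_sense: float, t_prime: float
                           ) -> "tuple[float, float] | None":
    """Causal tracking error eps(t' - dT_sense), per axis.

    Compares the sensed position at ``t_prime`` with the MLC position
    interpolated at the look-back time ``t_prime - delta_T_sense``, using
    only samples up to ``t_prime``. Returns ``None`` when either trace lacks
    the required history (the caller skips this cycle).
    """
    if delta_T_sense < 0:
        raise TraceError("delta_T_sense must be >= 0")
    t_look = t_prime - delta_T_sense
    # causality: restrict both traces to samples at or before t' (with a
    # float tolerance so the sample taken at t' itself is admissible)
    t_cut = t_prime + 1e-9
    n_mlc = int(np.searchsorted(mlc.t, t_cut, side="right"))
    n_sen = int(np.searchsorted(sensed.t, t_cut, side="right"))
    if n_mlc == 0 or n_sen == 0:
        return None
    tm, xm, ym = mlc.t[:n_mlc], mlc.x[:n_mlc], mlc.y[:n_mlc]
    ts, xs, ys = sensed.t[:n_sen], sensed.x[:n_sen], sensed.y[:n_sen]
    if t_look < tm[0] or t_look > tm[-1] or t_prime < ts[0] or t_prime > ts[-1]:
        return None
    eps_x = np.interp(t_look, tm, xm) - np.interp(t_prime, ts, xs)
    eps_y = np.interp(t_look, tm, ym) - np.interp(t_prime, ts, ys)
    return float(eps_x), float(eps_y)


class ErrorBuffer:
    """Cyclic FIFO of per-axis tracking errors with timestamps.

    Strictly oldest-first eviction once ``capacity`` is exceeded; both axis
    stores stay equally long because samples are pushed as (t, eps_x, eps_y)
    triples.
    """

    def __init__(self, capacity: int = BUFFER_CAPACITY,
                 cycle_period: float = CYCLE_PERIOD) -> None:
        if capacity < 1 or cycle_period <= 0:
            raise ValueError("invalid buffer parameters")
        self.capacity = capacity
        self.cycle_period = cycle_period
        self._t: deque[float] = deque(maxlen=capacity)
        self._x: deque[float] = deque(maxlen=capacity)
        self._y: deque[float] = deque(maxlen=capacity)

    def __len__(self) -> int:
        return len(self._t)

    @property
    def span(self) -> float:
        """Nominal full-buffer time span in seconds (capacity x cycle)."""
        return self.capacity * self.cycle_period

    def push(self, t: float, eps_x: float, eps_y: float) -> None:
        """Append one error sample; rejects non-finite values (logged)."""
        if not (np.isfinite(t) and np.isfinite(eps_x) and np.isfinite(eps_y)):
            logger.warning("non-finite error sample rejected at t=%s", t)
            return
        self._t.append(float(t))
        self._x.append(float(eps_x))
        self._y.append(float(eps_y))

    def samples(self, axis: str) -> np.ndarray:
        if axis == "x":
            return np.fromiter(self._x, dtype=float, count=len(self._x))
        if axis == "y":
            return np.fromiter(self._y, dtype=float, count=len(self._y))
        raise ValueError(f"unknown axis {axis!r}")

    def timestamps(self) -> np.ndarray:
        return np.fromiter(self._t, dtype=float, count=len(self._t))


def push_error(buffer: ErrorBuffer, sample: tuple[float, float, float]
               ) -> ErrorBuffer:
    """Functional-style wrapper around :meth:`ErrorBuffer.push`."""
    buffer.push(*sample)
    return buffer


def kde_bandwidth(samples: np.ndarray,
                  fallback: float = FALLBACK_BANDWIDTH) -> float:
    """Normal-reference rule-of-thumb bandwidth for a 1-D Gaussian KDE.

    sigma = s * (4 / (3 N))^(1/5) with s the sample standard deviation
    (ddof=1). Degenerate inputs (< 2 samples, zero spread) fall back to the
    raster resolution (logged).
    """
    samples = np.asarray(samples, dtype=float)
    n = samples.size
    if n < 2:
        logger.warning("bandwidth fallback: fewer than 2 samples")
        return fallback
    s = float(np.std(samples, ddof=1))
    if s == 0.0:
        logger.warning("bandwidth fallback: zero sample variance")
        return fallback
    return s * (4.0 / (3.0 * n)) ** 0.2


@dataclass
class ErrorDensity:
    """Gaussian-KDE density of one axis's tracking error on a uniform grid."""

    axis: str
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n_samples: int

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.grid.shape != self.density.shape or self.grid.ndim != 1:
            raise ValueError("grid/density shape mismatch")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def mean(self) -> float:
        return float(np.trapezoid(self.grid * self.density, self.grid))


def estimate_density(buffer: ErrorBuffer, axis: str,
                     warmup: int = WARMUP_COUNT,
                     grid_step: float = DENSITY_GRID_STEP
                     ) -> "ErrorDensity | None":
    """Gaussian KDE of the buffered errors on one axis.

    density(x) = (1/N) sum_n phi_sigma(x - eps_n), evaluated on a grid
    spanning [min eps - 4 sigma, max eps + 4 sigma], then renormalized to
    unit integral (the raw kernel sum is normalized so that degrading a dose
    profile with the density conserves the dose scale). Returns ``None``
    below the warm-up threshold; the caller suspends margin generation.
    """
    eps = buffer.samples(axis)
    if eps.size < warmup:
        logger.debug("density unavailable: %d/%d warm-up samples", eps.size, warmup)
        return None
    sigma = kde_bandwidth(eps)
    lo = eps.min() - 4.0 * sigma
    hi = eps.max() + 4.0 * sigma
    n = max(2, int(np.ceil((hi - lo) / grid_step)) + 1)
    grid = lo + np.arange(n) * grid_step
    z = (grid[:, None] - eps[None, :]) / sigma
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (eps.size * sigma * np.sqrt(2.0 * np.pi))
    integral = np.trapezoid(dens, grid)
    dens = dens / integral
    return ErrorDensity(axis=axis, grid=grid, density=dens,
                        bandwidth=sigma, n_samples=int(eps.size))
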