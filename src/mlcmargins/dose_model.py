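"""Convolution dose model, penumbra-generating kernel, margin extraction.

The collimator's continuous dose roll-off (penumbra) is modelled by a
shift-invariant, symmetric penumbra-generating kernel (PGK) that converts an
ideal block field into the real static profile,

    D_static,real(x) = (PGK * D_static,ideal)(x).

The PGK is recovered from a measured (or synthetic) static profile by
Fourier deconvolution with waterlevel regularization of the ideal field's
spectrum. Tracking errors degrade the reference dose by convolution with the
error density,

    D_dyn(x) = (D_ref * p_eps)(x),

and the per-side margin at confidence level D_hat is the geometric distance
between the D_hat crossings of the reference and the degraded profile on
that side: expanding the aperture by this amount restores the reference
level at the original crossing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .error_stats import ErrorDensity
from .geometry import MAX_MARGIN, MarginSpec

logger = logging.getLogger(__name__)

#: Default waterlevel: spectral floor as a fraction of the peak magnitude of
#: the ideal field's spectrum.
DEFAULT_WATERLEVEL = 1e-3
#: Default confidence level D_hat (fraction of reference dose to restore).
DEFAULT_CONFIDENCE = 0.9

PROFILE_KINDS = ("ideal", "static_real", "measured", "degraded")


class DoseModelError(ValueError):
    """Invalid dose-model input."""


@dataclass
class DoseProfile1D:
    """1-D relative dose on a uniform grid (plateau ~ 1)."""

    x: np.ndarray
    dose: np.ndarray
    kind: str = "measured"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.dose = np.asarray(self.dose, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.dose.shape or self.x.size < 2:
            raise DoseModelError("x and dose must be matching 1-D arrays")
        steps = np.diff(self.x)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise DoseModelError("grid must be uniform")
        if np.any(self.dose < -1e-12):
            raise DoseModelError("dose must be non-negative")
        if self.kind not in PROFILE_KINDS:
            raise DoseModelError(f"unknown profile kind {self.kind!r}")
        if self.kind == "ideal" and not np.all((self.dose == 0.0) | (self.dose == 1.0)):
            raise DoseModelError("ideal profiles must be exact {0,1} indicators")

    @property
    def spacing(self) -> float:
        return float(self.x[1] - self.x[0])

    def integral(self) -> float:
        return float(self.dose.sum() * self.spacing)


@dataclass
class PGK:
    """Penumbra-generating kernel: symmetric, non-negative, unit integral."""

    offsets: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.offsets.shape != self.weights.shape or self.offsets.ndim != 1:
            raise DoseModelError("offsets/weights mismatch")
        if self.offsets.size % 2 != 1 or abs(self.offsets[self.offsets.size // 2]) > 1e-9:
            raise DoseModelError("offsets must be symmetric about 0 (odd length)")
        if np.any(self.weights < 0):
            raise DoseModelError("weights must be non-negative")

    @property
    def spacing(self) -> float:
        return float(self.offsets[1] - self.offsets[0])

    def integral(self) -> float:
        return float(self.weights.sum() * self.spacing)

    def sd(self) -> float:
        """Standard deviation of the kernel, mm."""
        w = self.weights / self.weights.sum()
        mu = float(np.sum(w * self.offsets))
        return float(np.sqrt(np.sum(w * (self.offsets - mu) ** 2)))


@dataclass(frozen=True)
class ConfidenceLevel:
    """Relative reference-dose level the margin controller aims to restore."""

    d_hat: float = DEFAULT_CONFIDENCE

    def __post_init__(self) -> None:
        if not 0.0 < self.d_hat < 1.0:
            raise DoseModelError("confidence level must lie in (0, 1)")


@dataclass
class MarginSolveResult:
    """Outcome of a one-sided margin solve."""

    margin: float
    saturated: bool
    x_ref: float
    x_dyn: float

    def __float__(self) -> float:
        return self.margin


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def ideal_block(field_width: float, grid: float = 0.25,
                span: float | None = None,
                expected_penumbra: float = 3.0) -> DoseProfile1D:
    """Ideal rectangular (block) dose: indicator of [-w/2, +w/2).

    Cell-center sampled on a symmetric grid (odd length, x = 0 included).
    ``span`` must exceed the field width by at least 8x the expected penumbra
    so deconvolution is not corrupted by edge effects.
    """
    if field_width <= 0 or grid <= 0:
        raise DoseModelError("field width and grid must be positive")
    if span is None:
        span = field_width + 16.0 * expected_penumbra
    if span <= field_width + 8.0 * expected_penumbra:
        raise DoseModelError("span too small: edge effects would corrupt deconvolution")
    half_n = int(np.ceil(span / 2.0 / grid))
    x = np.arange(-half_n, half_n + 1) * grid
    dose = ((x >= -field_width / 2.0) & (x < field_width / 2.0)).astype(float)
    return DoseProfile1D(x, dose, kind="ideal")


def gaussian_kernel_profile(sigma: float, grid: float,
                            halfwidth_sigmas: float = 6.0) -> PGK:
    """Discrete unit-integral Gaussian kernel (synthetic PGK)."""
    if sigma <= 0 or grid <= 0:
        raise DoseModelError("sigma and grid must be positive")
    half_n = int(np.ceil(halfwidth_sigmas * sigma / grid))
    off = np.arange(-half_n, half_n + 1) * grid
    w = np.exp(-0.5 * (off / sigma) ** 2)
    w /= w.sum() * grid
    return PGK(off, w)


def convolve_profile(profile: DoseProfile1D, kernel_offsets: np.ndarray,
                     kernel_weights: np.ndarray, kind: str = "static_real"
                     ) -> DoseProfile1D:
    """Discrete convolution of a profile with a centered symmetric-grid kernel.

    The kernel must share the profile's grid spacing and have an odd number
    of taps centered on offset 0, so 'same'-mode convolution stays aligned.
    """
    dx = profile.spacing
    if not np.isclose(kernel_offsets[1] - kernel_offsets[0], dx, rtol=1e-6):
        raise DoseModelError("kernel spacing must match profile spacing")
    n_k = len(kernel_weights)
    if n_k % 2 != 1:
        raise DoseModelError("kernel must have an odd number of taps")
    full = np.convolve(profile.dose, kernel_weights * dx, mode="full")
    start = (n_k - 1) // 2  # centered extraction works for any kernel length
    out = np.clip(full[start:start + profile.dose.size], 0.0, None)
    return DoseProfile1D(profile.x.copy(), out, kind=kind)


def apply_pgk(ideal: DoseProfile1D, pgk: PGK) -> DoseProfile1D:
    """Forward model: D_static,real = PGK * D_static,ideal."""
    return convolve_profile(ideal, pgk.offsets, pgk.weights, kind="static_real")


def estimate_pgk(measured: DoseProfile1D, ideal: DoseProfile1D,
                 waterlevel: float = DEFAULT_WATERLEVEL) -> PGK:
    """Recover the PGK by waterlevel-regularized Fourier deconvolution.

    The ideal field's spectrum is clipped from below at
    ``waterlevel x max|spectrum|`` before division (suppressing noise
    amplification at the block spectrum's zeros). The kernel estimate is
    centered, negatives are clipped, it is symmetrized by averaging with its
    mirror and renormalized to unit integral.
    """
    if not (0.0 < waterlevel < 1.0):
        raise DoseModelError("waterlevel must lie in (0, 1)")
    if measured.x.shape != ideal.x.shape or not np.allclose(measured.x, ideal.x):
        raise DoseModelError("measured and ideal profiles must share one grid")
    n = measured.x.size
    if n % 2 != 1:
        raise DoseModelError("profile grid must have odd length (x = 0 centered)")
    f_meas = np.fft.fft(measured.dose)
    f_ideal = np.fft.fft(ideal.dose)
    mag = np.abs(f_ideal)
    # the waterlevel must sit above the measurement-noise spectrum or the
    # division amplifies noise into the kernel; estimate the noise from the
    # plateau scatter and lift the floor accordingly
    interior = np.nonzero(ideal.dose > 0.5)[0]
    if interior.size > 20:
        interior = interior[10:-10]
    sigma_noise = float(np.std(measured.dose[interior])) if interior.size else 0.0
    waterlevel_eff = max(waterlevel, 3.0 * sigma_noise * np.sqrt(n) / mag.max())
    floor = waterlevel_eff * mag.max()
    low = mag < floor
    # lift low-magnitude bins to the waterlevel, keeping their phase
    phase = np.where(mag > 0, f_ideal / np.where(mag > 0, mag, 1.0), 1.0)
    f_reg = np.where(low, floor * phase, f_ideal)
    kernel = np.fft.ifft(f_meas / f_reg).real
    kernel = np.fft.fftshift(kernel)
    kernel = 0.5 * (kernel + kernel[::-1])  # enforce symmetry about center
    dx = measured.spacing
    center = n // 2

    # Restrict to the kernel's compact support before cleaning up: physical
    # penumbra kernels are compact, and the long-range ripple left by the
    # suppressed spectral bins (plus deconvolved measurement noise) would
    # otherwise dominate the second moment. The support is inferred from the
    # measured profile itself: the kernel cannot be wider than the edge
    # roll-off it produces, so the 0.95 -> 0.05 edge width (a robust,
    # noise-insensitive read-out) bounds it, with a 25% safety factor.
    plateau = float(np.max(measured.dose))
    hi95 = np.nonzero(measured.dose >= 0.95 * plateau)[0]
    hi05 = np.nonzero(measured.dose >= 0.05 * plateau)[0]
    edge_plus = (hi05[-1] - hi95[-1]) * dx
    edge_minus = (hi95[0] - hi05[0]) * dx
    pad = max(2, int(np.ceil(1.0 / dx)))
    half = min(center, int(np.ceil(1.25 * max(edge_plus, edge_minus) / dx)) + pad)

    # noise-adaptive cleanup: if the outer region (which holds no physical
    # kernel mass) shows a noise floor, suppress it by a 1 mm moving average
    # before the non-negativity clip, so clipped noise does not bias the
    # kernel's tails
    outer = np.concatenate([kernel[: center - 2 * half], kernel[center + 2 * half:]])
    if outer.size:
        noise = 1.4826 * float(np.median(np.abs(outer - np.median(outer))))
        if noise > 0.005 * kernel.max():
            w = max(3, int(np.round(1.0 / dx)) | 1)
            kernel = np.convolve(kernel, np.ones(w) / w, mode="same")
            outer_s = np.concatenate([kernel[: center - 2 * half],
                                      kernel[center + 2 * half:]])
            noise_s = 1.4826 * float(np.median(np.abs(outer_s - np.median(outer_s))))
            # hard-threshold the residual noise floor so the subsequent
            # non-negativity clip cannot rectify it into spurious tail mass
            kernel = np.where(np.abs(kernel) >= 1.5 * noise_s, kernel, 0.0)

    sl = slice(center - half, center + half + 1)
    offsets = (np.arange(n) - n // 2) * dx
    offsets, kernel = offsets[sl], np.clip(kernel[sl], 0.0, None)
    kernel = 0.5 * (kernel + kernel[::-1])
    total = kernel.sum() * dx
    if total <= 0:
        raise DoseModelError("deconvolution produced an empty kernel")
    return PGK(offsets, kernel / total)


def _resample_density(density: ErrorDensity, dx: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Resample a density to spacing ``dx`` on a symmetric grid about 0."""
    lo = min(density.grid[0], -density.grid[-1])
    half_n = int(np.ceil(max(abs(lo), abs(density.grid[-1])) / dx)) + 1
    grid = np.arange(-half_n, half_n + 1) * dx
    dens = np.interp(grid, density.grid, density.density, left=0.0, right=0.0)
    total = dens.sum() * dx
    if total <= 0:
        raise DoseModelError("density resampling lost all mass")
    return grid, dens / total


def degrade(ref: DoseProfile1D, density: ErrorDensity) -> DoseProfile1D:
    """Degrade the reference dose by the error density: D_dyn = D_ref * p_eps.

    A pure error shift +s (aperture displaced by +s relative to the target)
    moves dose to +s: D_dyn(x) = D_ref(x - s). The density is resampled onto
    the profile's grid spacing with renormalization (logged at debug level),
    so the total dose integral is conserved.
    """
    dx = ref.spacing
    if not np.isclose(density.step, dx, rtol=1e-9):
        logger.debug("density grid (%.3f mm) resampled to profile grid (%.3f mm)",
                     density.step, dx)
    grid, dens = _resample_density(density, dx)
    return convolve_profile(ref, grid, dens, kind="degraded")


def _crossing(profile: DoseProfile1D, level: float, side: str) -> float | None:
    """Outermost x where the profile crosses ``level`` on one side.

    Scans outward: the returned crossing is the last transition through the
    level when moving away from the field center (conservative for
    non-monotone shoulders). Linear interpolation between grid points.
    """
    d, x = profile.dose, profile.x
    above = d >= level
    if not above.any():
        return None
    idx = np.nonzero(above)[0]
    if side == "plus":
        i = idx[-1]
        if i == d.size - 1:
            return float(x[-1])
        x0, x1, d0, d1 = x[i], x[i + 1], d[i], d[i + 1]
    elif side == "minus":
        i = idx[0]
        if i == 0:
            return float(x[0])
        x0, x1, d0, d1 = x[i], x[i - 1], d[i], d[i - 1]
    else:
        raise DoseModelError(f"unknown side {side!r}")
    if d0 == d1:
        return float(x0)
    return float(x0 + (level - d0) / (d1 - d0) * (x1 - x0))


def extract_margin(ref: DoseProfile1D, dyn: DoseProfile1D,
                   level: ConfidenceLevel | float = DEFAULT_CONFIDENCE,
                   side: str = "plus",
                   max_margin: float = MAX_MARGIN) -> MarginSolveResult:
    """Solve for the one-sided margin at confidence level D_hat.

    m is the outward distance from the degraded profile's D_hat crossing to
    the reference's on the requested side, clamped to >= 0 (dose gained on a
    side never erodes the aperture). If the degraded profile never reaches
    D_hat the margin saturates at ``max_margin`` (flagged).
    """
    d_hat = level.d_hat if isinstance(level, ConfidenceLevel) else float(level)
    if not 0.0 < d_hat < 1.0:
        raise DoseModelError("confidence level must lie in (0, 1)")
    x_ref = _crossing(ref, d_hat, side)
    if x_ref is None:
        raise DoseModelError("reference profile never reaches the confidence level")
    x_dyn = _crossing(dyn, d_hat, side)
    if x_dyn is None:
        logger.warning("degraded profile never reaches D_hat=%.3f: margin saturated", d_hat)
        return MarginSolveResult(max_margin, True, x_ref, np.nan)
    if side == "plus":
        m = x_ref - x_dyn
    else:
        m = x_dyn - x_ref
    m = min(max(m, 0.0), max_margin)
    return MarginSolveResult(float(m), False, x_ref, x_dyn)


def margins_from_state(density_x: ErrorDensity | None,
                       density_y: ErrorDensity | None,
                       ref_x: DoseProfile1D, ref_y: DoseProfile1D,
                       level: ConfidenceLevel | float = DEFAULT_CONFIDENCE,
                       max_margin: float = MAX_MARGIN) -> MarginSpec:
    """Four per-side margins from the per-axis error densities.

    Each axis's reference profile is degraded with that axis's density and
    both shoulders are solved independently. Missing densities (warm-up)
    yield zero margins.
    """
    if density_x is None or density_y is None:
        logger.debug("margins suspended: error density not yet available")
        return MarginSpec(0.0, 0.0, 0.0, 0.0)
    dyn_x = degrade(ref_x, density_x)
    dyn_y = degrade(ref_y, density_y)
    mxp = extract_margin(ref_x, dyn_x, level, "plus", max_margin).margin
    mxm = extract_margin(ref_x, dyn_x, level, "minus", max_margin).margin
    myp = extract_margin(ref_y, dyn_y, level, "plus", max_margin).margin
    mym = extract_margin(ref_y, dyn_y, level, "minus", max_margin).margin
    return MarginSpec.clamped(mxp, mxm, myp, mym, max_margin=max_margin)
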