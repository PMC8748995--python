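"""Depth-resolved OCT attenuation fitting.

A spectral-domain OCT A-line records backscattered intensity as a function
of depth.  Under the single-scattering Beer-Lambert approximation the depth
profile of a laterally homogeneous medium is

    R(z) = mu_b' * exp(-2 * mu_s * z) * h(z) * H(z)

where ``mu_s`` (mm^-1) is the scattering coefficient, ``mu_b'`` the relative
back-scattering coefficient (absorbing source power, spectrometer efficiency
and detection geometry), ``h(z)`` the confocal weighting of the objective and
``H(z)`` the spectrometer sensitivity roll-off.  Absorption is negligible in
the near infrared and is not modelled.

Fitting each (block-averaged) A-line with the confocal parameters fixed from
an Intralipid-phantom calibration yields per-pixel estimates of ``mu_s`` and
``mu_b'``, which assemble into lateral optical-property maps.

Units: depths in micrometres, ``mu_s`` in mm^-1.  The factor of 1000 between
the two is applied in exactly one place (:data:`UM_PER_MM`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

UM_PER_MM = 1000.0

#: Bounds for the scattering coefficient, mm^-1.  Brain tissue values are
#: roughly 1-12 mm^-1; the upper bound brackets them with wide margin.
MU_S_BOUNDS = (0.0, 50.0)


# ---------------------------------------------------------------------------
# Configuration and containers
# ---------------------------------------------------------------------------

@dataclass
class SystemConfig:
    """Imaging-system geometry and fit-window settings.

    Parameters
    ----------
    z_spacing, lateral_spacing:
        Voxel pitch in micrometres (nominally 2.9 um isotropic: a 1.5 mm
        imaging depth divided over 512 axial pixels).
    zf, zrs:
        Focus depth and effective Rayleigh range of the confocal weighting
        ``h(z)``, micrometres.  Pre-calibrated on a phantom, then held fixed
        during tissue fitting.
    rolloff_decay:
        1/e depth (um) of the exponential sensitivity roll-off ``H(z)``;
        ``None`` disables roll-off (H == 1).
    fit_depth_min, fit_depth_max:
        Fit window in micrometres below the detected tissue surface.
    surface_threshold_frac:
        Fraction of the profile maximum used for surface detection.
    """

    z_spacing: float = 2.9
    lateral_spacing: float = 2.9
    zf: float = 300.0
    zrs: float = 120.0
    rolloff_decay: Optional[float] = None
    fit_depth_min: float = 30.0
    fit_depth_max: float = 450.0
    surface_threshold_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.z_spacing <= 0 or self.lateral_spacing <= 0:
            raise ValueError("voxel spacings must be positive")
        if self.zrs <= 0:
            raise ValueError("effective Rayleigh range zrs must be positive")
        if self.rolloff_decay is not None and self.rolloff_decay <= 0:
            raise ValueError("rolloff_decay must be positive or None")
        if not (self.fit_depth_max > self.fit_depth_min >= 0):
            raise ValueError("require fit_depth_max > fit_depth_min >= 0")


@dataclass
class ALineProfile:
    """A single depth profile R(z) at one lateral position."""

    intensities: np.ndarray
    z_grid: np.ndarray  # um, strictly increasing

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        if self.intensities.shape != self.z_grid.shape:
            raise ValueError("intensities and z_grid must have equal length")
        if self.z_grid.size and np.any(np.diff(self.z_grid) <= 0):
            raise ValueError("z_grid must be strictly increasing")


@dataclass
class OCTVolume:
    """3D reflectance volume indexed (x, y, z) with voxel spacings in um."""

    intensities: np.ndarray
    z_spacing: float
    lateral_spacing: float

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if not np.issubdtype(self.intensities.dtype, np.floating):
            self.intensities = self.intensities.astype(float)
        if self.intensities.ndim != 3:
            raise ValueError("volume must be 3D (x, y, z)")
        if self.z_spacing <= 0 or self.lateral_spacing <= 0:
            raise ValueError("voxel spacings must be positive")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def z_grid(self) -> np.ndarray:
        return np.arange(self.intensities.shape[2]) * self.z_spacing

    def profile(self, ix: int, iy: int) -> ALineProfile:
        return ALineProfile(self.intensities[ix, iy, :], self.z_grid)


@dataclass
class FitResult:
    mu_s: float            # mm^-1
    mu_b_rel: float        # relative intensity units
    residual_rms: float
    converged: bool
    n_iter: int = 0


@dataclass
class OpticalPropertyMap:
    """2D lateral map of a fitted quantity with a valid-fit mask."""

    values: np.ndarray
    quantity: str  # one of {"mu_s", "mu_b_rel", "ratio", "aip"}
    pixel_pitch: float  # um
    mask: np.ndarray = field(default=None)  # True where valid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("map values must be 2D")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values")
        if self.quantity not in {"mu_s", "mu_b_rel", "ratio", "aip"}:
            raise ValueError(f"unknown quantity {self.quantity!r}")


class NoSurfaceError(RuntimeError):
    """The A-line never crosses the surface-detection threshold."""


class FitWindowError(RuntimeError):
    """The usable fit window is too short or degenerate."""


def axial_pixel_size(total_depth_um: float = 1500.0,
                     spectrometer_pixels: int = 1024) -> float:
    """Axial voxel size implied by spectral-domain sampling.

    A spectrometer with N pixels yields N/2 usable axial pixels after the
    Fourier transform, so the voxel size is the total imaging depth divided
    by N/2 (1.5 mm over 512 pixels gives the nominal 2.9 um).
    """
    if total_depth_um <= 0 or spectrometer_pixels < 2:
        raise ValueError("need positive depth and >= 2 spectrometer pixels")
    return total_depth_um / (spectrometer_pixels // 2)


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def confocal_weight(z, zf: float, zrs: float):
    """Confocal axial weighting h(z) = 1 / (1 + ((z - zf)/zrs)^2).

    Unity at focus, 0.5 one Rayleigh range away, symmetric about ``zf``.
    """
    if zrs <= 0:
        raise ValueError("zrs must be positive")
    z = np.asarray(z, dtype=float)
    return 1.0 / (1.0 + ((z - zf) / zrs) ** 2)


def sensitivity_rolloff(z, config: SystemConfig):
    """Spectrometer sensitivity roll-off H(z), normalised to H(0) = 1.

    Modelled as ``exp(-z / rolloff_decay)``; identity when the config
    disables roll-off.  Monotone non-increasing in depth.
    """
    z = np.asarray(z, dtype=float)
    if config.rolloff_decay is None:
        return np.ones_like(z)
    return np.exp(-z / config.rolloff_decay)


def model_profile(mu_s: float, mu_b_rel: float, z_grid, config: SystemConfig) -> ALineProfile:
    """Evaluate the forward model R(z) on ``z_grid`` (um).

    ``mu_s`` is in mm^-1; the Beer-Lambert term is exp(-2 mu_s z) with z
    converted to mm once here.
    """
    if mu_s < 0 or mu_b_rel < 0:
        raise ValueError("mu_s and mu_b_rel must be nonnegative")
    z = np.asarray(z_grid, dtype=float)
    r = (mu_b_rel
         * np.exp(-2.0 * mu_s * z / UM_PER_MM)
         * confocal_weight(z, config.zf, config.zrs)
         * sensitivity_rolloff(z, config))
    return ALineProfile(r, z)


# ---------------------------------------------------------------------------
# Pre-processing
# ---------------------------------------------------------------------------

def block_average(volume: OCTVolume, block_lateral: float) -> OCTVolume:
    """Average A-lines over square lateral blocks before fitting.

    Reduces speckle: the mean of N unit-mean exponential draws has relative
    standard deviation 1/sqrt(N).  The output lateral pitch is
    ``n * lateral_spacing`` with ``n = floor(block_lateral / lateral_spacing)``;
    trailing partial blocks are dropped.
    """
    n = int(block_lateral // volume.lateral_spacing)
    if n < 1:
        raise ValueError("block_lateral smaller than one voxel")
    nx, ny, nz = volume.intensities.shape
    bx, by = nx // n, ny // n
    if bx == 0 or by == 0:
        raise ValueError("volume smaller than one block")
    v = volume.intensities[: bx * n, : by * n, :]
    v = v.reshape(bx, n, by, n, nz).mean(axis=(1, 3))
    return OCTVolume(v, volume.z_spacing, volume.lateral_spacing * n)


def detect_surface(profile: ALineProfile, threshold_frac: float = 0.2) -> int:
    """Index of the first sample exceeding ``threshold_frac`` of the maximum.

    The fit window is taken relative to this index so that fitting starts
    below the tissue surface.
    """
    r = profile.intensities
    if r.size == 0:
        raise NoSurfaceError("empty profile")
    peak = r.max()
    if peak <= 0:
        raise NoSurfaceError("profile has no positive intensity")
    idx = np.nonzero(r > threshold_frac * peak)[0]
    if idx.size == 0:  # threshold_frac >= 1
        raise NoSurfaceError("no sample exceeds the surface threshold")
    return int(idx[0])


def _fit_window(profile: ALineProfile, config: SystemConfig) -> np.ndarray:
    surf = detect_surface(profile, config.surface_threshold_frac)
    z0 = profile.z_grid[surf]
    zmin = z0 + config.fit_depth_min
    zmax = z0 + config.fit_depth_max
    sel = (profile.z_grid >= zmin) & (profile.z_grid <= zmax)
    if sel.sum() < 10:
        raise FitWindowError(
            f"only {int(sel.sum())} samples in the fit window; need >= 10")
    return sel


# ---------------------------------------------------------------------------
# Nonlinear least-squares estimation
# ---------------------------------------------------------------------------

def _log_linear_seed(z: np.ndarray, r: np.ndarray, config: SystemConfig):
    """Seed (mu_s, mu_b) from a log-linear regression of the windowed profile.

    ln R - ln h - ln H = ln mu_b - 2 mu_s z/1000 is linear in z; the slope
    and intercept give starting values, clipped into the optimiser bounds.
    """
    pos = r > 0
    if pos.sum() < 2:
        return 1.0, max(float(r.max()), 1e-6)
    zp, rp = z[pos], r[pos]
    y = (np.log(rp)
         - np.log(confocal_weight(zp, config.zf, config.zrs))
         - np.log(sensitivity_rolloff(zp, config)))
    slope, intercept = np.polyfit(zp, y, 1)
    mu_s0 = float(np.clip(-slope * UM_PER_MM / 2.0, 1e-3, MU_S_BOUNDS[1] - 1e-3))
    mu_b0 = float(np.clip(np.exp(intercept), 1e-9, None))
    return mu_s0, mu_b0


def fit_profile(profile: ALineProfile, config: SystemConfig,
                init: Optional[FitResult] = None) -> FitResult:
    """Estimate (mu_s, mu_b') for one A-line by trust-region least squares.

    The confocal parameters (zf, zrs) and the roll-off are fixed from the
    config; only the two optical properties are free.  Residuals are taken
    in the linear-intensity domain over the fit window.  Non-convergence is
    reported through the ``converged`` flag, never raised.
    """
    sel = _fit_window(profile, config)
    z = profile.z_grid[sel]
    r = profile.intensities[sel]
    if np.all(r <= 0):
        raise FitWindowError("profile is zero throughout the fit window")

    weight = confocal_weight(z, config.zf, config.zrs) * sensitivity_rolloff(z, config)
    z_mm = z / UM_PER_MM

    def residuals(p):
        return p[1] * np.exp(-2.0 * p[0] * z_mm) * weight - r

    def jac(p):
        e = np.exp(-2.0 * p[0] * z_mm) * weight
        return np.column_stack((-2.0 * z_mm * p[1] * e, e))

    if init is not None:
        x0 = (np.clip(init.mu_s, 1e-3, MU_S_BOUNDS[1] - 1e-3),
              max(init.mu_b_rel, 1e-9))
    else:
        x0 = _log_linear_seed(z, r, config)

    sol = least_squares(residuals, x0=x0, jac=jac, method="trf",
                        bounds=([MU_S_BOUNDS[0], 0.0], [MU_S_BOUNDS[1], np.inf]),
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    return FitResult(mu_s=float(sol.x[0]), mu_b_rel=float(sol.x[1]),
                     residual_rms=rms, converged=bool(sol.success),
                     n_iter=int(sol.nfev))


def calibrate_confocal(phantom_volume: OCTVolume, known_mu_s: float,
                       config: SystemConfig) -> tuple[float, float]:
    """Recover (zf, zrs) from a homogeneous phantom of known mu_s.

    All A-lines of the (laterally homogeneous) phantom are pooled into one
    mean profile; the forward model is then fitted with mu_s fixed at the
    phantom's known value, leaving the focus depth, Rayleigh range and a
    nuisance amplitude free.  Mirrors the Intralipid pre-calibration that
    fixes (zf, zrs) before tissue fitting.
    """
    if known_mu_s <= 0:
        raise ValueError("known_mu_s must be positive")
    mean_profile = ALineProfile(
        phantom_volume.intensities.mean(axis=(0, 1)), phantom_volume.z_grid)
    sel = _fit_window(mean_profile, config)
    z = mean_profile.z_grid[sel]
    r = mean_profile.intensities[sel]
    z_mm = z / UM_PER_MM
    beer = np.exp(-2.0 * known_mu_s * z_mm)

    def residuals(p):
        zf, zrs, mu_b = p
        h = 1.0 / (1.0 + ((z - zf) / zrs) ** 2)
        return mu_b * beer * h * sensitivity_rolloff(z, config) - r

    # peak of R / (Beer-Lambert * rolloff) seeds the focus depth
    corrected = r / (beer * sensitivity_rolloff(z, config))
    zf0 = float(z[np.argmax(corrected)])
    mu_b0 = float(corrected.max())
    sol = least_squares(residuals, x0=(zf0, 100.0, mu_b0), method="trf",
                        bounds=([z[0] - 500.0, 1.0, 0.0],
                                [z[-1] + 500.0, 5000.0, np.inf]),
                        xtol=1e-12, ftol=1e-12)
    return float(sol.x[0]), float(sol.x[1])


# ---------------------------------------------------------------------------
# Map-level operations
# ---------------------------------------------------------------------------

def fit_volume(volume: OCTVolume, config: SystemConfig,
               block_lateral: float = 30.0) -> tuple[OpticalPropertyMap, OpticalPropertyMap]:
    """Block-average then fit every A-line, producing mu_s and mu_b' maps.

    Pixels whose fit fails (no surface, short window, optimizer failure)
    are masked rather than aborting the whole map.
    """
    avg = block_average(volume, block_lateral)
    nx, ny, _ = avg.intensities.shape
    mu_s = np.full((nx, ny), np.nan)
    mu_b = np.full((nx, ny), np.nan)
    ok = np.zeros((nx, ny), dtype=bool)
    prev: Optional[FitResult] = None
    for ix in range(nx):
        for iy in range(ny):
            try:
                res = fit_profile(avg.profile(ix, iy), config, init=prev)
            except (NoSurfaceError, FitWindowError) as exc:
                logger.debug("pixel (%d, %d) skipped: %s", ix, iy, exc)
                prev = None
                continue
            mu_s[ix, iy] = res.mu_s
            mu_b[ix, iy] = res.mu_b_rel
            ok[ix, iy] = res.converged
            prev = res if res.converged else None
    pitch = avg.lateral_spacing
    return (OpticalPropertyMap(mu_s, "mu_s", pitch, ok),
            OpticalPropertyMap(mu_b, "mu_b_rel", pitch, ok))


def compute_aip(volume: OCTVolume) -> OpticalPropertyMap:
    """Average intensity projection: per-pixel depth mean of the volume."""
    return OpticalPropertyMap(volume.intensities.mean(axis=2), "aip",
                              volume.lateral_spacing)


def compute_ratio_map(mu_b_map: OpticalPropertyMap, mu_s_map: OpticalPropertyMap,
                      floor: float = 0.1) -> OpticalPropertyMap:
    """Elementwise mu_b'/mu_s, masked where mu_s <= floor or either input is masked."""
    if mu_b_map.values.shape != mu_s_map.values.shape:
        raise ValueError("maps must share a grid")
    if mu_b_map.pixel_pitch != mu_s_map.pixel_pitch:
        raise ValueError("maps must share a pixel pitch")
    valid = mu_b_map.mask & mu_s_map.mask & (mu_s_map.values > floor)
    vals = np.full_like(mu_s_map.values, np.nan)
    np.divide(mu_b_map.values, mu_s_map.values, out=vals, where=valid)
    return OpticalPropertyMap(vals, "ratio", mu_s_map.pixel_pitch, valid)


def calibrated_config(config: SystemConfig, zf: float, zrs: float) -> SystemConfig:
    """Return a copy of ``config`` with the calibrated confocal parameters."""
    return replace(config, zf=zf, zrs=zrs)
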