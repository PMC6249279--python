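"""2D SMLM data-frame model: pixel-integrated Gaussian PSF plus noise.

An activated emitter emits a Poisson-distributed number of photons per
frame with mean ``mean_photons`` (I*eta*dt); each detected photon lands
in a pixel with probability given by the product of 1D Gaussian
integrals of the PSF over the pixel's x and y extent.  The camera adds a
uniform Poisson background and white Gaussian read noise, parameterized
as signal-to-noise-density ratios with units um^2 per emitter:

    background mean / pixel   = mean_photons * pixel_area_um2 / SPNR
    Gaussian variance / pixel = mean_photons * pixel_area_um2 / SGNR

Defaults reproduce a high-NA visible-light setup: sigma = 78.26 nm PSF
standard deviation (FWHM = 2*sqrt(2 ln 2)*sigma = 184.28 nm), 3000
detected photons per activated emitter per frame, a 2048x2048 nm field
on a 16x16 grid of 128 nm pixels, SPNR = 0.2 and SGNR = 0.3 um^2.

``helix_phantom`` builds the standard test structure: emitters equally
spaced along a planar spiral, a shape whose local curvature exercises
both well-separated and heavily overlapping PSF configurations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .pointset import PointSet

__all__ = [
    "FrameModel",
    "Frame",
    "fwhm_from_sigma",
    "psf_pixel_fraction",
    "pixel_fractions",
    "expected_frame",
    "sample_frame",
    "helix_phantom",
]


@dataclass(frozen=True)
class FrameModel:
    """Optics, noise, and pixel-grid parameters of the frame model.

    ``spnr``/``sgnr`` may be ``inf`` to switch the corresponding noise
    source off entirely.
    """

    sigma: float = 78.26                  # PSF std dev, nm
    mean_photons: float = 3000.0          # detected photons / emitter / frame
    spnr: float = 0.2                     # signal-to-Poisson-noise ratio, um^2
    sgnr: float = 0.3                     # signal-to-Gaussian-noise ratio, um^2
    frame_nm: tuple[float, float] = (2048.0, 2048.0)
    pixel_nm: tuple[float, float] = (128.0, 128.0)

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if not self.mean_photons > 0:
            raise ValueError("mean_photons must be positive")
        for L, d in zip(self.frame_nm, self.pixel_nm):
            if not (L > 0 and d > 0):
                raise ValueError("frame and pixel sizes must be positive")
            if abs(L / d - round(L / d)) > 1e-9:
                raise ValueError(f"pixel size {d} does not tile frame size {L}")

    @property
    def n_pixels(self) -> tuple[int, int]:
        """(K_x, K_y) pixel counts."""
        return (
            int(round(self.frame_nm[0] / self.pixel_nm[0])),
            int(round(self.frame_nm[1] / self.pixel_nm[1])),
        )

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_nm[0] * self.pixel_nm[1] * 1e-6

    @property
    def fwhm(self) -> float:
        return fwhm_from_sigma(self.sigma)

    def poisson_background(self) -> float:
        """Uniform Poisson background mean per pixel (photons)."""
        return 0.0 if math.isinf(self.spnr) else self.mean_photons * self.pixel_area_um2 / self.spnr

    def gaussian_noise_var(self) -> float:
        """Gaussian read-noise variance per pixel (photons^2)."""
        return 0.0 if math.isinf(self.sgnr) else self.mean_photons * self.pixel_area_um2 / self.sgnr

    def pixel_edges(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel boundary coordinates along x and y (nm, length K+1)."""
        kx, ky = self.n_pixels
        return (
            np.linspace(0.0, self.frame_nm[0], kx + 1),
            np.linspace(0.0, self.frame_nm[1], ky + 1),
        )


@dataclass(frozen=True)
class Frame:
    """One simulated camera frame and the emitters that generated it.

    ``counts`` is a (K_y, K_x) array indexed [row = y pixel, col = x
    pixel]; values are real (Gaussian read noise makes them
    non-integer).
    """

    counts: np.ndarray
    active_truth: PointSet

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("frame contains non-finite counts")


def fwhm_from_sigma(sigma: float) -> float:
    """Full width at half maximum of a Gaussian: 2*sqrt(2 ln 2)*sigma."""
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    return 2.0 * math.sqrt(2.0 * math.log(2.0)) * sigma


def _axis_fractions(pos: np.ndarray, edges: np.ndarray, sigma: float) -> np.ndarray:
    """1D Gaussian integrals over pixel intervals: (n_emitters, n_pixels)."""
    z = (edges[None, :] - pos[:, None]) / sigma
    cdf = ndtr(z)
    return cdf[:, 1:] - cdf[:, :-1]


def pixel_fractions(emitters: np.ndarray, model: FrameModel) -> np.ndarray:
    """Photon-landing probability per pixel for each emitter.

    Returns an (n_emitters, K_y, K_x) array; entry [k, j, i] is the
    probability that a photon detected from emitter k lands in the pixel
    covering [i*dx, (i+1)*dx) x [j*dy, (j+1)*dy).  Rows integrate the
    PSF exactly over the pixel (error-function differences) rather than
    sampling its center, which matters when pixels are comparable to
    sigma.
    """
    emitters = np.atleast_2d(np.asarray(emitters, dtype=float))
    ex, ey = model.pixel_edges()
    fx = _axis_fractions(emitters[:, 0], ex, model.sigma)  # (K_em, Kx)
    fy = _axis_fractions(emitters[:, 1], ey, model.sigma)  # (K_em, Ky)
    return fy[:, :, None] * fx[:, None, :]


def psf_pixel_fraction(emitter, pixel_index: tuple[int, int], model: FrameModel) -> float:
    """Probability that a photon from ``emitter`` lands in pixel (i, j).

    ``pixel_index`` is (i, j) with i the x index and j the y index,
    0-based; pixel (i, j) covers [i*dx, (i+1)*dx) x [j*dy, (j+1)*dy).
    """
    i, j = pixel_index
    kx, ky = model.n_pixels
    if not (0 <= i < kx and 0 <= j < ky):
        raise IndexError(f"pixel index {pixel_index} outside {kx}x{ky} grid")
    frac = pixel_fractions(np.asarray(emitter, dtype=float)[None, :], model)
    return float(frac[0, j, i])


def expected_frame(active: PointSet | np.ndarray, model: FrameModel) -> np.ndarray:
    """Mean photon count per pixel for a set of activated emitters.

    Superposition of per-emitter PSF integrals scaled by the mean photon
    budget, plus the uniform Poisson background.  An empty active set
    yields the pure background frame.
    """
    kx, ky = model.n_pixels
    mu = np.full((ky, kx), model.poisson_background())
    coords = active.coords if isinstance(active, PointSet) else np.atleast_2d(active)
    if len(coords):
        mu += model.mean_photons * pixel_fractions(coords, model).sum(axis=0)
    return mu


def sample_frame(mu: np.ndarray, model: FrameModel, rng) -> np.ndarray:
    """Draw one noisy frame: Poisson(mu) + N(0, read-noise variance).

    Pixels are mutually independent; ``rng`` is a numpy Generator (or a
    seed for one).
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise ValueError("expected counts must be non-negative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    counts = rng.poisson(mu).astype(float)
    v_g = model.gaussian_noise_var()
    if v_g > 0:
        counts += rng.normal(0.0, math.sqrt(v_g), size=mu.shape)
    return counts


def helix_phantom(
    n_emitters: int = 250,
    spacing: float = 25.0,
    model: FrameModel | None = None,
    inner_radius: float = 200.0,
    turn_separation: float = 120.0,
) -> PointSet:
    """Emitters equally spaced along a planar spiral centred in the frame.

    The curve is an Archimedean spiral r = inner_radius + c*phi with c
    set by ``turn_separation`` (radial gap between successive turns).
    Points are placed at equal arc length ``spacing``; because the local
    curvature radius is >= ``inner_radius`` >> spacing, consecutive
    Euclidean gaps match the arc spacing to well under 1%.

    Raises if the spiral outgrows the frame.
    """
    if not spacing > 0:
        raise ValueError("spacing must be positive")
    if n_emitters < 1:
        raise ValueError("need at least one emitter")
    model = model or FrameModel()
    c = turn_separation / (2.0 * math.pi)
    total_arc = spacing * (n_emitters - 1)

    # arc length s(phi) = int sqrt(r^2 + c^2) dphi on a fine grid
    # generous phi range, then invert numerically
    phi_max = 2.0 * (math.sqrt(inner_radius**2 + 2 * c * total_arc) - inner_radius) / max(c, 1e-12) + 1.0
    phi_grid = np.linspace(0.0, phi_max, max(2000, 200 * n_emitters))
    r_grid = inner_radius + c * phi_grid
    ds = np.sqrt(r_grid**2 + c**2)
    s_grid = np.concatenate(([0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(phi_grid))))
    if s_grid[-1] < total_arc:
        raise ValueError("internal: spiral grid too short")
    phi = np.interp(np.arange(n_emitters) * spacing, s_grid, phi_grid)
    r = inner_radius + c * phi
    cx, cy = model.frame_nm[0] / 2.0, model.frame_nm[1] / 2.0
    pts = np.column_stack((cx + r * np.cos(phi), cy + r * np.sin(phi)))
    if (
        pts[:, 0].min() < 0 or pts[:, 1].min() < 0
        or pts[:, 0].max() > model.frame_nm[0] or pts[:, 1].max() > model.frame_nm[1]
    ):
        raise ValueError(
            f"helix phantom (max radius {r.max():.0f} nm) exceeds the "
            f"{model.frame_nm[0]:.0f}x{model.frame_nm[1]:.0f} nm frame"
        )
    return PointSet(pts)
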