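"""Fisher information, CRLB, and the information-achieving estimator.

For K activated emitters with coordinates theta = (x1, y1, ..., xK, yK)
the per-pixel expected count is mu(theta) (see :mod:`rmsmd.frames`).
With Poisson signal+background and additive Gaussian read noise of
variance v_g, the Fisher information matrix is approximated by the
variance-inflated Poisson form

    F = sum_pixels (d mu / d theta)(d mu / d theta)^T / (mu + v_g),

the Gaussian-approximation bound: exact mixed Poisson+Gaussian
information has no closed form, and the (mu + v_g) denominator reduces
to the pure-Poisson information as v_g -> 0.  The derivatives of the
pixel-integrated Gaussian PSF are closed-form (differences of Gaussian
densities at pixel edges).  The diagonal of F^{-1} is the CRLB: the
minimum variance any unbiased localization estimator can achieve.

The "information-achieving" estimator draws

    theta_hat = theta + U Lambda^{1/2} g,      g ~ N(0, I),

with F^{-1} = U Lambda U^T, i.e. theta_hat ~ N(theta, F^{-1}): an
unbiased Gaussian estimator whose covariance is exactly the inverse
Fisher information.  It bypasses fitting entirely and benchmarks the
best image any unbiased frame-by-frame localization algorithm could
produce.

The coverage-0.95 error ellipse of one emitter's estimate is the
Mahalanobis ball (theta_hat_i - theta_i)^T F_i (theta_hat_i - theta_i)
<= R^2 with R = sqrt(-2 ln 0.05) ~= 2.448 in 2D (Rayleigh quantile).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr
from scipy.stats import chi2

from .frames import FrameModel
from .pointset import PointSet

__all__ = [
    "FisherResult",
    "ProbabilityEllipse",
    "IllConditionedError",
    "fisher_matrix",
    "mu_and_gradient",
    "info_achieving_estimate",
    "probability_ellipse",
    "coverage_radius",
]

# Error out only where double precision genuinely gives out; heavily
# overlapping emitters legitimately produce very large but finite CRLBs.
_COND_LIMIT = 1e15
_NORM_CONST = 1.0 / math.sqrt(2.0 * math.pi)


class IllConditionedError(np.linalg.LinAlgError):
    """Fisher matrix numerically singular (e.g. coincident emitters)."""

    def __init__(self, cond: float):
        self.cond = cond
        super().__init__(
            f"Fisher matrix is ill-conditioned (condition number {cond:.3e}); "
            "emitters may coincide"
        )


@dataclass(frozen=True)
class FisherResult:
    """Fisher matrix of one frame's activated-emitter coordinates.

    ``crlb`` is the diagonal of ``finv`` in nm^2, ordered
    (x1, y1, ..., xK, yK); ``eig_vecs``/``eig_vals`` give the
    eigendecomposition finv = U diag(eig_vals) U^T used by the
    information-achieving estimator.
    """

    fisher: np.ndarray
    finv: np.ndarray
    crlb: np.ndarray
    eig_vecs: np.ndarray
    eig_vals: np.ndarray
    cond: float

    @property
    def n_emitters(self) -> int:
        return self.fisher.shape[0] // 2

    def block_inv(self, i: int) -> np.ndarray:
        """The i-th 2x2 diagonal block of F^{-1} (one emitter's covariance)."""
        return self.finv[2 * i : 2 * i + 2, 2 * i : 2 * i + 2]


@dataclass(frozen=True)
class ProbabilityEllipse:
    """Coverage ellipse of a single emitter's estimate.

    Boundary: center + R * U diag(sqrt(lam)) q over unit vectors q.
    """

    center: np.ndarray
    eig_vecs: np.ndarray
    eig_vals: np.ndarray
    radius: float      # the scalar R
    coverage: float

    @property
    def semi_axes(self) -> np.ndarray:
        """Semi-axis lengths R*sqrt(lam) (nm), descending."""
        return self.radius * np.sqrt(np.sort(self.eig_vals)[::-1])

    def boundary(self, n: int = 256) -> np.ndarray:
        """(n, 2) points on the ellipse boundary."""
        t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
        q = np.column_stack((np.cos(t), np.sin(t)))
        return self.center + self.radius * (q * np.sqrt(self.eig_vals)) @ self.eig_vecs.T

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Whether each 2D point lies inside (Mahalanobis <= R)."""
        d = np.atleast_2d(points) - self.center
        v = (d @ self.eig_vecs) / np.sqrt(self.eig_vals)
        return (v**2).sum(axis=1) <= self.radius**2


def _axis_cdf_and_pdf(pos: np.ndarray, edges: np.ndarray, sigma: float):
    z = (edges[None, :] - pos[:, None]) / sigma
    cdf = ndtr(z)
    pdf = _NORM_CONST * np.exp(-0.5 * z**2)
    frac = cdf[:, 1:] - cdf[:, :-1]
    # d frac / d emitter coordinate = (pdf(left) - pdf(right)) / sigma
    dfrac = (pdf[:, :-1] - pdf[:, 1:]) / sigma
    return frac, dfrac


def mu_and_gradient(active: np.ndarray, model: FrameModel):
    """Expected frame mu and its gradient w.r.t. emitter coordinates.

    Returns ``(mu, grad)`` with mu of shape (K_y, K_x) and grad of shape
    (2K, K_y, K_x) ordered (x1, y1, ..., xK, yK).  Gradients are
    analytic (Gaussian-density differences at pixel edges).
    """
    active = np.atleast_2d(np.asarray(active, dtype=float))
    k = active.shape[0]
    ex, ey = model.pixel_edges()
    fx, dfx = _axis_cdf_and_pdf(active[:, 0], ex, model.sigma)
    fy, dfy = _axis_cdf_and_pdf(active[:, 1], ey, model.sigma)
    kx, ky = model.n_pixels
    mu = np.full((ky, kx), model.poisson_background())
    mu += model.mean_photons * np.einsum("kj,ki->ji", fy, fx)
    grad = np.empty((2 * k, ky, kx))
    for i in range(k):
        grad[2 * i] = model.mean_photons * fy[i][:, None] * dfx[i][None, :]
        grad[2 * i + 1] = model.mean_photons * dfy[i][:, None] * fx[i][None, :]
    return mu, grad


def fisher_matrix(active: PointSet | np.ndarray, model: FrameModel) -> FisherResult:
    """Fisher information of the activated-emitter coordinates in a frame.

    Raises :class:`IllConditionedError` when the matrix is numerically
    singular (condition number above 1e12), which happens for
    (near-)coincident emitters.
    """
    coords = active.coords if isinstance(active, PointSet) else np.atleast_2d(active)
    if len(coords) < 1:
        raise ValueError("need at least one activated emitter")
    mu, grad = mu_and_gradient(coords, model)
    denom = mu + model.gaussian_noise_var()
    g = grad.reshape(grad.shape[0], -1)
    d = denom.reshape(-1)
    ok = d > 0  # pixels with zero mean and zero noise carry no information
    fisher = (g[:, ok] / d[ok]) @ g[:, ok].T
    fisher = 0.5 * (fisher + fisher.T)

    # invert through the symmetric eigendecomposition: F = V diag(w) V^T,
    # F^{-1} = V diag(1/w) V^T, which keeps the inverse symmetric PSD
    w, vecs = np.linalg.eigh(fisher)
    if w[-1] <= 0 or w[0] <= 0:
        raise IllConditionedError(float("inf"))
    cond = float(w[-1] / w[0])
    if cond > _COND_LIMIT:
        raise IllConditionedError(cond)
    inv_w = 1.0 / w
    finv = (vecs * inv_w) @ vecs.T
    finv = 0.5 * (finv + finv.T)
    return FisherResult(
        fisher=fisher,
        finv=finv,
        crlb=np.diag(finv).copy(),
        eig_vecs=vecs,
        eig_vals=inv_w,
        cond=cond,
    )


def info_achieving_estimate(theta: np.ndarray, fr: FisherResult, rng) -> np.ndarray:
    """One draw of the unbiased information-achieving estimator.

    ``theta`` is the flat (2K,) truth vector (or a (K, 2) array, which
    is flattened); the return has the same shape as the input.
    Estimates may land outside the frame; they are not clipped.
    """
    theta = np.asarray(theta, dtype=float)
    flat = theta.reshape(-1)
    if flat.shape[0] != fr.fisher.shape[0]:
        raise ValueError(
            f"theta has {flat.shape[0]} coordinates, Fisher matrix is "
            f"{fr.fisher.shape[0]}x{fr.fisher.shape[0]}"
        )
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    g = rng.standard_normal(flat.shape[0])
    est = flat + fr.eig_vecs @ (np.sqrt(fr.eig_vals) * g)
    return est.reshape(theta.shape)


def coverage_radius(coverage: float = 0.95, dim: int = 2) -> float:
    """Mahalanobis radius R with Pr(||v|| <= R) = coverage, v ~ N(0, I).

    In 2D this is the Rayleigh quantile sqrt(-2 ln(1 - coverage)),
    about 2.448 at 95%.
    """
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    return float(math.sqrt(chi2.ppf(coverage, dim)))


def probability_ellipse(
    center: np.ndarray, cov: np.ndarray, coverage: float = 0.95
) -> ProbabilityEllipse:
    """Coverage ellipse of a bivariate Gaussian estimate.

    ``cov`` is the emitter's 2x2 covariance block of F^{-1}; must be
    symmetric positive definite.
    """
    center = np.asarray(center, dtype=float).reshape(2)
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (2, 2) or not np.allclose(cov, cov.T, rtol=1e-8, atol=0):
        raise ValueError("covariance must be a symmetric 2x2 matrix")
    vals, vecs = np.linalg.eigh(cov)
    if np.any(vals <= 0):
        raise ValueError(f"covariance not positive definite (eigenvalues {vals})")
    return ProbabilityEllipse(
        center=center,
        eig_vecs=vecs,
        eig_vals=vals,
        radius=coverage_radius(coverage, 2),
        coverage=coverage,
    )
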