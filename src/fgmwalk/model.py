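"""Model core for Fisher's geometric model with a linearly moving optimum.

The model is parameterized by the number of traits ``n``, the shape of the
Gaussian fitness landscape ``Sigma`` (an n-by-n positive-definite matrix), the
covariance ``M`` of the multivariate-normal distribution of new mutational
effects, the velocity ``v`` of the optimum (one step per generation), and the
population-wide mutation supply ``Theta``.

Fitness follows the half-quadratic Gaussian convention

    w(z, t) = exp(-1/2 (z - v t)' Sigma^-1 (z - v t)),

with the optimum starting at the origin at t = 0.  Because the landscape is
Gaussian, the *log*-fitness difference between a mutant and the wild type is
exactly linear in time, which is what makes the moving-optimum analysis
tractable: a mutant that is deleterious today may become beneficial once the
optimum has receded far enough (its "lag time").
"""

from __future__ import annotations

import dataclasses
import math
from typing import Tuple

import numpy as np

__all__ = [
    "ModelSpecError",
    "ModelSpec",
    "DerivedScales",
    "LinearSelection",
    "correlated_matrix",
    "as_phenotype",
    "fitness",
    "log_fitness",
    "selection_coefficient",
    "linearize_selection",
    "fixation_probability",
    "gamma",
    "isotropize",
]

#: Relative eigenvalue floor below which Sigma / M are rejected as singular.
EIGENVALUE_FLOOR = 1e-12


class ModelSpecError(ValueError):
    """Raised when a model parameterization violates its invariants."""


def correlated_matrix(n: int, variance: float, rho: float) -> np.ndarray:
    """Equicorrelated covariance matrix: ``variance`` on the diagonal and
    ``rho * variance`` off-diagonal.

    Positive definiteness requires ``-1/(n-1) < rho < 1``; values outside
    that open interval are rejected.
    """
    if n < 1:
        raise ModelSpecError(f"n must be >= 1, got {n}")
    if variance <= 0:
        raise ModelSpecError(f"variance must be positive, got {variance}")
    lo = -1.0 / (n - 1) if n > 1 else -1.0
    if n > 1 and not (lo < rho < 1.0):
        raise ModelSpecError(
            f"rho={rho} outside the positive-definite range ({lo}, 1) for n={n}"
        )
    out = np.full((n, n), rho * variance)
    np.fill_diagonal(out, variance)
    return out


def _validate_pd(mat: np.ndarray, name: str, n: int) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (n, n):
        raise ModelSpecError(f"{name} must be {n}x{n}, got shape {mat.shape}")
    if not np.all(np.isfinite(mat)):
        raise ModelSpecError(f"{name} contains non-finite entries")
    if not np.allclose(mat, mat.T, rtol=0, atol=1e-10 * max(1.0, np.abs(mat).max())):
        raise ModelSpecError(f"{name} is not symmetric")
    mat = 0.5 * (mat + mat.T)
    w = np.linalg.eigvalsh(mat)
    if w[0] <= EIGENVALUE_FLOOR * w[-1] or w[0] <= 0:
        raise ModelSpecError(
            f"{name} is not positive definite (smallest eigenvalue {w[0]:.3e})"
        )
    return mat


class ModelSpec:
    """Full parameterization of the moving-optimum model.

    Parameters
    ----------
    n : int
        Number of traits (degree of pleiotropy).
    Sigma : (n, n) array_like
        Positive-definite shape of the Gaussian fitness landscape.
    M : (n, n) array_like
        Positive-definite mutational covariance.
    v : (n,) array_like
        Velocity of the optimum per generation (may be the zero vector).
    theta : float
        Population-wide mutation supply; new mutations arrive at rate theta/2.
    """

    __slots__ = ("n", "Sigma", "M", "v", "theta", "_Sigma_inv", "_M_chol")

    def __init__(self, n, Sigma, M, v, theta):
        n = int(n)
        if n < 1:
            raise ModelSpecError(f"n must be >= 1, got {n}")
        self.n = n
        self.Sigma = _validate_pd(Sigma, "Sigma", n)
        self.M = _validate_pd(M, "M", n)
        v = np.asarray(v, dtype=float).reshape(-1)
        if v.shape != (n,):
            raise ModelSpecError(f"v must have length {n}, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ModelSpecError("v contains non-finite entries")
        self.v = v
        theta = float(theta)
        if not (theta > 0) or not math.isfinite(theta):
            raise ModelSpecError(f"theta must be a positive real, got {theta}")
        self.theta = theta
        self._Sigma_inv = np.linalg.inv(self.Sigma)
        self._M_chol = np.linalg.cholesky(self.M)
        for a in ("Sigma", "M", "v"):
            getattr(self, a).setflags(write=False)

    # -- convenience constructors -------------------------------------------------

    @classmethod
    def from_params(
        cls,
        n: int,
        sigma_sq: float,
        m_sq: float = 1.0,
        rho_sigma: float = 0.0,
        rho_m: float = 0.0,
        v1: float | None = None,
        v=None,
        theta: float = 1.0,
    ) -> "ModelSpec":
        """Build a model from the equicorrelated (sigma^2, rho) parameterization.

        Either ``v1`` (optimum moving along the first trait axis) or a full
        velocity vector ``v`` must be given.
        """
        if (v1 is None) == (v is None):
            raise ModelSpecError("exactly one of v1 or v must be given")
        if v is None:
            v = np.zeros(n)
            v[0] = v1
        return cls(
            n,
            correlated_matrix(n, sigma_sq, rho_sigma),
            correlated_matrix(n, m_sq, rho_m),
            v,
            theta,
        )

    # -- derived quantities -------------------------------------------------------

    @property
    def Sigma_inv(self) -> np.ndarray:
        return self._Sigma_inv

    @property
    def M_chol(self) -> np.ndarray:
        """Lower-triangular Cholesky factor of M (used by the walk engine)."""
        return self._M_chol

    @property
    def delta_bar_sq(self) -> float:
        """Geometric mean of the eigenvalues of Sigma (mean landscape width)."""
        sign, logdet = np.linalg.slogdet(self.Sigma)
        return float(np.exp(logdet / self.n))

    @property
    def m_bar_sq(self) -> float:
        """Geometric mean of the eigenvalues of M (mean mutational variance)."""
        sign, logdet = np.linalg.slogdet(self.M)
        return float(np.exp(logdet / self.n))

    def derived_scales(self) -> "DerivedScales":
        return DerivedScales(self.delta_bar_sq, self.m_bar_sq, gamma(self))

    def optimum(self, t: float) -> np.ndarray:
        return self.v * t

    def is_canonical(self, rtol: float = 1e-9) -> bool:
        """True if Sigma is isotropic, m_bar^2 = 1 and v lies along +e1."""
        sig = self.Sigma
        iso = np.allclose(sig, sig[0, 0] * np.eye(self.n), rtol=rtol,
                          atol=rtol * abs(sig[0, 0]))
        mbar = abs(self.m_bar_sq - 1.0) <= 1e-9
        v_ok = self.v[0] >= 0 and (self.n == 1 or
                                   np.allclose(self.v[1:], 0, atol=1e-12 * max(1.0, abs(self.v[0]))))
        return bool(iso and mbar and v_ok)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "sigma_matrix": self.Sigma.tolist(),
            "m_matrix": self.M.tolist(),
            "v": self.v.tolist(),
            "theta": self.theta,
        }

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"ModelSpec(n={self.n}, theta={self.theta}, "
                f"delta_bar_sq={self.delta_bar_sq:.4g}, m_bar_sq={self.m_bar_sq:.4g}, "
                f"gamma={gamma(self):.4g})")


@dataclasses.dataclass(frozen=True)
class DerivedScales:
    """Scalar summaries of a model: landscape width, mutational scale, and the
    scaled rate of environmental change gamma."""

    delta_bar_sq: float
    m_bar_sq: float
    gamma: float


@dataclasses.dataclass(frozen=True)
class LinearSelection:
    """Linear-in-time description of a mutant's selection coefficient.

    ``s_linear(t) = lam * (t - tau)`` equals the log-fitness difference
    ln w(x,t) - ln w(y,t) exactly for the Gaussian landscape.  ``tau`` is the
    lag time at which the mutant becomes neutral; when ``lam == 0`` the
    selection coefficient never changes sign and ``tau`` is set to the +inf
    sentinel with ``tau_infinite`` flagged.
    """

    lam: float
    tau: float
    s0: float
    tau_infinite: bool = False

    def s_linear(self, t):
        if self.tau_infinite:
            return np.broadcast_to(np.asarray(self.s0, dtype=float),
                                   np.shape(t)).copy() if np.ndim(t) else self.s0
        return self.lam * (np.asarray(t, dtype=float) - self.tau)


def as_phenotype(z, n: int) -> np.ndarray:
    """Validate and return a phenotype vector of length n."""
    z = np.asarray(z, dtype=float).reshape(-1)
    if z.shape != (n,):
        raise ModelSpecError(f"phenotype must have length {n}, got {z.shape}")
    if not np.all(np.isfinite(z)):
        raise ModelSpecError("phenotype contains non-finite entries")
    return z


def log_fitness(z, t: float, model: ModelSpec) -> float:
    """ln w(z, t) = -1/2 (z - v t)' Sigma^-1 (z - v t)."""
    z = as_phenotype(z, model.n)
    if not math.isfinite(t):
        raise ModelSpecError(f"time must be finite, got {t}")
    d = z - model.v * t
    return float(-0.5 * d @ model.Sigma_inv @ d)


def fitness(z, t: float, model: ModelSpec) -> float:
    """Gaussian stabilizing-selection fitness against the moving optimum.

    Returns a value in (0, 1]; equals 1 exactly at the optimum z = v t.
    """
    return math.exp(log_fitness(z, t, model))


def selection_coefficient(x, y, t: float, model: ModelSpec) -> float:
    """Exact selection coefficient s = w(x,t)/w(y,t) - 1 of mutant x against
    wild type y at time t.  Always > -1."""
    return math.expm1(log_fitness(x, t, model) - log_fitness(y, t, model))


def linearize_selection(x, y, model: ModelSpec) -> LinearSelection:
    """Linear-in-time selection coefficient of mutant x against wild type y.

    For the Gaussian landscape the log-fitness difference is *exactly*
    ``lam * (t - tau)`` with ``lam = v' Sigma^-1 (x - y)`` and
    ``tau = (x' Sigma^-1 x - y' Sigma^-1 y) / (2 lam)``; the quadratic time
    terms cancel.  It agrees with the exact selection coefficient to first
    order whenever |s| is small.
    """
    x = as_phenotype(x, model.n)
    y = as_phenotype(y, model.n)
    Si = model.Sigma_inv
    lam = float(model.v @ Si @ (x - y))
    quad = float(x @ Si @ x - y @ Si @ y)
    if lam == 0.0:
        # s never crosses zero; the constant offset is -quad/2
        return LinearSelection(lam=0.0, tau=math.inf, s0=-0.5 * quad,
                               tau_infinite=True)
    tau = quad / (2.0 * lam)
    return LinearSelection(lam=lam, tau=tau, s0=-lam * tau)


def fixation_probability(s, mode: str = "linear"):
    """Fixation probability of a beneficial mutant with selection coefficient s.

    mode="linear": clamp(2s, 0, 1) (Haldane's 2s, clamped to remain a
    probability); mode="exp": max(0, 1 - exp(-2s)).  Both return 0 for s <= 0:
    chance fixation of deleterious mutations is neglected.
    """
    s = np.asarray(s, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ModelSpecError("selection coefficient must be finite")
    if mode == "linear":
        out = np.clip(2.0 * s, 0.0, 1.0)
    elif mode == "exp":
        out = np.maximum(0.0, -np.expm1(-2.0 * s))
    else:
        raise ModelSpecError(f"unknown fixation-probability mode {mode!r}")
    return float(out) if out.ndim == 0 else out


def _rotation_to_e1(u: np.ndarray) -> np.ndarray:
    """Proper rotation R (det +1) with R u = |u| e1.

    Built from the deterministic Householder reflection mapping u-hat to e1;
    since a reflection reverses orientation, the sign of the last axis is
    flipped to restore det +1 so that "above/below" the optimum's track keeps
    its meaning in canonical coordinates.
    """
    n = u.shape[0]
    norm = np.linalg.norm(u)
    e1 = np.zeros(n)
    e1[0] = 1.0
    if norm == 0.0:
        return np.eye(n)
    w = u / norm - e1
    wn = np.linalg.norm(w)
    if wn < 1e-15:
        return np.eye(n)
    w /= wn
    R = np.eye(n) - 2.0 * np.outer(w, w)
    if n >= 2:
        R[-1] *= -1.0  # undo the reflection's orientation reversal
    return R


def _sigma_inv_sqrt(model: ModelSpec) -> np.ndarray:
    w, U = np.linalg.eigh(model.Sigma)
    if w[0] <= EIGENVALUE_FLOOR * w[-1]:
        raise ModelSpecError("Sigma is numerically singular")
    return (U / np.sqrt(w)) @ U.T


def isotropize(model: ModelSpec) -> Tuple[ModelSpec, np.ndarray]:
    """Reduce a general model to canonical form: isotropic selection with
    width delta_bar^2 / m_bar^2, movement along the positive first axis, and a
    transformed mutational covariance with unit geometric-mean variance.

    Returns ``(canonical_model, T)`` where ``T = scale * R * Sigma^{-1/2}``
    maps phenotypes of the original model to canonical coordinates
    (``Sigma* = T Sigma T' = sigma*^2 I``, ``M* = T M T'``, ``v* = T v``).
    Fitness is exactly invariant: ``w*(T z, t) = w(z, t)``, hence so are
    selection coefficients and gamma.  If ``v = 0`` the rotation is the
    identity (the canonical direction is undefined but the model is still
    isotropic after the transform).
    """
    A = _sigma_inv_sqrt(model)
    vA = A @ model.v
    R = _rotation_to_e1(vA)
    scale = math.sqrt(model.delta_bar_sq / model.m_bar_sq)
    T = scale * (R @ A)
    M_star = T @ model.M @ T.T
    M_star = 0.5 * (M_star + M_star.T)
    v_star = T @ model.v
    # clean numerical dust off the rotated velocity: exactly along +e1
    v_clean = np.zeros(model.n)
    v_clean[0] = np.linalg.norm(v_star)
    sigma_star_sq = model.delta_bar_sq / model.m_bar_sq
    canon = ModelSpec(model.n, sigma_star_sq * np.eye(model.n), M_star,
                      v_clean, model.theta)
    return canon, T


def gamma(model: ModelSpec) -> float:
    """Scaled rate of environmental change.

    Defined in canonical coordinates as gamma = v1* sigma*^2 / (Theta m_bar*^3)
    with m_bar* = 1, which for an isotropic model with v along the first axis
    reduces to gamma = v1 sigma^2 / (Theta m_bar^3).  gamma is invariant under
    the isotropizing transform and under a common rescaling of all phenotypic
    units; it is zero iff v = 0.
    """
    if np.all(model.v == 0.0):
        return 0.0
    # closed form of the canonical quantities, avoiding the full transform:
    # v1* = |Sigma^{-1/2} v| * delta_bar / m_bar, sigma*^2 = delta_bar^2/m_bar^2
    A = _sigma_inv_sqrt(model)
    v1_star = np.linalg.norm(A @ model.v) * math.sqrt(
        model.delta_bar_sq / model.m_bar_sq)
    sigma_star_sq = model.delta_bar_sq / model.m_bar_sq
    return float(v1_star * sigma_star_sq / model.theta)
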