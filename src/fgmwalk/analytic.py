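"""Semi-analytic distribution of adaptive substitutions.

Starting from a wild type ``y`` at time 0, fixations form an inhomogeneous
Poisson process whose instantaneous rate integrates the product of the
mutational input Theta p(alpha)/2 and the fixation probability 2s over the
set of currently beneficial mutant phenotypes.  From that rate this module
computes

* ``substitution_rate``       -- g(t, y), the instantaneous fixation rate,
* ``WaitingTime``             -- the survival function F(t|y) = exp(-int g),
* ``conditional_step_density``-- psi(alpha | y, t), the step distribution
  given that a step happens at time t,
* ``step_distribution``       -- phi(alpha | y), the unconditional
  distribution of the next adaptive step, via two algebraically equivalent
  but numerically independent routes, and
* ``first_step_moments_uniform`` -- moments of the first step in the
  slow-change (environmentally limited) regime, where the Gaussian mutational
  density is flattened to a uniform density of the same height at the origin.

Throughout, the "linearized" selection coefficient is the log-fitness
difference, which is exactly linear in time for the Gaussian landscape:
``s_lin = (R^2 - |w|^2)/2`` where ``w = Sigma^(-1/2) (alpha - b)``,
``b = v t - y`` and ``R^2 = b' Sigma^-1 b``.  The beneficial set is then the
interior of the ellipsoid through the origin and 2b (a ball of radius |v|t
centered at v t in the isotropic case with y = 0).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Optional

import numpy as np
from scipy import integrate

from .model import ModelSpec, ModelSpecError, as_phenotype, linearize_selection

__all__ = [
    "UniformMutationApprox",
    "StepDistribution",
    "FirstStepMoments",
    "mutation_density_at_zero",
    "unit_ball_volume",
    "beneficial_set_indicator",
    "substitution_rate",
    "WaitingTime",
    "conditional_step_density",
    "phi_pointwise",
    "step_distribution",
    "first_step_moments_uniform",
    "canonical_model",
]


def unit_ball_volume(n: int) -> float:
    """Volume of the n-dimensional unit ball."""
    return math.pi ** (n / 2) / math.gamma(n / 2 + 1)


def mutation_density_at_zero(model: ModelSpec) -> float:
    """Density p0 of the Gaussian distribution of new mutations at alpha = 0."""
    sign, logdet = np.linalg.slogdet(model.M)
    return float((2 * math.pi) ** (-model.n / 2) * math.exp(-0.5 * logdet))


@dataclasses.dataclass(frozen=True)
class UniformMutationApprox:
    """Uniform (flat, improper) stand-in for the mutational density with the
    same height p0 at the origin; integrals against it run over the bounded
    beneficial set only, so all quantities stay finite."""

    p0: float

    @classmethod
    def for_model(cls, model: ModelSpec) -> "UniformMutationApprox":
        return cls(mutation_density_at_zero(model))


# ---------------------------------------------------------------------------
# beneficial-set geometry
# ---------------------------------------------------------------------------


class _Geometry:
    """Whitened coordinates of the beneficial ellipsoid at time t.

    alpha = b + C w with C = Sigma^(1/2); the linearized selection
    coefficient is (R^2 - |w|^2)/2 and the beneficial set is |w| < R.
    """

    def __init__(self, model: ModelSpec):
        w, U = np.linalg.eigh(model.Sigma)
        self.C = (U * np.sqrt(w)) @ U.T
        self.Cinv = (U / np.sqrt(w)) @ U.T
        self.detC = float(np.prod(np.sqrt(w)))
        self.model = model

    def center_radius(self, y: np.ndarray, t: float):
        b = self.model.v * t - y
        R = float(np.linalg.norm(self.Cinv @ b))
        return b, R


def _mvn_logpdf(alpha: np.ndarray, model: ModelSpec) -> np.ndarray:
    """Log-density of MVN(0, M) evaluated at rows of alpha."""
    sol = np.linalg.solve(model.M, alpha.T).T
    q = np.einsum("ij,ij->i", alpha, sol)
    sign, logdet = np.linalg.slogdet(model.M)
    return -0.5 * (q + logdet + model.n * math.log(2 * math.pi))


def beneficial_set_indicator(x, y, t: float, model: ModelSpec,
                             linearized: bool = True) -> bool:
    """True iff mutant x has strictly positive selection coefficient against
    wild type y at time t (linearized and exact s share the same sign)."""
    x = as_phenotype(x, model.n)
    y = as_phenotype(y, model.n)
    b = model.v * t - y
    d = x - y - b
    return bool(d @ model.Sigma_inv @ d < b @ model.Sigma_inv @ b)


# ---------------------------------------------------------------------------
# ball quadrature / Monte Carlo
# ---------------------------------------------------------------------------


def _ball_nodes(n: int, R: float, n_radial: int = 48, n_angular: int = 64):
    """Product quadrature nodes/weights for the ball |w| < R, n <= 3."""
    if R <= 0:
        return np.empty((0, n)), np.empty(0)
    xr, wr = np.polynomial.legendre.leggauss(n_radial)
    r = 0.5 * R * (xr + 1.0)
    wr = 0.5 * R * wr
    if n == 1:
        nodes = np.concatenate([-r, r])[:, None]
        weights = np.concatenate([wr, wr])
        return nodes, weights
    if n == 2:
        th = 2 * math.pi * np.arange(n_angular) / n_angular
        wth = np.full(n_angular, 2 * math.pi / n_angular)
        rr, tt = np.meshgrid(r, th, indexing="ij")
        nodes = np.stack([rr * np.cos(tt), rr * np.sin(tt)], axis=-1).reshape(-1, 2)
        weights = (np.outer(wr * r, wth)).reshape(-1)
        return nodes, weights
    if n == 3:
        xc, wc = np.polynomial.legendre.leggauss(max(16, n_radial // 2))
        th = 2 * math.pi * np.arange(n_angular) / n_angular
        wth = np.full(n_angular, 2 * math.pi / n_angular)
        rr, cc, tt = np.meshgrid(r, xc, th, indexing="ij")
        sin_phi = np.sqrt(1 - cc ** 2)
        nodes = np.stack(
            [rr * sin_phi * np.cos(tt), rr * sin_phi * np.sin(tt), rr * cc],
            axis=-1,
        ).reshape(-1, 3)
        weights = (
            wr[:, None, None] * rr ** 2 * wc[None, :, None] * wth[None, None, :]
        ).reshape(-1)
        return nodes, weights
    raise ModelSpecError("product quadrature only implemented for n <= 3")


def _ball_integral(model: ModelSpec, y, t: float, density: str,
                   exact_s: bool, method: str, rng=None, n_mc: int = 200_000,
                   moments: bool = False):
    """Integrate p(alpha) * s_+(alpha) (and optionally alpha-moments) over the
    beneficial set.  Returns (mass, mean, raw_second_moment) when
    ``moments=True``, else the scalar mass."""
    geo = _Geometry(model)
    y = as_phenotype(y, model.n)
    b, R = geo.center_radius(y, t)
    n = model.n
    if R <= 0:
        if moments:
            return 0.0, np.zeros(n), np.zeros((n, n))
        return 0.0

    if method == "quadrature" and n <= 3:
        w, wt = _ball_nodes(n, R)
        jac = geo.detC
    elif method in ("monte_carlo", "quadrature"):
        rng = np.random.default_rng(rng)
        u = rng.standard_normal((n_mc, n))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        radii = R * rng.random(n_mc) ** (1.0 / n)
        w = u * radii[:, None]
        vol = unit_ball_volume(n) * R ** n
        wt = np.full(n_mc, vol / n_mc)
        jac = geo.detC
    else:
        raise ModelSpecError(f"unknown integration method {method!r}")

    alphas = b[None, :] + w @ geo.C.T
    s = 0.5 * (R ** 2 - np.einsum("ij,ij->i", w, w))
    if exact_s:
        s = np.expm1(s)
    if density == "gaussian":
        p = np.exp(_mvn_logpdf(alphas, model))
    elif density == "uniform":
        p = np.full(alphas.shape[0], mutation_density_at_zero(model))
    else:
        raise ModelSpecError(f"unknown density {density!r}")
    f = p * s * wt * jac
    mass = float(f.sum())
    if not moments:
        return mass
    mean = (f[:, None] * alphas).sum(axis=0)
    second = (f[:, None, None] * alphas[:, :, None] * alphas[:, None, :]).sum(axis=0)
    return mass, mean, second


# ---------------------------------------------------------------------------
# substitution rate g(t, y)
# ---------------------------------------------------------------------------


def substitution_rate(
    t: float,
    y,
    model: ModelSpec,
    method: str = "quadrature",
    density: str = "gaussian",
    exact_s: bool = False,
    rng=None,
    n_mc: int = 200_000,
) -> float:
    """Instantaneous rate g(t, y) of substitutions of any kind at time t.

    ``method="uniform_closed_form"`` evaluates the exact slow-regime formula
    g(t) = Theta p0 V_n r^(n+2) / (sigma^2 (n+2)) with r = v1 t, and requires
    a canonical (isotropized) model with the wild type at the origin.
    """
    if t < 0:
        raise ModelSpecError("t must be >= 0")
    y = as_phenotype(y, model.n)
    if method == "uniform_closed_form":
        if not model.is_canonical():
            raise ModelSpecError(
                "uniform_closed_form requires a canonical model; isotropize first"
            )
        if np.any(y != 0):
            raise ModelSpecError("uniform_closed_form assumes y = 0")
        n = model.n
        sigma_sq = float(model.Sigma[0, 0])
        r = model.v[0] * t
        p0 = mutation_density_at_zero(model)
        return model.theta * p0 * unit_ball_volume(n) * r ** (n + 2) / (
            sigma_sq * (n + 2)
        )
    mass = _ball_integral(model, y, t, density, exact_s, method, rng=rng, n_mc=n_mc)
    return model.theta * mass


# ---------------------------------------------------------------------------
# waiting-time distribution
# ---------------------------------------------------------------------------


class WaitingTime:
    """Survival function F(t|y) = exp(-int_0^t g) of the time to the next
    substitution, precomputed on a time grid.

    The grid extends until F < ``tail`` (default 1e-10); ``survival`` and
    ``density`` interpolate the cumulative hazard (piecewise-cubic via
    Simpson-consistent trapezoids on a dense grid).
    """

    def __init__(self, y, model: ModelSpec, density: str = "gaussian",
                 grid_points: int = 2049, tail: float = 1e-10,
                 t_max: Optional[float] = None):
        self.model = model
        self.y = as_phenotype(y, model.n)
        self.density_kind = density
        # v = 0 with y at the optimum: nothing is ever beneficial, F == 1
        self._zero_hazard = (np.all(model.v == 0.0) and np.all(self.y == 0.0))
        if self._zero_hazard:
            self.t_max = 1.0
            self.t_grid = np.linspace(0.0, 1.0, 2)
            self.g_grid = np.zeros(2)
            self.H_grid = np.zeros(2)
            return
        if t_max is None:
            t_max = self._find_t_max(tail)
        self.t_max = t_max
        self.t_grid = np.linspace(0.0, t_max, grid_points)
        geo = _Geometry(model)
        g = np.array(
            [model.theta * _ball_integral(model, self.y, t, density, False,
                                          "quadrature")
             if model.n <= 3 else
             model.theta * _ball_integral(model, self.y, t, density, False,
                                          "monte_carlo", rng=0)
             for t in self.t_grid]
        )
        self.g_grid = g
        H = integrate.cumulative_trapezoid(g, self.t_grid, initial=0.0)
        self.H_grid = H
        if not np.all(np.isfinite(H)):
            raise ArithmeticError("cumulative hazard integration failed")

    def _find_t_max(self, tail: float) -> float:
        target = -math.log(tail)
        t = 1.0
        for _ in range(200):
            H = self._hazard_to(t)
            if H >= target:
                return t
            t *= 2.0
        raise ArithmeticError("failed to bracket the waiting-time tail")

    def _hazard_to(self, t: float) -> float:
        val, _ = integrate.quad(
            lambda s: self.model.theta * _ball_integral(
                self.model, self.y, s, self.density_kind, False,
                "quadrature" if self.model.n <= 3 else "monte_carlo", rng=0),
            0.0, t, limit=100)
        return val

    def hazard(self, t):
        return np.interp(t, self.t_grid, self.g_grid)

    def cumulative_hazard(self, t):
        return np.interp(t, self.t_grid, self.H_grid)

    def survival(self, t):
        """F(t|y): probability that no fixation has happened before t."""
        return np.exp(-self.cumulative_hazard(t))

    def density(self, t):
        """f(t|y) = g(t, y) F(t|y)."""
        return self.hazard(t) * self.survival(t)

    def median(self) -> float:
        target = math.log(2.0)
        if self.H_grid[-1] < target:
            return math.inf
        idx = int(np.searchsorted(self.H_grid, target))
        return float(np.interp(target, self.H_grid[idx - 1: idx + 1],
                               self.t_grid[idx - 1: idx + 1]))

    def mean(self) -> float:
        if self._zero_hazard:
            return math.inf
        return float(np.trapezoid(np.exp(-self.H_grid), self.t_grid))


# ---------------------------------------------------------------------------
# conditional and unconditional step distributions
# ---------------------------------------------------------------------------


def conditional_step_density(alpha, t: float, y, model: ModelSpec,
                             density: str = "gaussian",
                             g: Optional[float] = None) -> float:
    """psi(alpha | y, t): the step density given a step occurs at time t.

    Proportional to the mutational density weighted by the (linearized,
    positive-part) selection coefficient; zero outside the beneficial set.
    ``g`` may carry a precomputed substitution rate g(t, y) to avoid
    recomputing the normalization on repeated calls at the same t.
    """
    alpha = as_phenotype(alpha, model.n)
    y = as_phenotype(y, model.n)
    if g is None:
        g = substitution_rate(t, y, model, method="quadrature", density=density)
    if g <= 0:
        raise ModelSpecError(f"g(t={t}, y)=0: conditional density undefined")
    ls = linearize_selection(y + alpha, y, model)
    s = ls.s_linear(t)
    if s <= 0:
        return 0.0
    if density == "gaussian":
        p = math.exp(_mvn_logpdf(alpha[None, :], model)[0])
    else:
        p = mutation_density_at_zero(model)
    return model.theta * p * s / g


def phi_pointwise(alphas, y, model: ModelSpec, wt: WaitingTime,
                  route: str = "psi_f", density: str = "gaussian") -> np.ndarray:
    """Evaluate the unconditional step density phi(alpha | y) at given points.

    route="psi_f": integrate psi(alpha|y,t) f(t|y) over waiting times, with
    psi normalized numerically through g(t, y).
    route="lagtime": per-alpha lag-time form
    Theta p(alpha) int lam (t - tau)_+ F(t|y) dt, using the linear-in-time
    selection coefficient (lam, tau) of each alpha directly.

    The two routes are algebraically identical but follow independent numeric
    paths; their pointwise agreement is a consistency check of the machinery.
    """
    alphas = np.atleast_2d(np.asarray(alphas, dtype=float))
    y = as_phenotype(y, model.n)
    t = wt.t_grid
    Si = model.Sigma_inv
    lam = alphas @ (Si @ model.v)
    x = y[None, :] + alphas
    quad = np.einsum("ij,jk,ik->i", x, Si, x) - float(y @ Si @ y)
    # s_lin(t) = lam*t - quad/2 for every alpha (exact log-fitness difference)
    s_mat = lam[:, None] * t[None, :] - 0.5 * quad[:, None]
    s_pos = np.maximum(s_mat, 0.0)
    if density == "gaussian":
        p = np.exp(_mvn_logpdf(alphas, model))
    elif density == "uniform":
        p = np.full(alphas.shape[0], mutation_density_at_zero(model))
    else:
        raise ModelSpecError(f"unknown density {density!r}")

    if route == "psi_f":
        g = wt.g_grid
        F = np.exp(-wt.H_grid)
        with np.errstate(divide="ignore", invalid="ignore"):
            psi = np.where(g[None, :] > 0,
                           model.theta * p[:, None] * s_pos / g[None, :], 0.0)
        integrand = psi * (g * F)[None, :]
        return np.trapezoid(integrand, t, axis=1)
    if route == "lagtime":
        F = np.exp(-wt.H_grid)
        integrand = s_pos * F[None, :]
        return model.theta * p * np.trapezoid(integrand, t, axis=1)
    raise ModelSpecError(f"unknown route {route!r}")


@dataclasses.dataclass
class StepDistribution:
    """Representation of the distribution of the next adaptive step.

    Either an empirical sample of effect vectors (kind="empirical") or a set
    of grid points with density weights (kind="grid").
    """

    kind: str
    n: int
    samples: Optional[np.ndarray] = None
    points: Optional[np.ndarray] = None
    weights: Optional[np.ndarray] = None
    seed: Optional[int] = None

    def total_mass(self) -> float:
        if self.kind == "empirical":
            return 1.0
        return float(self.weights.sum())

    def mean(self) -> np.ndarray:
        if self.kind == "empirical":
            return self.samples.mean(axis=0)
        w = self.weights / self.weights.sum()
        return (w[:, None] * self.points).sum(axis=0)

    def cov(self) -> np.ndarray:
        if self.kind == "empirical":
            return np.cov(self.samples.T, ddof=1).reshape(self.n, self.n)
        w = self.weights / self.weights.sum()
        mu = self.mean()
        d = self.points - mu
        return (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0)

    def cv(self, axis: int = 0) -> float:
        mu = self.mean()[axis]
        sd = math.sqrt(self.cov()[axis, axis])
        return sd / abs(mu)


def step_distribution(
    y,
    model: ModelSpec,
    method: str = "integrate",
    density: str = "gaussian",
    route: str = "psi_f",
    grid_half_width: Optional[float] = None,
    grid_points: int = 41,
    replicates: int = 2000,
    seed: int = 0,
) -> StepDistribution:
    """Unconditional distribution phi(alpha | y) of the next adaptive step.

    method="integrate" evaluates phi on a regular grid (n <= 2) via the
    chosen route; method="simulate" pools first steps from replicated
    adaptive walks.
    """
    y = as_phenotype(y, model.n)
    if np.all(model.v == 0) and np.all(y == 0):
        raise ModelSpecError("v = 0 and y at the optimum: no step ever occurs")
    if method == "simulate":
        from .walk import walk_ensemble

        ens = walk_ensemble(model, replicates, max_steps=1, seed=seed)
        return StepDistribution(kind="empirical", n=model.n,
                                samples=ens.first_steps, seed=seed)
    if method != "integrate":
        raise ModelSpecError(f"unknown method {method!r}")
    if model.n > 2:
        raise ModelSpecError("grid integration implemented for n <= 2")
    wt = WaitingTime(y, model, density=density)
    if grid_half_width is None:
        # scale from the typical step: optimum displacement at the mean wait
        grid_half_width = 4.0 * max(
            float(np.linalg.norm(model.v)) * wt.mean(),
            math.sqrt(model.m_bar_sq),
        )
    axes = [np.linspace(-grid_half_width, grid_half_width, grid_points)] * model.n
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    dens = phi_pointwise(pts, y, model, wt, route=route, density=density)
    cell = np.prod([a[1] - a[0] for a in axes])
    return StepDistribution(kind="grid", n=model.n, points=pts,
                            weights=dens * cell)


# ---------------------------------------------------------------------------
# first-step moments under the uniform approximation
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class FirstStepMoments:
    """Moments of the first adaptive step in the environmentally limited
    (uniform-mutation) regime, wild type starting at the optimum."""

    mean_a1: float
    var_a1: float
    var_perp: float
    cv_a1: float
    mean_waiting_time: float


def canonical_model(n: int, gamma_value: float, sigma_sq: float = 10.0,
                    theta: float = 1.0) -> ModelSpec:
    """Isotropic canonical model (m^2 = 1) with the optimum speed chosen to
    realize a given scaled rate of environmental change."""
    v1 = gamma_value * theta / sigma_sq
    return ModelSpec.from_params(n, sigma_sq=sigma_sq, m_sq=1.0, v1=v1,
                                 theta=theta)


def first_step_moments_uniform(model: ModelSpec,
                               warn_threshold: float = 1.0) -> FirstStepMoments:
    """First-step moments under the uniform-mutation approximation.

    Uses the beneficial-ball geometry: given a step at time t, the step is
    distributed on the ball of radius r = v1 t centered at v t with density
    proportional to the linearized selection coefficient, giving
    E[alpha_1 | t] = r and Var(alpha_1 | t) = Var(alpha_perp | t) =
    r^2/(n+4).  The waiting-time density is f(t) = (n+3) c t^(n+2)
    exp(-c t^(n+3)) with c = Theta p0 V_n v1^(n+2) / (sigma^2 (n+2)(n+3));
    the time moments are obtained by one-dimensional quadrature.

    The coefficient of variation of alpha_1 depends only on n (the scale
    parameter c cancels).  A warning is issued when the predicted mean step
    exceeds ``warn_threshold`` times the mean mutational standard deviation,
    where the uniform approximation degrades.
    """
    if not model.is_canonical():
        raise ModelSpecError(
            "first_step_moments_uniform requires a canonical model; "
            "isotropize first")
    n = model.n
    sigma_sq = float(model.Sigma[0, 0])
    v1 = float(model.v[0])
    if v1 <= 0:
        raise ModelSpecError("v1 must be positive for a first step to occur")
    p0 = mutation_density_at_zero(model)
    c = model.theta * p0 * unit_ball_volume(n) * v1 ** (n + 2) / (
        sigma_sq * (n + 2) * (n + 3))

    k_exp = n + 3

    def t_moment(k: int) -> float:
        # E[T^k] = c^(-k/(n+3)) * int u^(k/(n+3)) e^-u du  (u = c t^(n+3))
        val, _ = integrate.quad(
            lambda u: u ** (k / k_exp) * math.exp(-u), 0.0, np.inf, limit=200)
        return c ** (-k / k_exp) * val

    ET = t_moment(1)
    ET2 = t_moment(2)
    mean_a1 = v1 * ET
    var_a1 = v1 ** 2 * (ET2 / (n + 4) + ET2 - ET ** 2)
    var_perp = v1 ** 2 * ET2 / (n + 4)
    cv = math.sqrt(var_a1) / mean_a1
    if mean_a1 > warn_threshold * math.sqrt(model.m_bar_sq):
        warnings.warn(
            "predicted mean first step exceeds the mean mutational standard "
            "deviation; the uniform approximation is unreliable here",
            RuntimeWarning, stacklevel=2)
    return FirstStepMoments(mean_a1=mean_a1, var_a1=var_a1, var_perp=var_perp,
                            cv_a1=cv, mean_waiting_time=ET)
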