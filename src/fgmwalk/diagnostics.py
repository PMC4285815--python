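"""Summary statistics and deterministic reference dynamics.

Includes the step-size correlation between the direction of the moving
optimum and an orthogonal direction, the "kite" lag diagnostics (systematic
displacement of the mean phenotype above or below the optimum's track), the
deterministic canonical-equation trajectory, the empirical G-matrix of a
simulated population, and summaries of the fitness effects of fixed
mutations.  Directions are defined in canonical (isotropized) coordinates:
axis 1 is the direction of the moving optimum, all remaining axes are
"orthogonal".
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np
from scipy import integrate as _integrate
from scipy import stats as _stats

from .model import ModelSpec, ModelSpecError, isotropize
from .walk import WalkResult

__all__ = [
    "StepCorrelation",
    "KiteDiagnostics",
    "step_correlation",
    "kite_lag",
    "walk_kite_lag",
    "canonical_trajectory",
    "equilibrium_lag",
    "empirical_G",
    "fitness_effect_summaries",
]


@dataclasses.dataclass(frozen=True)
class StepCorrelation:
    r: float
    n_steps: int
    degenerate: bool = False


@dataclasses.dataclass(frozen=True)
class KiteDiagnostics:
    mean_parallel_lag: float
    mean_orthogonal_lag: np.ndarray


def step_correlation(alphas) -> StepCorrelation:
    """Pearson correlation between fixed-step components alpha_1 and alpha_2."""
    alphas = np.asarray(alphas, dtype=float)
    m = alphas.shape[0]
    if m < 3:
        return StepCorrelation(r=float("nan"), n_steps=m, degenerate=True)
    a1, a2 = alphas[:, 0], alphas[:, 1]
    if np.var(a1) == 0 or np.var(a2) == 0:
        return StepCorrelation(r=float("nan"), n_steps=m, degenerate=True)
    return StepCorrelation(r=float(np.corrcoef(a1, a2)[0, 1]), n_steps=m)


def kite_lag(times, mean_phenotypes, model: ModelSpec,
             burn_in: float = 0.2) -> KiteDiagnostics:
    """Time-averaged lag of the mean phenotype relative to the moving optimum.

    Inputs are in the model's raw coordinates; they are mapped to canonical
    coordinates first, so "orthogonal" means all canonical axes beyond the
    first.  Positive orthogonal lag = the phenotype trails above the
    optimum's track (flying kite); negative = below (diving kite).  The first
    ``burn_in`` fraction of the series is discarded.
    """
    times = np.asarray(times, dtype=float)
    z = np.atleast_2d(np.asarray(mean_phenotypes, dtype=float))
    if z.shape[0] != times.size:
        raise ModelSpecError("times and mean_phenotypes lengths differ")
    canon, T = isotropize(model)
    z_star = z @ T.T
    opt_star = np.outer(times, canon.v)
    lag = z_star - opt_star
    k = int(burn_in * times.size)
    lag = lag[k:]
    mean = lag.mean(axis=0)
    return KiteDiagnostics(mean_parallel_lag=float(mean[0]),
                           mean_orthogonal_lag=mean[1:])


def walk_kite_lag(walks: Sequence[WalkResult], model: ModelSpec,
                  n_grid: int = 200, burn_in: float = 0.2) -> KiteDiagnostics:
    """Kite diagnostics pooled over an ensemble of adaptive walks, sampling
    each walk's piecewise-constant phenotype on a uniform time grid."""
    par, orth = [], []
    for w in walks:
        if not w.records:
            continue
        grid = np.linspace(0.0, w.final_time, n_grid)
        z = w.phenotype_at(grid)
        d = kite_lag(grid, z, model, burn_in=burn_in)
        par.append(d.mean_parallel_lag)
        orth.append(d.mean_orthogonal_lag)
    if not par:
        raise ModelSpecError("no walk in the ensemble has any substitution")
    return KiteDiagnostics(mean_parallel_lag=float(np.mean(par)),
                           mean_orthogonal_lag=np.mean(orth, axis=0))


def equilibrium_lag(model: ModelSpec, rate_constant: float) -> np.ndarray:
    """Stationary lag z_opt - z_bar of the canonical equation: solves
    c M Sigma^-1 lag = v."""
    if rate_constant <= 0:
        raise ModelSpecError("rate_constant must be positive")
    return np.linalg.solve(model.M @ model.Sigma_inv, model.v) / rate_constant


def canonical_trajectory(model: ModelSpec, rate_constant: float, t_grid,
                         z0=None) -> np.ndarray:
    """Deterministic mean-phenotype trajectory under the canonical equation
    of adaptive dynamics, dz/dt = c M beta(t) with selection gradient
    beta(t) = Sigma^-1 (z_opt(t) - z).

    The long-time lag z_opt - z approaches ``equilibrium_lag``.  Integrated
    with an implicit solver (the system is linear and can be stiff for large
    c or strong correlations).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if rate_constant <= 0:
        raise ModelSpecError("rate_constant must be positive")
    if np.any(np.diff(t_grid) <= 0):
        raise ModelSpecError("t_grid must be strictly increasing")
    n = model.n
    z0 = np.zeros(n) if z0 is None else np.asarray(z0, dtype=float)
    A = rate_constant * model.M @ model.Sigma_inv

    def rhs(t, z):
        return A @ (model.v * t - z)

    sol = _integrate.solve_ivp(
        rhs, (t_grid[0], t_grid[-1]), z0, t_eval=t_grid, method="LSODA",
        jac=lambda t, z: -A, rtol=1e-10, atol=1e-12)
    if not sol.success:  # pragma: no cover - defensive
        raise ArithmeticError(f"ODE integration failed: {sol.message}")
    return sol.y.T


def empirical_G(phenotypes) -> np.ndarray:
    """Population covariance matrix of individual phenotypes (the empirical
    G-matrix; zero for a monomorphic population)."""
    z = np.atleast_2d(np.asarray(phenotypes, dtype=float))
    if z.shape[0] < 2:
        raise ModelSpecError("need at least two individuals")
    d = z - z.mean(axis=0)
    return d.T @ d / z.shape[0]


def fitness_effect_summaries(s_values, norm_alphas=None) -> dict:
    """Distributional summaries of the selection coefficients of fixed
    mutations (and optionally of the total step sizes ||alpha||).

    The modality diagnostic fits a Gaussian kernel density (Silverman
    bandwidth) and flags an interior mode when the density argmax is not in
    the lowest decile of the observed range.
    """
    s = np.asarray(s_values, dtype=float)
    if s.size < 1:
        raise ModelSpecError("need at least one record")
    out = {
        "mean_s": float(s.mean()),
        "median_s": float(np.median(s)),
        "q10_s": float(np.quantile(s, 0.1)),
        "q90_s": float(np.quantile(s, 0.9)),
    }
    out["interior_mode_s"] = _interior_mode(s)
    if norm_alphas is not None:
        na = np.asarray(norm_alphas, dtype=float)
        out["mean_norm"] = float(na.mean())
        out["interior_mode_norm"] = _interior_mode(na)
    return out


def _interior_mode(x: np.ndarray) -> bool:
    if x.size < 10 or np.ptp(x) == 0:
        return False
    kde = _stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    mode = grid[int(np.argmax(kde(grid)))]
    return bool(mode > x.min() + 0.1 * np.ptp(x))
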