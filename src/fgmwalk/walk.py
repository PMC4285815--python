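"""Stochastic adaptive-walk simulation.

The walk approximation treats the population as monomorphic: mutations arrive
as a Poisson process with rate Theta/2, each proposal draws a multivariate
normal effect from the mutational covariance M, and a proposal arriving at
time t with selection coefficient s fixes with probability p_fix(s) — in
which case the population phenotype jumps instantaneously.  Interactions
between cosegregating mutations (linkage, clonal interference, epistasis) are
deliberately outside this engine; see the individual-based simulator.

Proposals are generated in adaptively growing batches and thinned with
vectorized numpy arithmetic, which keeps slow-optimum regimes (tens of
thousands of proposals per substitution) tractable.  Results are exactly
reproducible for a given seed.
"""

from __future__ import annotations

import dataclasses
import math
from typing import List, Optional, Sequence

import numpy as np

from .model import ModelSpec, ModelSpecError, as_phenotype, fitness

__all__ = [
    "SubstitutionRecord",
    "WalkResult",
    "EnsembleResult",
    "simulate_walk",
    "walk_ensemble",
    "mean_fitness_trace",
]

_CHUNK_MIN = 1024
_CHUNK_MAX = 1 << 17


@dataclasses.dataclass(frozen=True)
class SubstitutionRecord:
    """One fixed mutation along an adaptive walk."""

    index: int
    time: float
    alpha: np.ndarray
    s_at_origin: float
    phenotype_before: np.ndarray
    phenotype_after: np.ndarray


@dataclasses.dataclass
class WalkResult:
    """Ordered substitutions of one walk plus its provenance."""

    records: List[SubstitutionRecord]
    seed: object
    termination: str  # step_limit | time_limit | extinct
    model: ModelSpec
    final_time: float
    start: np.ndarray
    n_proposals: int = 0
    proposal_times: Optional[np.ndarray] = None
    proposal_s: Optional[np.ndarray] = None

    def alphas(self) -> np.ndarray:
        if not self.records:
            return np.empty((0, self.model.n))
        return np.array([r.alpha for r in self.records])

    def phenotype_at(self, t) -> np.ndarray:
        """Piecewise-constant phenotype trajectory evaluated at times t."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        times = np.array([r.time for r in self.records])
        phen = np.vstack([self.start] + [r.phenotype_after for r in self.records])
        idx = np.searchsorted(times, t, side="right")
        return phen[idx]


def simulate_walk(
    model: ModelSpec,
    start=None,
    max_steps: Optional[int] = None,
    max_time: Optional[float] = None,
    pfix_mode: str = "linear",
    extinction_threshold: Optional[float] = None,
    seed=0,
    rng: Optional[np.random.Generator] = None,
    mutation_chol: Optional[np.ndarray] = None,
    collect_proposals: bool = False,
) -> WalkResult:
    """Simulate one adaptive walk.

    Parameters
    ----------
    model : ModelSpec
    start : array_like, optional
        Initial phenotype (defaults to the optimum at t = 0, i.e. the origin).
    max_steps, max_time :
        Termination controls; at least one must be finite.
    pfix_mode : {"linear", "exp"}
        Fixation-probability approximation: clamp(2s, 0, 1) or 1 - exp(-2s).
    extinction_threshold : float, optional
        If set, terminate with ``termination="extinct"`` as soon as the
        wild-type fitness (evaluated at proposal arrival times) drops below
        this value.  Off by default.
    seed, rng :
        Either a seed (int or numpy SeedSequence) or an explicit Generator.
    mutation_chol : (n, n) array, optional
        Square root of M used to map standard-normal draws to effects
        (defaults to cholesky(M)).  Passing ``T @ cholesky(M)`` of an
        isotropizing transform reproduces a walk in transformed coordinates
        from identical underlying draws.
    collect_proposals : bool
        If True, record every proposal's arrival time and selection
        coefficient (diagnostics only; memory grows with the proposal count).
    """
    if max_steps is None and max_time is None:
        raise ModelSpecError("at least one of max_steps / max_time must be set")
    if pfix_mode not in ("linear", "exp"):
        raise ModelSpecError(f"unknown pfix_mode {pfix_mode!r}")
    n = model.n
    y = np.zeros(n) if start is None else as_phenotype(start, n).copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    L = model.M_chol if mutation_chol is None else np.asarray(mutation_chol, float)

    Si = model.Sigma_inv
    Si_v = Si @ model.v
    scale = 2.0 / model.theta
    t = 0.0
    t_cap = math.inf if max_time is None else float(max_time)
    step_cap = math.inf if max_steps is None else int(max_steps)

    records: List[SubstitutionRecord] = []
    n_prop = 0
    prop_t: List[np.ndarray] = []
    prop_s: List[np.ndarray] = []
    termination = "time_limit"
    chunk = _CHUNK_MIN

    while True:
        if len(records) >= step_cap:
            termination = "step_limit"
            break
        gaps = rng.exponential(scale, size=chunk)
        times = t + np.cumsum(gaps)
        z = rng.standard_normal((chunk, n))
        u = rng.random(chunk)
        alphas = z @ L.T

        in_time = times <= t_cap
        if not in_time.all():
            last = int(np.searchsorted(times, t_cap, side="right"))
            times, alphas, u = times[:last], alphas[:last], u[:last]

        if times.size:
            # s = exp(-1/2 a'Si a - a'Si y + t a'Si v) - 1, vectorized
            q = np.einsum("ij,jk,ik->i", alphas, Si, alphas)
            ay = alphas @ (Si @ y)
            av = alphas @ Si_v
            expo = -0.5 * q - ay + times * av
            # cap the log-ratio: far-from-optimum regimes would overflow exp,
            # but any s this large is accepted with probability 1 anyway
            s = np.expm1(np.minimum(expo, 700.0))
            if pfix_mode == "linear":
                pf = np.clip(2.0 * s, 0.0, 1.0)
            else:
                pf = np.maximum(0.0, -np.expm1(-2.0 * s))
            accept = u < pf

            stop_ext = None
            if extinction_threshold is not None:
                d = y[None, :] - np.outer(times, model.v)
                logw = -0.5 * np.einsum("ij,jk,ik->i", d, Si, d)
                below = logw < math.log(extinction_threshold)
                if below.any():
                    stop_ext = int(np.argmax(below))

            hit = int(np.argmax(accept)) if accept.any() else None
            if stop_ext is not None and (hit is None or stop_ext <= hit):
                n_prop += stop_ext + 1
                if collect_proposals:
                    prop_t.append(times[: stop_ext + 1])
                    prop_s.append(s[: stop_ext + 1])
                t = float(times[stop_ext])
                termination = "extinct"
                break
            if hit is not None:
                n_prop += hit + 1
                if collect_proposals:
                    prop_t.append(times[: hit + 1])
                    prop_s.append(s[: hit + 1])
                t = float(times[hit])
                alpha = alphas[hit].copy()
                before = y.copy()
                y = y + alpha
                records.append(
                    SubstitutionRecord(
                        index=len(records) + 1,
                        time=t,
                        alpha=alpha,
                        s_at_origin=float(s[hit]),
                        phenotype_before=before,
                        phenotype_after=y.copy(),
                    )
                )
                chunk = _CHUNK_MIN
                continue
            # no acceptance in this (possibly truncated) chunk
            n_prop += times.size
            if collect_proposals:
                prop_t.append(times.copy())
                prop_s.append(s.copy())
            if times.size:
                t = float(times[-1])

        if times.size < chunk:  # ran past max_time
            t = t_cap
            termination = "time_limit"
            break
        chunk = min(chunk * 2, _CHUNK_MAX)

    return WalkResult(
        records=records,
        seed=seed,
        termination=termination,
        model=model,
        final_time=t,
        start=np.zeros(n) if start is None else as_phenotype(start, n),
        n_proposals=n_prop,
        proposal_times=np.concatenate(prop_t) if collect_proposals and prop_t else None,
        proposal_s=np.concatenate(prop_s) if collect_proposals and prop_s else None,
    )


@dataclasses.dataclass
class EnsembleResult:
    """Replicated walks plus pooled step arrays.

    ``first_steps`` stacks the effect vector of each walk's first substitution
    (walks with no substitution are omitted); ``all_steps`` pools every
    substitution of every walk.
    """

    walks: List[WalkResult]
    first_steps: np.ndarray
    all_steps: np.ndarray
    first_times: np.ndarray
    all_s: np.ndarray
    seed: int

    def to_frame(self):
        import pandas as pd

        rows = []
        for w_id, w in enumerate(self.walks):
            for r in w.records:
                row = {"walk_id": w_id, "index": r.index, "time": r.time,
                       "s_at_origin": r.s_at_origin}
                for j, a in enumerate(r.alpha, 1):
                    row[f"alpha_{j}"] = a
                for j, p in enumerate(r.phenotype_after, 1):
                    row[f"phenotype_{j}"] = p
                rows.append(row)
        return pd.DataFrame(rows)


def walk_ensemble(
    model: ModelSpec,
    replicates: int,
    max_steps: Optional[int] = None,
    max_time: Optional[float] = None,
    pfix_mode: str = "linear",
    extinction_threshold: Optional[float] = None,
    seed: int = 0,
) -> EnsembleResult:
    """Run ``replicates`` independent walks with child seeds spawned
    deterministically from the master seed."""
    if replicates < 1:
        raise ModelSpecError("replicates must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(replicates)
    walks = []
    first, allsteps, ftimes, all_s = [], [], [], []
    for child in children:
        w = simulate_walk(
            model,
            max_steps=max_steps,
            max_time=max_time,
            pfix_mode=pfix_mode,
            extinction_threshold=extinction_threshold,
            seed=child,
            rng=np.random.default_rng(child),
        )
        walks.append(w)
        if w.records:
            first.append(w.records[0].alpha)
            ftimes.append(w.records[0].time)
            for r in w.records:
                allsteps.append(r.alpha)
                all_s.append(r.s_at_origin)
    n = model.n
    return EnsembleResult(
        walks=walks,
        first_steps=np.array(first) if first else np.empty((0, n)),
        all_steps=np.array(allsteps) if allsteps else np.empty((0, n)),
        first_times=np.array(ftimes),
        all_s=np.array(all_s),
        seed=seed,
    )


def mean_fitness_trace(walk: WalkResult, model: ModelSpec, grid: Sequence[float]):
    """Wild-type fitness along a time grid.

    Under the walk approximation the population is monomorphic, so the mean
    fitness is the wild-type fitness; it decays between substitutions as the
    optimum recedes and jumps upward at each substitution time.
    """
    grid = np.asarray(grid, dtype=float)
    phen = walk.phenotype_at(grid)
    return np.array([fitness(z, t, model) for z, t in zip(phen, grid)])
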