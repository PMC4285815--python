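"""Forward-in-time individual-based simulation.

Diploid individuals carry L unlinked additive loci; each allele is a vector
of contributions to the n traits (universal pleiotropy, continuum of
alleles), and the phenotype is the sum over all 2L allele effects with no
environmental variance.  The life cycle per discrete generation is

1. viability selection -- each individual survives with probability w(z, t),
2. population regulation -- if survivors exceed the carrying capacity K,
   random individuals are culled down to K,
3. reproduction -- survivors are randomly paired (monogamous pairs, no
   sexes); each pair produces exactly B offspring.  Offspring inherit one
   randomly segregating allele per parent per locus (free recombination
   between loci) and mutate with probability u/2 per gamete per locus, the
   mutant effect adding an MVN(0, M) deviate to the copied parental allele.

Fixations are detected from the per-locus allele genealogy: a substitution is
recorded whenever the root of the "allele tree" changes, i.e. when all live
alleles acquire a new most recent common ancestor.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .model import ModelSpec, ModelSpecError

__all__ = [
    "AlleleStore",
    "PopulationState",
    "IBSSubstitution",
    "IBSResult",
    "init_population",
    "generation_step",
    "detect_substitutions",
    "brute_force_mrca",
    "run_ibs",
    "theta_from_census",
    "heterozygosity",
    "empirical_phenotypes",
]


class AlleleStore:
    """Per-locus allele table: effect vectors plus the mutational genealogy
    (parent pointers; -1 marks a founder)."""

    def __init__(self, n: int):
        self.n = n
        self.effects: List[np.ndarray] = []
        self.parents: List[int] = []
        self.children: Dict[int, List[int]] = {}

    def add(self, effect: np.ndarray, parent: int) -> int:
        idx = len(self.effects)
        self.effects.append(np.asarray(effect, dtype=float))
        self.parents.append(parent)
        if parent >= 0:
            self.children.setdefault(parent, []).append(idx)
        return idx

    def effect_of(self, idx: int) -> np.ndarray:
        return self.effects[idx]

    def __len__(self) -> int:
        return len(self.effects)


@dataclasses.dataclass
class PopulationState:
    """Population genotypes plus per-locus genealogies.

    ``genotypes[i, l, g]`` is the allele index (into ``stores[l]``) carried by
    individual i at locus l on haplotype g.
    """

    genotypes: np.ndarray  # (N, L, 2) int64
    generation: int
    stores: List[AlleleStore]
    roots: List[int]
    model: ModelSpec
    extinct: bool = False

    @property
    def census(self) -> int:
        return self.genotypes.shape[0]

    @property
    def L(self) -> int:
        return self.genotypes.shape[1]


@dataclasses.dataclass(frozen=True)
class IBSSubstitution:
    locus: int
    generation_detected: int
    root_allele_id_old: int
    root_allele_id_new: int
    effect_delta: np.ndarray


def init_population(K: int, L: int, model: ModelSpec,
                    founder_diversity: int = 1) -> PopulationState:
    """K identical homozygous individuals with phenotype 0.

    ``founder_diversity > 1`` instead seeds each locus with that many distinct
    zero-effect founder alleles assigned round-robin over the 2K allele
    copies (used for neutral drift experiments; root-change detection is
    disabled while multiple founder lineages coexist).
    """
    if K < 2:
        raise ModelSpecError("K must be >= 2")
    if L < 1:
        raise ModelSpecError("L must be >= 1")
    stores = [AlleleStore(model.n) for _ in range(L)]
    zero = np.zeros(model.n)
    for st in stores:
        for _ in range(max(1, founder_diversity)):
            st.add(zero, -1)
    if founder_diversity <= 1:
        genotypes = np.zeros((K, L, 2), dtype=np.int64)
    else:
        ids = np.arange(2 * K, dtype=np.int64) % founder_diversity
        genotypes = np.tile(ids.reshape(K, 1, 2), (1, L, 1))
    return PopulationState(genotypes=genotypes, generation=0, stores=stores,
                           roots=[0] * L, model=model)


def empirical_phenotypes(state: PopulationState) -> np.ndarray:
    """Phenotype of every individual: sum of its 2L allele effect vectors."""
    n = state.model.n
    out = np.zeros((state.census, n))
    for l, st in enumerate(state.stores):
        eff = np.asarray(st.effects)
        out += eff[state.genotypes[:, l, 0]]
        out += eff[state.genotypes[:, l, 1]]
    return out


def _log_fitness_many(z: np.ndarray, t: float, model: ModelSpec) -> np.ndarray:
    d = z - model.v * t
    return -0.5 * np.einsum("ij,jk,ik->i", d, model.Sigma_inv, d)


def generation_step(
    state: PopulationState,
    params: dict,
    rng: np.random.Generator,
    selection: bool = True,
) -> Tuple[PopulationState, dict]:
    """Advance the population by one generation (selection, regulation,
    reproduction with segregation and mutation).

    ``params`` must provide K, B and mu.  Returns the new state and an event
    dict; extinction (fewer than 2 survivors) is signaled as a terminal event
    with ``state.extinct`` set, not an exception.
    """
    K, B, mu = int(params["K"]), int(params["B"]), float(params["mu"])
    model = state.model
    N = state.census
    t = state.generation
    if state.extinct or N == 0:
        raise ModelSpecError("population already extinct")

    # (1) viability selection
    if selection:
        logw = _log_fitness_many(empirical_phenotypes(state), t, model)
        survive = rng.random(N) < np.exp(logw)
        surv_idx = np.flatnonzero(survive)
    else:
        surv_idx = np.arange(N)
    # (2) regulation to carrying capacity
    if surv_idx.size > K:
        surv_idx = surv_idx[rng.permutation(surv_idx.size)[:K]]
    n_surv = surv_idx.size
    events = {"census_before": N, "survivors": int(n_surv)}
    if n_surv < 2:
        state.extinct = True
        state.genotypes = state.genotypes[surv_idx]
        state.generation = t + 1
        events["extinct"] = True
        return state, events

    # (3) reproduction: random monogamous pairs, exactly B offspring each
    perm = surv_idx[rng.permutation(n_surv)]
    n_pairs = n_surv // 2
    mothers = np.repeat(perm[:n_pairs], B)
    fathers = np.repeat(perm[n_pairs: 2 * n_pairs], B)
    n_off = n_pairs * B
    L = state.L

    bits = rng.integers(0, 2, size=(n_off, L, 2))
    geno = state.genotypes
    child = np.empty((n_off, L, 2), dtype=np.int64)
    child[:, :, 0] = np.take_along_axis(geno[mothers], bits[:, :, :1], axis=2)[:, :, 0]
    child[:, :, 1] = np.take_along_axis(geno[fathers], bits[:, :, 1:], axis=2)[:, :, 0]

    # mutation: probability mu/2 per gamete per locus (rate mu per diploid locus)
    if mu > 0:
        hits = np.argwhere(rng.random((n_off, L, 2)) < mu / 2.0)
        if hits.size:
            deviates = rng.standard_normal((hits.shape[0], model.n)) @ model.M_chol.T
            for (o, l, g), dev in zip(hits, deviates):
                parent_id = int(child[o, l, g])
                eff = state.stores[l].effect_of(parent_id) + dev
                child[o, l, g] = state.stores[l].add(eff, parent_id)
        events["mutations"] = int(hits.shape[0])
    else:
        events["mutations"] = 0

    state.genotypes = child
    state.generation = t + 1
    events["census_after"] = int(n_off)
    return state, events


# ---------------------------------------------------------------------------
# substitution detection
# ---------------------------------------------------------------------------


def _live_counts(state: PopulationState, locus: int) -> np.ndarray:
    ids = state.genotypes[:, locus, :].ravel()
    return np.bincount(ids, minlength=len(state.stores[locus]))


def detect_substitutions(state: PopulationState) -> List[IBSSubstitution]:
    """Incremental allele-tree root tracking.

    For each locus, prune subtrees without live descendants from the root's
    children graph, then advance the root along every edge where the old root
    has no live copies and exactly one surviving child subtree — each such
    edge is one substitution.  Detection requires a single founder lineage.
    """
    out: List[IBSSubstitution] = []
    for l in range(state.L):
        st = state.stores[l]
        counts = _live_counts(state, l)
        root = state.roots[l]

        # subtree live totals below the current root, pruning dead branches
        def subtree_live(node: int) -> int:
            total = int(counts[node]) if node < counts.size else 0
            kids = st.children.get(node, [])
            alive_kids = []
            for k in kids:
                sub = subtree_live(k)
                if sub > 0:
                    alive_kids.append(k)
                total += sub
            st.children[node] = alive_kids
            return total

        total = subtree_live(root)
        if total == 0:
            continue  # locus lineage lost (possible only pre-extinction)
        while True:
            own = int(counts[root]) if root < counts.size else 0
            kids = st.children.get(root, [])
            if own == 0 and len(kids) == 1:
                new_root = kids[0]
                out.append(IBSSubstitution(
                    locus=l,
                    generation_detected=state.generation,
                    root_allele_id_old=root,
                    root_allele_id_new=new_root,
                    effect_delta=st.effect_of(new_root) - st.effect_of(root),
                ))
                root = new_root
            else:
                break
        state.roots[l] = root
    return out


def brute_force_mrca(state: PopulationState, locus: int) -> Optional[int]:
    """MRCA of all live alleles at a locus, recomputed from scratch from the
    raw parent pointers (independent oracle for the incremental detector).
    Returns None when live alleles span multiple founder lineages."""
    st = state.stores[locus]
    live = np.unique(state.genotypes[:, locus, :])

    def path_to_founder(a: int) -> List[int]:
        path = [a]
        while st.parents[path[-1]] >= 0:
            path.append(st.parents[path[-1]])
        return path[::-1]  # founder first

    paths = [path_to_founder(int(a)) for a in live]
    first = paths[0]
    depth = 0
    while all(len(p) > depth and p[depth] == first[depth] for p in paths):
        depth += 1
    if depth == 0:
        return None
    return first[depth - 1]


# ---------------------------------------------------------------------------
# run driver
# ---------------------------------------------------------------------------


def theta_from_census(K: int, L: int, mu: float, B: int,
                      convention: str = "post_reproduction") -> float:
    """Population- and genome-wide mutation supply Theta = 2 N L u.

    convention="post_reproduction" uses the offspring census N = B * (K // 2)
    produced each generation by a population at carrying capacity (N = 2K for
    B = 4); convention="carrying_capacity" uses N = K.  The first is the
    accounting under which the standard configuration K=1000, L=10, u=5e-6,
    B=4 yields Theta = 0.2.
    """
    if convention == "post_reproduction":
        N = B * (K // 2)
    elif convention == "carrying_capacity":
        N = K
    else:
        raise ModelSpecError(f"unknown census convention {convention!r}")
    return 2.0 * N * L * mu


@dataclasses.dataclass
class IBSResult:
    substitutions: pd.DataFrame
    summaries: pd.DataFrame
    termination: str  # max_substitutions | max_generations | extinct
    theta: float
    seed: int
    final_state: PopulationState


def run_ibs(
    model: ModelSpec,
    params: dict,
    max_substitutions: Optional[int] = None,
    max_generations: Optional[int] = None,
    seed: int = 0,
    selection: bool = True,
    founder_diversity: int = 1,
    record_every: int = 1,
    detect: bool = True,
) -> IBSResult:
    """Run the individual-based simulation until a substitution or generation
    cap is hit (or the population goes extinct)."""
    if max_substitutions is None and max_generations is None:
        raise ModelSpecError(
            "at least one of max_substitutions / max_generations must be set")
    rng = np.random.default_rng(seed)
    K, L = int(params["K"]), int(params["L"])
    state = init_population(K, L, model, founder_diversity=founder_diversity)
    subs: List[IBSSubstitution] = []
    rows = []
    termination = "max_generations"
    gen_cap = max_generations if max_generations is not None else np.inf
    sub_cap = max_substitutions if max_substitutions is not None else np.inf

    while state.generation < gen_cap:
        if record_every and state.generation % record_every == 0:
            z = empirical_phenotypes(state)
            logw = _log_fitness_many(z, state.generation, model)
            row = {"generation": state.generation, "census": state.census,
                   "mean_fitness": float(np.exp(logw).mean())}
            mz = z.mean(axis=0)
            opt = model.optimum(state.generation)
            for j in range(model.n):
                row[f"mean_z_{j + 1}"] = mz[j]
                row[f"opt_{j + 1}"] = opt[j]
            rows.append(row)
        state, events = generation_step(state, params, rng, selection=selection)
        if events.get("extinct"):
            termination = "extinct"
            break
        if detect and founder_diversity <= 1:
            subs.extend(detect_substitutions(state))
            if len(subs) >= sub_cap:
                termination = "max_substitutions"
                break

    sub_rows = []
    for s in subs:
        row = {"locus": s.locus, "generation": s.generation_detected,
               "old_root": s.root_allele_id_old, "new_root": s.root_allele_id_new}
        for j, d in enumerate(s.effect_delta, 1):
            row[f"effect_delta_{j}"] = d
        sub_rows.append(row)
    return IBSResult(
        substitutions=pd.DataFrame(sub_rows),
        summaries=pd.DataFrame(rows),
        termination=termination,
        theta=theta_from_census(K, L, float(params["mu"]), int(params["B"])),
        seed=seed,
        final_state=state,
    )


def heterozygosity(state: PopulationState) -> np.ndarray:
    """Per-locus expected heterozygosity 1 - sum p_i^2 over allele
    frequencies (gene diversity)."""
    out = np.empty(state.L)
    for l in range(state.L):
        ids = state.genotypes[:, l, :].ravel()
        counts = np.bincount(ids)
        p = counts[counts > 0] / ids.size
        out[l] = 1.0 - float(np.sum(p * p))
    return out
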