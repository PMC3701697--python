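"""Network-module activity analysis.

Given the set of tentative "input metabolites" matched from the significant
feature list, the method searches the reference metabolite network for
candidate modules that connect them, scores each module for both enrichment
of input metabolites and topological modularity, and calibrates the scores
against a permutation null:

1. subnetworks connecting input metabolites within 1..4 reaction steps are
   extracted (shortest-path semantics; beyond four steps the network is
   essentially exhausted);
2. each subnetwork is further divided by recursive leading-eigenvector
   (spectral) bipartitioning into structural modules;
3. candidates are pruned of protruding edges that do not reach an input
   metabolite, then scored:

       Q = E_M / E - (sum_i k_i / 2E)^2          (Newman-Girvan, one module
                                                  against the whole network)
       A = (m / N) * Q * N^{-1/2}                (default activity score)

   where N is the module size, m the number of input metabolites in it,
   E_M its internal edge count, E the total edge count and k_i the global
   degrees.  The N^{-1/2} factor counteracts the size bias of raw
   modularity; the scorer is pluggable so any enrichment-times-modularity
   form can be substituted;
4. the same steps run on many random draws from the reference feature list;
   the pooled random-module scores are fitted by a two-parameter Gamma
   distribution (MLE), whose upper tail converts an observed score into a
   p-value.  When too few positive scores exist for a stable fit, an
   empirical tail rank is used instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .matching import FeatureTable, MatchMap, TheoreticalIndex

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateModule",
    "ScoredModule",
    "GammaNull",
    "extract_connecting_subnetworks",
    "spectral_split",
    "agglomerative_split",
    "prune_protruding_edges",
    "newman_girvan_modularity",
    "activity_score",
    "default_scorer",
    "find_candidate_modules",
    "build_null_module_scores",
    "fit_gamma_mle",
    "score_to_pvalue",
]

MIN_MODULE_SIZE = 3   # smallest candidate module, nodes
MIN_SEEDS = 2         # a module must "connect" at least two input metabolites
MIN_GAMMA_SAMPLES = 20


@dataclass(frozen=True)
class CandidateModule:
    """A connected candidate subgraph with its input-metabolite content."""

    nodes: frozenset[str]
    seeds: frozenset[str]          # input metabolites among the nodes
    provenance: str = "connecting-subnetwork"

    @property
    def N(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        return len(self.seeds)

    def internal_edges(self, graph: nx.Graph) -> int:
        return graph.subgraph(self.nodes).number_of_edges()


@dataclass(frozen=True)
class ScoredModule:
    module: CandidateModule
    Q: float
    A: float
    p_value: float | None = None


# ---------------------------------------------------------------------------
# Step 2: connecting subnetworks


def extract_connecting_subnetworks(
    graph: nx.Graph,
    seeds: Iterable[str],
    max_steps: int = 4,
    min_size: int = MIN_MODULE_SIZE,
    min_seeds: int = MIN_SEEDS,
) -> list[CandidateModule]:
    """Subnetworks connecting input metabolites within 1..max_steps reactions.

    For each step bound k, the subgraph induced by the seeds plus every node
    lying on a shortest path of length <= k between some seed pair is taken;
    its connected components holding at least ``min_seeds`` seeds are
    returned (deduplicated by node set across k).  Seeds absent from the
    graph are dropped with a logged count.
    """
    if not 1 <= max_steps <= 4:
        raise ValueError("max_steps must be between 1 and 4")
    seeds = set(seeds)
    present = seeds & set(graph.nodes)
    if len(present) < len(seeds):
        logger.info("dropped %d input metabolites absent from the network", len(seeds) - len(present))
    if not present:
        return []
    dist = {
        s: nx.single_source_shortest_path_length(graph, s, cutoff=max_steps)
        for s in present
    }
    seed_list = sorted(present)
    out: list[CandidateModule] = []
    seen: set[frozenset[str]] = set()
    for k in range(1, max_steps + 1):
        included: set[str] = set()
        pairs = [
            (s, t)
            for i, s in enumerate(seed_list)
            for t in seed_list[i + 1:]
            if dist[s].get(t, max_steps + 1) <= k
        ]
        if not pairs:
            continue
        for v in graph.nodes:
            for s, t in pairs:
                d_st = dist[s][t]
                if dist[s].get(v, k + 1) + dist[t].get(v, k + 1) == d_st:
                    included.add(v)
                    break
        included |= present
        sub = graph.subgraph(included)
        for comp in nx.connected_components(sub):
            comp_seeds = comp & present
            if len(comp_seeds) >= min_seeds and len(comp) >= min_size:
                key = frozenset(comp)
                if key not in seen:
                    seen.add(key)
                    out.append(CandidateModule(key, frozenset(comp_seeds), "connecting-subnetwork"))
    return out


# ---------------------------------------------------------------------------
# Step 3: spectral splitting


def _partition_modularity(sub: nx.Graph, s: np.ndarray, nodes: list) -> float:
    """Modularity of the two-group partition encoded by sign vector s."""
    m = sub.number_of_edges()
    if m == 0:
        return 0.0
    groups = [
        {n for n, si in zip(nodes, s) if si > 0},
        {n for n, si in zip(nodes, s) if si <= 0},
    ]
    groups = [g for g in groups if g]
    return nx.community.modularity(sub, groups)


def _best_bipartition(sub: nx.Graph) -> tuple[float, np.ndarray] | None:
    """Leading-eigenvector bipartition with Kernighan-Lin fine-tuning.

    Returns (Q, sign vector) for the best split found, or None when the
    graph admits no modularity-positive split.
    """
    nodes = list(sub.nodes)
    n = len(nodes)
    m = sub.number_of_edges()
    if n < 2 or m == 0:
        return None
    A = nx.to_numpy_array(sub, nodelist=nodes)
    k = A.sum(axis=1)
    B = A - np.outer(k, k) / (2.0 * m)
    evals, evecs = np.linalg.eigh(B)
    lead = evecs[:, -1]
    s = np.where(lead >= 0, 1.0, -1.0)

    def q_of(sv: np.ndarray) -> float:
        return float(sv @ B @ sv) / (4.0 * m)

    # Kernighan-Lin style fine-tuning: per pass move each vertex once,
    # greedily, keeping the best intermediate state; repeat to convergence.
    best_q = q_of(s)
    improved = True
    while improved:
        improved = False
        state = s.copy()
        free = set(range(n))
        trail = []
        q = best_q
        while free:
            gains = {}
            for i in free:
                state[i] = -state[i]
                gains[i] = q_of(state)
                state[i] = -state[i]
            i_best = max(gains, key=lambda i: (gains[i], -i))
            state[i_best] = -state[i_best]
            q = gains[i_best]
            free.discard(i_best)
            trail.append((q, state.copy()))
        q_max, s_max = max(trail, key=lambda t: t[0])
        if q_max > best_q + 1e-12:
            best_q, s = q_max, s_max
            improved = True
    if best_q <= 1e-12 or len(set(s)) < 2:
        return None
    return best_q, s


def spectral_split(
    module: CandidateModule,
    graph: nx.Graph,
    min_size: int = MIN_MODULE_SIZE,
) -> list[CandidateModule]:
    """Recursively bipartition a module by the leading-eigenvector method.

    Recursion stops when no split increases modularity (of the part treated
    as a standalone graph) or when a part would fall below ``min_size``.
    All intermediate and leaf parts that are connected and large enough are
    returned, the unsplit input module first.
    """
    results: list[CandidateModule] = [module]
    seen = {module.nodes}

    def rec(nodes: frozenset[str]) -> None:
        sub = graph.subgraph(nodes)
        split = _best_bipartition(sub)
        if split is None:
            return
        _, s = split
        node_list = list(sub.nodes)
        part1 = frozenset(n for n, si in zip(node_list, s) if si > 0)
        part2 = frozenset(nodes - part1)
        if min(len(part1), len(part2)) < min_size:
            return
        for part in (part1, part2):
            for comp in nx.connected_components(graph.subgraph(part)):
                comp = frozenset(comp)
                if len(comp) >= min_size and comp not in seen:
                    seen.add(comp)
                    results.append(
                        CandidateModule(comp, module.seeds & comp, "spectral-split")
                    )
                if len(comp) >= 2 * min_size:
                    rec(comp)

    if module.N >= 2 * min_size:
        rec(module.nodes)
    return results


def agglomerative_split(
    module: CandidateModule,
    graph: nx.Graph,
    min_size: int = MIN_MODULE_SIZE,
) -> list[CandidateModule]:
    """Alternative modularization: greedy modularity agglomeration (CNM).

    Swappable for :func:`spectral_split` to probe how robust the downstream
    activity network is to the choice of module-finding algorithm.
    """
    sub = graph.subgraph(module.nodes)
    results = [module]
    seen = {module.nodes}
    if sub.number_of_edges() == 0 or module.N < 2 * min_size:
        return results
    for community in nx.community.greedy_modularity_communities(sub):
        for comp in nx.connected_components(graph.subgraph(community)):
            comp = frozenset(comp)
            if len(comp) >= min_size and comp not in seen:
                seen.add(comp)
                results.append(CandidateModule(comp, module.seeds & comp, "agglomerative-split"))
    return results


# ---------------------------------------------------------------------------
# Step 4: pruning


def prune_protruding_edges(
    module: CandidateModule, seeds: Iterable[str], graph: nx.Graph
) -> CandidateModule:
    """Iteratively strip non-seed leaf nodes (and their edges).

    Protruding branches that do not end in an input metabolite contribute
    nothing to the activity score and are removed.
    """
    seeds = set(seeds)
    sub = nx.Graph(graph.subgraph(module.nodes))
    while True:
        leaves = [n for n, d in sub.degree if d <= 1 and n not in seeds and sub.number_of_nodes() > 1]
        if not leaves:
            break
        sub.remove_nodes_from(leaves)
    nodes = frozenset(sub.nodes)
    return CandidateModule(nodes, frozenset(seeds & nodes), module.provenance)


# ---------------------------------------------------------------------------
# Step 5: scoring


def newman_girvan_modularity(module: CandidateModule, graph: nx.Graph) -> float:
    """Single-community Newman-Girvan modularity against the whole network.

    Q = E_M/E - (sum_{i in M} k_i / 2E)^2, with degrees k_i and edge count E
    taken from the full reference network.
    """
    E = graph.number_of_edges()
    if E == 0:
        raise ValueError("reference network has no edges; modularity undefined")
    E_M = module.internal_edges(graph)
    k_sum = sum(graph.degree[n] for n in module.nodes)
    return E_M / E - (k_sum / (2.0 * E)) ** 2


def default_scorer(m: int, N: int, Q: float) -> float:
    """Default activity score: enrichment (m/N) times modularity, with a
    1/sqrt(N) factor to counteract the size bias of raw modularity."""
    return (m / N) * Q / np.sqrt(N)


Scorer = Callable[[int, int, float], float]


def activity_score(
    module: CandidateModule, graph: nx.Graph, scorer: Scorer = default_scorer
) -> float:
    """Activity score of a candidate module (must contain input metabolites)."""
    if module.m == 0:
        raise ValueError("modules without input metabolites are never scored")
    return float(scorer(module.m, module.N, newman_girvan_modularity(module, graph)))


def find_candidate_modules(
    graph: nx.Graph,
    seeds: Iterable[str],
    max_steps: int = 4,
    min_size: int = MIN_MODULE_SIZE,
    min_seeds: int = MIN_SEEDS,
    splitter: Callable = spectral_split,
    scorer: Scorer = default_scorer,
) -> list[ScoredModule]:
    """Steps 2-5 in one sweep: extract, split, prune, deduplicate, score."""
    seeds = set(seeds)
    subnets = extract_connecting_subnetworks(graph, seeds, max_steps, min_size, min_seeds)
    candidates: dict[frozenset[str], CandidateModule] = {}
    for sn in subnets:
        for cand in splitter(sn, graph, min_size):
            pruned = prune_protruding_edges(cand, seeds, graph)
            if pruned.N >= min_size and pruned.m >= min_seeds and pruned.nodes not in candidates:
                candidates[pruned.nodes] = pruned
    return [
        ScoredModule(c, newman_girvan_modularity(c, graph), activity_score(c, graph, scorer))
        for c in candidates.values()
    ]


# ---------------------------------------------------------------------------
# Steps 6-8: permutation null, Gamma calibration, p-values


def build_null_module_scores(
    L_ref: FeatureTable,
    n_perm: int,
    sig_size: int,
    *,
    graph: nx.Graph,
    index: TheoreticalIndex,
    ppm_tol: float = 10.0,
    max_steps: int = 4,
    min_size: int = MIN_MODULE_SIZE,
    min_seeds: int = MIN_SEEDS,
    splitter: Callable = spectral_split,
    scorer: Scorer = default_scorer,
    rng: np.random.Generator | None = None,
) -> list[float]:
    """Pooled activity scores of modules arising from random feature draws.

    Each permutation draws ``sig_size`` features uniformly without
    replacement from the reference list (unmatched features included),
    reruns matching and the module search, and contributes every candidate
    score to one pooled null.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if sig_size > len(L_ref):
        raise ValueError("sig_size cannot exceed the reference list size")
    rng = rng if rng is not None else np.random.default_rng()
    mz_all = L_ref.mz
    scores: list[float] = []
    for _ in range(n_perm):
        idx = rng.choice(len(L_ref), size=sig_size, replace=False)
        recs = index.lookup(mz_all[idx], [L_ref.features[i].feature_id for i in idx], ppm_tol)
        perm_seeds = {r.metabolite_id for r in recs}
        for sm in find_candidate_modules(
            graph, perm_seeds, max_steps, min_size, min_seeds, splitter, scorer
        ):
            scores.append(sm.A)
    if not scores:
        logger.warning("permutation null is empty: no random features matched any metabolite")
    return scores


@dataclass
class GammaNull:
    """A permutation null summarized as a fitted Gamma distribution.

    ``fallback`` marks pools too small or degenerate for a stable MLE, in
    which case the empirical pool is used for tail probabilities.
    """

    shape: float | None
    scale: float | None
    n_samples: int
    samples: np.ndarray
    fitted_by: str = "MLE"
    fallback: bool = False
    n_dropped: int = 0


def fit_gamma_mle(samples: Sequence[float], min_samples: int = MIN_GAMMA_SAMPLES) -> GammaNull:
    """Two-parameter Gamma MLE over the strictly positive samples.

    Non-positive values are dropped (and counted).  Fewer than
    ``min_samples`` positives, or a degenerate pool, triggers the empirical
    fallback instead of a crash.
    """
    arr = np.asarray(samples, dtype=float)
    pos = arr[arr > 0]
    n_dropped = arr.size - pos.size
    if n_dropped:
        logger.info("dropped %d non-positive scores before Gamma fit", n_dropped)
    if pos.size < min_samples or np.ptp(pos) < 1e-12:
        return GammaNull(None, None, pos.size, pos, fallback=True, n_dropped=n_dropped)
    try:
        shape, _, scale = stats.gamma.fit(pos, floc=0.0)
    except Exception:  # optimizer failure
        return GammaNull(None, None, pos.size, pos, fallback=True, n_dropped=n_dropped)
    if not (np.isfinite(shape) and np.isfinite(scale) and shape > 0 and scale > 0):
        return GammaNull(None, None, pos.size, pos, fallback=True, n_dropped=n_dropped)
    return GammaNull(float(shape), float(scale), pos.size, pos, n_dropped=n_dropped)


def score_to_pvalue(score: float, null: GammaNull) -> float:
    """Upper-tail probability of a module score under the permutation null."""
    if null.fallback:
        n = null.samples.size
        return (1.0 + int(np.sum(null.samples >= score))) / (1.0 + n)
    p = float(stats.gamma.sf(score, null.shape, scale=null.scale))
    return min(max(p, 5e-324), 1.0)
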