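"""Pathway enrichment with permutation-calibrated p-values.

Enrichment of tentative metabolites on each pathway is tested with Fisher's
exact test (right tail of the hypergeometric distribution) and its more
conservative EASE variant (one hit removed before testing, which penalizes
pathways with very few hits).  Two corrections specific to untargeted
metabolomics data apply throughout:

* the *smaller-of* rule — because one m/z feature may tentatively match
  several metabolites of the same pathway, the overlap count k is the
  smaller of (overlapping metabolites, distinct supporting features);
* pathway size K and the universe N are restricted to metabolites matchable
  from the reference feature list, so the test reflects the analytical
  coverage of the experiment rather than the whole model.

Significance is then calibrated by permutation: random feature lists of the
same size as the significant list are drawn from the reference list, their
per-pathway Fisher p-values pooled across all pathways and permutations,
and a Gamma distribution fitted (MLE) to the pool.  The adjusted p-value of
a pathway is the fitted null's probability of a p-value at least as small
as the observed EASE score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matching import FeatureTable, MatchMap, TheoreticalIndex
from .model_io import MetabolicModel, Pathway, pathway_universe_size
from .modules import GammaNull, fit_gamma_mle

__all__ = [
    "EnrichmentTable",
    "PathwayResult",
    "overlap_count",
    "fisher_right_tail",
    "ease_score",
    "enrich_pathways",
    "build_null_pathway_pvalues",
    "fit_pathway_null",
    "pathway_significance",
]


@dataclass(frozen=True)
class EnrichmentTable:
    """A 2x2 enrichment configuration: k of n selected fall in a category of
    size K within a universe of size N_tot."""

    k: int
    n: int
    K: int
    N_tot: int

    def __post_init__(self) -> None:
        ok = 0 <= self.k <= min(self.n, self.K) and self.n <= self.N_tot and self.K <= self.N_tot
        if not ok:
            raise ValueError(f"invalid enrichment table {self}")


@dataclass
class PathwayResult:
    pathway_id: str
    name: str
    table: EnrichmentTable
    fet_p: float
    ease_p: float
    adjusted_p: float | None
    overlap_metabolites: frozenset[str]
    supporting_features: frozenset[str]


def overlap_count(
    pathway_universe: frozenset[str] | set[str],
    matched: MatchMap,
) -> tuple[int, frozenset[str], frozenset[str]]:
    """Overlap k of matched metabolites with one pathway, smaller-of rule.

    Returns (k, overlapping metabolite ids, distinct supporting feature
    ids); k = min of the two cardinalities, since a single feature matching
    several pathway members would otherwise inflate the overlap.
    """
    overlap = frozenset(matched.metabolites & set(pathway_universe))
    feats = frozenset(matched.features_of(overlap))
    return min(len(overlap), len(feats)), overlap, feats


def fisher_right_tail(t: EnrichmentTable) -> float:
    """P(X >= k) for X ~ Hypergeometric(N_tot, K, n) — Fisher's exact test."""
    return float(stats.hypergeom.sf(t.k - 1, t.N_tot, t.K, t.n))


def ease_score(t: EnrichmentTable) -> float:
    """Conservative EASE variant: Fisher's right tail with one hit removed."""
    return fisher_right_tail(EnrichmentTable(max(t.k - 1, 0), t.n, t.K, t.N_tot))


def enrich_pathways(
    model: MetabolicModel,
    matched_sig: MatchMap,
    matchable_ref: frozenset[str] | set[str],
) -> list[PathwayResult]:
    """FET + EASE for every pathway with a non-empty matchable universe.

    ``matchable_ref`` is the set of metabolites matchable from the reference
    feature list; it defines both the universe size N_tot and each pathway
    size K.  ``adjusted_p`` is left unset here (see
    :func:`pathway_significance`).
    """
    universe = frozenset(matchable_ref)
    n = len(matched_sig.metabolites & universe)
    results = []
    for pw in model.pathways:
        pw_universe = pw.metabolite_ids & universe
        K = len(pw_universe)
        if K == 0:
            continue
        k, overlap, feats = overlap_count(pw_universe, matched_sig)
        t = EnrichmentTable(min(k, n, K), n, K, len(universe))
        results.append(
            PathwayResult(
                pw.id, pw.name, t,
                fet_p=fisher_right_tail(t),
                ease_p=ease_score(t),
                adjusted_p=None,
                overlap_metabolites=overlap,
                supporting_features=feats,
            )
        )
    return results


def build_null_pathway_pvalues(
    L_ref: FeatureTable,
    n_perm: int,
    sig_size: int,
    model: MetabolicModel,
    *,
    index: TheoreticalIndex,
    ppm_tol: float = 10.0,
    rng: np.random.Generator | None = None,
) -> list[float]:
    """Pooled per-pathway Fisher p-values under random draws from L_ref.

    All p-values from all pathways and all permutations enter one pool (not
    only each permutation's minimum), because metabolic pathways vary
    greatly in size and organization.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if sig_size > len(L_ref):
        raise ValueError("sig_size cannot exceed the reference list size")
    rng = rng if rng is not None else np.random.default_rng()
    matchable = _matchable_universe(model, L_ref, index, ppm_tol)
    mz_all = L_ref.mz
    pool: list[float] = []
    for _ in range(n_perm):
        idx = rng.choice(len(L_ref), size=sig_size, replace=False)
        recs = index.lookup(mz_all[idx], [L_ref.features[i].feature_id for i in idx], ppm_tol)
        pool.extend(r.fet_p for r in enrich_pathways(model, MatchMap(recs), matchable))
    return pool


def _matchable_universe(
    model: MetabolicModel, L_ref: FeatureTable, index: TheoreticalIndex, ppm_tol: float
) -> frozenset[str]:
    recs = index.lookup(L_ref.mz, L_ref.feature_ids, ppm_tol)
    return frozenset(r.metabolite_id for r in recs)


def fit_pathway_null(null_pool: Sequence[float]) -> GammaNull:
    """Gamma MLE over the pooled permutation p-values (empirical fallback)."""
    return fit_gamma_mle(null_pool)


def pathway_significance(ease_p: float, null: GammaNull) -> float:
    """Adjusted p-value: null probability of a p-value at least as small.

    The fitted Gamma's CDF is evaluated at the observed EASE score; with the
    empirical fallback, the rank of the EASE score within the pool is used.
    """
    if null.fallback:
        n = null.samples.size
        return (1.0 + int(np.sum(null.samples <= ease_p))) / (1.0 + n)
    p = float(stats.gamma.cdf(ease_p, null.shape, scale=null.scale))
    return min(max(p, 5e-324), 1.0)


def pathway_report(results: Sequence[PathwayResult]) -> pd.DataFrame:
    """Tab-ready report, sorted by adjusted p-value then Fisher p-value."""
    rows = [
        {
            "pathway_id": r.pathway_id,
            "name": r.name,
            "overlap_k": r.table.k,
            "pathway_size_K": r.table.K,
            "fet_p": r.fet_p,
            "ease_p": r.ease_p,
            "adjusted_p": r.adjusted_p,
            "metabolites": ";".join(sorted(r.overlap_metabolites)),
            "features": ";".join(sorted(r.supporting_features)),
        }
        for r in results
    ]
    df = pd.DataFrame(rows, columns=[
        "pathway_id", "name", "overlap_k", "pathway_size_K",
        "fet_p", "ease_p", "adjusted_p", "metabolites", "features",
    ])
    return df.sort_values(["adjusted_p", "fet_p", "pathway_id"], na_position="last").reset_index(drop=True)
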