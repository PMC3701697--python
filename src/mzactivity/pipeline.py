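"""End-to-end orchestration: load -> match -> modules -> pathways -> network.

One permutation loop serves both the module-score null and the pathway
p-value null (the same random draws from the reference list), halving the
permutation cost.  Everything downstream of the RNG seed is deterministic,
and the full run configuration is serialized next to the reports for
reproducibility.

Also hosts the preprocessing utilities for raw intensity tables: intensity
floor filtering, missing-value imputation, log2 transform, in-class
coefficient-of-variation filtering, and dual t-test feature selection.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import matching, modules, network, pathways
from .matching import FeatureTable, MatchMap, TheoreticalIndex, build_derivative_table
from .model_io import MetabolicModel, load_model, to_metabolite_graph
from .modules import ScoredModule, default_scorer, spectral_split
from .network import ActivityNetwork, build_activity_network, export_network
from .pathways import PathwayResult, enrich_pathways, fit_pathway_null, pathway_significance

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "PipelineResult",
    "select_significant",
    "preprocess_features",
    "dual_ttest_select",
    "analyze",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """All tunable parameters of one run, serializable to JSON."""

    model_path: str = ""
    ref_path: str = ""
    sig_path: str = ""
    input_path: str = ""          # single-file alternative to ref/sig
    cutoff: float = 0.05          # significance cutoff for single-file input
    mode: str = "positive"
    ppm_tol: float = 10.0
    n_perm: int = 100
    enforce_primary: bool = False
    max_steps: int = 4
    module_min_size: int = 3
    module_sig_p: float = 0.05    # module p-value feeding the network
    pathway_sig_p: float = 0.05   # adjusted pathway p feeding the network
    seed: int = 0
    out_prefix: str = "mzactivity_run"

    def validate(self) -> None:
        if self.mode not in ("positive", "negative"):
            raise ValueError(f"unknown ion mode {self.mode!r}")
        if not 0 < self.ppm_tol <= 1000:
            raise ValueError("ppm_tol out of range")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 1 <= self.max_steps <= 4:
            raise ValueError("max_steps must be in 1..4")
        if not 0 <= self.cutoff <= 1:
            raise ValueError("cutoff must be a probability")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def select_significant(table: FeatureTable, cutoff: float) -> tuple[FeatureTable, FeatureTable]:
    """Split one feature table into (L_sig, L_ref) by a p-value cutoff."""
    if any(f.p_value is None for f in table):
        raise ValueError("feature table has missing p_value entries; cannot select")
    sig_idx = [i for i, f in enumerate(table) if f.p_value < cutoff]
    if not sig_idx:
        logger.warning("significance cutoff %g selects no features", cutoff)
    return table.subset(sig_idx, role="significant"), table


def preprocess_features(
    raw: pd.DataFrame,
    classes: Mapping[str, Sequence[str]],
    intensity_floor: float = 10_000.0,
    impute_value: float = 1_000.0,
    cv_max: float = 0.2,
) -> pd.DataFrame:
    """Standard intensity-table cleanup, applied in order.

    1. drop features whose intensity stays below ``intensity_floor`` in
       every sample class;
    2. impute missing intensities to ``impute_value``;
    3. log2-transform;
    4. drop features whose in-class coefficient of variation, averaged over
       classes, exceeds ``cv_max``.

    ``classes`` maps a class label to its intensity column names.  Removal
    counts are logged.
    """
    if not classes:
        raise ValueError("no sample classes given")
    cols = [c for cls in classes.values() for c in cls]
    missing = [c for c in cols if c not in raw.columns]
    if missing:
        raise ValueError(f"intensity columns not in table: {missing}")
    df = raw.copy()

    above = pd.DataFrame(
        {label: (df[list(cls)].max(axis=1) >= intensity_floor) for label, cls in classes.items()}
    )
    keep = above.any(axis=1)
    logger.info("intensity floor removed %d features", int((~keep).sum()))
    df = df[keep]

    df[cols] = df[cols].fillna(impute_value)
    df[cols] = np.log2(df[cols])

    cvs = pd.DataFrame(
        {
            label: df[list(cls)].std(axis=1, ddof=1) / df[list(cls)].mean(axis=1)
            for label, cls in classes.items()
        }
    )
    keep = cvs.mean(axis=1) <= cv_max
    logger.info("CV filter removed %d features", int((~keep).sum()))
    return df[keep].reset_index(drop=True)


def dual_ttest_select(
    df: pd.DataFrame,
    case_cols: Sequence[str],
    control_cols_a: Sequence[str],
    control_cols_b: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided t-tests of case vs two control groups; a feature is
    significant only when p < alpha against *both* controls.

    Returns the input with added columns p_vs_a, p_vs_b, significant.
    """
    out = df.copy()
    case = df[list(case_cols)].to_numpy(dtype=float)
    pa = stats.ttest_ind(case, df[list(control_cols_a)].to_numpy(dtype=float), axis=1).pvalue
    pb = stats.ttest_ind(case, df[list(control_cols_b)].to_numpy(dtype=float), axis=1).pvalue
    out["p_vs_a"] = pa
    out["p_vs_b"] = pb
    out["significant"] = (pa < alpha) & (pb < alpha)
    return out


@dataclass
class AnalysisResult:
    """In-memory result bundle of one analysis."""

    scored_modules: list[ScoredModule]
    module_null: modules.GammaNull
    pathway_results: list[PathwayResult]
    pathway_null: modules.GammaNull
    activity_network: ActivityNetwork
    match_map_ref: MatchMap
    match_map_sig: MatchMap
    n_perm: int
    seed: int

    @property
    def significant_modules(self) -> list[ScoredModule]:
        return [m for m in self.scored_modules if m.p_value is not None]


def analyze(
    model: MetabolicModel,
    L_ref: FeatureTable,
    L_sig: FeatureTable,
    *,
    mode: str = "positive",
    ppm_tol: float = 10.0,
    n_perm: int = 100,
    enforce_primary: bool = False,
    max_steps: int = 4,
    module_min_size: int = 3,
    module_sig_p: float = 0.05,
    pathway_sig_p: float = 0.05,
    splitter: Callable = spectral_split,
    scorer: Callable = default_scorer,
    seed: int = 0,
) -> AnalysisResult:
    """Run matching, module analysis, pathway analysis and network assembly.

    The permutation loop is shared: each random draw from L_ref feeds both
    the module-score pool and the pathway p-value pool.
    """
    rng = np.random.default_rng(seed)
    rules = build_derivative_table(mode)
    index = TheoreticalIndex(model, rules)
    graph = to_metabolite_graph(model)

    map_ref = matching.match_features(
        L_ref, model, mode, ppm_tol, enforce_primary=enforce_primary, index=index
    )
    map_sig = matching.match_features(
        L_sig, model, mode, ppm_tol,
        enforce_primary=enforce_primary, reference=L_ref, index=index,
    )
    seeds = map_sig.metabolites
    matchable_ref = frozenset(map_ref.metabolites)
    logger.info(
        "matched %d/%d reference and %d/%d significant features to %d tentative metabolites",
        len(map_ref.features), len(L_ref), len(map_sig.features), len(L_sig), len(seeds),
    )

    observed = modules.find_candidate_modules(
        graph, seeds, max_steps, module_min_size, splitter=splitter, scorer=scorer
    )
    logger.info("found %d candidate modules from user data", len(observed))

    sig_size = len(L_sig)
    mz_all = L_ref.mz
    null_scores: list[float] = []
    null_pvals: list[float] = []
    for _ in range(n_perm):
        idx = rng.choice(len(L_ref), size=sig_size, replace=False)
        recs = index.lookup(mz_all[idx], [L_ref.features[i].feature_id for i in idx], ppm_tol)
        perm_map = MatchMap(recs)
        for sm in modules.find_candidate_modules(
            graph, perm_map.metabolites, max_steps, module_min_size,
            splitter=splitter, scorer=scorer,
        ):
            null_scores.append(sm.A)
        null_pvals.extend(
            r.fet_p for r in enrich_pathways(model, perm_map, matchable_ref)
        )
    logger.info("permutations produced %d random modules", len(null_scores))

    module_null = modules.fit_gamma_mle(null_scores)
    scored = [
        ScoredModule(sm.module, sm.Q, sm.A, modules.score_to_pvalue(sm.A, module_null))
        for sm in observed
    ]
    scored.sort(key=lambda s: (s.p_value, -s.A, sorted(s.module.nodes)))

    pathway_null = fit_pathway_null(null_pvals)
    pw_results = enrich_pathways(model, map_sig, matchable_ref)
    for r in pw_results:
        r.adjusted_p = pathway_significance(r.ease_p, pathway_null)
    pw_results.sort(key=lambda r: (r.adjusted_p, r.fet_p, r.pathway_id))

    sig_modules = [s for s in scored if s.p_value < module_sig_p]
    sig_pathways = [r for r in pw_results if r.adjusted_p < pathway_sig_p]
    net = build_activity_network(
        sig_modules, sig_pathways, map_ref, graph, rules, enforce_primary=enforce_primary
    )
    logger.info(
        "%d significant modules, %d significant pathways, activity network of %d metabolites",
        len(sig_modules), len(sig_pathways), len(net.metabolites),
    )
    return AnalysisResult(
        scored, module_null, pw_results, pathway_null, net,
        map_ref, map_sig, n_perm, seed,
    )


def module_report(result: AnalysisResult, match_map_sig: MatchMap) -> pd.DataFrame:
    by_met = match_map_sig.by_metabolite()
    rows = []
    for i, sm in enumerate(result.scored_modules):
        feats = sorted({r.feature_id for mid in sm.module.seeds for r in by_met.get(mid, [])})
        rows.append(
            {
                "module_id": f"module_{i}",
                "N": sm.module.N,
                "m": sm.module.m,
                "E_M": None,  # filled by caller with graph access if wanted
                "A": sm.A,
                "p_value": sm.p_value,
                "metabolites": ";".join(sorted(sm.module.nodes)),
                "features": ";".join(feats),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["module_id", "N", "m", "E_M", "A", "p_value", "metabolites", "features"],
    )


def run_pipeline(config: RunConfig, model: MetabolicModel | None = None) -> dict[str, Path]:
    """Full run from files to report bundle; returns the written paths.

    Outputs: <prefix>.modules.tsv, <prefix>.pathways.tsv,
    <prefix>.network.graphml, <prefix>.network.sif, <prefix>.matches.tsv,
    <prefix>.config.json, <prefix>.log.
    """
    config.validate()
    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    log_path = prefix.with_suffix(".log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("mzactivity")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    t0 = time.time()
    try:
        try:
            if model is None:
                model = load_model(config.model_path)
        except Exception as exc:
            raise RuntimeError(f"[model_io] failed to load model: {exc}") from exc
        try:
            if config.input_path:
                table = FeatureTable.from_tsv(config.input_path)
                L_sig, L_ref = select_significant(table, config.cutoff)
            else:
                L_ref = FeatureTable.from_tsv(config.ref_path, role="reference")
                L_sig = FeatureTable.from_tsv(config.sig_path, role="significant")
        except Exception as exc:
            raise RuntimeError(f"[feature_input] failed to read feature tables: {exc}") from exc

        result = analyze(
            model, L_ref, L_sig,
            mode=config.mode, ppm_tol=config.ppm_tol, n_perm=config.n_perm,
            enforce_primary=config.enforce_primary, max_steps=config.max_steps,
            module_min_size=config.module_min_size,
            module_sig_p=config.module_sig_p, pathway_sig_p=config.pathway_sig_p,
            seed=config.seed,
        )

        graph = to_metabolite_graph(model)
        mod_df = module_report(result, result.match_map_sig)
        mod_df["E_M"] = [
            sm.module.internal_edges(graph) for sm in result.scored_modules
        ]
        paths: dict[str, Path] = {}
        paths["modules"] = Path(f"{prefix}.modules.tsv")
        mod_df.to_csv(paths["modules"], sep="\t", index=False)
        paths["pathways"] = Path(f"{prefix}.pathways.tsv")
        pathways.pathway_report(result.pathway_results).to_csv(
            paths["pathways"], sep="\t", index=False
        )
        paths["network_graphml"] = Path(f"{prefix}.network.graphml")
        export_network(result.activity_network, "graphml", paths["network_graphml"])
        paths["network_sif"] = Path(f"{prefix}.network.sif")
        export_network(result.activity_network, "sif", paths["network_sif"])
        paths["matches"] = Path(f"{prefix}.matches.tsv")
        result.match_map_ref.to_dataframe().to_csv(paths["matches"], sep="\t", index=False)
        paths["config"] = Path(f"{prefix}.config.json")
        config.to_json(paths["config"])
        logger.info("run complete in %.1f s", time.time() - t0)
        paths["log"] = log_path
        return paths
    finally:
        handler.close()
        root.removeHandler(handler)
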