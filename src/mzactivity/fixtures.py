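"""Synthetic metabolic models and feature tables with known ground truth.

The generator emulates, at toy scale, the two structures the method relies
on: a modular metabolite network (a planted-partition graph realized as
1-reactant/1-product reactions, one pathway per block) and an LC/MS feature
table in which

* each metabolite emits its primary ion with high probability, plus
  optional C13 / sodium-adduct forms, at theoretical m/z with sub-ppm
  jitter;
* decoy features (defaulting to three times the true-feature count, since
  most real features match nothing) are drawn clear of every theoretical
  m/z window;
* the features of one planted block carry small p-values, so the
  significant list concentrates on one known module/pathway.

Metabolite masses are spaced widely enough that matching is unambiguous by
construction; everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .matching import (
    FeatureTable,
    MzFeature,
    build_derivative_table,
    compute_derivative_mz,
)
from .model_io import MetabolicModel, Metabolite, Pathway, Reaction

__all__ = ["FixtureTruth", "generate_toy_model", "simulate_feature_table"]


@dataclass
class FixtureTruth:
    """Ground truth of one synthetic experiment."""

    planted_nodes: tuple[str, ...] = ()
    planted_pathway: str = ""
    blocks: dict[str, tuple[str, ...]] = field(default_factory=dict)
    emitted_forms: dict[str, tuple[str, ...]] = field(default_factory=dict)
    n_decoys: int = 0
    effect: float = 0.0
    sig_alpha: float = 0.05
    ppm_jitter: float = 0.0
    seed: int = 0


def generate_toy_model(
    n_modules: int = 4,
    module_size: int = 6,
    p_in: float = 0.8,
    p_out: float = 0.02,
    mass_range: tuple[float, float] = (100.0, 800.0),
    min_spacing: float = 0.05,
    seed: int = 0,
) -> tuple[MetabolicModel, FixtureTruth]:
    """Planted-partition metabolic model with one pathway per block.

    Each block is guaranteed internally connected (a spanning path plus
    random within-block edges at rate ``p_in``); blocks are bridged at rate
    ``p_out``.  Every edge becomes a 1-reactant/1-product reaction with a
    synthetic EC number.  Metabolite masses are drawn uniquely from
    ``mass_range`` with pairwise separation > ``min_spacing`` so matching
    is unambiguous.
    """
    if not p_in > p_out:
        raise ValueError("p_in must exceed p_out")
    if module_size < 3:
        raise ValueError("module_size must be >= 3")
    rng = np.random.default_rng(seed)
    n_total = n_modules * module_size
    lo, hi = mass_range
    if (hi - lo) / min_spacing < 3 * n_total:
        raise ValueError(
            f"mass range {mass_range} cannot hold {n_total} masses at spacing {min_spacing}"
        )

    masses = _spaced_masses(rng, n_total, lo, hi, min_spacing, _EMISSION_DELTAS)
    ids = [f"M{b}_{i}" for b in range(n_modules) for i in range(module_size)]
    blocks = {
        f"P{b}": tuple(f"M{b}_{i}" for i in range(module_size)) for b in range(n_modules)
    }
    metabolites = {
        mid: Metabolite(mid, name=mid.lower(), mono_mass=float(mass))
        for mid, mass in zip(ids, masses)
    }

    edges: list[tuple[str, str]] = []
    for b in range(n_modules):
        members = blocks[f"P{b}"]
        for i in range(len(members) - 1):  # spanning path keeps the block connected
            edges.append((members[i], members[i + 1]))
        for i in range(len(members)):
            for j in range(i + 2, len(members)):
                if rng.random() < p_in:
                    edges.append((members[i], members[j]))
    block_list = list(blocks.values())
    for a in range(n_modules):
        for b in range(a + 1, n_modules):
            for u in block_list[a]:
                for v in block_list[b]:
                    if rng.random() < p_out:
                        edges.append((u, v))

    reactions = [
        Reaction(f"R{n:04d}", (u,), (v,), (f"1.1.1.{n % 97 + 1}",))
        for n, (u, v) in enumerate(edges)
    ]
    pathways = [
        Pathway(pid, f"pathway {pid}", frozenset(members))
        for pid, members in blocks.items()
    ]
    model = MetabolicModel(metabolites, reactions, pathways, frozenset())
    truth = FixtureTruth(
        planted_nodes=blocks["P0"],
        planted_pathway="P0",
        blocks=blocks,
        seed=seed,
    )
    return model, truth


# Pairwise mass-shift differences among the emitted derivative forms
# (M+H, M(C13)+H, M+Na).  Masses are kept min_spacing clear of every other
# mass offset by each of these, so no emitted ion of one metabolite can fall
# into an emitted-form window of another.
_EMISSION_SHIFTS = (1.00728, 2.01064, 22.98922)
_EMISSION_DELTAS = tuple(
    sorted({round(a - b, 5) for a in _EMISSION_SHIFTS for b in _EMISSION_SHIFTS})
)


def _spaced_masses(
    rng: np.random.Generator,
    n: int,
    lo: float,
    hi: float,
    min_spacing: float,
    deltas: tuple[float, ...] = (0.0,),
) -> np.ndarray:
    """Uniform masses; every (mass + delta) stays min_spacing clear of the rest."""
    masses: list[float] = []
    for _ in range(100 * n):
        cand = rng.uniform(lo, hi)
        ok = all(
            abs(cand - (m + d)) > min_spacing for m in masses for d in deltas
        )
        if ok:
            masses.append(cand)
            if len(masses) == n:
                return np.array(masses)
    raise ValueError("could not place masses with the requested spacing")


_DEFAULT_FORM_PROBS: Mapping[str, float] = {
    "M+H[1+]": 0.95,
    "M(C13)+H[1+]": 0.5,
    "M+Na[1+]": 0.3,
}


def simulate_feature_table(
    model: MetabolicModel,
    truth: FixtureTruth,
    n_decoys: int | None = None,
    sig_alpha: float = 0.05,
    effect: float = 2.0,
    forms_per_metabolite: Mapping[str, float] = _DEFAULT_FORM_PROBS,
    ppm_jitter: float = 0.3,
    mode: str = "positive",
    ppm_tol: float = 10.0,
    seed: int = 0,
) -> tuple[FeatureTable, FeatureTable, FixtureTruth]:
    """Simulate (L_ref, L_sig) with the planted block differentially changed.

    ``effect`` separates planted from background p-values in orders of
    magnitude: planted features get p = u * 10**(-effect) with u ~ U(0,1),
    background features p = u.  effect = 0 therefore makes the planted
    block indistinguishable from noise, while ``effect = inf`` is the
    noise-free limit (planted p ~ 0, all background p above ``sig_alpha``).
    Decoy masses avoid a 3x-tolerance window around every theoretical
    derivative m/z of every model metabolite.
    """
    rng = np.random.default_rng(seed)
    rules = {r.form_name: r for r in build_derivative_table(mode)}
    for form in forms_per_metabolite:
        if form not in rules:
            raise ValueError(f"unknown derivative form {form!r}")
    planted = set(truth.planted_nodes)
    noise_free = np.isinf(effect)

    def draw_p(is_planted: bool) -> float:
        if noise_free:
            return 1e-12 if is_planted else rng.uniform(sig_alpha, 1.0)
        u = rng.uniform()
        return u * 10.0 ** (-effect) if is_planted else u

    features: list[MzFeature] = []
    emitted: dict[str, list[str]] = {}
    counter = 0
    for mid in sorted(model.metabolites):
        met = model.metabolites[mid]
        if not met.matchable:
            continue
        for form, prob in forms_per_metabolite.items():
            if rng.random() >= prob:
                continue
            theo = compute_derivative_mz(met.mono_mass, rules[form])
            mz = theo * (1.0 + rng.uniform(-ppm_jitter, ppm_jitter) * 1e-6)
            features.append(
                MzFeature(
                    feature_id=f"F{counter:05d}",
                    mz=mz,
                    rtime=float(rng.uniform(30.0, 1200.0)),
                    p_value=draw_p(mid in planted),
                    statistic=float(rng.normal(3.0 if mid in planted else 0.0, 1.0)),
                )
            )
            emitted.setdefault(mid, []).append(form)
            counter += 1

    n_true = counter
    if n_decoys is None:
        n_decoys = 3 * n_true
    all_theo = np.sort(
        [
            compute_derivative_mz(met.mono_mass, rule)
            for met in model.metabolites.values()
            if met.matchable
            for rule in build_derivative_table(mode)
        ]
    )
    lo = float(all_theo.min() - 2.0)
    hi = float(all_theo.max() + 2.0)
    guard = 3.0 * ppm_tol * 1e-6
    placed = 0
    while placed < n_decoys:
        cand = rng.uniform(lo, hi)
        j = np.searchsorted(all_theo, cand)
        near = [all_theo[i] for i in (j - 1, j) if 0 <= i < all_theo.size]
        if any(abs(cand - t) <= guard * t for t in near):
            continue
        features.append(
            MzFeature(
                feature_id=f"F{counter:05d}",
                mz=cand,
                rtime=float(rng.uniform(30.0, 1200.0)),
                p_value=draw_p(False),
                statistic=float(rng.normal(0.0, 1.0)),
            )
        )
        counter += 1
        placed += 1

    L_ref = FeatureTable(features, role="reference")
    sig_idx = [i for i, f in enumerate(features) if f.p_value is not None and f.p_value < sig_alpha]
    L_sig = L_ref.subset(sig_idx, role="significant")
    filled = FixtureTruth(
        planted_nodes=truth.planted_nodes,
        planted_pathway=truth.planted_pathway,
        blocks=truth.blocks,
        emitted_forms={k: tuple(v) for k, v in emitted.items()},
        n_decoys=n_decoys,
        effect=effect,
        sig_alpha=sig_alpha,
        ppm_jitter=ppm_jitter,
        seed=seed,
    )
    return L_ref, L_sig, filled
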