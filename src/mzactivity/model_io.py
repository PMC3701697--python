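"""Metabolic model loading and the metabolite-centric reference network.

A genome-scale metabolic model (metabolites, reactions, enzymes, pathway
definitions) is the prior knowledge base of the whole method.  Because LC/MS
metabolomics measures metabolites only, the model is converted to an
undirected *metabolite-centric* graph before any statistics: nodes are
metabolites, and each reaction contributes an edge for every
(reactant, product) pair.  Ubiquitous "currency" compounds (water, ATP, ...)
are excluded from edges so that they cannot create biologically meaningless
shortcuts.  Enzyme EC numbers ride along as edge annotations for later
visualization; they play no role in the statistics.

The model interchange format is a small JSON dialect::

    {
      "metabolites": [{"id", "name", "mono_mass", "formula"}, ...],
      "reactions":   [{"id", "reactants": [...], "products": [...],
                       "enzymes": [...]}, ...],
      "pathways":    [{"id", "name", "metabolites": [...]}, ...],
      "currency":    [ids]            # optional
    }

Masses are neutral monoisotopic masses in Da.  Metabolites without a mass
are kept (they may be intermediate network nodes) but can never match an
observed m/z feature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "Metabolite",
    "Reaction",
    "Pathway",
    "MetabolicModel",
    "ModelFormatError",
    "ModelIntegrityError",
    "DEFAULT_CURRENCY",
    "load_model",
    "write_model",
    "to_metabolite_graph",
    "pathway_universe_size",
]

#: Common currency metabolites excluded from graph edges by default when a
#: model file carries no explicit "currency" list.  Matching is by exact id
#: or (case-insensitive) name.
DEFAULT_CURRENCY = frozenset(
    {
        "H2O", "H+", "CO2", "O2", "ATP", "ADP", "AMP",
        "NAD+", "NADH", "NADP+", "NADPH", "CoA",
        "phosphate", "diphosphate",
    }
)


class ModelFormatError(ValueError):
    """A model file does not parse under the JSON dialect."""


class ModelIntegrityError(ValueError):
    """A record references an id that does not resolve within the model."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    mono_mass: float | None = None  # neutral monoisotopic mass, Da
    formula: str | None = None

    def __post_init__(self) -> None:
        if self.mono_mass is not None and not self.mono_mass > 0:
            raise ModelFormatError(
                f"metabolite {self.id!r}: mono_mass must be > 0, got {self.mono_mass}"
            )

    @property
    def matchable(self) -> bool:
        """Whether this metabolite can ever match an m/z feature."""
        return self.mono_mass is not None


@dataclass(frozen=True)
class Reaction:
    id: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    enzymes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.reactants or not self.products:
            raise ModelFormatError(
                f"reaction {self.id!r}: reactants and products must be non-empty"
            )


@dataclass(frozen=True)
class Pathway:
    id: str
    name: str
    metabolite_ids: frozenset[str]


@dataclass
class MetabolicModel:
    """A metabolic model with referential integrity enforced on construction."""

    metabolites: dict[str, Metabolite]
    reactions: list[Reaction]
    pathways: list[Pathway]
    currency_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        ids = set(self.metabolites)
        for rxn in self.reactions:
            for mid in (*rxn.reactants, *rxn.products):
                if mid not in ids:
                    raise ModelIntegrityError(
                        f"reaction {rxn.id!r} references unknown metabolite {mid!r}"
                    )
        for pw in self.pathways:
            for mid in pw.metabolite_ids:
                if mid not in ids:
                    raise ModelIntegrityError(
                        f"pathway {pw.id!r} references unknown metabolite {mid!r}"
                    )

    @property
    def matchable_ids(self) -> frozenset[str]:
        """Ids of metabolites carrying a monoisotopic mass."""
        return frozenset(m.id for m in self.metabolites.values() if m.matchable)

    def pathway_by_id(self, pid: str) -> Pathway:
        for pw in self.pathways:
            if pw.id == pid:
                return pw
        raise KeyError(pid)


def _resolve_currency(model_ids: Mapping[str, Metabolite], declared: Iterable[str] | None) -> frozenset[str]:
    if declared is not None:
        return frozenset(declared)
    # Default list matches on id or name, case-insensitively.
    lowered = {c.lower() for c in DEFAULT_CURRENCY}
    return frozenset(
        m.id for m in model_ids.values()
        if m.id.lower() in lowered or m.name.lower() in lowered
    )


def load_model(path: str | Path, dialect: str = "json") -> MetabolicModel:
    """Load a metabolic model file.

    Raises :class:`ModelFormatError` on malformed records (naming the
    offending record) and :class:`ModelIntegrityError` on dangling ids.
    """
    if dialect != "json":
        raise ValueError(f"unsupported model dialect: {dialect!r}")
    path = Path(path)
    try:
        raw = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not valid JSON: {exc}") from exc
    return model_from_dict(raw)


def model_from_dict(raw: Mapping) -> MetabolicModel:
    metabolites: dict[str, Metabolite] = {}
    for rec in raw.get("metabolites", []):
        try:
            met = Metabolite(
                id=str(rec["id"]),
                name=str(rec.get("name", "")),
                mono_mass=(None if rec.get("mono_mass") is None else float(rec["mono_mass"])),
                formula=rec.get("formula"),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ModelFormatError(f"malformed metabolite record {rec!r}: {exc}") from exc
        if met.id in metabolites:
            raise ModelFormatError(f"duplicate metabolite id {met.id!r}")
        metabolites[met.id] = met

    reactions = []
    for rec in raw.get("reactions", []):
        try:
            reactions.append(
                Reaction(
                    id=str(rec["id"]),
                    reactants=tuple(rec["reactants"]),
                    products=tuple(rec["products"]),
                    enzymes=tuple(rec.get("enzymes", ())),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ModelFormatError(f"malformed reaction record {rec!r}: {exc}") from exc

    pathways = []
    for rec in raw.get("pathways", []):
        try:
            pathways.append(
                Pathway(
                    id=str(rec["id"]),
                    name=str(rec.get("name", rec["id"])),
                    metabolite_ids=frozenset(rec["metabolites"]),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ModelFormatError(f"malformed pathway record {rec!r}: {exc}") from exc

    currency = _resolve_currency(metabolites, raw.get("currency"))
    return MetabolicModel(metabolites, reactions, pathways, currency)


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "metabolites": [
            {"id": m.id, "name": m.name, "mono_mass": m.mono_mass, "formula": m.formula}
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "reactants": list(r.reactants),
                "products": list(r.products),
                "enzymes": list(r.enzymes),
            }
            for r in model.reactions
        ],
        "pathways": [
            {"id": p.id, "name": p.name, "metabolites": sorted(p.metabolite_ids)}
            for p in model.pathways
        ],
        "currency": sorted(model.currency_ids),
    }


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Serialize a model back to the JSON dialect (round-trip safe)."""
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1), encoding="utf-8")


def to_metabolite_graph(model: MetabolicModel) -> nx.Graph:
    """Convert a model to the undirected metabolite-centric network.

    Every reaction joins each (reactant, product) pair by an edge unless
    either end is a currency metabolite.  Parallel edges are merged, with
    reaction ids and enzyme ECs unioned on the surviving edge; self-loops
    are never created.  Non-currency metabolites appearing in any reaction
    become nodes even if all their potential edges were suppressed.
    """
    g = nx.Graph()
    currency = model.currency_ids
    for rxn in model.reactions:
        for mid in (*rxn.reactants, *rxn.products):
            if mid not in currency:
                g.add_node(mid)
        for u in rxn.reactants:
            if u in currency:
                continue
            for v in rxn.products:
                if v in currency or u == v:
                    continue
                if g.has_edge(u, v):
                    g[u][v]["reactions"].add(rxn.id)
                    g[u][v]["enzymes"].update(rxn.enzymes)
                else:
                    g.add_edge(u, v, reactions={rxn.id}, enzymes=set(rxn.enzymes))
    return g


def pathway_universe_size(pathway: Pathway, matchable: frozenset[str] | set[str]) -> int:
    """Size of a pathway restricted to experimentally visible metabolites.

    Pathway size for enrichment is defined against the metabolites that can
    be matched in the reference feature list, reflecting the analytical
    coverage of the experiment, never against the full model.
    """
    return len(pathway.metabolite_ids & set(matchable))
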