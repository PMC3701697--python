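"""Assembly of the experiment-specific activity network.

Metabolites predicted by significant modules and pathways are more likely
to be real.  They are collected, all their derivative forms are looked up
in the reference feature list, and a confidence rating filters for
qualified predictions:

* **high**   — the primary ion (M+H[1+] / M-H[-]) and its C13 isotopologue
  partner are both present;
* **medium** — the primary ion alone, or at least two distinct non-primary
  forms;
* **low**    — exactly one non-primary form (or nothing).

Qualified means high or medium; when primary-ion presence is enforced
("-z" semantics), a qualified metabolite must additionally show the primary
form.  Qualified metabolites carry over their connections (with enzyme EC
annotations) from the reference metabolite network, forming the activity
network.  Exports to GraphML, SIF and TSV are provided in place of figure
rendering, plus a utility comparing predictions with an independent
annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .matching import DerivativeRule, MatchMap
from .modules import ScoredModule
from .pathways import PathwayResult

__all__ = [
    "ConfidenceRating",
    "ActivityNetwork",
    "AgreementSummary",
    "rate_confidence",
    "build_activity_network",
    "export_network",
    "read_graphml",
    "compare_to_annotation",
]


@dataclass(frozen=True)
class ConfidenceRating:
    metabolite_id: str
    forms_present: Mapping[str, tuple[str, ...]]  # form -> supporting feature ids
    rating: str                                   # high | medium | low
    qualified: bool


def _primary_and_partner(rules: Sequence[DerivativeRule]) -> tuple[str, str | None]:
    primary = next(r.form_name for r in rules if r.is_primary)
    partner = next((r.form_name for r in rules if r.c13_of_primary), None)
    return primary, partner


def rate_confidence(
    metabolite_id: str,
    match_map_ref: MatchMap,
    rules: Sequence[DerivativeRule],
    enforce_primary: bool = False,
) -> ConfidenceRating:
    """Rate one metabolite by the derivative forms present in L_ref."""
    forms = {f: tuple(feats) for f, feats in match_map_ref.forms_of(metabolite_id).items()}
    primary, partner = _primary_and_partner(rules)
    has_primary = primary in forms
    non_primary = [f for f in forms if f != primary]
    if has_primary and partner is not None and partner in forms:
        rating = "high"
    elif has_primary or len(non_primary) >= 2:
        rating = "medium"
    else:
        rating = "low"
    qualified = rating in ("high", "medium")
    if enforce_primary:
        qualified = qualified and has_primary
    return ConfidenceRating(metabolite_id, forms, rating, qualified)


@dataclass
class ActivityNetwork:
    """Qualified predicted metabolites plus their reference-network edges."""

    graph: nx.Graph                                   # nodes annotated with rating etc.
    provenance: dict[str, list[str]]                  # node -> contributing module/pathway ids
    ratings: dict[str, ConfidenceRating]
    isolates: frozenset[str]                          # qualified but unconnected nodes

    @property
    def metabolites(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)


def build_activity_network(
    sig_modules: Sequence[ScoredModule],
    sig_pathways: Sequence[PathwayResult],
    match_map_ref: MatchMap,
    graph: nx.Graph,
    rules: Sequence[DerivativeRule],
    enforce_primary: bool = False,
    node_values: Mapping[str, float] | None = None,
) -> ActivityNetwork:
    """Union the metabolites of significant modules and pathways, filter by
    confidence, and induce their subgraph from the reference network.

    Qualified metabolites that end up without any connection are retained
    as flagged isolates.  Every node records which module(s)/pathway(s)
    contributed it.
    """
    provenance: dict[str, list[str]] = {}
    for i, sm in enumerate(sig_modules):
        for node in sm.module.nodes:
            provenance.setdefault(node, []).append(f"module:{i}")
    for pr in sig_pathways:
        for node in pr.overlap_metabolites:
            provenance.setdefault(node, []).append(f"pathway:{pr.pathway_id}")

    ratings = {
        mid: rate_confidence(mid, match_map_ref, rules, enforce_primary)
        for mid in sorted(provenance)
    }
    qualified = [mid for mid in sorted(provenance) if ratings[mid].qualified]

    net = nx.Graph()
    sub = graph.subgraph([q for q in qualified if q in graph])
    net.add_nodes_from(qualified)
    for u, v, data in sub.edges(data=True):
        net.add_edge(u, v, enzymes=sorted(data.get("enzymes", ())),
                     reactions=sorted(data.get("reactions", ())))
    for mid in qualified:
        rating = ratings[mid]
        net.nodes[mid]["rating"] = rating.rating
        net.nodes[mid]["forms"] = ";".join(sorted(rating.forms_present))
        net.nodes[mid]["provenance"] = ";".join(provenance[mid])
        feats = sorted({f for feats in rating.forms_present.values() for f in feats})
        net.nodes[mid]["features"] = ";".join(feats)
        if node_values and mid in node_values:
            net.nodes[mid]["value"] = float(node_values[mid])
    isolates = frozenset(n for n in net.nodes if net.degree[n] == 0)
    return ActivityNetwork(net, {k: provenance[k] for k in qualified},
                           {k: ratings[k] for k in qualified}, isolates)


def export_network(net: ActivityNetwork, fmt: str, path: str | Path) -> list[Path]:
    """Write an activity network to GraphML, SIF or TSV node/edge tables.

    Attribute export is lossless (lists flattened to ';'-joined strings);
    enzyme ECs are carried on edges.  Returns the written paths.
    """
    path = Path(path)
    if fmt == "graphml":
        g = nx.Graph()
        g.add_nodes_from(net.graph.nodes(data=True))
        for u, v, data in net.graph.edges(data=True):
            g.add_edge(u, v,
                       enzymes=";".join(data.get("enzymes", ())),
                       reactions=";".join(data.get("reactions", ())))
        nx.write_graphml(g, path)
        return [path]
    if fmt == "sif":
        lines = []
        for u, v, data in sorted(net.graph.edges(data=True)):
            enzymes = data.get("enzymes", ())
            relation = enzymes[0] if enzymes else "rxn"
            lines.append(f"{u}\t{relation}\t{v}")
        for iso in sorted(net.isolates):
            lines.append(iso)
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        return [path]
    if fmt == "tsv":
        node_path = path.with_suffix(".nodes.tsv")
        edge_path = path.with_suffix(".edges.tsv")
        nodes = pd.DataFrame(
            [{"metabolite_id": n, **d} for n, d in sorted(net.graph.nodes(data=True))]
        )
        edges = pd.DataFrame(
            [
                {"source": u, "target": v,
                 "enzymes": ";".join(d.get("enzymes", ())),
                 "reactions": ";".join(d.get("reactions", ()))}
                for u, v, d in sorted(net.graph.edges(data=True))
            ],
            columns=["source", "target", "enzymes", "reactions"],
        )
        nodes.to_csv(node_path, sep="\t", index=False)
        edges.to_csv(edge_path, sep="\t", index=False)
        return [node_path, edge_path]
    raise ValueError(f"unknown export format {fmt!r}; expected graphml, sif or tsv")


def read_graphml(path: str | Path) -> nx.Graph:
    """Read back a GraphML export (round-trip helper)."""
    return nx.read_graphml(Path(path))


@dataclass
class AgreementSummary:
    n_agreed: int
    n_disagreed: int
    n_not_annotated: int
    detail: pd.DataFrame  # metabolite_id, status, predicted_name, annotated_names

    @property
    def agreement_rate(self) -> float | None:
        denom = self.n_agreed + self.n_disagreed
        return None if denom == 0 else self.n_agreed / denom


def compare_to_annotation(
    predicted: ActivityNetwork,
    annotation: Mapping[str, str],
    metabolite_names: Mapping[str, str],
) -> AgreementSummary:
    """Compare predicted metabolites with an independent feature annotation.

    ``annotation`` maps feature ids to metabolite names from the original
    study.  A predicted metabolite whose supporting features carry no
    annotation cannot be compared and is counted ``not_annotated``
    (excluded from the agreement denominator); otherwise it is ``agreed``
    when any annotated name matches (case-insensitive) and ``disagreed``
    when none does.
    """
    rows = []
    n_agreed = n_disagreed = n_not = 0
    for mid in sorted(predicted.metabolites):
        feats = predicted.graph.nodes[mid].get("features", "")
        feat_ids = [f for f in feats.split(";") if f]
        names = {annotation[f] for f in feat_ids if f in annotation}
        predicted_name = metabolite_names.get(mid, mid)
        if not names:
            status = "not_annotated"
            n_not += 1
        elif predicted_name.casefold() in {n.casefold() for n in names}:
            status = "agreed"
            n_agreed += 1
        else:
            status = "disagreed"
            n_disagreed += 1
        rows.append(
            {"metabolite_id": mid, "status": status,
             "predicted_name": predicted_name, "annotated_names": ";".join(sorted(names))}
        )
    detail = pd.DataFrame(rows, columns=["metabolite_id", "status", "predicted_name", "annotated_names"])
    return AgreementSummary(n_agreed, n_disagreed, n_not, detail)
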