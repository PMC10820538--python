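"""Rule-network export as a bipartite item/rule graph.

Each retained rule becomes an intermediate rule node; antecedent items
point into it and it points to the consequent items, so multi-item
antecedents like ``E11, I10, N08 -> N18`` are encoded faithfully (a plain
item-to-item digraph cannot represent them). Node and edge insertion order
is deterministic. Serialized as GraphML plus a flat edge-list CSV; no
layout coordinates are computed.
"""

from __future__ import annotations

from typing import Sequence

import networkx as nx
import pandas as pd

from .arm import AssociationRule, rank_rules, read_rules_csv

__all__ = ["rules_to_graph", "write_graphml", "write_edgelist_csv", "graph_from_rules_csv"]


def rules_to_graph(rules: Sequence[AssociationRule]) -> nx.DiGraph:
    """Build the bipartite item/rule digraph for a set of retained rules.

    Item nodes carry ``kind='item'``; rule nodes carry ``kind='rule'`` and
    the rule's measures. Edges antecedent-item -> rule -> consequent-item
    carry the rule id.
    """
    g = nx.DiGraph()
    ranked = rank_rules(rules)
    for code in sorted({c for r in ranked for c in r.items}):
        g.add_node(code, kind="item", label=code)
    for idx, rule in enumerate(ranked, start=1):
        # content-based id: stable across measure rounding in exports
        rid = "rule:" + ",".join(sorted(rule.antecedent)) + "=>" + ",".join(
            sorted(rule.consequent)
        )
        g.add_node(
            rid,
            kind="rule",
            label=rule.label(),
            n=rule.count,
            support=rule.support,
            confidence=rule.confidence,
            lift=rule.lift,
            is_measure=rule.is_measure,
        )
        for code in sorted(rule.antecedent):
            g.add_edge(code, rid, rule=rid)
        for code in sorted(rule.consequent):
            g.add_edge(rid, code, rule=rid)
    return g


def write_graphml(g: nx.DiGraph, path) -> None:
    nx.write_graphml(g, path)


def write_edgelist_csv(g: nx.DiGraph, path) -> None:
    rows = [
        {"source": u, "target": v, "rule": d.get("rule", "")}
        for u, v, d in g.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "rule"]).to_csv(path, index=False)


def graph_from_rules_csv(path) -> nx.DiGraph:
    """Rebuild the rule graph from an exported rule table (information-preserving)."""
    from .arm import is_measure

    df = read_rules_csv(path)
    rules = [
        AssociationRule(
            antecedent=frozenset(str(row["antecedent"]).split(", ")),
            consequent=frozenset(str(row["consequent"]).split(", ")),
            count=int(row["n"]),
            support=float(row["support"]),
            confidence=float(row["confidence"]),
            lift=float(row["lift"]),
            is_measure=float(row["is"]),
        )
        for _, row in df.iterrows()
    ]
    return rules_to_graph(rules)
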