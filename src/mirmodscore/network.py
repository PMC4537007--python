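"""Bipartite miR-target network, module detection and connectivity statistics.

The degree of connectivity (DOC) of a miR is its number of integrated
target-mRNAs; for an mRNA, the number of miRs predicted to regulate it.
Per-stratum averages follow

    avg_doc      = 2 * n_edges / (n_mirs + n_mrnas)
    avg_mir_doc  = n_edges / n_mirs
    avg_mrna_doc = n_edges / n_mrnas

with edges counted within the stratum.  The No-Module row absorbs every
edge not internal to one of the ranked modules (cross-module edges and
edges among unassigned nodes alike) -- this attribution keeps the
within-stratum edge counts summing to the network total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NO_MODULE = "no_module"


@dataclass
class BipartiteNetwork:
    graph: nx.Graph

    @property
    def mir_nodes(self) -> set:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == "mir"}

    @property
    def mrna_nodes(self) -> set:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == "mrna"}

    @property
    def edges(self) -> set:
        return {(m, g) if self.graph.nodes[m]["kind"] == "mir" else (g, m)
                for m, g in self.graph.edges()}

    def degree_of(self, node) -> int:
        return self.graph.degree[node]


@dataclass
class ModuleAssignment:
    """node -> module label, ranked module labels, and per-module +1/-1 weights."""

    module_of: dict
    modules: list
    direction_weight: dict = field(default_factory=dict)

    def members(self, label: str) -> set:
        return {n for n, lab in self.module_of.items() if lab == label}


def build_network(edges: pd.DataFrame) -> BipartiteNetwork:
    """Build the bipartite graph from an integrated edge table.

    ``edges`` needs columns ``mir_id`` and ``mrna_id``.  Nodes are exactly
    the ids appearing in the edges (no isolated nodes by construction); an
    id occurring on both sides is an identifier collision and rejected.
    """
    if len(edges) == 0:
        raise ValueError("empty edge set")
    mirs = set(edges["mir_id"])
    mrnas = set(edges["mrna_id"])
    collision = mirs & mrnas
    if collision:
        raise ValueError(f"ids appear on both sides: {sorted(collision)[:5]}")
    g = nx.Graph()
    # sorted insertion keeps detection independent of hash randomization
    g.add_nodes_from(sorted(mirs), kind="mir", bipartite=0)
    g.add_nodes_from(sorted(mrnas), kind="mrna", bipartite=1)
    g.add_edges_from(
        sorted(edges[["mir_id", "mrna_id"]].itertuples(index=False)))
    logger.info("network: %d miRs, %d mRNAs, %d edges", len(mirs), len(mrnas),
                g.number_of_edges())
    return BipartiteNetwork(g)


def _avg_mir_degree(net: BipartiteNetwork, community: set) -> float:
    sub = net.graph.subgraph(community)
    mirs = [n for n in community if net.graph.nodes[n]["kind"] == "mir"]
    if not mirs:
        return 0.0
    return float(np.mean([sub.degree[m] for m in mirs]))


def detect_modules(net: BipartiteNetwork, method: str = "greedy",
                   n_top: int = 4, seed: int = 0) -> ModuleAssignment:
    """Community detection, ranking the top ``n_top`` communities as modules.

    Methods: ``greedy`` (modularity maximization, deterministic),
    ``components`` (connected components), ``label_propagation``
    (seeded).  Communities are ranked by average within-community miR
    degree (ties: larger community first, then lexicographic smallest
    member); the first ``n_top`` become ``Module-1`` .. ``Module-n``; all
    remaining nodes are labeled ``no_module``.
    """
    g = net.graph
    if method == "greedy":
        comms = list(nx.community.greedy_modularity_communities(g))
    elif method == "components":
        comms = [set(c) for c in nx.connected_components(g)]
    elif method == "label_propagation":
        comms = [set(c) for c in
                 nx.community.asyn_lpa_communities(g, seed=seed)]
    else:
        raise ValueError(f"unknown module-detection method {method!r}")

    ranked = sorted(
        (set(c) for c in comms),
        key=lambda c: (-_avg_mir_degree(net, c), -len(c), min(map(str, c))),
    )
    if n_top > len(ranked):
        logger.warning("requested %d modules but only %d communities found",
                       n_top, len(ranked))
        n_top = len(ranked)
    module_of = {n: NO_MODULE for n in g.nodes}
    labels = []
    for k in range(n_top):
        lab = f"Module-{k + 1}"
        labels.append(lab)
        for n in ranked[k]:
            module_of[n] = lab
    logger.info("modules: %s (+%d nodes unassigned)",
                {lab: sum(v == lab for v in module_of.values()) for lab in labels},
                sum(v == NO_MODULE for v in module_of.values()))
    return ModuleAssignment(module_of=module_of, modules=labels)


def assign_direction_weights(modules: ModuleAssignment,
                             differential: pd.DataFrame,
                             column: str = "log2fc_combo") -> ModuleAssignment:
    """Set each module's +1/-1 weight from the sign of its miRs' mean log2FC.

    ``differential`` is the factorial-selection table; miRs missing from it
    are ignored.  A module whose miR mean log2FC is >= 0 gets +1, else -1.
    """
    for lab in modules.modules:
        mirs = [n for n in modules.members(lab) if n in differential.index]
        if not mirs:
            modules.direction_weight[lab] = 1
            logger.warning("module %s has no miRs in the differential table; "
                           "defaulting weight to +1", lab)
            continue
        mean_fc = differential.loc[mirs, column].mean()
        modules.direction_weight[lab] = 1 if mean_fc >= 0 else -1
    return modules


def stratum_stats(n_mirs: int, n_mrnas: int, n_edges: int) -> dict:
    """Connectivity averages for one stratum (NaN on empty node sets)."""
    n_nodes = n_mirs + n_mrnas
    return {
        "n_mirs": n_mirs,
        "n_mrnas": n_mrnas,
        "n_edges": n_edges,
        "avg_doc": 2 * n_edges / n_nodes if n_nodes else float("nan"),
        "avg_mir_doc": n_edges / n_mirs if n_mirs else float("nan"),
        "avg_mrna_doc": n_edges / n_mrnas if n_mrnas else float("nan"),
    }


def connectivity_report(net: BipartiteNetwork,
                        modules: ModuleAssignment) -> pd.DataFrame:
    """Per-stratum composition and average degrees of connectivity.

    Rows: Whole Network, each ranked module, No Module.  Within-module
    edges have both endpoints in the module; the No-Module row counts all
    remaining edges (cross-module plus edges among unassigned nodes).
    Values are full precision; round to 2 decimals for display.
    """
    unassigned = {n for n in net.graph.nodes
                  if modules.module_of.get(n, NO_MODULE) == NO_MODULE}
    missing = set(net.graph.nodes) - set(modules.module_of)
    if missing:
        raise ValueError(f"assignment does not cover nodes: {sorted(missing)[:5]}")

    def _counts(nodes: set) -> tuple[int, int]:
        mirs = sum(net.graph.nodes[n]["kind"] == "mir" for n in nodes)
        return mirs, len(nodes) - mirs

    rows = {}
    n_mirs, n_mrnas = _counts(set(net.graph.nodes))
    total_edges = net.graph.number_of_edges()
    rows["Whole Network"] = stratum_stats(n_mirs, n_mrnas, total_edges)

    within_sum = 0
    for lab in modules.modules:
        members = modules.members(lab) & set(net.graph.nodes)
        m, g = _counts(members)
        e = net.graph.subgraph(members).number_of_edges()
        within_sum += e
        rows[lab] = stratum_stats(m, g, e)

    m, g = _counts(unassigned)
    rows["No Module"] = stratum_stats(m, g, total_edges - within_sum)
    return pd.DataFrame(rows).T


def overconnected_mirs(net: BipartiteNetwork, threshold: int = 50) -> list:
    """miRs with degree strictly greater than ``threshold``, sorted."""
    return sorted(m for m in net.mir_nodes if net.graph.degree[m] > threshold)


def round_report(report: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Half-even rounding of the average columns for display."""
    out = report.copy()
    for col in ("avg_doc", "avg_mir_doc", "avg_mrna_doc"):
        out[col] = [float(np.round(v, decimals)) for v in out[col]]
    return out
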