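"""Directed gene-gene association networks from all-vs-all selection.

CrossBoruta runs the shadow-feature selection once per target gene,
with every other gene as a candidate predictor; every non-rejected
feature becomes a directed edge target -> feature carrying the
iteration-averaged meanImp and normHits. Restricting the edge table to
the age-associated hit set yields the aging network, on which three
node statistics are computed:

* AAS (asymmetric association strength): summed incoming meanImp (the
  node acting as a feature of other targets) divided by summed outgoing
  meanImp (the node as a target). log2(AAS) > 0 flags hierarchically
  superior actors; a node that is never a target has no defined AAS.
* hub score: number of distinct targets that selected the node.
* closeness centrality: per connected component, (n_comp - 1) / sum of
  shortest-path distances (unweighted undirected by default; a weighted
  variant uses edge length 1/meanImp).
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .boruta import CONFIRMED, REJECTED, TENTATIVE, BorutaConfig, boruta_ensemble

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["target", "feature", "meanImp", "normHits", "decision"]

#: sentinel for an AAS that cannot be formed (node never selected as target)
NO_VALUE = "no value"


@dataclass
class EdgeTable:
    """Directed target -> feature association table."""

    edges: pd.DataFrame  # columns EDGE_COLUMNS
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in EDGE_COLUMNS if c not in self.edges.columns]
        if missing:
            raise ValueError(f"edge table missing columns: {missing}")
        if (self.edges["target"] == self.edges["feature"]).any():
            raise ValueError("self-edges are not allowed")
        if self.edges["decision"].isin([REJECTED]).any():
            raise ValueError("rejected pairs must be absent from the edge table")
        if self.edges.duplicated(["target", "feature"]).any():
            raise ValueError("duplicate (target, feature) pairs")

    def __len__(self) -> int:
        return len(self.edges)

    def sorted(self) -> "EdgeTable":
        e = self.edges.sort_values(["target", "feature"]).reset_index(drop=True)
        return EdgeTable(e, dict(self.provenance))

    def write_tsv(self, path: str | Path) -> None:
        self.sorted().edges.to_csv(path, sep="\t", index=False)

    @staticmethod
    def read_tsv(path: str | Path) -> "EdgeTable":
        return EdgeTable(pd.read_csv(path, sep="\t", dtype={"target": str, "feature": str}))


@dataclass
class AASValue:
    ratio: float | None
    log2: float | None
    defined: bool


@dataclass
class AgingNetwork:
    graph: nx.DiGraph
    node_table: pd.DataFrame  # index gene: origin, AAS_log2, hub_score, closeness, module

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def target_seed(master_seed: int, target: str) -> int:
    """Stable per-target seed: hash of (master seed, target id).

    Independent of target execution order, so parallel and serial runs
    agree.
    """
    digest = hashlib.sha256(f"{master_seed}:{target}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def crossboruta(X: pd.DataFrame, targets, config: BorutaConfig,
                covariates: pd.DataFrame | None = None) -> EdgeTable:
    """Run the ensemble selection once per target gene.

    ``X`` is genes x samples (harmonized scale). Predictors for each
    target are all other genes (plus optional covariate columns). A
    feature that is non-rejected in >= 1 iteration becomes an edge; its
    decision is "confirmed" when confirmed in a majority of the
    iterations where it was non-rejected, else "tentative".
    """
    if config.mode != "numeric":
        raise ValueError("crossboruta requires numeric mode")
    targets = list(targets)
    unknown = set(targets) - set(X.index)
    if unknown:
        raise ValueError(f"targets outside the gene universe: {sorted(unknown)[:5]}")
    rows = []
    skipped = []
    for t in sorted(targets):
        y = X.loc[t].to_numpy(dtype=float)
        if y.std() == 0:
            skipped.append(t)
            logger.info("target %s constant after harmonization; skipped", t)
            continue
        predictors = X.drop(index=t).T
        if covariates is not None:
            predictors = pd.concat([predictors, covariates.loc[predictors.index]], axis=1)
        cfg = replace(config, seed=target_seed(config.seed, t))
        ens = boruta_ensemble(predictors, y, cfg)
        dec = pd.DataFrame({i: r.decision for i, r in enumerate(ens.runs)})
        for f in ens.hit_set:
            n_nonrej = int(ens.n_nonrejected[f])
            n_conf = int((dec.loc[f] == CONFIRMED).sum())
            decision = CONFIRMED if n_conf * 2 > n_nonrej else TENTATIVE
            rows.append((t, f, float(ens.mean_imp[f]), float(ens.norm_hits[f]), decision))
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    prov = {
        "seed": config.seed,
        "n_targets": len(targets),
        "skipped_constant": skipped,
        "config": {
            "n_trees": config.n_trees, "max_runs": config.max_runs,
            "alpha": config.alpha, "n_iterations": config.n_iterations,
        },
    }
    return EdgeTable(edges, prov).sorted()


def restrict_to_hits(table: EdgeTable, hits, modules: pd.Series | None = None,
                     origins: pd.Series | None = None) -> AgingNetwork:
    """Keep only edges with both endpoints in the hit set; every hit is a
    node (isolated hits retained) and node metrics are computed."""
    hits = sorted(set(hits))
    if not hits:
        raise ValueError("hit set must be nonempty")
    hit_set = set(hits)
    e = table.edges
    kept = e[e["target"].isin(hit_set) & e["feature"].isin(hit_set)]

    g = nx.DiGraph()
    g.add_nodes_from(hits)
    for row in kept.itertuples(index=False):
        g.add_edge(row.target, row.feature, meanImp=float(row.meanImp),
                   normHits=float(row.normHits), decision=row.decision)

    close = closeness(g)
    node_rows = {}
    for node in hits:
        a = aas(g, node)
        node_rows[node] = {
            "origin": (origins.get(node, "NVA") if origins is not None else ""),
            "AAS_ratio": a.ratio if a.defined else np.nan,
            "AAS_log2": a.log2 if (a.defined and a.log2 is not None) else np.nan,
            "AAS_defined": a.defined,
            "hub_score": hub_score(g, node),
            "closeness": close[node],
            "module": (modules.get(node, GREY_DEFAULT) if modules is not None else ""),
        }
    node_table = pd.DataFrame.from_dict(node_rows, orient="index").loc[hits]
    node_table.index.name = "gene"
    for node, attrs in node_table.iterrows():
        g.nodes[node].update(attrs.to_dict())
    return AgingNetwork(graph=g, node_table=node_table)


GREY_DEFAULT = "grey"


def aas(network: nx.DiGraph | AgingNetwork, node: str) -> AASValue:
    """Asymmetric association strength of one node.

    ratio = (sum meanImp over in-edges, node as selected feature)
          / (sum meanImp over out-edges, node as target).
    Undefined (sentinel) when the node was never a target; -inf log2
    when it was a target but never a feature.
    """
    g = network.graph if isinstance(network, AgingNetwork) else network
    if node not in g:
        raise KeyError(f"node {node!r} not in network")
    in_sum = sum(d["meanImp"] for _, _, d in g.in_edges(node, data=True))
    out_sum = sum(d["meanImp"] for _, _, d in g.out_edges(node, data=True))
    if out_sum == 0:
        return AASValue(ratio=None, log2=None, defined=False)
    ratio = in_sum / out_sum
    log2 = math.log2(ratio) if ratio > 0 else float("-inf")
    return AASValue(ratio=ratio, log2=log2, defined=True)


def hub_score(network: nx.DiGraph | AgingNetwork | EdgeTable, node: str,
              decision_filter=(CONFIRMED, TENTATIVE)) -> int:
    """Number of distinct targets that selected ``node`` as a feature
    with a decision in ``decision_filter``."""
    decision_filter = set(decision_filter)
    if isinstance(network, EdgeTable):
        e = network.edges
        sub = e[(e["feature"] == node) & e["decision"].isin(decision_filter)]
        return int(sub["target"].nunique())
    g = network.graph if isinstance(network, AgingNetwork) else network
    if node not in g:
        raise KeyError(f"node {node!r} not in network")
    return sum(1 for _t, _f, d in g.in_edges(node, data=True)
               if d.get("decision") in decision_filter)


def closeness(network: nx.DiGraph | AgingNetwork, weighted: bool = False) -> dict[str, float]:
    """Per-component closeness: c(i) = (n_comp - 1) / sum_j d(i, j).

    Unweighted undirected by default; the weighted variant uses edge
    length 1/meanImp. Isolated nodes get 0.
    """
    g = network.graph if isinstance(network, AgingNetwork) else network
    ug = g.to_undirected()
    if weighted:
        for u, v, d in ug.edges(data=True):
            d["length"] = 1.0 / d["meanImp"] if d.get("meanImp", 0) > 0 else float("inf")
        return nx.closeness_centrality(ug, distance="length", wf_improved=False)
    return nx.closeness_centrality(ug, wf_improved=False)


def quantile_threshold(values, q: float = 0.90) -> float:
    """Empirical quantile, linear-interpolation convention."""
    arr = np.asarray([v for v in np.asarray(values, dtype=float).ravel() if np.isfinite(v)])
    if arr.size == 0:
        raise ValueError("no finite values for quantile")
    return float(np.quantile(arr, q, method="linear"))


def feature_hierarchy_query(full_table: EdgeTable, gene_set,
                            decision_filter=(CONFIRMED, TENTATIVE)):
    """Targets depending on any member of ``gene_set``.

    Returns (targets, n_targets, n_edges): the set of target variables
    with at least one passing edge to a gene in the set, their count,
    and the number of matching edges.
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("gene_set must be nonempty")
    e = full_table.edges
    sub = e[e["feature"].isin(gene_set) & e["decision"].isin(set(decision_filter))]
    targets = set(sub["target"])
    return targets, len(targets), len(sub)


def export_network(network: AgingNetwork, path: str | Path, fmt: str = "graphml") -> None:
    """Write the network with node and edge attributes (GraphML or TSV
    edge list); round-trips losslessly through :func:`read_network`."""
    path = Path(path)
    if fmt == "graphml":
        g = nx.DiGraph()
        for node, attrs in network.node_table.iterrows():
            out = {}
            for k, v in attrs.items():
                if k in ("AAS_log2", "AAS_ratio"):
                    out[k] = NO_VALUE if (isinstance(v, float) and math.isnan(v)) else str(v)
                elif isinstance(v, (bool, np.bool_)):
                    out[k] = bool(v)
                elif isinstance(v, (int, np.integer)):
                    out[k] = int(v)
                elif isinstance(v, (float, np.floating)):
                    out[k] = float(v)
                else:
                    out[k] = str(v)
            g.add_node(node, **out)
        for u, v, d in network.graph.edges(data=True):
            g.add_edge(u, v, meanImp=float(d["meanImp"]), normHits=float(d["normHits"]),
                       decision=str(d["decision"]))
        nx.write_graphml(g, path)
    elif fmt == "tsv":
        rows = [
            {"target": u, "feature": v, "meanImp": d["meanImp"],
             "normHits": d["normHits"], "decision": d["decision"]}
            for u, v, d in network.graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=EDGE_COLUMNS).sort_values(
            ["target", "feature"]
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def read_network(path: str | Path) -> AgingNetwork:
    """Read a GraphML file written by :func:`export_network`."""
    raw = nx.read_graphml(Path(path))
    g = nx.DiGraph()
    node_rows = {}
    for node, attrs in raw.nodes(data=True):
        row = dict(attrs)
        for k in ("AAS_log2", "AAS_ratio"):
            if k in row:
                row[k] = np.nan if row[k] == NO_VALUE else float(row[k])
        if "AAS_defined" in row:
            row["AAS_defined"] = row["AAS_defined"] in (True, "True", "true")
        if "hub_score" in row:
            row["hub_score"] = int(row["hub_score"])
        if "closeness" in row:
            row["closeness"] = float(row["closeness"])
        g.add_node(node, **row)
        node_rows[node] = row
    for u, v, d in raw.edges(data=True):
        g.add_edge(u, v, meanImp=float(d["meanImp"]), normHits=float(d["normHits"]),
                   decision=str(d["decision"]))
    node_table = pd.DataFrame.from_dict(node_rows, orient="index")
    node_table.index.name = "gene"
    return AgingNetwork(graph=g, node_table=node_table.loc[sorted(g.nodes)])
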