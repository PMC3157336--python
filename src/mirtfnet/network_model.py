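"""Regulatory model construction downstream of the transfecting miRNA.

The model is a cascade rooted at the transfecting miRNA.  Step 1 admits the
root's direct targets that are kinases or active TFs.  Subsequent steps add
further active TFs reachable through kinase-TF protein interactions or
TF-TF target edges (a TF-TF edge is a TF->gene annotation whose gene is
itself an active TF).  Kinase activity is never measured here; kinases are
admitted purely as connectors and are pruned when they lead to no active
TF.  Active TFs that no path reaches are reported, not dropped.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .datamodel import (
    EDGE_KINASE_TF,
    EDGE_MIRNA_KINASE,
    EDGE_MIRNA_TF,
    EDGE_TF_TF,
    NODE_KINASE,
    NODE_MIRNA,
    NODE_TF,
    TF,
    ExpressionProfile,
    IntersectionModel,
    RegulatorCatalog,
    RegulatoryModel,
    RunConfig,
)

logger = logging.getLogger("mirtfnet")


def _source_label(catalog: RegulatorCatalog, regulator: str) -> str:
    ts = catalog.target_sets.get(regulator)
    if ts is None or not ts.sources:
        return "targets"
    return ",".join(sorted(ts.sources))


def build_model(
    root: str,
    active_tfs: Iterable[str],
    catalog: RegulatorCatalog,
    config: RunConfig | None = None,
) -> RegulatoryModel:
    """Breadth-first cascade expansion from the transfecting miRNA.

    Layer 1 adds the root's direct kinase and active-TF targets; each
    further layer (up to ``config.max_cascade_steps`` edge layers in total)
    adds active TFs connected from any node already in the model via a
    kinase-TF interaction or a TF-TF target edge.  Kinases with no onward
    edge to an active TF are pruned afterwards.
    """
    config = config or RunConfig()
    active = set(active_tfs)
    kinase_ids = catalog.kinases
    model = RegulatoryModel(root=root, nodes={root: NODE_MIRNA})

    root_targets = (
        catalog.targets_of(root) if root in catalog.target_sets else set()
    )
    if not root_targets:
        logger.warning("root miRNA %s has no targets in the catalog", root)
    root_src = _source_label(catalog, root)

    frontier: list[str] = []
    for gene in sorted(root_targets):
        if gene in active:
            model.nodes[gene] = NODE_TF
            model.edges.add((root, gene, EDGE_MIRNA_TF, root_src))
            frontier.append(gene)
        elif gene in kinase_ids:
            model.nodes[gene] = NODE_KINASE
            model.edges.add((root, gene, EDGE_MIRNA_KINASE, root_src))
            frontier.append(gene)

    kin_out: dict[str, set[str]] = {}
    for k, tf in catalog.kinase_tf_edges:
        kin_out.setdefault(k, set()).add(tf)

    for _ in range(2, config.max_cascade_steps + 1):
        added: list[str] = []
        for node in frontier:
            if model.nodes[node] == NODE_KINASE:
                for tf in sorted(kin_out.get(node, ()) & active):
                    model.edges.add((node, tf, EDGE_KINASE_TF, "ppi"))
                    if tf not in model.nodes:
                        model.nodes[tf] = NODE_TF
                        added.append(tf)
            elif model.nodes[node] == NODE_TF and node in catalog.target_sets:
                if catalog.kind_of(node) != TF:
                    continue
                for tf in sorted(catalog.targets_of(node) & active - {node}):
                    model.edges.add((node, tf, EDGE_TF_TF, _source_label(catalog, node)))
                    if tf not in model.nodes:
                        model.nodes[tf] = NODE_TF
                        added.append(tf)
        if not added:
            break
        frontier = added

    _prune_dead_end_kinases(model)
    model.connected_tfs = {n for n, t in model.nodes.items() if t == NODE_TF}
    model.unconnected_active_tfs = active - model.connected_tfs
    if model.unconnected_active_tfs:
        logger.info(
            "%s: %d active TF(s) could not be connected to the root",
            root, len(model.unconnected_active_tfs),
        )
    return model


def _prune_dead_end_kinases(model: RegulatoryModel) -> None:
    """Drop kinases (and their incoming edges) that reach no TF."""
    with_out = {u for u, v, t, _ in model.edges if t == EDGE_KINASE_TF}
    dead = {
        n for n, t in model.nodes.items() if t == NODE_KINASE and n not in with_out
    }
    if not dead:
        return
    logger.info("pruned %d kinase(s) with no path to an active TF", len(dead))
    for n in dead:
        del model.nodes[n]
    model.edges = {e for e in model.edges if e[0] not in dead and e[1] not in dead}


def explained_fraction(
    model: RegulatoryModel,
    profile: ExpressionProfile,
    catalog: RegulatorCatalog,
    config: RunConfig | None = None,
) -> float:
    """Fraction of differentially expressed genes the model accounts for.

    A DE gene (fold change beyond ``config.fc_threshold`` in either
    direction) counts as explained when it is a direct target of the root
    miRNA or a target of an active TF connected to the root.  Updates
    ``model.explained_genes`` / ``model.explained_fraction`` and returns
    the fraction (0 when there are no DE genes).
    """
    config = config or RunConfig()
    threshold = config.l2fc_threshold
    de_genes = {g for g, v in profile.values.items() if abs(v) >= threshold}
    covered: set[str] = set()
    if model.root in catalog.target_sets:
        covered |= catalog.targets_of(model.root)
    for tf in model.connected_tfs:
        if tf in catalog.target_sets:
            covered |= catalog.targets_of(tf)
    model.explained_genes = de_genes & covered
    model.explained_fraction = (
        len(model.explained_genes) / len(de_genes) if de_genes else 0.0
    )
    return model.explained_fraction


def intersect_models(
    models: Sequence[RegulatoryModel], k: int
) -> IntersectionModel:
    """Nodes and edges present in at least k of the given models.

    Edge identity ignores the provenance label; node types are taken from
    the first model defining each node.
    """
    if not models:
        raise ValueError("need at least one model to intersect")
    if not 1 <= k <= len(models):
        raise ValueError(f"support threshold k={k} outside 1..{len(models)}")
    node_counts: Counter[str] = Counter()
    edge_counts: Counter[tuple[str, str, str]] = Counter()
    node_types: dict[str, str] = {}
    for m in models:
        node_counts.update(m.nodes.keys())
        edge_counts.update(m.edge_keys())
        for n, t in m.nodes.items():
            node_types.setdefault(n, t)
    keep_nodes = {n: c for n, c in node_counts.items() if c >= k}
    keep_edges = {
        e: c
        for e, c in edge_counts.items()
        if c >= k and e[0] in keep_nodes and e[1] in keep_nodes
    }
    return IntersectionModel(
        k=k,
        n_models=len(models),
        node_support=keep_nodes,
        edge_support=keep_edges,
        node_types={n: node_types[n] for n in keep_nodes},
    )


def to_networkx(model: RegulatoryModel) -> nx.DiGraph:
    g = nx.DiGraph(root=model.root)
    for n, t in model.nodes.items():
        g.add_node(n, node_type=t, role="root" if n == model.root else "member")
    for n in sorted(model.unconnected_active_tfs):
        g.add_node(n, node_type=NODE_TF, role="unconnected_active_tf")
    for u, v, t, src in model.edges:
        g.add_edge(u, v, edge_type=t, provenance=src)
    return g


def export_model(model: RegulatoryModel, out_dir: str | Path) -> dict[str, Path]:
    """Write node/edge TSV tables plus a GraphML file; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nodes_path = out_dir / "nodes.tsv"
    edges_path = out_dir / "edges.tsv"
    graphml_path = out_dir / "model.graphml"
    with open(nodes_path, "w") as fh:
        fh.write("node\ttype\trole\n")
        for n in sorted(model.nodes):
            role = "root" if n == model.root else "member"
            fh.write(f"{n}\t{model.nodes[n]}\t{role}\n")
        for n in sorted(model.unconnected_active_tfs):
            fh.write(f"{n}\t{NODE_TF}\tunconnected_active_tf\n")
    with open(edges_path, "w") as fh:
        fh.write("source\ttarget\ttype\tprovenance\n")
        for u, v, t, src in sorted(model.edges):
            fh.write(f"{u}\t{v}\t{t}\t{src}\n")
    nx.write_graphml(to_networkx(model), graphml_path)
    return {"nodes": nodes_path, "edges": edges_path, "graphml": graphml_path}


def import_model(out_dir: str | Path) -> RegulatoryModel:
    """Re-read an exported model; inverse of :func:`export_model`."""
    out_dir = Path(out_dir)
    nodes: dict[str, str] = {}
    unconnected: set[str] = set()
    root = None
    with open(out_dir / "nodes.tsv") as fh:
        next(fh)
        for line in fh:
            n, t, role = line.rstrip("\n").split("\t")
            if role == "unconnected_active_tf":
                unconnected.add(n)
                continue
            nodes[n] = t
            if role == "root":
                root = n
    if root is None:
        raise ValueError(f"{out_dir}/nodes.tsv: no root node found")
    edges: set[tuple[str, str, str, str]] = set()
    with open(out_dir / "edges.tsv") as fh:
        next(fh)
        for line in fh:
            u, v, t, src = line.rstrip("\n").split("\t")
            edges.add((u, v, t, src))
    model = RegulatoryModel(root=root, nodes=nodes, edges=edges)
    model.connected_tfs = {n for n, t in nodes.items() if t == NODE_TF}
    model.unconnected_active_tfs = unconnected
    return model
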