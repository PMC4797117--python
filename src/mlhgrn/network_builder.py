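"""Bottom-up layer-by-layer construction of the hierarchical network.

Starting from the pathway genes (layer 0), each round evaluates every
(pair, regulator) triplet against the current bottom layer, corrects the
interference p-values, tallies interference counts per regulator, selects
the regulators to keep (top-k, top-percent or WSCCA), and promotes them to a
new layer.  The kept regulators are removed from the candidate pool and the
new layer becomes the bottom for the next round, until the requested number
of layers is reached, a round selects nothing, or the pool empties.

An edge is drawn from every selected regulator to each distinct bottom-layer
gene occurring in its interfered pairs; pair-level evidence (the pairs and
the best adjusted p-value) is retained on the edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from . import layer_selection as ls
from . import triplet_engine as te
from .config import RunConfig
from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = ["Edge", "HierarchicalNetwork", "build_layer", "build_ml_hgrn"]


@dataclass
class Edge:
    """Directed regulator -> target edge between adjacent layers."""

    regulator: str
    target: str
    layer_index: int          # layer of the *regulator*; targets sit one below
    pairs: list[tuple[str, str]] = field(default_factory=list)
    best_p: float | None = None


@dataclass
class HierarchicalNetwork:
    """Ordered layers of genes plus the edges connecting adjacent layers.

    ``layers[0]`` is the pathway (bottom) layer; gene sets are pairwise
    disjoint and every edge runs from layer i+1 to layer i.
    """

    layers: list[list[str]]
    edges: list[Edge]
    params: dict
    stop_reason: str = ""
    interference_counts: dict[str, int] = field(default_factory=dict)
    #: (layer_index, TripletResult) for every retained triplet of every round
    triplet_log: list[tuple[int, te.TripletResult]] = field(default_factory=list)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for li, genes in enumerate(self.layers):
            for gene in genes:
                g.add_node(
                    gene,
                    layer=li,
                    interference_count=self.interference_counts.get(gene, 0),
                )
        for e in self.edges:
            g.add_edge(
                e.regulator,
                e.target,
                relation="regulates",
                layer=e.layer_index,
                n_pairs=len(e.pairs),
                best_p=float("nan") if e.best_p is None else e.best_p,
            )
        return g


def _edges_for(
    selected: list[str], results: list[te.TripletResult], layer_index: int
) -> list[Edge]:
    by_z: dict[str, dict[str, Edge]] = {z: {} for z in selected}
    for t in results:
        if not t.interferes or t.z_id not in by_z:
            continue
        for target in (t.x_id, t.y_id):
            e = by_z[t.z_id].setdefault(
                target, Edge(t.z_id, target, layer_index)
            )
            e.pairs.append((t.x_id, t.y_id))
            p = t.p_adjusted if t.p_adjusted is not None else t.operative_p
            if e.best_p is None or p < e.best_p:
                e.best_p = p
    return [
        e
        for z in selected
        for _, e in sorted(by_z[z].items())
    ]


def build_layer(
    current_bottom: pd.DataFrame,
    pool: pd.DataFrame,
    config: RunConfig,
    layer_index: int = 1,
):
    """One round of the bottom-up recursion.

    Returns ``(selected, edges, diagnostics)`` where ``selected`` is the
    ordered list of regulators kept for the new layer (empty = automatic
    termination), ``edges`` connect them to the current bottom genes, and
    ``diagnostics`` reports triplet/tally counts.  An empty pool is a
    termination signal, not an error.
    """
    if pool.shape[0] == 0:
        return [], [], {"n_triplets": 0, "n_interfering": 0, "tallies": [],
                        "results": []}
    results = te.evaluate_layer(
        current_bottom, pool, config.alpha1, config.alpha2, config.alpha3
    )
    results = te.correct_pvalues(
        results, config.correction, config.correction_alpha, config.correction_mode
    )
    tallies = te.tally_interference(results)
    if config.selection_mode == "topk":
        selected = ls.select_top_k(tallies, config.k)
    elif config.selection_mode == "percent":
        selected = ls.select_top_percent(tallies, config.percent)
    else:
        selected = ls.wscca_select(
            current_bottom,
            pool,
            tallies,
            lam_grid=config.lam_grid,
            folds=config.cv_folds,
            lam_scale=config.lam_scale,
            seed=config.seed + layer_index,
        )
    edges = _edges_for(selected, results, layer_index)
    diagnostics = {
        "n_triplets": len(results),
        "n_interfering": sum(t.interferes for t in results),
        "tallies": tallies,
        "results": results,
    }
    return selected, edges, diagnostics


def build_ml_hgrn(
    pathway: pd.DataFrame,
    regulators: pd.DataFrame,
    max_layers: int | None = None,
    config: RunConfig | None = None,
) -> HierarchicalNetwork:
    """Iterate :func:`build_layer` until ``max_layers`` regulatory layers are
    built, a round selects zero regulators, or the pool empties."""
    config = config or RunConfig()
    if max_layers is None:
        max_layers = config.max_layers
    if max_layers < 1:
        raise InputError(f"max_layers must be >= 1, got {max_layers}")
    overlap = sorted(set(pathway.index) & set(regulators.index))
    if overlap:
        raise InputError(f"gene ids present in both inputs: {overlap}")

    # constant pathway genes are dropped once, up front
    const = pathway.index[pathway.nunique(axis=1) <= 1]
    if len(const):
        logger.warning("dropping %d constant pathway gene(s): %s", len(const), list(const))
        pathway = pathway.drop(index=const)

    layers: list[list[str]] = [list(pathway.index)]
    edges: list[Edge] = []
    counts: dict[str, int] = {}
    triplet_log: list[tuple[int, te.TripletResult]] = []
    bottom, pool = pathway, regulators.copy()
    stop_reason = "max_layers_reached"
    for li in range(1, max_layers + 1):
        if pool.shape[0] == 0:
            stop_reason = "empty_pool"
            break
        selected, new_edges, diag = build_layer(bottom, pool, config, layer_index=li)
        triplet_log.extend((li, t) for t in diag["results"])
        if not selected:
            stop_reason = "no_regulators_selected"
            break
        tally_counts = {t.z_id: t.count for t in diag["tallies"]}
        for z in selected:
            counts[z] = tally_counts.get(z, 0)
        layers.append(list(selected))
        edges.extend(new_edges)
        bottom = pool.loc[selected]
        pool = pool.drop(index=selected)
        logger.info("layer %d: kept %d regulators", li, len(selected))
    return HierarchicalNetwork(
        layers=layers,
        edges=edges,
        params=config.to_dict(),
        stop_reason=stop_reason,
        interference_counts=counts,
        triplet_log=triplet_log,
    )
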