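"""Delimited-text readers and network writers.

Expression matrices are plain delimited text: first column gene identifiers,
header row of sample identifiers, one gene per row.  Networks are written as
SIF (``source<TAB>regulates<TAB>target``), GraphML (with a ``layer`` node
attribute), a flat edge-list TSV, and a layer table TSV.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .config import RunConfig
from .errors import InputError
from .network_builder import HierarchicalNetwork, build_ml_hgrn
from .triplet_engine import TripletResult

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "write_sif",
    "write_graphml",
    "write_edges_tsv",
    "write_layers_tsv",
    "write_triplets_tsv",
    "run_pipeline",
]


def read_expression(path, delimiter: str = "\t", drop_constant: bool = True) -> pd.DataFrame:
    """Read a genes x samples matrix from delimited text.

    Duplicate gene identifiers are rejected; non-numeric cells raise an
    ``InputError`` locating the offending row and column; constant-expression
    genes are dropped with a warning (they carry no rank information).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if df.shape[1] == 0:
        raise InputError(f"{path}: no sample columns found")
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise InputError(f"{path}: duplicate gene identifiers: {dupes}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad) or (df[col].isna().any()):
            offender = bad[0] if len(bad) else df.index[df[col].isna()][0]
            raise InputError(
                f"{path}: non-numeric value at gene {offender!r}, sample {col!r}"
            )
        df[col] = coerced
    df.index = df.index.astype(str)
    if drop_constant:
        const = df.index[df.nunique(axis=1) <= 1]
        if len(const):
            logger.warning(
                "%s: dropping %d constant gene(s): %s", path, len(const), list(const)
            )
            df = df.drop(index=const)
    logger.info("%s: %d genes x %d samples", path, *df.shape)
    return df


def write_expression(df: pd.DataFrame, path, delimiter: str = "\t") -> None:
    df.to_csv(path, sep=delimiter, index_label="gene_id")


def write_sif(network: HierarchicalNetwork, path) -> None:
    with open(path, "w") as fh:
        for e in network.edges:
            fh.write(f"{e.regulator}\tregulates\t{e.target}\n")


def write_graphml(network: HierarchicalNetwork, path) -> None:
    nx.write_graphml(network.to_networkx(), path)


def write_edges_tsv(network: HierarchicalNetwork, path) -> None:
    rows = [
        {
            "regulator": e.regulator,
            "target": e.target,
            "layer": e.layer_index,
            "n_pairs": len(e.pairs),
            "best_p": e.best_p,
        }
        for e in network.edges
    ]
    pd.DataFrame(rows, columns=["regulator", "target", "layer", "n_pairs", "best_p"]).to_csv(
        path, sep="\t", index=False
    )


def write_layers_tsv(network: HierarchicalNetwork, path) -> None:
    rows = [
        {
            "gene_id": gene,
            "layer_index": li,
            "interference_count": network.interference_counts.get(gene, 0),
        }
        for li, genes in enumerate(network.layers)
        for gene in genes
    ]
    pd.DataFrame(rows, columns=["gene_id", "layer_index", "interference_count"]).to_csv(
        path, sep="\t", index=False
    )


def write_triplets_tsv(
    results: Sequence[TripletResult], path, layers: Sequence[int] | None = None
) -> None:
    """Dump retained triplets: x, y, z, r_xy, r_xy_z, p1, p2, p3, p_adj,
    circumstance, interferes (plus a layer column when provided)."""
    rows = [
        {
            "x": t.x_id, "y": t.y_id, "z": t.z_id,
            "r_xy": t.r_xy, "r_xy_z": t.r_xy_given_z,
            "p1": t.p1, "p2": t.p2, "p3": t.p3, "p_adj": t.p_adjusted,
            "circumstance": t.circumstance, "interferes": t.interferes,
        }
        for t in results
    ]
    cols = ["x", "y", "z", "r_xy", "r_xy_z", "p1", "p2", "p3", "p_adj",
            "circumstance", "interferes"]
    frame = pd.DataFrame(rows, columns=cols)
    if layers is not None:
        frame.insert(0, "layer", list(layers))
    frame.to_csv(path, sep="\t", index=False)


def run_pipeline(
    config: RunConfig, pathway_path, tf_path, delimiter: str = "\t"
) -> HierarchicalNetwork:
    """End-to-end run: read inputs, build the network, write all artifacts.

    Writes ``<prefix>.layers.tsv``, ``<prefix>.edges.tsv``, ``<prefix>.sif``,
    ``<prefix>.graphml``, ``<prefix>.triplets.tsv`` and ``<prefix>.log``.
    On failure any partial outputs are removed and the error re-raised.
    """
    prefix = str(config.output_prefix)
    artifacts = [
        f"{prefix}.layers.tsv",
        f"{prefix}.edges.tsv",
        f"{prefix}.sif",
        f"{prefix}.graphml",
        f"{prefix}.triplets.tsv",
        f"{prefix}.log",
    ]
    try:
        pathway = read_expression(pathway_path, delimiter)
        tfs = read_expression(tf_path, delimiter)
        network = build_ml_hgrn(pathway, tfs, config.max_layers, config)
        write_layers_tsv(network, artifacts[0])
        write_edges_tsv(network, artifacts[1])
        write_sif(network, artifacts[2])
        write_graphml(network, artifacts[3])
        write_triplets_tsv(
            [t for _, t in network.triplet_log],
            artifacts[4],
            layers=[li for li, _ in network.triplet_log],
        )
        with open(artifacts[5], "w") as fh:
            fh.write(f"config: {network.params}\n")
            fh.write(f"stop_reason: {network.stop_reason}\n")
            fh.write(f"layers: {[len(l) for l in network.layers]}\n")
    except Exception:
        for a in artifacts:
            if os.path.exists(a):
                os.remove(a)
        raise
    return network
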