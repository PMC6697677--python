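"""Construction, summary and export of ceRNA regulatory networks.

A regulatory triple is a (circRNA, miRNA, mRNA) tuple in which the circRNA is
dysregulated, both target-map edges exist, and the mRNA is dysregulated in the
same direction as the circRNA; the miRNA's own DE status is deliberately
ignored (sponging need not change miRNA abundance).  Triples sharing the same
circRNA and mRNA through different bridging miRNAs are distinct.  Networks are
built separately per direction (and, upstream, per time point).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .diffexpr import dysregulated_ids
from .targets import TargetMap

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True, order=True)
class RegulatoryTriple:
    circ_id: str
    mirna_id: str
    mrna_id: str
    direction: str


def build_network(
    circ_de: pd.DataFrame,
    mrna_de: pd.DataFrame,
    circ2mir: TargetMap,
    mir2mrna: TargetMap,
    direction: str,
) -> set[RegulatoryTriple]:
    """Enumerate all regulatory triples for one direction.

    Exactly the tuple set {(c, m, g): c dysregulated ``direction``,
    (c, m) in circ2mir, (m, g) in mir2mrna, g dysregulated ``direction``}.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    circ_dys = dysregulated_ids(circ_de, direction)
    mrna_dys = dysregulated_ids(mrna_de, direction)
    c2m = circ2mir.adjacency()
    m2g = mir2mrna.adjacency()
    triples: set[RegulatoryTriple] = set()
    for c in circ_dys:
        for m in c2m.get(c, ()):
            for g in m2g.get(m, ()):
                if g in mrna_dys:
                    triples.add(RegulatoryTriple(c, m, g, direction))
    return triples


@dataclasses.dataclass(frozen=True)
class DegreeStats:
    median: float
    q1: float
    q3: float
    max: int

    @classmethod
    def of(cls, degrees: Iterable[int], method: str = "linear") -> "DegreeStats":
        arr = np.asarray(sorted(degrees), dtype=float)
        if arr.size == 0:
            return cls(0.0, 0.0, 0.0, 0)
        q1, med, q3 = np.percentile(arr, [25, 50, 75], method=method)
        return cls(float(med), float(q1), float(q3), int(arr.max()))


@dataclasses.dataclass(frozen=True)
class NetworkSummary:
    """Size and per-node-degree complexity statistics of a triple network.

    Degrees are taken over the projected bipartite edges: a miRNA's
    in-degree counts distinct upstream circRNAs, its out-degree distinct
    downstream mRNAs, and an mRNA's in-degree distinct upstream miRNAs.
    """

    n_triples: int
    n_circ: int
    n_mirna: int
    n_mrna: int
    mirna_in_degree: DegreeStats
    mirna_out_degree: DegreeStats
    mrna_in_degree: DegreeStats


def summarize_network(
    triples: set[RegulatoryTriple], quantile_method: str = "linear"
) -> NetworkSummary:
    """Complexity statistics with an interpolated quantile convention.

    ``quantile_method`` is passed to :func:`numpy.percentile`; the default
    linear interpolation reproduces fractional quartiles such as 54.25.
    """
    if not triples:
        zero = DegreeStats(0.0, 0.0, 0.0, 0)
        return NetworkSummary(0, 0, 0, 0, zero, zero, zero)
    circ_by_mir: dict[str, set[str]] = {}
    mrna_by_mir: dict[str, set[str]] = {}
    mir_by_mrna: dict[str, set[str]] = {}
    for t in triples:
        circ_by_mir.setdefault(t.mirna_id, set()).add(t.circ_id)
        mrna_by_mir.setdefault(t.mirna_id, set()).add(t.mrna_id)
        mir_by_mrna.setdefault(t.mrna_id, set()).add(t.mirna_id)
    return NetworkSummary(
        n_triples=len(triples),
        n_circ=len({t.circ_id for t in triples}),
        n_mirna=len(circ_by_mir),
        n_mrna=len(mir_by_mrna),
        mirna_in_degree=DegreeStats.of((len(v) for v in circ_by_mir.values()), quantile_method),
        mirna_out_degree=DegreeStats.of((len(v) for v in mrna_by_mir.values()), quantile_method),
        mrna_in_degree=DegreeStats.of((len(v) for v in mir_by_mrna.values()), quantile_method),
    )


# --------------------------------------------------------------------------
# export


def projected_edges(triples: set[RegulatoryTriple]) -> set[tuple[str, str, str]]:
    """Unique (source, interaction, target) edges of the triple set.

    Every triple contributes one ``sponges`` (circRNA-miRNA) and one
    ``targets`` (miRNA-mRNA) edge; triples share edges.
    """
    edges: set[tuple[str, str, str]] = set()
    for t in triples:
        edges.add((t.circ_id, "sponges", t.mirna_id))
        edges.add((t.mirna_id, "targets", t.mrna_id))
    return edges


def export_sif(triples: set[RegulatoryTriple], path: str | Path) -> None:
    """Write the network as a Cytoscape SIF file (unique projected edges)."""
    with open(path, "w") as fh:
        for s, rel, t in sorted(projected_edges(triples)):
            fh.write(f"{s}\t{rel}\t{t}\n")


def export_node_attributes(
    triples: set[RegulatoryTriple],
    path: str | Path,
    circ_de: pd.DataFrame | None = None,
    mrna_de: pd.DataFrame | None = None,
) -> None:
    """Write a node-attribute TSV (node id, layer, direction, fold change)."""
    fc: dict[str, float] = {}
    for de in (circ_de, mrna_de):
        if de is not None:
            fc.update(zip(de["feature_id"], de["fold_change"]))
    rows = []
    seen: set[str] = set()
    for t in sorted(triples):
        for node, layer in ((t.circ_id, "circRNA"), (t.mirna_id, "miRNA"), (t.mrna_id, "mRNA")):
            if node in seen:
                continue
            seen.add(node)
            rows.append(
                {
                    "node_id": node,
                    "layer": layer,
                    "direction": t.direction if layer != "miRNA" else "",
                    "fold_change": fc.get(node, ""),
                }
            )
    pd.DataFrame(rows, columns=["node_id", "layer", "direction", "fold_change"]).to_csv(
        path, sep="\t", index=False
    )


def export_graphml(triples: set[RegulatoryTriple], path: str | Path) -> None:
    """Write the network as GraphML, embedding the exact triple list.

    Projected edges carry an ``interaction`` attribute; the full triple set
    is additionally stored as a JSON graph attribute so that re-import
    reproduces it exactly even for triple sets whose edge projection is not
    join-closed.
    """
    g = nx.DiGraph()
    layer = {}
    for t in triples:
        layer[t.circ_id] = "circRNA"
        layer[t.mirna_id] = "miRNA"
        layer[t.mrna_id] = "mRNA"
    for node, lay in layer.items():
        g.add_node(node, layer=lay)
    for s, rel, t in projected_edges(triples):
        g.add_edge(s, t, interaction=rel)
    g.graph["triples"] = json.dumps(
        sorted([t.circ_id, t.mirna_id, t.mrna_id, t.direction] for t in triples)
    )
    nx.write_graphml(g, path)


def read_graphml_network(path: str | Path) -> set[RegulatoryTriple]:
    """Re-import a GraphML file written by :func:`export_graphml`."""
    g = nx.read_graphml(path)
    raw = json.loads(g.graph.get("triples", "[]"))
    return {RegulatoryTriple(c, m, r, d) for c, m, r, d in raw}


def export_network(
    triples: set[RegulatoryTriple],
    outdir: str | Path,
    prefix: str,
    circ_de: pd.DataFrame | None = None,
    mrna_de: pd.DataFrame | None = None,
    graphml: bool = True,
) -> list[Path]:
    """Write SIF + node attributes (+ GraphML) under ``outdir``; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = [outdir / f"{prefix}.sif", outdir / f"{prefix}.nodes.tsv"]
    export_sif(triples, paths[0])
    export_node_attributes(triples, paths[1], circ_de, mrna_de)
    if graphml:
        paths.append(outdir / f"{prefix}.graphml")
        export_graphml(triples, paths[2])
    return paths
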