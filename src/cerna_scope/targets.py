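"""Directed bipartite target maps between adjacent RNA layers.

Two relations are allowed: circRNA -> miRNA (a circRNA carries miRNA response
elements for its target miRNAs) and miRNA -> mRNA (a miRNA represses its
target mRNAs).  Maps are plain edge sets read from two-column TSV edge lists;
composition of the two maps yields circRNA -> mRNA reachability through a
bridging miRNA, the backbone of every downstream analysis.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import defaultdict
from pathlib import Path

logger = logging.getLogger(__name__)

VALID_RELATIONS = {("circRNA", "miRNA"), ("miRNA", "mRNA")}


@dataclasses.dataclass(frozen=True)
class TargetMap:
    """Directed bipartite edge set between two adjacent RNA layers."""

    source_layer: str
    target_layer: str
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if (self.source_layer, self.target_layer) not in VALID_RELATIONS:
            raise ValueError(
                f"unsupported relation {self.source_layer} -> {self.target_layer}; "
                f"allowed: {sorted(VALID_RELATIONS)}"
            )
        object.__setattr__(self, "edges", frozenset(self.edges))
        for s, t in self.edges:
            if not s or not t:
                raise ValueError("edge with empty id")
            if s == t:
                raise ValueError(f"self-pair {s!r}")

    def __len__(self) -> int:
        return len(self.edges)

    def targets_of(self, source_id: str) -> set[str]:
        return self.adjacency().get(source_id, set())

    def adjacency(self) -> dict[str, set[str]]:
        """Source id -> set of target ids (cached per instance)."""
        cached = self.__dict__.get("_adjacency")
        if cached is None:
            adj: dict[str, set[str]] = defaultdict(set)
            for s, t in self.edges:
                adj[s].add(t)
            cached = dict(adj)
            self.__dict__["_adjacency"] = cached
        return cached

    def sources(self) -> set[str]:
        return {s for s, _ in self.edges}

    def all_targets(self) -> set[str]:
        return {t for _, t in self.edges}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.source_layer}\t{self.target_layer}\n")
            for s, t in sorted(self.edges):
                fh.write(f"{s}\t{t}\n")


def read_edge_list(path: str | Path, source_layer: str, target_layer: str) -> TargetMap:
    """Read a two-column TSV edge list into a :class:`TargetMap`.

    A header row is tolerated (detected as a first row matching the layer
    names or common header tokens).  Duplicate edges are dropped with a
    logged count; rows without exactly two nonempty fields raise an error
    naming the offending line numbers.
    """
    edges: list[tuple[str, str]] = []
    bad_lines: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and _looks_like_header(fields, source_layer, target_layer):
                continue
            if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
                bad_lines.append(lineno)
                continue
            edges.append((fields[0].strip(), fields[1].strip()))
    if bad_lines:
        raise ValueError(f"{path}: malformed rows at lines {bad_lines}")
    unique = set(edges)
    n_dup = len(edges) - len(unique)
    if n_dup:
        logger.info("%s: dropped %d duplicate edges", path, n_dup)
    if not unique:
        logger.warning("%s: empty edge list", path)
    return TargetMap(source_layer, target_layer, frozenset(unique))


def _looks_like_header(fields: list[str], source_layer: str, target_layer: str) -> bool:
    if len(fields) != 2:
        return False
    header_tokens = {source_layer.lower(), target_layer.lower(), "source", "target",
                     "source_id", "target_id"}
    return fields[0].strip().lower() in header_tokens and fields[1].strip().lower() in header_tokens


def downstream_mrnas(
    circ_ids, circ2mir: TargetMap, mir2mrna: TargetMap
) -> dict[str, set[tuple[str, str]]]:
    """Relational join: circRNA id -> {(bridging miRNA id, mRNA id)} pairs.

    Each (circ, mRNA) pair appears once per distinct bridging miRNA.  circ
    ids absent from the circ -> miRNA map are returned with an empty set and
    logged.
    """
    _check_composable(circ2mir, mir2mrna)
    c2m = circ2mir.adjacency()
    m2g = mir2mrna.adjacency()
    out: dict[str, set[tuple[str, str]]] = {}
    missing = []
    for c in circ_ids:
        if c not in c2m:
            missing.append(c)
            out[c] = set()
            continue
        pairs: set[tuple[str, str]] = set()
        for m in c2m[c]:
            for g in m2g.get(m, ()):
                pairs.add((m, g))
        out[c] = pairs
    if missing:
        logger.info("downstream_mrnas: %d circRNA ids absent from map", len(missing))
    return out


def downstream_mrna_set(circ_ids, circ2mir: TargetMap, mir2mrna: TargetMap) -> set[str]:
    """Union of mRNA ids reachable from any of ``circ_ids``."""
    join = downstream_mrnas(circ_ids, circ2mir, mir2mrna)
    return {g for pairs in join.values() for _, g in pairs}


def _check_composable(circ2mir: TargetMap, mir2mrna: TargetMap) -> None:
    if circ2mir.source_layer != "circRNA" or circ2mir.target_layer != "miRNA":
        raise ValueError("first map must be circRNA -> miRNA")
    if mir2mrna.source_layer != "miRNA" or mir2mrna.target_layer != "mRNA":
        raise ValueError("second map must be miRNA -> mRNA")


def write_triples_tsv(triples, path: str | Path) -> None:
    """Write (circ, miRNA, mRNA) tuples as a three-column TSV."""
    with open(path, "w") as fh:
        fh.write("circ_id\tmirna_id\tmrna_id\n")
        for c, m, g in sorted(triples):
            fh.write(f"{c}\t{m}\t{g}\n")
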