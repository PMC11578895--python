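"""Typed regulatory networks, genomic intervals and node score vectors.

The central container is :class:`RegulatoryNetwork`, a tripartite graph
linking transcription factors (TFs) to candidate regulatory regions
(enhancers / accessible peaks, carrying genomic intervals) and to target
genes, with non-negative edge importances as produced by enhancer-driven
GRN inference pipelines.  Downstream modules treat the network as the
substrate for score propagation, so this module also defines
:class:`NodeSeed` (a per-node score vector with a context label) and the
plain-text interchange formats everything round-trips through.

All genomic coordinates are 0-based half-open (BED convention).  Region
node ids use the canonical self-describing form ``"chrom:start-end"`` so a
network file needs no side table to be interpretable.
"""
from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

NODE_KINDS = ("TF", "gene", "region")
EDGE_LAYERS = ("tf-region", "region-gene", "tf-gene")

#: node kinds implied by each edge layer, (source kind, target kind)
_LAYER_KINDS = {
    "tf-region": ("TF", "region"),
    "region-gene": ("region", "gene"),
    "tf-gene": ("TF", "gene"),
}

_REGION_ID_RE = re.compile(r"^(?P<chrom>[^\s:]+):(?P<start>\d+)-(?P<end>\d+)$")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class IntegrityError(ValueError):
    """Cross-references between objects are inconsistent."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def contains_position(self, pos_1based: int) -> bool:
        """Whether a 1-based genomic position falls in this interval.

        A SNP at 1-based position p occupies 0-based index p - 1, so it
        overlaps [start, end) iff start <= p - 1 < end.
        """
        return self.start <= pos_1based - 1 < self.end


def parse_region_id(node_id: str) -> GenomicInterval | None:
    """Parse a canonical ``chrom:start-end`` region id, or return None."""
    m = _REGION_ID_RE.match(node_id)
    if m is None:
        return None
    return GenomicInterval(m["chrom"], int(m["start"]), int(m["end"]))


@dataclass(frozen=True)
class NetworkNode:
    id: str
    kind: str
    interval: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise ValueError(f"node {self.id!r}: kind must be one of {NODE_KINDS}, got {self.kind!r}")
        if self.kind == "region" and self.interval is None:
            raise ValueError(f"region node {self.id!r} requires a genomic interval")


@dataclass(frozen=True)
class GeneAnnotation:
    """Genomic location of a gene (0-based half-open); strand is carried but
    no operation is strand-sensitive."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")


class NodeSeed:
    """Per-node score vector with a context label (a trait or a cell cluster).

    Scores must be finite; non-negative unless ``allow_negative`` is set
    (min-combined z-scores legitimately go below zero, but propagation
    seeds never do).
    """

    def __init__(
        self,
        scores: Mapping[str, float],
        context: str = "",
        allow_negative: bool = False,
    ) -> None:
        clean: dict[str, float] = {}
        for node_id, s in scores.items():
            s = float(s)
            if not math.isfinite(s):
                raise ValueError(f"seed score for {node_id!r} is not finite")
            if s < 0 and not allow_negative:
                raise ValueError(f"seed score for {node_id!r} is negative")
            clean[str(node_id)] = s
        self.scores = clean
        self.context = context

    def __len__(self) -> int:
        return len(self.scores)

    def __getitem__(self, node_id: str) -> float:
        return self.scores[node_id]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.scores

    def items(self):
        return self.scores.items()

    def restrict_to(self, node_ids: Iterable[str]) -> "NodeSeed":
        keep = set(node_ids)
        return NodeSeed(
            {k: v for k, v in self.scores.items() if k in keep},
            context=self.context,
            allow_negative=True,
        )

    def __repr__(self) -> str:
        return f"NodeSeed(context={self.context!r}, n={len(self.scores)})"


class RegulatoryNetwork:
    """Validated tripartite TF / region / gene graph with weighted edges.

    Edges carry a non-negative finite ``importance`` and a ``layer`` in
    {tf-region, region-gene, tf-gene}.  Duplicate (source, target, layer)
    rows are collapsed by summing importances; self-loops and dangling
    endpoints are rejected.
    """

    def __init__(
        self,
        nodes: Iterable[NetworkNode],
        edges: Iterable[tuple[str, str, float, str]],
    ) -> None:
        node_map: dict[str, NetworkNode] = {}
        for node in nodes:
            if node.id in node_map:
                raise IntegrityError(f"duplicate node id {node.id!r}")
            node_map[node.id] = node
        rows = []
        for source, target, importance, layer in edges:
            importance = float(importance)
            if layer not in EDGE_LAYERS:
                raise ValueError(f"unknown edge layer {layer!r}")
            if not math.isfinite(importance) or importance < 0:
                raise ValueError(
                    f"edge {source}->{target}: importance must be finite and >= 0, got {importance}"
                )
            if source == target:
                raise IntegrityError(f"self-loop on node {source!r}")
            for endpoint in (source, target):
                if endpoint not in node_map:
                    raise IntegrityError(f"edge endpoint {endpoint!r} is not a declared node")
            rows.append((source, target, importance, layer))
        if rows:
            df = pd.DataFrame(rows, columns=["source", "target", "importance", "layer"])
            df = (
                df.groupby(["source", "target", "layer"], as_index=False, sort=True)["importance"]
                .sum()[["source", "target", "importance", "layer"]]
            )
        else:
            df = pd.DataFrame(columns=["source", "target", "importance", "layer"])
        self._nodes = node_map
        self._edges = df.reset_index(drop=True)

    # -- accessors ---------------------------------------------------------
    @property
    def nodes(self) -> dict[str, NetworkNode]:
        return self._nodes

    @property
    def node_ids(self) -> list[str]:
        return list(self._nodes)

    @property
    def edges(self) -> pd.DataFrame:
        return self._edges.copy()

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def nodes_of_kind(self, kind: str) -> list[str]:
        return [n.id for n in self._nodes.values() if n.kind == kind]

    def to_networkx(self, directed: bool = False) -> nx.Graph:
        g: nx.Graph = nx.DiGraph() if directed else nx.Graph()
        for node in self._nodes.values():
            g.add_node(node.id, kind=node.kind)
        for row in self._edges.itertuples(index=False):
            if not directed and g.has_edge(row.source, row.target):
                g[row.source][row.target]["importance"] += row.importance
            else:
                g.add_edge(row.source, row.target, importance=row.importance, layer=row.layer)
        return g

    def __repr__(self) -> str:
        return f"RegulatoryNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


# ---------------------------------------------------------------------------
# connectivity


def connected_components(
    net: RegulatoryNetwork, node_subset: Iterable[str]
) -> list[set[str]]:
    """Connected components of the subgraph induced by ``node_subset``.

    Edge direction is ignored: subnetwork extraction is purely topological.
    Components are sorted by decreasing size, ties broken by the
    lexicographically smallest member.
    """
    subset = set(node_subset)
    unknown = subset - set(net.nodes)
    if unknown:
        raise IntegrityError(f"unknown node ids in subset: {sorted(unknown)[:5]}")
    g = net.to_networkx(directed=False).subgraph(subset)
    comps = [set(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


# ---------------------------------------------------------------------------
# I/O

_EDGE_COLUMNS = ("source", "target", "importance", "layer")


def _infer_nodes_from_edges(edges: pd.DataFrame) -> list[NetworkNode]:
    kinds: dict[str, str] = {}
    for row in edges.itertuples(index=False):
        src_kind, tgt_kind = _LAYER_KINDS[row.layer]
        for node_id, kind in ((row.source, src_kind), (row.target, tgt_kind)):
            prev = kinds.get(node_id)
            if prev is None or prev == kind:
                kinds[node_id] = kind
            elif {prev, kind} == {"TF", "gene"}:
                # a TF is also a gene; the TF role wins for typing purposes
                kinds[node_id] = "TF"
            else:
                raise IntegrityError(
                    f"node {node_id!r} used inconsistently as {prev} and {kind}"
                )
    nodes = []
    for node_id, kind in kinds.items():
        interval = parse_region_id(node_id) if kind == "region" else None
        if kind == "region" and interval is None:
            raise FormatError(
                f"region node id {node_id!r} is not of the form 'chrom:start-end' "
                "and no node table was given"
            )
        nodes.append(NetworkNode(node_id, kind, interval))
    return nodes


def _read_node_table(path: str | Path) -> list[NetworkNode]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "id" not in df.columns or "kind" not in df.columns:
        raise FormatError("node table requires columns 'id' and 'kind'")
    nodes = []
    for row in df.itertuples(index=False):
        interval = None
        chrom = getattr(row, "chrom", None)
        if isinstance(chrom, str) and chrom and chrom.lower() != "nan":
            interval = GenomicInterval(chrom, int(float(row.start)), int(float(row.end)))
        elif row.kind == "region":
            interval = parse_region_id(row.id)
        nodes.append(NetworkNode(row.id, row.kind, interval))
    return nodes


def read_network(
    edge_path: str | Path, node_table: str | Path | None = None
) -> RegulatoryNetwork:
    """Load a network from a tab-delimited edge list.

    The edge list must have header columns source, target, importance,
    layer.  Node kinds are taken from an optional node table (TSV with id,
    kind and optional chrom/start/end/strand); without one they are
    inferred from the layer column and region intervals are parsed from
    ``chrom:start-end`` ids.
    """
    edges = pd.read_csv(edge_path, sep="\t", dtype={"source": str, "target": str})
    for col in _EDGE_COLUMNS:
        if col not in edges.columns:
            raise FormatError(f"edge list {edge_path}: missing required column {col!r}")
    bad_layers = set(edges["layer"]) - set(EDGE_LAYERS)
    if bad_layers:
        raise FormatError(f"edge list {edge_path}: unknown layer values {sorted(bad_layers)}")
    if (edges["importance"] < 0).any():
        raise ValueError(f"edge list {edge_path}: negative importance values")
    if node_table is not None:
        nodes = _read_node_table(node_table)
        known = {n.id for n in nodes}
        missing = (set(edges["source"]) | set(edges["target"])) - known
        if missing:
            raise IntegrityError(
                f"edges reference nodes absent from the node table: {sorted(missing)[:5]}"
            )
    else:
        nodes = _infer_nodes_from_edges(edges)
    edge_tuples = list(edges[list(_EDGE_COLUMNS)].itertuples(index=False, name=None))
    return RegulatoryNetwork(nodes, edge_tuples)


def write_network(net: RegulatoryNetwork, edge_path: str | Path) -> None:
    """Write just the edge list (node kinds recoverable from layers/ids)."""
    net.edges.to_csv(edge_path, sep="\t", index=False)


def write_subnetwork(
    net: RegulatoryNetwork,
    scores: NodeSeed | None,
    prefix: str | Path,
    json_too: bool = True,
) -> dict[str, Path]:
    """Write node and edge tables (and a single-document JSON export).

    Produces ``<prefix>.nodes.tsv`` (id, kind, chrom, start, end, score)
    and ``<prefix>.edges.tsv``; nodes without a score get an empty score
    field, never a fabricated 0.  Round-trips losslessly through
    :func:`read_network` for nodes and edges.
    """
    prefix = Path(prefix)
    if scores is not None:
        unknown = set(scores.scores) - set(net.nodes)
        if unknown:
            raise IntegrityError(f"scores reference unknown nodes: {sorted(unknown)[:5]}")
    node_rows = []
    for node in net.nodes.values():
        iv = node.interval
        score = scores.scores.get(node.id) if scores is not None else None
        node_rows.append(
            {
                "id": node.id,
                "kind": node.kind,
                "chrom": iv.chrom if iv else "",
                "start": iv.start if iv else "",
                "end": iv.end if iv else "",
                "score": "" if score is None else score,
            }
        )
    nodes_path = prefix.with_name(prefix.name + ".nodes.tsv")
    edges_path = prefix.with_name(prefix.name + ".edges.tsv")
    pd.DataFrame(node_rows, columns=["id", "kind", "chrom", "start", "end", "score"]).to_csv(
        nodes_path, sep="\t", index=False
    )
    net.edges.to_csv(edges_path, sep="\t", index=False)
    out = {"nodes": nodes_path, "edges": edges_path}
    if json_too:
        json_path = prefix.with_name(prefix.name + ".json")
        doc = {
            "nodes": [
                {
                    "id": n.id,
                    "kind": n.kind,
                    "score": scores.scores.get(n.id) if scores is not None else None,
                }
                for n in net.nodes.values()
            ],
            "edges": [
                {
                    "source": r.source,
                    "target": r.target,
                    "importance": r.importance,
                    "layer": r.layer,
                }
                for r in net.edges.itertuples(index=False)
            ],
        }
        json_path.write_text(json.dumps(doc, indent=1))
        out["json"] = json_path
    return out


@dataclass(frozen=True)
class BedInterval:
    chrom: str
    start: int
    end: int
    name: str = ""

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


def read_bed(path: str | Path) -> list[BedInterval]:
    """Read BED3+ intervals (0-based half-open); names default to
    ``chrom:start-end``.  Empty or inverted intervals raise with the
    offending line number."""
    out: list[BedInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected at least 3 BED columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: empty or inverted interval {chrom}:{start}-{end}"
                )
            name = parts[3] if len(parts) > 3 and parts[3] else f"{chrom}:{start}-{end}"
            out.append(BedInterval(chrom, start, end, name))
    return out


def read_gene_bed(path: str | Path, strand: str = ".") -> list[GeneAnnotation]:
    """Read gene annotations from BED4 (name column = gene id)."""
    return [
        GeneAnnotation(iv.name, iv.chrom, iv.start, iv.end, strand)
        for iv in read_bed(path)
    ]


def write_node_seed(seed: NodeSeed, path: str | Path) -> None:
    pd.DataFrame(
        sorted(seed.scores.items()), columns=["node", "score"]
    ).to_csv(path, sep="\t", index=False)


def read_node_seed(path: str | Path, context: str = "") -> NodeSeed:
    df = pd.read_csv(path, sep="\t", dtype={"node": str})
    if "node" not in df.columns or "score" not in df.columns:
        raise FormatError(f"{path}: node seed requires columns 'node' and 'score'")
    return NodeSeed(dict(zip(df["node"], df["score"])), context=context, allow_negative=True)
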