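"""Pathway collections (GMT) and the pathway-hierarchy relation graph.

A pathway collection maps pathway ids to sets of molecule identifiers.
Identifiers are opaque strings (ChEBI, UniProt, ENSEMBL, ...); a single
pathway may mix namespaces, which is what makes multi-omics scoring work.
The hierarchy graph is a Reactome-style parent->child DAG used for network
export and neighbourhood queries.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "PathwayDef",
    "PathwayCollection",
    "HierarchyGraph",
    "read_gmt",
    "write_gmt",
    "merge_multiomics",
    "filter_coverage",
    "read_hierarchy",
]


@dataclass
class PathwayDef:
    """One pathway: an id, a free-text name, and a set of member molecules."""

    id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("pathway id must be non-empty")
        self.members = frozenset(self.members)
        if not self.members:
            raise ValueError(f"pathway {self.id!r} has no members")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class PathwayCollection:
    """Ordered list of pathways with unique ids.

    Order is stable and defines the column order of every score matrix
    derived from the collection, so runs are reproducible.
    """

    pathways: list[PathwayDef] = field(default_factory=list)
    source_tag: str = ""

    def __post_init__(self) -> None:
        ids = [p.id for p in self.pathways]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate pathway ids: {dup}")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def __contains__(self, pathway_id: str) -> bool:
        return any(p.id == pathway_id for p in self.pathways)

    def __getitem__(self, pathway_id: str) -> PathwayDef:
        for p in self.pathways:
            if p.id == pathway_id:
                return p
        raise KeyError(pathway_id)

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.pathways]

    def all_members(self) -> set[str]:
        out: set[str] = set()
        for p in self.pathways:
            out |= p.members
        return out


@dataclass
class HierarchyGraph:
    """Parent->child pathway relations; must form a DAG."""

    edges: list[tuple[str, str]]

    def __post_init__(self) -> None:
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"hierarchy contains a cycle: {cycle}")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_edges_from(self.edges)
        return g

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    def restrict(self, ids: set[str]) -> "HierarchyGraph":
        """Induced subgraph on the given pathway ids."""
        keep = [(a, b) for a, b in self.edges if a in ids and b in ids]
        return HierarchyGraph(edges=keep)


def read_gmt(path) -> PathwayCollection:
    """Read a GMT file: tab-separated ``id<TAB>description<TAB>member...``.

    UTF-8, no header; trailing empty fields are ignored; members are
    deduplicated; line order is preserved.
    """
    pathways: list[PathwayDef] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f for f in line.split("\t")]
            while fields and fields[-1] == "":
                fields.pop()
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            pid, name, *members = fields
            if pid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            seen.add(pid)
            pathways.append(PathwayDef(id=pid, name=name, members=frozenset(members)))
    return PathwayCollection(pathways=pathways, source_tag=str(path))


def write_gmt(collection: PathwayCollection, path) -> None:
    """Write a collection in GMT format (members sorted for determinism)."""
    buf = io.StringIO()
    for p in collection:
        buf.write("\t".join([p.id, p.name, *sorted(p.members)]) + "\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def merge_multiomics(collections: list[PathwayCollection]) -> PathwayCollection:
    """Union pathways with the same id across collections.

    Pathways present in one input only are kept unchanged; order follows
    first appearance. This is how per-omics pathway definitions become a
    single multi-omics collection whose members span identifier namespaces.
    """
    if not collections:
        raise ValueError("need at least one collection")
    order: list[str] = []
    members: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for coll in collections:
        for p in coll:
            if p.id not in members:
                order.append(p.id)
                members[p.id] = set(p.members)
                names[p.id] = p.name
            else:
                members[p.id] |= p.members
    merged = [
        PathwayDef(id=pid, name=names[pid], members=frozenset(members[pid]))
        for pid in order
    ]
    tag = "+".join(c.source_tag for c in collections if c.source_tag)
    return PathwayCollection(pathways=merged, source_tag=tag)


def filter_coverage(
    collection: PathwayCollection,
    observed: set[str],
    min_coverage: int = 2,
) -> tuple[PathwayCollection, pd.DataFrame]:
    """Restrict pathways to observed molecules and drop low-coverage ones.

    Each retained pathway's members are intersected with `observed`;
    pathways covered by fewer than `min_coverage` molecules are dropped.
    Returns the filtered collection and a per-pathway coverage report
    (pathway id, name, coverage) over the *input* collection.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    if not observed:
        raise ValueError("observed molecule set is empty")
    kept: list[PathwayDef] = []
    rows = []
    for p in collection:
        covered = p.members & observed
        rows.append({"pathway_id": p.id, "name": p.name, "coverage": len(covered)})
        if len(covered) >= min_coverage:
            kept.append(PathwayDef(id=p.id, name=p.name, members=frozenset(covered)))
    report = pd.DataFrame(rows, columns=["pathway_id", "name", "coverage"])
    return PathwayCollection(pathways=kept, source_tag=collection.source_tag), report


def read_hierarchy(path) -> HierarchyGraph:
    """Read a two-column tab-separated parent/child relation file."""
    edges: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            edges.append((fields[0], fields[1]))
    return HierarchyGraph(edges=edges)
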