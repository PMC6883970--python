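"""Build an integrative pathway resource from several databases.

A curated mapping catalog links equivalent pathways ("analogs") across
databases; its transitive closure yields equivalence classes.  Each class
is merged into a single pathway whose gene set is the union of the member
gene sets and whose network is the graph union of the member networks.
Pathways exclusive to one database are carried over unchanged.  A merged
pathway whose members span every configured database is a "super pathway";
one spanning at least two but not all is an "analog"; a single-member one
is "exclusive".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .io import GeneSet, ParseError, PathwayNetwork, database_of

logger = logging.getLogger(__name__)

#: Naming priority when analog members disagree on a pathway name.
DEFAULT_PRIORITY = ("kegg", "reactome", "wikipathways")


@dataclass
class MappingCatalog:
    """Equivalence classes of pathway identifiers across databases."""

    pairs: frozenset[frozenset[str]]
    classes: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.classes:
            self.classes = _closure(self.pairs)
        for cls in self.classes:
            databases = [database_of(p) for p in cls]
            if len(set(databases)) < len(databases):
                raise ValueError(
                    f"equivalence class {sorted(cls)} links two pathways of "
                    "the same database (ambiguous curation)"
                )

    def class_of(self, pathway_id: str) -> frozenset[str] | None:
        for cls in self.classes:
            if pathway_id in cls:
                return cls
        return None

    def __len__(self) -> int:
        return len(self.classes)


def _closure(pairs) -> list[frozenset[str]]:
    """Connected components of the mapping graph = transitive closure."""
    graph = nx.Graph()
    for pair in pairs:
        a, b = tuple(pair)
        graph.add_edge(a, b)
    return sorted(
        (frozenset(c) for c in nx.connected_components(graph)),
        key=lambda c: min(c),
    )


def read_mapping_catalog(path, databases: list[str] | None = None) -> MappingCatalog:
    """Read a two-column TSV of equivalent pathway-id pairs.

    A header row is detected by the absence of a database prefix in its
    cells.  Pairs linking two pathways of the same database are rejected,
    as are identifiers without a prefix.  An empty file yields an empty
    catalog.
    """
    pairs: set[frozenset[str]] = set()
    with open(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected two pathway-id columns")
        a, b = fields[0], fields[1]
        if lineno == 1 and (":" not in a or ":" not in b):
            continue  # header row
        db_a, db_b = database_of(a), database_of(b)
        if db_a == db_b:
            raise ParseError(
                f"{path}:{lineno}: pair ({a}, {b}) links two {db_a} pathways"
            )
        if databases is not None:
            for db in (db_a, db_b):
                if db not in databases:
                    raise ParseError(
                        f"{path}:{lineno}: unknown database prefix {db!r}"
                    )
        pairs.add(frozenset((a, b)))
    return MappingCatalog(pairs=frozenset(pairs))


def write_mapping_catalog(catalog: MappingCatalog, path) -> None:
    with open(path, "w") as handle:
        handle.write("pathway_id_a\tpathway_id_b\n")
        for pair in sorted(catalog.pairs, key=sorted):
            a, b = sorted(pair)
            handle.write(f"{a}\t{b}\n")


@dataclass
class MergedPathway:
    """One pathway of the merged resource."""

    mpath_id: str
    name: str
    member_ids: tuple[str, ...]
    genes: frozenset[str]
    tier: str  # exclusive | analog | super
    network: PathwayNetwork | None = None

    @property
    def member_databases(self) -> frozenset[str]:
        return frozenset(database_of(m) for m in self.member_ids)


def _mpath_id(member_ids) -> str:
    return "mpath:" + "|".join(sorted(member_ids))


def _tier(member_dbs: frozenset[str], all_dbs: frozenset[str]) -> str:
    # super pathways span every configured database (three or more of them);
    # spanning some-but-not-all, or all of just two, is an analog
    if len(member_dbs) == 1:
        return "exclusive"
    if member_dbs == all_dbs and len(all_dbs) >= 3:
        return "super"
    return "analog"


def _pick_name(members: list[GeneSet], priority) -> str:
    rank = {db: i for i, db in enumerate(priority)}
    best = min(members, key=lambda gs: (rank.get(gs.database, len(rank)), gs.pathway_id))
    return best.name


def merge_gene_sets(
    databases: list[list[GeneSet]],
    catalog: MappingCatalog,
    priority=DEFAULT_PRIORITY,
) -> list[MergedPathway]:
    """Merge gene-set collections into one resource using the catalog.

    Every equivalence class becomes one merged pathway whose genes are the
    exact union of member gene sets; unmapped pathways pass through
    unchanged as tier ``exclusive``.  The output size obeys
    ``sum(db sizes) - sum(class size - 1)``.
    """
    by_id: dict[str, GeneSet] = {}
    for collection in databases:
        for gs in collection:
            if gs.pathway_id in by_id:
                raise ValueError(f"duplicate pathway id {gs.pathway_id!r} across inputs")
            by_id[gs.pathway_id] = gs
    missing = sorted(
        pid for cls in catalog.classes for pid in cls if pid not in by_id
    )
    if missing:
        raise ValueError(f"catalog references unloaded pathways: {missing}")

    all_dbs = frozenset(gs.database for gs in by_id.values())
    merged: list[MergedPathway] = []
    mapped: set[str] = set()
    for cls in catalog.classes:
        members = [by_id[pid] for pid in sorted(cls)]
        mapped.update(cls)
        genes = frozenset().union(*(gs.genes for gs in members))
        member_dbs = frozenset(gs.database for gs in members)
        merged.append(
            MergedPathway(
                mpath_id=_mpath_id(cls),
                name=_pick_name(members, priority),
                member_ids=tuple(sorted(cls)),
                genes=genes,
                tier=_tier(member_dbs, all_dbs),
            )
        )
    for pid in sorted(by_id):
        if pid in mapped:
            continue
        gs = by_id[pid]
        merged.append(
            MergedPathway(
                mpath_id=_mpath_id([pid]),
                name=gs.name,
                member_ids=(pid,),
                genes=gs.genes,
                tier="exclusive",
            )
        )
    merged.sort(key=lambda m: m.mpath_id)
    return merged


def merge_networks(
    networks: list[list[PathwayNetwork]],
    catalog: MappingCatalog,
) -> dict[str, PathwayNetwork]:
    """Graph-union member networks per equivalence class.

    Edges are relation-typed, so an activation and an inhibition between
    the same gene pair both survive the union; such conflicting-sign pairs
    are logged for curation.  Classes with no member network yield none.
    Returns a mapping from merged pathway id to merged network.
    """
    by_id: dict[str, PathwayNetwork] = {}
    for collection in networks:
        for net in collection:
            by_id[net.pathway_id] = net

    out: dict[str, PathwayNetwork] = {}
    mapped: set[str] = set()
    for cls in catalog.classes:
        mapped.update(cls)
        members = [by_id[pid] for pid in sorted(cls) if pid in by_id]
        if not members:
            continue
        nodes = frozenset().union(*(n.nodes for n in members))
        edges = frozenset().union(*(n.edges for n in members))
        signed = {(s, t) for s, t, _ in edges}
        for s, t in sorted(signed):
            if (s, t, "activation") in edges and (s, t, "inhibition") in edges:
                logger.warning(
                    "conflicting-sign edge %s->%s retained in merged pathway %s",
                    s, t, _mpath_id(cls),
                )
        out[_mpath_id(cls)] = PathwayNetwork(
            pathway_id=_mpath_id(cls),
            database="mpath",
            nodes=nodes,
            edges=edges,
        )
    for pid, net in by_id.items():
        if pid not in mapped:
            out[_mpath_id([pid])] = PathwayNetwork(
                pathway_id=_mpath_id([pid]),
                database="mpath",
                nodes=net.nodes,
                edges=net.edges,
            )
    return out


def composition_report(merged: list[MergedPathway]) -> pd.DataFrame:
    """Tabulate merged-resource composition by tier and source database.

    Rows: one per (exclusive, database) combination, one each for analog
    and super tiers, and a total; the counts sum to the total.
    """
    if not merged:
        raise ValueError("no merged pathways to report on")
    rows: list[tuple[str, int]] = []
    exclusive = [m for m in merged if m.tier == "exclusive"]
    for db in sorted({next(iter(m.member_databases)) for m in exclusive}):
        count = sum(1 for m in exclusive if next(iter(m.member_databases)) == db)
        rows.append((f"exclusive:{db}", count))
    rows.append(("analog", sum(1 for m in merged if m.tier == "analog")))
    rows.append(("super", sum(1 for m in merged if m.tier == "super")))
    rows.append(("total", len(merged)))
    return pd.DataFrame(rows, columns=["category", "count"])


def write_merge_report(merged: list[MergedPathway], path) -> None:
    frame = pd.DataFrame(
        {
            "mpath_id": [m.mpath_id for m in merged],
            "members": ["|".join(m.member_ids) for m in merged],
            "tier": [m.tier for m in merged],
            "n_genes": [len(m.genes) for m in merged],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def merged_gene_sets(merged: list[MergedPathway]) -> list[GeneSet]:
    """View merged pathways as plain gene sets (database ``mpath``)."""
    return [
        GeneSet(
            pathway_id=m.mpath_id,
            name=m.name,
            database="mpath",
            genes=m.genes,
        )
        for m in merged
    ]
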