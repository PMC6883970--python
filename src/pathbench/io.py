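"""Readers and writers for the plain-text formats the toolkit exchanges.

Four artifacts move between tools: pathway gene sets (GMT), pathway
topologies (signed edge lists), scored gene tables (RNK-style two-column
TSV), and gene-by-sample expression matrices (TSV with a header row).
Database provenance is carried as a prefix on every pathway identifier
(``kegg:hsa04330``); gene identifiers are opaque, case-sensitive strings
and are never remapped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RELATIONS = frozenset({"activation", "inhibition"})


class ParseError(ValueError):
    """A file violated its declared plain-text format."""


def database_of(pathway_id: str) -> str:
    """Return the database prefix of a pathway identifier.

    >>> database_of("kegg:hsa04330")
    'kegg'
    """
    if ":" not in pathway_id:
        raise ParseError(
            f"pathway id {pathway_id!r} has no database prefix (expected 'db:id')"
        )
    return pathway_id.split(":", 1)[0]


@dataclass(frozen=True)
class GeneSet:
    """One pathway's membership: identifier, provenance, and gene symbols."""

    pathway_id: str
    name: str
    database: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.pathway_id!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class PathwayNetwork:
    """Directed signed interaction graph for one pathway.

    Edges are ``(source, target, relation)`` with relation one of
    ``activation`` / ``inhibition``.  Parallel edges of opposite sign may
    coexist; self-loops are allowed but logged.
    """

    pathway_id: str
    database: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str, str]]

    def __post_init__(self) -> None:
        for source, target, relation in self.edges:
            if relation not in RELATIONS:
                raise ValueError(f"unknown relation {relation!r}")
            if source not in self.nodes or target not in self.nodes:
                raise ValueError(
                    f"edge endpoint missing from nodes: ({source}, {target})"
                )
            if source == target:
                logger.warning(
                    "self-loop on %s in pathway %s", source, self.pathway_id
                )


@dataclass
class ScoredGeneTable:
    """Genes with real-valued scores (e.g. log2 fold changes).

    ``significant`` optionally flags genes that passed an upstream
    differential-expression cutoff; it indexes a subset of ``scores``.
    """

    scores: pd.Series
    significant: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates:
            raise ValueError("duplicate gene symbols in scored table")
        if not all(math.isfinite(v) for v in self.scores.to_numpy()):
            raise ValueError("non-finite scores in scored table")

    @property
    def genes(self) -> list[str]:
        return list(self.scores.index)

    def ranked(self) -> pd.Series:
        """Scores sorted descending; ties broken by gene symbol for determinism."""
        order = sorted(
            self.scores.index, key=lambda g: (-self.scores[g], g)
        )
        return self.scores.loc[order]

    def de_genes(self) -> pd.Series:
        """Scores restricted to genes flagged significant upstream."""
        if self.significant is None:
            raise ValueError("scored table carries no significance flags")
        flagged = self.significant[self.significant].index
        return self.scores.loc[[g for g in self.scores.index if g in set(flagged)]]


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from a GMT file (tab-separated, one set per line).

    Each line holds ``pathway_id<TAB>description<TAB>gene...``.  Duplicate
    genes within a line are dropped with a warning; lines with fewer than
    three fields, empty gene lists, and repeated pathway ids are rejected.
    """
    gene_sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            pathway_id, name = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {pathway_id!r} is empty")
            unique = frozenset(genes)
            if len(unique) < len(genes):
                logger.warning(
                    "%s:%d: duplicate genes in %s de-duplicated",
                    path, lineno, pathway_id,
                )
            if pathway_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate pathway id {pathway_id!r}")
            seen.add(pathway_id)
            gene_sets.append(
                GeneSet(
                    pathway_id=pathway_id,
                    name=name,
                    database=database_of(pathway_id) if ":" in pathway_id else "",
                    genes=unique,
                )
            )
    return gene_sets


def write_gmt(gene_sets: list[GeneSet], path) -> None:
    """Write gene sets as GMT; round-trips through :func:`read_gmt`."""
    if not gene_sets:
        raise ValueError("refusing to write an empty GMT file")
    with open(path, "w") as handle:
        for gs in gene_sets:
            for gene in gs.genes:
                if "\t" in gene or "\n" in gene:
                    raise ValueError(
                        f"gene {gene!r} contains a tab/newline; GMT cannot encode it"
                    )
            genes = "\t".join(sorted(gs.genes))
            handle.write(f"{gs.pathway_id}\t{gs.name}\t{genes}\n")


def read_network(path, pathway_id: str = "", database: str = "") -> PathwayNetwork:
    """Read a signed edge list: ``source<TAB>relation<TAB>target`` per line.

    Isolated nodes are declared on two-field ``node<TAB>.`` lines.
    Duplicate identical edges collapse; an unknown relation token is an error.
    """
    nodes: set[str] = set()
    edges: set[tuple[str, str, str]] = set()
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) == 2 and fields[1] == ".":
                nodes.add(fields[0])
                continue
            if len(fields) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 'source\\trelation\\ttarget'"
                )
            source, relation, target = fields
            if relation not in RELATIONS:
                raise ParseError(
                    f"{path}:{lineno}: unknown relation {relation!r} "
                    f"(expected one of {sorted(RELATIONS)})"
                )
            nodes.update((source, target))
            edges.add((source, target, relation))
    return PathwayNetwork(
        pathway_id=pathway_id or str(path),
        database=database,
        nodes=frozenset(nodes),
        edges=frozenset(edges),
    )


def write_network(network: PathwayNetwork, path) -> None:
    """Write a signed edge list; isolated nodes get ``node<TAB>.`` lines."""
    touched = {e[0] for e in network.edges} | {e[1] for e in network.edges}
    with open(path, "w") as handle:
        for source, target, relation in sorted(network.edges):
            handle.write(f"{source}\t{relation}\t{target}\n")
        for node in sorted(network.nodes - touched):
            handle.write(f"{node}\t.\n")


def read_expression(path, sep: str = "\t") -> pd.DataFrame:
    """Read a gene-by-sample expression matrix.

    First column holds gene symbols, the header row sample identifiers.
    Repeated measurements of the same gene are averaged; any non-numeric
    or non-finite cell is an error.
    """
    frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        bad = numeric.isna()
        gene = bad.index[bad.any(axis=1)][0]
        sample = bad.columns[bad.loc[gene]][0]
        raise ParseError(
            f"{path}: non-numeric value {frame.loc[gene, sample]!r} "
            f"at gene {gene!r}, sample {sample!r}"
        )
    if not np.isfinite(numeric.to_numpy()).all():
        raise ParseError(f"{path}: non-finite expression value")
    if numeric.index.has_duplicates:
        logger.info("%s: averaging duplicate gene rows", path)
        numeric = numeric.groupby(level=0, sort=False).mean()
    numeric.index.name = "gene"
    return numeric


def write_expression(matrix: pd.DataFrame, path, sep: str = "\t") -> None:
    matrix.to_csv(path, sep=sep, index_label="gene")


def read_scored_table(path, sep: str = "\t") -> ScoredGeneTable:
    """Read an RNK-style scored gene table.

    Two or three columns: gene, score, and optionally a 0/1 significance
    flag.  A header row is detected by a non-numeric second field.
    """
    frame = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    try:
        float(frame.iloc[0, 1])
    except (ValueError, TypeError):
        frame = frame.iloc[1:].reset_index(drop=True)
    genes = frame.iloc[:, 0]
    if genes.duplicated().any():
        raise ParseError(f"{path}: duplicate gene symbols in scored table")
    scores = pd.to_numeric(frame.iloc[:, 1], errors="coerce")
    if scores.isna().any():
        row = int(scores.index[scores.isna()][0])
        raise ParseError(f"{path}: non-numeric score in row {row + 1}")
    scores.index = genes.to_list()
    significant = None
    if frame.shape[1] >= 3:
        flags = pd.to_numeric(frame.iloc[:, 2], errors="coerce")
        if flags.isna().any():
            raise ParseError(f"{path}: non-numeric significance flag")
        significant = flags.astype(bool)
        significant.index = genes.to_list()
    return ScoredGeneTable(scores=scores, significant=significant)


def write_scored_table(table: ScoredGeneTable, path, sep: str = "\t") -> None:
    frame = table.scores.rename("score").to_frame()
    if table.significant is not None:
        frame["significant"] = table.significant.astype(int)
    frame.to_csv(path, sep=sep, header=False)
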