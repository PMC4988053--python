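"""A local, file-backed repository of networks indexed on seven metadata dimensions.

Networks are classified along Compendium, Development stage, ChIP factor,
Experimental technique, Species, Tissue/Cell-line, and Treatment.  Each
dimension carries an ontology (a forest; flat value lists are depth-1
forests), and a record matches an ontology node if its assignment is that
node or any descendant.  Faceted browsing drills into the records one
dimension at a time, in any order, showing only dimensions that still
separate the remaining networks.

Persistence is deliberately plain: a directory holding one TSV per network,
a JSON index, and one ontology TSV per dimension — portable, diff-able, and
single-user by design.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from .errors import DataError
from .network_model import (DIMENSIONS, Network, NetworkMetadata,
                            read_network, write_network)

__all__ = [
    "OntologyNode",
    "FacetState",
    "RepositoryRecord",
    "NetworkRepository",
    "SpeciesCensus",
    "enumerate_derived_networks",
    "ENCODE_CENSUS",
]


@dataclass(frozen=True)
class OntologyNode:
    dimension: str
    node_id: str
    label: str
    parent: str | None = None


@dataclass
class FacetState:
    """At most one selected ontology node per dimension."""

    selections: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for dim in self.selections:
            if dim not in DIMENSIONS:
                raise ValueError(f"unknown dimension {dim!r}")

    def with_selection(self, dimension: str, node_id: str) -> "FacetState":
        new = dict(self.selections)
        new[dimension] = node_id
        return FacetState(new)


@dataclass
class RepositoryRecord:
    metadata: NetworkMetadata
    edge_list_path: Path
    dimension_assignments: dict[str, str] = field(default_factory=dict)

    @property
    def network_id(self) -> str:
        return self.metadata.network_id


class NetworkRepository:
    """Directory-backed network repository with faceted, ontology-aware queries."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.records: dict[str, RepositoryRecord] = {}
        self.ontologies: dict[str, dict[str, OntologyNode]] = {d: {} for d in DIMENSIONS}

    # -- lifecycle --------------------------------------------------------

    @classmethod
    def init(cls, path: str | Path) -> "NetworkRepository":
        """Create an empty repository directory structure."""
        repo = cls(path)
        (repo.path / "networks").mkdir(parents=True, exist_ok=True)
        (repo.path / "ontologies").mkdir(parents=True, exist_ok=True)
        repo.save()
        return repo

    @classmethod
    def open(cls, path: str | Path) -> "NetworkRepository":
        repo = cls(path)
        index = repo.path / "index.json"
        if not index.exists():
            raise DataError(f"not a repository (no index.json): {repo.path}")
        with open(index) as fh:
            data = json.load(fh)
        for dim in DIMENSIONS:
            ont_path = repo.path / "ontologies" / f"{dim}.tsv"
            if ont_path.exists():
                with open(ont_path, newline="") as fh:
                    for row in csv.reader(fh, delimiter="\t"):
                        if not row or row[0].startswith("#"):
                            continue
                        node_id, label = row[0], row[1] if len(row) > 1 else row[0]
                        parent = row[2] if len(row) > 2 and row[2] else None
                        repo.ontologies[dim][node_id] = OntologyNode(dim, node_id, label, parent)
        for rec in data.get("records", []):
            meta = NetworkMetadata.from_dict(rec["metadata"])
            repo.records[meta.network_id] = RepositoryRecord(
                meta, repo.path / rec["edge_list_path"],
                dict(rec.get("dimension_assignments", {})))
        return repo

    def save(self) -> None:
        data = {"records": [
            {
                "metadata": rec.metadata.to_dict(),
                "edge_list_path": str(rec.edge_list_path.relative_to(self.path)),
                "dimension_assignments": rec.dimension_assignments,
            }
            for _, rec in sorted(self.records.items())
        ]}
        with open(self.path / "index.json", "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)
            fh.write("\n")
        for dim in DIMENSIONS:
            nodes = self.ontologies[dim]
            if not nodes:
                continue
            with open(self.path / "ontologies" / f"{dim}.tsv", "w", newline="") as fh:
                writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
                for node_id, node in sorted(nodes.items()):
                    writer.writerow([node.node_id, node.label, node.parent or ""])

    # -- ontology ---------------------------------------------------------

    def add_ontology_node(self, dimension: str, node_id: str,
                          label: str | None = None,
                          parent: str | None = None) -> OntologyNode:
        if dimension not in DIMENSIONS:
            raise ValueError(f"unknown dimension {dimension!r}")
        if parent is not None and parent not in self.ontologies[dimension]:
            raise DataError(f"parent node {parent!r} not in {dimension} ontology")
        node = OntologyNode(dimension, node_id, label if label is not None else node_id, parent)
        self._check_acyclic(dimension, node)
        self.ontologies[dimension][node_id] = node
        return node

    def _check_acyclic(self, dimension: str, node: OntologyNode) -> None:
        seen = {node.node_id}
        cur = node.parent
        while cur is not None:
            if cur in seen:
                raise DataError(f"cycle in {dimension} ontology at {cur!r}")
            seen.add(cur)
            cur = self.ontologies[dimension].get(cur, OntologyNode(dimension, cur, cur)).parent

    def _ancestors_and_self(self, dimension: str, node_id: str) -> list[str]:
        """Node ids from ``node_id`` up to its root (inclusive)."""
        chain = []
        cur: str | None = node_id
        nodes = self.ontologies[dimension]
        while cur is not None and cur not in chain:
            chain.append(cur)
            node = nodes.get(cur)
            cur = node.parent if node else None
        return chain

    def _top_ancestor(self, dimension: str, node_id: str) -> str:
        return self._ancestors_and_self(dimension, node_id)[-1]

    # -- records ----------------------------------------------------------

    def register_network(self, network: Network) -> RepositoryRecord:
        """Persist a network and index it under its non-null dimension values.

        Dimension values not yet present in an ontology are auto-created as
        root-level nodes.
        """
        nid = network.metadata.network_id
        if not nid:
            raise DataError("network must carry a network_id to be registered")
        if nid in self.records:
            raise DataError(f"network id already registered: {nid!r}")
        edge_path = self.path / "networks" / f"{nid}.tsv"
        meta_path = self.path / "networks" / f"{nid}.meta.json"
        write_network(network, edge_path, "tsv", metadata_path=meta_path)
        assignments: dict[str, str] = {}
        for dim, value in network.metadata.dimension_values().items():
            if value not in self.ontologies[dim]:
                self.add_ontology_node(dim, value)
            assignments[dim] = value
        record = RepositoryRecord(network.metadata, edge_path, assignments)
        self.records[nid] = record
        self.save()
        return record

    def get_network(self, network_id: str) -> Network:
        rec = self.records.get(network_id)
        if rec is None:
            raise DataError(f"no such network: {network_id!r}")
        meta_path = rec.edge_list_path.parent / (rec.edge_list_path.stem + ".meta.json")
        if not meta_path.exists():
            meta_path = None
        net = read_network(rec.edge_list_path, meta_path)
        net.metadata = rec.metadata
        return net

    def iter_networks(self) -> Iterator[Network]:
        for nid in sorted(self.records):
            yield self.get_network(nid)

    def __len__(self) -> int:
        return len(self.records)

    # -- faceted queries --------------------------------------------------

    def _matches(self, record: RepositoryRecord, dimension: str, node_id: str) -> bool:
        assigned = record.dimension_assignments.get(dimension)
        if assigned is None:
            return False
        return node_id in self._ancestors_and_self(dimension, assigned)

    def select_records(self, state: FacetState) -> list[RepositoryRecord]:
        """Records matching every selection (descendant-inclusive)."""
        for dim, node_id in state.selections.items():
            if node_id not in self.ontologies[dim]:
                raise DataError(f"unknown {dim} node {node_id!r}")
        return [
            rec for _, rec in sorted(self.records.items())
            if all(self._matches(rec, dim, node)
                   for dim, node in state.selections.items())
        ]

    def browse(self, state: FacetState | None = None) -> dict[str, list[tuple[str, int]]]:
        """Per unselected dimension, the top-level nodes that separate the
        remaining records, with descendant-inclusive record counts.

        Dimensions where fewer than two nodes match are omitted — they no
        longer separate the remaining networks.
        """
        state = state if state is not None else FacetState()
        matched = self.select_records(state)
        out: dict[str, list[tuple[str, int]]] = {}
        for dim in DIMENSIONS:
            if dim in state.selections:
                continue
            counts: dict[str, int] = {}
            for rec in matched:
                assigned = rec.dimension_assignments.get(dim)
                if assigned is None:
                    continue
                top = self._top_ancestor(dim, assigned)
                counts[top] = counts.get(top, 0) + 1
            if len(counts) >= 2:
                out[dim] = sorted(counts.items())
        return out


# ---------------------------------------------------------------------------
# Repository census arithmetic


@dataclass(frozen=True)
class SpeciesCensus:
    """Per-species counts of the five network categories in a repository.

    Open-chromatin derived networks are not stored directly: every
    open-chromatin experiment is combined with every binding-site network
    variant, plus any imported pre-computed footprint networks.
    """

    curated_database: int = 0
    literature: int = 0
    binding_site_variants: int = 0
    chip_networks: int = 0
    open_chromatin_experiments: int = 0
    open_chromatin_imported: int = 0

    @property
    def open_chromatin_networks(self) -> int:
        return (self.open_chromatin_experiments * self.binding_site_variants
                + self.open_chromatin_imported)

    @property
    def global_networks(self) -> int:
        return self.curated_database + self.literature + self.binding_site_variants

    @property
    def total(self) -> int:
        return (self.curated_database + self.literature + self.binding_site_variants
                + self.chip_networks + self.open_chromatin_networks)


def enumerate_derived_networks(census: dict[str, SpeciesCensus]) -> dict:
    """Derive network counts per species and overall from category counts.

    Open-chromatin count per species = experiments x binding-site variants
    + imported networks; species total sums the five categories; overall
    totals sum across species.
    """
    per_species = {}
    for species, c in census.items():
        per_species[species] = {
            "curated_database": c.curated_database,
            "literature": c.literature,
            "binding_site_variants": c.binding_site_variants,
            "chip_networks": c.chip_networks,
            "open_chromatin_networks": c.open_chromatin_networks,
            "global_networks": c.global_networks,
            "total": c.total,
        }
    return {
        "per_species": per_species,
        "global_networks": sum(c.global_networks for c in census.values()),
        "chip_networks": sum(c.chip_networks for c in census.values()),
        "open_chromatin_networks": sum(c.open_chromatin_networks for c in census.values()),
        "grand_total": sum(c.total for c in census.values()),
    }


#: Category/experiment counts of the ENCODE-derived network compendium
#: (curated databases, literature, binding-site variants, ChIP networks,
#: open-chromatin experiments, imported footprint networks per species).
ENCODE_CENSUS: dict[str, SpeciesCensus] = {
    "human": SpeciesCensus(curated_database=4, literature=4, binding_site_variants=12,
                           chip_networks=1206, open_chromatin_experiments=207 + 54 + 37,
                           open_chromatin_imported=41),
    "mouse": SpeciesCensus(curated_database=2, literature=4, binding_site_variants=12,
                           chip_networks=162, open_chromatin_experiments=150,
                           open_chromatin_imported=0),
    "worm": SpeciesCensus(curated_database=2, literature=4, binding_site_variants=8,
                          chip_networks=561),
    "fly": SpeciesCensus(curated_database=3, literature=4, binding_site_variants=22,
                         chip_networks=119),
}
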