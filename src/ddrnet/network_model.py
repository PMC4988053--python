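"""The directed regulatory-network data model and its on-disk formats.

A network is a graph ``G = (V, E)`` whose nodes are gene identifiers and
whose edges are *directed* TF -> target-gene pairs.  Edge identity for every
set operation in the package is the ``(tf, tg)`` pair alone; the attached
evidence records (binding sites, ChIP peaks, literature references, ...)
never distinguish edges.  The node set V is induced by E.

On disk a network is an edge-list TSV (columns ``tf``, ``tg``, ``support``,
``evidence``; the evidence column is one JSON array per row, keeping the
file grep-able but lossless) plus an optional JSON metadata sidecar holding
the seven classification dimensions.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .errors import ParseError
from .genomic_io import GenomicFeature

__all__ = [
    "EVIDENCE_KINDS",
    "DIMENSIONS",
    "Evidence",
    "Edge",
    "NetworkMetadata",
    "Network",
    "read_network",
    "write_network",
]

EVIDENCE_KINDS = ("TFBS", "ChIP", "OpenChromatin", "Database", "Literature", "Transferred")

#: The seven metadata dimensions spanning the repository's data cube.
DIMENSIONS = (
    "compendium",
    "development_stage",
    "chip_factor",
    "technique",
    "species",
    "tissue_cell_line",
    "treatment",
)


@dataclass(frozen=True)
class Evidence:
    """One piece of support for a TF -> TG edge.

    ``TFBS`` evidence must carry a motif p-value; the three genomic kinds
    (``TFBS``, ``ChIP``, ``OpenChromatin``) must carry the underlying
    feature and its signed distance to the credited TSS.
    """

    kind: str
    source_network_id: str = ""
    feature: GenomicFeature | None = None
    p_value: float | None = None
    tss_distance_bp: int | None = None
    tss_gene: str | None = None
    pmids: tuple[str, ...] = ()
    origin_edge: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVIDENCE_KINDS:
            raise ValueError(f"unknown evidence kind {self.kind!r}")
        if self.kind == "TFBS" and self.p_value is None:
            raise ValueError("TFBS evidence requires a p-value")
        if self.kind in {"TFBS", "ChIP", "OpenChromatin"}:
            if self.feature is None or self.tss_distance_bp is None:
                raise ValueError(f"{self.kind} evidence requires feature and TSS distance")
        object.__setattr__(self, "pmids", tuple(self.pmids))
        if self.origin_edge is not None:
            object.__setattr__(self, "origin_edge", tuple(self.origin_edge))

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "source_network_id": self.source_network_id}
        if self.feature is not None:
            d["feature"] = {k: v for k, v in asdict(self.feature).items() if v not in (None, "")}
        if self.p_value is not None:
            d["p_value"] = self.p_value
        if self.tss_distance_bp is not None:
            d["tss_distance_bp"] = self.tss_distance_bp
        if self.tss_gene is not None:
            d["tss_gene"] = self.tss_gene
        if self.pmids:
            d["pmids"] = list(self.pmids)
        if self.origin_edge is not None:
            d["origin_edge"] = list(self.origin_edge)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Evidence":
        feat = None
        if "feature" in d:
            feat = GenomicFeature(**d["feature"])
        origin = tuple(d["origin_edge"]) if d.get("origin_edge") else None
        return cls(
            kind=d["kind"],
            source_network_id=d.get("source_network_id", ""),
            feature=feat,
            p_value=d.get("p_value"),
            tss_distance_bp=d.get("tss_distance_bp"),
            tss_gene=d.get("tss_gene"),
            pmids=tuple(d.get("pmids", ())),
            origin_edge=origin,
        )


@dataclass
class Edge:
    """A directed TF -> TG edge with its evidence records.

    ``support`` is always the number of *distinct source networks*
    contributing evidence, recomputed whenever evidence changes.
    """

    tf: str
    tg: str
    evidence: list[Evidence] = field(default_factory=list)

    @property
    def support(self) -> int:
        return max(1, len({ev.source_network_id for ev in self.evidence}))

    @property
    def key(self) -> tuple[str, str]:
        return (self.tf, self.tg)


@dataclass
class NetworkMetadata:
    """The seven-dimension classification of a network plus its build parameters."""

    network_id: str = ""
    compendium: str | None = None
    development_stage: str | None = None
    chip_factor: str | None = None
    technique: str | None = None
    species: str | None = None
    tissue_cell_line: str | None = None
    treatment: str | None = None
    construction_params: dict = field(default_factory=dict)

    def dimension_values(self) -> dict[str, str]:
        """Non-null dimension fields as {dimension: value}."""
        return {d: getattr(self, d) for d in DIMENSIONS if getattr(self, d) is not None}

    def to_dict(self) -> dict:
        return {
            "network_id": self.network_id,
            **{d: getattr(self, d) for d in DIMENSIONS},
            "construction_params": dict(self.construction_params),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkMetadata":
        known = {"network_id", *DIMENSIONS, "construction_params"}
        return cls(**{k: v for k, v in d.items() if k in known})


class Network:
    """A directed TF -> TG network: edge-keyed map plus metadata.

    Self-loops are permitted; duplicate ``(tf, tg)`` keys are impossible by
    construction (evidence merges into the existing edge).
    """

    def __init__(self, metadata: NetworkMetadata | None = None):
        self.metadata = metadata if metadata is not None else NetworkMetadata()
        self.edges: dict[tuple[str, str], Edge] = {}
        #: builder tallies (dropped records, unmapped matrices, ...); not serialized
        self.diagnostics: dict = {}

    # -- construction -----------------------------------------------------

    def add_evidence(self, tf: str, tg: str, evidence: Evidence | list[Evidence]) -> Edge:
        if isinstance(evidence, Evidence):
            evidence = [evidence]
        edge = self.edges.get((tf, tg))
        if edge is None:
            edge = Edge(tf, tg, [])
            self.edges[(tf, tg)] = edge
        edge.evidence.extend(evidence)
        return edge

    # -- views ------------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for tf, tg in self.edges:
            out.add(tf)
            out.add(tg)
        return out

    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edges)

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.edges

    def __iter__(self):
        return iter(self.edges.values())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"Network(id={self.metadata.network_id!r}, "
                f"|V|={len(self.nodes)}, |E|={len(self.edges)})")

    def sorted_edges(self) -> list[Edge]:
        return [self.edges[k] for k in sorted(self.edges)]

    def copy_metadata(self, **overrides) -> NetworkMetadata:
        d = self.metadata.to_dict()
        d.update(overrides)
        return NetworkMetadata.from_dict(d)


# ---------------------------------------------------------------------------
# I/O

_TSV_HEADER = ["tf", "tg", "support", "evidence"]


def read_network(edge_list_path: str | Path,
                 metadata_path: str | Path | None = None) -> Network:
    """Read a network from an edge-list TSV plus optional metadata JSON.

    Accepts headered (``tf<TAB>tg[<TAB>support[<TAB>evidence]]``) and
    headerless two-or-more-column files.  Duplicate ``(tf, tg)`` rows merge:
    evidence concatenates and support is recomputed.  Rows without an
    evidence column get a single ``Database`` evidence record attributed to
    this network, so every edge satisfies the evidence/support invariants.
    """
    metadata = NetworkMetadata()
    if metadata_path is not None:
        with open(metadata_path) as fh:
            metadata = NetworkMetadata.from_dict(json.load(fh))
    if not metadata.network_id:
        metadata.network_id = Path(edge_list_path).stem

    net = Network(metadata)
    with open(edge_list_path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and [c.strip().lower() for c in row[:2]] == ["tf", "tg"]:
                continue
            if row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ParseError(f"edge row needs >=2 columns, got {len(row)}",
                                 str(edge_list_path), lineno)
            tf, tg = row[0], row[1]
            ev_json = row[3] if len(row) > 3 else ""
            if ev_json.strip():
                try:
                    records = json.loads(ev_json)
                except json.JSONDecodeError:
                    raise ParseError("malformed evidence JSON",
                                     str(edge_list_path), lineno) from None
                try:
                    evidence = [Evidence.from_dict(r) for r in records]
                except (KeyError, TypeError, ValueError) as exc:
                    raise ParseError(f"invalid evidence record: {exc}",
                                     str(edge_list_path), lineno) from None
            else:
                evidence = [Evidence(kind="Database",
                                     source_network_id=metadata.network_id)]
            net.add_evidence(tf, tg, evidence)
    return net


def write_network(network: Network, path: str | Path, format: str = "tsv",
                  metadata_path: str | Path | None = None) -> None:
    """Write a network as lossless TSV or as Cytoscape-style SIF.

    Rows are ordered lexicographically by (tf, tg) so output is
    deterministic.  ``tsv`` round-trips through :func:`read_network`.
    """
    if format not in {"tsv", "sif"}:
        raise ValueError(f"unknown network format {format!r}")
    with open(path, "w", newline="") as fh:
        if format == "sif":
            for edge in network.sorted_edges():
                fh.write(f"{edge.tf}\tregulates\t{edge.tg}\n")
        else:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(_TSV_HEADER)
            for edge in network.sorted_edges():
                ev = json.dumps([e.to_dict() for e in edge.evidence],
                                separators=(",", ":"), sort_keys=True)
                writer.writerow([edge.tf, edge.tg, edge.support, ev])
    if metadata_path is not None:
        with open(metadata_path, "w") as fh:
            json.dump(network.metadata.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
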