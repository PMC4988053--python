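"""The network algebra: set operations, orthology transfer, and filters.

All operations treat edges purely as directed ``(tf, tg)`` gene-id pairs;
evidence travels with surviving edges but never affects edge identity.
Every operation returns a *new* network and leaves its inputs untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import DataError, ParseError
from .network_model import Edge, Evidence, Network, NetworkMetadata

__all__ = [
    "OrthologyMap",
    "read_orthology",
    "union_networks",
    "intersect_networks",
    "difference_networks",
    "transfer_network",
    "gene_set_filter",
    "support_filter",
    "binding_site_filter",
]


@dataclass
class OrthologyMap:
    """A species-pair gene -> gene(s) mapping; one-to-many and many-to-many allowed."""

    species_from: str = ""
    species_to: str = ""
    pairs: set[tuple[str, str]] = field(default_factory=set)

    def add(self, gene_from: str, gene_to: str) -> None:
        self.pairs.add((gene_from, gene_to))

    def orthologs(self, gene: str) -> list[str]:
        return sorted(b for a, b in self.pairs if a == gene)

    def inverse(self) -> "OrthologyMap":
        return OrthologyMap(self.species_to, self.species_from,
                            {(b, a) for a, b in self.pairs})

    def _forward(self) -> dict[str, list[str]]:
        fwd: dict[str, list[str]] = {}
        for a, b in sorted(self.pairs):
            fwd.setdefault(a, []).append(b)
        return fwd

    def __len__(self) -> int:
        return len(self.pairs)


def read_orthology(path: str | Path) -> OrthologyMap:
    """Read a two-column gene_from/gene_to TSV.

    An optional leading ``#``-prefixed header names the two species, e.g.
    ``#human<TAB>mouse``.
    """
    omap = OrthologyMap()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if line.startswith("#"):
                if len(cols) == 2:
                    omap.species_from = cols[0].lstrip("#").strip()
                    omap.species_to = cols[1].strip()
                continue
            if len(cols) != 2:
                raise ParseError(f"expected 2 columns, got {len(cols)}", str(path), lineno)
            omap.add(cols[0], cols[1])
    return omap


def _attributed(edge: Edge, network: Network) -> list[Evidence]:
    """Evidence with empty source ids re-attributed to the owning network."""
    out = []
    for ev in edge.evidence:
        if not ev.source_network_id and network.metadata.network_id:
            ev = Evidence(**{**_ev_fields(ev),
                             "source_network_id": network.metadata.network_id})
        out.append(ev)
    return out


def _ev_fields(ev: Evidence) -> dict:
    return {
        "kind": ev.kind, "source_network_id": ev.source_network_id,
        "feature": ev.feature, "p_value": ev.p_value,
        "tss_distance_bp": ev.tss_distance_bp, "tss_gene": ev.tss_gene,
        "pmids": ev.pmids, "origin_edge": ev.origin_edge,
    }


def union_networks(networks: list[Network],
                   metadata: NetworkMetadata | None = None) -> Network:
    """Edge union; evidence concatenates, support counts distinct source networks."""
    if not networks:
        raise ValueError("union requires at least one network")
    out = Network(metadata if metadata is not None else NetworkMetadata())
    for net in networks:
        for edge in net.sorted_edges():
            out.add_evidence(edge.tf, edge.tg, _attributed(edge, net))
    return out


def intersect_networks(networks: list[Network],
                       metadata: NetworkMetadata | None = None) -> Network:
    """Edges present in every input; evidence from all inputs concatenated."""
    if len(networks) < 2:
        raise ValueError("intersection requires at least two networks")
    common = set(networks[0].edges)
    for net in networks[1:]:
        common &= set(net.edges)
    out = Network(metadata if metadata is not None else NetworkMetadata())
    for key in sorted(common):
        for net in networks:
            out.add_evidence(*key, _attributed(net.edges[key], net))
    return out


def difference_networks(a: Network, b: Network,
                        metadata: NetworkMetadata | None = None) -> Network:
    """Edges of ``a`` absent from ``b``; evidence from ``a`` only."""
    out = Network(metadata if metadata is not None else NetworkMetadata())
    for edge in a.sorted_edges():
        if edge.key not in b.edges:
            out.add_evidence(edge.tf, edge.tg, _attributed(edge, a))
    return out


def transfer_network(n: Network, orth: OrthologyMap,
                     policy: str = "all_pairs") -> Network:
    """Map a network into another species via an orthology map.

    Each edge ``(a, b)`` expands to the cross-product of the orthologs of
    ``a`` and ``b``.  Edges with an unmapped endpoint are dropped (count in
    ``diagnostics['n_dropped_edges']``).  Under ``one2one_only``, genes with
    other than exactly one ortholog count as unmapped.  Produced edges carry
    ``Transferred`` evidence — one record per distinct origin source network,
    so support survives the transfer.
    """
    if policy not in {"all_pairs", "one2one_only"}:
        raise ValueError(f"unknown transfer policy {policy!r}")
    if (n.metadata.species and orth.species_from
            and n.metadata.species != orth.species_from):
        raise DataError(
            f"network species {n.metadata.species!r} does not match "
            f"orthology source species {orth.species_from!r}")

    fwd = orth._forward()
    if policy == "one2one_only":
        fwd = {g: targets for g, targets in fwd.items() if len(targets) == 1}

    meta = n.copy_metadata(
        network_id=(f"{n.metadata.network_id}::transferred-to-{orth.species_to}"
                    if n.metadata.network_id else ""),
        species=orth.species_to or None,
    )
    meta.construction_params["transfer_policy"] = policy
    out = Network(meta)
    dropped = 0
    for edge in n.sorted_edges():
        tfs = fwd.get(edge.tf)
        tgs = fwd.get(edge.tg)
        if not tfs or not tgs:
            dropped += 1
            continue
        sources = sorted({ev.source_network_id for ev in _attributed(edge, n)})
        for tf2 in tfs:
            for tg2 in tgs:
                out.add_evidence(tf2, tg2, [
                    Evidence(kind="Transferred", source_network_id=src,
                             origin_edge=edge.key)
                    for src in sources
                ])
    out.diagnostics["n_dropped_edges"] = dropped
    return out


def gene_set_filter(n: Network, genes: set[str], mode: str = "induced") -> Network:
    """Keep edges with both (``induced``) or >=1 (``any_endpoint``) endpoints in ``genes``."""
    if mode not in {"induced", "any_endpoint"}:
        raise ValueError(f"unknown gene-set filter mode {mode!r}")
    out = Network(n.copy_metadata())
    for edge in n.sorted_edges():
        inside = (edge.tf in genes, edge.tg in genes)
        keep = all(inside) if mode == "induced" else any(inside)
        if keep:
            out.add_evidence(edge.tf, edge.tg, list(edge.evidence))
    return out


def support_filter(n: Network, min_support: int = 1) -> Network:
    """Keep edges observed in at least ``min_support`` distinct source networks."""
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    out = Network(n.copy_metadata())
    for edge in n.sorted_edges():
        if edge.support >= min_support:
            out.add_evidence(edge.tf, edge.tg, list(edge.evidence))
    return out


def binding_site_filter(n: Network, max_pvalue: float | None = None,
                        max_tss_distance_bp: int | None = None) -> Network:
    """Filter edges by binding p-value and/or binding-to-TSS distance.

    An edge survives iff at least one of its evidence records satisfies
    *all* given criteria (``p <= max_pvalue``; ``|distance| <= max distance``;
    both inclusive).  A record lacking a filtered attribute fails that
    criterion.  Surviving edges keep only their satisfying records.
    """
    if max_pvalue is None and max_tss_distance_bp is None:
        raise ValueError("binding_site_filter needs at least one criterion")

    def ok(ev: Evidence) -> bool:
        if max_pvalue is not None:
            if ev.p_value is None or ev.p_value > max_pvalue:
                return False
        if max_tss_distance_bp is not None:
            if ev.tss_distance_bp is None or abs(ev.tss_distance_bp) > max_tss_distance_bp:
                return False
        return True

    out = Network(n.copy_metadata())
    for edge in n.sorted_edges():
        keep = [ev for ev in edge.evidence if ok(ev)]
        if keep:
            out.add_evidence(edge.tf, edge.tg, keep)
    return out
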