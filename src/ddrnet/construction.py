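"""Build data-derived regulatory networks (DDRNs) from genomic evidence.

Three builders, mirroring how context-specific regulatory networks are
derived from ENCODE-class data:

* **ChIP**: an edge from the ChIP-ed factor to every gene with a peak in
  its promoter window.
* **TFBS**: an edge TF -> TG for every PWM hit (below the p-value
  threshold) of a matrix associated with the TF inside the TG's promoter
  window.
* **Open chromatin**: the TFBS rule restricted to hits lying in accessible
  chromatin — any overlap with an open-chromatin peak, or, in footprint
  mode, full containment in a 6-40 bp digital genomic footprint.

The promoter window is the closed interval ``[tss - w, tss + w]`` around
each annotated TSS; defaults are w = 5,000 bp for human/mouse and 500 bp
for worm/fly.  A feature is credited to a gene if its interval intersects
the window (the most permissive reading; midpoint-only assignment is
available as a flag).  Window lookup uses an interval tree but is
contract-equal to the brute-force all-pairs scan.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .genomic_io import GenomicFeature, MotifHit, MotifTFMap, TSSAnnotation
from .network_model import Evidence, Network, NetworkMetadata

__all__ = [
    "WINDOW_PRESETS",
    "PVALUE_STANDARD",
    "PVALUE_HIGH_CONFIDENCE",
    "ConstructionParams",
    "TSSAssignment",
    "assign_features_to_genes",
    "build_chip_network",
    "build_tfbs_network",
    "build_open_chromatin_network",
]

#: Promoter half-widths by species group (bp).
WINDOW_PRESETS = {"human": 5000, "mouse": 5000, "worm": 500, "fly": 500}
#: Standard and high-confidence PWM-hit p-value thresholds.
PVALUE_STANDARD = 1e-5
PVALUE_HIGH_CONFIDENCE = 1e-6


@dataclass
class ConstructionParams:
    """Tunable parameters of the network builders.

    window_bp
        Promoter half-width; the window is ``[tss - w, tss + w]`` closed.
    pvalue_threshold
        Maximum PWM-hit p-value kept (inclusive); ``None`` only for ChIP.
    footprint_min_bp / footprint_max_bp
        Length range of open-chromatin peaks eligible as footprints.
    midpoint_only
        Credit a feature by its midpoint rather than any-overlap.
    """

    window_bp: int = 5000
    pvalue_threshold: float | None = PVALUE_STANDARD
    footprint_min_bp: int = 6
    footprint_max_bp: int = 40
    midpoint_only: bool = False

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.pvalue_threshold is not None and not (0.0 < self.pvalue_threshold <= 1.0):
            raise ValueError("pvalue_threshold must lie in (0, 1]")
        if not (1 <= self.footprint_min_bp <= self.footprint_max_bp):
            raise ValueError("need 1 <= footprint_min_bp <= footprint_max_bp")

    def to_dict(self) -> dict:
        return {
            "window_bp": self.window_bp,
            "pvalue_threshold": self.pvalue_threshold,
            "footprint_min_bp": self.footprint_min_bp,
            "footprint_max_bp": self.footprint_max_bp,
            "midpoint_only": self.midpoint_only,
        }


@dataclass(frozen=True)
class TSSAssignment:
    """A feature credited to one TSS of one gene.

    ``signed_distance_bp`` is feature midpoint minus TSS, with the sign
    flipped on minus-strand genes so that positive always means downstream
    of the TSS.
    """

    feature: GenomicFeature
    gene_id: str
    tss_position: int
    signed_distance_bp: int


def _signed_distance(feature: GenomicFeature, tss: int, strand: str) -> int:
    d = feature.midpoint - tss
    return -d if strand == "-" else d


def assign_features_to_genes(
    features: Sequence[GenomicFeature],
    tss: Sequence[TSSAnnotation],
    window_bp: int,
    midpoint_only: bool = False,
) -> list[TSSAssignment]:
    """Assign each feature to every (gene, TSS) whose window it intersects.

    A feature may be assigned to several genes and to several TSSs of one
    gene; each (feature, TSS) pair yields exactly one assignment.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    # one tree of closed TSS windows per chromosome
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for ann in tss:
        for pos in ann.tss_positions:
            lo = max(0, pos - window_bp)
            trees[ann.chrom].addi(lo, pos + window_bp + 1, (ann.gene_id, pos, ann.strand))

    out: list[TSSAssignment] = []
    for feat in features:
        tree = trees.get(feat.chrom)
        if tree is None:
            continue
        if midpoint_only:
            overlaps = tree.at(feat.midpoint)
        else:
            overlaps = tree.overlap(feat.start, feat.end)
        for iv in sorted(overlaps, key=lambda iv: iv.data):
            gene_id, pos, strand = iv.data
            out.append(TSSAssignment(feat, gene_id, pos,
                                     _signed_distance(feat, pos, strand)))
    return out


def _dedupe_per_gene(assignments: Iterable[TSSAssignment]) -> dict[str, list[TSSAssignment]]:
    """Group assignments by gene, one record per (feature, tss) pair."""
    by_gene: dict[str, dict[tuple, TSSAssignment]] = defaultdict(dict)
    for a in assignments:
        key = (a.feature.chrom, a.feature.start, a.feature.end,
               a.feature.feature_id, a.feature.source_id, a.tss_position)
        by_gene[a.gene_id].setdefault(key, a)
    return {g: list(d.values()) for g, d in by_gene.items()}


def build_chip_network(
    peaks: Sequence[GenomicFeature],
    chiped_tf: str,
    tss: Sequence[TSSAnnotation],
    params: ConstructionParams,
    metadata: NetworkMetadata | None = None,
) -> Network:
    """Infer edges from the ChIP-ed factor to every gene with a promoter peak."""
    if not chiped_tf:
        raise ValueError("chiped_tf must be a non-empty gene id")
    metadata = metadata if metadata is not None else NetworkMetadata()
    metadata.construction_params.setdefault("mode", "chip")
    metadata.construction_params.update(window_bp=params.window_bp)
    net = Network(metadata)
    assignments = assign_features_to_genes(peaks, tss, params.window_bp,
                                           params.midpoint_only)
    for gene, assigns in sorted(_dedupe_per_gene(assignments).items()):
        for a in assigns:
            net.add_evidence(chiped_tf, gene, Evidence(
                kind="ChIP",
                source_network_id=metadata.network_id,
                feature=a.feature,
                tss_distance_bp=a.signed_distance_bp,
                tss_gene=gene,
            ))
    net.diagnostics["n_peaks"] = len(peaks)
    net.diagnostics["n_assigned_peaks"] = len({
        (a.feature.chrom, a.feature.start, a.feature.end) for a in assignments})
    return net


def _hits_to_network(
    hits: Sequence[MotifHit],
    motif_map: MotifTFMap,
    tss: Sequence[TSSAnnotation],
    params: ConstructionParams,
    metadata: NetworkMetadata,
    kind: str,
) -> Network:
    net = Network(metadata)
    kept = [h for h in hits if h.p_value <= params.pvalue_threshold]
    tf_by_matrix: dict[str, list[str]] = defaultdict(list)
    for m, tf in sorted(motif_map.pairs):
        tf_by_matrix[m].append(tf)

    unmapped = 0
    feat_to_hit = {}
    feats = []
    for h in kept:
        if h.matrix_id not in tf_by_matrix:
            unmapped += 1
            continue
        feats.append(h.feature)
        feat_to_hit[id(h.feature)] = h
    assignments = assign_features_to_genes(feats, tss, params.window_bp,
                                           params.midpoint_only)
    by_gene = _dedupe_per_gene(assignments)
    for gene, assigns in sorted(by_gene.items()):
        for a in assigns:
            hit = feat_to_hit[id(a.feature)]
            for tf in tf_by_matrix[hit.matrix_id]:
                net.add_evidence(tf, gene, Evidence(
                    kind=kind,
                    source_network_id=metadata.network_id,
                    feature=a.feature,
                    p_value=hit.p_value,
                    tss_distance_bp=a.signed_distance_bp,
                    tss_gene=gene,
                ))
    net.diagnostics["n_hits"] = len(hits)
    net.diagnostics["n_hits_below_threshold"] = len(kept)
    net.diagnostics["n_unmapped_matrix_hits"] = unmapped
    return net


def build_tfbs_network(
    hits: Sequence[MotifHit],
    motif_map: MotifTFMap,
    tss: Sequence[TSSAnnotation],
    params: ConstructionParams,
    metadata: NetworkMetadata | None = None,
) -> Network:
    """Infer TF -> TG edges from PWM hits in promoter windows.

    Hits above the p-value threshold are discarded (comparison inclusive:
    ``p <= threshold`` is kept); hits whose matrix has no TF mapping are
    tallied in ``network.diagnostics['n_unmapped_matrix_hits']`` and
    contribute no edge.  Many-to-many matrix/TF mappings expand fully.
    """
    if params.pvalue_threshold is None:
        raise ValueError("TFBS construction requires a p-value threshold")
    metadata = metadata if metadata is not None else NetworkMetadata()
    metadata.construction_params.setdefault("mode", "tfbs")
    metadata.construction_params.update(window_bp=params.window_bp,
                                        pvalue_threshold=params.pvalue_threshold)
    return _hits_to_network(hits, motif_map, tss, params, metadata, "TFBS")


def build_open_chromatin_network(
    open_peaks: Sequence[GenomicFeature],
    hits: Sequence[MotifHit],
    motif_map: MotifTFMap,
    tss: Sequence[TSSAnnotation],
    params: ConstructionParams,
    metadata: NetworkMetadata | None = None,
    footprint_mode: bool = False,
) -> Network:
    """Infer TFBS edges supported by accessible chromatin.

    Plain mode keeps a hit if its interval intersects >=1 open-chromatin
    peak.  Footprint mode keeps only peaks whose length lies in
    ``[footprint_min_bp, footprint_max_bp]`` (6-40 bp by default) and
    requires the hit to lie fully inside such a footprint.  The result is
    always a subset of the corresponding TFBS network.
    """
    if params.pvalue_threshold is None:
        raise ValueError("open-chromatin construction requires a p-value threshold")
    metadata = metadata if metadata is not None else NetworkMetadata()
    metadata.construction_params.setdefault("mode", "open_chromatin")
    metadata.construction_params.update(footprint_mode=footprint_mode)

    eligible = open_peaks
    if footprint_mode:
        eligible = [p for p in open_peaks
                    if params.footprint_min_bp <= p.length <= params.footprint_max_bp]
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for p in eligible:
        trees[p.chrom].addi(p.start, p.end, None)

    def accessible(hit: MotifHit) -> bool:
        tree = trees.get(hit.feature.chrom)
        if tree is None:
            return False
        if footprint_mode:
            return any(iv.begin <= hit.feature.start and hit.feature.end <= iv.end
                       for iv in tree.overlap(hit.feature.start, hit.feature.end))
        return bool(tree.overlap(hit.feature.start, hit.feature.end))

    open_hits = [h for h in hits if accessible(h)]
    net = _hits_to_network(open_hits, motif_map, tss, params, metadata, "OpenChromatin")
    net.diagnostics["n_hits"] = len(hits)
    net.diagnostics["n_open_hits"] = len(open_hits)
    net.diagnostics["n_eligible_open_peaks"] = len(eligible)
    return net
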