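"""Network metrics, two-group comparison, gene-set overlap, and evidence lookup.

The metrics mirror what a comparative network browser exposes: interaction
and gene counts, per-gene in/out/total degree (optionally normalized by
network size), and the fraction of a fixed reference sub-network recovered
in a larger network.  When exactly two groups of networks are compared on a
metric, a Welch two-sample two-sided t-test is applied (unequal variances,
Welch-Satterthwaite degrees of freedom) — the safe default for unequal group
sizes; no multiple-testing correction is applied across metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import stats

from .errors import DataError
from .netops import OrthologyMap
from .network_model import Evidence, Network

__all__ = [
    "NetworkStats",
    "GroupComparison",
    "network_stats",
    "degree",
    "normalized_degree",
    "subnetwork_overlap",
    "group_compare",
    "geneset_interaction_counts",
    "EvidenceRecord",
    "evidence_lookup",
]


@dataclass(frozen=True)
class NetworkStats:
    network_id: str
    n_interactions: int
    n_genes: int


def network_stats(n: Network) -> NetworkStats:
    """Interaction and (edge-induced) gene counts of a network."""
    return NetworkStats(n.metadata.network_id, len(n.edges), len(n.nodes))


def degree(n: Network, gene: str, direction: str = "total") -> int:
    """Number of edges at ``gene``: as tf (out), tg (in), or either (total).

    A self-loop counts once toward the total degree.
    """
    if direction not in {"in", "out", "total"}:
        raise ValueError(f"unknown degree direction {direction!r}")
    if direction == "out":
        return sum(1 for tf, _ in n.edges if tf == gene)
    if direction == "in":
        return sum(1 for _, tg in n.edges if tg == gene)
    return sum(1 for tf, tg in n.edges if tf == gene or tg == gene)


def normalized_degree(n: Network, gene: str, direction: str = "total") -> float:
    """Degree divided by network size |E| (comparable across network sizes)."""
    if len(n.edges) == 0:
        raise DataError("normalized degree is undefined for an empty network")
    return degree(n, gene, direction) / len(n.edges)


def subnetwork_overlap(n: Network, reference: Network) -> float:
    """Fraction of the reference sub-network's edges found in ``n``.

    The denominator is the full reference edge set — reference edges whose
    genes do not occur in ``n`` count as misses — so fractions stay
    comparable when one reference is held against many networks.
    """
    if len(reference.edges) == 0:
        raise DataError("subnetwork_overlap needs a non-empty reference")
    hits = sum(1 for key in reference.edges if key in n.edges)
    return hits / len(reference.edges)


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    group_a: tuple[float, ...]
    group_b: tuple[float, ...]
    t_statistic: float
    p_value: float


def group_compare(metric_values_a: list[float], metric_values_b: list[float],
                  metric: str = "") -> GroupComparison:
    """Welch two-sample two-sided t-test between two groups of metric values.

    Degenerate input (both groups constant): equal means give t=0, p=1;
    unequal constant means are reported as t=+-inf, p=0.
    """
    a = tuple(float(x) for x in metric_values_a)
    b = tuple(float(x) for x in metric_values_b)
    if len(a) < 2 or len(b) < 2:
        raise DataError("each group needs at least two values")
    if len(set(a)) == 1 and len(set(b)) == 1:
        mean_a = sum(a) / len(a)
        mean_b = sum(b) / len(b)
        if mean_a == mean_b:
            return GroupComparison(metric, a, b, 0.0, 1.0)
        t = float("inf") if mean_a > mean_b else float("-inf")
        return GroupComparison(metric, a, b, t, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(metric, a, b, float(t), float(p))


def geneset_interaction_counts(repo, genes: set[str]) -> list[tuple[str, int]]:
    """Per repository network, the number of edges with both endpoints in ``genes``.

    Sorted by descending count, ties broken by network id.
    """
    if not genes:
        raise DataError("gene set must be non-empty")
    counts = []
    for net in repo.iter_networks():
        c = sum(1 for tf, tg in net.edges if tf in genes and tg in genes)
        counts.append((net.metadata.network_id, c))
    return sorted(counts, key=lambda item: (-item[1], item[0]))


@dataclass(frozen=True)
class EvidenceRecord:
    """One evidence record of a TF -> TG pair, as reported by the lookup."""

    network_id: str
    tf: str
    tg: str
    evidence: Evidence
    orthologous: bool = False


def evidence_lookup(repo, tf: str, tg: str,
                    orthology: list[OrthologyMap] | None = None) -> list[EvidenceRecord]:
    """Collect all evidence for a TF -> TG pair across the repository.

    When orthology maps are supplied, the pair is projected into each target
    species (all-pairs ortholog expansion) and evidence found there is
    appended, flagged ``orthologous``.
    """
    records: list[EvidenceRecord] = []

    def collect(pair_tf: str, pair_tg: str, species: str | None, flag: bool) -> None:
        for net in repo.iter_networks():
            if species is not None and net.metadata.species != species:
                continue
            edge = net.edges.get((pair_tf, pair_tg))
            if edge is None:
                continue
            for ev in edge.evidence:
                records.append(EvidenceRecord(net.metadata.network_id,
                                              pair_tf, pair_tg, ev, flag))

    collect(tf, tg, None, False)
    for omap in (orthology or []):
        for tf2 in omap.orthologs(tf):
            for tg2 in omap.orthologs(tg):
                collect(tf2, tg2, omap.species_to or None, True)
    return records
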