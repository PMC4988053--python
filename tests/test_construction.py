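"""Promoter-window assignment and network builders, checked against a
brute-force all-pairs oracle."""

import numpy as np
import pytest

from ddrnet import (ConstructionParams, GenomicFeature, MotifHit, MotifTFMap,
                    TSSAnnotation, assign_features_to_genes, build_chip_network,
                    build_open_chromatin_network, build_tfbs_network)


def brute_force_assign(features, tss, window_bp):
    """Independent O(n*m) oracle: every (feature, TSS) pair whose closed
    window [t-w, t+w] intersects the half-open feature interval."""
    out = set()
    for i, f in enumerate(features):
        for ann in tss:
            if ann.chrom != f.chrom:
                continue
            for pos in ann.tss_positions:
                if f.start <= pos + window_bp and f.end - 1 >= pos - window_bp:
                    out.add((i, ann.gene_id, pos))
    return out


def as_key_set(assignments, features):
    index = {id(f): i for i, f in enumerate(features)}
    return {(index[id(a.feature)], a.gene_id, a.tss_position) for a in assignments}


TSS_A = TSSAnnotation("A", "chr1", "+", (10000,))


def test_assignment_example_inside_window_with_signed_distance():
    feat = GenomicFeature("chr1", 12000, 12200)
    (a,) = assign_features_to_genes([feat], [TSS_A], 5000)
    assert a.gene_id == "A" and a.signed_distance_bp == 2100  # midpoint 12100


def test_assignment_example_outside_window():
    feat = GenomicFeature("chr1", 15100, 15200)  # nearest point 15100, distance 5100
    assert assign_features_to_genes([feat], [TSS_A], 5000) == []


def test_assignment_boundary_touching_window_edge():
    # feature ending exactly at t - w must still intersect the closed window
    feat = GenomicFeature("chr1", 4990, 5001)
    (a,) = assign_features_to_genes([feat], [TSS_A], 5000)
    assert a.tss_position == 10000
    gone = GenomicFeature("chr1", 4990, 5000)  # last covered base 4999 < 5000
    assert assign_features_to_genes([gone], [TSS_A], 5000) == []


def test_minus_strand_flips_distance_sign():
    ann = TSSAnnotation("B", "chr1", "-", (10000,))
    feat = GenomicFeature("chr1", 12000, 12200)
    (a,) = assign_features_to_genes([feat], [ann], 5000)
    assert a.signed_distance_bp == -2100  # downstream of a minus-strand TSS


def test_empty_inputs_give_empty_assignment():
    assert assign_features_to_genes([], [TSS_A], 5000) == []
    assert assign_features_to_genes([GenomicFeature("chr1", 1, 2)], [], 5000) == []


@pytest.mark.parametrize("seed", range(8))
def test_interval_index_equals_brute_force(seed):
    rng = np.random.default_rng(seed)
    chroms = ["chr1", "chr2"]
    features = [
        GenomicFeature(chroms[rng.integers(0, 2)], int(s), int(s) + int(rng.integers(1, 500)))
        for s in rng.integers(0, 200_000, size=300)
    ]
    tss = [
        TSSAnnotation(f"G{i}", chroms[rng.integers(0, 2)],
                      "+" if rng.random() < 0.5 else "-",
                      tuple(int(x) for x in rng.integers(0, 200_000,
                                                         size=rng.integers(1, 4))))
        for i in range(40)
    ]
    w = int(rng.integers(100, 8000))
    got = as_key_set(assign_features_to_genes(features, tss, w), features)
    assert got == brute_force_assign(features, tss, w)


def make_scene():
    """Two genes; one hit in A's window only, one in B's, one in neither."""
    tss = [TSSAnnotation("A", "chr1", "+", (10000,)),
           TSSAnnotation("B", "chr1", "+", (40000,))]
    def hit(start, matrix, p):
        return MotifHit(GenomicFeature("chr1", start, start + 10), matrix, p)
    return tss, hit


def test_build_tfbs_threshold_and_mapping():
    tss, hit = make_scene()
    mmap = MotifTFMap({("M1", "TFA")})
    hits = [hit(12000, "M1", 1e-6),    # in A's window, passes
            hit(41000, "M1", 5e-6),    # in B's window, p above 1e-6 only
            hit(25000, "M1", 1e-9),    # outside all windows
            hit(12500, "MX", 1e-9)]    # unmapped matrix
    std = build_tfbs_network(hits, mmap, tss, ConstructionParams(pvalue_threshold=1e-5))
    assert std.edge_set() == {("TFA", "A"), ("TFA", "B")}
    hc = build_tfbs_network(hits, mmap, tss, ConstructionParams(pvalue_threshold=1e-6))
    assert hc.edge_set() == {("TFA", "A")}  # boundary p == threshold kept
    assert std.diagnostics["n_unmapped_matrix_hits"] == 1


def test_build_tfbs_many_to_many_matrix_expansion():
    tss, hit = make_scene()
    mmap = MotifTFMap({("M1", "TFA"), ("M1", "TFB")})
    net = build_tfbs_network([hit(41000, "M1", 1e-7)], mmap, tss, ConstructionParams())
    assert net.edge_set() == {("TFA", "B"), ("TFB", "B")}


def test_build_chip_window_presets():
    tss = [TSSAnnotation("A", "chr1", "+", (10000,))]
    peak = GenomicFeature("chr1", 12000, 12200)  # distance 2100
    wide = build_chip_network([peak], "TF1", tss, ConstructionParams(window_bp=5000))
    assert wide.edge_set() == {("TF1", "A")}
    (ev,) = wide.edges[("TF1", "A")].evidence
    assert ev.kind == "ChIP" and ev.tss_distance_bp == 2100
    narrow = build_chip_network([peak], "TF1", tss, ConstructionParams(window_bp=500))
    assert len(narrow) == 0  # worm/fly window excludes the peak
    assert len(build_chip_network([], "TF1", tss, ConstructionParams())) == 0


def test_open_chromatin_overlay_and_footprint_rules():
    tss, hit = make_scene()
    mmap = MotifTFMap({("M1", "TFA")})
    h = [hit(12000, "M1", 1e-7)]  # occupies [12000, 12010)
    params = ConstructionParams()
    covering = GenomicFeature("chr1", 11995, 12020)       # 25 bp, contains hit
    touching = GenomicFeature("chr1", 12005, 12100)       # overlaps, no containment
    long_peak = GenomicFeature("chr1", 11990, 12040)      # 50 bp: not a footprint

    assert build_open_chromatin_network([covering], h, mmap, tss, params).edge_set() \
        == {("TFA", "A")}
    assert len(build_open_chromatin_network([], h, mmap, tss, params)) == 0
    # plain overlay: intersection suffices
    assert len(build_open_chromatin_network([touching], h, mmap, tss, params)) == 1
    # footprint mode: needs full containment in a 6-40 bp peak
    fp = build_open_chromatin_network([touching], h, mmap, tss, params, footprint_mode=True)
    assert len(fp) == 0
    fp2 = build_open_chromatin_network([covering], h, mmap, tss, params, footprint_mode=True)
    assert fp2.edge_set() == {("TFA", "A")}
    assert (ev.kind == "OpenChromatin" for ev in fp2.edges[("TFA", "A")].evidence)
    # a 50 bp peak is outside the 6-40 bp footprint length range
    fp3 = build_open_chromatin_network([long_peak], h, mmap, tss, params, footprint_mode=True)
    assert len(fp3) == 0 and fp3.diagnostics["n_eligible_open_peaks"] == 0


def test_window_and_threshold_monotonicity(small_bundle):
    sp = small_bundle.species["S1"]
    for w1, w2 in [(500, 2000), (2000, 5000)]:
        e1 = build_tfbs_network(sp.hits, sp.motif_map, sp.tss,
                                ConstructionParams(window_bp=w1)).edge_set()
        e2 = build_tfbs_network(sp.hits, sp.motif_map, sp.tss,
                                ConstructionParams(window_bp=w2)).edge_set()
        assert e1 <= e2
    hc = build_tfbs_network(sp.hits, sp.motif_map, sp.tss,
                            ConstructionParams(pvalue_threshold=1e-6)).edge_set()
    std = build_tfbs_network(sp.hits, sp.motif_map, sp.tss,
                             ConstructionParams(pvalue_threshold=1e-5)).edge_set()
    assert hc <= std


def test_overlay_subset_of_tfbs(small_bundle):
    sp = small_bundle.species["S1"]
    params = ConstructionParams()
    tfbs = build_tfbs_network(sp.hits, sp.motif_map, sp.tss, params).edge_set()
    for fp in (False, True):
        oc = build_open_chromatin_network(sp.open_peaks, sp.hits, sp.motif_map,
                                          sp.tss, params, footprint_mode=fp).edge_set()
        assert oc <= tfbs
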