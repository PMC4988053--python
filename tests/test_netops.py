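"""Network set algebra, orthology transfer, and the three filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ddrnet import (DataError, Evidence, Network, NetworkMetadata,
                    OrthologyMap, binding_site_filter, difference_networks,
                    gene_set_filter, GenomicFeature, intersect_networks,
                    read_orthology, support_filter, transfer_network,
                    union_networks)
from conftest import make_network, random_network


A = lambda: make_network([("x", "y"), ("x", "z")], network_id="A")
B = lambda: make_network([("x", "y")], network_id="B")


class TestSetOps:
    def test_union_evidence_and_support(self):
        u = union_networks([A(), B()])
        assert u.edge_set() == {("x", "y"), ("x", "z")}
        assert u.edges[("x", "y")].support == 2
        assert u.edges[("x", "z")].support == 1

    def test_union_identity_and_neutral_element(self):
        assert union_networks([A()]).edge_set() == A().edge_set()
        assert union_networks([A(), make_network([], network_id="E")]).edge_set() \
            == A().edge_set()

    def test_intersection(self):
        assert intersect_networks([A(), B()]).edge_set() == {("x", "y")}
        assert intersect_networks([A(), A()]).edge_set() == A().edge_set()
        disjoint = make_network([("p", "q")], network_id="C")
        assert len(intersect_networks([A(), disjoint])) == 0

    def test_difference(self):
        assert difference_networks(A(), B()).edge_set() == {("x", "z")}
        assert len(difference_networks(A(), A())) == 0
        assert difference_networks(A(), make_network([], network_id="E")).edge_set() \
            == A().edge_set()

    def test_operations_leave_inputs_untouched(self):
        a, b = A(), B()
        union_networks([a, b]); intersect_networks([a, b]); difference_networks(a, b)
        assert a.edge_set() == {("x", "y"), ("x", "z")} and len(b) == 1

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_inclusion_exclusion_and_subset_laws(self, seed):
        rng = np.random.default_rng(seed)
        a = random_network(rng, "A")
        b = random_network(rng, "B")
        u = union_networks([a, b]).edge_set()
        i = intersect_networks([a, b]).edge_set()
        d = difference_networks(a, b).edge_set()
        assert len(u) == len(a.edges) + len(b.edges) - len(i)
        assert i <= a.edge_set() and i <= b.edge_set()
        assert d & b.edge_set() == set()
        assert u == union_networks([b, a]).edge_set()  # commutative


class TestTransfer:
    def test_one_to_many_cross_product(self):
        n = make_network([("a", "b")], network_id="n", species="sp1")
        orth = OrthologyMap("sp1", "sp2", {("a", "a'"), ("b", "b1'"), ("b", "b2'")})
        t = transfer_network(n, orth)
        assert t.edge_set() == {("a'", "b1'"), ("a'", "b2'")}
        assert t.metadata.species == "sp2"
        for edge in t:
            assert all(ev.kind == "Transferred" and ev.origin_edge == ("a", "b")
                       for ev in edge.evidence)

    def test_identity_map_fixes_network(self):
        n = make_network([("a", "b"), ("b", "c")], network_id="n")
        orth = OrthologyMap("s", "s", {(g, g) for g in n.nodes})
        assert transfer_network(n, orth).edge_set() == n.edge_set()

    def test_unmapped_endpoint_drops_edge(self):
        n = make_network([("a", "b")], network_id="n")
        t = transfer_network(n, OrthologyMap("s1", "s2", {("a", "a'")}))
        assert len(t) == 0 and t.diagnostics["n_dropped_edges"] == 1

    def test_one2one_only_policy_skips_multi_orthologs(self):
        n = make_network([("a", "b"), ("a", "c")], network_id="n")
        orth = OrthologyMap("s1", "s2",
                            {("a", "a'"), ("b", "b1'"), ("b", "b2'"), ("c", "c'")})
        t = transfer_network(n, orth, policy="one2one_only")
        assert t.edge_set() == {("a'", "c'")}
        assert t.diagnostics["n_dropped_edges"] == 1

    def test_species_mismatch_raises(self):
        n = make_network([("a", "b")], network_id="n", species="human")
        with pytest.raises(DataError):
            transfer_network(n, OrthologyMap("mouse", "human", {("a", "x")}))

    @pytest.mark.parametrize("seed", range(10))
    def test_bijective_roundtrip_is_identity(self, seed):
        rng = np.random.default_rng(seed)
        n = random_network(rng, "n")
        orth = OrthologyMap("s1", "s2", {(g, g + "'") for g in n.nodes})
        back = transfer_network(transfer_network(n, orth), orth.inverse())
        assert back.edge_set() == n.edge_set()

    def test_support_survives_transfer(self):
        u = union_networks([A(), B()])
        orth = OrthologyMap("", "", {(g, g + "'") for g in u.nodes})
        t = transfer_network(u, orth)
        assert t.edges[("x'", "y'")].support == 2


class TestFilters:
    def test_gene_set_filter_modes(self):
        n = make_network([("x", "y"), ("x", "z")])
        assert gene_set_filter(n, {"x", "y"}).edge_set() == {("x", "y")}
        assert gene_set_filter(n, {"y"}, "any_endpoint").edge_set() == {("x", "y")}
        assert len(gene_set_filter(n, set())) == 0
        assert gene_set_filter(n, {"x", "y", "z", "w"}).edge_set() == n.edge_set()

    def test_support_filter_thresholds(self):
        nets = [make_network(e, network_id=f"n{i}") for i, e in enumerate(
            [[("x", "y"), ("x", "z"), ("y", "z")],
             [("x", "y"), ("x", "z")],
             [("x", "y")]])]
        u = union_networks(nets)
        assert len(support_filter(u, 2)) == 2
        assert support_filter(u, 1).edge_set() == u.edge_set()
        assert support_filter(u, 3).edge_set() == {("x", "y")}

    @pytest.mark.parametrize("seed", range(10))
    def test_support_filter_k_equals_intersection(self, seed):
        rng = np.random.default_rng(100 + seed)
        k = int(rng.integers(2, 5))
        nets = [random_network(rng, f"n{i}") for i in range(k)]
        assert support_filter(union_networks(nets), k).edge_set() \
            == intersect_networks(nets).edge_set()

    def _evidence_net(self):
        n = Network(NetworkMetadata(network_id="n"))
        feat = GenomicFeature("chr1", 0, 10)
        n.add_evidence("t", "g", [
            Evidence(kind="TFBS", source_network_id="s1", feature=feat,
                     p_value=1e-6, tss_distance_bp=2100),
            Evidence(kind="TFBS", source_network_id="s2", feature=feat,
                     p_value=1e-3, tss_distance_bp=-6000),
        ])
        n.add_evidence("t", "h", Evidence(kind="Literature",
                                          source_network_id="s3", pmids=("1",)))
        return n

    def test_binding_site_filter_pvalue_boundary_inclusive(self):
        out = binding_site_filter(self._evidence_net(), max_pvalue=1e-6)
        assert out.edge_set() == {("t", "g")}
        assert len(out.edges[("t", "g")].evidence) == 1

    def test_binding_site_filter_distance_absolute(self):
        out = binding_site_filter(self._evidence_net(), max_tss_distance_bp=5000)
        (edge,) = list(out)
        assert edge.key == ("t", "g")
        assert [ev.tss_distance_bp for ev in edge.evidence] == [2100]

    def test_edge_lacking_attribute_fails_criterion(self):
        # literature-only edge has no p-value: removed by a p-value filter
        out = binding_site_filter(self._evidence_net(), max_pvalue=1e-2)
        assert ("t", "h") not in out.edge_set()

    def test_criteria_conjunctive_within_one_record(self):
        n = self._evidence_net()
        # p passes on record 1, distance on neither jointly with that p
        out = binding_site_filter(n, max_pvalue=1e-3, max_tss_distance_bp=3000)
        assert out.edge_set() == {("t", "g")}
        out2 = binding_site_filter(n, max_pvalue=1e-4, max_tss_distance_bp=5500)
        assert out2.edge_set() == {("t", "g")}  # record 1 satisfies both
        out3 = binding_site_filter(n, max_pvalue=1e-4, max_tss_distance_bp=1000)
        assert len(out3) == 0

    def test_no_criterion_is_an_error(self):
        with pytest.raises(ValueError):
            binding_site_filter(self._evidence_net())

    @pytest.mark.parametrize("seed", range(5))
    def test_filters_monotone_under_tightening(self, seed):
        rng = np.random.default_rng(200 + seed)
        nets = [random_network(rng, f"n{i}") for i in range(3)]
        u = union_networks(nets)
        for k1, k2 in [(1, 2), (2, 3)]:
            assert support_filter(u, k2).edge_set() <= support_filter(u, k1).edge_set()
        genes = sorted(u.nodes)
        small, large = set(genes[:4]), set(genes[:8])
        assert gene_set_filter(u, small).edge_set() <= gene_set_filter(u, large).edge_set()


def test_read_orthology_with_species_header(tmp_path):
    p = tmp_path / "orth.tsv"
    p.write_text("#human\tmouse\ng1\tm1\ng1\tm2\ng2\tm3\n")
    omap = read_orthology(p)
    assert (omap.species_from, omap.species_to) == ("human", "mouse")
    assert omap.orthologs("g1") == ["m1", "m2"]
    assert len(omap) == 3
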