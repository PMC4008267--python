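"""Pearson scoring, sign classification, network assembly/export, recovery."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirtarnet import (
    CandidatePair,
    DECriteria,
    InteractionEdge,
    TargetCorrelationModel,
    build_network,
    call_de,
    export_network,
    pearson_r,
    recovery,
    score_pairs,
)
from mirtarnet.errors import ConsistencyError


def pearson_bruteforce(x, y):
    """Direct covariance / sd oracle."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    dx, dy = x - x.mean(), y - y.mean()
    return float(np.sum(dx * dy) / math.sqrt(np.sum(dx**2) * np.sum(dy**2)))


class TestPearson:
    def test_exact_anticorrelation(self):
        r, n = pearson_r([1, 2, 3], [3, 2, 1])
        assert r == -1.0 and n == 3

    def test_self_correlation(self):
        assert pearson_r([1, 2, 3], [1, 2, 3])[0] == 1.0

    def test_against_direct_computation(self):
        x, y = [1, 2, 3, 5], [2, 1, 4, 3]
        r, _ = pearson_r(x, y)
        assert r == pytest.approx(pearson_bruteforce(x, y))
        assert r == pytest.approx(0.5292, abs=1e-4)

    def test_against_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(42)
        for _ in range(50):
            x = rng.normal(size=int(rng.integers(3, 20)))
            y = rng.normal(size=x.size)
            assert pearson_r(x, y)[0] == pytest.approx(
                stats.pearsonr(x, y).statistic, abs=1e-12
            )

    def test_zero_variance_signals_undefined(self):
        r, n = pearson_r([1.0, 1.0, 1.0], [1, 2, 3])
        assert math.isnan(r) and n == 3

    def test_length_mismatch_and_short_input(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            pearson_r([1, 2], [2, 1])

    @given(
        xs=st.lists(st.floats(-50, 50), min_size=3, max_size=12),
        a=st.floats(0.1, 10),
        b=st.floats(-5, 5),
    )
    @settings(derandomize=True, max_examples=200)
    def test_symmetry_affine_invariance_negation(self, xs, a, b):
        rng = np.random.default_rng(abs(hash(tuple(xs))) % 2**31)
        ys = list(rng.normal(0, 1, len(xs)))
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            return
        r, _ = pearson_r(xs, ys)
        assert pearson_r(ys, xs)[0] == pytest.approx(r, abs=1e-9)
        scaled = [a * x + b for x in xs]
        if np.ptp(scaled) > 0:
            assert pearson_r(scaled, ys)[0] == pytest.approx(r, rel=1e-6, abs=1e-9)
        assert pearson_r([-x for x in xs], ys)[0] == pytest.approx(-r, abs=1e-9)


@pytest.fixture(scope="module")
def scored(noise_free_bundle):
    b = noise_free_bundle
    candidates = [
        CandidatePair(e.mirna_id, e.gene_id, frozenset({"truthful"}))
        for e in b.truth.edges[:10]
    ]
    # one candidate pointing at an unregulated, flat gene
    flat_gene = sorted(set(g.gene_id for g in b.utrs) - {e.gene_id for e in b.truth.edges})[0]
    candidates.append(CandidatePair(b.truth.edges[0].mirna_id, flat_gene, frozenset({"t"})))
    return b, score_pairs(candidates, b.mirna_matrix, b.mrna_matrix)


class TestScorePairs:
    def test_planted_edges_high_confidence(self, scored):
        b, edges = scored
        for e in edges[:10]:
            assert e.r == -1.0
            assert e.sign == "negative"
            assert e.high_confidence

    def test_flat_gene_unclassified(self, scored):
        _, edges = scored
        assert edges[-1].sign == "none"
        assert not edges[-1].high_confidence

    def test_missing_feature_named(self, noise_free_bundle):
        b = noise_free_bundle
        with pytest.raises(LookupError, match="miR-999"):
            score_pairs(
                [CandidatePair("miR-999", "GENE0001", frozenset({"t"}))],
                b.mirna_matrix,
                b.mrna_matrix,
            )

    def test_noisy_true_candidates_mostly_negative(self, default_bundle):
        b = default_bundle
        candidates = [
            CandidatePair(e.mirna_id, e.gene_id, frozenset({"x"})) for e in b.truth.edges
        ]
        edges = score_pairs(candidates, b.mirna_matrix, b.mrna_matrix)
        frac_neg = np.mean([e.sign == "negative" for e in edges])
        assert frac_neg >= 0.9

    def test_intensity_mode_runs(self, default_bundle):
        b = default_bundle
        cand = [CandidatePair(e.mirna_id, e.gene_id, frozenset({"x"}))
                for e in b.truth.edges[:5]]
        edges = score_pairs(cand, b.mirna_matrix, b.mrna_matrix, mode="intensity")
        assert all(e.n == 24 for e in edges)

    def test_invalid_edge_construction_rejected(self):
        with pytest.raises(ValueError):
            InteractionEdge("m", "g", 1.5, 12, "positive", False, 1)
        with pytest.raises(ValueError):
            InteractionEdge("m", "g", 0.9, 12, "positive", True, 1)


class TestModelResults:
    def test_fit_returns_classified_results(self, default_bundle):
        b = default_bundle
        cand = [CandidatePair(e.mirna_id, e.gene_id, frozenset({"x"}))
                for e in b.truth.edges]
        res = TargetCorrelationModel(cand, b.mirna_matrix, b.mrna_matrix).fit(r_min=0.5)
        assert len(res.edges) == len(cand)
        assert set(res.frame.columns) >= {"mirna_id", "gene_id", "r", "sign"}
        assert "high-confidence" in res.summary()

    def test_recovery_from_results(self, noise_free_bundle):
        b = noise_free_bundle
        cand = [CandidatePair(e.mirna_id, e.gene_id, frozenset({"x"}))
                for e in b.truth.edges]
        res = TargetCorrelationModel(cand, b.mirna_matrix, b.mrna_matrix).fit()
        rep = res.recovery(b.truth)
        assert rep.precision == rep.recall == 1.0


@pytest.fixture(scope="module")
def toy_network(noise_free_bundle):
    b = noise_free_bundle
    de_mir = call_de(b.mirna_matrix, DECriteria(), "d9")
    de_gene = call_de(b.mrna_matrix, DECriteria(), "d9")
    cand = [CandidatePair(e.mirna_id, e.gene_id, frozenset({"x"}))
            for e in b.truth.edges[:6]]
    edges = score_pairs(cand, b.mirna_matrix, b.mrna_matrix)
    tf = [b.truth.edges[0].gene_id]
    return build_network(edges, de_mir, de_gene, tf), edges, tf


class TestBuildAndExport:
    def test_bipartite_with_roles(self, toy_network):
        net, edges, tf = toy_network
        assert net.number_of_edges() == 6
        assert nx.is_bipartite(net)
        roles = nx.get_node_attributes(net, "role")
        assert roles[tf[0]] == "transcription_factor"
        assert {roles[e.mirna_id] for e in edges} == {"mirna"}

    def test_structural_invariants(self, toy_network):
        net, _, _ = toy_network
        for u, v, d in net.edges(data=True):
            assert abs(d["r"]) <= 1
            assert not d["high_confidence"] or d["sign"] == "negative"

    def test_unclassified_edges_excluded_by_default(self, noise_free_bundle, toy_network):
        b = noise_free_bundle
        net, edges, _ = toy_network
        flat_gene = sorted(
            set(u.gene_id for u in b.utrs) - {e.gene_id for e in b.truth.edges}
        )[0]
        extra = score_pairs(
            [CandidatePair(b.truth.edges[0].mirna_id, flat_gene, frozenset({"t"}))],
            b.mirna_matrix,
            b.mrna_matrix,
        )
        de_mir = call_de(b.mirna_matrix, DECriteria(), "d9")
        de_gene = call_de(b.mrna_matrix, DECriteria(), "d9")
        dropped = build_network(edges + extra, de_mir, de_gene)
        kept = build_network(edges + extra, de_mir, de_gene, keep_unclassified=True)
        assert dropped.number_of_edges() == 6
        assert kept.number_of_edges() == 7

    def test_missing_de_annotation_rejected(self, toy_network, noise_free_bundle):
        b = noise_free_bundle
        net, edges, _ = toy_network
        de_mir = call_de(b.mirna_matrix, DECriteria(), "d9")
        de_gene = call_de(b.mrna_matrix.subset(["GENE0001"]), DECriteria(), "d9")
        bad = [e for e in edges if e.gene_id != "GENE0001"]
        with pytest.raises(ConsistencyError):
            build_network(bad, de_mir, de_gene)

    def test_sif_lines_and_edge_colors(self, toy_network, tmp_path):
        net, edges, _ = toy_network
        paths = export_network(net, tmp_path, "SIF")
        lines = paths["network"].read_text().splitlines()
        assert len(lines) == 6
        assert lines == sorted(lines)
        assert all(line.split("\t")[1] == "negative" for line in lines)
        edge_lines = paths["edges"].read_text().splitlines()[1:]
        # negative correlation is drawn green, positive red
        assert all(line.endswith("green") for line in edge_lines)

    def test_graphml_round_trip(self, toy_network, tmp_path):
        net, _, _ = toy_network
        paths = export_network(net, tmp_path, "GraphML")
        back = nx.read_graphml(paths["network"])
        assert set(back.nodes) == set(net.nodes)
        for u, v, d in net.edges(data=True):
            d2 = back.edges[u, v]
            assert d2["sign"] == d["sign"]
            assert float(d2["r"]) == pytest.approx(d["r"])
            assert d2["color"] == d["color"]

    def test_byte_stable_export(self, toy_network, tmp_path):
        net, _, _ = toy_network
        p1 = export_network(net, tmp_path / "a", "SIF")
        p2 = export_network(net, tmp_path / "b", "SIF")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_unknown_format_rejected(self, toy_network, tmp_path):
        net, _, _ = toy_network
        with pytest.raises(ValueError):
            export_network(net, tmp_path, "dot")


class TestRecovery:
    def edge(self, m, g, hc=True):
        return InteractionEdge(m, g, -0.9 if hc else 0.9, 12,
                               "negative" if hc else "positive", hc, 3)

    def test_perfect_recovery(self):
        truth = {("m1", "g1"), ("m2", "g2")}
        edges = [self.edge("m1", "g1"), self.edge("m2", "g2")]
        rep = recovery(truth, edges)
        assert rep.precision == rep.recall == rep.f1 == 1.0

    def test_disjoint_sets(self):
        rep = recovery({("m1", "g1")}, [self.edge("m9", "g9")])
        assert rep.precision == 0.0 and rep.recall == 0.0

    def test_partial_overlap_arithmetic(self):
        truth = {(f"m{i}", f"g{i}") for i in range(10)}
        edges = [self.edge(f"m{i}", f"g{i}") for i in range(8)]
        edges += [self.edge("mx", "gx"), self.edge("my", "gy")]
        rep = recovery(truth, edges)
        assert rep.true_positives == 8
        assert rep.precision == pytest.approx(0.8)
        assert rep.recall == pytest.approx(0.8)
        assert rep.f1 == pytest.approx(0.8)

    def test_high_conf_filter(self):
        truth = {("m1", "g1")}
        edges = [self.edge("m1", "g1", hc=False)]
        assert recovery(truth, edges, high_conf_only=True).recall == 0.0
        assert recovery(truth, edges, high_conf_only=False).recall == 1.0

    def test_empty_inference_flagged(self):
        rep = recovery({("m1", "g1")}, [])
        assert rep.precision == 1.0 and not rep.precision_defined
        assert rep.recall == 0.0
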