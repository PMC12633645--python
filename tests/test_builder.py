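"""Pair generation, correlation testing and snapshot/network assembly.

The correlation oracle here is a from-scratch evaluation of
r = sum(dx*dy) / sqrt(sum(dx^2) * sum(dy^2)) and the two-sided p-value
2*S(|t|; n-2) with t = r*sqrt((n-2)/(1-r^2)) — independent of the
implementation path under test.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import tgcn
from tgcn.builder import REASON_CONSTANT, REASON_UNDERSIZED
from tgcn.synthetic import PlantedContact, PlantedDesign, StratumSpec


def oracle_pearson(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    dx = x - x.mean()
    dy = y - y.mean()
    r = float(np.sum(dx * dy) / math.sqrt(np.sum(dx**2) * np.sum(dy**2)))
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


class TestGeneratePairs:
    @pytest.mark.parametrize("n", [2, 3, 8, 50])
    def test_counts_and_canonical_order(self, n):
        genes = [f"G{i:03d}" for i in range(n)]
        pairs = tgcn.generate_pairs(genes)
        assert len(pairs) == n * (n - 1) // 2
        assert len(set(pairs)) == len(pairs)
        assert all(a < b for a, b in pairs)
        assert pairs == sorted(pairs)

    def test_matches_brute_force_enumeration(self):
        genes = sorted(tgcn.CASE_STUDY_GENES)
        expected = [
            (genes[i], genes[j])
            for i in range(len(genes))
            for j in range(i + 1, len(genes))
        ]
        assert tgcn.generate_pairs(tgcn.CASE_STUDY_GENES) == sorted(expected)
        assert len(expected) == 28

    def test_single_gene_warns_and_yields_nothing(self):
        with pytest.warns(UserWarning):
            assert tgcn.generate_pairs(["G1"]) == []

    def test_input_order_does_not_matter(self):
        assert tgcn.generate_pairs(["B", "A", "C"]) == tgcn.generate_pairs(
            ["C", "A", "B"]
        )


class TestCorrelate:
    def test_hand_derived_example(self):
        # sum(dx*dy)=4, sum(dx^2)=sum(dy^2)=5 -> r = 4/5
        c = tgcn.correlate([1, 2, 3, 4], [1, 3, 2, 4])
        assert c.r == pytest.approx(0.8)

    def test_self_correlation_is_one(self):
        c = tgcn.correlate([1.0, 2.5, 4.0], [1.0, 2.5, 4.0])
        assert c.r == pytest.approx(1.0)

    def test_sign_flip_gives_minus_one(self):
        c = tgcn.correlate([1, 2, 3], [-1, -2, -3])
        assert c.r == pytest.approx(-1.0)

    def test_constant_vector_flagged_undefined(self):
        c = tgcn.correlate([1, 1, 1, 1], [1, 2, 3, 4])
        assert not c.defined and c.reason == REASON_CONSTANT

    def test_undersized_flagged_undefined(self):
        c = tgcn.correlate([1, 2], [3, 4])
        assert not c.defined and c.reason == REASON_UNDERSIZED and c.n == 2

    def test_length_mismatch_is_alignment_error(self):
        with pytest.raises(tgcn.AlignmentError):
            tgcn.correlate([1, 2, 3], [1, 2])

    def test_matches_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        worst_r = worst_p = 0.0
        for _ in range(1000):
            n = int(rng.integers(3, 201))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + rng.uniform(-1, 1) * x
            c = tgcn.correlate(x, y)
            r_ref, p_ref = oracle_pearson(x, y)
            worst_r = max(worst_r, abs(c.r - r_ref) / max(abs(r_ref), 1e-300))
            worst_p = max(worst_p, abs(c.p - p_ref) / max(p_ref, 1e-300))
        assert worst_r < 1e-12 and worst_p < 1e-12

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(-1e3, 1e3, allow_nan=False),
                st.floats(-1e3, 1e3, allow_nan=False),
            ),
            min_size=3,
            max_size=40,
        )
    )
    def test_oracle_equivalence_property(self, data):
        x = [a for a, _ in data]
        y = [b for _, b in data]
        c = tgcn.correlate(x, y)
        if not c.defined:
            assert np.ptp(x) == 0 or np.ptp(y) == 0
            return
        r_ref, p_ref = oracle_pearson(x, y)
        assert c.r == pytest.approx(r_ref, rel=1e-9, abs=1e-9)
        assert c.p == pytest.approx(p_ref, rel=1e-9, abs=1e-12)


def make_stratum(label, vectors):
    vecs = {g: np.asarray(v, float) for g, v in vectors.items()}
    n = len(next(iter(vecs.values())))
    return tgcn.ExpressionStratum(
        age_group=tgcn.AgeGroup(label),
        tissues=frozenset({"t"}),
        vectors=vecs,
        sample_ids=tuple(f"s{i}" for i in range(n)),
    )


class TestBuildSnapshot:
    def test_strict_threshold_boundary(self):
        # choose vectors, then verify the retained set against computed p
        rng = np.random.default_rng(0)
        stratum = make_stratum(
            "20-29", {g: rng.normal(size=10) for g in ("A", "B", "C")}
        )
        pairs = tgcn.generate_pairs(["A", "B", "C"])
        results = {
            (res.gene_i, res.gene_j): res
            for res in tgcn.build_snapshot(stratum, pairs, alpha=0.5)[1]
        }
        for alpha in (0.05, 0.5, 0.9):
            snap, _ = tgcn.build_snapshot(stratum, pairs, alpha=alpha)
            expected = {pair for pair, res in results.items() if res.p < alpha}
            assert set(snap.edges) == expected

    def test_p_equal_alpha_excluded_p_below_included(self):
        # exact-boundary semantics exercised directly on the retention rule
        stratum = make_stratum("20-29", {"A": [1, 2, 3, 4], "B": [1, 3, 2, 4]})
        c = tgcn.correlate(stratum.vectors["A"], stratum.vectors["B"])
        snap_at, _ = tgcn.build_snapshot(stratum, [("A", "B")], alpha=c.p)
        assert snap_at.n_edges == 0
        snap_above, _ = tgcn.build_snapshot(
            stratum, [("A", "B")], alpha=min(c.p * 1.001, 0.999)
        )
        assert snap_above.n_edges == 1

    def test_undersized_stratum_yields_no_edges(self):
        stratum = make_stratum("30-39", {"A": [1, 2], "B": [2, 1]})
        snap, results = tgcn.build_snapshot(stratum, [("A", "B")], alpha=0.05)
        assert snap.n_edges == 0
        assert all(res.reason == REASON_UNDERSIZED for res in results)

    def test_isolated_nodes_kept(self):
        stratum = make_stratum("30-39", {"A": [1, 2, 3], "B": [9, 9, 9]})
        snap, _ = tgcn.build_snapshot(stratum, [("A", "B")], alpha=0.05)
        assert set(snap.nodes) == {"A", "B"}

    def test_missing_endpoint_is_lookup_error(self):
        stratum = make_stratum("30-39", {"A": [1, 2, 3]})
        with pytest.raises(tgcn.GeneLookupError, match="'B'"):
            tgcn.build_snapshot(stratum, [("A", "B")], alpha=0.05)

    def test_audit_lists_every_pair(self):
        rng = np.random.default_rng(1)
        stratum = make_stratum(
            "40-49", {g: rng.normal(size=8) for g in "ABCD"}
        )
        pairs = tgcn.generate_pairs(list("ABCD"))
        _, results = tgcn.build_snapshot(stratum, pairs, alpha=1e-9)
        assert len(results) == 6

    def test_positive_only_drops_negative_edges(self):
        stratum = make_stratum(
            "20-29",
            {"A": [1, 2, 3, 4, 5], "B": [5, 4, 3, 2, 1], "C": [1.1, 2, 3.2, 3.9, 5]},
        )
        pairs = tgcn.generate_pairs(["A", "B", "C"])
        both, _ = tgcn.build_snapshot(stratum, pairs, alpha=0.05)
        pos, _ = tgcn.build_snapshot(stratum, pairs, alpha=0.05, positive_only=True)
        assert ("A", "B") in both.edges and ("A", "B") not in pos.edges
        assert ("A", "C") in pos.edges

    def test_bh_correction_is_no_less_conservative(self):
        rng = np.random.default_rng(7)
        stratum = make_stratum(
            "50-59", {f"G{i}": rng.normal(size=20) for i in range(6)}
        )
        pairs = tgcn.generate_pairs([f"G{i}" for i in range(6)])
        raw, _ = tgcn.build_snapshot(stratum, pairs, alpha=0.3)
        bh, _ = tgcn.build_snapshot(stratum, pairs, alpha=0.3, bh=True)
        assert set(bh.edges) <= set(raw.edges)


class TestBuildTemporalNetwork:
    def test_planted_pair_recovered_only_in_its_stratum(self):
        design = PlantedDesign(
            genes=("GA", "GB", "GC"),
            strata={lab: StratumSpec(n=20) for lab in tgcn.AGE_GROUP_LABELS},
            planted=(PlantedContact("GA", "GB", "30-39", 0.99),),
            seed=5,
        )
        ds, _ = tgcn.generate(design)
        tn, _ = tgcn.build_temporal_network(["GA", "GB", "GC"], ds, workers=1)
        contact = tgcn.contact_of(tn, "GA", "GB")
        assert contact[tgcn.AgeGroup("30-39").index].present

    def test_alpha_near_one_keeps_every_defined_pair(self, small_dataset):
        ds, _ = small_dataset
        tn, audit = tgcn.build_temporal_network(
            ["GA", "GB", "GC", "GD"], ds, alpha=1 - 1e-12, workers=1
        )
        defined = sum(1 for res in audit if res.defined)
        assert tn.n_edges == defined

    def test_alpha_monotonicity(self, small_dataset):
        ds, _ = small_dataset
        genes = ["GA", "GB", "GC", "GD"]
        tn_loose, _ = tgcn.build_temporal_network(genes, ds, alpha=0.5, workers=1)
        tn_tight, _ = tgcn.build_temporal_network(genes, ds, alpha=0.01, workers=1)
        for s_tight, s_loose in zip(tn_tight, tn_loose):
            assert set(s_tight.edges) <= set(s_loose.edges)

    def test_worker_count_invariance(self, small_dataset, tmp_path):
        ds, _ = small_dataset
        genes = ["GA", "GB", "GC", "GD"]
        exports = {}
        for workers in (1, 4):
            tn, _ = tgcn.build_temporal_network(genes, ds, workers=workers)
            out = tmp_path / f"w{workers}"
            paths = tgcn.export_edge_lists(tn, out)
            exports[workers] = [p.read_bytes() for p in paths]
        assert exports[1] == exports[4]

    def test_fewer_than_two_genes_rejected(self, small_dataset):
        ds, _ = small_dataset
        with pytest.raises(tgcn.ConfigurationError):
            tgcn.build_temporal_network(["GA"], ds)

    def test_invalid_alpha_rejected(self, small_dataset):
        ds, _ = small_dataset
        with pytest.raises(tgcn.ConfigurationError):
            tgcn.build_temporal_network(["GA", "GB"], ds, alpha=1.5)

    def test_no_surviving_stratum_is_empty_network_error(self, small_dataset):
        ds, _ = small_dataset
        with pytest.raises(tgcn.EmptyNetworkError):
            tgcn.build_temporal_network(
                ["GA", "GB"], ds, tissues={"nonexistent tissue"}
            )

    def test_gene_records_resolve_to_dataset_rows(self, small_dataset):
        ds, _ = small_dataset
        records = [
            tgcn.GeneRecord("ga", "ENSG00000999001.1", "GA"),
            tgcn.GeneRecord("gb", "ENSG00000999002.1", "GB"),
        ]
        tn, _ = tgcn.build_temporal_network(records, ds, workers=1)
        assert tn.nodes == ("GA", "GB")
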