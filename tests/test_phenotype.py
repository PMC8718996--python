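"""Uncertainty, vulnerability, cluster annotation and descriptive stats."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sbmpheno import (BehavioralTable, StochasticBlockModel,
                      adjusted_rand_index, annotate_clusters, anova_f,
                      build_report, connectivity_summary, flag_subjects,
                      occupancy, simulate_sbm_network, uncertainty,
                      vulnerability_score)
from sbmpheno.phenotype import AmbiguousAnnotationError
from sbmpheno.sbm import PosteriorSamples


def make_samples(z_rows, K=None):
    z = np.asarray(z_rows, dtype=int)
    K = K or int(z.max())
    S = z.shape[0]
    return PosteriorSamples(z=z, pi=np.full((S, K), 1 / K),
                            theta=np.full((S, K, K), 0.5),
                            log_post=np.zeros(S))


class TestUncertaintyVulnerability:
    def test_definitional_identities(self):
        # u_i = 1 - occupancy(i, z_map_i) exactly; occupancy rows sum to 1
        rows = [[1, 2, 2], [1, 1, 2], [1, 2, 2], [1, 1, 2], [2, 1, 2],
                [1, 2, 2], [1, 1, 2], [1, 2, 2], [1, 1, 2], [1, 1, 2]]
        s = make_samples(rows)
        z_map = np.array([1, 2, 2])
        occ = occupancy(s)
        np.testing.assert_allclose(occ.sum(axis=1), 1.0)
        u = uncertainty(s, z_map)
        np.testing.assert_allclose(
            u, 1 - occ[np.arange(3), z_map - 1])
        # subject 0 matches z_map in 9 of 10 samples -> u = 0.10
        assert u[0] == pytest.approx(0.10)
        v = vulnerability_score(s, 1)
        np.testing.assert_allclose(v, occ[:, 0])
        assert ((v >= 0) & (v <= 1)).all()

    def test_extremes(self):
        s = make_samples([[1, 2]] * 5)
        assert uncertainty(s, [1, 2]).tolist() == [0.0, 0.0]
        assert uncertainty(s, [2, 1]).tolist() == [1.0, 1.0]
        assert vulnerability_score(s, 1).tolist() == [1.0, 0.0]
        assert vulnerability_score(s, 2).tolist() == [0.0, 1.0]

    def test_dimension_and_range_errors(self):
        s = make_samples([[1, 2]] * 3)
        with pytest.raises(ValueError):
            uncertainty(s, [1, 2, 1])
        with pytest.raises(ValueError):
            vulnerability_score(s, 3)

    def test_boundary_nodes_have_higher_uncertainty(self):
        # a node wired equally into both blocks flips between them, while
        # core nodes stay put.  (Not node 0: the canonical first-occurrence
        # rule pins the first node's label, giving it zero uncertainty by
        # construction.)
        theta = np.array([[0.6, 0.05], [0.05, 0.6]])
        net, z = simulate_sbm_network(z=np.repeat([1, 2], 20), theta=theta,
                                      seed=3)
        A = net.A.copy()
        boundary = 10
        A[boundary, :] = 0
        A[:, boundary] = 0
        for j in list(range(0, 7)) + list(range(20, 27)):
            A[boundary, j] = A[j, boundary] = 1
        net2 = type(net)(A=A)
        res = StochasticBlockModel(net2, k=2).fit(4000, 500, seed=0)
        u = res.uncertainty()
        assert u[boundary] > np.median(np.delete(u, boundary))
        assert u[boundary] > 0.05


class TestAnnotateClusters:
    @staticmethod
    def table_with_labels(comps):
        # three clusters of 2 subjects, constant composite per cluster,
        # two sites interleaved so the table can be flagged standardized=False
        rows = []
        for k, c in enumerate(comps):
            for r in range(2):
                rows.append({"subject_id": f"s{k}_{r}", "site": "A",
                             "m1": c, "m2": c})
        df = pd.DataFrame(rows)
        t = BehavioralTable(data=df, measures=["m1", "m2"])
        t.standardized = True  # bypass moment check: synthetic composites
        z = np.repeat(np.arange(len(comps)) + 1, 2)
        return t, z

    def test_ordered_composites_named(self):
        t, z = self.table_with_labels([1.0, 0.0, -1.0])
        ann, k_v, comps = annotate_clusters(z, t)
        assert ann == {1: "vulnerable", 2: "intermediate", 3: "resilient"}
        assert k_v == 1
        assert comps[1] == pytest.approx(1.0)

    def test_orientation_flip_reverses_order(self):
        t, z = self.table_with_labels([1.0, 0.0, -1.0])
        ann, k_v, _ = annotate_clusters(z, t, orientation=[-1, -1])
        assert ann == {3: "vulnerable", 2: "intermediate", 1: "resilient"}
        assert k_v == 3

    def test_tied_composites_rejected(self):
        t, z = self.table_with_labels([0.5, 0.5, -1.0])
        with pytest.raises(AmbiguousAnnotationError):
            annotate_clusters(z, t)

    def test_non_three_k_gets_ordinal_ranks(self):
        t, z = self.table_with_labels([1.0, -1.0])
        ann, k_v, _ = annotate_clusters(z, t)
        assert ann == {1: "rank 1", 2: "rank 2"}
        assert k_v == 1


class TestFlagging:
    def test_threshold_rules(self):
        u = np.array([0.15, 0.05, 0.12])
        v = np.array([0.50, 0.99, 0.95])
        ids = np.array(["a", "b", "c"])
        uncertain, borderline = flag_subjects(u, v, ids=ids)
        assert uncertain == ["a", "c"]    # u > 0.10
        assert borderline == ["a"]        # u > 0.10 and v < 0.90
        # boundary values are excluded by the strict inequalities
        u2, b2 = flag_subjects(np.array([0.10]), np.array([0.90]))
        assert u2 == [] and b2 == []

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            flag_subjects([0.1], [0.5], u_thresh=1.5)


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        f, p = anova_f([1, 2, 3, 1, 2, 3], [1, 1, 1, 2, 2, 2])
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_f(self):
        # SSB = 4 (df 1), SSW = 1 (df 2) -> F = 8
        f, _ = anova_f([0, 1, 2, 3], [1, 1, 2, 2])
        assert f == pytest.approx(8.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            anova_f([1, 2, 3], [1, 1, 1])

    def test_zero_within_variance_flagged(self):
        with pytest.raises(ValueError, match="infinite"):
            anova_f([1, 1, 2, 2], [1, 1, 2, 2])


class TestARI:
    def test_unit_values(self):
        assert adjusted_rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0
        assert adjusted_rand_index([1, 1, 2, 2], [2, 2, 1, 1]) == 1.0
        assert adjusted_rand_index([1, 1, 2, 2],
                                   [1, 2, 1, 2]) == pytest.approx(-0.5)
        assert adjusted_rand_index([1, 2, 3, 4],
                                   [1, 1, 1, 1]) == pytest.approx(0.0)

    def test_against_pair_counting_oracle(self):
        # brute-force: ARI = (sum C(n_ij,2) - E) / (max - E)
        def oracle(z1, z2):
            from math import comb
            z1, z2 = np.asarray(z1), np.asarray(z2)
            n = len(z1)
            cells = {}
            for a, b in zip(z1, z2):
                cells[(a, b)] = cells.get((a, b), 0) + 1
            idx = sum(comb(c, 2) for c in cells.values())
            a_ = sum(comb(int((z1 == u).sum()), 2) for u in set(z1))
            b_ = sum(comb(int((z2 == u).sum()), 2) for u in set(z2))
            expected = a_ * b_ / comb(n, 2)
            mx = (a_ + b_) / 2
            return (idx - expected) / (mx - expected)

        rng = np.random.default_rng(0)
        for _ in range(20):
            z1 = rng.integers(1, 4, size=12)
            z2 = rng.integers(1, 4, size=12)
            if len(set(z1)) == 1 and len(set(z2)) == 1:
                continue
            assert adjusted_rand_index(z1, z2) == pytest.approx(
                oracle(z1, z2), abs=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(z1=st.lists(st.integers(1, 3), min_size=2, max_size=10),
           z2=st.lists(st.integers(1, 3), min_size=2, max_size=10))
    def test_symmetric_and_permutation_invariant(self, z1, z2):
        if len(z1) != len(z2):
            z2 = (z2 * len(z1))[: len(z1)]
        a = adjusted_rand_index(z1, z2)
        assert a == pytest.approx(adjusted_rand_index(z2, z1))
        relabeled = [{1: 3, 2: 1, 3: 2}[v] for v in z2]
        assert a == pytest.approx(adjusted_rand_index(z1, relabeled))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([1, 2], [1, 2, 3])


class TestConnectivitySummary:
    def test_constant_draws_zero_width(self):
        s = make_samples([[1, 2]] * 5)
        mean, lo, hi = connectivity_summary(s)
        np.testing.assert_allclose(mean, 0.5)
        np.testing.assert_allclose(lo, hi)

    def test_quantile_rule_on_grid(self):
        # draws 0.1 .. 1.0: mean 0.55; linear-interpolation quantiles give
        # [0.1225, 0.9775]
        vals = np.linspace(0.1, 1.0, 10)
        theta = np.tile(vals[:, None, None], (1, 1, 1))
        s = PosteriorSamples(z=np.ones((10, 2), dtype=int),
                             pi=np.ones((10, 1)), theta=theta,
                             log_post=np.zeros(10))
        mean, lo, hi = connectivity_summary(s)
        assert mean[0, 0] == pytest.approx(0.55)
        assert lo[0, 0] == pytest.approx(0.1225)
        assert hi[0, 0] == pytest.approx(0.9775)

    def test_symmetric_output(self, planted_network):
        net, _, _ = planted_network
        res = StochasticBlockModel(net, k=2).fit(500, 100, seed=0)
        mean, lo, hi = connectivity_summary(res.samples)
        np.testing.assert_array_equal(mean, mean.T)
        np.testing.assert_array_equal(lo, lo.T)
        np.testing.assert_array_equal(hi, hi.T)


class TestReport:
    def test_end_to_end_report(self, planted_network):
        net, z, _ = planted_network
        res = StochasticBlockModel(net, k=2).fit(800, 100, seed=1)
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "subject_id": [f"r{i}" for i in range(net.n)],
            "site": ["A"] * net.n,
            "m1": np.where(z == 1, 1.0, -1.0) + 0.01 * rng.normal(size=net.n),
        })
        table = BehavioralTable(data=df, measures=["m1"])
        table.standardized = True  # synthetic composite scale
        report = build_report(res, table)
        frame = report.to_frame()
        assert len(frame) == net.n
        assert set(frame.columns) >= {"subject_id", "cluster", "uncertainty",
                                      "vulnerability"}
        assert report.k_v in (1, 2)
        assert (report.anova["F"] > 0).all()
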