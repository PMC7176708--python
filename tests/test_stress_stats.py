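"""Weighted percentiles, PERMANOVA and Holm correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mandifem.errors import InvalidArgumentError
from mandifem.stress_stats import (
    holm_adjust,
    permanova,
    permanova_pairwise,
    summarize_specimen,
    weighted_percentile,
)


def expansion_oracle(values, int_weights, p):
    """Replicate each value by its integer weight; standard lower quantile."""
    expanded = np.repeat(values, int_weights)
    expanded.sort()
    n = expanded.size
    k = int(np.ceil(p / 100.0 * n)) - 1
    return expanded[max(k, 0)]


class TestWeightedPercentile:
    def test_constant_field(self):
        assert weighted_percentile([5.0, 5.0, 5.0], [1.0, 1.0, 1.0], 50) == 5.0

    def test_hand_case(self):
        # mass 1/4 on 1 and 3/4 on 2 -> the median is 2
        assert weighted_percentile([1.0, 2.0], [1.0, 3.0], 50) == 2.0

    def test_matches_expansion_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = int(rng.integers(1, 12))
            values = rng.normal(size=n) * 10
            weights = rng.integers(1, 10, size=n)
            p = float(rng.uniform(1, 99))
            assert weighted_percentile(values, weights, p) == expansion_oracle(
                values, weights, p
            )

    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30),
        st.floats(1.0, 99.0),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_uniform_weights_match_unweighted_quantile(self, values, p):
        values = np.asarray(values)
        w = np.ones_like(values)
        assert weighted_percentile(values, w, p) == expansion_oracle(
            values, np.ones(values.size, dtype=int), p
        )

    def test_invalid_inputs(self):
        with pytest.raises(InvalidArgumentError):
            weighted_percentile([], [], 50)
        with pytest.raises(InvalidArgumentError):
            weighted_percentile([1.0], [0.0], 50)
        with pytest.raises(InvalidArgumentError):
            weighted_percentile([1.0], [1.0], 0)


class TestSummarize:
    def _fake_field(self, vm):
        from mandifem.fem import StressField

        vm = np.asarray(vm, dtype=float)
        return StressField(
            element_vm=vm,
            element_components=np.zeros((vm.size, 3)),
            nodal_displacements=np.zeros((1, 2)),
        )

    def _mesh(self, n):
        from mandifem.meshing import structured_rect_mesh

        return structured_rect_mesh(1.0, 1.0, n, 1)

    def test_constant_field_all_percentiles_equal(self):
        mesh = self._mesh(4)
        fields = {s: self._fake_field(np.full(4, 2.5)) for s in ("IB", "CB", "PB", "MB")}
        summary = summarize_specimen(fields, mesh, "x")
        assert all(v == 2.5 for v in summary.values.values())

    def test_percentiles_monotone(self):
        rng = np.random.default_rng(1)
        mesh = self._mesh(50)
        fields = {
            s: self._fake_field(rng.gamma(2.0, 1.0, size=50))
            for s in ("IB", "CB", "PB", "MB")
        }
        summary = summarize_specimen(fields, mesh, "x")
        for s in ("IB", "CB", "PB", "MB"):
            vals = [summary.values[f"{s}_M{p}"] for p in (25, 50, 75, 95)]
            assert vals == sorted(vals)

    def test_linearity_under_force_doubling(self):
        rng = np.random.default_rng(2)
        mesh = self._mesh(20)
        vm = rng.gamma(2.0, 1.0, size=20)
        f1 = {s: self._fake_field(vm) for s in ("IB", "CB", "PB", "MB")}
        f2 = {s: self._fake_field(2 * vm) for s in ("IB", "CB", "PB", "MB")}
        s1 = summarize_specimen(f1, mesh, "x")
        s2 = summarize_specimen(f2, mesh, "x")
        np.testing.assert_allclose(s2.as_array(), 2 * s1.as_array(), rtol=1e-12)

    def test_missing_scenario_rejected(self):
        mesh = self._mesh(4)
        with pytest.raises(InvalidArgumentError, match="missing"):
            summarize_specimen({"IB": self._fake_field(np.ones(4))}, mesh, "x")


class TestPermanova:
    def test_matches_scikit_bio_pseudo_f(self):
        """Cross-check the pseudo-F against an independent implementation."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(3)
        x = rng.normal(size=(14, 5))
        groups = np.array(["a"] * 7 + ["b"] * 7)
        f_obs, _ = permanova(x, groups, n_perm=99, seed=0)
        from scipy.spatial.distance import pdist, squareform

        dm = skbio_stats.DistanceMatrix(squareform(pdist(x)))
        res = skbio_stats.permanova(dm, grouping=list(groups), permutations=99)
        assert f_obs == pytest.approx(res["test statistic"], rel=1e-10)

    def test_power_on_separated_groups(self):
        rng = np.random.default_rng(4)
        x = np.vstack([rng.normal(0, 1, (10, 3)), rng.normal(3, 1, (10, 3))])
        groups = np.array(["a"] * 10 + ["b"] * 10)
        _, p = permanova(x, groups, n_perm=999, seed=1)
        assert p <= 0.01

    def test_exact_enumeration_small_sample(self):
        """Monte-Carlo p agrees with exhaustive enumeration for n = 4 + 4."""
        from itertools import combinations

        rng = np.random.default_rng(5)
        x = rng.normal(size=(8, 3))
        x[:4] += 1.0
        groups = np.array(["a"] * 4 + ["b"] * 4)
        f_obs, p_mc = permanova(x, groups, n_perm=9999, seed=2)

        idx = np.arange(8)
        fs = []
        for combo in combinations(idx, 4):
            g = np.array(["b"] * 8)
            g[list(combo)] = "a"
            f, _ = permanova(x, g, n_perm=1, seed=0)
            fs.append(f)
        p_exact = np.mean(np.asarray(fs) >= f_obs - 1e-12)
        # MC error at 9999 permutations
        se = np.sqrt(p_exact * (1 - p_exact) / 9999)
        assert abs(p_mc - p_exact) < 4 * se + 1e-4

    def test_invariances(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(12, 4))
        groups = np.array(["a"] * 6 + ["b"] * 6)
        f0, p0 = permanova(x, groups, n_perm=499, seed=3)
        # permuting columns and shifting all rows leaves distances unchanged
        f1, p1 = permanova(x[:, ::-1] + 7.0, groups, n_perm=499, seed=3)
        assert f1 == pytest.approx(f0, rel=1e-10)
        assert p1 == p0

    def test_small_group_rejected(self):
        with pytest.raises(InvalidArgumentError):
            permanova(np.zeros((3, 2)), np.array(["a", "a", "b"]), n_perm=9)

    def test_pairwise_table(self):
        rng = np.random.default_rng(8)
        x = np.vstack(
            [rng.normal(0, 1, (6, 3)), rng.normal(2, 1, (6, 3)), rng.normal(4, 1, (6, 3))]
        )
        groups = np.array(["a"] * 6 + ["b"] * 6 + ["c"] * 6)
        table = permanova_pairwise(x, groups, n_perm=199, seed=0)
        assert len(table) == 3
        assert np.all(table["p_holm"] >= table["p_raw"])
        assert np.all((table["p_raw"] > 0) & (table["p_raw"] <= 1))


class TestHolm:
    def test_hand_computation(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.2]), [0.2])

    def test_all_ones_capped(self):
        np.testing.assert_allclose(holm_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(9)
        p = rng.uniform(size=10)
        _, adj, _, _ = sm.multipletests(p, method="holm")
        np.testing.assert_allclose(holm_adjust(p), adj, rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            holm_adjust([0.5, 1.5])
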