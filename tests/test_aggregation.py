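import numpy as np
import pytest

from imrf import (
    ImportanceTensor,
    aggregate,
    group_importances,
    intersect_and_rank,
    top_d,
)
from imrf.aggregation import GroupRanking, RankedFeatureList


# --------------------------------------------------------------------------
# independent brute-force reference: materializes every intermediate object
# with plain Python, no shared code with the implementation
# --------------------------------------------------------------------------

def brute_force_aggregate(rows, q, d):
    L, m = len(rows), len(rows[0])
    size = L // q
    group_vectors = []
    for g in range(q):
        vec = [sum(rows[l][j] for l in range(g * size, (g + 1) * size)) / size for j in range(m)]
        group_vectors.append(vec)
    top_sets = []
    for vec in group_vectors:
        order = sorted(range(m), key=lambda j: (-vec[j], j))
        top_sets.append(order[:d])
    common = set(top_sets[0])
    for s in top_sets[1:]:
        common &= set(s)
    entries = []
    for j in common:
        positions = [s.index(j) + 1 for s in top_sets]
        importances = [group_vectors[g][j] for g in range(q)]
        entries.append((j, sum(positions) / q, sum(importances) / q))
    entries.sort(key=lambda t: (t[1], -t[2], t[0]))
    return entries


def make_ranking(names_at_positions, importances=None, group_index=1):
    d = len(names_at_positions)
    return GroupRanking(
        group_index=group_index,
        feature_names=list(names_at_positions),
        positions=list(range(1, d + 1)),
        importances=importances or [float(d - i) for i in range(d)],
    )


class TestGroupImportances:
    def test_identity_grouping(self):
        values = np.random.default_rng(0).dirichlet(np.ones(5), size=4)
        tensor = ImportanceTensor(values, [f"f{j}" for j in range(5)])
        assert np.allclose(group_importances(tensor, 4), values)

    def test_single_group_is_column_mean(self):
        values = np.random.default_rng(1).dirichlet(np.ones(3), size=4)
        tensor = ImportanceTensor(values, ["a", "b", "c"])
        assert np.allclose(group_importances(tensor, 1), values.mean(axis=0, keepdims=True))

    def test_contiguous_pairs(self):
        rows = np.array([[0.5, 0.3, 0.2], [0.1, 0.8, 0.1], [0.6, 0.2, 0.2], [0.2, 0.2, 0.6]])
        tensor = ImportanceTensor(rows, ["a", "b", "c"])
        vectors = group_importances(tensor, 2)
        assert np.allclose(vectors[0], (rows[0] + rows[1]) / 2)
        assert np.allclose(vectors[1], (rows[2] + rows[3]) / 2)

    def test_interleaved_option(self):
        rows = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
        tensor = ImportanceTensor(rows, ["a", "b"])
        vectors = group_importances(tensor, 2, interleaved=True)
        assert np.allclose(vectors[0], [1.0, 0.0])

    def test_groups_stay_normalized(self):
        values = np.random.default_rng(2).dirichlet(np.ones(6), size=8)
        tensor = ImportanceTensor(values, [f"f{j}" for j in range(6)])
        assert np.allclose(group_importances(tensor, 4).sum(axis=1), 1.0)

    def test_q_not_dividing_L(self):
        tensor = ImportanceTensor(np.ones((4, 2)) / 2, ["a", "b"])
        with pytest.raises(ValueError, match="divisor"):
            group_importances(tensor, 3)


class TestTopD:
    def test_simple_order(self):
        r = top_d(np.array([0.5, 0.3, 0.2]), 2, ["f1", "f2", "f3"])
        assert r.feature_names == ["f1", "f2"] and r.positions == [1, 2]

    def test_all_equal_breaks_by_index(self):
        r = top_d(np.array([0.25, 0.25, 0.25, 0.25]), 2, ["f1", "f2", "f3", "f4"])
        assert r.feature_names == ["f1", "f2"]

    def test_documented_tie_rule(self):
        r = top_d(np.array([0.1, 0.4, 0.4, 0.1]), 3, ["f1", "f2", "f3", "f4"])
        assert r.feature_names == ["f2", "f3", "f1"]

    def test_d_larger_than_m(self):
        with pytest.raises(ValueError, match="exceeds"):
            top_d(np.array([0.5, 0.5]), 3, ["a", "b"])


class TestIntersectAndRank:
    def test_idempotence_on_identical_rankings(self):
        g = make_ranking(["a", "b", "c"])
        out = intersect_and_rank([g, g, g])
        assert out.feature_names == ["a", "b", "c"]
        assert out.mean_positions == [1.0, 2.0, 3.0]
        assert len(out) == g.d

    def test_partial_overlap(self):
        g1 = make_ranking(["f1", "f2", "f3"])
        g2 = make_ranking(["f2", "f3", "f4"], group_index=2)
        out = intersect_and_rank([g1, g2])
        assert out.feature_names == ["f2", "f3"]
        assert out.mean_positions == [1.5, 2.5]
        assert len(out) < 3

    def test_disjoint_sets_give_empty_list(self, caplog):
        g1 = make_ranking(["a", "b"])
        g2 = make_ranking(["c", "d"], group_index=2)
        out = intersect_and_rank([g1, g2])
        assert len(out) == 0

    def test_position_tie_broken_by_importance_then_index(self):
        g1 = make_ranking(["a", "b"], importances=[0.6, 0.4])
        g2 = make_ranking(["b", "a"], importances=[0.7, 0.3], group_index=2)
        out = intersect_and_rank([g1, g2], feature_order=["a", "b"])
        # both at mean position 1.5; b has higher mean importance (0.55 vs 0.45)
        assert out.feature_names == ["b", "a"]


class TestFullAggregation:
    def test_k_at_most_d(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            tensor = ImportanceTensor(rng.dirichlet(np.ones(6), size=4), [f"f{j}" for j in range(6)])
            out = aggregate(tensor, q=2, d=3)
            assert len(out) <= 3

    def test_scale_invariance_of_ranking(self):
        rng = np.random.default_rng(4)
        values = rng.dirichlet(np.ones(6), size=4)
        names = [f"f{j}" for j in range(6)]
        base = aggregate(ImportanceTensor(values, names), q=2, d=4)
        shifted = values + 0.05
        shifted = shifted / shifted.sum(axis=1, keepdims=True)
        out = aggregate(ImportanceTensor(shifted, names), q=2, d=4)
        assert out.feature_names == base.feature_names

    @pytest.mark.parametrize("q", [1, 2, 4])
    def test_matches_brute_force_oracle(self, q):
        rng = np.random.default_rng(100 + q)
        for _ in range(150):
            m = int(rng.integers(2, 9))
            L = 4
            d = int(rng.integers(1, min(4, m) + 1))
            values = rng.dirichlet(np.ones(m), size=L)
            names = [f"f{j}" for j in range(m)]
            out = aggregate(ImportanceTensor(values, names), q=q, d=d)
            expected = brute_force_aggregate(values.tolist(), q, d)
            assert out.feature_names == [names[j] for j, _, _ in expected]
            assert np.allclose(out.mean_positions, [p for _, p, _ in expected])
            assert np.allclose(out.mean_importances, [imp for _, _, imp in expected])
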