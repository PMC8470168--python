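import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiberknn.features import FeatureVector, NormalizationParams
from fiberknn.knn import (
    CategoryStore,
    FiberModel,
    Hyperparams,
    explain,
    fit,
    manhattan_distance,
    predict,
    predict_many,
)
from fiberknn.products import ProductTable
from tests._oracles import oracle_knn_predict, oracle_manhattan
from tests.conftest import mk, random_table


def store_model(rows, k=8, metric="manhattan", weighting="inverse", category="bread"):
    """Model with a single hand-built store of (id, normalized vec, fiber)."""
    n_feat = len(rows[0][1])
    store = CategoryStore(
        ids=np.array([r[0] for r in rows], dtype=str),
        features=np.array([r[1] for r in rows], dtype=float),
        fiber=np.array([r[2] for r in rows], dtype=float),
    )
    params = NormalizationParams((0,) * 6, (1,) * 6)
    return FiberModel(params, {category: store}, Hyperparams(k, metric, weighting))


def query_vector(model, vec, pid="q", category="bread"):
    """Predict directly from a pre-normalized vector via the store scan."""
    from fiberknn.knn import _prediction_from_distances
    from scipy.spatial.distance import cdist

    store = model.stores[category]
    metric = {"manhattan": "cityblock", "euclidean": "euclidean"}[model.hyper.metric]
    d = cdist(np.asarray(vec, dtype=float)[None, :], store.features, metric=metric)[0]
    return _prediction_from_distances(model, store, d, pid)


class TestManhattanDistance:
    def test_identity(self):
        x = FeatureVector((0.1,) * 6, normalized=True)
        assert manhattan_distance(x, x) == 0

    def test_hand_sum(self):
        x = (0.1, 0.2, 0.3, 0.0, 0.5, 0.4)
        y = (0.2, 0.2, 0.1, 0.1, 0.5, 0.0)
        assert manhattan_distance(x, y) == pytest.approx(0.8, abs=1e-12)
        assert manhattan_distance(x, y) == pytest.approx(oracle_manhattan(x, y), abs=1e-12)

    @given(st.lists(st.floats(-1, 2), min_size=6, max_size=6),
           st.lists(st.floats(-1, 2), min_size=6, max_size=6))
    def test_symmetry_and_nonnegativity(self, x, y):
        assert manhattan_distance(x, y) == manhattan_distance(y, x) >= 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            manhattan_distance([0.0] * 6, [0.0] * 5)


class TestFit:
    def test_partition_conservation(self, rng):
        table = random_table(rng, n=10, n_categories=2)
        model = fit(table)
        assert sum(len(s) for s in model.stores.values()) == 10
        assert set(model.stores) == set(table.categories())

    def test_refit_determinism(self, rng, tmp_path):
        table = random_table(rng, n=20)
        fit(table).to_json(tmp_path / "a.json")
        fit(table).to_json(tmp_path / "b.json")
        assert (tmp_path / "a.json").read_text() == (tmp_path / "b.json").read_text()

    def test_missing_fiber_names_product(self, rng):
        table = random_table(rng, n=5)
        table.records[2] = dataclasses.replace(table.records[2], fiber=None)
        with pytest.raises(ValueError, match=table.records[2].product_id):
            fit(table)

    def test_json_round_trip_predicts_identically(self, rng, tmp_path):
        table = random_table(rng, n=40, n_categories=2)
        queries = random_table(rng, n=10, n_categories=2, with_fiber=False, prefix="q")
        model = fit(table)
        model.to_json(tmp_path / "m.json")
        loaded = FiberModel.from_json(tmp_path / "m.json")
        for q in queries.records:
            assert predict(model, q) == predict(loaded, q)


class TestPredict:
    def test_hand_weighted_average(self):
        # neighbors at distances 1 and 3 with fibers 2 and 4:
        # Q = (2*1 + 4/3) / (1 + 1/3) = 2.5
        model = store_model([("a", [1, 0, 0, 0, 0, 0], 2.0), ("b", [3, 0, 0, 0, 0, 0], 4.0)], k=2)
        p = query_vector(model, [0, 0, 0, 0, 0, 0])
        assert p.predicted_fiber == pytest.approx(2.5, abs=1e-12)
        assert p.d1 == 1.0
        assert p.k_effective == 2

    def test_zero_distance_exact_match(self):
        model = store_model(
            [("a", [0.2, 0, 0, 0, 0, 0], 6.0), ("b", [0.9, 0, 0, 0, 0, 0], 1.0)], k=2
        )
        p = query_vector(model, [0.2, 0, 0, 0, 0, 0])
        assert p.predicted_fiber == 6.0

    def test_zero_distance_multiple_matches_averaged(self):
        model = store_model(
            [
                ("a", [0.2, 0, 0, 0, 0, 0], 6.0),
                ("b", [0.2, 0, 0, 0, 0, 0], 2.0),
                ("c", [0.9, 0, 0, 0, 0, 0], 100.0),
            ],
            k=3,
        )
        p = query_vector(model, [0.2, 0, 0, 0, 0, 0])
        assert p.predicted_fiber == 4.0

    def test_equidistant_neighbors_give_plain_mean(self):
        model = store_model(
            [("a", [0.5, 0, 0, 0, 0, 0], 1.0), ("b", [-0.5, 0, 0, 0, 0, 0], 5.0)], k=2
        )
        p = query_vector(model, [0, 0, 0, 0, 0, 0])
        assert p.predicted_fiber == pytest.approx(3.0, abs=1e-12)

    def test_unknown_category_lists_known(self, rng):
        model = fit(random_table(rng, n=10, n_categories=1))
        with pytest.raises(ValueError, match="cat0"):
            predict(model, mk("q", category="unknown"))

    def test_leave_self_out_by_id(self, rng):
        table = random_table(rng, n=10, n_categories=1)
        model = fit(table)
        record = table.records[0]
        p = predict(model, record)
        assert record.product_id not in [n.product_id for n in p.neighbors]

    def test_duplicate_formulation_still_counts(self):
        # identical features under a different id remain eligible neighbors
        model = store_model(
            [("q", [0.3, 0, 0, 0, 0, 0], 9.0), ("twin", [0.3, 0, 0, 0, 0, 0], 5.0)], k=1
        )
        p = query_vector(model, [0.3, 0, 0, 0, 0, 0], pid="q")
        assert [n.product_id for n in p.neighbors] == ["twin"]
        assert p.predicted_fiber == 5.0

    def test_tie_break_ascending_id(self):
        model = store_model(
            [
                ("z", [0.1, 0, 0, 0, 0, 0], 1.0),
                ("a", [-0.1, 0, 0, 0, 0, 0], 2.0),
                ("m", [0.9, 0, 0, 0, 0, 0], 3.0),
            ],
            k=1,
        )
        p = query_vector(model, [0, 0, 0, 0, 0, 0])
        assert [n.product_id for n in p.neighbors] == ["a"]

    def test_k_saturation(self, rng):
        table = random_table(rng, n=15, n_categories=1)
        query = mk("q", category="cat0", sugar=4.0, carb=22.0)
        big = fit(table, Hyperparams(k=100))
        exact = fit(table, Hyperparams(k=15))
        assert predict(big, query).predicted_fiber == predict(exact, query).predicted_fiber

    def test_caution_flag(self):
        model = store_model([("a", [1, 0, 0, 0, 0, 0], 2.0), ("b", [2, 0, 0, 0, 0, 0], 2.0)], k=1)
        assert query_vector(model, [0, 0, 0, 0, 0, 0]).caution is True
        near = store_model([("a", [0.01, 0, 0, 0, 0, 0], 2.0)], k=1)
        assert query_vector(near, [0, 0, 0, 0, 0, 0]).caution is False

    def test_batch_matches_single(self, rng):
        table = random_table(rng, n=60, n_categories=3)
        queries = random_table(rng, n=20, n_categories=3, with_fiber=False, prefix="q")
        model = fit(table)
        batch, skipped = predict_many(model, queries)
        assert not skipped
        for record, bp in zip(queries.records, batch):
            assert predict(model, record) == bp


class TestProperties:
    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_oracle_equivalence_random_stores(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        k = int(rng.integers(1, 12))
        weighting = ["inverse", "uniform"][int(rng.integers(2))]
        rows = [
            (f"s{i:03d}", rng.uniform(0, 1, 6).tolist(), float(rng.uniform(0, 15)))
            for i in range(n)
        ]
        model = store_model(rows, k=k, weighting=weighting)
        qvec = rng.uniform(0, 1, 6).tolist()
        p = query_vector(model, qvec)
        expected, d1, ids = oracle_knn_predict(rows, qvec, "q", k, weighting=weighting)
        assert p.predicted_fiber == pytest.approx(expected, abs=1e-9)
        assert p.d1 == pytest.approx(d1, abs=1e-9)
        assert [nb.product_id for nb in p.neighbors] == ids

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_convexity_and_category_closure(self, seed):
        rng = np.random.default_rng(seed)
        table = random_table(rng, n=40, n_categories=2)
        queries = random_table(rng, n=10, n_categories=2, with_fiber=False, prefix="q")
        model = fit(table)
        cat_of = {r.product_id: r.category for r in table.records}
        for q in queries.records:
            p = predict(model, q)
            fibers = [n.fiber for n in p.neighbors]
            assert min(fibers) - 1e-12 <= p.predicted_fiber <= max(fibers) + 1e-12
            assert p.predicted_fiber >= 0
            assert all(cat_of[n.product_id] == q.category for n in p.neighbors)
            dists = [n.distance for n in p.neighbors]
            assert dists == sorted(dists)

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_nested_model_consistency(self, seed):
        # adding a store product beyond the current k-th neighbor distance
        # leaves the prediction unchanged
        rng = np.random.default_rng(seed)
        rows = [
            (f"s{i:03d}", rng.uniform(0, 1, 6).tolist(), float(rng.uniform(0, 15)))
            for i in range(12)
        ]
        model = store_model(rows, k=4)
        qvec = rng.uniform(0, 1, 6).tolist()
        before = query_vector(model, qvec)
        kth = before.neighbors[-1].distance
        far_vec = [v + kth + 0.5 for v in qvec]  # Manhattan distance > kth
        bigger = store_model(rows + [("zzz-far", far_vec, 99.0)], k=4)
        after = query_vector(bigger, qvec)
        assert after == before


class TestExplain:
    def test_weight_shares_sum_to_one(self, rng):
        table = random_table(rng, n=20, n_categories=1)
        model = fit(table)
        p = predict(model, mk("q", category="cat0", sugar=3.0, carb=18.0))
        report = explain(p, model)
        assert len(report.splitlines()) == p.k_effective + 1
        shares = [float(line.split("weight_share=")[1].split()[0])
                  for line in report.splitlines()[1:]]
        # shares are printed with 3 decimals, so allow rounding slack
        assert sum(shares) == pytest.approx(1.0, abs=5e-3)

    def test_uniform_shares_equal(self, rng):
        table = random_table(rng, n=12, n_categories=1)
        model = fit(table, Hyperparams(k=4, weighting="uniform"))
        p = predict(model, mk("q", category="cat0", sugar=3.0, carb=18.0))
        report = explain(p, model)
        shares = {line.split("weight_share=")[1].split()[0]
                  for line in report.splitlines()[1:]}
        assert shares == {"0.250"}

    def test_exact_match_marked(self):
        model = store_model([("a", [0.2, 0, 0, 0, 0, 0], 6.0)], k=1)
        p = query_vector(model, [0.2, 0, 0, 0, 0, 0])
        assert "[exact match]" in explain(p, model)


class TestHyperparams:
    def test_defaults(self):
        h = Hyperparams()
        assert (h.k, h.metric, h.weighting) == (8, "manhattan", "inverse")

    @pytest.mark.parametrize(
        "kwargs", [{"k": 0}, {"metric": "cosine"}, {"weighting": "gaussian"}]
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            Hyperparams(**kwargs)
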