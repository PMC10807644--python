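"""GraphSAGE: aggregation, forward pass, training and inductive prediction."""

import numpy as np
import pandas as pd
import pytest

import cuprosage as cp
from cuprosage.pairgraph import PairNodeGraph
from cuprosage.sage import (SageModel, _full_operator, _init_sage,
                            mean_aggregate, sage_forward, sample_neighbors)


# --- primitives -------------------------------------------------------------

def test_mean_aggregate_examples_and_loop_oracle(rng):
    assert np.array_equal(mean_aggregate(np.array([1.0, 1.0]),
                                         np.array([[3.0, 3.0]])),
                          np.array([2.0, 2.0]))
    h = np.array([0.5, -0.5])
    assert np.array_equal(mean_aggregate(h, np.empty((0, 2))), h)

    vecs = rng.normal(size=(5, 7))
    h = rng.normal(size=7)
    expect = h.copy()
    for v in vecs:          # independent loop oracle
        expect = expect + v
    expect = expect / 6.0
    assert mean_aggregate(h, vecs) == pytest.approx(expect, abs=1e-12)

    with pytest.raises(ValueError):
        mean_aggregate(np.ones(3), np.ones((2, 4)))


def test_sample_neighbors_contracts(rng):
    nbrs = np.array([4, 7, 9])
    w = np.array([1.0, 0.5, 1.0])
    assert set(sample_neighbors(nbrs, w, 5, rng)) == {4, 7, 9}
    assert len(sample_neighbors(np.empty(0), np.empty(0), 3, rng)) == 0
    s1 = sample_neighbors(nbrs, w, 2, np.random.default_rng(77))
    s2 = sample_neighbors(nbrs, w, 2, np.random.default_rng(77))
    assert np.array_equal(s1, s2)


def test_weighted_sampling_frequency_two_to_one():
    """Weight-1 neighbour drawn twice as often as weight-0.5 at size 1."""
    nbrs = np.array([0, 1])
    w = np.array([1.0, 0.5])
    rng = np.random.default_rng(5)
    n = 10_000
    hits = sum(sample_neighbors(nbrs, w, 1, rng)[0] == 0 for _ in range(n))
    p = hits / n
    se = np.sqrt((2 / 3) * (1 / 3) / n)
    assert abs(p - 2 / 3) < 4 * se


# --- forward pass -----------------------------------------------------------

def _path_graph_fixture():
    """4-node path graph 0-1-2-3 with 2-dim features."""
    nodes = pd.DataFrame({"node_id": list("abcd"),
                          "drug": ["d"] * 4, "target": list("wxyz"),
                          "label": [0, 1, 0, 1]})
    edges = np.array([[0, 1, 1.0], [1, 2, 1.0], [2, 3, 1.0]])
    X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [-1.0, 0.5]])
    return PairNodeGraph(nodes=nodes, features=X, edges=edges, metadata={})


def _hand_model():
    rng = np.random.default_rng(42)
    dims = (2, 3, 2, 2)
    model = _init_sage(dims, rng)
    return model


def test_forward_matches_hand_unrolled_three_layers():
    graph = _path_graph_fixture()
    model = _hand_model()
    ops = [_full_operator(graph)] * 3
    got = sage_forward(model, graph.features, ops)

    # independent unrolling with explicit neighbour lists
    nbrs = {0: [1], 1: [0, 2], 2: [1, 3], 3: [2]}
    H = graph.features
    for k in range(3):
        d = model.dims[k]
        H_next = np.zeros((4, model.dims[k + 1]))
        for v in range(4):
            m = (H[v] + sum(H[u] for u in nbrs[v])) / (1 + len(nbrs[v]))
            z = model.Ws[k][:, :d] @ H[v] + model.Ws[k][:, d:] @ m + model.bs[k]
            H_next[v] = np.maximum(z, 0) if k < 2 else z
        H = H_next
    expect = 1 / (1 + np.exp(-(H @ model.head_w + model.head_b)))
    assert got == pytest.approx(expect, abs=1e-8)


def test_zero_weights_give_half_probability():
    graph = _path_graph_fixture()
    model = _hand_model()
    for W in model.Ws:
        W[:] = 0.0
    model.head_w[:] = 0.0
    model.head_b = 0.0
    probs = sage_forward(model, graph.features, [_full_operator(graph)] * 3)
    assert np.allclose(probs, 0.5)


def test_forward_invariant_to_stored_neighbor_order():
    graph = _path_graph_fixture()
    model = _hand_model()
    flipped = PairNodeGraph(nodes=graph.nodes, features=graph.features,
                            edges=graph.edges[::-1].copy(), metadata={})
    a = sage_forward(model, graph.features, [_full_operator(graph)] * 3)
    b = sage_forward(model, graph.features, [_full_operator(flipped)] * 3)
    assert a == pytest.approx(b, abs=1e-12)


def test_dimension_mismatch_errors():
    graph = _path_graph_fixture()
    model = _hand_model()
    with pytest.raises(ValueError):
        sage_forward(model, np.ones((4, 5)), [_full_operator(graph)] * 3)
    with pytest.raises(ValueError):
        SageModel(Ws=model.Ws[:2], bs=model.bs, head_w=model.head_w,
                  head_b=0.0, dims=model.dims)


# --- training ---------------------------------------------------------------

def test_training_reproducible_and_learns_planted_structure(pair_graph):
    est = cp.GraphSAGE(pair_graph, hidden=(32, 16, 8))
    r1 = est.fit(epochs=60, seed=3)
    r2 = est.fit(epochs=60, seed=3)
    assert r1.run.loss == r2.run.loss
    assert r1.run.repeat_accuracies == r2.run.repeat_accuracies
    assert len(np.intersect1d(r1.run.train_idx, r1.run.test_idx)) == 0
    y = pair_graph.labels()
    majority = max(y.mean(), 1 - y.mean())
    assert r1.run.repeat_accuracies[0] > majority  # beats the null ceiling
    assert r1.run.loss[-1] < r1.run.loss[0]


def test_single_class_training_split_rejected():
    graph = _path_graph_fixture()
    graph.nodes["label"] = 1
    with pytest.raises(ValueError):
        cp.GraphSAGE(graph, hidden=(3, 2, 2)).fit(epochs=2)


def test_model_json_roundtrip(tmp_path):
    model = _hand_model()
    model.to_json(tmp_path / "sage.json")
    back = SageModel.from_json(tmp_path / "sage.json")
    graph = _path_graph_fixture()
    ops = [_full_operator(graph)] * 3
    assert np.allclose(sage_forward(back, graph.features, ops),
                       sage_forward(model, graph.features, ops))


# --- inductive prediction ---------------------------------------------------

def test_attach_and_predict_contract(drug_world, pair_graph):
    res = cp.GraphSAGE(pair_graph, hidden=(32, 16, 8)).fit(epochs=40, seed=1)
    before = res.model.checksum()

    new = pd.DataFrame({"id": ["NEW_0"], "name": ["new-drug"]})
    feats = pd.DataFrame(
        np.zeros((1, drug_world.drug_features.shape[1])), index=["NEW_0"])
    feats.iloc[0] = drug_world.drug_features.iloc[0].to_numpy()
    new.attrs["features"] = feats
    conn = pd.DataFrame(
        [drug_world.drug_connections.iloc[0].to_numpy()], index=["NEW_0"],
        columns=drug_world.drug_connections.columns)
    ranking = res.attach_and_predict(new, conn, drug_world)

    # no-retraining contract: weights untouched by prediction
    assert res.model.checksum() == before
    assert len(ranking) == len(drug_world.targets)
    assert (ranking["score"].diff().dropna() <= 1e-12).all()  # sorted desc
    assert ((ranking["score"] >= 0) & (ranking["score"] <= 1)).all()

    with pytest.raises(KeyError, match="NEW_1"):
        bad = pd.DataFrame({"id": ["NEW_1"], "name": ["x"]})
        res.attach_and_predict(bad, None, drug_world)


def test_clone_of_training_drug_scores_close_to_original(drug_world, pair_graph):
    """A new drug identical in features and connections to a training drug
    ranks its targets like that drug (full-neighbourhood mode)."""
    res = cp.GraphSAGE(pair_graph, hidden=(32, 16, 8)).fit(epochs=40, seed=1)
    probe = drug_world.drugs["id"].iloc[0]
    new = pd.DataFrame({"id": ["CLONE"], "name": ["clone"]})
    feats = pd.DataFrame([drug_world.drug_features.loc[probe].to_numpy()],
                         index=["CLONE"])
    new.attrs["features"] = feats
    conn = pd.DataFrame([drug_world.drug_connections.loc[probe].to_numpy()],
                        index=["CLONE"],
                        columns=drug_world.drug_connections.columns)
    ranking = res.attach_and_predict(new, conn, drug_world)
    probs = res.predict_proba()
    node_mask = pair_graph.nodes["drug"] == probe
    orig = pd.Series(probs[node_mask.to_numpy()],
                     index=pair_graph.nodes.loc[node_mask, "target"])
    clone = ranking.set_index("target_id")["score"]
    shared = orig.index.intersection(clone.index)
    assert len(shared) > 0
    # clone scores correlate strongly with the original drug's node scores
    corr = np.corrcoef(orig[shared], clone[shared])[0, 1]
    assert corr > 0.9
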