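"""Inductive GraphSAGE node classifier over the pair-node graph.

Three mean-aggregation layers (k = 3): at each layer the representation of a
node is sigma(W_k . [h_v || mean({h_v} union sampled-neighbour h_u)]), with a
rectifier on layers 1-2, identity on layer 3, and an affine + logistic head
mapping the final representation to an interaction probability.  Neighbour
mini-batch sampling is uniform without replacement, optionally weighted by
the 0.5/1 edge features (a 0.5-edge neighbour is sampled half as often).
Training minimises binary cross-entropy on the training nodes with the Adam
update; everything is seeded and reproducible.

Because the aggregator is learned rather than per-node embeddings, unseen
(drug, target) pair nodes can be attached to the graph and scored with the
trained weights, without any retraining — the inductive path the analysis
relies on for ranking candidate targets of newly screened drugs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .pairgraph import PairNodeGraph, assemble_features


# ---------------------------------------------------------------------------
# neighbor sampling and aggregation primitives
# ---------------------------------------------------------------------------

def sample_neighbors(neighbors: np.ndarray, weights: np.ndarray, size: int,
                     rng: np.random.Generator, weighted: bool = True) -> np.ndarray:
    """Sample min(size, degree) neighbours without replacement.

    With ``weighted`` the edge weights act as sampling weights through the
    Gumbel-top-k race (inclusion odds of a weight-1 neighbour are twice those
    of a weight-0.5 neighbour at size 1).  Isolated nodes yield an empty set.
    """
    deg = len(neighbors)
    if deg == 0:
        return np.empty(0, dtype=np.int64)
    if size >= deg:
        return np.asarray(neighbors, dtype=np.int64)
    w = np.asarray(weights, float) if weighted else np.ones(deg)
    keys = np.log(w) + rng.gumbel(size=deg)
    top = np.argpartition(-keys, size - 1)[:size]
    return np.asarray(neighbors, dtype=np.int64)[top]


def mean_aggregate(h_self: np.ndarray, neighbor_vectors: np.ndarray) -> np.ndarray:
    """Element-wise mean over {self} union neighbours (self-only fallback)."""
    h_self = np.asarray(h_self, float)
    if len(neighbor_vectors) == 0:
        return h_self.copy()
    nb = np.asarray(neighbor_vectors, float)
    if nb.shape[1] != h_self.shape[0]:
        raise ValueError("vector length mismatch in mean aggregation")
    return (h_self + nb.sum(axis=0)) / (1.0 + nb.shape[0])


def _padded_adjacency(graph: PairNodeGraph):
    nbrs, wts = graph.adjacency()
    n = graph.n_nodes
    maxdeg = max((len(x) for x in nbrs), default=0)
    idx = np.full((n, maxdeg), -1, dtype=np.int64)
    w = np.zeros((n, maxdeg))
    for v in range(n):
        d = len(nbrs[v])
        idx[v, :d] = nbrs[v]
        w[v, :d] = wts[v]
    deg = np.array([len(x) for x in nbrs], dtype=np.int64)
    return idx, w, deg


def _sampled_operator(idx: np.ndarray, w: np.ndarray, deg: np.ndarray,
                      size: int, rng: np.random.Generator,
                      weighted: bool) -> sp.csr_matrix:
    """Sparse row-stochastic operator A with A @ H = mean({h_v} + sampled nbrs)."""
    n, maxdeg = idx.shape
    rows, cols = [np.arange(n)], [np.arange(n)]  # self terms
    if maxdeg > 0:
        valid = idx >= 0
        keys = np.where(valid,
                        (np.log(np.where(w > 0, w, 1.0)) if weighted else 0.0)
                        + rng.gumbel(size=(n, maxdeg)),
                        -np.inf)
        k = min(size, maxdeg)
        top = np.argpartition(-keys, k - 1, axis=1)[:, :k]
        chosen = np.take_along_axis(idx, top, axis=1)
        chosen_valid = np.take_along_axis(valid, top, axis=1)
        r, c = np.nonzero(chosen_valid)
        rows.append(r)
        cols.append(chosen[r, c])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    counts = np.bincount(rows, minlength=n).astype(float)
    data = 1.0 / counts[rows]
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def _full_operator(graph: PairNodeGraph) -> sp.csr_matrix:
    """Deterministic full-neighbourhood operator (unweighted mean, self incl.)."""
    n = graph.n_nodes
    if len(graph.edges):
        a = graph.edges[:, 0].astype(np.int64)
        b = graph.edges[:, 1].astype(np.int64)
        rows = np.concatenate([np.arange(n), a, b])
        cols = np.concatenate([np.arange(n), b, a])
    else:
        rows = cols = np.arange(n)
    counts = np.bincount(rows, minlength=n).astype(float)
    data = 1.0 / counts[rows]
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class SageModel:
    """Weight stacks of the 3 aggregation layers plus the logistic head."""

    Ws: list            # W_k, shape (d_out, 2 * d_in)
    bs: list
    head_w: np.ndarray
    head_b: float
    dims: tuple         # (input, h1, h2, h3)
    sample_sizes: tuple = (10, 10, 10)
    weighted_sampling: bool = True
    seed: int = 0

    def __post_init__(self):
        if len(self.Ws) != 3:
            raise ValueError("layer count must be 3")
        for k, W in enumerate(self.Ws):
            if W.shape != (self.dims[k + 1], 2 * self.dims[k]):
                raise ValueError(f"layer {k + 1} weight shape mismatch: {W.shape}")

    def checksum(self) -> float:
        return float(sum(np.abs(W).sum() for W in self.Ws)
                     + sum(np.abs(b).sum() for b in self.bs)
                     + np.abs(self.head_w).sum() + abs(self.head_b))

    def to_json(self, path) -> None:
        payload = {"dims": list(self.dims),
                   "sample_sizes": list(self.sample_sizes),
                   "weighted_sampling": self.weighted_sampling,
                   "seed": self.seed,
                   "Ws": [W.tolist() for W in self.Ws],
                   "bs": [b.tolist() for b in self.bs],
                   "head_w": self.head_w.tolist(),
                   "head_b": self.head_b}
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SageModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(Ws=[np.array(W) for W in d["Ws"]],
                   bs=[np.array(b) for b in d["bs"]],
                   head_w=np.array(d["head_w"]), head_b=d["head_b"],
                   dims=tuple(d["dims"]),
                   sample_sizes=tuple(d["sample_sizes"]),
                   weighted_sampling=d["weighted_sampling"], seed=d["seed"])


def _init_sage(dims: tuple, rng: np.random.Generator) -> SageModel:
    Ws, bs = [], []
    for k in range(3):
        fan_in = 2 * dims[k]
        bound = np.sqrt(6.0 / fan_in)
        Ws.append(rng.uniform(-bound, bound, size=(dims[k + 1], fan_in)))
        bs.append(np.zeros(dims[k + 1]))
    head_w = rng.uniform(-0.1, 0.1, size=dims[3])
    return SageModel(Ws=Ws, bs=bs, head_w=head_w, head_b=0.0, dims=dims)


def sage_forward(model: SageModel, H0: np.ndarray, operators,
                 return_cache: bool = False):
    """Three-layer forward pass; probability per node.

    ``operators`` is a list of three row-stochastic aggregation matrices
    (sampled or full-neighbourhood); with full neighbourhoods the pass is
    deterministic.
    """
    if H0.shape[1] != model.dims[0]:
        raise ValueError(f"feature dim {H0.shape[1]} != model input {model.dims[0]}")
    H = H0
    cache = []
    for k in range(3):
        A = operators[k]
        M = A @ H
        d = model.dims[k]
        W_self, W_nbr = model.Ws[k][:, :d], model.Ws[k][:, d:]
        Z = H @ W_self.T + M @ W_nbr.T + model.bs[k]
        H_next = np.maximum(Z, 0.0) if k < 2 else Z
        cache.append((H, M, Z))
        H = H_next
    logits = H @ model.head_w + model.head_b
    prob = 1.0 / (1.0 + np.exp(-logits))
    if return_cache:
        return prob, (cache, H)
    return prob


def _backward_sage(model: SageModel, prob, y, train_mask, operators, cache, H3):
    """Gradient of mean BCE over training nodes w.r.t. all parameters."""
    n_train = train_mask.sum()
    dlogit = np.where(train_mask, prob - y, 0.0) / n_train
    g_head_w = H3.T @ dlogit
    g_head_b = dlogit.sum()
    dH = np.outer(dlogit, model.head_w)
    gWs, gbs = [None] * 3, [None] * 3
    for k in range(2, -1, -1):
        H_in, M, Z = cache[k]
        dZ = dH if k == 2 else dH * (Z > 0)
        d = model.dims[k]
        W_self, W_nbr = model.Ws[k][:, :d], model.Ws[k][:, d:]
        gWs[k] = np.hstack([dZ.T @ H_in, dZ.T @ M])
        gbs[k] = dZ.sum(axis=0)
        if k > 0:
            dH = dZ @ W_self + operators[k].T @ (dZ @ W_nbr)
    return gWs, gbs, g_head_w, g_head_b


@dataclass
class TrainRun:
    loss: list = field(default_factory=list)
    test_accuracy: list = field(default_factory=list)
    train_idx: np.ndarray | None = None
    test_idx: np.ndarray | None = None
    repeat_accuracies: list = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": np.arange(1, len(self.loss) + 1),
                             "loss": self.loss,
                             "test_accuracy": self.test_accuracy})


class GraphSAGE:
    """GraphSAGE classifier on a PairNodeGraph; ``fit`` returns SageResults."""

    def __init__(self, graph: PairNodeGraph, hidden: tuple = (64, 32, 16),
                 sample_sizes: tuple = (10, 10, 10), weighted_sampling: bool = True,
                 l2: float = 3e-4, l1_input: float = 0.0, resample_every: int = 5):
        self.graph = graph
        self.dims = (graph.features.shape[1], *hidden)
        self.sample_sizes = sample_sizes
        self.l2 = l2
        self.l1_input = l1_input
        self.weighted_sampling = weighted_sampling
        self.resample_every = resample_every
        self._padded = _padded_adjacency(graph)
        self._full_ops = None

    def full_operators(self) -> list:
        if self._full_ops is None:
            self._full_ops = [_full_operator(self.graph)] * 3
        return self._full_ops

    def _split(self, seed: int, test_fraction: float = 0.2):
        y = self.graph.labels()
        meta_train = self.graph.metadata.get("train_idx")
        if meta_train is not None:
            train = np.asarray(meta_train, dtype=np.int64)
            test = np.setdiff1d(np.arange(len(y)), train)
            return train, test
        rng = np.random.default_rng(seed)
        train = []
        for lab in np.unique(y):
            members = np.flatnonzero(y == lab)
            n_tr = int(round((1 - test_fraction) * members.size))
            train.append(rng.choice(members, size=n_tr, replace=False))
        train = np.sort(np.concatenate(train))
        return train, np.setdiff1d(np.arange(len(y)), train)

    def _fit_once(self, epochs: int, lr: float, seed: int, train, test):
        rng = np.random.default_rng(seed)
        model = _init_sage(self.dims, rng)
        model.sample_sizes = self.sample_sizes
        model.weighted_sampling = self.weighted_sampling
        model.seed = seed
        X = self.graph.features.astype(float)
        y = self.graph.labels().astype(float)
        mask = np.zeros(len(y), dtype=bool)
        mask[train] = True
        idx, w, deg = self._padded
        params = model.Ws + model.bs + [model.head_w]
        m_t = [np.zeros_like(p) for p in params] + [0.0]
        v_t = [np.zeros_like(p) for p in params] + [0.0]
        b1, b2, eps = 0.9, 0.999, 1e-8
        trace_loss, trace_acc = [], []
        operators = None
        t = 0
        for epoch in range(epochs):
            if operators is None or epoch % self.resample_every == 0:
                operators = [
                    _sampled_operator(idx, w, deg, s, rng, self.weighted_sampling)
                    for s in self.sample_sizes]
            prob, (cache, H3) = sage_forward(model, X, operators,
                                             return_cache=True)
            p_tr = np.clip(prob[train], 1e-12, 1 - 1e-12)
            loss = -np.mean(y[train] * np.log(p_tr)
                            + (1 - y[train]) * np.log(1 - p_tr))
            gWs, gbs, ghw, ghb = _backward_sage(model, prob, y, mask,
                                                operators, cache, H3)
            if self.l2 > 0:  # weight decay on the transform matrices only
                gWs = [g + 2.0 * self.l2 * W for g, W in zip(gWs, model.Ws)]
                ghw = ghw + 2.0 * self.l2 * model.head_w
            if self.l1_input > 0:  # sparse-input penalty: layer 1 prunes
                gWs[0] = gWs[0] + self.l1_input * np.sign(model.Ws[0])
            grads = gWs + gbs + [ghw, ghb]
            t += 1
            for i, g in enumerate(grads):
                m_t[i] = b1 * m_t[i] + (1 - b1) * g
                v_t[i] = b2 * v_t[i] + (1 - b2) * (g * g if i < len(grads) - 1
                                                  else g ** 2)
                mhat = m_t[i] / (1 - b1 ** t)
                vhat = v_t[i] / (1 - b2 ** t)
                upd = lr * mhat / (np.sqrt(vhat) + eps)
                if i < 3:
                    model.Ws[i] -= upd
                elif i < 6:
                    model.bs[i - 3] -= upd
                elif i == 6:
                    model.head_w -= upd
                else:
                    model.head_b -= upd
            # per-epoch trace uses the current sampled operators (cheap);
            # the definitive accuracy below uses full neighbourhoods
            acc = float(np.mean((prob[test] >= 0.5) == (y[test] >= 0.5)))
            trace_loss.append(float(loss))
            trace_acc.append(acc)
        prob_eval = sage_forward(model, X, self.full_operators())
        final_acc = float(np.mean((prob_eval[test] >= 0.5) == (y[test] >= 0.5)))
        return model, trace_loss, trace_acc, final_acc

    def fit(self, epochs: int = 300, lr: float = 0.01, n_repeats: int = 1,
            seed: int = 0) -> "SageResults":
        train, test = self._split(seed)
        y = self.graph.labels()
        if len(np.unique(y[train])) < 2:
            raise ValueError("training split contains a single class")
        run = TrainRun(train_idx=train, test_idx=test)
        model = None
        for r in range(n_repeats):
            model, loss, acc, final_acc = self._fit_once(epochs, lr, seed + r,
                                                         train, test)
            if r == 0:
                run.loss, run.test_accuracy = loss, acc
            run.repeat_accuracies.append(final_acc)
        return SageResults(self, model, run)


class SageResults:
    """Fitted classifier: weights, training curves, inductive prediction."""

    def __init__(self, estimator: GraphSAGE, model: SageModel, run: TrainRun):
        self.estimator = estimator
        self.model = model
        self.run = run

    @property
    def accuracy_mean(self) -> float:
        return float(np.mean(self.run.repeat_accuracies))

    @property
    def accuracy_sd(self) -> float:
        return float(np.std(self.run.repeat_accuracies, ddof=1)) \
            if len(self.run.repeat_accuracies) > 1 else 0.0

    def predict_proba(self) -> np.ndarray:
        """Deterministic full-neighbourhood probabilities for graph nodes."""
        return sage_forward(self.model,
                            self.estimator.graph.features.astype(float),
                            self.estimator.full_operators())

    def summary(self) -> str:
        r = self.run
        return "\n".join([
            "GraphSAGE pair-node classifier",
            "==============================",
            f"dims          : {' -> '.join(map(str, self.model.dims))} -> sigmoid",
            f"sample sizes  : {self.model.sample_sizes} "
            f"(weighted={self.model.weighted_sampling})",
            f"train / test  : {len(r.train_idx)} / {len(r.test_idx)} nodes",
            f"repeats       : {len(r.repeat_accuracies)}",
            f"test accuracy : {self.accuracy_mean:.3f} "
            + (f"+/- {self.accuracy_sd:.3f}" if len(r.repeat_accuracies) > 1 else ""),
        ])

    # --- inductive attachment ---------------------------------------------
    def attach_and_predict(self, new_drugs: pd.DataFrame,
                           new_drug_connections: pd.DataFrame | None,
                           world, top_n: int | None = None) -> pd.DataFrame:
        """Score every (new drug, target) pair without touching the weights.

        New pair nodes are featurised with the stored selection mask and wired
        to the existing nodes by the pair-graph edge rule (drug component from
        ``new_drug_connections``; target component from the world's target
        connections plus target identity).  Embeddings of the existing nodes
        are taken from the trained graph and never modified.
        """
        graph = self.estimator.graph
        mask = graph.selection_mask
        tconn = world.target_connections.to_numpy().astype(bool)
        t_index = list(world.target_connections.index)
        t_pos = {t: i for i, t in enumerate(t_index)}
        target_ids = world.targets["id"].tolist()
        tnames = dict(zip(world.targets["id"], world.targets.get(
            "name", world.targets["id"])))
        dnames = dict(zip(new_drugs["id"], new_drugs.get("name", new_drugs["id"])))

        # frozen layer-wise representations of the existing nodes
        full_ops = self.estimator.full_operators()
        X = graph.features.astype(float)
        H_layers = [X]
        H = X
        for k in range(3):
            M = full_ops[k] @ H
            d = self.model.dims[k]
            Z = (H @ self.model.Ws[k][:, :d].T + M @ self.model.Ws[k][:, d:].T
                 + self.model.bs[k])
            H = np.maximum(Z, 0.0) if k < 2 else Z
            H_layers.append(H)

        node_t = graph.nodes["target"].to_numpy()
        node_t_idx = np.array([t_pos[t] for t in node_t])
        rows = []
        for _, drow in new_drugs.iterrows():
            did = drow["id"]
            if "features" in new_drugs.attrs:
                dvec = np.asarray(new_drugs.attrs["features"].loc[did], float)
            else:
                raise KeyError(f"missing feature vector for drug {did}")
            if new_drug_connections is not None and did in new_drug_connections.index:
                dconn_row = new_drug_connections.loc[did]
            else:
                dconn_row = None
            for tid in target_ids:
                tvec = world.target_features.loc[tid].to_numpy()
                feat = assemble_features(dvec, tvec, mask)
                # edge rule against existing nodes
                t_match = tconn[t_pos[tid]][node_t_idx] | (node_t == tid)
                if dconn_row is not None:
                    d_match = dconn_row.reindex(
                        graph.nodes["drug"]).fillna(False).to_numpy().astype(bool)
                else:
                    d_match = np.zeros(graph.n_nodes, dtype=bool)
                wgt = 0.5 * d_match + 0.5 * t_match
                nbr = np.flatnonzero(wgt > 0)
                h = feat.astype(float)
                for k in range(3):
                    Hk = H_layers[k]
                    m = mean_aggregate(h, Hk[nbr]) if len(nbr) else h.copy()
                    d = self.model.dims[k]
                    z = (self.model.Ws[k][:, :d] @ h
                         + self.model.Ws[k][:, d:] @ m + self.model.bs[k])
                    h = np.maximum(z, 0.0) if k < 2 else z
                score = float(1.0 / (1.0 + np.exp(-(h @ self.model.head_w
                                                    + self.model.head_b))))
                rows.append({"drug_id": did, "drug_name": dnames.get(did, did),
                             "target_id": tid,
                             "target_name": tnames.get(tid, tid),
                             "score": score})
        ranking = pd.DataFrame(rows).sort_values(
            "score", ascending=False, kind="stable").reset_index(drop=True)
        return ranking.head(top_n) if top_n else ranking


def precision_at_k(ranking: pd.DataFrame, true_pairs: set, k: int = 10) -> float:
    """Fraction of the top-k ranked (drug, target) pairs that truly interact."""
    top = ranking.head(k)
    hits = sum((d, t) in true_pairs
               for d, t in zip(top["drug_id"], top["target_id"]))
    return hits / k
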