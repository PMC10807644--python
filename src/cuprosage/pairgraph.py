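"""Pair-node drug-target graph construction.

Each node is one (drug, target) pair, labelled 1 when the pair interacts.
Edges connect two pair-nodes according to the entity connection networks:
weight 1 when both the drug pair and the target pair are connected, 0.5 when
exactly one is, and no edge when neither is.  Sharing an endpoint counts as
"connected" by default (two nodes with the same drug have a connected drug
pair); a strict mode turns that off.

Node features are the concatenated drug and target feature vectors restricted
to a selection mask (variance filter followed by top-k univariate mutual
information with the label, computed on training nodes only).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


def augment_targets(core_targets, candidate_pool, similarity: pd.DataFrame,
                    threshold: float = 0.90) -> dict:
    """Core targets plus pool members with similarity > threshold to any core.

    ``similarity`` must hold values in [0, 1] and index/columns covering both
    sets.  Returns the augmented id list plus a provenance log.
    """
    sim = similarity.to_numpy()
    if np.any((sim < 0) | (sim > 1)):
        raise ValueError("similarity values must lie in [0, 1]")
    core = list(dict.fromkeys(core_targets))
    added, log = [], []
    for cand in candidate_pool:
        if cand in core:
            continue
        best = float(similarity.loc[cand, core].max())
        if best > threshold:
            added.append(cand)
            log.append({"target": cand, "max_similarity": best})
    return {"targets": core + added, "n_core": len(core), "n_added": len(added),
            "log": log}


def build_pair_nodes(drug_ids, target_ids, interactions: set,
                     negative_policy: str = "ratio", ratio: float = 1.5,
                     seed: int = 0) -> pd.DataFrame:
    """Pair-node table (node_id, drug, target, label).

    All interacting pairs become label-1 nodes; non-interacting pairs are
    subsampled at ``ratio`` negatives per positive (seeded, uniform) or kept
    in full under policy ``"all"``.
    """
    drug_ids, target_ids = list(drug_ids), list(target_ids)
    known = {(d, t) for d in drug_ids for t in target_ids}
    bad = set(interactions) - known
    if bad:
        raise KeyError(f"interactions reference unknown entities: {sorted(bad)[:5]}")
    pos = [(d, t) for d in drug_ids for t in target_ids if (d, t) in interactions]
    neg = [(d, t) for d in drug_ids for t in target_ids if (d, t) not in interactions]
    if negative_policy == "all":
        chosen_neg = neg
    elif negative_policy == "ratio":
        n_neg = min(len(neg), int(round(ratio * len(pos))))
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(neg), size=n_neg, replace=False)
        chosen_neg = [neg[i] for i in sorted(idx)]
    else:
        raise ValueError(f"unknown negative_policy: {negative_policy}")
    pairs = pos + chosen_neg
    return pd.DataFrame({
        "node_id": [f"N{i:05d}" for i in range(len(pairs))],
        "drug": [p[0] for p in pairs],
        "target": [p[1] for p in pairs],
        "label": [1] * len(pos) + [0] * len(chosen_neg),
    })


def _histogram_mi(x: np.ndarray, y: np.ndarray, bins: int = 10) -> float:
    """Mutual information of a continuous feature with a binary label by
    quantile-bin counting (natural log)."""
    edges = np.quantile(x, np.linspace(0, 1, bins + 1))
    edges = np.unique(edges)
    if len(edges) < 2:
        return 0.0
    cells = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)
    mi = 0.0
    n = len(x)
    for c in range(len(edges) - 1):
        for lab in (0, 1):
            n_joint = np.sum((cells == c) & (y == lab))
            if n_joint == 0:
                continue
            p_joint = n_joint / n
            p_c = np.sum(cells == c) / n
            p_l = np.sum(y == lab) / n
            mi += p_joint * np.log(p_joint / (p_c * p_l))
    return float(mi)


def select_features(features: np.ndarray, labels: np.ndarray, k: int = 249,
                    bins: int = 10, train_idx=None) -> np.ndarray:
    """Selection mask: drop zero-variance columns, keep top-k by histogram MI.

    MI is computed on ``train_idx`` rows only (all rows when omitted) to avoid
    label leakage.  Deterministic given the data; ties break by column index.
    """
    X = np.asarray(features, float)
    y = np.asarray(labels).astype(int)
    if train_idx is not None:
        X_fit, y_fit = X[train_idx], y[train_idx]
    else:
        X_fit, y_fit = X, y
    if len(np.unique(y_fit)) < 2:
        raise ValueError("need both classes to select features")
    var = X_fit.var(axis=0)
    alive = np.flatnonzero(var > 0)
    if k > alive.size:
        raise ValueError(f"k={k} exceeds {alive.size} non-constant features")
    mi = np.array([_histogram_mi(X_fit[:, j], y_fit, bins) for j in alive])
    order = np.lexsort((alive, -mi))  # MI descending, index ascending on ties
    return np.sort(alive[order[:k]])


def assemble_features(drug_vec: np.ndarray, target_vec: np.ndarray,
                      mask: np.ndarray | None = None) -> np.ndarray:
    """Concatenated (drug, target) features restricted to the mask."""
    full = np.concatenate([np.asarray(drug_vec, float),
                           np.asarray(target_vec, float)])
    if mask is None:
        return full
    mask = np.asarray(mask)
    if mask.size and mask.max() >= full.size:
        raise IndexError("selection mask exceeds concatenated feature length")
    return full[mask]


def _check_symmetric(conn: pd.DataFrame, what: str) -> None:
    M = conn.to_numpy()
    if not np.array_equal(M, M.T):
        raise ValueError(f"{what} connection matrix must be symmetric")


def build_edges(nodes: pd.DataFrame, drug_connections: pd.DataFrame,
                target_connections: pd.DataFrame,
                self_connected: bool = True) -> np.ndarray:
    """Edge array (a, b, weight) over all unordered node pairs.

    d = drugs connected (or identical, unless strict mode); t likewise for
    targets; weight 1 if both, 0.5 if exactly one, no edge if neither.
    Vectorised over the full node-pair matrix.
    """
    _check_symmetric(drug_connections, "drug")
    _check_symmetric(target_connections, "target")
    d_idx = drug_connections.index.get_indexer(nodes["drug"])
    t_idx = target_connections.index.get_indexer(nodes["target"])
    if (d_idx < 0).any() or (t_idx < 0).any():
        raise KeyError("node references an entity absent from the connection nets")
    D = drug_connections.to_numpy().astype(bool)
    T = target_connections.to_numpy().astype(bool)
    if self_connected:
        D = D | np.eye(len(D), dtype=bool)
        T = T | np.eye(len(T), dtype=bool)
    d_conn = D[np.ix_(d_idx, d_idx)]
    t_conn = T[np.ix_(t_idx, t_idx)]
    weight = 0.5 * d_conn + 0.5 * t_conn
    iu = np.triu_indices(len(nodes), k=1)
    w = weight[iu]
    keep = w > 0
    return np.column_stack([iu[0][keep], iu[1][keep], w[keep]])


@dataclass
class PairNodeGraph:
    """Pair-node graph: node table, feature matrix, weighted edge list."""

    nodes: pd.DataFrame           # node_id, drug, target, label
    features: np.ndarray          # n_nodes x n_selected
    edges: np.ndarray             # (a, b, weight) rows, indices into nodes
    selection_mask: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def labels(self) -> np.ndarray:
        return self.nodes["label"].to_numpy()

    def adjacency(self) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Per-node neighbor index and edge-weight arrays."""
        nbrs = [[] for _ in range(self.n_nodes)]
        wts = [[] for _ in range(self.n_nodes)]
        for a, b, w in self.edges:
            a, b = int(a), int(b)
            nbrs[a].append(b)
            wts[a].append(w)
            nbrs[b].append(a)
            wts[b].append(w)
        return ([np.array(x, dtype=np.int64) for x in nbrs],
                [np.array(x, dtype=float) for x in wts])

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.nodes.to_csv(out / "nodes.tsv", sep="\t", index=False)
        pd.DataFrame(self.edges, columns=["a", "b", "weight"]).to_csv(
            out / "edges.tsv", sep="\t", index=False)
        feat = pd.DataFrame(self.features, index=self.nodes["node_id"])
        feat.to_csv(out / "features.tsv", sep="\t")
        meta = dict(self.metadata)
        meta["n_nodes"] = self.n_nodes
        meta["n_edges"] = self.n_edges
        if self.selection_mask is not None:
            meta["selection_mask"] = np.asarray(self.selection_mask).tolist()
        (out / "metadata.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, outdir) -> "PairNodeGraph":
        out = Path(outdir)
        nodes = pd.read_csv(out / "nodes.tsv", sep="\t")
        edges = pd.read_csv(out / "edges.tsv", sep="\t").to_numpy()
        features = pd.read_csv(out / "features.tsv", sep="\t", index_col=0).to_numpy()
        meta = json.loads((out / "metadata.json").read_text())
        mask = np.array(meta.pop("selection_mask")) if "selection_mask" in meta else None
        return cls(nodes=nodes, features=features, edges=edges,
                   selection_mask=mask, metadata=meta)


def build_pair_graph(world, negative_policy: str = "ratio", ratio: float = 1.5,
                     k_features: int = 249, self_connected: bool = True,
                     train_fraction: float = 0.8, seed: int = 0) -> PairNodeGraph:
    """End-to-end graph build from a drug world (synthetic or tabular).

    Feature selection is fitted on a seeded stratified training subset of the
    nodes (recorded in metadata) so the held-out nodes never inform the mask.
    """
    drug_ids = world.drugs["id"].tolist()
    target_ids = world.targets["id"].tolist()
    inter = world.interaction_set()
    nodes = build_pair_nodes(drug_ids, target_ids, inter,
                             negative_policy=negative_policy, ratio=ratio,
                             seed=seed)
    dF = world.drug_features.loc[nodes["drug"]].to_numpy()
    tF = world.target_features.loc[nodes["target"]].to_numpy()
    full = np.hstack([dF, tF])
    y = nodes["label"].to_numpy()
    rng = np.random.default_rng(seed)
    train_idx = _stratified_train_idx(y, train_fraction, rng)
    mask = select_features(full, y, k=min(k_features, full.shape[1]),
                           train_idx=train_idx)
    edges = build_edges(nodes, world.drug_connections, world.target_connections,
                        self_connected=self_connected)
    return PairNodeGraph(
        nodes=nodes, features=full[:, mask], edges=edges, selection_mask=mask,
        metadata={"seed": seed, "train_idx": train_idx.tolist(),
                  "negative_policy": negative_policy, "ratio": ratio,
                  "self_connected": self_connected},
    )


def _stratified_train_idx(y: np.ndarray, fraction: float,
                          rng: np.random.Generator) -> np.ndarray:
    idx = []
    for lab in np.unique(y):
        members = np.flatnonzero(y == lab)
        n_tr = int(round(fraction * members.size))
        idx.append(rng.choice(members, size=n_tr, replace=False))
    return np.sort(np.concatenate(idx))
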