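"""Minimal numpy engine for the graph neural risk models.

Implements forward and hand-derived reverse-mode gradients for

* a graph convolutional network (neighbour-mean aggregation including self,
  learned linear maps, ReLU, optional residual connections, mean-pool
  readout, MLP predictor), and
* a directed message-passing network whose hidden states live on directed
  bonds; the update for bond (k -> m) aggregates incoming bond states at k
  excluding the reverse bond (m -> k), so messages never flow straight back.

Training is full-batch Adam with class-weighted binary cross-entropy. The
gradients are validated against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

from .mol_features import MolGraph


class GraphBatch:
    """A list of molecular graphs packed into one disjoint-union graph."""

    def __init__(self, graphs: list[MolGraph]):
        if not graphs:
            raise ValueError("empty graph batch")
        atom_off, bond_off = 0, 0
        X, E, src, dst, rev, gid = [], [], [], [], [], []
        for i, g in enumerate(graphs):
            X.append(g.atom_features)
            E.append(g.bond_features)
            src.append(g.bond_src + atom_off)
            dst.append(g.bond_dst + atom_off)
            rev.append(g.rev + bond_off)
            gid.append(np.full(g.n_atoms, i))
            atom_off += g.n_atoms
            bond_off += g.n_bonds
        self.X = np.concatenate(X, axis=0)
        self.E = np.concatenate(E, axis=0) if bond_off else np.zeros((0, 6))
        self.src = np.concatenate(src).astype(int) if bond_off else np.zeros(0, int)
        self.dst = np.concatenate(dst).astype(int) if bond_off else np.zeros(0, int)
        self.rev = np.concatenate(rev).astype(int) if bond_off else np.zeros(0, int)
        self.graph_id = np.concatenate(gid).astype(int)
        self.n_graphs = len(graphs)
        self.n_atoms = atom_off
        self.atoms_per_graph = np.bincount(self.graph_id, minlength=self.n_graphs)
        deg = np.bincount(self.dst, minlength=self.n_atoms)
        self.inv_deg1 = 1.0 / (1.0 + deg)  # mean over neighbourhood incl. self


def _glorot(rng: np.random.Generator, d_in: int, d_out: int) -> np.ndarray:
    s = np.sqrt(6.0 / (d_in + d_out))
    return rng.uniform(-s, s, size=(d_in, d_out))


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-2,
                 b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.params, self.lr, self.b1, self.b2, self.eps = params, lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            self.params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


class _MLPHead:
    """Predictor head: optional hidden ReLU layers then a scalar logit."""

    def __init__(self, rng: np.random.Generator, d_in: int, hidden: int,
                 n_hidden_layers: int, prefix: str):
        self.prefix = prefix
        self.dims = [d_in] + [hidden] * n_hidden_layers + [1]
        self.params: dict[str, np.ndarray] = {}
        for i, (a, b) in enumerate(zip(self.dims[:-1], self.dims[1:])):
            self.params[f"{prefix}W{i}"] = _glorot(rng, a, b)
            self.params[f"{prefix}b{i}"] = np.zeros(b)

    def forward(self, G: np.ndarray, dropout: float, train: bool,
                rng: np.random.Generator):
        cache = {"acts": [G], "pre": [], "masks": []}
        h = G
        n_lin = len(self.dims) - 1
        for i in range(n_lin):
            z = h @ self.params[f"{self.prefix}W{i}"] + self.params[f"{self.prefix}b{i}"]
            cache["pre"].append(z)
            if i < n_lin - 1:
                h = np.maximum(z, 0.0)
                if train and dropout > 0:
                    mask = (rng.random(h.shape) >= dropout) / (1 - dropout)
                    h = h * mask
                    cache["masks"].append(mask)
                else:
                    cache["masks"].append(None)
                cache["acts"].append(h)
            else:
                h = z
        return h[:, 0], cache

    def backward(self, dlogit: np.ndarray, cache,
                 grads: dict[str, np.ndarray]) -> np.ndarray:
        n_lin = len(self.dims) - 1
        dz = dlogit[:, None]
        for i in reversed(range(n_lin)):
            h_in = cache["acts"][i]
            grads[f"{self.prefix}W{i}"] = h_in.T @ dz
            grads[f"{self.prefix}b{i}"] = dz.sum(axis=0)
            dh = dz @ self.params[f"{self.prefix}W{i}"].T
            if i > 0:
                mask = cache["masks"][i - 1]
                if mask is not None:
                    dh = dh * mask
                dz = dh * (cache["pre"][i - 1] > 0)
            else:
                dz = dh  # gradient w.r.t. the head input
        return dz


def _mean_pool(H: np.ndarray, batch: GraphBatch) -> np.ndarray:
    G = np.zeros((batch.n_graphs, H.shape[1]))
    np.add.at(G, batch.graph_id, H)
    return G / batch.atoms_per_graph[:, None]


def _mean_pool_back(dG: np.ndarray, batch: GraphBatch) -> np.ndarray:
    return dG[batch.graph_id] / batch.atoms_per_graph[batch.graph_id][:, None]


class GCNNet:
    """Stacked mean-aggregation graph convolutions with residuals."""

    def __init__(self, d_atom: int, hidden: int = 32, n_layers: int = 2,
                 mlp_hidden: int = 16, dropout: float = 0.0,
                 residual: bool = True, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_layers, self.dropout, self.residual = n_layers, dropout, residual
        self.params: dict[str, np.ndarray] = {}
        dims = [d_atom] + [hidden] * n_layers
        for i in range(n_layers):
            self.params[f"W{i}"] = _glorot(rng, dims[i], dims[i + 1])
            self.params[f"b{i}"] = np.zeros(dims[i + 1])
        self.head = _MLPHead(rng, hidden if n_layers else d_atom, mlp_hidden,
                             1, "head_")
        self.params.update(self.head.params)
        self.head.params = self.params

    def _agg(self, H: np.ndarray, batch: GraphBatch) -> np.ndarray:
        M = H.copy()
        np.add.at(M, batch.dst, H[batch.src])
        return M * batch.inv_deg1[:, None]

    def _agg_back(self, dM: np.ndarray, batch: GraphBatch) -> np.ndarray:
        scaled = dM * batch.inv_deg1[:, None]
        dH = scaled.copy()
        np.add.at(dH, batch.src, scaled[batch.dst])
        return dH

    def forward(self, batch: GraphBatch, train: bool = False,
                rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        H = batch.X
        cache = {"H": [H], "M": [], "pre": [], "masks": []}
        for i in range(self.n_layers):
            M = self._agg(H, batch)
            Z = M @ self.params[f"W{i}"] + self.params[f"b{i}"]
            Hn = np.maximum(Z, 0.0)
            if train and self.dropout > 0:
                mask = (rng.random(Hn.shape) >= self.dropout) / (1 - self.dropout)
                Hn = Hn * mask
            else:
                mask = None
            if self.residual and Hn.shape == H.shape:
                Hn = Hn + H
            cache["M"].append(M)
            cache["pre"].append(Z)
            cache["masks"].append(mask)
            cache["H"].append(Hn)
            H = Hn
        G = _mean_pool(H, batch)
        logit, head_cache = self.head.forward(G, self.dropout, train, rng)
        cache["head"] = head_cache
        cache["batch"] = batch
        return logit, cache

    def backward(self, dlogit: np.ndarray, cache) -> dict[str, np.ndarray]:
        batch = cache["batch"]
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dG = self.head.backward(dlogit, cache["head"], grads)
        dH = _mean_pool_back(dG, batch)
        for i in reversed(range(self.n_layers)):
            H_in = cache["H"][i]
            d_relu = dH.copy()
            if self.residual and cache["H"][i + 1].shape == H_in.shape:
                d_res = dH
            else:
                d_res = None
            mask = cache["masks"][i]
            if mask is not None:
                d_relu = d_relu * mask
            dZ = d_relu * (cache["pre"][i] > 0)
            grads[f"W{i}"] += cache["M"][i].T @ dZ
            grads[f"b{i}"] += dZ.sum(axis=0)
            dM = dZ @ self.params[f"W{i}"].T
            dH = self._agg_back(dM, batch)
            if d_res is not None:
                dH = dH + d_res
        return grads


class DMPNNNet:
    """Directed message passing on bonds, excluding reverse-bond back-flow."""

    def __init__(self, d_atom: int, d_bond: int, hidden: int = 32,
                 depth: int = 3, ffn_hidden: int = 16, ffn_layers: int = 1,
                 dropout: float = 0.0, d_extra: int = 0, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.depth, self.dropout, self.d_extra = depth, dropout, d_extra
        self.params = {
            "Wi": _glorot(rng, d_atom + d_bond, hidden),
            "Wh": _glorot(rng, hidden, hidden),
            "Wo": _glorot(rng, d_atom + hidden, hidden),
            "bo": np.zeros(hidden),
        }
        self.head = _MLPHead(rng, hidden + d_extra, ffn_hidden, ffn_layers,
                             "head_")
        self.params.update(self.head.params)
        self.head.params = self.params

    def _message(self, h: np.ndarray, batch: GraphBatch) -> np.ndarray:
        s = np.zeros((batch.n_atoms, h.shape[1]))
        np.add.at(s, batch.dst, h)
        return s[batch.src] - h[batch.rev]

    def _message_back(self, dm: np.ndarray, batch: GraphBatch) -> np.ndarray:
        t = np.zeros((batch.n_atoms, dm.shape[1]))
        np.add.at(t, batch.src, dm)
        return t[batch.dst] - dm[batch.rev]

    def forward(self, batch: GraphBatch, extra: np.ndarray | None = None,
                train: bool = False, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        inp = np.concatenate([batch.X[batch.src], batch.E], axis=1)
        pre0 = inp @ self.params["Wi"]
        h0 = np.maximum(pre0, 0.0)
        cache = {"inp": inp, "pre0": pre0, "h": [h0], "m": [], "pre": [],
                 "masks": []}
        h = h0
        for _ in range(self.depth):
            m = self._message(h, batch)
            pre = h0 + m @ self.params["Wh"]
            h = np.maximum(pre, 0.0)
            if train and self.dropout > 0:
                mask = (rng.random(h.shape) >= self.dropout) / (1 - self.dropout)
                h = h * mask
            else:
                mask = None
            cache["m"].append(m)
            cache["pre"].append(pre)
            cache["masks"].append(mask)
            cache["h"].append(h)
        s_atom = np.zeros((batch.n_atoms, h.shape[1]))
        np.add.at(s_atom, batch.dst, h)
        a_in = np.concatenate([batch.X, s_atom], axis=1)
        pre_a = a_in @ self.params["Wo"] + self.params["bo"]
        h_atom = np.maximum(pre_a, 0.0)
        G = _mean_pool(h_atom, batch)
        if extra is not None:
            G = np.concatenate([G, extra], axis=1)
        logit, head_cache = self.head.forward(G, self.dropout, train, rng)
        cache.update(a_in=a_in, pre_a=pre_a, head=head_cache, batch=batch,
                     G_dim=h_atom.shape[1])
        return logit, cache

    def backward(self, dlogit: np.ndarray, cache) -> dict[str, np.ndarray]:
        batch = cache["batch"]
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dG_full = self.head.backward(dlogit, cache["head"], grads)
        dG = dG_full[:, :cache["G_dim"]]
        dh_atom = _mean_pool_back(dG, batch)
        dpre_a = dh_atom * (cache["pre_a"] > 0)
        grads["Wo"] += cache["a_in"].T @ dpre_a
        grads["bo"] += dpre_a.sum(axis=0)
        da_in = dpre_a @ self.params["Wo"].T
        ds_atom = da_in[:, batch.X.shape[1]:]
        dh = ds_atom[batch.dst] if batch.dst.size else np.zeros_like(cache["h"][-1])
        dh0 = np.zeros_like(cache["h"][0])
        for t in reversed(range(self.depth)):
            mask = cache["masks"][t]
            if mask is not None:
                dh = dh * mask
            dpre = dh * (cache["pre"][t] > 0)
            dh0 += dpre
            grads["Wh"] += cache["m"][t].T @ dpre
            dm = dpre @ self.params["Wh"].T
            dh = self._message_back(dm, batch)
        dh0 += dh  # gradient reaching h^(0) through the first message step
        dpre0 = dh0 * (cache["pre0"] > 0)
        grads["Wi"] += cache["inp"].T @ dpre0
        return grads


def bce_loss_grad(logits: np.ndarray, y: np.ndarray,
                  weights: np.ndarray) -> tuple[float, np.ndarray]:
    """Weighted binary cross-entropy; returns (loss, dloss/dlogits)."""
    p = 1.0 / (1.0 + np.exp(-logits))
    eps = 1e-12
    loss = -np.mean(weights * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    dlogit = weights * (p - y) / logits.size
    return float(loss), dlogit


def train_net(net, batch: GraphBatch, y: np.ndarray,
              extra: np.ndarray | None = None, epochs: int = 200,
              lr: float = 5e-3, seed: int = 0) -> list[float]:
    """Full-batch Adam training with class-weighted BCE; returns loss trace."""
    y = np.asarray(y, dtype=float)
    n_pos = max(y.sum(), 1.0)
    n_neg = max((1 - y).sum(), 1.0)
    weights = np.where(y == 1, len(y) / (2 * n_pos), len(y) / (2 * n_neg))
    opt = _Adam(net.params, lr=lr)
    rng = np.random.default_rng(seed)
    trace = []
    for _ in range(epochs):
        if isinstance(net, DMPNNNet):
            logits, cache = net.forward(batch, extra=extra, train=True, rng=rng)
        else:
            logits, cache = net.forward(batch, train=True, rng=rng)
        loss, dlogit = bce_loss_grad(logits, y, weights)
        grads = net.backward(dlogit, cache)
        opt.step(grads)
        trace.append(loss)
    return trace


def predict_net(net, batch: GraphBatch,
                extra: np.ndarray | None = None) -> np.ndarray:
    if isinstance(net, DMPNNNet):
        logits, _ = net.forward(batch, extra=extra, train=False)
    else:
        logits, _ = net.forward(batch, train=False)
    return 1.0 / (1.0 + np.exp(-logits))
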