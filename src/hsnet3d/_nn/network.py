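"""The hierarchical multi-task 3D network graph.

Five branch feature extractors (or one shared extractor) each feed a
binary semantic head; the malignancy head sees the concatenation of the
five branch feature vectors and the five semantic head probabilities, so
the disease-level prediction is an explicit function of interpretable
semantic evidence.  Branch features are tapped at the activation output,
before dropout, so inference features are unaffected by dropped units.

Each conv block is: Conv3D -> BatchNorm -> ReLU (feature tap point) ->
MaxPool(2) -> Dropout.  After the blocks: Flatten -> Dense(feature_dim)
-> ReLU (the branch feature vector) -> Dropout -> Dense(1) per semantic
head.  The malignancy head is Dense(h) -> ReLU -> Dropout per hidden
width, then Dense(1).
"""

from __future__ import annotations

import numpy as np

from .layers import (Conv3D, BatchNorm, ReLU, Dropout, MaxPool3D, AvgPool3D,
                     Flatten, Dense)


class ConfigError(ValueError):
    pass


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _Sequential:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class MultiTaskNet3D:
    """Six-head hierarchical network over cubic intensity patches.

    Head order: the five semantic tasks in canonical order, malignancy
    last.  ``shared_extractor=True`` is the baseline variant: a single
    feature extractor (and feature dense layer) serves all five semantic
    heads, so the five branch feature vectors are identical.
    """

    N_BRANCHES = 5

    def __init__(self, patch_size: int, conv_blocks: int, filters,
                 branch_feature_dim: int, dropout_rate: float,
                 shared_extractor: bool, malignancy_head_dims,
                 pool: str = "max", seed: int = 0):
        if pool not in ("max", "avg"):
            raise ConfigError("pool must be 'max' or 'avg'")
        self.pool = pool
        filters = list(filters)
        if conv_blocks > len(filters):
            filters = filters + [filters[-1]] * (conv_blocks - len(filters))
        size = patch_size
        for i in range(conv_blocks):
            if size < 2 or size % 2:
                raise ConfigError(
                    f"patch size {patch_size} cannot pass pooling block {i + 1}: "
                    f"spatial extent {size} is not an even number >= 2"
                )
            size //= 2
        self.patch_size = patch_size
        self.conv_blocks = conv_blocks
        self.filters = filters[:conv_blocks]
        self.branch_feature_dim = branch_feature_dim
        self.dropout_rate = dropout_rate
        self.shared_extractor = shared_extractor
        self.malignancy_head_dims = list(malignancy_head_dims)
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self._registry = []  # (path, layer)
        # input standardization, set from the training set before fitting
        self.input_mean = np.zeros((), dtype=np.float32)
        self.input_scale = np.ones((), dtype=np.float32)

        flat_dim = (size ** 3) * self.filters[-1]
        n_ext = 1 if shared_extractor else self.N_BRANCHES
        self.extractors = [
            self._build_extractor(f"shared" if shared_extractor else f"branch{b}",
                                  flat_dim)
            for b in range(n_ext)
        ]
        self.sem_heads = []
        for b in range(self.N_BRANCHES):
            layers = [Dropout(dropout_rate, self.rng),
                      Dense(branch_feature_dim, 1, self.rng)]
            self._register(f"head{b}", layers)
            self.sem_heads.append(_Sequential(layers))

        fusion_dim = self.N_BRANCHES * branch_feature_dim + self.N_BRANCHES
        layers = []
        fin = fusion_dim
        for i, h in enumerate(self.malignancy_head_dims):
            layers += [Dense(fin, h, self.rng), ReLU(), Dropout(dropout_rate, self.rng)]
            fin = h
        layers.append(Dense(fin, 1, self.rng))
        self._register("malignancy", layers)
        self.malignancy_head = _Sequential(layers)
        self.fusion_dim = fusion_dim
        self._p_sem = None

    # -- construction helpers ------------------------------------------------

    def _build_extractor(self, path: str, flat_dim: int) -> _Sequential:
        layers = []
        cin = 1
        for i in range(self.conv_blocks):
            conv = Conv3D(cin, self.filters[i], self.rng)
            if i == 0:
                conv._first_layer = True
            pool = MaxPool3D() if self.pool == "max" else AvgPool3D()
            layers += [conv, BatchNorm(self.filters[i]), ReLU(),
                       pool, Dropout(self.dropout_rate, self.rng)]
            cin = self.filters[i]
        layers += [Flatten(), Dense(flat_dim, self.branch_feature_dim, self.rng),
                   ReLU()]
        self._register(path, layers)
        return _Sequential(layers)

    def _register(self, path: str, layers) -> None:
        for i, layer in enumerate(layers):
            self._registry.append((f"{path}/{i}.{type(layer).__name__}", layer))

    # -- forward / backward --------------------------------------------------

    def _prepare(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.ndim != 4 or x.shape[1:] != (self.patch_size,) * 3:
            raise ValueError(
                f"expected (n, {self.patch_size}, {self.patch_size}, "
                f"{self.patch_size}) volumes, got {x.shape}"
            )
        x = (x - self.input_mean) / self.input_scale
        return x[:, None]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Probabilities (n, 6): five semantic heads then malignancy."""
        x = self._prepare(x)
        if self.shared_extractor:
            f = self.extractors[0].forward(x, train)
            feats = [f] * self.N_BRANCHES
        else:
            feats = [ext.forward(x, train) for ext in self.extractors]
        z_sem = np.concatenate(
            [self.sem_heads[b].forward(feats[b], train) for b in range(self.N_BRANCHES)],
            axis=1)
        p_sem = _sigmoid(z_sem)
        fusion = np.concatenate(feats + [p_sem], axis=1).astype(np.float32)
        z_mal = self.malignancy_head.forward(fusion, train)
        self._p_sem = p_sem
        return np.concatenate([p_sem, _sigmoid(z_mal)], axis=1)

    def backward(self, dz: np.ndarray) -> None:
        """Backpropagate d(loss)/d(logits) for all six heads, filling grads."""
        dz = np.asarray(dz, dtype=np.float32)
        dz_sem, dz_mal = dz[:, :5], dz[:, 5:6]
        d_fusion = self.malignancy_head.backward(dz_mal)
        fd = self.branch_feature_dim
        d_p_sem = d_fusion[:, 5 * fd:]
        p = self._p_sem
        dz_sem_total = dz_sem + d_p_sem * p * (1.0 - p)

        d_feats = []
        for b in range(self.N_BRANCHES):
            d_f = self.sem_heads[b].backward(
                np.ascontiguousarray(dz_sem_total[:, b:b + 1]))
            d_f = d_f + d_fusion[:, b * fd:(b + 1) * fd]
            d_feats.append(d_f.astype(np.float32))
        if self.shared_extractor:
            self.extractors[0].backward(sum(d_feats))
        else:
            for ext, d_f in zip(self.extractors, d_feats):
                ext.backward(d_f)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Deterministic inference (dropout off, BN running stats)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        return np.concatenate(
            [self.forward(x[i:i + batch_size], train=False)
             for i in range(0, x.shape[0], batch_size)], axis=0)

    # -- parameter access ----------------------------------------------------

    def parameters(self) -> dict:
        """Live references to every trainable tensor, by stable name."""
        out = {}
        for path, layer in self._registry:
            for k, v in layer.params().items():
                out[f"{path}/{k}"] = v
        return out

    def gradients(self) -> dict:
        out = {}
        for path, layer in self._registry:
            for k, v in layer.grads().items():
                out[f"{path}/{k}"] = v
        return out

    def set_input_normalization(self, mean: float, scale: float) -> None:
        self.input_mean[...] = mean
        self.input_scale[...] = max(float(scale), 1e-6)

    def bn_state(self) -> dict:
        out = {"input/mean": self.input_mean, "input/scale": self.input_scale}
        for path, layer in self._registry:
            for k, v in layer.state().items():
                out[f"{path}/{k}"] = v
        return out

    def snapshot(self) -> dict:
        """Deep copy of trainable parameters + BN running statistics."""
        return {k: v.copy() for k, v in {**self.parameters(), **self.bn_state()}.items()}

    def load_snapshot(self, snap: dict) -> None:
        live = {**self.parameters(), **self.bn_state()}
        if set(snap) != set(live):
            missing = set(live) ^ set(snap)
            raise KeyError(f"parameter name mismatch: {sorted(missing)[:5]} ...")
        for k, v in snap.items():
            live[k][...] = v

    def count_parameters(self) -> int:
        return int(sum(v.size for v in self.parameters().values()))

    # -- batch-norm statistic refresh (after SWA averaging) ------------------

    def refresh_bn_stats(self, x: np.ndarray, batch_size: int = 64) -> None:
        """Recompute BN running stats as the mean of batch moments over x."""
        bns = [layer for _, layer in self._registry if isinstance(layer, BatchNorm)]
        if not bns:
            return
        drops = [layer for _, layer in self._registry if isinstance(layer, Dropout)]
        rates = [d.rate for d in drops]
        for d in drops:
            d.rate = 0.0  # statistics are for the inference-time network
        for bn in bns:
            bn.start_accumulation()
        try:
            for i in range(0, x.shape[0], batch_size):
                self.forward(x[i:i + batch_size], train=True)
        finally:
            for bn in bns:
                bn.finish_accumulation()
            for d, r in zip(drops, rates):
                d.rate = r
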