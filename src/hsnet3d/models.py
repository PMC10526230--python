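"""Architecture configuration and model construction.

Two variants share one code path:

* the **shared-extractor baseline** (HSCNN style): a single 3D feature
  extractor feeds all five semantic heads;
* **HSNet**: one dedicated, deeper 3D feature extractor per semantic
  task, with branch features tapped at the activation output (before
  dropout).

Both end in five semantic probability heads plus a malignancy head fed
by the concatenated branch features and semantic probabilities.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict

import numpy as np

from ._nn.network import MultiTaskNet3D, ConfigError

__all__ = ["ArchConfig", "ConfigError", "build_model", "forward",
           "count_parameters", "save_model", "load_model"]


@dataclass(frozen=True)
class ArchConfig:
    """Hyperparameters of the six-head network.

    ``shared_extractor=True`` selects the baseline; it must come with a
    strictly shallower block count than the per-branch variant, which is
    the deeper architecture by construction.
    """

    patch_size: int = 32
    n_branches: int = 5
    conv_blocks_per_branch: int = 3
    filters_per_block: tuple = (8, 16, 32)
    kernel_size: int = 3
    branch_feature_dim: int = 32
    dropout_rate: float = 0.0
    shared_extractor: bool = False
    malignancy_head_dims: tuple = (64,)
    pool: str = "max"

    def __post_init__(self):
        if self.n_branches != 5:
            raise ConfigError("the hierarchical design uses exactly 5 semantic branches")
        if self.kernel_size != 3:
            raise ConfigError("only 3x3x3 kernels are supported")
        if self.conv_blocks_per_branch < 1:
            raise ConfigError("need at least one conv block")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must be in [0, 1)")

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def hsnet(cls, **kw) -> "ArchConfig":
        """The five-extractor, deeper variant (3 conv blocks by default)."""
        kw.setdefault("conv_blocks_per_branch", 3)
        return cls(shared_extractor=False, **kw)

    @classmethod
    def hscnn(cls, **kw) -> "ArchConfig":
        """The shared-extractor, shallower baseline (2 conv blocks)."""
        kw.setdefault("conv_blocks_per_branch", 2)
        return cls(shared_extractor=True, **kw)


def build_model(cfg: ArchConfig, seed: int = 0) -> MultiTaskNet3D:
    """Instantiate the network with seeded weight initialization."""
    return MultiTaskNet3D(
        patch_size=cfg.patch_size,
        conv_blocks=cfg.conv_blocks_per_branch,
        filters=cfg.filters_per_block,
        branch_feature_dim=cfg.branch_feature_dim,
        dropout_rate=cfg.dropout_rate,
        shared_extractor=cfg.shared_extractor,
        malignancy_head_dims=cfg.malignancy_head_dims,
        pool=cfg.pool,
        seed=seed,
    )


def forward(model: MultiTaskNet3D, volumes: np.ndarray) -> np.ndarray:
    """Inference-mode probabilities (n, 6); dropout off, deterministic."""
    return model.predict_proba(volumes)


def count_parameters(model: MultiTaskNet3D) -> int:
    """Total number of trainable scalars."""
    return model.count_parameters()


def expected_parameter_count(cfg: ArchConfig) -> int:
    """Closed-form trainable-parameter count from the layer arithmetic.

    Per conv block on cin -> cout channels: 27*cin*cout + cout conv
    weights/biases plus 2*cout batch-norm scales/shifts.  The feature
    dense layer maps the flattened final block to branch_feature_dim;
    each semantic head is feature_dim + 1; the malignancy head stacks
    dense layers from 5*feature_dim + 5 through the configured widths
    down to one logit.
    """
    filters = list(cfg.filters_per_block)
    blocks = cfg.conv_blocks_per_branch
    if blocks > len(filters):
        filters += [filters[-1]] * (blocks - len(filters))
    filters = filters[:blocks]

    per_extractor = 0
    cin = 1
    size = cfg.patch_size
    for cout in filters:
        per_extractor += 27 * cin * cout + cout   # conv W + b
        per_extractor += 2 * cout                 # BN gamma + beta
        cin = cout
        size //= 2
    flat = size ** 3 * filters[-1]
    per_extractor += flat * cfg.branch_feature_dim + cfg.branch_feature_dim

    n_ext = 1 if cfg.shared_extractor else cfg.n_branches
    total = n_ext * per_extractor
    total += cfg.n_branches * (cfg.branch_feature_dim + 1)  # semantic heads

    fin = cfg.n_branches * cfg.branch_feature_dim + cfg.n_branches
    for h in cfg.malignancy_head_dims:
        total += fin * h + h
        fin = h
    total += fin + 1
    return total


# ---------------------------------------------------------------------------
# Checkpoints: one archive holding named tensors + JSON architecture metadata
# ---------------------------------------------------------------------------

def save_model(model: MultiTaskNet3D, cfg: ArchConfig, path,
               metadata: dict | None = None) -> None:
    snap = model.snapshot()
    meta = {"arch": cfg.as_dict(), "seed": model.seed, **(metadata or {})}
    buf = io.BytesIO()
    np.savez(buf, **snap)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("tensors.npz", buf.getvalue())
        zf.writestr("meta.json", json.dumps(meta, indent=1))


def load_model(path):
    """Rebuild a checkpointed model; returns (model, cfg, metadata)."""
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        with zf.open("tensors.npz") as fh:
            tensors = dict(np.load(io.BytesIO(fh.read())))
    arch = meta.pop("arch")
    arch["filters_per_block"] = tuple(arch["filters_per_block"])
    arch["malignancy_head_dims"] = tuple(arch["malignancy_head_dims"])
    cfg = ArchConfig(**arch)
    model = build_model(cfg, seed=meta.get("seed", 0))
    model.load_snapshot(tensors)
    return model, cfg, meta
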