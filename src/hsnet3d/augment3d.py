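"""Training-set expansion by axis transposition and flipping of 3D volumes.

The 48 rigid symmetries of the cube (3! axis permutations x 2^3 axis
flips) leave a cubic voxel grid invariant, so applying any of them to a
nodule patch yields another valid patch with identical labels.  Training
sets are expanded 6x by keeping the original plus five distinct
non-identity symmetries per sample; test and validation sets are never
expanded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SymmetryOp:
    """One cube symmetry: output axis i is input axis ``perm[i]``, flipped iff ``flips[i]``."""

    perm: tuple
    flips: tuple

    def __post_init__(self):
        if sorted(self.perm) != [0, 1, 2]:
            raise ValueError(f"perm must be a bijection of (0,1,2), got {self.perm}")
        if len(self.flips) != 3:
            raise ValueError("flips must have length 3")
        object.__setattr__(self, "perm", tuple(int(p) for p in self.perm))
        object.__setattr__(self, "flips", tuple(bool(f) for f in self.flips))

    @property
    def is_identity(self) -> bool:
        return self.perm == (0, 1, 2) and not any(self.flips)

    def apply(self, volume: np.ndarray) -> np.ndarray:
        """Transform a cubic (D,D,D) array, or a (N,D,D,D) batch."""
        volume = np.asarray(volume)
        offset = volume.ndim - 3
        if volume.ndim < 3 or len({volume.shape[offset + i] for i in range(3)}) != 1:
            raise ValueError("symmetry ops require a cubic volume (trailing dims equal)")
        axes = tuple(range(offset)) + tuple(offset + p for p in self.perm)
        out = np.transpose(volume, axes)
        flip_axes = tuple(offset + i for i, f in enumerate(self.flips) if f)
        if flip_axes:
            out = np.flip(out, axis=flip_axes)
        return np.ascontiguousarray(out)

    def compose(self, other: "SymmetryOp") -> "SymmetryOp":
        """The op equivalent to applying ``other`` first, then ``self``."""
        perm = tuple(other.perm[p] for p in self.perm)
        flips = tuple(other.flips[self.perm[i]] ^ self.flips[i] for i in range(3))
        return SymmetryOp(perm, flips)

    def inverse(self) -> "SymmetryOp":
        inv_perm = tuple(int(i) for i in np.argsort(self.perm))
        inv_flips = tuple(self.flips[inv_perm[i]] for i in range(3))
        return SymmetryOp(inv_perm, inv_flips)


IDENTITY = SymmetryOp((0, 1, 2), (False, False, False))


def enumerate_symmetries() -> list:
    """All 48 cube symmetries, identity first, in a fixed deterministic order."""
    from itertools import permutations, product

    ops = [IDENTITY]
    for perm in permutations((0, 1, 2)):
        for flips in product((False, True), repeat=3):
            op = SymmetryOp(perm, flips)
            if not op.is_identity:
                ops.append(op)
    return ops


def apply_symmetry(volume: np.ndarray, op: SymmetryOp) -> np.ndarray:
    """Functional alias for :meth:`SymmetryOp.apply`."""
    return op.apply(volume)


@dataclass
class AugmentedSet:
    """An expanded training set with provenance back to the source samples."""

    volumes: np.ndarray        # (factor * n, D, D, D)
    labels: np.ndarray         # (factor * n, n_tasks)
    source_index: np.ndarray   # (factor * n,) index into the input set
    op_index: np.ndarray       # (factor * n,) index into enumerate_symmetries()
    source_ids: list           # id per output sample, copied from its source


def expand_training_set(volumes, labels, factor: int = 6, seed: int = 0,
                        ids=None) -> AugmentedSet:
    """Expand a training set ``factor``-fold with distinct cube symmetries.

    Each source sample contributes the original volume plus ``factor - 1``
    distinct non-identity symmetries drawn without replacement, so the
    output has exactly ``factor * n`` samples.  Labels are copied unchanged.
    Deterministic for a fixed seed.
    """
    if not 1 <= factor <= 48:
        raise ValueError(f"augmentation factor must be in 1..48, got {factor}")
    volumes = np.asarray(volumes)
    labels = np.asarray(labels)
    n = volumes.shape[0]
    if labels.shape[0] != n:
        raise ValueError("volumes and labels disagree on sample count")
    if ids is None:
        ids = [str(i) for i in range(n)]
    ops = enumerate_symmetries()
    rng = np.random.default_rng(seed)

    out_vols, out_labels, src_idx, op_idx, out_ids = [], [], [], [], []
    for i in range(n):
        chosen = [0]  # identity: the original always survives
        if factor > 1:
            chosen += list(rng.choice(np.arange(1, 48), size=factor - 1, replace=False))
        for k in chosen:
            out_vols.append(ops[k].apply(volumes[i]))
            out_labels.append(labels[i])
            src_idx.append(i)
            op_idx.append(k)
            out_ids.append(ids[i])
    return AugmentedSet(
        volumes=np.stack(out_vols),
        labels=np.stack(out_labels),
        source_index=np.asarray(src_idx),
        op_index=np.asarray(op_idx),
        source_ids=out_ids,
    )
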