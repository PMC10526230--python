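"""Synthetic 3D lung-nodule phantom generator.

Renders cubic CT-like intensity patches in which every semantic ordinal
level controls one visual property of the nodule, monotonically:

* **sphericity** — the ellipsoid aspect ratio (level 5 = sphere);
* **margin** — Gaussian blur applied to the scene edge (level 5 = sharp);
* **subtlety** — the contrast of the nodule shell above the lung
  background (level 5 = high contrast);
* **texture** — the density of the inner core, from ground-glass-like
  (well below the shell) up to solid (level 5);
* **calcification** — a hyperdense inclusion pattern mimicking the
  radiological patterns (popcorn, laminated, solid, non-central,
  central); level 6 renders no inclusion;
* **malignancy** — overall nodule size and the amplitude/count of radial
  spiculation spikes, both monotone in the suspicion level.

The nodule is a two-zone oblate ellipsoid: an inner core (normalized
ellipsoid radius rho <= 0.6) filled at the texture-controlled core
density and an outer shell (0.6 < rho <= 1) filled at background +
contrast.  Spikes
extend the rho <= 1 boundary along random directions.  Margin blur is
applied only in a band around the nodule boundary — edge sharpness is a
boundary property, and restricting it there keeps the interior texture,
contrast and calcification signals intact even for heavily blurred
margins.  Gaussian background noise is added last.  Continuous render parameters receive +/-10% multiplicative
jitter within a level so adjacent levels overlap slightly and the
classification task is non-degenerate.

Intensities are HU-like floats; normalization is the model's concern.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .semantics import OrdinalAttributes, BinaryLabels, binarize, ALL_FEATURES


class SizingError(ValueError):
    """The requested nodule does not fit inside the voxel grid."""


@dataclass(frozen=True)
class PhantomConfig:
    """Generator configuration: grid, background, and per-level lookup tables."""

    grid_size: int = 32
    background_mean: float = -800.0
    background_sd: float = 50.0
    #: ellipsoid long/short aspect ratio per sphericity level (5 = sphere)
    aspect_ratio: dict = field(default_factory=lambda: {1: 3.0, 2: 2.2, 3: 1.6, 4: 1.25, 5: 1.0})
    #: scene blur sigma (voxels) per margin level (5 = sharpest edge)
    edge_blur_sigma: dict = field(default_factory=lambda: {1: 2.5, 2: 2.0, 3: 1.5, 4: 1.0, 5: 0.5})
    #: shell intensity above background per subtlety level
    contrast: dict = field(default_factory=lambda: {1: 100.0, 2: 200.0, 3: 300.0, 4: 450.0, 5: 600.0})
    #: inner-core density per texture level (ground-glass .. solid)
    core_density: dict = field(default_factory=lambda: {1: -600.0, 2: -450.0, 3: -300.0, 4: -150.0, 5: 50.0})
    #: reference ellipsoid scale per malignancy level, in voxels on the
    #: reference 32-voxel grid (rescaled in proportion to grid_size)
    size_scale: dict = field(default_factory=lambda: {1: 5.0, 2: 5.5, 3: 6.0, 4: 6.5, 5: 7.0})
    #: radial spike amplitude (voxels) per malignancy level
    spiculation_amplitude: dict = field(default_factory=lambda: {1: 0.0, 2: 0.4, 3: 0.8, 4: 1.2, 5: 1.6})
    #: number of spikes per malignancy level
    spiculation_count: dict = field(default_factory=lambda: {1: 0, 2: 3, 3: 5, 4: 8, 5: 11})
    inclusion_intensity: float = 800.0
    inclusion_radius: float = 2.2
    #: multiplicative jitter half-width on continuous render parameters
    jitter: float = 0.10
    #: categorical level probabilities per feature; None = uniform
    level_probs: dict | None = None

    def __post_init__(self):
        if self.grid_size < 16:
            raise ValueError("grid_size must be >= 16")
        for name in ("aspect_ratio", "edge_blur_sigma", "contrast",
                     "core_density", "size_scale", "spiculation_amplitude"):
            tab = getattr(self, name)
            vals = [tab[k] for k in sorted(tab)]
            diffs = np.diff(vals)
            decreasing = name in ("aspect_ratio", "edge_blur_sigma")
            ok = np.all(diffs < 0) if decreasing else np.all(diffs > 0)
            if not (ok and np.all(np.isfinite(vals))):
                raise ValueError(f"lookup table {name!r} must be finite and monotone")

    def as_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class AttributeSet:
    """Ordinal levels plus the realized continuous render parameters."""

    ordinal: OrdinalAttributes
    semi_axes: tuple                # (3,) ellipsoid semi-axes, voxels
    blur_sigma: float
    contrast: float                 # shell intensity above background
    core_density: float             # inner-core intensity
    spike_amplitude: float          # voxels
    spike_dirs: tuple               # (k, 3) unit directions
    inclusion_offsets: tuple        # (m, 3) voxel offsets from nodule center
    inclusion_radius: float
    noise_seed: int


def _jittered(rng: np.random.Generator, value: float, frac: float) -> float:
    return float(value * rng.uniform(1.0 - frac, 1.0 + frac))


def _unit_vectors(rng: np.random.Generator, k: int) -> np.ndarray:
    if k == 0:
        return np.zeros((0, 3))
    v = rng.normal(size=(k, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _inclusion_offsets(level: int, rng: np.random.Generator,
                       semi: np.ndarray, radius: float) -> np.ndarray:
    """Voxel offsets of calcification inclusions for pattern levels 1-5."""
    def at_rho(rho, k):
        dirs = _unit_vectors(rng, k)
        return dirs * semi * rho

    if level == 1:      # popcorn: several scattered blobs
        return at_rho(0.55, 6)
    if level == 2:      # laminated: blob ring on a random great circle
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        a = np.cross(n, [1.0, 0.0, 0.0])
        if np.linalg.norm(a) < 1e-6:
            a = np.cross(n, [0.0, 1.0, 0.0])
        a /= np.linalg.norm(a)
        b = np.cross(n, a)
        angles = np.linspace(0, 2 * np.pi, 10, endpoint=False)
        ring = np.outer(np.cos(angles), a) + np.outer(np.sin(angles), b)
        return ring * semi * 0.7
    if level == 3:      # solid: one large central mass
        return np.zeros((1, 3))
    if level == 4:      # non-central: a single off-center blob
        return at_rho(0.5, 1)
    if level == 5:      # central: a single central blob
        return np.zeros((1, 3))
    return np.zeros((0, 3))  # level 6: absent


def sample_attributes(config: PhantomConfig, rng) -> AttributeSet:
    """Draw ordinal levels and realize continuous render parameters.

    Levels come from the configured categorical priors (uniform by
    default); malignancy additionally sets the size scale and spiculation
    from their monotone tables.  Deterministic for a given RNG state.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    levels = {}
    for feat in ALL_FEATURES:
        n = 6 if feat == "calcification" else 5
        probs = None if config.level_probs is None else config.level_probs.get(feat)
        if probs is None:
            probs = np.full(n, 1.0 / n)
        levels[feat] = int(rng.choice(np.arange(1, n + 1), p=np.asarray(probs)))
    ordinal = OrdinalAttributes(**levels)

    j = config.jitter
    # size-like quantities are specified for the reference 32-voxel grid
    gs = config.grid_size / 32.0
    s = _jittered(rng, config.size_scale[ordinal.malignancy], j) * gs
    ar = max(1.0, _jittered(rng, config.aspect_ratio[ordinal.sphericity], j))
    # volume-preserving oblate semi-axes with long/short ratio = ar; the
    # flattened axis is chosen at random (augmentation covers orientation)
    semi = np.array([s * ar ** (1.0 / 3.0), s * ar ** (1.0 / 3.0), s * ar ** (-2.0 / 3.0)])
    semi = semi[rng.permutation(3)]

    k = config.spiculation_count[ordinal.malignancy]
    amp = _jittered(rng, config.spiculation_amplitude[ordinal.malignancy], j) * gs
    inc_r = _jittered(rng, config.inclusion_radius, j) * max(gs, 0.7)
    inc = _inclusion_offsets(ordinal.calcification, rng, semi, inc_r)
    return AttributeSet(
        ordinal=ordinal,
        semi_axes=tuple(float(x) for x in semi),
        blur_sigma=_jittered(rng, config.edge_blur_sigma[ordinal.margin], j),
        contrast=_jittered(rng, config.contrast[ordinal.subtlety], j),
        core_density=_jittered(rng, config.core_density[ordinal.texture], j),
        spike_amplitude=amp,
        spike_dirs=tuple(map(tuple, _unit_vectors(rng, k))),
        inclusion_offsets=tuple(map(tuple, inc)),
        inclusion_radius=inc_r,
        noise_seed=int(rng.integers(0, 2 ** 31 - 1)),
    )


@dataclass
class VolumeSample:
    """One rendered phantom: intensities + attributes + binary labels."""

    intensities: np.ndarray
    attrs: AttributeSet
    labels: BinaryLabels
    id: str = ""


#: spike angular sharpness (von Mises style concentration)
_SPIKE_KAPPA = 30.0


def render_volume(attrs: AttributeSet, config: PhantomConfig) -> VolumeSample:
    """Render one phantom volume from realized attributes.

    Raises :class:`SizingError` when the nodule (including spikes) would
    not fit inside the grid with a one-voxel margin.
    """
    g = config.grid_size
    semi = np.asarray(attrs.semi_axes, dtype=float)
    reach = float(semi.max() + attrs.spike_amplitude)
    if reach > (g - 1) / 2.0 - 1.0:
        raise SizingError(
            f"nodule reach {reach:.1f} voxels exceeds grid half-extent "
            f"{(g - 1) / 2.0 - 1.0:.1f} (grid_size={g})"
        )

    center = (g - 1) / 2.0
    coords = np.stack(np.meshgrid(*([np.arange(g, dtype=np.float64)] * 3),
                                  indexing="ij"), axis=-1) - center
    rho = np.sqrt(((coords / semi) ** 2).sum(axis=-1))

    # spiculation raises the rho <= 1 boundary along the spike directions
    bound = np.ones_like(rho)
    dirs = np.asarray(attrs.spike_dirs, dtype=float)
    if dirs.size and attrs.spike_amplitude > 0:
        r = np.linalg.norm(coords, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(r[..., None] > 0, coords / np.maximum(r, 1e-9)[..., None], 0.0)
        amp_rel = attrs.spike_amplitude / float(np.exp(np.log(semi).mean()))
        for u in dirs:
            cos = unit @ u
            bound += amp_rel * np.exp(_SPIKE_KAPPA * (cos - 1.0))

    nodule = rho <= bound
    core = rho <= 0.6
    scene = np.full((g, g, g), config.background_mean, dtype=np.float64)
    scene[nodule] = config.background_mean + attrs.contrast
    scene[core] = attrs.core_density

    for off in np.asarray(attrs.inclusion_offsets, dtype=float).reshape(-1, 3):
        d = np.linalg.norm(coords - off, axis=-1)
        scene[d <= attrs.inclusion_radius] = config.inclusion_intensity

    # edge feathering: blend toward the blurred scene only near the boundary
    blurred = ndimage.gaussian_filter(scene, sigma=attrs.blur_sigma, mode="nearest")
    r_geo = float(np.exp(np.log(semi).mean()))
    dist = (rho - bound) * r_geo          # signed voxel distance, approx.
    tau = max(0.9 * attrs.blur_sigma, 0.4)
    edge_w = np.exp(-0.5 * (dist / tau) ** 2)
    scene = scene + edge_w * (blurred - scene)
    noise_rng = np.random.default_rng(attrs.noise_seed)
    scene += noise_rng.normal(0.0, config.background_sd, size=scene.shape)

    return VolumeSample(
        intensities=scene.astype(np.float32),
        attrs=attrs,
        labels=binarize(attrs.ordinal),
    )


def sample_volume(config: PhantomConfig, rng) -> VolumeSample:
    """Draw attributes and render, in one step."""
    return render_volume(sample_attributes(config, rng), config)


# ---------------------------------------------------------------------------
# Image statistics (one per semantic attribute, for discriminability checks)
# ---------------------------------------------------------------------------

def nodule_mask(volume: np.ndarray, config: PhantomConfig) -> np.ndarray:
    """Adaptive threshold segmentation used by the image statistics.

    The cut sits at 40% of the nodule's own peak excess over background,
    which keeps faint (subtlety 1) nodules while excluding the soft halo
    that heavy margin blur spreads around bright ones.
    """
    smooth = ndimage.gaussian_filter(np.asarray(volume, dtype=float), 1.0)
    frame = np.ones_like(smooth, dtype=bool)
    frame[2:-2, 2:-2, 2:-2] = False
    bg = float(np.median(smooth[frame]))
    cand = smooth > bg + 40.0
    if not cand.any():
        return cand
    peak = float(np.percentile(smooth[cand], 75))
    return smooth > bg + 0.4 * (peak - bg)


def image_statistics(volume: np.ndarray, config: PhantomConfig) -> dict:
    """Scalar statistics, each matched to one semantic attribute.

    ``anisotropy`` (sphericity, decreasing), ``edge_sharpness`` (margin,
    increasing), ``shell_contrast`` (subtlety), ``core_density``
    (texture), ``max_intensity`` (calcification presence), and
    ``nodule_volume`` (malignancy via size).
    """
    vol = np.asarray(volume, dtype=float)
    mask = nodule_mask(vol, config)
    out = {"max_intensity": float(vol.max()), "nodule_volume": float(mask.sum())}
    if mask.sum() < 8:
        out.update(anisotropy=np.nan, edge_sharpness=np.nan,
                   shell_contrast=np.nan, core_density=np.nan)
        return out

    pts = np.argwhere(mask).astype(float)
    cov = np.cov(pts.T)
    evals = np.sort(np.linalg.eigvalsh(cov))
    out["anisotropy"] = float(evals[-1] / max(evals[0], 1e-9))

    bg = float(np.median(vol[~mask]))
    nod_vals = vol[mask]

    # subtlety: median excess of the nodule interior over background.
    # A fixed low threshold keeps faint nodules; one erosion drops the
    # blur halo; hyperdense (calcified) voxels are excluded so the
    # statistic reads contrast, not calcification.
    smooth = ndimage.gaussian_filter(vol, 1.0)
    broad = ndimage.binary_erosion(smooth > config.background_mean + 45.0,
                                   iterations=1)
    if broad.sum() >= 8:
        inner = vol[broad]
        soft_inner = inner[inner < config.inclusion_intensity / 2.0]
        out["shell_contrast"] = float(
            np.median(soft_inner if soft_inner.size else inner) - bg)
    else:
        out["shell_contrast"] = float(np.median(nod_vals) - bg)

    dt = ndimage.distance_transform_edt(mask)
    deep_vals = vol[dt >= 0.55 * dt.max()]
    # ignore hyperdense (calcified) voxels: the statistic targets the
    # non-calcified interior density
    soft = deep_vals[deep_vals < config.inclusion_intensity / 2.0]
    out["core_density"] = float(np.median(soft if soft.size else deep_vals))

    smooth = ndimage.gaussian_filter(vol, 0.8)
    grad = np.stack(np.gradient(smooth))
    gmag = np.sqrt((grad ** 2).sum(axis=0))
    band = ndimage.binary_dilation(mask, iterations=1) & ~ndimage.binary_erosion(mask, iterations=1)
    peak = float(np.percentile(smooth[mask], 90))
    scale = max(peak - bg, 1.0)
    out["edge_sharpness"] = float(np.percentile(gmag[band], 90) / scale)
    return out


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def generate_arrays(n: int, config: PhantomConfig, seed: int):
    """Generate n phantoms in memory: (volumes, ordinal table, binary labels).

    Returns ``(X, table, Y)`` with X of shape (n, g, g, g), ``table`` a
    DataFrame with id + ordinal + ``_bin`` columns, and Y the (n, 6)
    binary label array in canonical feature order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    volumes, rows = [], []
    for i in range(n):
        s = sample_volume(config, rng)
        s.id = f"phantom-{i:05d}"
        volumes.append(s.intensities)
        row = {"id": s.id, **s.attrs.ordinal.as_dict()}
        row.update({f + "_bin": v for f, v in s.labels.as_dict().items()})
        rows.append(row)
    table = pd.DataFrame(rows)
    y = table[[f + "_bin" for f in ALL_FEATURES]].to_numpy()
    return np.stack(volumes), table, y


def generate_dataset(n: int, config: PhantomConfig, out_dir, seed: int = 0) -> dict:
    """Write n phantom volumes (NIfTI) plus a label CSV and JSON manifest.

    Re-running with the same seed and config reproduces a byte-identical
    CSV and voxel-identical volumes.
    """
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    X, table, _ = generate_arrays(n, config, seed)
    paths = []
    for i, sample_id in enumerate(table["id"]):
        p = out_dir / f"{sample_id}.nii.gz"
        nib.save(nib.Nifti1Image(X[i], affine=np.eye(4)), p)
        paths.append(p.name)
    labels_path = out_dir / "labels.csv"
    table.to_csv(labels_path, index=False)
    manifest = {
        "n": n,
        "seed": seed,
        "config_hash": config.hash(),
        "config": config.as_dict(),
        "labels": labels_path.name,
        "volumes": paths,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def load_dataset(manifest_path):
    """Load a generated dataset back into (X, table, Y) arrays."""
    import nibabel as nib

    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    table = pd.read_csv(root / manifest["labels"])
    X = np.stack([np.asarray(nib.load(root / p).dataobj) for p in manifest["volumes"]])
    y = table[[f + "_bin" for f in ALL_FEATURES]].to_numpy()
    return X, table, y
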