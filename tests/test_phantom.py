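"""Phantom generator: determinism, geometry, label consistency, signals."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from hsnet3d.phantom import (PhantomConfig, AttributeSet, SizingError,
                             sample_attributes, render_volume, generate_arrays,
                             generate_dataset, load_dataset, image_statistics,
                             nodule_mask)
from hsnet3d.semantics import OrdinalAttributes, binarize, ALL_FEATURES


@pytest.fixture(scope="module")
def config():
    return PhantomConfig()


def fixed_attrs(config, semi=(9.0, 9.0, 9.0), blur=0.5, contrast=450.0,
                core=-150.0, calcification=6, **ordinal_overrides):
    levels = dict(malignancy=1, margin=5, sphericity=5, subtlety=4,
                  texture=4, calcification=calcification)
    levels.update(ordinal_overrides)
    return AttributeSet(
        ordinal=OrdinalAttributes(**levels),
        semi_axes=semi, blur_sigma=blur, contrast=contrast, core_density=core,
        spike_amplitude=0.0, spike_dirs=(), inclusion_offsets=(),
        inclusion_radius=2.2, noise_seed=7,
    )


# ---------------------------------------------------------------------------
# attribute sampling
# ---------------------------------------------------------------------------

def test_sample_attributes_seed_determinism(config):
    a = sample_attributes(config, np.random.default_rng(11))
    b = sample_attributes(config, np.random.default_rng(11))
    assert a == b


def test_malignancy_level_controls_spiculation_and_size(config):
    assert (config.spiculation_amplitude[5] > config.spiculation_amplitude[1])
    assert (config.size_scale[5] > config.size_scale[1])
    rng = np.random.default_rng(0)
    draws = [sample_attributes(config, rng) for _ in range(300)]
    high = [d for d in draws if d.ordinal.malignancy == 5]
    low = [d for d in draws if d.ordinal.malignancy == 1]
    assert min(d.spike_amplitude for d in high) > \
        max(d.spike_amplitude for d in low)
    assert min(max(d.semi_axes) for d in high) > 0  # realized and positive


def test_uniform_level_frequencies_within_three_binomial_sds(config):
    rng = np.random.default_rng(123)
    n = 10_000
    levels = np.array([sample_attributes(config, rng).ordinal.sphericity
                       for _ in range(n)])
    p = 0.2
    bound = 3 * np.sqrt(p * (1 - p) / n)
    for lv in range(1, 6):
        assert abs((levels == lv).mean() - p) < bound


def test_realized_parameters_respect_jitter_bounds(config):
    rng = np.random.default_rng(5)
    for _ in range(100):
        a = sample_attributes(config, rng)
        lo, hi = 1 - config.jitter, 1 + config.jitter
        tab = config.contrast[a.ordinal.subtlety]
        assert tab * lo <= a.contrast <= tab * hi
        tab = config.edge_blur_sigma[a.ordinal.margin]
        assert tab * lo <= a.blur_sigma <= tab * hi


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def test_rendered_volume_shape_and_label_consistency(config):
    rng = np.random.default_rng(3)
    for _ in range(10):
        s = render_volume(sample_attributes(config, rng), config)
        assert s.intensities.shape == (config.grid_size,) * 3
        assert np.isfinite(s.intensities).all()
        assert s.labels == binarize(s.attrs.ordinal)


def test_calcification_absent_renders_no_hyperdense_voxel(config):
    s = render_volume(fixed_attrs(config, calcification=6), config)
    assert s.intensities.max() < config.inclusion_intensity - 100


def test_calcification_present_renders_hyperdense_voxels(config):
    rng = np.random.default_rng(1)
    a = sample_attributes(PhantomConfig(
        level_probs={"calcification": [0, 0, 0, 0, 1, 0]}), rng)
    s = render_volume(a, config)
    assert s.intensities.max() > s.intensities.mean() + 500


def test_spherical_nodule_has_isotropic_second_moments(config):
    s = render_volume(fixed_attrs(config, semi=(8.0, 8.0, 8.0)), config)
    mask = nodule_mask(s.intensities, config)
    evals = np.sort(np.linalg.eigvalsh(np.cov(np.argwhere(mask).T)))
    assert evals[-1] / evals[0] <= 1.15


def test_flat_nodule_has_anisotropic_second_moments(config):
    s = render_volume(fixed_attrs(config, semi=(9.0, 9.0, 3.5)), config)
    mask = nodule_mask(s.intensities, config)
    evals = np.sort(np.linalg.eigvalsh(np.cov(np.argwhere(mask).T)))
    assert evals[-1] / evals[0] > 2.0


def test_eroded_core_mean_matches_configured_core_density(config):
    core = -150.0
    s = render_volume(fixed_attrs(config, core=core), config)
    g = config.grid_size
    c = (g - 1) / 2.0
    coords = np.stack(np.meshgrid(*([np.arange(g)] * 3), indexing="ij"),
                      axis=-1) - c
    rho = np.sqrt(((coords / 9.0) ** 2).sum(axis=-1))
    deep = rho <= 0.35
    n_core = int(deep.sum())
    tol = 3 * config.background_sd / np.sqrt(n_core)
    assert abs(s.intensities[deep].mean() - core) < tol + 5.0


def test_higher_contrast_increases_nodule_excess(config):
    lo = render_volume(fixed_attrs(config, contrast=100.0), config)
    hi = render_volume(fixed_attrs(config, contrast=600.0), config)
    bg = config.background_mean
    mask = nodule_mask(lo.intensities, config)
    assert abs(hi.intensities[mask].mean() - bg) > \
        abs(lo.intensities[mask].mean() - bg)


def test_oversized_nodule_raises_sizing_error(config):
    with pytest.raises(SizingError):
        render_volume(fixed_attrs(config, semi=(15.5, 8.0, 8.0)), config)


def test_config_validation():
    with pytest.raises(ValueError):
        PhantomConfig(grid_size=8)
    with pytest.raises(ValueError, match="contrast"):
        PhantomConfig(contrast={1: 300.0, 2: 200.0, 3: 300.0, 4: 450.0, 5: 600.0})


# ---------------------------------------------------------------------------
# monotone discriminability: every attribute recoverable from one statistic
# ---------------------------------------------------------------------------

def test_single_statistic_discriminability(phantom_batch, config):
    """Each binary label is separable by its matching image statistic
    (AUC > 0.8 on 200 default-config samples), so the learning task the
    phantoms pose is solvable."""
    from hsnet3d.evalstats import roc_auc

    X, table, Y = phantom_batch
    stats = pd.DataFrame([image_statistics(X[i], config)
                          for i in range(X.shape[0])])
    matched = {
        "sphericity": ("anisotropy", -1.0),
        "margin": ("edge_sharpness", +1.0),
        "subtlety": ("shell_contrast", +1.0),
        "texture": ("core_density", +1.0),
        "calcification": ("max_intensity", -1.0),
        "malignancy": ("nodule_volume", +1.0),
    }
    aucs = {}
    for feat, (stat, sign) in matched.items():
        y = table[feat + "_bin"].to_numpy()
        aucs[feat] = roc_auc(sign * stats[stat].to_numpy(), y)
    assert all(v > 0.8 for v in aucs.values()), aucs


def test_generated_labels_match_binarized_ordinals(phantom_batch):
    X, table, Y = phantom_batch
    for feat in ALL_FEATURES:
        expected = ((table[feat] == 6) if feat == "calcification"
                    else (table[feat] >= 4)).astype(int)
        assert (table[feat + "_bin"] == expected).all()
    assert np.array_equal(Y, table[[f + "_bin" for f in ALL_FEATURES]].to_numpy())


# ---------------------------------------------------------------------------
# dataset generation on disk
# ---------------------------------------------------------------------------

def test_generate_arrays_count_and_precondition(config):
    X, table, Y = generate_arrays(5, config, seed=0)
    assert X.shape == (5, config.grid_size, config.grid_size, config.grid_size)
    assert len(table) == 5 and Y.shape == (5, 6)
    with pytest.raises(ValueError):
        generate_arrays(0, config, seed=0)


def test_dataset_roundtrip_and_reproducibility(tmp_path, config):
    cfg = PhantomConfig(grid_size=16)
    m1 = generate_dataset(4, cfg, tmp_path / "a", seed=9)
    m2 = generate_dataset(4, cfg, tmp_path / "b", seed=9)
    csv_a = (tmp_path / "a" / "labels.csv").read_bytes()
    csv_b = (tmp_path / "b" / "labels.csv").read_bytes()
    assert csv_a == csv_b
    assert m1["config_hash"] == m2["config_hash"]
    Xa, ta, Ya = load_dataset(tmp_path / "a" / "manifest.json")
    Xb, tb, Yb = load_dataset(tmp_path / "b" / "manifest.json")
    assert np.array_equal(Xa, Xb)
    assert np.array_equal(Ya, Yb)
    assert list(ta["id"]) == [f"phantom-{i:05d}" for i in range(4)]
    with open(tmp_path / "a" / "manifest.json") as fh:
        manifest = json.load(fh)
    assert manifest["n"] == 4 and manifest["seed"] == 9
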