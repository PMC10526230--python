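"""Scikit-learn style estimator for the hierarchical nodule classifier.

:class:`HSNetClassifier` wraps network construction and the full training
recipe (6-head multi-task loss, SGD/Adam/RMSProp, cyclical learning rate,
stochastic weight averaging, early stopping) behind fit/predict_proba, so
it composes with sklearn model selection utilities.  ``X`` is an array of
cubic intensity patches (n, D, D, D); ``y`` is the (n, 6) binary label
matrix in canonical head order (calcification, margin, sphericity,
subtlety, texture, malignancy).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .models import ArchConfig, build_model
from .train import TrainConfig, train
from .semantics import ALL_FEATURES


class HSNetClassifier(BaseEstimator, ClassifierMixin):
    """Hierarchical multi-task 3D CNN for nodule semantic attributes.

    Parameters mirror :class:`~hsnet3d.models.ArchConfig` and
    :class:`~hsnet3d.train.TrainConfig`.  ``arch='hscnn'`` selects the
    shared-extractor baseline (2 conv blocks unless overridden);
    ``arch='hsnet'`` the five-extractor deeper variant (3 blocks).

    Attributes (after fit)
    ----------------------
    net_ : the trained network
    arch_config_, train_config_ : resolved configuration objects
    history_ : per-epoch losses/accuracies and per-iteration learning rates
    n_parameters_ : trainable parameter count
    feature_names_ : tuple of the six head names, in output column order
    """

    def __init__(self, arch="hsnet", patch_size=32, conv_blocks_per_branch=None,
                 filters_per_block=(8, 16, 32), branch_feature_dim=32,
                 dropout_rate=0.0, malignancy_head_dims=(64,), pool="max",
                 optimizer="sgd", momentum=0.9, base_lr=2e-3, max_lr=8e-3,
                 clr_step_epochs=2.0, use_clr=True, use_swa=True,
                 swa_start_epoch=None, epochs=20, batch_size=16,
                 loss_weights=(1.0,) * 6, early_stop=True,
                 validation_fraction=0.15, random_state=0):
        self.arch = arch
        self.patch_size = patch_size
        self.conv_blocks_per_branch = conv_blocks_per_branch
        self.filters_per_block = filters_per_block
        self.branch_feature_dim = branch_feature_dim
        self.dropout_rate = dropout_rate
        self.malignancy_head_dims = malignancy_head_dims
        self.pool = pool
        self.optimizer = optimizer
        self.momentum = momentum
        self.base_lr = base_lr
        self.max_lr = max_lr
        self.clr_step_epochs = clr_step_epochs
        self.use_clr = use_clr
        self.use_swa = use_swa
        self.swa_start_epoch = swa_start_epoch
        self.epochs = epochs
        self.batch_size = batch_size
        self.loss_weights = loss_weights
        self.early_stop = early_stop
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _resolve_configs(self):
        if self.arch not in ("hsnet", "hscnn"):
            raise ValueError("arch must be 'hsnet' or 'hscnn'")
        blocks = self.conv_blocks_per_branch
        if blocks is None:
            blocks = 3 if self.arch == "hsnet" else 2
        arch_cfg = ArchConfig(
            patch_size=self.patch_size,
            conv_blocks_per_branch=blocks,
            filters_per_block=tuple(self.filters_per_block),
            branch_feature_dim=self.branch_feature_dim,
            dropout_rate=self.dropout_rate,
            shared_extractor=(self.arch == "hscnn"),
            malignancy_head_dims=tuple(self.malignancy_head_dims),
            pool=self.pool,
        )
        train_cfg = TrainConfig(
            optimizer=self.optimizer, momentum=self.momentum,
            base_lr=self.base_lr, max_lr=self.max_lr,
            clr_step_epochs=self.clr_step_epochs, use_clr=self.use_clr,
            use_swa=self.use_swa, swa_start_epoch=self.swa_start_epoch,
            epochs=self.epochs, batch_size=self.batch_size,
            loss_weights=tuple(self.loss_weights), early_stop=self.early_stop,
            seed=self.random_state,
        )
        return arch_cfg, train_cfg

    @staticmethod
    def _check_xy(X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 4 or len({X.shape[1], X.shape[2], X.shape[3]}) != 1:
            raise ValueError("X must be (n, D, D, D) cubic volumes")
        if y.ndim != 2 or y.shape[1] != 6:
            raise ValueError("y must be an (n, 6) binary label matrix")
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y disagree on sample count")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("y must be binary 0/1")
        return X, y.astype(np.float32)

    def fit(self, X, y, X_val=None, y_val=None):
        """Train the network.  A validation set is held out from (X, y)
        unless one is supplied explicitly; it is used for early-stopping
        checkpoint selection only, never for gradient updates."""
        X, y = self._check_xy(X, y)
        arch_cfg, train_cfg = self._resolve_configs()
        if X_val is None:
            strat = y[:, -1] if 0 < y[:, -1].mean() < 1 else None
            X, X_val, y, y_val = train_test_split(
                X, y, test_size=self.validation_fraction,
                random_state=self.random_state, stratify=strat)
        else:
            X_val, y_val = self._check_xy(X_val, y_val)

        net = build_model(arch_cfg, seed=self.random_state)
        net.set_input_normalization(float(X.mean()), float(X.std()))
        net, history = train(net, (X, y), (X_val, y_val), train_cfg)
        self.net_ = net
        self.history_ = history
        self.arch_config_ = arch_cfg
        self.train_config_ = train_cfg
        self.n_parameters_ = net.count_parameters()
        self.feature_names_ = ALL_FEATURES
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        """Per-head positive-class probabilities, shape (n, 6)."""
        check_is_fitted(self, "net_")
        return self.net_.predict_proba(np.asarray(X, dtype=np.float32))

    def predict(self, X):
        """Binary head decisions at threshold 0.5 (ties positive), (n, 6)."""
        return (self.predict_proba(X) >= 0.5).astype(int)

    def score(self, X, y):
        """Accuracy of the malignancy (main) head."""
        y = np.asarray(y)
        return float((self.predict(X)[:, -1] == y[:, -1]).mean())
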