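"""Comparison models behind one fit/predict contract.

Every wrapper — including the volumetric CNN — exposes the same interface so
the cross-validation harness is model-agnostic:

* ``fit(vols_train, y_train, vols_val, y_val, seed)``
* classification: ``predict_labels(vols)`` and ``predict_scores(vols)``
  (score of the positive class);
* regression: ``predict(vols)`` returning scalars.

The MLP and SVM consume flattened volumes downsampled to 16^3 by block
averaging; the 2D CNN consumes the central axial slice; the traditional
regressors consume ROI-mean feature vectors over supplied region masks.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeRegressor

from .nn import TrainConfig, build_cnn2d, build_cnn3d, predict, train_model
from .volume import Volume

__all__ = [
    "build_baselines", "volumes_to_array", "downsample_flatten", "central_slice",
    "Cnn3dModel", "Cnn2dModel", "MlpModel", "SvmModel",
    "PolynomialRegressionModel", "TreeRegressionModel", "ForestRegressionModel",
    "RoiFeatureRegressor",
]


def volumes_to_array(vols) -> np.ndarray:
    """Stack volumes into a (B, 1, D, H, W) float32 array."""
    arrs = [v.data if isinstance(v, Volume) else np.asarray(v) for v in vols]
    return np.stack(arrs).astype(np.float32)[:, None]


def downsample_flatten(vols, target: int = 16) -> np.ndarray:
    """Block-average each axis down to ``target`` and flatten (B, target^3)."""
    X = volumes_to_array(vols)[:, 0]
    out = []
    for arr in X:
        for ax, s in enumerate(arr.shape):
            f = s // target
            if f > 1:
                shape = list(arr.shape)
                shape[ax:ax + 1] = [target, f]
                arr = arr.reshape(shape).mean(axis=ax + 1)
        out.append(arr.reshape(-1))
    return np.stack(out)


def central_slice(vols) -> np.ndarray:
    """Central axial slice of each volume, shape (B, 1, D, H)."""
    X = volumes_to_array(vols)[:, 0]
    k = X.shape[-1] // 2
    return X[..., k][:, None]


class _VoxelStandardizer:
    """Per-voxel z-scoring with training-set statistics.

    Removes the anatomical baseline pattern shared by all subjects so the
    network sees deviations, not absolute uptake; voxels with (near-)zero
    training variance — e.g. everything outside the brain mask — are left
    at zero.
    """

    def fit(self, X: np.ndarray) -> "_VoxelStandardizer":
        self.mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd < 1e-6] = 1.0
        self.sd = sd
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return ((X - self.mu) / self.sd).astype(np.float32)


class Cnn3dModel:
    """The volumetric CNN behind the common harness contract.

    Inputs are standardized per voxel with training-set statistics;
    regression targets are likewise standardized during optimization and
    predictions mapped back, so the near-zero output head starts at the
    training-mean prediction.
    """

    def __init__(self, task: str = "classify", train_cfg: TrainConfig | None = None) -> None:
        self.task = task
        self.train_cfg = train_cfg or TrainConfig()
        self.model = None
        self.history = None

    def fit(self, vols_train, y_train, vols_val, y_val, seed: int = 0):
        X_tr = volumes_to_array(vols_train)
        X_va = volumes_to_array(vols_val)
        self.scaler = _VoxelStandardizer().fit(X_tr)
        y_train = np.asarray(y_train)
        y_val = np.asarray(y_val)
        if self.task == "regress":
            self._y_mu = float(np.mean(y_train))
            self._y_sd = float(np.std(y_train)) or 1.0
            y_train = (y_train - self._y_mu) / self._y_sd
            y_val = (y_val - self._y_mu) / self._y_sd
        cfg = self.train_cfg.model_copy(update={"seed": seed})
        self.model = build_cnn3d(X_tr.shape[2:], task=self.task, seed=seed)
        self.model, self.history = train_model(
            self.model, self.scaler.transform(X_tr), y_train,
            self.scaler.transform(X_va), y_val, cfg)
        return self

    def _predict_raw(self, vols) -> np.ndarray:
        X = self.scaler.transform(volumes_to_array(vols))
        return predict(self.model, X, batch_size=self.train_cfg.batch_test)

    def predict_scores(self, vols) -> np.ndarray:
        return self._predict_raw(vols)[:, 1]

    def predict_labels(self, vols) -> np.ndarray:
        return self._predict_raw(vols).argmax(axis=1)

    def predict(self, vols) -> np.ndarray:
        out = self._predict_raw(vols)
        if self.task == "regress":
            return out * self._y_sd + self._y_mu
        return out


class Cnn2dModel:
    """2D CNN baseline on the central axial slice (same standardization)."""

    def __init__(self, train_cfg: TrainConfig | None = None) -> None:
        self.train_cfg = train_cfg or TrainConfig()
        self.model = None
        self.history = None

    def fit(self, vols_train, y_train, vols_val, y_val, seed: int = 0):
        X_tr = central_slice(vols_train)
        X_va = central_slice(vols_val)
        self.scaler = _VoxelStandardizer().fit(X_tr)
        cfg = self.train_cfg.model_copy(update={"seed": seed})
        self.model = build_cnn2d(X_tr.shape[2:], task="classify", seed=seed)
        self.model, self.history = train_model(
            self.model, self.scaler.transform(X_tr), y_train,
            self.scaler.transform(X_va), y_val, cfg)
        return self

    def predict_scores(self, vols) -> np.ndarray:
        X = self.scaler.transform(central_slice(vols))
        return predict(self.model, X, batch_size=1)[:, 1]

    def predict_labels(self, vols) -> np.ndarray:
        X = self.scaler.transform(central_slice(vols))
        return predict(self.model, X, batch_size=1).argmax(axis=1)


class MlpModel:
    """Single-hidden-layer (128) perceptron on downsampled flattened volumes."""

    def __init__(self, target: int = 16, max_iter: int = 500) -> None:
        self.target, self.max_iter = target, max_iter

    def fit(self, vols_train, y_train, vols_val, y_val, seed: int = 0):
        X = downsample_flatten(vols_train, self.target)
        self.clf = make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(128,), max_iter=self.max_iter, random_state=seed),
        ).fit(X, np.asarray(y_train))
        return self

    def predict_scores(self, vols) -> np.ndarray:
        return self.clf.predict_proba(downsample_flatten(vols, self.target))[:, 1]

    def predict_labels(self, vols) -> np.ndarray:
        return self.clf.predict(downsample_flatten(vols, self.target))


class SvmModel:
    """RBF-kernel SVM (C = 1) on downsampled flattened volumes."""

    def __init__(self, target: int = 16, C: float = 1.0) -> None:
        self.target, self.C = target, C

    def fit(self, vols_train, y_train, vols_val, y_val, seed: int = 0):
        X = downsample_flatten(vols_train, self.target)
        self.clf = make_pipeline(StandardScaler(), SVC(kernel="rbf", C=self.C, random_state=seed)).fit(
            X, np.asarray(y_train))
        return self

    def predict_scores(self, vols) -> np.ndarray:
        return self.clf.decision_function(downsample_flatten(vols, self.target))

    def predict_labels(self, vols) -> np.ndarray:
        return self.clf.predict(downsample_flatten(vols, self.target))


class RoiFeatureRegressor:
    """Base for the traditional regressors: features are ROI means over the
    supplied boolean region masks."""

    def __init__(self, region_masks) -> None:
        if not region_masks:
            raise ValueError("need at least one region mask")
        self.region_masks = [np.asarray(m, dtype=bool) for m in region_masks]

    def _features(self, vols) -> np.ndarray:
        rows = []
        for v in vols:
            data = v.data if isinstance(v, Volume) else np.asarray(v)
            rows.append([float(data[m].mean()) for m in self.region_masks])
        return np.asarray(rows)

    def fit(self, vols_train, y_train, vols_val=None, y_val=None, seed: int = 0):
        self.reg = self._make(seed)
        self.reg.fit(self._features(vols_train), np.asarray(y_train, dtype=float))
        return self

    def predict(self, vols) -> np.ndarray:
        return np.asarray(self.reg.predict(self._features(vols)), dtype=float)


class PolynomialRegressionModel(RoiFeatureRegressor):
    def __init__(self, region_masks, degree: int = 2) -> None:
        super().__init__(region_masks)
        self.degree = degree

    def _make(self, seed):
        return make_pipeline(PolynomialFeatures(self.degree), LinearRegression())


class TreeRegressionModel(RoiFeatureRegressor):
    def _make(self, seed):
        return DecisionTreeRegressor(random_state=seed)


class ForestRegressionModel(RoiFeatureRegressor):
    def _make(self, seed):
        return RandomForestRegressor(n_estimators=100, random_state=seed)


def build_baselines(kind: str, **config):
    """Factory: 'cnn3d', 'mlp', 'svm', 'cnn2d', 'poly_reg', 'tree_reg', 'forest_reg'."""
    kinds = {
        "cnn3d": Cnn3dModel,
        "mlp": MlpModel,
        "svm": SvmModel,
        "cnn2d": Cnn2dModel,
        "poly_reg": PolynomialRegressionModel,
        "tree_reg": TreeRegressionModel,
        "forest_reg": ForestRegressionModel,
    }
    if kind not in kinds:
        raise ValueError(f"unknown model kind {kind!r}; choose from {sorted(kinds)}")
    return kinds[kind](**config)
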