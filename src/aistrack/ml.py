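"""Feature selection and supervised models for relocation inference.

Neighborhood components analysis (NCA) here is the diagonal,
feature-selection variant: per-feature nonnegative weights enter a weighted
L1 distance, and stochastic gradient ascent maximizes the expected
leave-one-out soft-nearest-neighbor accuracy minus a ridge penalty
(lambda = 3e-5 by default).  Weights below 10% of the maximum are discarded.
The selected features feed a random-forest relocation detector; a wide
single-hidden-layer network (100 ReLU units) regresses the relocation
magnitude from amplitude-change features.  Both use a 60/20/20
train/validation/hold-out split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, r2_score
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler


@dataclass
class NCAConfig:
    lam: float = 3e-5  # ridge regularization weight
    threshold_frac: float = 0.10  # of the max weight
    learning_rate: float = 0.3
    epochs: int = 40
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if not (0 < self.threshold_frac < 1):
            raise ValueError("threshold_frac must lie in (0, 1)")


@dataclass
class NCAWeights:
    w: np.ndarray  # nonnegative per-feature weights
    selected: np.ndarray  # boolean mask: w >= threshold_frac * max(w)
    objective_trace: np.ndarray  # per-epoch objective (smoothed trend check)


def _nca_objective_and_grad(Xb, yb, Xr, yr, w, lam):
    """Soft LOO accuracy of batch points against reference points, and its
    gradient w.r.t. the weights.  Distances: d_ij = sum_l w_l |x_il - x_jl|.

    The batch is compared against itself, so the diagonal (self-pairs) is
    excluded by index — zero distances from collapsed weights must not be
    mistaken for self-pairs."""
    # (b, r, p) absolute differences
    D = np.abs(Xb[:, None, :] - Xr[None, :, :])
    dist = D @ w  # (b, r)
    same = yb[:, None] == yr[None, :]
    logits = -dist
    n = min(logits.shape)
    logits[np.arange(n), np.arange(n)] = -np.inf
    logits -= np.max(np.where(np.isfinite(logits), logits, -1e30), axis=1, keepdims=True)
    p = np.exp(logits)
    denom = p.sum(axis=1, keepdims=True)
    denom[denom == 0] = 1.0
    p /= denom  # p_ij
    p_i = (p * same).sum(axis=1)  # per-point expected accuracy

    # grad_l = mean_i [ p_i * sum_k p_ik D_ikl - sum_{j in class} p_ij D_ijl ] - 2 lam w_l
    expected_D = np.einsum("br,brl->bl", p, D)
    class_D = np.einsum("br,brl->bl", p * same, D)
    grad = (p_i[:, None] * expected_D - class_D).mean(axis=0) - 2 * lam * w
    obj = p_i.mean() - lam * np.sum(w**2)
    return obj, grad


def nca_feature_weights(X: np.ndarray, y: np.ndarray, cfg: NCAConfig | None = None) -> NCAWeights:
    """Diagonal-NCA feature weights for a binary (or multiclass) labeling.

    ``X`` should be standardized.  Deterministic given ``cfg.seed``.  Weights
    are clipped nonnegative after every step; the returned mask keeps features
    with weight >= ``threshold_frac`` of the maximum.
    """
    if cfg is None:
        cfg = NCAConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes for NCA")
    n, p = X.shape
    rng = np.random.default_rng(cfg.seed)
    w = np.full(p, 1.0 / np.sqrt(p))  # unit-norm start keeps initial distances O(1)
    trace = []
    lr = cfg.learning_rate
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        epoch_obj = []
        for s in range(0, n, cfg.batch_size):
            idx = perm[s : s + cfg.batch_size]
            obj, grad = _nca_objective_and_grad(X[idx], y[idx], X[idx], y[idx], w, cfg.lam)
            w = np.clip(w + lr * grad, 0.0, None)
            epoch_obj.append(obj)
        trace.append(float(np.mean(epoch_obj)))
        lr = cfg.learning_rate / (1.0 + 0.05 * epoch)
    if w.max() <= 0:
        selected = np.zeros(p, dtype=bool)
    else:
        selected = w >= cfg.threshold_frac * w.max()
    return NCAWeights(w, selected, np.asarray(trace))


# ---------------------------------------------------------------------------
# splits

def split_indices(n: int, seed: int, fractions=(0.6, 0.2, 0.2)):
    """Seeded 60/20/20 train/validation/hold-out split of ``range(n)``."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


# ---------------------------------------------------------------------------
# detector

@dataclass
class TrainedDetector:
    model: RandomForestClassifier
    scaler: StandardScaler
    feature_mask: np.ndarray
    split_seed: int
    metrics: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = self.scaler.transform(X)[:, self.feature_mask]
        return self.model.predict(Xs).astype(bool)


def train_detector(
    X: np.ndarray,
    y: np.ndarray,
    split_seed: int = 0,
    feature_mask: np.ndarray | None = None,
    nca_cfg: NCAConfig | None = None,
    n_trees: int = 100,
) -> TrainedDetector:
    """Random-forest relocation detector on NCA-selected features.

    Features are z-scored with training statistics; NCA runs on the training
    split only (unless a precomputed ``feature_mask`` is given).  Metrics
    (confusion matrix, accuracy, TPR, FPR) are reported on the hold-out split,
    which is disjoint from training and validation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(bool)
    tr, va, ho = split_indices(len(X), split_seed)
    scaler = StandardScaler().fit(X[tr])
    Xs = scaler.transform(X)

    if feature_mask is None:
        nca = nca_feature_weights(Xs[tr], y[tr], nca_cfg or NCAConfig(seed=split_seed))
        feature_mask = nca.selected
    feature_mask = np.asarray(feature_mask, dtype=bool)
    if not feature_mask.any():
        raise ValueError("empty selected-feature mask")

    rf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=split_seed, n_jobs=1
    )
    rf.fit(Xs[tr][:, feature_mask], y[tr])

    def _metrics(idx):
        pred = rf.predict(Xs[idx][:, feature_mask])
        cm = confusion_matrix(y[idx], pred, labels=[False, True])
        tn, fp, fn, tp = cm.ravel()
        return {
            "confusion": cm.tolist(),
            "accuracy": float((tp + tn) / max(cm.sum(), 1)),
            "tpr": float(tp / max(tp + fn, 1)),
            "fpr": float(fp / max(fp + tn, 1)),
        }

    metrics = {"validation": _metrics(va), "holdout": _metrics(ho),
               "n_features_selected": int(feature_mask.sum())}
    return TrainedDetector(rf, scaler, feature_mask, split_seed, metrics)


# ---------------------------------------------------------------------------
# magnitude regressor

@dataclass
class TrainedRegressor:
    model: MLPRegressor
    x_scaler: StandardScaler
    y_mean: float
    y_scale: float
    split_seed: int
    metrics: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = self.x_scaler.transform(X)
        return self.model.predict(Xs) * self.y_scale + self.y_mean


def train_magnitude_regressor(
    X: np.ndarray,
    magnitudes: np.ndarray,
    split_seed: int = 0,
    max_iter: int = 500,
) -> TrainedRegressor:
    """Wide single-hidden-layer (100 ReLU units) relocation-magnitude
    regressor with a linear output.

    Expects valid-relocation rows only (amplitude-change features).  Uses the
    60/20/20 split; training stops early on the validation fold.  Hold-out
    RMSE and R^2 are reported; a constant target is refused as degenerate.
    """
    X = np.asarray(X, dtype=float)
    yv = np.asarray(magnitudes, dtype=float)
    if np.isnan(yv).any():
        raise ValueError("magnitudes contain NaN (sham rows?); pass valid rows only")
    tr, va, ho = split_indices(len(X), split_seed)
    if len(tr) < 50:
        raise ValueError(f"only {len(tr)} training rows; need >= 50")
    if np.ptp(yv[tr]) == 0:
        raise ValueError("constant relocation target: R^2 undefined")

    x_scaler = StandardScaler().fit(X[tr])
    y_mean, y_scale = float(yv[tr].mean()), float(yv[tr].std())
    Xs = x_scaler.transform(X)
    ys = (yv - y_mean) / y_scale

    # explicit validation fold drives early stopping
    best_val, best_state, stall = np.inf, None, 0
    mlp = MLPRegressor(
        hidden_layer_sizes=(100,),
        activation="relu",
        solver="adam",
        random_state=split_seed,
        max_iter=1,
        warm_start=True,
        learning_rate_init=1e-3,
    )
    import warnings

    for epoch in range(max_iter):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mlp.fit(Xs[tr], ys[tr])
        val_rmse = float(np.sqrt(np.mean((mlp.predict(Xs[va]) - ys[va]) ** 2)))
        if val_rmse < best_val - 1e-5:
            best_val, stall = val_rmse, 0
            best_state = [w.copy() for w in mlp.coefs_], [b.copy() for b in mlp.intercepts_]
        else:
            stall += 1
            if stall >= 25:
                break
    if best_state is not None:
        mlp.coefs_, mlp.intercepts_ = best_state

    pred_ho = mlp.predict(Xs[ho]) * y_scale + y_mean
    metrics = {
        "holdout_rmse": float(np.sqrt(np.mean((pred_ho - yv[ho]) ** 2))),
        "holdout_r2": float(r2_score(yv[ho], pred_ho)),
        "n_train": int(len(tr)),
        "epochs_run": epoch + 1,
    }
    return TrainedRegressor(mlp, x_scaler, y_mean, y_scale, split_seed, metrics)
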