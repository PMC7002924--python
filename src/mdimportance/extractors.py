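"""Six feature-importance estimators sharing a common output contract.

Supervised (need per-frame state labels):
    KL   symmetric Kullback-Leibler divergence, one state vs the rest,
         per feature (histogram-based; no model is fitted)
    RF   random-forest mean decrease impurity (Gini), multiclass or
         one-vs-rest
    MLP  multilayer-perceptron classifier + layer-wise relevance
         propagation from the predicted class score to the inputs

Unsupervised:
    PCA  importance R_i = sum_{j<j_max} |lambda_j T_ij| over leading
         components, with three j_max criteria
    AE   autoencoder (MLP regressor, input == output, symmetric hidden
         layers) + LRP from the reconstruction to the inputs
    RBM  Bernoulli restricted Boltzmann machine + LRP from the hidden
         activation probabilities to the inputs

All estimators emit an :class:`ImportanceProfile` with per-feature scores
normalized to an upper bound of 1; supervised ones may add per-state rows
and the LRP-based ones a per-frame matrix.  ``run_repeated`` adds
cross-validated refitting and iteration averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold
from sklearn.neural_network import BernoulliRBM, MLPClassifier, MLPRegressor

from .featurization import FeatureMatrix, LabelSet
from .lrp import Layer, NetworkSpec, average_relevance, lrp

__all__ = [
    "ImportanceProfile",
    "ExtractorSpec",
    "pca_importance",
    "kl_importance",
    "rf_importance",
    "mlp_lrp_importance",
    "ae_lrp_importance",
    "rbm_lrp_importance",
    "run_repeated",
    "EXTRACTORS",
    "SUPERVISED",
]


@dataclass
class ImportanceProfile:
    """Normalized importance with optional per-state/per-frame resolution."""

    per_feature: np.ndarray
    method: str
    hyperparameters: dict = field(default_factory=dict)
    per_state: np.ndarray | None = None  # (n_states, n_features)
    per_frame: np.ndarray | None = None  # (n_samples, n_features), LRP methods
    per_atom: np.ndarray | None = None
    std: np.ndarray | None = None
    n_iterations: int = 1
    model_score: float | None = None
    all_zero: bool = False
    model: object | None = field(default=None, repr=False)


def _normalize(v: np.ndarray) -> tuple[np.ndarray, bool]:
    """Divide by the max (max |.| when no positive mass); flag all-zero."""
    v = np.asarray(v, dtype=float)
    top = v.max() if v.size else 0.0
    if top <= 0:
        top = np.abs(v).max() if v.size else 0.0
    if top == 0:
        return v.copy(), True
    return v / top, False


def _require_scaled(fm: FeatureMatrix, method: str) -> None:
    lo, hi = fm.values.min(), fm.values.max()
    if lo < -1e-9 or hi > 1 + 1e-9:
        raise ValueError(
            f"{method} requires features scaled to [0, 1] "
            f"(observed range [{lo:.3g}, {hi:.3g}]); apply minmax_scale first"
        )


# ---------------------------------------------------------------------------
# PCA


def _j_max(lambdas: np.ndarray, criterion) -> int:
    """Number of leading components per criterion.

    criteria: ("fixed", k); ("cumulative_variance", theta) -> smallest
    leading set with cumulative variance >= theta; ("eigengap", ratio) ->
    stop after the first component whose eigenvalue exceeds the next by
    the given factor (all components if no such gap).
    """
    name, value = criterion
    if name == "fixed":
        return min(int(value), len(lambdas))
    if name == "cumulative_variance":
        csum = np.cumsum(lambdas)
        return int(np.searchsorted(csum, value - 1e-12) + 1)
    if name == "eigengap":
        for j in range(len(lambdas) - 1):
            if lambdas[j + 1] > 0 and lambdas[j] / lambdas[j + 1] >= value:
                return j + 1
        return len(lambdas)
    raise ValueError(f"unknown PCA criterion {name!r}")


def pca_importance(fm: FeatureMatrix, criterion=("cumulative_variance", 0.75)) -> ImportanceProfile:
    """Eigenvalue-weighted component loadings: R_i = sum_j |lambda_j T_ij|.

    Eigenvalues are normalized to sum to 1; the sum runs over the leading
    j_max components selected by ``criterion``.
    """
    if fm.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    pca = PCA()
    pca.fit(fm.values)
    lambdas = pca.explained_variance_ratio_
    total = lambdas.sum()
    if total > 0:
        lambdas = lambdas / total
    jmax = _j_max(lambdas, criterion)
    raw = np.abs(lambdas[:jmax, None] * pca.components_[:jmax]).sum(axis=0)
    per_feature, all_zero = _normalize(raw)
    return ImportanceProfile(
        per_feature,
        "PCA",
        {"criterion": criterion, "j_max": jmax},
        all_zero=all_zero,
        model=pca,
    )


# ---------------------------------------------------------------------------
# KL divergence


def kl_importance(
    fm: FeatureMatrix, labels: LabelSet, bin_width_fraction: float = 0.01
) -> ImportanceProfile:
    """Symmetric KL divergence between one state and the rest, per feature.

    For each feature, in-state and rest-of-data histograms P and Q share
    bins of width ``bin_width_fraction`` times the observed range; empty
    bins get a 1e-9 pseudocount before normalization and the divergence
    (1/2)KL(P||Q) + (1/2)KL(Q||P) uses natural logarithms.  Per-state rows
    are normalized to max 1, then averaged and renormalized into the
    ensemble profile.
    """
    if labels.n_states < 2:
        raise ValueError("KL importance needs at least 2 states")
    counts = np.bincount(labels.state_index, minlength=labels.n_states)
    if np.any(counts == 0):
        raise ValueError(f"empty state: {np.flatnonzero(counts == 0).tolist()}")
    n_bins = max(int(round(1.0 / bin_width_fraction)), 2)
    X = fm.values
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span[span == 0] = 1.0
    # shared per-feature binning for all states
    idx = np.clip(((X - lo) / span * n_bins).astype(int), 0, n_bins - 1)
    offset = np.arange(fm.n_features) * n_bins
    flat = idx + offset  # (n, f) unique bin ids per feature
    per_state = np.empty((labels.n_states, fm.n_features))
    total = np.bincount(flat.ravel(), minlength=n_bins * fm.n_features)
    for s in range(labels.n_states):
        mask = labels.state_index == s
        h_in = np.bincount(flat[mask].ravel(), minlength=n_bins * fm.n_features)
        h_out = total - h_in
        p = h_in.reshape(fm.n_features, n_bins).astype(float) + 1e-9
        q = h_out.reshape(fm.n_features, n_bins).astype(float) + 1e-9
        p /= p.sum(axis=1, keepdims=True)
        q /= q.sum(axis=1, keepdims=True)
        per_state[s] = 0.5 * (p * np.log(p / q) + q * np.log(q / p)).sum(axis=1)
    per_state_norm = np.stack([_normalize(row)[0] for row in per_state])
    per_feature, all_zero = _normalize(per_state_norm.mean(axis=0))
    return ImportanceProfile(
        per_feature,
        "KL",
        {"bin_width_fraction": bin_width_fraction, "n_bins": n_bins},
        per_state=per_state_norm,
        all_zero=all_zero,
    )


# ---------------------------------------------------------------------------
# Random forest


def rf_importance(
    fm: FeatureMatrix,
    labels: LabelSet,
    mode: str = "multiclass",
    n_estimators: int = 100,
    max_depth: int | None = None,
    min_samples_leaf: int = 1,
    max_features: int | float | str = "sqrt",
    seed: int = 0,
) -> ImportanceProfile:
    """Gini mean-decrease-impurity importance from a random forest.

    ``one_vs_rest`` fits one binary forest per state (state-specific
    rows); ``multiclass`` fits a single forest (ensemble profile only).
    """
    if labels.n_states < 2:
        raise ValueError("RF importance needs at least 2 states")
    if mode not in ("multiclass", "one_vs_rest"):
        raise ValueError(f"unknown mode {mode!r}")
    params = dict(
        n_estimators=n_estimators,
        criterion="gini",
        max_depth=max_depth,
        min_samples_leaf=min_samples_leaf,
        max_features=max_features,
        n_jobs=1,
    )
    hyper = {"mode": mode, **params}
    if mode == "multiclass":
        forest = RandomForestClassifier(random_state=seed, **params)
        forest.fit(fm.values, labels.state_index)
        per_feature, all_zero = _normalize(forest.feature_importances_)
        return ImportanceProfile(per_feature, "RF", hyper, all_zero=all_zero, model=forest)
    per_state = np.empty((labels.n_states, fm.n_features))
    last = None
    for s in range(labels.n_states):
        forest = RandomForestClassifier(random_state=seed + s, **params)
        forest.fit(fm.values, (labels.state_index == s).astype(int))
        per_state[s] = _normalize(forest.feature_importances_)[0]
        last = forest
    per_feature, all_zero = _normalize(per_state.mean(axis=0))
    return ImportanceProfile(
        per_feature, "RF", hyper, per_state=per_state, all_zero=all_zero, model=last
    )


# ---------------------------------------------------------------------------
# MLP + LRP


def mlp_lrp_importance(
    fm: FeatureMatrix,
    labels: LabelSet,
    hidden_layers: tuple[int, ...] = (30,),
    activation: str = "relu",
    solver: str = "adam",
    alpha: float = 1e-4,
    max_iter: int = 200,
    tol: float = 1e-6,
    n_fits: int = 1,
    seed: int = 0,
) -> ImportanceProfile:
    """MLP classifier + LRP with true-class output masks.

    Relevance is propagated per training frame from the predicted class
    probability of the frame's true class back to the inputs (z+ in the
    hidden stack, zB at the [0,1]-bounded input).  Per-state importance is
    the normalized mean relevance over that state's frames; the ensemble
    profile is the normalized mean over all frames.

    The default ``tol`` is deliberately small: on easily separable data
    the loss plateaus within a few epochs while the weights are still
    close to their random initialization, and relevance read off such a
    network is nearly flat.  Training further concentrates weight on the
    discriminative inputs and sharpens the profile.  ``n_fits`` averages
    the per-frame relevance of several independently initialized
    classifiers: the initialization-dependent part of the relevance
    background averages out while the signal persists.
    """
    _require_scaled(fm, "MLP")
    if n_fits < 1:
        raise ValueError("n_fits must be >= 1")
    per_frame_sum = None
    clf = None
    for k in range(n_fits):
        clf = MLPClassifier(
            hidden_layer_sizes=hidden_layers,
            activation=activation,
            solver=solver,
            alpha=alpha,
            max_iter=max_iter,
            tol=tol,
            random_state=seed + k,
        )
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", category=ConvergenceWarning)
            clf.fit(fm.values, labels.state_index)
        if clf.n_iter_ >= max_iter:
            warnings.warn(
                f"MLP did not converge in {max_iter} iterations (loss {clf.loss_:.4g}); "
                "returning the profile anyway",
                stacklevel=2,
            )
        net = NetworkSpec.from_sklearn_mlp(clf, "softmax", input_bounds=(0.0, 1.0))
        if len(clf.classes_) == 2:
            # sklearn's binary classifier has a single logistic output (the
            # logit of class 1).  Expand it into an equivalent two-column
            # softmax head [-w, +w]: softmax of (-z, z) preserves the
            # prediction while letting class-0 relevance flow along the
            # inhibitory (negative-weight) paths that actually encode it.
            last = net.layers[-1]
            net.layers[-1] = Layer(
                np.hstack([-last.weights, last.weights]),
                np.concatenate([-last.bias, last.bias]),
                "softmax",
            )
        # column order of clf.classes_ may differ from state order
        class_pos = {c: i for i, c in enumerate(clf.classes_)}
        targets = np.zeros((fm.n_samples, net.n_outputs))
        targets[np.arange(fm.n_samples), [class_pos[s] for s in labels.state_index]] = 1.0
        rel = lrp(net, fm.values, targets)
        per_frame_sum = rel if per_frame_sum is None else per_frame_sum + rel
    per_frame = per_frame_sum / n_fits
    per_state = np.stack(
        [_normalize(per_frame[labels.state_index == s].mean(axis=0))[0] for s in range(labels.n_states)]
    )
    per_feature, all_zero = _normalize(per_frame.mean(axis=0))
    return ImportanceProfile(
        per_feature,
        "MLP",
        {
            "hidden_layers": hidden_layers,
            "activation": activation,
            "solver": solver,
            "alpha": alpha,
            "max_iter": max_iter,
            "tol": tol,
            "n_fits": n_fits,
        },
        per_state=per_state,
        per_frame=per_frame,
        all_zero=all_zero,
        model=clf,
    )


# ---------------------------------------------------------------------------
# Autoencoder + LRP


def ae_lrp_importance(
    fm: FeatureMatrix,
    hidden_layers: tuple[int, ...] = (50,),
    alpha: float = 1e-4,
    epochs: int = 200,
    learning_rate: float = 1e-3,
    batch_size: int | str = "auto",
    seed: int = 0,
) -> ImportanceProfile:
    """Autoencoder (input == output regression) + LRP with a ones mask.

    ``hidden_layers`` must be symmetric (encoder and decoder of the same
    shape).  Every reconstructed output contributes, so the output mask is
    all ones.
    """
    if tuple(hidden_layers) != tuple(reversed(hidden_layers)):
        raise ValueError("hidden_layers must be symmetric (same encoder/decoder shape)")
    reg = MLPRegressor(
        hidden_layer_sizes=hidden_layers,
        activation="relu",
        solver="adam",
        alpha=alpha,
        max_iter=epochs,
        learning_rate_init=learning_rate,
        batch_size=batch_size,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        reg.fit(fm.values, fm.values)
    if not np.isfinite(reg.loss_):
        raise ValueError(f"autoencoder reconstruction loss is not finite ({reg.loss_})")
    bounds = (0.0, 1.0) if fm.is_scaled() else None
    net = NetworkSpec.from_sklearn_mlp(reg, "identity", input_bounds=bounds)
    per_frame = lrp(net, fm.values)
    per_feature, all_zero = _normalize(per_frame.mean(axis=0))
    return ImportanceProfile(
        per_feature,
        "AE",
        {
            "hidden_layers": tuple(hidden_layers),
            "alpha": alpha,
            "epochs": epochs,
            "learning_rate": learning_rate,
            "batch_size": batch_size,
        },
        per_frame=per_frame,
        all_zero=all_zero,
        model=reg,
    )


# ---------------------------------------------------------------------------
# RBM + LRP


def rbm_lrp_importance(
    fm: FeatureMatrix,
    n_hidden: int = 10,
    learning_rate: float = 0.01,
    n_iter: int = 20,
    seed: int = 0,
) -> ImportanceProfile:
    """Bernoulli RBM (stochastic maximum likelihood) + LRP.

    Inputs must lie in [0, 1]: the RBM reads them as activation
    probabilities — physically sensible for scaled inverse distances
    (contact => high value), not for Cartesian coordinates.  Relevance is
    seeded with the hidden-unit activation probabilities and propagated
    with the zB rule.
    """
    _require_scaled(fm, "RBM")
    if learning_rate >= 1.0:
        warnings.warn(
            f"RBM learning rate {learning_rate} is very high and is known to "
            "degrade importance extraction; consider <= 0.1",
            stacklevel=2,
        )
    rbm = BernoulliRBM(
        n_components=n_hidden, learning_rate=learning_rate, n_iter=n_iter, random_state=seed
    )
    rbm.fit(fm.values)
    net = NetworkSpec.from_sklearn_rbm(rbm)
    hidden = net.forward(fm.values)[-1]
    per_frame = lrp(net, fm.values, targets=np.ones_like(hidden))
    per_feature, all_zero = _normalize(per_frame.mean(axis=0))
    return ImportanceProfile(
        per_feature,
        "RBM",
        {"n_hidden": n_hidden, "learning_rate": learning_rate, "n_iter": n_iter},
        per_frame=per_frame,
        all_zero=all_zero,
        model=rbm,
    )


# ---------------------------------------------------------------------------
# Repeated fitting with cross-validation

SUPERVISED = {"KL", "RF", "MLP"}

EXTRACTORS = {
    "PCA": pca_importance,
    "KL": kl_importance,
    "RF": rf_importance,
    "MLP": mlp_lrp_importance,
    "AE": ae_lrp_importance,
    "RBM": rbm_lrp_importance,
}


@dataclass(frozen=True)
class ExtractorSpec:
    """An estimator name plus keyword overrides, e.g. ExtractorSpec('RF',
    {'n_estimators': 500, 'mode': 'one_vs_rest'})."""

    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in EXTRACTORS:
            raise ValueError(
                f"unknown method {self.method!r}; choose from {sorted(EXTRACTORS)}"
            )

    def run(self, fm: FeatureMatrix, labels: LabelSet | None, seed: int | None = None) -> ImportanceProfile:
        fn = EXTRACTORS[self.method]
        params = dict(self.params)
        if seed is not None and self.method not in ("KL", "PCA"):
            params.setdefault("seed", seed)
        if self.method in SUPERVISED:
            if labels is None:
                raise ValueError(f"{self.method} is supervised and needs labels")
            return fn(fm, labels, **params)
        return fn(fm, **params)


def run_repeated(
    spec: ExtractorSpec,
    fm: FeatureMatrix,
    labels: LabelSet | None,
    n_iterations: int = 5,
    n_folds: int = 3,
    seed: int = 0,
) -> ImportanceProfile:
    """Refit on shuffled cross-validation folds and average the profiles.

    Each iteration reshuffles the samples into ``n_folds`` folds; the
    estimator is fitted on every training split, and for classifier-backed
    methods the held-out accuracy is recorded.  Returns the per-feature
    mean (renormalized to max 1) with its standard deviation and the mean
    cross-validated model score.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    profiles, scores, states = [], [], []
    for it in range(n_iterations):
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed + it)
        for fold, (train, test) in enumerate(kf.split(fm.values)):
            sub = fm.subset_samples(train)
            sub_labels = labels.subset(train) if labels is not None else None
            prof = spec.run(sub, sub_labels, seed=seed + 1000 * it + fold)
            profiles.append(prof.per_feature)
            if prof.per_state is not None:
                states.append(prof.per_state)
            model = prof.model
            if (
                labels is not None
                and spec.method in SUPERVISED
                and model is not None
                and hasattr(model, "score")
                # one-vs-rest fits binary models; their accuracy against the
                # multiclass labels is not meaningful, so skip it
                and set(getattr(model, "classes_", [])) == set(range(labels.n_states))
            ):
                scores.append(model.score(fm.values[test], labels.state_index[test]))
    stack = np.stack(profiles)
    mean, all_zero = _normalize(stack.mean(axis=0))
    per_state = None
    if states:
        per_state = np.stack(
            [_normalize(row)[0] for row in np.stack(states).mean(axis=0)]
        )
    return ImportanceProfile(
        mean,
        spec.method,
        dict(spec.params),
        per_state=per_state,
        std=stack.std(axis=0),
        n_iterations=n_iterations,
        model_score=float(np.mean(scores)) if scores else None,
        all_zero=all_zero,
    )
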