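"""Coordinate ensembles -> scaled feature matrices, and back to atoms.

Feature kinds
-------------
cartesian
    3N raw coordinates per frame, column order atom0.x, atom0.y, atom0.z, ...
    Deliberately unaligned: no superposition is performed.
distance_full / inverse_distance_full
    All N(N-1)/2 interatomic distances (or their reciprocals).
distance_reduced / inverse_distance_reduced
    Distances from atom i to atoms i+1..i+4 only — the smallest internal
    coordinate set that still triangulates every atom's position.

Filters (contact-change and range) are defined on *raw* distances, in the
units of the input coordinates; invert after filtering.  Min-max scaling
to [0, 1] is required by all the downstream estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FeatureMatrix",
    "LabelSet",
    "cartesian_features",
    "distance_features",
    "invert_distances",
    "inverse_distance_features",
    "filter_contact_changing",
    "filter_range",
    "minmax_scale",
    "unscale",
    "drop_constant_features",
    "block_shuffle",
    "aggregate_importance_per_atom",
]

_DISTANCE_KINDS = {"distance_full", "distance_reduced"}
_INVERSE_KINDS = {"inverse_distance_full", "inverse_distance_reduced"}


@dataclass
class FeatureMatrix:
    """Samples x features with per-feature descriptors and scaling record.

    descriptors are ``(atom, axis)`` tuples with axis in {'x','y','z'} for
    cartesian features, or ``(i, j)`` atom pairs with i < j for distance
    features.  ``scaling`` holds the per-feature (min, max) used by
    :func:`minmax_scale`; ``constant_mask`` flags zero-variance features.
    """

    values: np.ndarray  # (n_samples, n_features)
    descriptors: list[tuple]
    kind: str
    scaling: tuple[np.ndarray, np.ndarray] | None = None
    constant_mask: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def is_scaled(self) -> bool:
        return self.scaling is not None

    def subset_samples(self, idx: np.ndarray) -> "FeatureMatrix":
        return replace(self, values=self.values[idx])

    def subset_features(self, idx: np.ndarray) -> "FeatureMatrix":
        idx = np.asarray(idx)
        scaling = None
        if self.scaling is not None:
            scaling = (self.scaling[0][idx], self.scaling[1][idx])
        cmask = self.constant_mask[idx] if self.constant_mask is not None else None
        return FeatureMatrix(
            self.values[:, idx],
            [self.descriptors[i] for i in idx],
            self.kind,
            scaling,
            cmask,
        )


@dataclass
class LabelSet:
    """Per-frame state indices with their one-hot expansion."""

    state_index: np.ndarray
    n_states: int | None = None

    def __post_init__(self) -> None:
        self.state_index = np.asarray(self.state_index, dtype=int)
        if self.n_states is None:
            self.n_states = int(self.state_index.max()) + 1
        if self.state_index.min() < 0 or self.state_index.max() >= self.n_states:
            raise ValueError("state indices outside [0, n_states)")

    @property
    def one_hot(self) -> np.ndarray:
        return np.eye(self.n_states, dtype=int)[self.state_index]

    def subset(self, idx: np.ndarray) -> "LabelSet":
        return LabelSet(self.state_index[idx], self.n_states)


def _check_coords(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
    if coords.shape[0] == 0:
        raise ValueError("empty trajectory")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coords contain non-finite values")
    return coords


def cartesian_features(coords: np.ndarray) -> FeatureMatrix:
    """Flatten (n_frames, n_atoms, 3) into 3N columns, unscaled."""
    coords = _check_coords(coords)
    n_frames, n_atoms, _ = coords.shape
    descriptors = [(a, ax) for a in range(n_atoms) for ax in "xyz"]
    return FeatureMatrix(coords.reshape(n_frames, 3 * n_atoms).copy(), descriptors, "cartesian")


def _pair_indices(n_atoms: int, mode: str) -> tuple[np.ndarray, np.ndarray]:
    if mode == "full":
        return np.triu_indices(n_atoms, k=1)
    if mode == "reduced":
        ii, jj = [], []
        for i in range(n_atoms):
            for k in range(1, 5):
                if i + k < n_atoms:
                    ii.append(i)
                    jj.append(i + k)
        return np.asarray(ii), np.asarray(jj)
    raise ValueError(f"unknown mode {mode!r}")


def distance_features(coords: np.ndarray, mode: str = "full", chunk: int = 256) -> FeatureMatrix:
    """Raw interatomic distances (full pair set or the i..i+4 reduced set)."""
    coords = _check_coords(coords)
    n_frames = coords.shape[0]
    ii, jj = _pair_indices(coords.shape[1], mode)
    values = np.empty((n_frames, len(ii)))
    for start in range(0, n_frames, chunk):  # chunked: full pair sets are wide
        block = coords[start : start + chunk]
        diff = block[:, ii, :] - block[:, jj, :]
        values[start : start + chunk] = np.linalg.norm(diff, axis=2)
    if np.any(values == 0):
        frame, feat = np.argwhere(values == 0)[0]
        raise ValueError(
            f"coincident atoms: zero distance at frame {frame}, pair {(int(ii[feat]), int(jj[feat]))}"
        )
    descriptors = [(int(i), int(j)) for i, j in zip(ii, jj)]
    return FeatureMatrix(values, descriptors, f"distance_{mode}")


def invert_distances(fm: FeatureMatrix) -> FeatureMatrix:
    """1/distance transform; applied after any distance-space filtering."""
    if fm.kind not in _DISTANCE_KINDS:
        raise ValueError(f"expected raw distances, got kind {fm.kind!r}")
    return FeatureMatrix(1.0 / fm.values, list(fm.descriptors), "inverse_" + fm.kind)


def inverse_distance_features(coords: np.ndarray, mode: str = "full") -> FeatureMatrix:
    return invert_distances(distance_features(coords, mode))


def filter_contact_changing(fm: FeatureMatrix, cutoff: float) -> FeatureMatrix:
    """Keep pairs whose distance crosses ``cutoff`` within the data set.

    A pair survives iff its minimum distance over samples is below the
    cutoff AND its maximum is above it — i.e. the contact forms in some
    frames and breaks in others.
    """
    if fm.kind not in _DISTANCE_KINDS:
        raise ValueError("contact-change filter operates on raw distances")
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    keep = (fm.values.min(axis=0) < cutoff) & (fm.values.max(axis=0) > cutoff)
    return fm.subset_features(np.flatnonzero(keep))


def filter_range(fm: FeatureMatrix, lower: float, upper: float) -> FeatureMatrix:
    """Drop pairs that stay above ``upper`` or below ``lower`` throughout."""
    if fm.kind not in _DISTANCE_KINDS:
        raise ValueError("range filter operates on raw distances")
    if lower >= upper:
        raise ValueError("lower must be < upper")
    always_above = fm.values.min(axis=0) > upper
    always_below = fm.values.max(axis=0) < lower
    keep = ~(always_above | always_below)
    return fm.subset_features(np.flatnonzero(keep))


def minmax_scale(fm: FeatureMatrix) -> FeatureMatrix:
    """Per-feature (x - min)/(max - min) onto [0, 1].

    Constant features map to 0 and are flagged in ``constant_mask``; the
    (min, max) record allows exact inversion for non-constant features.
    """
    lo = fm.values.min(axis=0)
    hi = fm.values.max(axis=0)
    span = hi - lo
    constant = span == 0
    safe = np.where(constant, 1.0, span)
    values = (fm.values - lo) / safe
    values[:, constant] = 0.0
    return FeatureMatrix(values, list(fm.descriptors), fm.kind, (lo, hi), constant)


def unscale(fm: FeatureMatrix) -> FeatureMatrix:
    if fm.scaling is None:
        raise ValueError("feature matrix has no scaling record")
    lo, hi = fm.scaling
    return FeatureMatrix(fm.values * (hi - lo) + lo, list(fm.descriptors), fm.kind)


def drop_constant_features(fm: FeatureMatrix) -> tuple[FeatureMatrix, int]:
    """Remove zero-variance columns (they break scaling and KL binning).

    Returns the reduced matrix and the number of dropped features.
    """
    span = fm.values.max(axis=0) - fm.values.min(axis=0)
    keep = np.flatnonzero(span > 0)
    return fm.subset_features(keep), fm.n_features - len(keep)


def block_shuffle(
    fm: FeatureMatrix, labels: LabelSet, block_size: int, seed: int
) -> tuple[FeatureMatrix, LabelSet]:
    """Permute samples by contiguous blocks, co-permuting labels.

    Blocks of consecutive frames are kept intact to preserve local temporal
    correlation while decorrelating labels from trajectory order; the last
    block may be shorter.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    n = fm.n_samples
    starts = np.arange(0, n, block_size)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(starts))
    idx = np.concatenate([np.arange(s, min(s + block_size, n)) for s in starts[order]])
    return fm.subset_samples(idx), labels.subset(idx)


def aggregate_importance_per_atom(
    feature_importance: np.ndarray,
    descriptors: list[tuple],
    normalization: str = "minmax",
) -> np.ndarray:
    """Map per-feature importance to per-atom importance.

    Each atom's raw score is the sum of the importance of every feature
    whose descriptor involves it (both endpoints of a distance pair; the
    x, y, z triplet of a cartesian atom).  With dense feature sets every
    atom participates in many features, so the sums carry a large shared
    baseline; the default ``minmax`` normalization maps the scores onto
    [0, 1] by subtracting the minimum before dividing by the range, which
    removes that baseline.  ``normalization='max'`` divides by the maximum
    only, preserving true zeros.  A constant (or all-zero) input is
    returned as zeros.
    """
    if normalization not in ("minmax", "max"):
        raise ValueError(f"unknown normalization {normalization!r}")
    imp = np.asarray(feature_importance, dtype=float)
    if imp.shape[0] != len(descriptors):
        raise ValueError("importance length does not match descriptors")
    if not np.all(np.isfinite(imp)):
        raise ValueError("importance contains non-finite values")
    n_atoms = 0
    for d in descriptors:
        a = d[0] if isinstance(d[1], str) else max(d[0], d[1])
        n_atoms = max(n_atoms, a + 1)
    scores = np.zeros(n_atoms)
    for w, d in zip(imp, descriptors):
        if isinstance(d[1], str):  # (atom, axis)
            scores[d[0]] += w
        else:  # (i, j) pair
            scores[d[0]] += w
            scores[d[1]] += w
    if normalization == "minmax":
        scores = scores - scores.min()
    top = scores.max()
    return scores / top if top > 0 else scores
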