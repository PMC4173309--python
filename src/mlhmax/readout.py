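"""Linear readout: layer outputs -> fixed-length vectors -> long/short decisions.

Any tap point of the hierarchy is flattened into a deterministic
fixed-length feature vector; a single L2-regularized linear classifier
(ridge regression on +/-1 targets) is trained on the cross-fin training set
and applied to test stimuli.  The decision score is the affine score; ties
at exactly 0 are broken as "long".

Intermediate S1/C1/S2 maps are far too large to feed to the classifier
whole, so each response map is area-averaged onto a small fixed grid before
concatenation (the grid sizes are configuration, capped at ``cap``
features); the C2 vector and the raw input image are used unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import RidgeClassifier

from .hmax import LAYERS, preprocess

__all__ = ["VectorizeConfig", "LinearReadout", "vectorize", "train_classifier",
           "classify", "percent_correct"]

LONG, SHORT = "long", "short"


@dataclass(frozen=True)
class VectorizeConfig:
    """Grid sides for area-averaging each response map before concatenation.

    Defaults use the finest grids that respect the feature cap (10 scales x
    4 orientations x 22^2 = 19 360 for S1), so vectorization adds as little
    spatial pooling of its own as possible -- position tolerance should come
    from the model's C layers, not from the readout.
    """

    s1_grid: int = 22
    c1_grid: int = 22
    s2_grid: int = 2
    cap: int = 20000


def _grid_average(m: np.ndarray, g: int) -> np.ndarray:
    """Area-average a 2-D map onto a g x g grid (near-equal pixel bins).

    Maps smaller than the grid are first integer-upsampled so every bin is
    non-empty; the mapping is deterministic and shape-dependent only.
    """
    h, w = m.shape
    if h < g or w < g:
        rep = int(np.ceil(g / min(h, w)))
        m = np.repeat(np.repeat(m, rep, axis=0), rep, axis=1)
        h, w = m.shape
    row_edges = np.linspace(0, h, g + 1).astype(int)
    col_edges = np.linspace(0, w, g + 1).astype(int)
    rows = np.add.reduceat(m, row_edges[:-1], axis=0)
    cells = np.add.reduceat(rows, col_edges[:-1], axis=1)
    counts = np.outer(np.diff(row_edges), np.diff(col_edges))
    return (cells / counts).astype(np.float32)


def vectorize(layer_output, layer_id: str, cfg: VectorizeConfig = VectorizeConfig()) -> np.ndarray:
    """Flatten one layer's output into the fixed-length feature vector.

    * ``input``: the normalized (inverted) raster, flattened;
    * ``s1``/``c1``: every (scale-or-band, orientation) map averaged onto a
      ``s1_grid``/``c1_grid`` square, concatenated;
    * ``s2``: every (band, prototype) map averaged onto an ``s2_grid``
      square, concatenated in (band, size-group, prototype) order;
    * ``c2``: the C2 vector unchanged.
    """
    if layer_id not in LAYERS:
        raise ValueError(f"unknown layer {layer_id!r}")
    if layer_id == "input":
        vec = preprocess(np.asarray(layer_output)).ravel().astype(np.float32)
    elif layer_id in ("s1", "c1"):
        g = cfg.s1_grid if layer_id == "s1" else cfg.c1_grid
        parts = [_grid_average(om, g).ravel()
                 for m in layer_output for om in m]
        vec = np.concatenate(parts)
    elif layer_id == "s2":
        parts = []
        for band in sorted(layer_output):
            for s in sorted(layer_output[band]):
                arr = layer_output[band][s]
                parts.extend(_grid_average(pm, cfg.s2_grid).ravel() for pm in arr)
        vec = np.concatenate(parts)
    else:  # c2
        vec = np.asarray(layer_output, dtype=np.float32).ravel()
    if layer_id != "input" and vec.size > cfg.cap:
        raise ValueError(f"{layer_id} vector length {vec.size} exceeds cap {cfg.cap}; "
                         "reduce the grid sizes")
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite feature values")
    return vec


@dataclass
class LinearReadout:
    """Trained linear decision rule w.x + b; positive scores mean "long"."""

    weights: np.ndarray
    bias: float
    layer_id: str
    n_train: int
    alpha: float
    seed: int | None
    training_order: np.ndarray = field(repr=False, default=None)


def train_classifier(vectors: np.ndarray, labels, layer_id: str = "c2",
                     alpha: float = 1.0,
                     rng: np.random.Generator | None = None,
                     seed: int | None = None) -> LinearReadout:
    """Fit the L2-regularized linear rule on labelled feature vectors.

    The training-order permutation is drawn, applied and recorded for
    provenance (the ridge solution itself is order-independent).
    """
    X = np.asarray(vectors, dtype=np.float32)
    y = np.asarray([1 if l == LONG else -1 for l in labels])
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("vectors must be (n_samples, n_features) matching labels")
    if len(np.unique(y)) < 2 or min(np.bincount((y > 0).astype(int))) < 1:
        raise ValueError("need examples of both classes")
    if np.all(X == X[0]):
        raise ValueError("degenerate features: all training vectors identical")
    rng = rng if rng is not None else np.random.default_rng(seed)
    perm = rng.permutation(len(y))
    clf = RidgeClassifier(alpha=alpha, fit_intercept=True)
    clf.fit(X[perm], y[perm])
    return LinearReadout(weights=clf.coef_.ravel().astype(np.float64),
                         bias=float(clf.intercept_[0]), layer_id=layer_id,
                         n_train=len(y), alpha=alpha, seed=seed, training_order=perm)


def classify(model: LinearReadout, vectors: np.ndarray):
    """Decide long/short for one vector or a batch; returns (labels, scores).

    A score of exactly 0 is classified "long" (fixed tie-break).
    """
    X = np.atleast_2d(np.asarray(vectors, dtype=np.float64))
    if X.shape[1] != model.weights.shape[0]:
        raise ValueError(f"feature length {X.shape[1]} != model length {model.weights.shape[0]}")
    scores = X @ model.weights + model.bias
    labels = np.where(scores >= 0.0, LONG, SHORT)
    return labels, scores


def percent_correct(model: LinearReadout, vectors: np.ndarray, labels) -> float:
    """Classification accuracy in percent."""
    pred, _ = classify(model, vectors)
    truth = np.asarray(labels)
    return 100.0 * float(np.mean(pred == truth))
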