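"""Decision units: extreme learning machine and prototype matching.

An ELM is a single-hidden-layer feed-forward network whose hidden-node
parameters (a_i, b_i) are drawn at random and never trained; only the
output weights are fitted, in closed form, as the minimum-norm least-squares
solution of H beta = T where H is the hidden-layer output matrix and T the
one-hot target matrix.  With L >= N hidden nodes and distinct inputs the
interpolation is exact with probability one ("zero training error").

Three hidden-node types are supported:

* ``sigmoid``  — additive node, logistic g(a.x + b)
* ``rbf``      — radial node, exp(-b * ||x - a||^2), b > 0
* ``wavelet``  — Mexican-hat radial node, (1 - z^2) exp(-z^2 / 2) with
  z = ||x - a|| / b

The prototype classifier scores a frame descriptor against 5 stored
prototypes per action class by normalised cross-correlation and reports the
per-class maximum — plain template matching.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ELMModel",
    "PrototypeSet",
    "hidden_output",
    "elm_train",
    "elm_predict",
    "prototype_score",
    "save_elm",
    "load_elm",
]

NODE_TYPES = ("sigmoid", "rbf", "wavelet")


@dataclass
class ELMModel:
    a: np.ndarray  # (L, n) hidden input weights / centres
    b: np.ndarray  # (L,) biases or widths
    beta_out: np.ndarray  # (L, m) output weights
    node_type: str
    classes: np.ndarray  # class labels, index-aligned with output columns
    rng_seed: int

    @property
    def L(self) -> int:
        return self.a.shape[0]

    @property
    def n_features(self) -> int:
        return self.a.shape[1]


@dataclass
class PrototypeSet:
    """Per-class prototype descriptors: exactly 5 unit-norm images each."""

    prototypes: dict  # class name -> (5, ...) array
    class_names: tuple

    def __post_init__(self):
        for name in self.class_names:
            if self.prototypes[name].shape[0] != 5:
                raise ValueError("exactly 5 prototypes required per class")


def _hidden_matrix(a: np.ndarray, b: np.ndarray, X: np.ndarray, node_type: str) -> np.ndarray:
    if node_type == "sigmoid":
        z = X @ a.T + b[None, :]
        return 1.0 / (1.0 + np.exp(-z))
    if node_type == "rbf":
        d2 = ((X[:, None, :] - a[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-b[None, :] * d2)
    if node_type == "wavelet":
        d = np.sqrt(((X[:, None, :] - a[None, :, :]) ** 2).sum(axis=2))
        z = d / b[None, :]
        return (1.0 - z**2) * np.exp(-(z**2) / 2.0)
    raise ValueError(f"unknown node_type {node_type!r}")


def hidden_output(model: ELMModel, x: np.ndarray) -> np.ndarray:
    """Hidden-layer outputs G(a_i, b_i, x) for one feature vector."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_features,):
        raise ValueError("feature dimension mismatch")
    return _hidden_matrix(model.a, model.b, x[None, :], model.node_type)[0]


def elm_train(
    X: np.ndarray,
    y,
    L: int,
    node_type: str = "sigmoid",
    seed: int = 0,
    ridge: float = 0.0,
) -> ELMModel:
    """Fit an ELM: random hidden layer + least-squares output weights.

    ``a`` is drawn uniform[-1, 1], ``b`` uniform[0, 1] (shifted away from 0
    for the radial types, whose width must be positive); ``beta_out`` is the
    minimum-norm solution of H beta = T via the pseudo-inverse, or the ridge
    solution when ``ridge > 0``.  Deterministic given ``seed``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if L < 1:
        raise ValueError("L must be >= 1")
    if X.shape[0] != y.shape[0] or X.shape[0] < 1:
        raise ValueError("X and y must have matching, non-zero sample counts")
    if node_type not in NODE_TYPES:
        raise ValueError(f"node_type must be one of {NODE_TYPES}")
    classes = np.unique(y)
    T = np.zeros((X.shape[0], classes.size))
    for j, cls in enumerate(classes):
        T[y == cls, j] = 1.0
    rng = np.random.default_rng(seed)
    a = rng.uniform(-1.0, 1.0, size=(L, X.shape[1]))
    b = rng.uniform(0.0, 1.0, size=L)
    if node_type in ("rbf", "wavelet"):
        b = 0.05 + 0.95 * b  # widths must stay positive
    H = _hidden_matrix(a, b, X, node_type)
    if ridge > 0:
        beta = np.linalg.solve(H.T @ H + ridge * np.eye(L), H.T @ T)
    else:
        beta = np.linalg.pinv(H) @ T
    return ELMModel(a=a, b=b, beta_out=beta, node_type=node_type, classes=classes, rng_seed=seed)


def elm_predict(model: ELMModel, X: np.ndarray):
    """Predict labels and per-class scores; argmax with lowest-index ties."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError("feature dimension mismatch")
    H = _hidden_matrix(model.a, model.b, X, model.node_type)
    scores = H @ model.beta_out
    labels = model.classes[np.argmax(scores, axis=1)]
    return labels, scores


def prototype_score(prototypes: PrototypeSet, frame_descriptor: np.ndarray) -> dict:
    """Per-class best normalised cross-correlation against the prototypes.

    NCC is computed over flattened descriptors: sum((x - x_bar)(p - p_bar))
    / (N sigma_x sigma_p), in [-1, 1].  A zero-variance descriptor scores 0
    for every class.
    """
    x = np.asarray(frame_descriptor, dtype=float).ravel()
    sx = x.std()
    out = {}
    if sx < 1e-12:
        return {name: 0.0 for name in prototypes.class_names}
    xc = (x - x.mean()) / sx
    for name in prototypes.class_names:
        best = -1.0
        for p in prototypes.prototypes[name]:
            p = np.asarray(p, dtype=float).ravel()
            if p.shape != x.shape:
                raise ValueError("descriptor shape does not match prototypes")
            sp = p.std()
            if sp < 1e-12:
                ncc = 0.0
            else:
                ncc = float(xc @ ((p - p.mean()) / sp) / x.size)
            best = max(best, ncc)
        out[name] = best
    return out


def save_elm(model: ELMModel, path) -> None:
    """Serialize an ELM to a zip archive; bit-exact round trip."""
    meta = {
        "node_type": model.node_type,
        "L": int(model.L),
        "n_features": int(model.n_features),
        "n_classes": int(model.classes.size),
        "rng_seed": int(model.rng_seed),
        "classes": [str(c) for c in model.classes],
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=1))
        for name, arr in (("a", model.a), ("b", model.b), ("beta_out", model.beta_out)):
            buf = io.BytesIO()
            np.save(buf, arr)
            zf.writestr(name + ".npy", buf.getvalue())


def load_elm(path) -> ELMModel:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        arrays = {
            name: np.load(io.BytesIO(zf.read(name + ".npy")))
            for name in ("a", "b", "beta_out")
        }
    return ELMModel(
        a=arrays["a"],
        b=arrays["b"],
        beta_out=arrays["beta_out"],
        node_type=meta["node_type"],
        classes=np.array(meta["classes"]),
        rng_seed=meta["rng_seed"],
    )
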