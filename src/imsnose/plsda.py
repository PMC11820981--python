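"""Full-matrix PLS-DA: NIPALS decomposition, class prediction, VIP maps.

Classification is cast as PLS2 regression of the mean-centred feature
matrix onto a one-hot class-membership matrix.  The NIPALS algorithm
extracts latent variables one at a time: for component ``a`` it finds the
X-weight vector ``w_a`` (unit norm) maximising covariance with the Y
scores, forms the X scores ``t_a = X w_a``, the X loadings
``p_a = X't_a / t_a't_a`` and Y loadings ``q_a = Y't_a / t_a't_a``, then
deflates ``X <- X - t_a p_a'``.  Only X is deflated; regressing the
original Y on the mutually orthogonal scores gives identical predictions.
A sample is assigned to the class whose predicted membership column is
largest (ties break to the lowest class index).

Variable importance in projection (VIP) summarises how much each feature
contributes to the fitted latent space:

    VIP_j = sqrt( J * sum_a SS_a w_ja^2 / sum_a SS_a ),
    SS_a = (t_a' t_a) * ||q_a||^2

with J the number of features, so the mean squared VIP is exactly 1 and
features above 1 are conventionally called important.  Averaged over the
models of an external-validation ensemble and reshaped back into map
coordinates, the VIP vector becomes an interpretable 2D importance map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import h5py
import numpy as np

from .errors import MalformedInputError, ParameterError
from .io import unflatten

__all__ = [
    "ClassEncoding",
    "PLSModel",
    "VIPMap",
    "encode_labels",
    "fit_pls",
    "transform",
    "predict",
    "vip_scores",
    "average_vip_map",
    "save_model",
    "load_model",
]


@dataclass
class ClassEncoding:
    """One-hot class membership matrix with its column order."""

    class_names: list[str]
    Y: np.ndarray


def encode_labels(y, class_names) -> ClassEncoding:
    """Encode labels as one-hot rows in the order given by ``class_names``."""
    class_names = list(class_names)
    index = {c: j for j, c in enumerate(class_names)}
    Y = np.zeros((len(y), len(class_names)))
    for i, label in enumerate(y):
        if label not in index:
            raise MalformedInputError(
                f"label {label!r} not among classes {class_names}"
            )
        Y[i, index[label]] = 1.0
    return ClassEncoding(class_names=class_names, Y=Y)


@dataclass
class PLSModel:
    """Centred NIPALS PLS2 decomposition.

    ``W`` (n_features x A) are the unit-norm X weights, ``P`` the X
    loadings, ``Q`` (n_classes x A) the Y loadings and ``T`` the training
    scores; ``x_mean``/``y_mean`` are the training centring vectors.
    """

    x_mean: np.ndarray
    y_mean: np.ndarray
    W: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    T: np.ndarray
    A: int
    class_names: list[str]

    @property
    def n_features(self) -> int:
        return self.W.shape[0]


def fit_pls(X: np.ndarray, Y: np.ndarray, A: int, *,
            class_names=None, tol: float = 1e-10,
            max_iter: int = 500) -> PLSModel:
    """Fit a PLS2 model with ``A`` latent variables by NIPALS.

    ``X`` and ``Y`` are centred by their column means (stored on the
    model); no autoscaling is applied.  If the residual X matrix runs out
    of rank before ``A`` components, the model is truncated with a warning.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, j = X.shape
    if A < 1:
        raise ParameterError("A must be at least 1")
    if A > min(n - 1, j):
        raise ParameterError(
            f"A = {A} exceeds min(n_samples - 1, n_features) = {min(n - 1, j)}"
        )
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    xnorm = np.linalg.norm(Xc)
    if xnorm == 0.0:
        raise ParameterError("X has zero variance")

    Ws, Ps, Qs, Ts = [], [], [], []
    eps = np.finfo(float).eps * max(n, j) * xnorm
    for _ in range(A):
        # start from the Y column with the largest remaining variance
        u = Yc[:, int(np.argmax((Yc**2).sum(axis=0)))].copy()
        w = np.zeros(j)
        for _ in range(max_iter):
            w_new = Xc.T @ u
            nw = np.linalg.norm(w_new)
            if nw <= eps:
                break
            w_new /= nw
            t = Xc @ w_new
            tt = t @ t
            if tt <= eps**2:
                break
            q = Yc.T @ t / tt
            qq = q @ q
            if qq == 0.0:
                break
            u = Yc @ q / qq
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
        if np.linalg.norm(w) == 0.0:
            break
        t = Xc @ w
        tt = t @ t
        if tt <= eps**2:
            break
        p = Xc.T @ t / tt
        q = Yc.T @ t / tt
        Xc = Xc - np.outer(t, p)
        Ws.append(w)
        Ps.append(p)
        Qs.append(q)
        Ts.append(t)
    if not Ws:
        raise ParameterError("X has no usable variance for even one component")
    if len(Ws) < A:
        warnings.warn(
            f"rank exhausted after {len(Ws)} of {A} requested components",
            stacklevel=2,
        )
    return PLSModel(
        x_mean=x_mean,
        y_mean=y_mean,
        W=np.column_stack(Ws),
        P=np.column_stack(Ps),
        Q=np.column_stack(Qs),
        T=np.column_stack(Ts),
        A=len(Ws),
        class_names=list(class_names) if class_names is not None
        else [f"class_{k}" for k in range(Y.shape[1])],
    )


def transform(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Project new samples onto the model's score space (sequential
    deflation, so truncating to the first ``a`` columns gives the scores of
    the ``a``-component model)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_features:
        raise MalformedInputError(
            f"feature count {X.shape[1]} != model's {model.n_features}"
        )
    Xc = X - model.x_mean
    T = np.empty((X.shape[0], model.A))
    for a in range(model.A):
        t = Xc @ model.W[:, a]
        T[:, a] = t
        Xc = Xc - np.outer(t, model.P[:, a])
    return T


def _yhat_from_scores(model: PLSModel, T: np.ndarray,
                      n_components: int) -> np.ndarray:
    return model.y_mean + T[:, :n_components] @ model.Q[:, :n_components].T


def predict(model: PLSModel, X: np.ndarray,
            n_components: int | None = None):
    """Predict class labels and membership estimates for new samples.

    Returns ``(labels, Yhat)``; the label is the argmax class of each row
    of ``Yhat`` (ties go to the lowest class index).  ``n_components``
    truncates the model to its first latent variables.
    """
    a = model.A if n_components is None else int(n_components)
    if not 1 <= a <= model.A:
        raise ParameterError(f"n_components must be in [1, {model.A}]")
    T = transform(model, X)
    Yhat = _yhat_from_scores(model, T, a)
    idx = np.argmax(Yhat, axis=1)  # np.argmax returns the first maximum
    labels = np.array([model.class_names[k] for k in idx], dtype=object)
    return labels, Yhat


def vip_scores(model: PLSModel) -> np.ndarray:
    """Wold VIP scores of a fitted model (mean squared VIP = 1)."""
    ss = np.einsum("ia,ia->a", model.T, model.T) * (model.Q**2).sum(axis=0)
    wnorm2 = (model.W / np.linalg.norm(model.W, axis=0)) ** 2
    j = model.n_features
    return np.sqrt(j * (wnorm2 @ ss) / ss.sum())


@dataclass
class VIPMap:
    """Ensemble-averaged VIP scores in feature and map coordinates."""

    vip: np.ndarray
    map: np.ndarray
    threshold: float = 1.0

    @property
    def important_mask(self) -> np.ndarray:
        """Boolean map of features conventionally deemed important."""
        return self.map > self.threshold


def average_vip_map(models, shape_info: tuple[int, int]) -> VIPMap:
    """Average VIP vectors over an ensemble of models and reshape them into
    the 2D map geometry recorded in ``shape_info``."""
    models = list(models)
    if not models:
        raise MalformedInputError("no models given")
    j = models[0].n_features
    for m in models:
        if m.n_features != j:
            raise MalformedInputError("models disagree on feature count")
    if j != shape_info[0] * shape_info[1]:
        raise MalformedInputError("shape_info does not match feature count")
    vip = np.mean([vip_scores(m) for m in models], axis=0)
    return VIPMap(vip=vip, map=unflatten(vip, shape_info))


def save_model(model: PLSModel, path) -> None:
    """Serialise a fitted model into an HDF5 container under ``/model``."""
    with h5py.File(path, "w") as f:
        g = f.create_group("model")
        for name in ("x_mean", "y_mean", "W", "P", "Q", "T"):
            g.create_dataset(name, data=getattr(model, name))
        g.attrs["A"] = model.A
        g.attrs["class_names"] = list(model.class_names)


def load_model(path) -> PLSModel:
    with h5py.File(path, "r") as f:
        g = f["model"]
        return PLSModel(
            x_mean=g["x_mean"][()],
            y_mean=g["y_mean"][()],
            W=g["W"][()],
            P=g["P"][()],
            Q=g["Q"][()],
            T=g["T"][()],
            A=int(g.attrs["A"]),
            class_names=[str(c) for c in g.attrs["class_names"]],
        )
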