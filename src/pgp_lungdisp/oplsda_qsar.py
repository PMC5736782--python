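"""Orthogonal PLS discriminant analysis (OPLS-DA) on physico-chemical descriptors.

OPLS-DA separates the descriptor variation into a single component predictive
of class membership and one or more components orthogonal to it, then
regresses the coded class response on the predictive score.  For two classes
the response is a single dummy variable (A -> 0, B -> 1 by default), centred
before regression; the fitted numeric response decodes to a class via a 0.5
threshold (ties classify as B).

Algorithm (NIPALS-style, unit-variance scaled X, centred y):

1. ``w = X'y / ||X'y||`` -- the predictive weight vector.
2. For each orthogonal component: ``t = Xw``; ``p = X't/(t't)``;
   ``w_o = p - (w'p) w`` normalised; ``t_o = X w_o``;
   ``p_o = X't_o/(t_o't_o)``; deflate ``X <- X - t_o p_o'``.
3. Final predictive component ``t = Xw`` on the deflated matrix and a
   univariate regression ``y = y_mean + b t``.

Because ``X'y`` is invariant under the orthogonal deflation, ``w`` is the same
direction throughout; the deflation only removes class-orthogonal variation
from the scores.  R2Y is the in-model fraction of response variance explained;
Q2 = 1 - PRESS/SS under cross-validation (see :func:`cross_validate_q2` for
the two supported schemes).
"""
from __future__ import annotations

import json
import pathlib
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core_io import CANONICAL_DESCRIPTORS, DescriptorMatrix, SchemaError

__all__ = [
    "OplsModel",
    "ClassPrediction",
    "uv_scale",
    "fit_oplsda",
    "cross_validate_q2",
    "predict",
    "export_scores_loadings",
]

_EPS_COMPONENT = 1e-10  # below this norm a further component is numerically void
_ORTHO_TOL = 1e-8


def _as_array(X, names: Sequence[str] | None = None) -> tuple[np.ndarray, tuple[str, ...], tuple[str, ...]]:
    """Coerce a DescriptorMatrix or ndarray to (values, descriptor names, row names)."""
    if isinstance(X, DescriptorMatrix):
        return X.values, tuple(CANONICAL_DESCRIPTORS), X.names
    arr = np.asarray(X, dtype=float)
    if names is None:
        names = tuple(f"x{i}" for i in range(arr.shape[1]))
    rows = tuple(f"sample{i}" for i in range(arr.shape[0]))
    return arr, tuple(names), rows


def uv_scale(
    X, means: np.ndarray | None = None, sds: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit-variance scaling: per-column mean 0, sample SD 1 (n-1 denominator).

    With ``means``/``sds`` given, applies a previously learned scaling instead.
    Zero-variance columns are rejected by name.
    """
    arr, names, _ = _as_array(X)
    if means is None:
        means = arr.mean(axis=0)
        sds = arr.std(axis=0, ddof=1)
        zero = np.flatnonzero(sds == 0)
        if zero.size:
            raise ValueError(
                f"zero-variance column(s): {[names[i] for i in zero]}"
            )
    return (arr - means) / sds, np.asarray(means), np.asarray(sds)


@dataclass(frozen=True)
class ClassPrediction:
    name: str
    y_value: float
    predicted_class: str  # "A" or "B"
    t_pred: float
    t_orth: tuple[float, ...]


@dataclass(frozen=True)
class OplsModel:
    """A fitted OPLS-DA model with full scaling/weights provenance."""

    descriptor_names: tuple[str, ...]
    compound_names: tuple[str, ...]
    column_means: np.ndarray
    column_sds: np.ndarray
    w: np.ndarray  # predictive weights, unit norm
    p: np.ndarray  # predictive loadings
    t_pred: np.ndarray  # predictive scores (training)
    W_o: np.ndarray  # (n_orth, k) orthogonal weights
    P_o: np.ndarray  # (n_orth, k) orthogonal loadings
    T_o: np.ndarray  # (n_orth, n) orthogonal scores (training)
    b: float  # regression coefficient of centred y on t_pred
    y_center: float
    y_coding: Mapping[str, float]
    threshold: float
    n_orth: int
    r2y: float
    q2: float
    misclassified_names: tuple[str, ...] = ()

    def decode(self, y_value: float) -> str:
        """Numeric response -> class label; ties at the threshold go to B."""
        inv = {v: k for k, v in self.y_coding.items()}
        hi = inv[max(self.y_coding.values())]
        lo = inv[min(self.y_coding.values())]
        return hi if y_value >= self.threshold else lo

    # -- serialisation ------------------------------------------------------

    def to_json(self, path: str | pathlib.Path | None = None) -> str:
        payload = {
            "descriptor_names": list(self.descriptor_names),
            "compound_names": list(self.compound_names),
            "column_means": self.column_means.tolist(),
            "column_sds": self.column_sds.tolist(),
            "w": self.w.tolist(),
            "p": self.p.tolist(),
            "t_pred": self.t_pred.tolist(),
            "W_o": self.W_o.tolist(),
            "P_o": self.P_o.tolist(),
            "T_o": self.T_o.tolist(),
            "b": self.b,
            "y_center": self.y_center,
            "y_coding": dict(self.y_coding),
            "threshold": self.threshold,
            "n_orth": self.n_orth,
            "r2y": self.r2y,
            "q2": self.q2,
            "misclassified_names": list(self.misclassified_names),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            pathlib.Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | pathlib.Path) -> "OplsModel":
        if isinstance(source, pathlib.Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            source = pathlib.Path(source).read_text()
        d = json.loads(source)
        return cls(
            descriptor_names=tuple(d["descriptor_names"]),
            compound_names=tuple(d["compound_names"]),
            column_means=np.array(d["column_means"]),
            column_sds=np.array(d["column_sds"]),
            w=np.array(d["w"]),
            p=np.array(d["p"]),
            t_pred=np.array(d["t_pred"]),
            W_o=np.array(d["W_o"]).reshape(d["n_orth"], -1),
            P_o=np.array(d["P_o"]).reshape(d["n_orth"], -1),
            T_o=np.array(d["T_o"]).reshape(d["n_orth"], -1),
            b=d["b"],
            y_center=d["y_center"],
            y_coding=d["y_coding"],
            threshold=d["threshold"],
            n_orth=d["n_orth"],
            r2y=d["r2y"],
            q2=d["q2"],
            misclassified_names=tuple(d["misclassified_names"]),
        )


def _components(Xs: np.ndarray, yc: np.ndarray, n_orth: int):
    """Core NIPALS extraction on scaled X and centred y."""
    Xd = Xs.copy()
    Wo, Po, To = [], [], []
    for i in range(n_orth):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw < _EPS_COMPONENT:
            raise ValueError(
                f"orthogonal component {i + 1}: weight norm {nw:.2e} is "
                "numerically zero; reduce n_orth"
            )
        w = w / nw
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        wo = p - (w @ p) * w
        nwo = np.linalg.norm(wo)
        if nwo < _EPS_COMPONENT:
            raise ValueError(
                f"orthogonal component {i + 1}: no class-orthogonal variation "
                "remains; reduce n_orth"
            )
        wo = wo / nwo
        to = Xd @ wo
        po = Xd.T @ to / (to @ to)
        Xd = Xd - np.outer(to, po)
        Wo.append(wo)
        Po.append(po)
        To.append(to)
    w = Xd.T @ yc
    nw = np.linalg.norm(w)
    if nw < _EPS_COMPONENT:
        raise ValueError("predictive weight norm is numerically zero")
    w = w / nw
    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    b = float(t @ yc / (t @ t))
    k, n = Xs.shape[1], Xs.shape[0]
    W_o = np.array(Wo) if Wo else np.empty((0, k))
    P_o = np.array(Po) if Po else np.empty((0, k))
    T_o = np.array(To) if To else np.empty((0, n))
    return w, p, t, b, W_o, P_o, T_o


def _strip_orthogonal(Xs: np.ndarray, W_o: np.ndarray, P_o: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove stored orthogonal components; returns (deflated X, orth scores)."""
    Xd = Xs.copy()
    scores = []
    for wo, po in zip(W_o, P_o):
        to = Xd @ wo
        Xd = Xd - np.outer(to, po)
        scores.append(to)
    T = np.array(scores).reshape(len(W_o), -1) if len(W_o) else np.empty((0, Xs.shape[0]))
    return Xd, T


def _code_y(labels: Sequence[str], y_coding: Mapping[str, float]) -> np.ndarray:
    unknown = sorted(set(labels) - set(y_coding))
    if unknown:
        raise ValueError(f"labels without a y-coding: {unknown}")
    return np.array([y_coding[l] for l in labels], dtype=float)


def fit_oplsda(
    X,
    y_labels: Sequence[str] | None = None,
    n_orth: int | str = 1,
    folds: int = 7,
    y_coding: Mapping[str, float] | None = None,
    threshold: float = 0.5,
    cv_scheme: str = "refit_all",
) -> OplsModel:
    """Fit an OPLS-DA model and cross-validate its predictivity.

    ``X`` is a :class:`DescriptorMatrix` (labels taken from its groups unless
    ``y_labels`` is given) or a plain array with explicit ``y_labels``.
    ``n_orth="auto"`` starts at 0 and adds orthogonal components while the
    cross-validated Q2 improves by more than 0.01.  The predictive score sign
    is fixed so the higher-coded class (B) has positive mean score.
    """
    y_coding = dict(y_coding or {"A": 0.0, "B": 1.0})
    arr, dnames, rnames = _as_array(X)
    if y_labels is None:
        if not isinstance(X, DescriptorMatrix):
            raise ValueError("y_labels required when X is a plain array")
        y_labels = X.groups
    y_labels = list(y_labels)
    counts = {l: y_labels.count(l) for l in set(y_labels)}
    if len(counts) != 2 or min(counts.values()) < 2:
        raise ValueError("need exactly two classes with >= 2 samples each")
    if not 2 <= folds <= len(y_labels):
        raise ValueError("folds must lie in [2, n_samples]")
    y = _code_y(y_labels, y_coding)

    if n_orth == "auto":
        best_k, best_q2 = 0, cross_validate_q2(
            arr, y_labels, 0, folds, y_coding=y_coding, scheme=cv_scheme
        )
        k = 0
        while True:
            k += 1
            try:
                q2_k = cross_validate_q2(
                    arr, y_labels, k, folds, y_coding=y_coding, scheme=cv_scheme
                )
            except ValueError:
                break
            if q2_k > best_q2 + 0.01:
                best_k, best_q2 = k, q2_k
            else:
                break
        n_orth = best_k

    n_orth = int(n_orth)
    Xs, means, sds = uv_scale(arr)
    yc = y - y.mean()
    w, p, t, b, W_o, P_o, T_o = _components(Xs, yc, n_orth)

    # sign convention: mean predictive score of the higher-coded class positive
    hi = max(y_coding.values())
    t_hi = t[y == hi]
    if t_hi.mean() < 0:
        w, p, t, b = -w, -p, -t, -b

    _assert_orthogonality(t, T_o, yc)

    y_hat = y.mean() + b * t
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum(yc**2))
    r2y = 1.0 - ss_res / ss_tot
    q2 = cross_validate_q2(arr, y_labels, n_orth, folds, y_coding=y_coding, scheme=cv_scheme)

    inv = {v: k for k, v in y_coding.items()}
    predicted = [inv[hi] if v >= threshold else inv[min(y_coding.values())] for v in y_hat]
    mis = tuple(n for n, pred, true in zip(rnames, predicted, y_labels) if pred != true)

    return OplsModel(
        descriptor_names=dnames,
        compound_names=rnames,
        column_means=means,
        column_sds=sds,
        w=w,
        p=p,
        t_pred=t,
        W_o=W_o,
        P_o=P_o,
        T_o=T_o,
        b=b,
        y_center=float(y.mean()),
        y_coding=y_coding,
        threshold=threshold,
        n_orth=n_orth,
        r2y=r2y,
        q2=q2,
        misclassified_names=mis,
    )


def _assert_orthogonality(t: np.ndarray, T_o: np.ndarray, yc: np.ndarray) -> None:
    """Model invariants, checked after every fit."""
    ny = np.linalg.norm(yc)
    nt = np.linalg.norm(t)
    for to in T_o:
        nto = np.linalg.norm(to)
        if nto == 0:
            continue
        if abs(to @ yc) / (nto * ny) > _ORTHO_TOL:
            raise RuntimeError("orthogonal score not orthogonal to the response")
        if abs(t @ to) / (nt * nto) > _ORTHO_TOL:
            raise RuntimeError("predictive score not orthogonal to t_orth")


def cross_validate_q2(
    X,
    y_labels: Sequence[str],
    n_orth: int,
    folds: int,
    y_coding: Mapping[str, float] | None = None,
    scheme: str = "refit_all",
) -> float:
    """Cross-validated Q2 = 1 - PRESS/SS with round-robin fold assignment.

    Row ``i`` goes to fold ``i mod folds``.  Under the default
    ``scheme="refit_all"``, scaling and every component (orthogonal and
    predictive) are re-estimated inside each training fold.  Under
    ``scheme="fixed_orthogonal"`` the orthogonal filter from the full-data
    model is held fixed and only the predictive component is re-estimated per
    fold; this isolates the predictive dimension's predictivity and matches
    how commercial chemometrics software reports Q2 for orthogonal-filtered
    models.  SS is the total response variation about the overall mean.
    A training fold that lacks one of the classes degrades the submodel; it is
    retained with a warning.
    """
    y_coding = dict(y_coding or {"A": 0.0, "B": 1.0})
    if scheme not in ("refit_all", "fixed_orthogonal"):
        raise ValueError(f"unknown cv scheme {scheme!r}")
    arr, _, _ = _as_array(X)
    y = _code_y(list(y_labels), y_coding)
    n = len(y)
    if not 2 <= folds <= n:
        raise ValueError("folds must lie in [2, n_samples]")

    if scheme == "fixed_orthogonal":
        Xs_full, _, _ = uv_scale(arr)
        _, _, _, _, W_o_full, P_o_full, _ = _components(Xs_full, y - y.mean(), n_orth)

    assignment = np.arange(n) % folds
    press = 0.0
    for f in range(folds):
        test = assignment == f
        ytr = y[~test]
        if len(np.unique(ytr)) < 2:
            # degenerate submodel: the best prediction is the training mean
            warnings.warn(
                f"cross-validation fold {f}: training set lacks one class; "
                "fold retained with a mean-only submodel",
                stacklevel=2,
            )
            press += float(np.sum((y[test] - ytr.mean()) ** 2))
            continue
        Xtr_s, mu, sd = uv_scale(arr[~test])
        Xts_s = (arr[test] - mu) / sd
        ytr_c = ytr - ytr.mean()
        if scheme == "refit_all":
            w, _, _, b, W_o, P_o, _ = _components(Xtr_s, ytr_c, n_orth)
        else:
            Xtr_s, _ = _strip_orthogonal(Xtr_s, W_o_full, P_o_full)
            Xts_s, _ = _strip_orthogonal(Xts_s, W_o_full, P_o_full)
            w, _, _, b, W_o, P_o, _ = _components(Xtr_s, ytr_c, 0)
        Xts_d, _ = _strip_orthogonal(Xts_s, W_o, P_o)
        y_pred = ytr.mean() + b * (Xts_d @ w)
        press += float(np.sum((y[test] - y_pred) ** 2))
    ss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / ss


def predict(model: OplsModel, X_new) -> list[ClassPrediction]:
    """Classify new compounds with a fitted model.

    The new descriptor block is scaled with the training parameters, stripped
    of the stored orthogonal components, and projected on the predictive
    weights.
    """
    if isinstance(X_new, DescriptorMatrix):
        arr, names, rnames = X_new.values, tuple(CANONICAL_DESCRIPTORS), X_new.names
    else:
        arr = np.asarray(X_new, dtype=float)
        names = model.descriptor_names
        rnames = tuple(f"sample{i}" for i in range(arr.shape[0]))
    if tuple(names) != tuple(model.descriptor_names):
        raise SchemaError(
            "descriptor columns do not match the training descriptors: "
            f"expected {list(model.descriptor_names)}"
        )
    if arr.shape[1] != len(model.descriptor_names):
        raise SchemaError("descriptor count mismatch")
    Xs = (arr - model.column_means) / model.column_sds
    Xd, T_orth = _strip_orthogonal(Xs, model.W_o, model.P_o)
    t = Xd @ model.w
    y_val = model.y_center + model.b * t
    out = []
    for i, name in enumerate(rnames):
        out.append(
            ClassPrediction(
                name=name,
                y_value=float(y_val[i]),
                predicted_class=model.decode(float(y_val[i])),
                t_pred=float(t[i]),
                t_orth=tuple(float(T_orth[k, i]) for k in range(model.n_orth)),
            )
        )
    return out


def export_scores_loadings(model: OplsModel):
    """Plot-ready score and loading tables.

    Scores: one row per training compound with the predictive score and the
    first orthogonal score (NaN when the model has none).  Loadings: one row
    per descriptor with the predictive weight-loading and the first orthogonal
    loading.  With B coded high and the sign convention fixed at fit time,
    Group-B compounds sit at positive predictive scores (the right-hand side
    of a scores plot) and descriptors associated with Group A carry the
    opposite loading sign.
    """
    import pandas as pd

    t_o1 = model.T_o[0] if model.n_orth else np.full(len(model.t_pred), np.nan)
    p_o1 = model.P_o[0] if model.n_orth else np.full(len(model.w), np.nan)
    scores = pd.DataFrame(
        {
            "compound": list(model.compound_names),
            "t_pred": model.t_pred,
            "t_orth1": t_o1,
        }
    )
    loadings = pd.DataFrame(
        {
            "descriptor": list(model.descriptor_names),
            "predictive_loading": model.w,
            "orthogonal_loading1": p_o1,
        }
    )
    return scores, loadings
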