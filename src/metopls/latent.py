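"""Latent-variable models: NIPALS PCA, OPLS and OPLS-DA with VIP.

The API follows the statsmodels convention: a model object is built from
data, ``fit()`` returns a results object carrying scores, loadings,
explained-variance bookkeeping and diagnostics, with ``summary()`` for a
human-readable table.

PCA is computed by NIPALS with deflation — the chemometrics reference
algorithm, well behaved in the small-n / large-J regime of metabolomics
panels — and is checked against an SVD oracle in the tests. OPLS is the
published single-response algorithm: the predictive weight is proportional
to X'y; each orthogonal component removes, from X, structured variation
uncorrelated with y; the predictive component is then recomputed on the
filtered X. Because deflating a y-orthogonal component leaves X'y unchanged,
the predictive weight vector is exactly invariant under the orthogonal
deflations, and every orthogonal score is exactly uncorrelated with y.

All fits are deterministic: NIPALS starts from the column of maximal
variance, and component signs follow the largest-|loading|-positive
convention.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConvergenceError,
    DegenerateError,
    DegenerateYError,
    NotCenteredError,
    RankError,
    ShapeError,
)

_CENTER_TOL = 1e-8


def _as_matrix(X) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(i) for i in X.index], [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ShapeError("X must be 2-D")
    return (
        arr,
        [f"s{i}" for i in range(arr.shape[0])],
        [f"v{j}" for j in range(arr.shape[1])],
    )


def _check_centered(X: np.ndarray) -> None:
    col_means = X.mean(axis=0)
    scale = max(1.0, float(np.abs(X).max(initial=0.0)))
    if np.abs(col_means).max(initial=0.0) > _CENTER_TOL * scale:
        raise NotCenteredError(
            f"column means up to {np.abs(col_means).max():.3g}; center X first"
        )


def _fix_sign(vec: np.ndarray, *companions: np.ndarray) -> None:
    """Flip signs in place so the entry of largest magnitude is positive."""
    j = int(np.argmax(np.abs(vec)))
    if vec[j] < 0:
        vec *= -1.0
        for c in companions:
            c *= -1.0


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class PCA:
    """Principal component analysis of a centered (usually autoscaled) matrix.

    Parameters
    ----------
    X : DataFrame or array, n_samples × n_variables, column means ~ 0.
    """

    def __init__(self, X) -> None:
        self.X, self.ids, self.var_ids = _as_matrix(X)
        _check_centered(self.X)

    def fit(self, n_components: int = 2, tol: float = 1e-12, maxiter: int = 20000) -> "PCAResults":
        X = self.X.copy()
        n, J = X.shape
        max_comp = min(n - 1, J)
        if not (1 <= n_components <= max_comp):
            raise ValueError(f"n_components must lie in [1, {max_comp}]")
        ss_total = float(np.sum(X * X))
        if ss_total == 0.0:
            raise DegenerateError("X is identically zero")
        T = np.zeros((n, n_components))
        P = np.zeros((J, n_components))
        r2x = []
        for a in range(n_components):
            t = X[:, int(np.argmax(X.var(axis=0)))].copy()
            if float(t @ t) == 0.0:
                # exhausted rank: component carries nothing
                r2x.append(0.0)
                continue
            for _ in range(maxiter):
                p = X.T @ t / float(t @ t)
                p /= np.linalg.norm(p)
                t_new = X @ p
                if np.linalg.norm(t_new - t) <= tol * np.linalg.norm(t_new):
                    t = t_new
                    break
                t = t_new
            else:
                raise ConvergenceError(f"NIPALS did not converge for component {a + 1}")
            _fix_sign(p, t)
            T[:, a] = t
            P[:, a] = p
            r2x.append(float(t @ t) / ss_total)
            X = X - np.outer(t, p)
        comp = [f"t{a + 1}" for a in range(n_components)]
        return PCAResults(
            scores=pd.DataFrame(T, index=self.ids, columns=comp),
            loadings=pd.DataFrame(P, index=self.var_ids, columns=[f"p{a+1}" for a in range(n_components)]),
            r2x_per_component=r2x,
        )


@dataclass
class PCAResults:
    """Scores, unit-norm loadings and explained variance of a PCA fit."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    r2x_per_component: list[float]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def t(self, a: int = 1) -> pd.Series:
        """Score vector of component ``a`` (1-based; t1 is the first)."""
        return self.scores[f"t{a}"]

    def flip_component(self, a: int = 1) -> None:
        """Negate one component's scores and loadings (orientation is a
        convention; flipping changes nothing the model explains)."""
        self.scores[f"t{a}"] *= -1.0
        self.loadings[f"p{a}"] *= -1.0

    def hotelling_t2(self, alpha: float = 0.05) -> tuple[pd.Series, float, pd.Series]:
        """Per-sample Hotelling T², its F-based critical limit and outlier flags."""
        T = self.scores.to_numpy()
        n, A = T.shape
        if n <= A + 1:
            raise DegenerateError(f"need n > A + 1 (n={n}, A={A})")
        var = T.var(axis=0, ddof=1)
        if np.any(var == 0):
            t2_vals = np.zeros(n)
        else:
            t2_vals = np.sum(T * T / var, axis=1)
        limit = A * (n - 1) * (n + 1) / (n * (n - A)) * stats.f.ppf(1 - alpha, A, n - A)
        t2 = pd.Series(t2_vals, index=self.scores.index, name="T2")
        flags = pd.Series(t2_vals > limit, index=self.scores.index, name="outlier")
        return t2, float(limit), flags

    def summary(self) -> str:
        lines = [
            "PCA results",
            f"  samples:    {self.scores.shape[0]}",
            f"  components: {self.n_components}",
        ]
        for a, r2 in enumerate(self.r2x_per_component, start=1):
            lines.append(f"  R2X[{a}] = {r2:.4f}")
        lines.append(f"  R2X(cum) = {sum(self.r2x_per_component):.4f}")
        return "\n".join(lines)

    def plot_scores(self, ax=None, groups: dict[str, str] | None = None, alpha: float = 0.05):
        """Scatter of t1 vs t2 with the Hotelling T² ellipse."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t1 = self.scores.iloc[:, 0]
        t2 = self.scores.iloc[:, 1] if self.n_components > 1 else t1 * 0.0
        if groups:
            labels = [groups.get(s, "?") for s in self.scores.index]
            for g in dict.fromkeys(labels):
                mask = [l == g for l in labels]
                ax.scatter(t1[mask], t2[mask], label=g, s=30)
            ax.legend(fontsize=7)
        else:
            ax.scatter(t1, t2, s=30)
        if self.n_components >= 2:
            n = len(t1)
            A = 2
            f = stats.f.ppf(1 - alpha, A, n - A) * A * (n - 1) * (n + 1) / (n * (n - A))
            s1 = np.sqrt(t1.var(ddof=1) * f)
            s2 = np.sqrt(t2.var(ddof=1) * f)
            th = np.linspace(0, 2 * np.pi, 200)
            ax.plot(s1 * np.cos(th), s2 * np.sin(th), "k--", lw=0.8)
        ax.axhline(0, color="gray", lw=0.5)
        ax.axvline(0, color="gray", lw=0.5)
        ax.set_xlabel(f"t1 ({self.r2x_per_component[0] * 100:.1f}% R2X)")
        if self.n_components > 1:
            ax.set_ylabel(f"t2 ({self.r2x_per_component[1] * 100:.1f}% R2X)")
        return ax


def pca_fit(X, n_components: int) -> PCAResults:
    """Functional wrapper: ``PCA(X).fit(n_components)``."""
    return PCA(X).fit(n_components)


# ---------------------------------------------------------------------------
# OPLS / OPLS-DA
# ---------------------------------------------------------------------------

class OPLS:
    """Single-response orthogonal projections to latent structures.

    Parameters
    ----------
    endog : response vector; centered internally (the mean is stored and
        restored in predictions).
    exog : centered (and typically unit-variance scaled) X matrix.
    n_orth : number of y-orthogonal components to strip from X.
    """

    y_kind = "quantitative"

    def __init__(self, endog, exog, n_orth: int = 0) -> None:
        self.X, self.ids, self.var_ids = _as_matrix(exog)
        _check_centered(self.X)
        y = np.asarray(endog, dtype=float).ravel()
        if y.shape[0] != self.X.shape[0]:
            raise ShapeError("endog and exog have different n")
        if np.var(y) == 0.0:
            raise DegenerateYError("response has zero variance")
        if n_orth < 0:
            raise ValueError("n_orth must be >= 0")
        self.y_mean = float(y.mean())
        self.y = y - self.y_mean
        self.n_orth = int(n_orth)
        self.class_map: dict[str, float] | None = None

    def fit(self) -> "OPLSResults":
        X = self.X.copy()
        y = self.y
        ss_x = float(np.sum(X * X))
        if ss_x == 0.0:
            raise RankError("X is identically zero")

        def _predictive(Xc):
            w = Xc.T @ y
            nw = np.linalg.norm(w)
            if nw <= 1e-300:
                raise RankError("X carries no covariance with y")
            w = w / nw
            t = Xc @ w
            tt = float(t @ t)
            if tt <= 1e-300:
                raise RankError("degenerate predictive score")
            p = Xc.T @ t / tt
            return w, t, p

        w, t, p = _predictive(X)
        W_o, T_o, P_o = [], [], []
        for _ in range(self.n_orth):
            w_o = p - float(w @ p) * w
            n_wo = np.linalg.norm(w_o)
            if n_wo <= 1e-12 * max(1.0, np.linalg.norm(p)):
                raise RankError("no further y-orthogonal structure in X")
            w_o = w_o / n_wo
            t_o = X @ w_o
            tt_o = float(t_o @ t_o)
            if tt_o <= 1e-300:
                raise RankError("degenerate orthogonal score")
            p_o = X.T @ t_o / tt_o
            _fix_sign(p_o, w_o, t_o)
            X = X - np.outer(t_o, p_o)
            W_o.append(w_o)
            T_o.append(t_o)
            P_o.append(p_o)
            w, t, p = _predictive(X)

        b = float(t @ y) / float(t @ t)
        resid = y - b * t
        ssy = float(y @ y)
        r2y = 1.0 - float(resid @ resid) / ssy if ssy > 0 else 0.0
        r2x_pred = float(t @ t) * float(p @ p) / ss_x
        r2x_orth = sum(
            float(to @ to) * float(po @ po) / ss_x for to, po in zip(T_o, P_o)
        )
        J = len(self.var_ids)
        return OPLSResults(
            w_pred=pd.Series(w, index=self.var_ids, name="w_pred"),
            t_pred=pd.Series(t, index=self.ids, name="t_pred"),
            p_pred=pd.Series(p, index=self.var_ids, name="p_pred"),
            W_orth=np.column_stack(W_o) if W_o else np.zeros((J, 0)),
            T_orth=np.column_stack(T_o) if T_o else np.zeros((len(self.ids), 0)),
            P_orth=np.column_stack(P_o) if P_o else np.zeros((J, 0)),
            b=b,
            y_mean=self.y_mean,
            r2y=r2y,
            r2x_pred=r2x_pred,
            r2x_orth=r2x_orth,
            y_kind=self.y_kind,
            class_map=dict(self.class_map) if self.class_map else None,
            var_ids=list(self.var_ids),
        )


class OPLSDA(OPLS):
    """Two-class discriminant OPLS: class labels become a 0/1 response."""

    y_kind = "two_class"

    def __init__(self, labels, exog, n_orth: int = 0, class_map: dict[str, float] | None = None) -> None:
        labels = [str(l) for l in np.asarray(labels).ravel()]
        classes = sorted(set(labels))
        if len(classes) != 2:
            raise NotImplementedError(
                f"OPLS-DA handles exactly two classes, got {len(classes)}"
            )
        if class_map is None:
            class_map = {classes[0]: 0.0, classes[1]: 1.0}
        if sorted(class_map) != classes:
            raise ValueError("class_map does not match the observed labels")
        for c in classes:
            if labels.count(c) < 2:
                raise DegenerateYError(f"class {c!r} has fewer than 2 samples")
        y = np.array([class_map[l] for l in labels])
        super().__init__(y, exog, n_orth)
        self.class_map = class_map


def encode_two_class(labels, class_map: dict[str, float] | None = None) -> np.ndarray:
    """Encode a two-class label vector as 0/1 (sorted label order by default)."""
    labels = [str(l) for l in np.asarray(labels).ravel()]
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise NotImplementedError("exactly two classes required")
    if class_map is None:
        class_map = {classes[0]: 0.0, classes[1]: 1.0}
    return np.array([class_map[l] for l in labels])


@dataclass
class OPLSResults:
    """Fitted OPLS(-DA) model: weights, scores, loadings and fit shares."""

    w_pred: pd.Series
    t_pred: pd.Series
    p_pred: pd.Series
    W_orth: np.ndarray
    T_orth: np.ndarray
    P_orth: np.ndarray
    b: float
    y_mean: float
    r2y: float
    r2x_pred: float
    r2x_orth: float
    y_kind: str
    class_map: dict[str, float] | None
    var_ids: list[str] = field(default_factory=list)

    @property
    def n_orth(self) -> int:
        return self.W_orth.shape[1]

    def vip(self) -> pd.Series:
        """Variable importance in projection.

        With the single predictive component kept here, ``VIP_j =
        sqrt(J) * |w_pred_j|`` (w_pred has unit norm), so the mean squared
        VIP over variables is exactly 1.
        """
        J = len(self.w_pred)
        return pd.Series(
            np.sqrt(J) * np.abs(self.w_pred.to_numpy()),
            index=self.w_pred.index,
            name="VIP",
        )

    def _filter(self, X_new: np.ndarray) -> np.ndarray:
        Xf = X_new.copy()
        for a in range(self.n_orth):
            t_o = Xf @ self.W_orth[:, a]
            Xf = Xf - np.outer(t_o, self.P_orth[:, a])
        return Xf

    def predict(self, X_new) -> tuple[np.ndarray, np.ndarray]:
        """Predict responses for new rows scaled like the training matrix.

        Returns ``(yhat, t_pred_new)``; for a two-class model ``yhat`` also
        decodes to labels via :meth:`classify`.
        """
        arr, _, cols = _as_matrix(X_new)
        if arr.shape[1] != len(self.w_pred):
            raise ShapeError(
                f"X_new has {arr.shape[1]} columns, model expects {len(self.w_pred)}"
            )
        t_new = self._filter(arr) @ self.w_pred.to_numpy()
        yhat = self.b * t_new + self.y_mean
        return yhat, t_new

    def classify(self, X_new) -> list[str]:
        """Nearest-encoded-value class decoding (two-class models only)."""
        if self.y_kind != "two_class" or not self.class_map:
            raise ValueError("classify() requires a two-class model")
        yhat, _ = self.predict(X_new)
        inv = {v: k for k, v in self.class_map.items()}
        codes = np.array(sorted(inv))
        out = []
        for v in yhat:
            out.append(inv[float(codes[np.argmin(np.abs(codes - v))])])
        return out

    def fitted_values(self) -> pd.Series:
        return pd.Series(
            self.b * self.t_pred.to_numpy() + self.y_mean,
            index=self.t_pred.index,
            name="yhat",
        )

    def summary(self) -> str:
        kind = "OPLS-DA" if self.y_kind == "two_class" else "OPLS"
        lines = [
            f"{kind} results",
            f"  samples:               {len(self.t_pred)}",
            f"  variables:             {len(self.w_pred)}",
            f"  orthogonal components: {self.n_orth}",
            f"  R2Y  = {self.r2y:.4f}",
            f"  R2X(pred) = {self.r2x_pred:.4f}",
            f"  R2X(orth) = {self.r2x_orth:.4f}",
        ]
        if self.class_map:
            lines.append(f"  classes: {self.class_map}")
        vip = self.vip().sort_values(ascending=False).head(5)
        lines.append("  top VIP: " + ", ".join(f"{m}={v:.2f}" for m, v in vip.items()))
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------
    def to_json(self, provenance: str | None = None) -> str:
        return json.dumps(
            {
                "y_kind": self.y_kind,
                "class_map": self.class_map,
                "b": self.b,
                "y_mean": self.y_mean,
                "r2y": self.r2y,
                "r2x_pred": self.r2x_pred,
                "r2x_orth": self.r2x_orth,
                "var_ids": self.var_ids,
                "sample_ids": list(self.t_pred.index),
                "w_pred": self.w_pred.to_numpy().tolist(),
                "t_pred": self.t_pred.to_numpy().tolist(),
                "p_pred": self.p_pred.to_numpy().tolist(),
                "W_orth": self.W_orth.tolist(),
                "T_orth": self.T_orth.tolist(),
                "P_orth": self.P_orth.tolist(),
                "provenance": provenance,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "OPLSResults":
        d = json.loads(text)
        var_ids = d["var_ids"]
        sample_ids = d["sample_ids"]
        J, n = len(var_ids), len(sample_ids)
        return cls(
            w_pred=pd.Series(d["w_pred"], index=var_ids, name="w_pred"),
            t_pred=pd.Series(d["t_pred"], index=sample_ids, name="t_pred"),
            p_pred=pd.Series(d["p_pred"], index=var_ids, name="p_pred"),
            W_orth=np.asarray(d["W_orth"]).reshape(J, -1),
            T_orth=np.asarray(d["T_orth"]).reshape(n, -1),
            P_orth=np.asarray(d["P_orth"]).reshape(J, -1),
            b=d["b"],
            y_mean=d["y_mean"],
            r2y=d["r2y"],
            r2x_pred=d["r2x_pred"],
            r2x_orth=d["r2x_orth"],
            y_kind=d["y_kind"],
            class_map=d["class_map"],
            var_ids=var_ids,
        )


def table_hash(frame: pd.DataFrame) -> str:
    """Stable provenance hash of a data table."""
    h = hashlib.sha256()
    h.update(",".join(map(str, frame.columns)).encode())
    h.update(",".join(map(str, frame.index)).encode())
    h.update(np.ascontiguousarray(frame.to_numpy(dtype=float)).tobytes())
    return h.hexdigest()


def opls_fit(X, y, n_orth: int = 0) -> OPLSResults:
    """Functional wrapper: ``OPLS(y, X, n_orth).fit()``."""
    return OPLS(y, X, n_orth).fit()


def oplsda_fit(X, labels, n_orth: int = 0, class_map: dict[str, float] | None = None) -> OPLSResults:
    """Functional wrapper: ``OPLSDA(labels, X, n_orth).fit()``."""
    return OPLSDA(labels, X, n_orth, class_map).fit()
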