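"""Model validation: cross-validated Q², permutation null, CV-ANOVA, and the
univariate statistics used for signature construction.

The guiding rule is strictness: centering and scaling are recomputed inside
every cross-validation training split, so no information from held-out
samples leaks into the model they are predicted with. Q²Y_cum is
``1 - PRESS/SSY`` with PRESS accumulated over out-of-fold predictions and SSY
the total response variation about its grand mean; under the null it is
negatively biased, which is exactly why a clearly positive Q² is evidence of
real structure.

A model passes the low-overfit verdict when Q²Y_cum > 0.5, the mean
permuted Q² is negative, and the CV-ANOVA p-value is below 0.05.

Folds are assigned venetian-blind (sample i → fold i mod k after ordering by
sample id), the de-facto chemometrics default. CV-ANOVA follows the
published approximation with latent components as model degrees of freedom;
it is approximate and documented as such. The Mann-Whitney-Wilcoxon and
Spearman statistics are delegated to scipy behind this module's surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConstantMetaboliteError,
    DegenerateError,
    DegenerateYError,
    FoldDegenerateError,
)
from .latent import OPLS, _as_matrix

import warnings


def _venetian_folds(ids: list[str], k: int) -> list[np.ndarray]:
    order = np.argsort(np.asarray(ids, dtype=object))
    folds: list[list[int]] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(int(idx))
    return [np.array(f, dtype=int) for f in folds if f]


def _fold_scale(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centers = train.mean(axis=0)
    scales = train.std(axis=0, ddof=1)
    if np.any(scales <= 0):
        j = int(np.argmax(scales <= 0))
        raise ConstantMetaboliteError(f"zero variance in training fold, column {j}")
    return (train - centers) / scales, (test - centers) / scales


def kfold_q2(
    X,
    y,
    n_orth: int,
    k: int = 7,
    ids: list[str] | None = None,
) -> tuple[float, float, float, np.ndarray]:
    """Cross-validated Q²Y_cum for an OPLS model with ``n_orth`` components.

    ``X`` is the *unscaled* matrix: each training split is autoscaled on its
    own, the held-out rows are scaled with the training parameters, and the
    held-out response is predicted after orthogonal filtering. Returns
    ``(q2, press, ssy, out_of_fold_predictions)``.
    """
    arr, row_ids, _ = _as_matrix(X)
    if ids is None:
        ids = row_ids
    y = np.asarray(y, dtype=float).ravel()
    n = arr.shape[0]
    if y.shape[0] != n:
        raise ValueError("X and y have different n")
    if k < 2:
        raise ValueError("k must be >= 2")
    if np.var(y) == 0.0:
        raise DegenerateYError("constant response")
    if n < 2 * k:
        warnings.warn(f"n={n} < 2k={2 * k}; folds are very small", stacklevel=2)
    folds = _venetian_folds(list(ids), k)
    yhat = np.full(n, np.nan)
    for test_idx in folds:
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        y_train = y[mask]
        if np.var(y_train) == 0.0:
            raise FoldDegenerateError("zero response variance in a training fold")
        X_train, X_test = _fold_scale(arr[mask], arr[test_idx])
        res = OPLS(y_train, X_train, n_orth).fit()
        yhat[test_idx], _ = res.predict(X_test)
    press = float(np.sum((y - yhat) ** 2))
    ssy = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / ssy, press, ssy, yhat


def select_n_orth(X, y, max_orth: int = 5, k: int = 7, gain: float = 0.01,
                  ids: list[str] | None = None) -> int:
    """Smallest number of orthogonal components A such that the Q² gain from
    A+1 is below ``gain``, scanning A = 0..max_orth."""
    if max_orth < 0:
        raise ValueError("max_orth must be >= 0")
    q_prev, *_ = kfold_q2(X, y, 0, k, ids)
    for A in range(max_orth):
        try:
            q_next, *_ = kfold_q2(X, y, A + 1, k, ids)
        except Exception:
            return A
        if q_next - q_prev < gain:
            return A
        q_prev = q_next
    return max_orth


def permutation_test(
    X,
    y,
    n_orth: int,
    n_perm: int = 200,
    seed: int = 0,
    k: int = 7,
    ids: list[str] | None = None,
) -> tuple[list[float], float]:
    """Q² under random permutations of the response.

    Each permutation refits the full cross-validation (fold assignment is by
    sample id and therefore shared). The identity permutation may occur by
    chance and is reported as-is; its probability is negligible at any
    realistic n. Returns the permuted Q² list and its mean (the summary
    convention for Q²Y_cum-perm).
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    y = np.asarray(y, dtype=float).ravel()
    if np.var(y) == 0.0:
        raise DegenerateYError("constant response")
    rng = np.random.default_rng(seed)
    perm_q2 = []
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        q2, *_ = kfold_q2(X, y_perm, n_orth, k, ids)
        perm_q2.append(float(q2))
    return perm_q2, float(np.mean(perm_q2))


def cv_anova(press: float, ssy: float, n: int, model_df: int) -> tuple[float, float]:
    """CV-ANOVA F-test of a latent model against the null model.

    ``F = ((SSY - PRESS)/d1) / (PRESS/d2)`` with ``d1`` the number of fitted
    latent components (predictive + orthogonal) and ``d2 = n - d1 - 1``;
    the p-value is the upper tail of F(d1, d2). F is clipped at 0 when the
    model predicts worse than the mean (PRESS >= SSY).
    """
    if model_df < 1:
        raise ValueError("model_df must be >= 1")
    d1 = model_df
    d2 = n - model_df - 1
    if d2 <= 0:
        raise DegenerateError(f"non-positive denominator df (n={n}, model_df={model_df})")
    if press < 0 or ssy <= 0:
        raise ValueError("need press >= 0 and ssy > 0")
    if press == 0.0:
        return float("inf"), 0.0
    F = ((ssy - press) / d1) / (press / d2)
    if F < 0:
        F = 0.0
    return float(F), float(stats.f.sf(F, d1, d2))


@dataclass
class ValidationReport:
    """Cross-validation and permutation diagnostics for one OPLS(-DA) model."""

    q2y_cum: float
    press: float
    ssy: float
    n_folds: int
    n_orth_selected: int
    perm_q2: list[float] = field(default_factory=list)
    q2y_cum_perm: float = float("nan")
    cv_anova_F: float = float("nan")
    cv_anova_p: float = float("nan")

    def __post_init__(self) -> None:
        if abs(self.q2y_cum - (1.0 - self.press / self.ssy)) > 1e-12:
            raise ValueError("q2y_cum != 1 - press/ssy")

    @property
    def verdict(self) -> bool:
        """True iff the model meets the low-overfit criteria:
        Q²Y_cum > 0.5, mean permuted Q² < 0, CV-ANOVA p < 0.05."""
        return (
            self.q2y_cum > 0.5
            and self.q2y_cum_perm < 0.0
            and self.cv_anova_p < 0.05
        )

    def to_dict(self) -> dict:
        return {
            "q2y_cum": self.q2y_cum,
            "press": self.press,
            "ssy": self.ssy,
            "n_folds": self.n_folds,
            "n_orth_selected": self.n_orth_selected,
            "q2y_cum_perm": self.q2y_cum_perm,
            "cv_anova_F": self.cv_anova_F,
            "cv_anova_p": self.cv_anova_p,
            "n_perm": len(self.perm_q2),
            "verdict": self.verdict,
        }

    def summary(self) -> str:
        return "\n".join(
            [
                "Validation report",
                f"  Q2Y_cum      = {self.q2y_cum:.4f}   ({self.n_folds}-fold CV, "
                f"{self.n_orth_selected} orthogonal comp.)",
                f"  Q2Y_cum-perm = {self.q2y_cum_perm:.4f}   ({len(self.perm_q2)} permutations)",
                f"  CV-ANOVA     F = {self.cv_anova_F:.3g}, p = {self.cv_anova_p:.3g}",
                f"  verdict (low overfit): {self.verdict}",
            ]
        )


def validate_opls(
    X,
    y,
    k: int = 7,
    n_perm: int = 200,
    seed: int = 0,
    max_orth: int = 5,
    n_orth: int | None = None,
    ids: list[str] | None = None,
) -> ValidationReport:
    """Full validation pass: select the orthogonal-component count by CV,
    compute Q², the permutation null and CV-ANOVA."""
    if n_orth is None:
        n_orth = select_n_orth(X, y, max_orth=max_orth, k=k, ids=ids)
    q2, press, ssy, _ = kfold_q2(X, y, n_orth, k, ids)
    perm_q2, perm_mean = permutation_test(X, y, n_orth, n_perm=n_perm, seed=seed, k=k, ids=ids)
    n = _as_matrix(X)[0].shape[0]
    F, p = cv_anova(press, ssy, n, model_df=1 + n_orth)
    return ValidationReport(
        q2y_cum=q2,
        press=press,
        ssy=ssy,
        n_folds=k,
        n_orth_selected=n_orth,
        perm_q2=perm_q2,
        q2y_cum_perm=perm_mean,
        cv_anova_F=F,
        cv_anova_p=p,
    )


# ---------------------------------------------------------------------------
# Univariate statistics
# ---------------------------------------------------------------------------

def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney-Wilcoxon test.

    Exact p by enumeration when the pooled sample is small (≤ 12) and tie
    free, otherwise the normal approximation with tie and continuity
    corrections. Reports ``min(U_a, U_b)`` so the statistic is symmetric in
    its arguments.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    small = a.size + b.size <= 12
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    u1 = float(res.statistic)
    u = min(u1, a.size * b.size - u1)
    return u, float(min(res.pvalue, 1.0))


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of average ranks).

    Returns NaN for a constant input vector; callers propagate it as a
    missing value in volcano outputs.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def spearman_profile(table: pd.DataFrame, y) -> pd.Series:
    """Spearman rho of every column against the response vector."""
    y = np.asarray(y, dtype=float).ravel()
    return pd.Series(
        {c: spearman(table[c].to_numpy(), y) for c in table.columns}, name="rho"
    )
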