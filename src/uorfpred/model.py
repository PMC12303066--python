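"""Interaction-term logistic model scoring 5'UTRs for stress-enhanced translation.

The score of a transcript is a logistic transform of an 11-term polynomial
in the four 5'UTR covariates A (uORF count), B (Atf4-like frame count),
C (length, nt) and D (%GC), including all six pairwise interactions:

    prescore = b0 + b1*A + b2*B + b3*C + b4*D
             + b5*A*B + b6*A*C + b7*A*D + b8*B*C + b9*B*D + b10*C*D
    score    = exp(prescore) / (1 + exp(prescore))

A transcript is called a positive hit when its score exceeds the threshold
(strictly; default 0.7) AND it carries at least one uORF — the mechanism
requires a uORF, so uORF-less transcripts never classify positive
regardless of score.

Training follows a 4-subset leave-one-out averaging protocol: the labeled
examples (pre-filtered to >= 1 uORF) are dealt into four class-stratified
subsets; each of the four groups of three subsets trains an unpenalized
logistic fit evaluated on the held-out subset; the final coefficients are
the element-wise mean of the four sub-model coefficient vectors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_COLUMNS, UTRFeatures

COEF_NAMES = (
    "beta0", "beta1_A", "beta2_B", "beta3_C", "beta4_D",
    "beta5_AB", "beta6_AC", "beta7_AD", "beta8_BC", "beta9_BD", "beta10_CD",
)

DEFAULT_THRESHOLD = 0.7


class SingleClassError(ValueError):
    """Training data contains only one class."""


class SubsetTooSmallError(ValueError):
    """A stratified subset lacks one of the two classes."""


@dataclass(frozen=True)
class CoefficientSet:
    """The 11 coefficients of the prescore polynomial, in formula order."""

    beta: tuple[float, ...]

    def __post_init__(self) -> None:
        beta = tuple(float(b) for b in self.beta)
        if len(beta) != 11:
            raise ValueError(f"expected 11 coefficients, got {len(beta)}")
        if not all(np.isfinite(beta)):
            raise ValueError("coefficients must be finite")
        object.__setattr__(self, "beta", beta)

    def to_json(self, path: str | Path, **metadata) -> None:
        payload = {"beta": list(self.beta), "names": list(COEF_NAMES), **metadata}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CoefficientSet":
        payload = json.loads(Path(path).read_text())
        return cls(beta=tuple(payload["beta"]))


@dataclass(frozen=True)
class Prediction:
    prescore: float
    score: float
    uorfs: int
    is_positive: bool


def interaction_design(X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Build the 11-column design: intercept, A, B, C, D and the six
    pairwise products A*B, A*C, A*D, B*C, B*D, C*D (raw, unstandardized)."""
    if isinstance(X, pd.DataFrame):
        X = X.loc[:, list(FEATURE_COLUMNS)].to_numpy()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 4:
        raise ValueError("expected an (n, 4) feature array ordered A, B, C, D")
    A, B, C, D = X.T
    return np.column_stack(
        [np.ones(len(X)), A, B, C, D, A * B, A * C, A * D, B * C, B * D, C * D]
    )


def prescore(
    f: UTRFeatures | Sequence[float], c: CoefficientSet
) -> float:
    """Evaluate the 11-term polynomial at one feature vector."""
    if isinstance(f, UTRFeatures):
        a, b, cc, d = f.as_tuple()
    else:
        a, b, cc, d = f
    row = np.array([[a, b, cc, d]], dtype=float)
    return float((interaction_design(row) @ np.asarray(c.beta))[0])


def score(f: UTRFeatures | Sequence[float], c: CoefficientSet) -> float:
    """Logistic transform of the prescore, overflow-safe, in (0, 1)."""
    from scipy.special import expit

    return float(expit(prescore(f, c)))


def classify(
    f: UTRFeatures | Sequence[float],
    c: CoefficientSet,
    threshold: float = DEFAULT_THRESHOLD,
) -> bool:
    """Positive hit: score strictly above threshold AND at least one uORF."""
    uorfs = f.uorfs if isinstance(f, UTRFeatures) else f[0]
    return score(f, c) > threshold and uorfs >= 1


def predict_one(
    f: UTRFeatures, c: CoefficientSet, threshold: float = DEFAULT_THRESHOLD
) -> Prediction:
    p = prescore(f, c)
    from scipy.special import expit

    s = float(expit(p))
    return Prediction(
        prescore=p,
        score=s,
        uorfs=f.uorfs,
        is_positive=s > threshold and f.uorfs >= 1,
    )


def fit_logistic(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | Sequence[int],
    ridge_alpha: float = 0.0,
) -> CoefficientSet:
    """Maximum-likelihood logistic fit on the 11-column interaction design.

    Unpenalized Newton/IRLS on raw features (tolerance 1e-8, at most 100
    iterations), so the coefficients apply directly to A, B, C in
    nucleotides and D in percent.  ``ridge_alpha > 0`` switches to an
    L2-penalized fit for mimicking library defaults.  Deterministic for a
    fixed input order.  Emits a non-convergence warning under
    quasi-separation instead of failing.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise SingleClassError("training data must contain both classes")
    design = interaction_design(X)
    if len(y) != len(design):
        raise ValueError("X and y length mismatch")
    if len(y) < 12:
        raise ValueError("need at least 12 examples to fit 11 coefficients")
    model = sm.Logit(y, design)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # re-raise our own warning below
        if ridge_alpha > 0:
            res = model.fit_regularized(
                alpha=ridge_alpha, L1_wt=0.0, maxiter=100, disp=0
            )
            converged = True
        else:
            res = model.fit(method="newton", tol=1e-8, maxiter=100, disp=0)
            converged = bool(res.mle_retvals.get("converged", True))
    if not converged:
        warnings.warn(
            "logistic fit did not converge (possible quasi-separation)",
            RuntimeWarning,
            stacklevel=2,
        )
    return CoefficientSet(beta=tuple(np.asarray(res.params, dtype=float)))


def stratified_subsets(
    y: np.ndarray, n_subsets: int, seed: int
) -> list[np.ndarray]:
    """Deal indices into class-stratified subsets.

    Within each class the indices are shuffled with the seeded generator
    and dealt round-robin, so subset class counts differ by at most one;
    remainder items land in the lowest-index subsets.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    buckets: list[list[int]] = [[] for _ in range(n_subsets)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            buckets[j % n_subsets].append(int(i))
    return [np.sort(np.array(b, dtype=int)) for b in buckets]


class TranslationTargetClassifier(ClassifierMixin, BaseEstimator):
    """Classifier for p-eIF2alpha-enhanced translation from 5'UTR features.

    Input ``X`` is an (n, 4) array or DataFrame of the covariates in the
    order A (uorfs), B (atf4like), C (length), D (gc_percent); ``y`` is
    binary (1 = translation enhanced under stress).  Training examples must
    already be filtered to transcripts with at least one uORF.

    Parameters
    ----------
    threshold : float, default 0.7
        Score cutoff; a hit needs score strictly above it and >= 1 uORF.
    cv_average : bool, default True
        Train four sub-models on the four leave-one-subset-out groups and
        average their coefficients; ``False`` fits once on all data.
    n_subsets : int, default 4
        Number of stratified subsets for the averaging protocol.
    ridge_alpha : float, default 0.0
        Optional L2 penalty; 0 gives the formula-faithful unpenalized MLE.
    random_state : int, default 0
        Seed for the stratified subset deal.

    Attributes
    ----------
    coefficients_ : CoefficientSet
        Final (averaged) coefficients.
    submodel_coefficients_ : list[CoefficientSet]
        Per-group coefficients (empty when ``cv_average=False``).
    fold_metrics_ : list[pandas.DataFrame]
        Held-out threshold-sweep metrics per group.
    classes_ : ndarray
        ``[0, 1]``.
    """

    def __init__(
        self,
        threshold: float = DEFAULT_THRESHOLD,
        cv_average: bool = True,
        n_subsets: int = 4,
        ridge_alpha: float = 0.0,
        random_state: int = 0,
    ):
        self.threshold = threshold
        self.cv_average = cv_average
        self.n_subsets = n_subsets
        self.ridge_alpha = ridge_alpha
        self.random_state = random_state

    def _validate(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            Xv = X.loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
        if Xv.ndim != 2 or Xv.shape[1] != 4:
            raise ValueError("X must be (n, 4): uorfs, atf4like, length, gc_percent")
        if not np.all(np.isfinite(Xv)):
            raise ValueError("X contains non-finite values")
        if y is None:
            return Xv
        yv = np.asarray(y).astype(int)
        if set(np.unique(yv)) - {0, 1}:
            raise ValueError("y must be binary 0/1")
        return Xv, yv

    def fit(self, X, y) -> "TranslationTargetClassifier":
        if not (0 <= self.threshold < 1):
            raise ValueError("threshold must be in [0, 1)")
        Xv, yv = self._validate(X, y)
        if len(np.unique(yv)) < 2:
            raise SingleClassError("training data must contain both classes")
        if np.any(Xv[:, 0] < 1):
            raise ValueError(
                "training examples must have at least one uORF "
                "(pre-filter the dataset to uorfs >= 1)"
            )
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 4
        if not self.cv_average:
            self.coefficients_ = fit_logistic(Xv, yv, ridge_alpha=self.ridge_alpha)
            self.submodel_coefficients_ = []
            self.fold_metrics_ = []
            return self

        subsets = stratified_subsets(yv, self.n_subsets, self.random_state)
        for k, sub in enumerate(subsets):
            if len(np.unique(yv[sub])) < 2:
                raise SubsetTooSmallError(f"subset {k} lacks a class")
        from .evaluation import threshold_sweep

        betas = []
        fold_metrics = []
        for held_out in range(self.n_subsets):
            train_idx = np.concatenate(
                [s for k, s in enumerate(subsets) if k != held_out]
            )
            test_idx = subsets[held_out]
            coefs = fit_logistic(
                Xv[train_idx], yv[train_idx], ridge_alpha=self.ridge_alpha
            )
            betas.append(coefs.beta)
            design = interaction_design(Xv[test_idx])
            from scipy.special import expit

            scores = expit(design @ np.asarray(coefs.beta))
            fold_metrics.append(
                threshold_sweep(scores, Xv[test_idx, 0], yv[test_idx])
            )
        self.submodel_coefficients_ = [CoefficientSet(beta=b) for b in betas]
        self.coefficients_ = CoefficientSet(
            beta=tuple(np.mean(np.asarray(betas), axis=0))
        )
        self.fold_metrics_ = fold_metrics
        self.subsets_ = subsets
        return self

    def decision_function(self, X) -> np.ndarray:
        """Prescore (log-odds) of each example."""
        check_is_fitted(self, "coefficients_")
        Xv = self._validate(X)
        return interaction_design(Xv) @ np.asarray(self.coefficients_.beta)

    def predict_proba(self, X) -> np.ndarray:
        from scipy.special import expit

        p1 = expit(self.decision_function(X))
        return np.column_stack([1 - p1, p1])

    def predict_score(self, X) -> np.ndarray:
        """The logistic score in (0, 1) — the model's published quantity."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        """1 for positive hits: score > threshold (strict) and uorfs >= 1."""
        Xv = self._validate(X)
        s = self.predict_score(Xv)
        return ((s > self.threshold) & (Xv[:, 0] >= 1)).astype(int)

    def save(self, path: str | Path, **metadata) -> None:
        check_is_fitted(self, "coefficients_")
        self.coefficients_.to_json(
            path,
            threshold=self.threshold,
            penalty="l2" if self.ridge_alpha > 0 else "none",
            seed=self.random_state,
            **metadata,
        )

    @classmethod
    def from_coefficients(
        cls, c: CoefficientSet, threshold: float = DEFAULT_THRESHOLD
    ) -> "TranslationTargetClassifier":
        est = cls(threshold=threshold)
        est.coefficients_ = c
        est.submodel_coefficients_ = []
        est.fold_metrics_ = []
        est.classes_ = np.array([0, 1])
        est.n_features_in_ = 4
        return est


def train(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | Sequence[int],
    seed: int = 0,
    ridge_alpha: float = 0.0,
) -> tuple[CoefficientSet, list[pd.DataFrame]]:
    """Run the 4-subset averaging protocol; thin functional wrapper around
    :class:`TranslationTargetClassifier`."""
    est = TranslationTargetClassifier(
        random_state=seed, ridge_alpha=ridge_alpha
    ).fit(X, y)
    return est.coefficients_, est.fold_metrics_
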