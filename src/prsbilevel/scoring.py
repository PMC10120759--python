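"""Group-wise PRS construction and cross-validated combination weights.

The final score is PRS = sum_k alpha_k PRS_k, where PRS_k scores only the
posterior effects of copies in annotation group k and the alpha_k are fitted
by 10-fold cross-validation on a separate individual-level validation set.
The hybrid variant adds gamma times an externally supplied conventional PRS
as one more regression column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold

from .datatypes import ExpandedDesign, PosteriorSummary, ValidationError
from .metrics import auc, efron_r2, r2

logger = logging.getLogger(__name__)


@dataclass
class GroupScores:
    """Per-individual group-wise PRS matrix (N x K)."""

    matrix: np.ndarray
    group_labels: list[str]
    individual_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[1] != len(self.group_labels):
            raise ValidationError("score matrix width != number of groups")
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("non-finite group scores")


@dataclass
class AlphaWeights:
    """Cross-validated combination weights (alpha per group, optional gamma)."""

    alpha: np.ndarray
    gamma: float | None = None
    intercept: float = 0.0
    fold_metrics: list[dict] = field(default_factory=list)


def group_scores(G: np.ndarray, post: PosteriorSummary,
                 design: ExpandedDesign | None = None,
                 individual_ids: list[str] | None = None) -> GroupScores:
    """PRS_k = sum over copies in group k of G_j * beta_tilde_{j,k}.

    Columns of G must align with the design's variants; summing the returned
    columns reproduces the total per-variant PRS.
    """
    design = design if design is not None else post.design
    G = np.asarray(G, dtype=float)
    if G.shape[1] != design.n_variants:
        raise ValidationError(
            f"G has {G.shape[1]} columns, design expects {design.n_variants}")
    k = design.n_groups
    # per-group effect vector on variants: scatter copy effects by group
    effects = np.zeros((design.n_variants, k))
    np.add.at(effects, (design.copy_variant, design.copy_group),
              post.beta_tilde_copies)
    return GroupScores(G @ effects, list(design.groups), individual_ids)


class GroupScoreCombiner(BaseEstimator):
    """Cross-validated linear combination of partitioned polygenic scores.

    Per fold, alpha is fitted on 9/10 of the validation samples by least
    squares (quantitative trait) or logistic maximum likelihood (binary) of
    the phenotype on the K score columns plus an intercept, and the held-out
    tenth is scored; the exported alpha is the across-fold mean. Constant
    score columns are dropped with a warning (their alpha is 0).

    Parameters
    ----------
    trait : "quantitative" or "binary"
    n_folds : number of CV folds (10 in the study design)
    nonnegative : constrain alpha >= 0 (quantitative traits only)
    random_state : seed for the fold permutation
    """

    def __init__(self, trait: str = "quantitative", n_folds: int = 10,
                 nonnegative: bool = False, random_state: int | None = None):
        self.trait = trait
        self.n_folds = n_folds
        self.nonnegative = nonnegative
        self.random_state = random_state

    def _fit_fold(self, X: np.ndarray, y: np.ndarray):
        if self.trait == "binary":
            model = LogisticRegression(C=np.inf, max_iter=1000)
            model.fit(X, y)
            return model.coef_.ravel(), float(model.intercept_[0])
        if self.nonnegative:
            design = np.column_stack([np.ones(len(X)), X])
            coef, _ = nnls(design, y)
            return coef[1:], float(coef[0])
        model = LinearRegression()
        model.fit(X, y)
        return model.coef_.ravel(), float(model.intercept_)

    def fit(self, scores: GroupScores | np.ndarray, y: np.ndarray,
            external: np.ndarray | None = None):
        """Fit fold-wise combination weights on validation data."""
        if isinstance(scores, GroupScores):
            X, labels = scores.matrix, list(scores.group_labels)
        else:
            X = np.atleast_2d(np.asarray(scores, dtype=float))
            labels = [f"g{i + 1}" for i in range(X.shape[1])]
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.size:
            raise ValidationError("scores and phenotype length mismatch")
        self.has_external_ = external is not None
        if self.has_external_:
            X = np.column_stack([X, np.asarray(external, dtype=float)])
            labels = labels + ["__external__"]
        n, k = X.shape
        if n < self.n_folds * max(k, 1):
            raise ValidationError(
                f"need at least {self.n_folds * k} samples for {k} columns")
        if self.trait not in ("quantitative", "binary"):
            raise ValidationError(f"unknown trait {self.trait!r}")

        keep = X.std(axis=0) > 0
        if not keep.all():
            dropped = [labels[i] for i in np.flatnonzero(~keep)]
            logger.warning("dropping constant score columns: %s", dropped)
        Xk = X[:, keep]

        if self.trait == "binary":
            splitter = StratifiedKFold(n_splits=self.n_folds, shuffle=True,
                                       random_state=self.random_state)
            split = splitter.split(Xk, y.astype(int))
        else:
            splitter = KFold(n_splits=self.n_folds, shuffle=True,
                             random_state=self.random_state)
            split = splitter.split(Xk)

        coefs, intercepts, fold_metrics = [], [], []
        for fold_id, (tr, te) in enumerate(split):
            coef, b0 = self._fit_fold(Xk[tr], y[tr])
            coefs.append(coef)
            intercepts.append(b0)
            pred = Xk[te] @ coef + b0
            rec: dict = {"fold": fold_id, "n": len(te)}
            if self.trait == "binary":
                prob = 1.0 / (1.0 + np.exp(-pred))
                if len(np.unique(y[te])) == 2:
                    rec["auc"] = auc(pred, y[te].astype(int))
                rec["efron_r2"] = efron_r2(prob, y[te])
            else:
                rec["r2"] = r2(pred, y[te]) if np.std(pred) > 0 else 0.0
            fold_metrics.append(rec)

        alpha = np.zeros(k)
        alpha[keep] = np.mean(coefs, axis=0)
        self.intercept_ = float(np.mean(intercepts))
        if self.has_external_:
            self.gamma_ = float(alpha[-1])
            alpha = alpha[:-1]
        else:
            self.gamma_ = None
        self.alpha_ = alpha
        self.fold_metrics_ = fold_metrics
        self.group_labels_ = labels[:-1] if self.has_external_ else labels
        return self

    def predict(self, scores: GroupScores | np.ndarray,
                external: np.ndarray | None = None) -> np.ndarray:
        """Combined score, sum_k alpha_k PRS_k (+ gamma * external)."""
        if not hasattr(self, "alpha_"):
            raise ValidationError("combiner is not fitted")
        X = scores.matrix if isinstance(scores, GroupScores) else \
            np.atleast_2d(np.asarray(scores, dtype=float))
        out = X @ self.alpha_ + self.intercept_
        if self.gamma_ is not None:
            if external is None:
                raise ValidationError("hybrid weights need the external score")
            out = out + self.gamma_ * np.asarray(external, dtype=float)
        return out

    def weights(self) -> AlphaWeights:
        return AlphaWeights(alpha=self.alpha_.copy(), gamma=self.gamma_,
                            intercept=self.intercept_,
                            fold_metrics=list(self.fold_metrics_))


def fit_alpha_cv(scores: GroupScores, y: np.ndarray, trait: str = "quantitative",
                 n_folds: int = 10, seed: int | None = None,
                 external: np.ndarray | None = None) -> AlphaWeights:
    """Functional wrapper over :class:`GroupScoreCombiner`."""
    combiner = GroupScoreCombiner(trait=trait, n_folds=n_folds,
                                  random_state=seed)
    combiner.fit(scores, y, external=external)
    return combiner.weights()


def combine(scores: GroupScores, w: AlphaWeights,
            external: np.ndarray | None = None,
            mode: str = "bils") -> np.ndarray:
    """Deterministic linear combination of group scores.

    mode "bils": sum_k alpha_k PRS_k; mode "hybrid" additionally requires the
    external conventional-method PRS and adds gamma times it.
    """
    if mode not in ("bils", "hybrid"):
        raise ValidationError(f"unknown mode {mode!r}")
    out = scores.matrix @ w.alpha
    if mode == "hybrid":
        if external is None:
            raise ValidationError("hybrid mode requires an external score")
        gamma = 0.0 if w.gamma is None else w.gamma
        out = out + gamma * np.asarray(external, dtype=float)
    return out
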