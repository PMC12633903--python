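"""Per-modality feature selection and nested feature-combination grids.

Selection is an L1-penalised (lasso) logistic regression of the binary
progression label on the modality's features, fitted *only* on training
rows (never validation or test — no leakage), with the penalty chosen by
5-fold cross-validated deviance on those same rows. Retained features are
ordered by decreasing |coefficient| and truncated to a per-modality cap.

The grid enumerator turns an ordered selection into the nested prefix
combinations used for the feature-combination sweeps (sizes 2..k, plus the
all-features combination of the source table).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV

__all__ = ["SelectedFeatures", "FeatureGrid", "lasso_select", "enumerate_feature_grid"]

_DEFAULT_CS = np.logspace(-2, 2, 9)


@dataclass(frozen=True)
class SelectedFeatures:
    """Ordered lasso picks for one modality (descending |coefficient|)."""

    modality: str
    feature_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    regularisation_c: float

    def __len__(self) -> int:
        return len(self.feature_names)


@dataclass(frozen=True)
class FeatureGrid:
    """Nested prefix combinations plus the all-features combination."""

    modality: str
    combinations: tuple[tuple[str, ...], ...]
    all_features_size: int


def _standardise(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Zero-mean unit-variance columns; returns (Xs, keep-mask).

    Constant columns cannot be standardised and carry no information for a
    linear fit; they are dropped with a warning.
    """
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    # sd of an exactly-constant column can come out ~1e-16 in floating point
    keep = sd > 1e-12 * (np.abs(mu) + 1.0)
    Xs = (X[:, keep] - mu[keep]) / sd[keep]
    return Xs, keep


def lasso_select(
    train_features,
    train_labels: np.ndarray,
    feature_names=None,
    modality: str = "unknown",
    max_k: int | None = None,
    fixed_c: float | None = None,
    cv: int = 5,
    seed: int = 0,
) -> SelectedFeatures:
    """Lasso-logistic selection on standardised training rows.

    ``train_features`` may be a :class:`~cmfp.cohort.ModalityTable` or an
    ndarray (then ``feature_names`` is required). The penalty strength is
    chosen by ``cv``-fold cross-validated deviance unless ``fixed_c``
    overrides it (``fixed_c`` is the inverse penalty, sklearn's ``C``).
    An all-zero fit returns an empty selection.
    """
    from .cohort import ModalityTable  # local import to avoid cycle at module load

    if isinstance(train_features, ModalityTable):
        X = train_features.values
        names = list(train_features.feature_names)
        modality = train_features.modality
    else:
        X = np.asarray(train_features, dtype=float)
        if feature_names is None:
            raise ValueError("feature_names required when passing a bare array")
        names = list(feature_names)
    y = np.asarray(train_labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("lasso_select needs both classes in train_labels")

    Xs, keep = _standardise(X)
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        warnings.warn(f"{modality}: dropping constant feature column(s) {dropped}")
    kept_names = [n for n, k in zip(names, keep) if k]

    if fixed_c is not None:
        model = LogisticRegression(
            l1_ratio=1.0, C=fixed_c, solver="liblinear", random_state=seed
        )
        model.fit(Xs, y)
        c_used = float(fixed_c)
    else:
        n_folds = min(cv, int(np.bincount(y).min()))
        if n_folds < 2:
            raise ValueError("too few samples per class for cross-validation")
        model = LogisticRegressionCV(
            l1_ratios=(1.0,),
            solver="liblinear",
            Cs=_DEFAULT_CS,
            cv=n_folds,
            scoring="neg_log_loss",
            random_state=seed,
            use_legacy_attributes=False,
        )
        model.fit(Xs, y)
        c_used = float(model.C_)

    coefs = model.coef_.ravel()
    nz = np.flatnonzero(coefs != 0.0)
    # descending |coef|; stable sort keeps source-column order on ties
    order = nz[np.argsort(-np.abs(coefs[nz]), kind="stable")]
    if max_k is not None:
        order = order[:max_k]
    return SelectedFeatures(
        modality=modality,
        feature_names=tuple(kept_names[i] for i in order),
        coefficients=tuple(float(coefs[i]) for i in order),
        regularisation_c=c_used,
    )


def select_with_fallback(
    table, labels: np.ndarray, max_k: int, seed: int = 0
) -> SelectedFeatures:
    """Lasso selection that never returns an empty feature list.

    If cross-validated lasso shrinks everything to zero (possible on an
    unlucky small resplit), retry at the weakest penalty in the path; if
    the fit is still all-zero, fall back to the first ``max_k`` source
    columns. Keeps the repeated-resplit training loop alive without
    touching validation or test rows.
    """
    sel = lasso_select(table, labels, max_k=max_k, seed=seed)
    if len(sel):
        return sel
    sel = lasso_select(table, labels, max_k=max_k, fixed_c=float(_DEFAULT_CS[-1]), seed=seed)
    if len(sel):
        return sel
    names = tuple(table.feature_names[:max_k])
    return SelectedFeatures(table.modality, names, (0.0,) * len(names), float("inf"))


def enumerate_feature_grid(
    selected: SelectedFeatures | None = None,
    full_feature_count: int = 0,
    ordered_features=None,
    modality: str | None = None,
) -> FeatureGrid:
    """Nested prefix combinations of an ordered feature list.

    Combinations are the prefixes of sizes 2..k of the ordered selection
    (so each is contained in the next), plus one "all features"
    combination standing for the untruncated source table. An explicit
    ``ordered_features`` list may replace the lasso ordering to reproduce
    a fixed published grid.
    """
    if ordered_features is not None:
        names = tuple(ordered_features)
        tag = modality or (selected.modality if selected else "unknown")
    elif selected is not None:
        names = selected.feature_names
        tag = selected.modality
    else:
        raise ValueError("provide selected features or an explicit ordered list")
    if len(names) < 2:
        raise ValueError("need at least 2 ordered features to build a grid")
    if full_feature_count < len(names):
        raise ValueError("full_feature_count smaller than the ordered list")
    combos = tuple(tuple(names[:i]) for i in range(2, len(names) + 1))
    return FeatureGrid(tag, combos, full_feature_count)
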