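"""Fold-internal preprocessing: SMOTE, standardization, LASSO selection, PCA.

The recipe is applied in the order SMOTE → standardize → LASSO → PCA, with
every statistic fitted on the (possibly augmented) training partition only
and then applied unchanged to validation data. The default scope is
per-fold, which guarantees the validation rows never influence any fitted
statistic; a global scope (fit once on the full table before
cross-validation) is also available because published feature counts are
often reported that way — it is the optimistic variant and is labelled as
such in reports.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .errors import ParameterError

logger = logging.getLogger(__name__)


class _quiet_sklearn(warnings.catch_warnings):
    """Silence scikit-learn's penalty-parameterization deprecation chatter."""

    def __enter__(self):
        out = super().__enter__()
        warnings.simplefilter("ignore", FutureWarning)
        warnings.filterwarnings("ignore", message=".*penalty is deprecated.*")
        return out

PCA_DIMS_DEFAULT = 16
SMOTE_NEIGHBORS_DEFAULT = 5

#: penalty grid searched by the internal LASSO cross-validation (inverse
#: regularization strengths; liblinear parameterization)
LASSO_C_GRID = np.logspace(-2.5, 2.5, 21)


@dataclass(frozen=True)
class PreprocessRecipe:
    """Configuration of the fold-internal preprocessing chain."""

    smote: bool = True
    smote_neighbors: int = SMOTE_NEIGHBORS_DEFAULT
    lasso_rule: str | float = "cv"  # "cv" = internal 5-fold AUC-maximizing; float = fixed C
    lasso_link: str = "logistic"  # or "linear" (L1 linear model on 0/1 labels)
    pca_dims: int = PCA_DIMS_DEFAULT
    scope: str = "per-fold"  # or "global"

    def __post_init__(self) -> None:
        if self.pca_dims < 1:
            raise ParameterError(f"pca_dims must be >= 1, got {self.pca_dims}")
        if self.smote_neighbors < 1:
            raise ParameterError(f"smote_neighbors must be >= 1, got {self.smote_neighbors}")
        if self.scope not in ("per-fold", "global"):
            raise ParameterError(f"scope must be 'per-fold' or 'global', got {self.scope!r}")
        if self.lasso_link not in ("logistic", "linear"):
            raise ParameterError(f"lasso_link must be 'logistic' or 'linear', got {self.lasso_link!r}")


@dataclass
class FittedPreprocessor:
    """Training-fold statistics: scaler parameters, selected features, PCA basis."""

    feature_subset: np.ndarray  # ordered indices retained by LASSO
    column_means: np.ndarray
    column_sds: np.ndarray  # zero-variance columns carry sd 1 (scale to 0)
    pca_basis: np.ndarray  # (len(feature_subset), effective_dims), orthonormal columns
    pca_center: np.ndarray
    explained_variance: np.ndarray
    effective_dims: int
    n_fit_rows: int = 0
    metadata: dict = field(default_factory=dict)


def smote_oversample(
    X_train: np.ndarray,
    y_train: np.ndarray,
    neighbors: int = SMOTE_NEIGHBORS_DEFAULT,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Equalize class counts by synthetic minority oversampling.

    Each synthetic point is ``x_i + u * (x_nn - x_i)`` with ``u ~ U(0, 1)``
    and ``x_nn`` one of x_i's ``neighbors`` nearest minority-class
    neighbors (Euclidean). Applied to the training partition of a fold
    only — never to validation rows.
    """
    X = np.asarray(X_train, dtype=np.float64)
    y = np.asarray(y_train)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ParameterError("SMOTE requires two classes in the training data")
    if classes.size > 2:
        raise ParameterError(f"SMOTE supports binary labels, got {classes.size} classes")
    if counts[0] == counts[1]:
        return X, y
    rng = np.random.default_rng(seed)
    minority = classes[np.argmin(counts)]
    X_min = X[y == minority]
    n_new = int(abs(counts[0] - counts[1]))
    if len(X_min) == 1:
        warnings.warn(
            "minority class has a single sample; SMOTE falls back to duplication",
            UserWarning,
            stacklevel=2,
        )
        synth = np.repeat(X_min, n_new, axis=0)
    else:
        k = min(neighbors, len(X_min) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
        # column 0 is the point itself
        nbr_idx = nn.kneighbors(X_min, return_distance=False)[:, 1:]
        base = rng.integers(0, len(X_min), size=n_new)
        pick = rng.integers(0, k, size=n_new)
        u = rng.random(n_new)
        partner = nbr_idx[base, pick]
        synth = X_min[base] + u[:, None] * (X_min[partner] - X_min[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out


def fit_standardizer(X_train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column mean and SD on training data; zero-variance SDs become 1.

    Constant columns can carry a tiny nonzero float SD from summation
    round-off, so near-zero SDs (relative to the column mean) are treated
    as zero variance; those columns scale to ≈0 instead of blowing up.
    """
    X = np.asarray(X_train, dtype=np.float64)
    means = X.mean(axis=0)
    sds = X.std(axis=0)  # population SD, matching the usual scaler convention
    constant = sds < 1e-10 * np.maximum(np.abs(means), 1.0)
    sds = np.where(constant, 1.0, sds)
    return means, sds


def apply_standardizer(X: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    return (np.asarray(X, dtype=np.float64) - means) / sds


def _binary01(y: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    if classes.size != 2:
        raise ParameterError(f"binary labels required, got classes {classes}")
    return (y == classes[1]).astype(int)


def lasso_select(
    X: np.ndarray,
    y: np.ndarray,
    rule: str | float = "cv",
    seed: int | None = None,
    link: str = "logistic",
) -> np.ndarray:
    """Indices of features with non-zero coefficients under an L1 penalty.

    ``rule="cv"`` picks the penalty by internal 5-fold cross-validation
    maximizing ROC AUC; a float fixes the inverse penalty strength C. The
    binary outcome is modelled with L1-penalized logistic regression by
    default (``link="linear"`` fits an L1 linear model on 0/1 labels
    instead). If the chosen penalty shrinks every coefficient to zero, the
    weakest penalty on the grid that retains at least one feature is used
    and a warning is logged.
    """
    X = np.asarray(X, dtype=np.float64)
    y01 = _binary01(np.asarray(y))

    if link == "linear":
        from sklearn.linear_model import Lasso, LassoCV

        if rule == "cv":
            model = LassoCV(cv=5, random_state=seed).fit(X, y01)
            coef = model.coef_
        else:
            coef = Lasso(alpha=1.0 / (2 * len(y01) * float(rule))).fit(X, y01).coef_
        selected = np.flatnonzero(coef != 0.0)
        if selected.size == 0:
            selected = _lasso_fallback(X, y01, seed, link)
        return selected

    if rule == "cv":
        n_min = int(np.bincount(y01).min())
        cv = StratifiedKFold(n_splits=min(5, max(2, n_min)), shuffle=True, random_state=seed)
        with _quiet_sklearn():
            model = LogisticRegressionCV(
                Cs=LASSO_C_GRID,
                penalty="l1",
                solver="liblinear",
                scoring="roc_auc",
                cv=cv,
                max_iter=1000,
                random_state=seed,
            ).fit(X, y01)
        coef = model.coef_.ravel()
    else:
        with _quiet_sklearn():
            model = LogisticRegression(
                penalty="l1", C=float(rule), solver="liblinear", max_iter=1000, random_state=seed
            ).fit(X, y01)
        coef = model.coef_.ravel()
    selected = np.flatnonzero(coef != 0.0)
    if selected.size == 0:
        selected = _lasso_fallback(X, y01, seed, link)
    return selected


def _lasso_fallback(X: np.ndarray, y01: np.ndarray, seed: int | None, link: str) -> np.ndarray:
    """Walk the penalty path from strong to weak until >= 1 feature survives."""
    logger.warning("LASSO selected no features at the chosen penalty; relaxing along the path")
    for C in LASSO_C_GRID:
        if link == "linear":
            from sklearn.linear_model import Lasso

            coef = Lasso(alpha=1.0 / (2 * len(y01) * C)).fit(X, y01).coef_
        else:
            with _quiet_sklearn():
                coef = (
                    LogisticRegression(
                        penalty="l1", C=C, solver="liblinear", max_iter=1000, random_state=seed
                    )
                    .fit(X, y01)
                    .coef_.ravel()
                )
        selected = np.flatnonzero(coef != 0.0)
        if selected.size:
            return selected
    logger.warning("no penalty on the grid retained a feature; keeping all columns")
    return np.arange(X.shape[1])


def fit_pca(X_selected: np.ndarray, dims: int = PCA_DIMS_DEFAULT) -> PCA:
    """Fit a PCA basis on (standardized) training data.

    The number of retained components is ``min(dims, rank, n_features,
    n_samples)`` — a 16-dimensional target with fewer selected features or
    a rank-deficient training matrix keeps what exists.
    """
    X = np.asarray(X_selected, dtype=np.float64)
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    n_comp = max(1, min(dims, rank, X.shape[1], X.shape[0]))
    return PCA(n_components=n_comp, svd_solver="full").fit(X)


def apply_pca(X: np.ndarray, pca: PCA) -> np.ndarray:
    return pca.transform(np.asarray(X, dtype=np.float64))


def fit_preprocessor(
    X_train: np.ndarray,
    y_train: np.ndarray,
    recipe: PreprocessRecipe,
    seed: int | None = None,
) -> tuple[FittedPreprocessor, np.ndarray, np.ndarray]:
    """Run the full chain on a training partition.

    Returns the fitted preprocessor plus the transformed (and possibly
    SMOTE-augmented) training matrix and labels, ready for model training.
    """
    X = np.asarray(X_train, dtype=np.float64)
    y = np.asarray(y_train)
    n_fit_rows = X.shape[0]
    if recipe.smote:
        X, y = smote_oversample(X, y, neighbors=recipe.smote_neighbors, seed=seed)
    means, sds = fit_standardizer(X)
    Z = apply_standardizer(X, means, sds)
    subset = lasso_select(Z, y, rule=recipe.lasso_rule, seed=seed, link=recipe.lasso_link)
    pca = fit_pca(Z[:, subset], dims=recipe.pca_dims)
    fitted = FittedPreprocessor(
        feature_subset=subset,
        column_means=means,
        column_sds=sds,
        pca_basis=pca.components_.T.copy(),
        pca_center=pca.mean_.copy(),
        explained_variance=pca.explained_variance_.copy(),
        effective_dims=int(pca.n_components_),
        n_fit_rows=n_fit_rows,
        metadata={"n_selected": int(subset.size), "smote": recipe.smote},
    )
    return fitted, transform(X, fitted), y


def transform(X: np.ndarray, fitted: FittedPreprocessor) -> np.ndarray:
    """Apply training-fold statistics to any matrix (validation or training)."""
    Z = apply_standardizer(X, fitted.column_means, fitted.column_sds)
    Zs = Z[:, fitted.feature_subset]
    return (Zs - fitted.pca_center) @ fitted.pca_basis
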