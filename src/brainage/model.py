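"""Brain-age estimation: LASSO feature selection + multiple linear regression.

The estimator follows the standard brain-age design. Features are
preprocessed with training-set statistics (see :mod:`brainage.preprocess`),
an L1-penalized regression (LASSO) on the normalized features selects the
age-related subset, and an ordinary multiple linear regression (MLR) on the
selected features predicts age in years. Accuracy in controls is measured
by leave-one-out cross-validation (LOOCV): each subject's brain age (BA) is
predicted by a model trained on the remaining n-1 controls. Patients are
scored by the model trained on *all* controls.

Two LOOCV placements of the selection step are supported:

* ``nested`` (default): confound removal, normalization, selection and the
  MLR are all refitted inside every fold — leakage-free.
* ``pooled``: preprocessing and selection are fitted once on the full
  training set and only the MLR is cross-validated. This reproduces the
  single-selected-set variant common in the applied literature (optimistic,
  since the held-out subject influenced selection) and admits the exact
  closed-form leave-one-out identity for OLS, making it cheap enough to
  re-run inside permutation tests.

:class:`BrainAgeModel` / :class:`BrainAgeResults` present the procedure in
the model/results idiom; the module-level functions are the underlying
operations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats as _sps
from sklearn.linear_model import Lasso, LassoCV

from .preprocess import Preprocessor
from .table import FeatureTable

__all__ = [
    "PipelineConfig",
    "SelectionResult",
    "OLSFit",
    "FittedBrainAgeModel",
    "AccuracyReport",
    "select_features",
    "fit_mlr",
    "predict_mlr",
    "loocv_predict",
    "accuracy",
    "rank_weights",
    "fit_pipeline",
    "BrainAgeModel",
    "BrainAgeResults",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the estimation pipeline.

    alpha : float or "cv"
        L1 penalty strength on z-scored features (default 0.3); ``"cv"``
        selects it by cross-validation over a log grid.
    selection : {"nested", "pooled"}
        Placement of the selection step relative to the LOOCV loop.
    rank_policy : {"error", "pinv"}
        What to do when the selected design is rank-deficient.
    """

    alpha: float | str = 0.3
    selection: str = "nested"
    preprocess_order: tuple[str, ...] = ("gender", "zscore")
    ddof: int = 1
    degenerate_policy: str = "drop"
    lasso_tol: float = 1e-6
    lasso_max_iter: int = 10000
    cv_alphas: tuple[float, ...] = tuple(np.logspace(-3, 1, 30).tolist())
    cv_folds: int = 5
    rank_policy: str = "error"

    def __post_init__(self) -> None:
        if self.selection not in ("nested", "pooled"):
            raise ValueError("selection must be 'nested' or 'pooled'")
        if self.rank_policy not in ("error", "pinv"):
            raise ValueError("rank_policy must be 'error' or 'pinv'")
        if isinstance(self.alpha, str) and self.alpha != "cv":
            raise ValueError("alpha must be a positive float or 'cv'")
        if not isinstance(self.alpha, str) and self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the L1 selection step: the surviving features."""

    feature_names: tuple[str, ...]  # input features, canonical order
    coef: np.ndarray                # LASSO coefficient per input feature
    alpha_used: float
    mode: str                       # "fixed-alpha" | "cv-alpha"

    @property
    def selected_names(self) -> tuple[str, ...]:
        return tuple(n for n, c in zip(self.feature_names, self.coef) if c != 0.0)

    @property
    def selected_idx(self) -> np.ndarray:
        return np.flatnonzero(self.coef != 0.0)

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.coef))


def select_features(
    X: np.ndarray,
    y: np.ndarray,
    feature_names,
    alpha: float | str = 0.3,
    config: PipelineConfig | None = None,
) -> SelectionResult:
    """L1-penalized selection of age-related features.

    ``X`` is the normalized training design (n x p), ``y`` chronological age.
    With a numeric ``alpha`` the penalty is fixed; ``alpha="cv"`` picks it by
    k-fold cross-validation over a log-spaced grid. An empty selection is
    legal (downstream regression then predicts the training mean).
    """
    cfg = config or PipelineConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("selection needs at least 2 training rows")
    if not np.isfinite(y).all():
        raise ValueError("non-finite age labels")
    if alpha == "cv":
        est = LassoCV(
            alphas=np.asarray(cfg.cv_alphas),
            cv=cfg.cv_folds,
            tol=cfg.lasso_tol,
            max_iter=cfg.lasso_max_iter,
        ).fit(X, y)
        return SelectionResult(
            tuple(feature_names), est.coef_.copy(), float(est.alpha_), "cv-alpha"
        )
    est = Lasso(
        alpha=float(alpha), tol=cfg.lasso_tol, max_iter=cfg.lasso_max_iter
    ).fit(X, y)
    return SelectionResult(
        tuple(feature_names), est.coef_.copy(), float(alpha), "fixed-alpha"
    )


@dataclass(frozen=True)
class OLSFit:
    """Ordinary least-squares fit: intercept plus per-feature weights
    (years per z-scored feature unit)."""

    intercept: float
    weights: np.ndarray
    feature_names: tuple[str, ...]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.weights.size == 0:
            return np.full(X.shape[0], self.intercept)
        return self.intercept + X @ self.weights


def fit_mlr(
    X_selected: np.ndarray,
    y: np.ndarray,
    feature_names=(),
    rank_policy: str = "error",
) -> OLSFit:
    """OLS of age on the selected features.

    Zero selected features gives the intercept-only model (predicts the
    training mean). A rank-deficient design raises by default; under
    ``rank_policy="pinv"`` the minimum-norm solution is returned.
    """
    X = np.asarray(X_selected, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape if X.ndim == 2 else (X.shape[0], 0)
    if k == 0:
        return OLSFit(float(y.mean()), np.empty(0), tuple(feature_names))
    if n <= k and rank_policy == "error":
        raise ValueError(
            f"OLS is ill-posed: {n} training rows for {k} features + intercept"
        )
    A = np.column_stack([np.ones(n), X])
    if rank_policy == "error":
        rank = np.linalg.matrix_rank(A)
        if rank < k + 1:
            raise np.linalg.LinAlgError(
                f"rank-deficient design (rank {rank} < {k + 1}); "
                "set rank_policy='pinv' to fit anyway"
            )
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return OLSFit(float(beta[0]), beta[1:], tuple(feature_names))


def predict_mlr(fit: OLSFit, X: np.ndarray) -> np.ndarray:
    return fit.predict(X)


@dataclass(frozen=True)
class AccuracyReport:
    """Agreement between predicted brain age and chronological age."""

    mae: float     # years
    rmse: float    # years
    pearson_r: float
    r2: float      # 1 - SSE/SST; may be negative
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def accuracy(ba: np.ndarray, ca: np.ndarray) -> AccuracyReport:
    """MAE, rMSE, Pearson r and R^2 = 1 - SSE/SST of predictions vs age.

    SSE is taken about the predictions and SST about the mean age, so R^2
    can be negative for predictions worse than the mean. Requires n >= 2 and
    non-zero age variance (otherwise r and R^2 are undefined).
    """
    ba = np.asarray(ba, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if ba.shape != ca.shape or ba.ndim != 1:
        raise ValueError("BA and CA must be equal-length 1-D vectors")
    if len(ba) < 2:
        raise ValueError("accuracy needs n >= 2")
    if not (np.isfinite(ba).all() and np.isfinite(ca).all()):
        raise ValueError("non-finite values in BA or CA")
    err = ba - ca
    sst = float(np.sum((ca - ca.mean()) ** 2))
    if sst == 0:
        raise ValueError("zero variance in CA: r and R^2 undefined")
    if np.std(ba) == 0:
        r = 0.0  # constant predictions carry no linear association
    else:
        r = float(_sps.pearsonr(ba, ca).statistic)
    return AccuracyReport(
        mae=float(np.mean(np.abs(err))),
        rmse=float(np.sqrt(np.mean(err**2))),
        pearson_r=r,
        r2=1.0 - float(np.sum(err**2)) / sst,
        n=len(ba),
    )


@dataclass(frozen=True)
class FittedBrainAgeModel:
    """A complete fitted pipeline: preprocessing, selection, regression."""

    preprocessor: Preprocessor
    selection: SelectionResult
    ols: OLSFit
    train_ids: tuple[str, ...]
    config: PipelineConfig = field(repr=False, default_factory=PipelineConfig)

    def predict(self, table: FeatureTable) -> np.ndarray:
        """Brain age (years) for every row of ``table``."""
        z = self.preprocessor.transform(table)
        X = z.values()[:, _indices_of(z.feature_names, self.selection)]
        return self.ols.predict(X)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.config).items()
            },
            "train_ids": list(self.train_ids),
            "selection": {
                "feature_names": list(self.selection.feature_names),
                "coef": self.selection.coef.tolist(),
                "alpha_used": self.selection.alpha_used,
                "mode": self.selection.mode,
            },
            "ols": {
                "intercept": self.ols.intercept,
                "weights": self.ols.weights.tolist(),
                "feature_names": list(self.ols.feature_names),
            },
            "preprocessor": {
                "confound": (
                    self.preprocessor.confound.to_dict()
                    if self.preprocessor.confound else None
                ),
                "norm_stats": (
                    self.preprocessor.norm_stats.to_dict()
                    if self.preprocessor.norm_stats else None
                ),
            },
        }
        Path(path).write_text(json.dumps(payload))


def _indices_of(available: tuple[str, ...], selection: SelectionResult) -> np.ndarray:
    pos = {n: j for j, n in enumerate(available)}
    try:
        return np.asarray([pos[n] for n in selection.selected_names], dtype=int)
    except KeyError as e:
        raise ValueError(f"selected feature {e.args[0]!r} absent after preprocessing")


def fit_pipeline(
    train: FeatureTable, config: PipelineConfig | None = None
) -> FittedBrainAgeModel:
    """Fit confound removal, normalization, selection and MLR on ``train``."""
    cfg = config or PipelineConfig()
    pp = Preprocessor(
        order=cfg.preprocess_order, ddof=cfg.ddof, degenerate_policy=cfg.degenerate_policy
    )
    z = pp.fit_transform(train)
    y = train.age
    sel = select_features(z.values(), y, z.feature_names, alpha=cfg.alpha, config=cfg)
    idx = _indices_of(z.feature_names, sel)
    ols = fit_mlr(
        z.values()[:, idx], y, feature_names=sel.selected_names,
        rank_policy=cfg.rank_policy,
    )
    return FittedBrainAgeModel(pp, sel, ols, tuple(train.subject_ids), cfg)


def _loocv_pooled(table: FeatureTable, cfg: PipelineConfig) -> np.ndarray:
    """Exact leave-one-out predictions of the pooled-selection variant.

    With preprocessing and selection fixed from the full set, the fold models
    are plain OLS refits, so the leave-one-out prediction is available in
    closed form from the hat matrix: yhat_(-i) = y_i - e_i / (1 - h_ii).
    """
    model = fit_pipeline(table, cfg)
    z = model.preprocessor.transform(table)
    idx = _indices_of(z.feature_names, model.selection)
    X = z.values()[:, idx]
    y = table.age
    n = len(y)
    A = np.column_stack([np.ones(n), X])
    # hat diagonal via least-squares solve; pinv covers the deficient case
    G = np.linalg.pinv(A.T @ A)
    H = np.einsum("ij,jk,ik->i", A, G, A)
    resid = y - A @ (G @ (A.T @ y))
    denom = 1.0 - H
    if np.any(denom < 1e-10):
        raise ValueError("leverage ~ 1: a subject is uniquely determining its fold")
    return y - resid / denom


def loocv_predict(
    table: FeatureTable, config: PipelineConfig | None = None
) -> np.ndarray:
    """Out-of-fold brain-age prediction for every subject in ``table``.

    Under ``nested`` selection each fold refits the full pipeline on the
    other n-1 subjects; under ``pooled`` the closed-form OLS identity is
    used (see module docstring). Errors in a fold are re-raised with the
    fold index attached.
    """
    cfg = config or PipelineConfig()
    n = table.n_subjects
    if n < 3:
        raise ValueError("LOOCV needs at least 3 subjects")
    if cfg.selection == "pooled":
        return _loocv_pooled(table, cfg)
    out = np.empty(n)
    all_idx = np.arange(n)
    for i in range(n):
        try:
            fold_train = table.select_rows(all_idx != i)
            model = fit_pipeline(fold_train, cfg)
            out[i] = model.predict(table.select_rows(all_idx == i))[0]
        except Exception as e:
            raise type(e)(f"LOOCV fold {i}: {e}") from e
    return out


def rank_weights(
    model: FittedBrainAgeModel | OLSFit, k: int | None = None
) -> list[tuple[str, float]]:
    """Top-k (feature, signed weight) pairs, ranked by |weight| descending.

    Ties are broken by the canonical feature order; ``k`` beyond the number
    of selected features returns them all.
    """
    ols = model.ols if isinstance(model, FittedBrainAgeModel) else model
    pairs = list(zip(ols.feature_names, ols.weights))
    order = sorted(range(len(pairs)), key=lambda j: (-abs(pairs[j][1]), j))
    ranked = [(pairs[j][0], float(pairs[j][1])) for j in order]
    return ranked if k is None else ranked[: max(k, 0)]


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------

class BrainAgeModel:
    """Brain-age estimator built from a control cohort.

    Parameters
    ----------
    nc_table : FeatureTable
        The control (NC) cohort the model is trained and cross-validated on.
    config : PipelineConfig, optional
        Pipeline settings (penalty strength, selection placement, ...).

    ``fit()`` runs the LOOCV evaluation and the final all-controls fit and
    returns a :class:`BrainAgeResults`.
    """

    def __init__(self, nc_table: FeatureTable, config: PipelineConfig | None = None):
        if (nc_table.group != "NC").any():
            raise ValueError("BrainAgeModel is trained on NC subjects only")
        self.nc_table = nc_table
        self.config = config or PipelineConfig()

    @classmethod
    def from_dataframe(cls, df, config: PipelineConfig | None = None):
        table = FeatureTable.from_dataframe(df)
        return cls(table.select_group("NC"), config)

    def fit(self) -> "BrainAgeResults":
        loocv_ba = loocv_predict(self.nc_table, self.config)
        final = fit_pipeline(self.nc_table, self.config)
        return BrainAgeResults(self, final, loocv_ba)


class BrainAgeResults:
    """Fitted brain-age model with its LOOCV evaluation in controls."""

    def __init__(
        self,
        model: BrainAgeModel,
        fitted: FittedBrainAgeModel,
        loocv_ba: np.ndarray,
    ):
        self.model = model
        self.fitted = fitted
        self.loocv_ba = loocv_ba
        self.loocv_accuracy = accuracy(loocv_ba, model.nc_table.age)

    @property
    def selected_features(self) -> tuple[str, ...]:
        return self.fitted.selection.selected_names

    @property
    def n_selected(self) -> int:
        return self.fitted.selection.n_selected

    def predict(self, table: FeatureTable) -> np.ndarray:
        """Brain age for new subjects from the all-controls model."""
        return self.fitted.predict(table)

    def top_weights(self, k: int = 20) -> list[tuple[str, float]]:
        return rank_weights(self.fitted, k)

    def summary(self) -> str:
        acc = self.loocv_accuracy
        lines = [
            "Brain-age model (LASSO selection + multiple linear regression)",
            f"  controls: n = {self.model.nc_table.n_subjects}",
            f"  penalty alpha = {self.fitted.selection.alpha_used:g} "
            f"({self.fitted.selection.mode}), selection {self.model.config.selection}",
            f"  selected features: {self.n_selected} of "
            f"{len(self.fitted.selection.feature_names)}",
            "  LOOCV accuracy in controls:",
            f"    MAE  = {acc.mae:6.2f} years",
            f"    rMSE = {acc.rmse:6.2f} years",
            f"    r    = {acc.pearson_r:6.3f}",
            f"    R2   = {acc.r2:6.3f}",
            "  top weights (years per z-unit):",
        ]
        for name, w in self.top_weights(10):
            lines.append(f"    {name:<16s} {w:+8.3f}")
        return "\n".join(lines)
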