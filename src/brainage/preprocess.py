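"""Train-set-anchored feature normalization and gender-confound removal.

Both transforms are fitted on training subjects only and then applied
unchanged to any table (the train/test separation of the brain-age design:
statistics estimated on controls never see test rows). The z-score is
Z = (x - u) / s with u, s the training mean and standard deviation; the
confound step replaces each feature with its residual from a per-feature
linear regression on gender fitted in the training set.

The configured default order is gender residualization first, then
z-scoring. Residualization is scale-equivariant, so the order affects only
the scale of the output; fixing one order keeps runs reproducible, and it
is configurable for sensitivity analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .table import FeatureTable

__all__ = [
    "NormalizationStats",
    "ConfoundModel",
    "Preprocessor",
    "fit_zscore",
    "apply_zscore",
    "fit_remove_gender",
    "apply_remove_gender",
]

#: features with training sd below this are considered degenerate
DEGENERATE_SD_EPS = 1e-12


@dataclass(frozen=True)
class NormalizationStats:
    """Per-feature training mean/sd plus bookkeeping of who was trained on."""

    feature_names: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    train_ids: tuple[str, ...]
    ddof: int = 1
    degenerate: tuple[str, ...] = field(default=())
    degenerate_policy: str = "drop"  # or "zero"

    @property
    def kept_names(self) -> tuple[str, ...]:
        if self.degenerate_policy == "drop":
            deg = set(self.degenerate)
            return tuple(n for n in self.feature_names if n not in deg)
        return self.feature_names

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "train_ids": list(self.train_ids),
            "ddof": self.ddof,
            "degenerate": list(self.degenerate),
            "degenerate_policy": self.degenerate_policy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        return cls(
            feature_names=tuple(d["feature_names"]),
            mean=np.asarray(d["mean"], dtype=float),
            sd=np.asarray(d["sd"], dtype=float),
            train_ids=tuple(d["train_ids"]),
            ddof=d["ddof"],
            degenerate=tuple(d["degenerate"]),
            degenerate_policy=d["degenerate_policy"],
        )


def fit_zscore(
    train: FeatureTable, ddof: int = 1, degenerate_policy: str = "drop"
) -> NormalizationStats:
    """Estimate per-feature mean and sd from training rows only.

    Features with sd below ``DEGENERATE_SD_EPS`` are flagged degenerate and,
    under the default ``drop`` policy, removed on apply; under ``zero`` they
    pass through as all-zero columns.
    """
    if train.n_subjects < 2:
        raise ValueError("z-score fit needs at least 2 training subjects")
    if degenerate_policy not in ("drop", "zero"):
        raise ValueError(f"unknown degenerate_policy {degenerate_policy!r}")
    X = train.values()
    u = X.mean(axis=0)
    s = X.std(axis=0, ddof=ddof)
    deg = tuple(
        n for n, sj in zip(train.feature_names, s) if sj < DEGENERATE_SD_EPS
    )
    return NormalizationStats(
        feature_names=train.feature_names,
        mean=u,
        sd=s,
        train_ids=tuple(train.subject_ids),
        ddof=ddof,
        degenerate=deg,
        degenerate_policy=degenerate_policy,
    )


def apply_zscore(table: FeatureTable, stats: NormalizationStats) -> FeatureTable:
    """Z = (x - u) / s using the *training* u, s (never recomputed here)."""
    if table.feature_names != stats.feature_names:
        raise ValueError("feature names do not match the normalization stats")
    X = table.values()
    safe_sd = np.where(stats.sd < DEGENERATE_SD_EPS, 1.0, stats.sd)
    Z = (X - stats.mean) / safe_sd
    deg = set(stats.degenerate)
    if deg:
        if stats.degenerate_policy == "drop":
            keep = [j for j, n in enumerate(stats.feature_names) if n not in deg]
            demo_cols = [c for c in table.df.columns if c not in stats.feature_names]
            out = table.df.loc[:, demo_cols].copy()
            kept_names = stats.kept_names
            for pos, j in enumerate(keep):
                out[kept_names[pos]] = Z[:, j]
            return FeatureTable(out, kept_names)
        Z[:, [j for j, n in enumerate(stats.feature_names) if n in deg]] = 0.0
    return table.with_features(Z)


@dataclass(frozen=True)
class ConfoundModel:
    """Per-feature intercept and gender coefficient fitted on training rows."""

    feature_names: tuple[str, ...]
    intercept: np.ndarray
    gender_coef: np.ndarray
    train_ids: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "intercept": self.intercept.tolist(),
            "gender_coef": self.gender_coef.tolist(),
            "train_ids": list(self.train_ids),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConfoundModel":
        return cls(
            feature_names=tuple(d["feature_names"]),
            intercept=np.asarray(d["intercept"], dtype=float),
            gender_coef=np.asarray(d["gender_coef"], dtype=float),
            train_ids=tuple(d["train_ids"]),
        )


def fit_remove_gender(train: FeatureTable) -> ConfoundModel:
    """Fit x_j ~ b0_j + b1_j * gender per feature by least squares.

    With a binary regressor the closed form is b1 = cov(g, x)/var(g),
    b0 = mean(x) - b1 * mean(g), vectorized across features.
    """
    g = train.gender
    if len(np.unique(g)) < 2:
        raise ValueError("gender residualization needs both gender levels in training")
    X = train.values()
    gc = g - g.mean()
    b1 = gc @ (X - X.mean(axis=0)) / (gc @ gc)
    b0 = X.mean(axis=0) - b1 * g.mean()
    return ConfoundModel(
        feature_names=train.feature_names,
        intercept=b0,
        gender_coef=b1,
        train_ids=tuple(train.subject_ids),
    )


def apply_remove_gender(table: FeatureTable, model: ConfoundModel) -> FeatureTable:
    """Replace each feature by its residual from the train-fitted regression."""
    if table.feature_names != model.feature_names:
        raise ValueError("feature names do not match the confound model")
    X = table.values()
    resid = X - (model.intercept + np.outer(table.gender, model.gender_coef))
    return table.with_features(resid)


@dataclass
class Preprocessor:
    """Composed confound-removal + normalization stage with a fixed order.

    ``order`` is a tuple naming the steps in application order; the default
    ``("gender", "zscore")`` residualizes gender first. A step may be left
    out (e.g. ``("zscore",)`` skips confound removal entirely). ``fit``
    records the training subject ids of every sub-model so leakage can be
    audited.
    """

    order: tuple[str, ...] = ("gender", "zscore")
    ddof: int = 1
    degenerate_policy: str = "drop"
    confound: ConfoundModel | None = None
    norm_stats: NormalizationStats | None = None

    def __post_init__(self) -> None:
        if not self.order or not set(self.order) <= {"gender", "zscore"}:
            raise ValueError(
                "order must be a non-empty subsequence of ('gender', 'zscore')"
            )
        if len(set(self.order)) != len(self.order):
            raise ValueError("order must not repeat steps")

    def fit(self, train: FeatureTable) -> "Preprocessor":
        work = train
        for step in self.order:
            if step == "gender":
                self.confound = fit_remove_gender(work)
                work = apply_remove_gender(work, self.confound)
            else:
                self.norm_stats = fit_zscore(
                    work, ddof=self.ddof, degenerate_policy=self.degenerate_policy
                )
                work = apply_zscore(work, self.norm_stats)
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        if ("gender" in self.order and self.confound is None) or (
            "zscore" in self.order and self.norm_stats is None
        ):
            raise RuntimeError("Preprocessor.transform called before fit")
        work = table
        for step in self.order:
            if step == "gender":
                work = apply_remove_gender(work, self.confound)
            else:
                work = apply_zscore(work, self.norm_stats)
        return work

    def fit_transform(self, train: FeatureTable) -> FeatureTable:
        self.fit(train)
        return self.transform(train)

    @property
    def train_ids(self) -> tuple[str, ...]:
        fitted = self.norm_stats or self.confound
        if fitted is None:
            raise RuntimeError("not fitted")
        return fitted.train_ids

    def to_json(self, path: str | Path) -> None:
        payload = {
            "order": list(self.order),
            "ddof": self.ddof,
            "degenerate_policy": self.degenerate_policy,
            "confound": self.confound.to_dict() if self.confound else None,
            "norm_stats": self.norm_stats.to_dict() if self.norm_stats else None,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "Preprocessor":
        d = json.loads(Path(path).read_text())
        pp = cls(
            order=tuple(d["order"]),
            ddof=d["ddof"],
            degenerate_policy=d["degenerate_policy"],
        )
        if d["confound"]:
            pp.confound = ConfoundModel.from_dict(d["confound"])
        if d["norm_stats"]:
            pp.norm_stats = NormalizationStats.from_dict(d["norm_stats"])
        return pp
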