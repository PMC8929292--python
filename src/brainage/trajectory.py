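"""Age-bias correction, brain-age-gap trajectories and age-band splitting.

Regression-based age prediction systematically over-predicts young subjects
and under-predicts old ones (regression to the mean), so the raw gap
BA - CA correlates with CA even in controls. The standard linear correction
fits, in the control group,

    offset = alpha * CA + beta          (OLS of BA - CA on CA)
    corrected BA = BA - offset

after which the mean corrected gap over the fitting controls is exactly
zero (an OLS residual property). The same offset is applied unchanged to
patients.

The patient gap-versus-age trajectory is then modelled by polynomial least
squares (degree 1 and 2); the models are compared by adjusted R^2 (primary)
with AIC reported, and for the quadratic the vertex -b/(2a) is the
stationary age used to split cohorts into a youth band (CA < vertex) and a
middle-age band (CA >= vertex).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BiasModel",
    "AgeBias",
    "fit_bias",
    "apply_bias",
    "TrajectoryFit",
    "BagTrajectory",
    "fit_trajectory",
    "compare_trajectories",
    "split_by_vertex",
    "build_prediction_records",
]


@dataclass(frozen=True)
class BiasModel:
    """Linear age-bias model: offset = alpha * CA + beta, fitted in controls."""

    alpha: float  # dimensionless slope of the offset in CA
    beta: float   # years
    fit_ids: tuple[str, ...] = ()

    def offset(self, ca: np.ndarray) -> np.ndarray:
        return self.alpha * np.asarray(ca, dtype=float) + self.beta

    def correct(self, ba: np.ndarray, ca: np.ndarray) -> np.ndarray:
        """corrected BA = BA - (alpha * CA + beta)."""
        return np.asarray(ba, dtype=float) - self.offset(ca)

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "beta": self.beta, "fit_ids": list(self.fit_ids)}


def fit_bias(ca: np.ndarray, ba: np.ndarray, ids=()) -> BiasModel:
    """OLS of the raw gap (BA - CA) on CA over the control group."""
    ca = np.asarray(ca, dtype=float)
    ba = np.asarray(ba, dtype=float)
    if len(ca) < 3:
        raise ValueError("bias fit needs at least 3 control records")
    if np.var(ca) == 0:
        raise ValueError("zero CA variance: bias slope undefined")
    gap = ba - ca
    alpha, beta = np.polyfit(ca, gap, 1)
    return BiasModel(float(alpha), float(beta), tuple(ids))


def apply_bias(ba: np.ndarray, ca: np.ndarray, model: BiasModel) -> np.ndarray:
    return model.correct(ba, ca)


class AgeBias:
    """Model/results wrapper around :func:`fit_bias`.

    ``AgeBias(ca, ba).fit()`` returns the fitted :class:`BiasModel`.
    """

    def __init__(self, ca: np.ndarray, ba: np.ndarray, ids=()):
        self.ca = np.asarray(ca, dtype=float)
        self.ba = np.asarray(ba, dtype=float)
        self.ids = tuple(ids)

    def fit(self) -> BiasModel:
        return fit_bias(self.ca, self.ba, self.ids)


@dataclass(frozen=True)
class TrajectoryFit:
    """Polynomial fit of the gap-vs-age trajectory.

    ``coefficients`` are in descending power order (numpy convention), so a
    quadratic is ``(a, b, c)`` for a*CA^2 + b*CA + c. The vertex -b/(2a)
    exists only for degree 2 with a != 0.
    """

    degree: int
    coefficients: tuple[float, ...]
    r2: float
    adj_r2: float
    aic: float
    n: int

    @property
    def quadratic_coefficient(self) -> float:
        if self.degree != 2:
            raise ValueError("no quadratic coefficient in a linear fit")
        return self.coefficients[0]

    @property
    def is_positive_quadratic(self) -> bool:
        return self.degree == 2 and self.coefficients[0] > 0

    @property
    def vertex(self) -> float:
        """Stationary age -b/(2a) of the quadratic (years)."""
        if self.degree != 2:
            raise ValueError("vertex defined only for a quadratic fit")
        a, b, _ = self.coefficients
        if a == 0:
            raise ValueError("vertex undefined: quadratic coefficient is zero")
        return -b / (2.0 * a)

    def predict(self, ca: np.ndarray) -> np.ndarray:
        return np.polyval(self.coefficients, np.asarray(ca, dtype=float))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coefficients"] = list(self.coefficients)
        if self.degree == 2 and self.coefficients[0] != 0:
            d["vertex"] = self.vertex
            d["positive_quadratic"] = self.is_positive_quadratic
        return d


def _gaussian_aic(resid: np.ndarray, k_params: int) -> float:
    # -2 loglik + 2k for a Gaussian error model (error variance counts as a
    # parameter), matching the usual OLS convention.
    n = len(resid)
    sse = float(np.sum(resid**2))
    sigma2 = max(sse / n, np.finfo(float).tiny)
    llf = -0.5 * n * (np.log(2 * np.pi) + np.log(sigma2) + 1.0)
    return float(-2.0 * llf + 2.0 * (k_params + 1))


def fit_trajectory(ca: np.ndarray, bag: np.ndarray, degree: int) -> TrajectoryFit:
    """Least-squares polynomial fit of BAG on CA (degree 1 or 2)."""
    ca = np.asarray(ca, dtype=float)
    bag = np.asarray(bag, dtype=float)
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    n = len(ca)
    if n <= degree + 1:
        raise ValueError(f"need n > {degree + 1} points for a degree-{degree} fit")
    if np.var(ca) == 0:
        raise ValueError("degenerate design: all CA equal")
    coef = np.polyfit(ca, bag, degree)
    pred = np.polyval(coef, ca)
    resid = bag - pred
    sst = float(np.sum((bag - bag.mean()) ** 2))
    sse = float(np.sum(resid**2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    p = degree  # predictors excluding intercept
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return TrajectoryFit(
        degree=degree,
        coefficients=tuple(float(c) for c in coef),
        r2=r2,
        adj_r2=float(adj),
        aic=_gaussian_aic(resid, degree + 1),
        n=n,
    )


def compare_trajectories(
    fit1: TrajectoryFit, fit2: TrajectoryFit
) -> tuple[TrajectoryFit, dict]:
    """Prefer the fit with higher adjusted R^2; AIC reported alongside."""
    preferred = fit2 if fit2.adj_r2 > fit1.adj_r2 else fit1
    criteria = {
        "adj_r2": {f"degree{fit1.degree}": fit1.adj_r2, f"degree{fit2.degree}": fit2.adj_r2},
        "aic": {f"degree{fit1.degree}": fit1.aic, f"degree{fit2.degree}": fit2.aic},
        "preferred_degree": preferred.degree,
    }
    return preferred, criteria


class BagTrajectory:
    """Gap-trajectory model: fits linear and quadratic and compares them.

    ``BagTrajectory(ca, bag).fit()`` returns a :class:`TrajectoryResults`
    carrying both fits, the preferred one, and the quadratic's vertex.
    """

    def __init__(self, ca: np.ndarray, bag: np.ndarray):
        self.ca = np.asarray(ca, dtype=float)
        self.bag = np.asarray(bag, dtype=float)

    def fit(self) -> "TrajectoryResults":
        linear = fit_trajectory(self.ca, self.bag, 1)
        quadratic = fit_trajectory(self.ca, self.bag, 2)
        preferred, criteria = compare_trajectories(linear, quadratic)
        return TrajectoryResults(self, linear, quadratic, preferred, criteria)


class TrajectoryResults:
    def __init__(self, model, linear, quadratic, preferred, criteria):
        self.model = model
        self.linear: TrajectoryFit = linear
        self.quadratic: TrajectoryFit = quadratic
        self.preferred: TrajectoryFit = preferred
        self.criteria: dict = criteria

    @property
    def vertex(self) -> float:
        return self.quadratic.vertex

    def summary(self) -> str:
        a, b, c = self.quadratic.coefficients
        lines = [
            "Gap-vs-age trajectory",
            f"  n = {self.quadratic.n}",
            f"  linear:    adjR2 = {self.linear.adj_r2:7.4f}, AIC = {self.linear.aic:9.2f}",
            f"  quadratic: adjR2 = {self.quadratic.adj_r2:7.4f}, AIC = {self.quadratic.aic:9.2f}",
            f"  quadratic coefficients: a = {a:+.5f}, b = {b:+.4f}, c = {c:+.3f}",
            f"  preferred: degree {self.preferred.degree}",
        ]
        if a != 0:
            kind = "positive (upward-opening)" if a > 0 else "negative"
            lines.append(f"  vertex age = {self.vertex:.2f} years ({kind} quadratic)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "linear": self.linear.to_dict(),
            "quadratic": self.quadratic.to_dict(),
            "criteria": self.criteria,
        }


def split_by_vertex(
    ca: np.ndarray, vertex: float, integer_band: bool = False
) -> np.ndarray:
    """Label each subject ``youth`` (CA < vertex) or ``middle`` (CA >= vertex).

    With ``integer_band=True`` the cut reproduces integer-year band tables
    (youth iff CA < floor(vertex)), so a vertex of 47.33 puts 47-year-olds
    in the middle band instead of the youth band. A vertex outside
    the observed age range triggers a warning but labels are still assigned.
    """
    ca = np.asarray(ca, dtype=float)
    if not np.isfinite(vertex):
        raise ValueError("vertex must be finite")
    if len(ca) and not (ca.min() <= vertex <= ca.max()):
        warnings.warn(
            f"vertex {vertex:.2f} lies outside the observed age range "
            f"[{ca.min():.1f}, {ca.max():.1f}]",
            stacklevel=2,
        )
    cut = np.floor(vertex) if integer_band else vertex
    return np.where(ca < cut, "youth", "middle")


def build_prediction_records(
    ids,
    group,
    ca: np.ndarray,
    ba_raw: np.ndarray,
    bias: BiasModel,
    vertex: float | None = None,
    integer_band: bool = False,
) -> pd.DataFrame:
    """Per-subject record table: CA, raw BA, corrected BA, BAG, age band."""
    ca = np.asarray(ca, dtype=float)
    ba_raw = np.asarray(ba_raw, dtype=float)
    corrected = bias.correct(ba_raw, ca)
    df = pd.DataFrame(
        {
            "subject_id": list(ids),
            "group": list(group),
            "ca": ca,
            "ba_raw": ba_raw,
            "ba_corrected": corrected,
            "bag": corrected - ca,
        }
    )
    if vertex is not None:
        df["age_band"] = split_by_vertex(ca, vertex, integer_band=integer_band)
    return df


def save_records(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def save_trajectory(fit: TrajectoryFit, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict()))
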