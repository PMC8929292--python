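"""Synthetic NC/SZ cohort generator.

Real multimodal-MRI cohorts of this kind are private clinical data, so the
generator produces feature tables with the statistical structure the
downstream analysis assumes: a healthy-control (NC) group whose effective
brain age equals chronological age (CA), and a patient (SZ) group whose
effective brain age deviates from CA by a quadratic brain-age-gap curve

    effective_age - CA = a * (CA - c)**2 + d,   a >= 0,

i.e. an upward-opening parabola with vertex at age ``c`` — an elevated gap
in youth that declines toward the vertex. Features come in three flavours:

* linear-informative:    intercept + slope * effective_age
* quadratic-informative: intercept + slope * effective_age
                                   + curvature * effective_age**2
* pure noise:            intercept only

all plus an additive per-feature gender effect ``gamma_j * gender`` with
``gamma_j ~ N(0, gender_effect_sd)`` on the informative columns, and i.i.d.
Gaussian noise ``N(0, noise_sd)`` everywhere. Informative columns are
spread round-robin across the sMRI/fMRI/DTI blocks so every modality subset
carries age signal.

Defaults mirror the motivating study's conditions: 205 NC and 138 SZ
subjects (154 SZ and 209 NC recruited minus 16/4 head-motion exclusions),
ages 20-60, a 1,430-column three-modality layout (492 sMRI + 738 fMRI +
200 DTI), and a patient gap curve with vertex near 47 years.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import MODALITIES, build_feature_names
from .table import FeatureTable

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "generate_cohort",
    "simulate_bag_observations",
    "analyzed_cohort_sizes",
]


def analyzed_cohort_sizes(
    recruited: dict[str, int] | None = None,
    excluded: dict[str, int] | None = None,
) -> dict[str, int]:
    """Analyzed group sizes after quality-control exclusions.

    Defaults encode the motivating study's accounting: 154 SZ and 209 NC
    recruited, 16 SZ and 4 NC excluded for excessive head motion, leaving
    138 SZ and 205 NC in the analysis.
    """
    recruited = {"SZ": 154, "NC": 209} if recruited is None else recruited
    excluded = {"SZ": 16, "NC": 4} if excluded is None else excluded
    out = {}
    for grp, n in recruited.items():
        n_exc = excluded.get(grp, 0)
        if n_exc < 0 or n_exc > n:
            raise ValueError(f"group {grp}: cannot exclude {n_exc} of {n}")
        out[grp] = n - n_exc
    return out


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters; identical config + seed gives byte-identical output.

    ``slope_range`` bounds the magnitude of the per-feature age slope
    (feature-units per year); signs are random. Quadratic-informative
    curvatures are drawn on the same scale then divided by the age span so
    the quadratic term contributes variance comparable to the linear one.
    """

    n_nc: int = 205
    n_sz: int = 138
    age_min: float = 20.0
    age_max: float = 60.0
    n_informative_linear: int = 30
    n_informative_quadratic: int = 10
    n_noise: int | None = None  # None -> pad to the full modality layout
    modalities: tuple[str, ...] = MODALITIES
    slope_range: tuple[float, float] = (0.5, 1.5)
    noise_sd: float = 30.0
    gender_effect_sd: float = 10.0
    bag_coeff_a: float = 0.01
    bag_vertex_c: float = 47.0
    bag_offset_d: float = 1.0
    integer_ages: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "age_min", "age_max", "noise_sd", "gender_effect_sd",
            "bag_coeff_a", "bag_vertex_c", "bag_offset_d",
        ):
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.age_min >= self.age_max:
            raise ValueError("age_min must be < age_max")
        for name in ("n_nc", "n_sz", "n_informative_linear", "n_informative_quadratic"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_noise is not None and self.n_noise < 0:
            raise ValueError("n_noise must be >= 0")
        if self.noise_sd < 0 or self.gender_effect_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.bag_coeff_a < 0:
            raise ValueError("bag_coeff_a must be >= 0 (upward-opening gap curve)")
        lo, hi = self.slope_range
        if not (np.isfinite(lo) and np.isfinite(hi)) or lo < 0 or hi < lo:
            raise ValueError("slope_range must be finite with 0 <= lo <= hi")

    @property
    def n_informative(self) -> int:
        return self.n_informative_linear + self.n_informative_quadratic

    def feature_names(self) -> list[str]:
        names = build_feature_names(self.modalities)
        if self.n_noise is None:
            if self.n_informative > len(names):
                raise ValueError(
                    f"{self.n_informative} informative features exceed the "
                    f"{len(names)}-column modality layout"
                )
            return names
        total = self.n_informative + self.n_noise
        if total > len(names):
            raise ValueError(
                f"{total} requested features exceed the {len(names)}-column layout"
            )
        # truncate by round-robin over modality blocks so every requested
        # modality stays represented, then restore canonical order
        by_mod: dict[str, list[str]] = {}
        for n in names:
            by_mod.setdefault(n.split(":", 1)[0], []).append(n)
        iters = {m: iter(v) for m, v in by_mod.items()}
        mods = list(by_mod)
        chosen: list[str] = []
        i = 0
        while len(chosen) < total:
            m = mods[i % len(mods)]
            try:
                chosen.append(next(iters[m]))
            except StopIteration:
                mods.remove(m)
                continue
            i += 1
        order = {n: j for j, n in enumerate(names)}
        return sorted(chosen, key=order.__getitem__)


@dataclass(frozen=True)
class GroundTruth:
    """Generating values recorded for oracle use in parameter-recovery tests."""

    subject_ids: tuple[str, ...]
    effective_age: np.ndarray  # years, one per subject
    chronological_age: np.ndarray
    group: tuple[str, ...]
    feature_names: tuple[str, ...]
    informative_idx: tuple[int, ...]
    intercepts: np.ndarray
    slopes: np.ndarray       # 0 for pure-noise columns
    curvatures: np.ndarray   # 0 unless quadratic-informative
    gender_coefs: np.ndarray
    noise_sd: float
    config: CohortConfig = field(repr=False)

    def bag(self) -> np.ndarray:
        """True brain-age gap (effective - chronological age) per subject."""
        return self.effective_age - self.chronological_age

    def noise_floor_sd(self) -> float:
        """Best-case sd (years) of any age estimator given the feature noise.

        With independent Gaussian noise of sd ``sigma`` on each feature and
        per-feature age sensitivity ``g_j = d feature_j / d age`` (evaluated
        at the mid-cohort age for quadratic columns), the Fisher information
        for age is ``sum_j g_j**2 / sigma**2``; its inverse square root is
        the Cramér–Rao floor on prediction error.
        """
        mid = 0.5 * (self.config.age_min + self.config.age_max)
        g = self.slopes + 2.0 * self.curvatures * mid
        info = float(np.sum(g**2))
        if info == 0:
            return float("inf")
        return float(self.noise_sd / np.sqrt(info))

    def noise_floor_mae(self) -> float:
        """MAE (years) of the best estimator: sqrt(2/pi) * floor sd."""
        return float(np.sqrt(2.0 / np.pi) * self.noise_floor_sd())

    def explainable_variance_fraction(self) -> float:
        """Fraction of CA variance the best estimator can explain."""
        var_age = float(np.var(self.chronological_age))
        floor = self.noise_floor_sd() ** 2
        return var_age / (var_age + floor)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "noise_sd": self.noise_sd,
            "subjects": {
                sid: {"group": g, "age": float(ca), "effective_age": float(ea)}
                for sid, g, ca, ea in zip(
                    self.subject_ids, self.group,
                    self.chronological_age, self.effective_age,
                )
            },
            "features": {
                name: {
                    "intercept": float(self.intercepts[j]),
                    "slope": float(self.slopes[j]),
                    "curvature": float(self.curvatures[j]),
                    "gender_coef": float(self.gender_coefs[j]),
                    "informative": j in set(self.informative_idx),
                }
                for j, name in enumerate(self.feature_names)
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _round_robin_informative(names: list[str], k: int) -> list[int]:
    """Column indices for k informative features, cycling across modalities."""
    by_mod: dict[str, list[int]] = {}
    for j, name in enumerate(names):
        by_mod.setdefault(name.split(":", 1)[0], []).append(j)
    mods = [m for m in MODALITIES if m in by_mod]
    iters = {m: iter(by_mod[m]) for m in mods}
    out: list[int] = []
    i = 0
    while len(out) < k:
        m = mods[i % len(mods)]
        try:
            out.append(next(iters[m]))
        except StopIteration:
            mods.remove(m)
            if not mods:
                raise ValueError("not enough feature columns for informative set")
            continue
        i += 1
    return out


def generate_cohort(config: CohortConfig) -> tuple[FeatureTable, GroundTruth]:
    """Draw one synthetic cohort; returns the table and its generating truth."""
    rng = np.random.default_rng(config.seed)
    names = config.feature_names()
    n = config.n_nc + config.n_sz
    p = len(names)

    ages = rng.uniform(config.age_min, config.age_max, size=n)
    if config.integer_ages:
        ages = np.floor(ages)  # integer years, uniform over [age_min, age_max)
    gender = rng.integers(0, 2, size=n).astype(float)
    group = ["NC"] * config.n_nc + ["SZ"] * config.n_sz
    ids = [f"NC{i + 1:04d}" for i in range(config.n_nc)] + [
        f"SZ{i + 1:04d}" for i in range(config.n_sz)
    ]

    eff = ages.copy()
    sz = np.arange(n) >= config.n_nc
    eff[sz] = ages[sz] + (
        config.bag_coeff_a * (ages[sz] - config.bag_vertex_c) ** 2
        + config.bag_offset_d
    )

    info_idx = _round_robin_informative(names, config.n_informative)
    lin_idx = info_idx[: config.n_informative_linear]
    quad_idx = info_idx[config.n_informative_linear:]

    intercepts = rng.normal(0.0, 10.0, size=p)
    slopes = np.zeros(p)
    curvatures = np.zeros(p)
    gender_coefs = np.zeros(p)
    lo, hi = config.slope_range
    signs = rng.choice([-1.0, 1.0], size=len(info_idx))
    mags = rng.uniform(lo, hi, size=len(info_idx))
    slopes[info_idx] = signs * mags
    # quadratic term scaled by the age span so both terms matter comparably
    span = config.age_max - config.age_min
    curvatures[quad_idx] = (
        rng.choice([-1.0, 1.0], size=len(quad_idx))
        * rng.uniform(lo, hi, size=len(quad_idx))
        / span
    )
    gender_coefs[info_idx] = rng.normal(0.0, config.gender_effect_sd, len(info_idx))

    X = np.tile(intercepts, (n, 1))
    X += eff[:, None] * slopes[None, :]
    X += (eff**2)[:, None] * curvatures[None, :]
    X += gender[:, None] * gender_coefs[None, :]
    X += rng.normal(0.0, config.noise_sd, size=(n, p))

    df = pd.DataFrame(
        {"subject_id": ids, "group": group, "age": ages, "gender": gender}
    )
    df = pd.concat([df, pd.DataFrame(X, columns=names)], axis=1)
    table = FeatureTable.from_dataframe(df)
    truth = GroundTruth(
        subject_ids=tuple(ids),
        effective_age=eff,
        chronological_age=ages,
        group=tuple(group),
        feature_names=tuple(names),
        informative_idx=tuple(info_idx),
        intercepts=intercepts,
        slopes=slopes,
        curvatures=curvatures,
        gender_coefs=gender_coefs,
        noise_sd=config.noise_sd,
        config=config,
    )
    return table, truth


def simulate_bag_observations(
    n: int,
    a: float = 0.01,
    c: float = 47.0,
    d: float = 1.0,
    noise_sd: float = 2.0,
    age_min: float = 20.0,
    age_max: float = 60.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (CA, observed BAG) pairs from BAG = a*(CA-c)^2 + d + N(0, sd^2).

    A lightweight oracle for trajectory-recovery experiments: it samples the
    gap curve directly instead of routing through feature generation and a
    fitted brain-age model.
    """
    rng = np.random.default_rng(seed)
    ca = rng.uniform(age_min, age_max, size=n)
    bag = a * (ca - c) ** 2 + d + rng.normal(0.0, noise_sd, size=n)
    return ca, bag
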