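"""Permutation significance of the age model and group-level statistics.

The permutation test asks whether the LOOCV accuracy could arise without
any age signal: the chronological-age labels of the training cohort are
shuffled ``n_perm`` times and the *entire* regression pipeline (confound
removal, normalization, selection, MLR, LOOCV) is re-run on each shuffled
cohort. The p-value uses add-one smoothing,

    p = (1 + #{MAE_perm <= MAE_observed}) / (1 + n_perm),

which avoids p = 0 and is exact under exchangeability.

Group comparisons are the field's standard ones — two-sample t-tests
(Welch by default, pooled optional), a t-test from printed summary
statistics (for desk-checking demographic tables), and the Pearson
chi-square test on a 2x2 contingency table (no continuity correction by
default). Implementations delegate to scipy.stats; the test suite carries
independent brute-force formula oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as _sps

from .model import PipelineConfig, accuracy, loocv_predict
from .table import FeatureTable

__all__ = [
    "PermutationResult",
    "GroupTestResult",
    "permutation_test_mae",
    "two_sample_t",
    "t_from_summary",
    "chi_square_2x2",
]


@dataclass(frozen=True)
class PermutationResult:
    """Observed LOOCV MAE against its label-permutation null distribution."""

    observed_mae: float
    permuted_mae: np.ndarray = field(repr=False)
    p_value: float
    n_perm: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed_mae": self.observed_mae,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "permuted_mae_mean": float(self.permuted_mae.mean()),
            "permuted_mae": self.permuted_mae.tolist(),
        }


def _with_permuted_ages(table: FeatureTable, perm: np.ndarray) -> FeatureTable:
    df = table.df.copy()
    df["age"] = table.age[perm]
    return FeatureTable(df, table.feature_names)


def permutation_test_mae(
    table: FeatureTable,
    config: PipelineConfig | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Label-permutation significance of the LOOCV MAE.

    Each permutation shuffles the age labels and re-runs the full pipeline,
    selection included, under the same :class:`PipelineConfig`. A failure
    inside a permutation is re-raised with the permutation index attached.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cfg = config or PipelineConfig()
    ca = table.age
    observed = accuracy(loocv_predict(table, cfg), ca).mae
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(table.n_subjects)
        try:
            shuffled = _with_permuted_ages(table, perm)
            ba = loocv_predict(shuffled, cfg)
            permuted[b] = float(np.mean(np.abs(ba - shuffled.age)))
        except Exception as e:
            raise RuntimeError(f"permutation {b} failed: {e}") from e
    p = (1.0 + float(np.sum(permuted <= observed))) / (1.0 + n_perm)
    return PermutationResult(observed, permuted, p, n_perm, seed)


@dataclass(frozen=True)
class GroupTestResult:
    """A classical test: statistic, degrees of freedom, p, group summaries."""

    test: str
    statistic: float
    df: float
    p_value: float
    summaries: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _summaries(x: np.ndarray, y: np.ndarray) -> dict:
    return {
        "group1": {"n": len(x), "mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1))},
        "group2": {"n": len(y), "mean": float(np.mean(y)), "sd": float(np.std(y, ddof=1))},
    }


def _welch_df(v1: float, n1: int, v2: float, n2: int) -> float:
    num = (v1 / n1 + v2 / n2) ** 2
    den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    return num / den


def two_sample_t(x, y, variant: str = "welch") -> GroupTestResult:
    """Two-sided two-sample t-test (``welch`` default, ``pooled`` optional)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if variant not in ("welch", "pooled"):
        raise ValueError("variant must be 'welch' or 'pooled'")
    if np.var(x, ddof=1) + np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            df = _welch_df(1, len(x), 1, len(y)) if variant == "welch" else len(x) + len(y) - 2
            return GroupTestResult(f"t-{variant}", 0.0, float(df), 1.0, _summaries(x, y))
        raise ValueError("zero combined variance with unequal means")
    res = _sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return GroupTestResult(
        test=f"t-{variant}",
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        summaries=_summaries(x, y),
    )


def t_from_summary(
    n1: int, m1: float, sd1: float,
    n2: int, m2: float, sd2: float,
    variant: str = "welch",
) -> GroupTestResult:
    """Two-sample t-test from printed summary statistics only.

    Lets a reader desk-check demographic tables (n, mean +- SD per group)
    without subject-level data.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if variant not in ("welch", "pooled"):
        raise ValueError("variant must be 'welch' or 'pooled'")
    res = _sps.ttest_ind_from_stats(
        m1, sd1, n1, m2, sd2, n2, equal_var=(variant == "pooled")
    )
    if variant == "welch":
        df = _welch_df(sd1**2, n1, sd2**2, n2)
    else:
        df = n1 + n2 - 2
    return GroupTestResult(
        test=f"t-{variant}-from-summary",
        statistic=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
        summaries={
            "group1": {"n": n1, "mean": m1, "sd": sd1},
            "group2": {"n": n2, "mean": m2, "sd": sd2},
        },
    )


def chi_square_2x2(table, correction: bool = False) -> GroupTestResult:
    """Pearson chi-square test of independence on a 2x2 count table.

    No Yates continuity correction by default. All four expected counts must
    be positive (zero marginals are rejected).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or not np.all(t == np.floor(t)):
        raise ValueError("counts must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal: expected counts undefined")
    chi2, p, dof, _ = _sps.chi2_contingency(t, correction=correction)
    return GroupTestResult(
        test="chi-square" + ("-yates" if correction else ""),
        statistic=float(chi2),
        df=float(dof),
        p_value=float(p),
        summaries={"observed": t.astype(int).tolist()},
    )
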