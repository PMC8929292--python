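"""End-to-end study orchestration.

``run_full_study`` wires the stages together in the fixed order:

  load/generate cohort -> gender residualize -> z-score -> LASSO selection
  -> NC LOOCV -> all-NC model -> SZ prediction -> age-bias correction
  -> linear/quadratic gap-trajectory fits + vertex -> age-band split
  -> group tests -> permutation test -> report.

All randomness flows from one root seed, stream-split per stage, so a rerun
with the same config reproduces the report exactly. When an output
directory is given, a manifest (config + seeds + package version) is
written before any computation, and a completed run directory contains the
manifest, the serialized model, per-subject prediction records, a flat CSV
of the statistical tests and a Markdown summary.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import (
    AccuracyReport,
    BrainAgeModel,
    PipelineConfig,
    accuracy,
    loocv_predict,
)
from .stats import PermutationResult, permutation_test_mae, two_sample_t, chi_square_2x2
from .synth import CohortConfig, generate_cohort
from .table import FeatureTable, read_feature_table, subset_modalities
from .trajectory import (
    BagTrajectory,
    BiasModel,
    build_prediction_records,
    fit_bias,
)

__all__ = ["RunConfig", "StudyReport", "run_full_study", "ablate_modalities"]

MODALITY_SUBSETS = (
    ("sMRI",),
    ("fMRI",),
    ("DTI",),
    ("sMRI", "fMRI"),
    ("sMRI", "DTI"),
    ("fMRI", "DTI"),
    ("sMRI", "fMRI", "DTI"),
)


@dataclass(frozen=True)
class RunConfig:
    """Everything a study run needs; fully JSON-serializable."""

    input_mode: str = "synthetic"            # "synthetic" | "csv"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    csv_path: str | None = None
    modalities: tuple[str, ...] = ("sMRI", "fMRI", "DTI")
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    perm_selection: str = "pooled"           # pipeline mode inside permutations
    n_perm: int = 200
    seed: int = 0
    integer_band: bool = False
    top_k_weights: int = 20
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("modalities",):
            d[key] = list(d[key])
        d["cohort"]["modalities"] = list(d["cohort"]["modalities"])
        d["cohort"]["slope_range"] = list(d["cohort"]["slope_range"])
        d["pipeline"]["preprocess_order"] = list(d["pipeline"]["preprocess_order"])
        d["pipeline"]["cv_alphas"] = list(d["pipeline"]["cv_alphas"])
        return d


def _stage_seeds(root: int, n: int = 4) -> list[int]:
    """Independent per-stage seeds derived from the root seed (< 2**31)."""
    ss = np.random.SeedSequence(root)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


@dataclass
class StudyReport:
    """All quantities the study computes, reproducible from the manifest."""

    manifest: dict
    nc_accuracy: AccuracyReport
    n_selected: int
    top_weights: list
    bias: BiasModel
    records: pd.DataFrame
    trajectory: dict
    vertex: float
    band_counts: dict
    group_tests: dict
    permutation: PermutationResult | None

    def to_dict(self) -> dict:
        return {
            "manifest": self.manifest,
            "nc_accuracy": self.nc_accuracy.to_dict(),
            "n_selected": self.n_selected,
            "top_weights": [[n, w] for n, w in self.top_weights],
            "bias": self.bias.to_dict(),
            "trajectory": self.trajectory,
            "vertex": self.vertex,
            "band_counts": self.band_counts,
            "group_tests": {k: v.to_dict() for k, v in self.group_tests.items()},
            "permutation": self.permutation.to_dict() if self.permutation else None,
        }

    def summary(self) -> str:
        acc = self.nc_accuracy
        lines = [
            "# Study report",
            "",
            f"Selected features: {self.n_selected}",
            f"NC LOOCV: MAE={acc.mae:.2f} y, rMSE={acc.rmse:.2f} y, "
            f"r={acc.pearson_r:.3f}, R2={acc.r2:.3f} (n={acc.n})",
            f"Bias model: offset = {self.bias.alpha:.4f}*CA + {self.bias.beta:.3f}",
            f"Trajectory vertex: {self.vertex:.2f} years "
            f"(quadratic a={self.trajectory['quadratic']['coefficients'][0]:+.5f})",
            f"Band counts: {self.band_counts}",
            "",
            "## Group tests (unadjusted p-values)",
        ]
        for name, res in self.group_tests.items():
            lines.append(
                f"- {name}: {res.test} stat={res.statistic:+.3f}, "
                f"df={res.df:.1f}, p={res.p_value:.4g}"
            )
        if self.permutation is not None:
            lines.append(
                f"\nPermutation test: observed MAE {self.permutation.observed_mae:.2f} y, "
                f"p = {self.permutation.p_value:.4g} ({self.permutation.n_perm} permutations)"
            )
        lines.append("\n## Top weights (years per z-unit)")
        for name, w in self.top_weights:
            lines.append(f"- {name}: {w:+.3f}")
        return "\n".join(lines)


def _load_tables(config: RunConfig) -> tuple[FeatureTable, FeatureTable]:
    if config.input_mode == "synthetic":
        cohort_cfg = dataclasses.replace(
            config.cohort, seed=_stage_seeds(config.seed)[0]
        )
        table, _ = generate_cohort(cohort_cfg)
    elif config.input_mode == "csv":
        if not config.csv_path:
            raise ValueError("csv input mode requires csv_path")
        table = read_feature_table(config.csv_path)
    else:
        raise ValueError(f"unknown input mode {config.input_mode!r}")
    if set(config.modalities) != {"sMRI", "fMRI", "DTI"}:
        table = subset_modalities(table, config.modalities)
    return table.select_group("NC"), table.select_group("SZ")


def run_full_study(config: RunConfig) -> StudyReport:
    """Run every stage of the study and assemble the report."""
    seeds = _stage_seeds(config.seed)
    manifest = {
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "version": __version__,
        "n_features": None,
    }
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    nc, sz = _load_tables(config)
    manifest["n_features"] = len(nc.feature_names)

    # controls: LOOCV evaluation + all-NC model; patients scored on the latter
    results = BrainAgeModel(nc, config.pipeline).fit()
    sz_ba_raw = results.predict(sz) if sz.n_subjects else np.empty(0)

    # age-bias correction fitted on NC out-of-fold predictions
    bias = fit_bias(nc.age, results.loocv_ba, ids=tuple(nc.subject_ids))

    # patient gap trajectory on corrected BAG, vertex-based band split
    sz_bag = bias.correct(sz_ba_raw, sz.age) - sz.age
    traj = BagTrajectory(sz.age, sz_bag).fit()
    vertex = traj.vertex

    records = pd.concat(
        [
            build_prediction_records(
                nc.subject_ids, nc.group, nc.age, results.loocv_ba,
                bias, vertex, config.integer_band,
            ),
            build_prediction_records(
                sz.subject_ids, sz.group, sz.age, sz_ba_raw,
                bias, vertex, config.integer_band,
            ),
        ],
        ignore_index=True,
    )
    band_counts = (
        records.groupby(["group", "age_band"]).size().to_dict()
    )
    band_counts = {f"{g}-{b}": int(n) for (g, b), n in band_counts.items()}

    group_tests = {}
    for grp in ("NC", "SZ"):
        for band in ("youth", "middle"):
            sub = records[(records["group"] == grp) & (records["age_band"] == band)]
            if len(sub) >= 2 and np.var(sub["ca"]) + np.var(sub["ba_corrected"]) > 0:
                group_tests[f"BA_vs_CA[{grp}-{band}]"] = two_sample_t(
                    sub["ba_corrected"], sub["ca"]
                )
    for band in ("youth", "middle"):
        a = records[(records["group"] == "SZ") & (records["age_band"] == band)]["bag"]
        b = records[(records["group"] == "NC") & (records["age_band"] == band)]["bag"]
        if len(a) >= 2 and len(b) >= 2:
            group_tests[f"BAG_SZ_vs_NC[{band}]"] = two_sample_t(a, b)
    counts = np.array(
        [
            [(nc.gender == 0).sum(), (nc.gender == 1).sum()],
            [(sz.gender == 0).sum(), (sz.gender == 1).sum()],
        ]
    )
    if (counts.sum(axis=0) > 0).all() and (counts.sum(axis=1) > 0).all():
        group_tests["gender_NC_vs_SZ"] = chi_square_2x2(counts)

    permutation = None
    if config.n_perm > 0:
        perm_cfg = dataclasses.replace(
            config.pipeline, selection=config.perm_selection
        )
        permutation = permutation_test_mae(
            nc, perm_cfg, n_perm=config.n_perm, seed=seeds[1]
        )

    report = StudyReport(
        manifest=manifest,
        nc_accuracy=results.loocv_accuracy,
        n_selected=results.n_selected,
        top_weights=results.top_weights(config.top_k_weights),
        bias=bias,
        records=records,
        trajectory=traj.to_dict(),
        vertex=vertex,
        band_counts=band_counts,
        group_tests=group_tests,
        permutation=permutation,
    )
    if out_dir:
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        results.fitted.to_json(out_dir / "model.json")
        records.to_csv(out_dir / "predictions.csv", index=False, float_format="%.17g")
        tests_df = pd.DataFrame(
            [
                {"name": k, "test": v.test, "statistic": v.statistic,
                 "df": v.df, "p_value": v.p_value}
                for k, v in group_tests.items()
            ]
        )
        tests_df.to_csv(out_dir / "tests.csv", index=False)
        (out_dir / "report.json").write_text(json.dumps(report.to_dict(), indent=1))
        (out_dir / "report.md").write_text(report.summary())
    return report


def ablate_modalities(
    table: FeatureTable,
    pipeline: PipelineConfig | None = None,
    subsets=MODALITY_SUBSETS,
) -> dict[tuple[str, ...], AccuracyReport]:
    """LOOCV accuracy of the identical pipeline per modality subset.

    ``table`` must be an NC cohort carrying all three modality blocks; each
    subset re-runs preprocessing, selection and LOOCV on its columns only.
    """
    cfg = pipeline or PipelineConfig()
    out: dict[tuple[str, ...], AccuracyReport] = {}
    for subset in subsets:
        sub = subset_modalities(table, subset)
        ba = loocv_predict(sub, cfg)
        out[tuple(subset)] = accuracy(ba, sub.age)
    return out
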