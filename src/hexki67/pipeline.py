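"""End-to-end orchestration: synthetic cohort → metrics → agreement → prognosis.

``run_full`` executes the stages in order (cells → tiles → texture →
regions → agreement → survival) and emits five artifacts: the per
case × platform × region metrics table, its summary-statistics analogue,
the cross-platform/cross-sampling agreement battery, the univariate Cox
table, the multivariable model-suite table, plus a JSON run manifest
sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform as _platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import compute_agreement
from .io import PipelineConfig, write_metrics
from .sampling import REGION_LABELS, region_metrics, metrics_row
from .survival import cox_fit, find_cutoff, fit_model_suite
from .synthetic import Cohort, SyntheticCohortSpec, generate_cohort

__all__ = [
    "compute_cohort_metrics",
    "marker_table",
    "agreement_table",
    "univariate_table",
    "summarize_metrics",
    "run_full",
]

INDICATOR_COLUMNS = [
    "ki67_pct",
    "entropy",
    "homogeneity",
    "contrast",
    "dissimilarity",
    "energy",
    "ashman_d",
]


def compute_cohort_metrics(
    cohort: Cohort,
    config: PipelineConfig | None = None,
    subsample_regions: list[str] | None = None,
) -> pd.DataFrame:
    """Per case × platform × region metrics for a generated cohort.

    Platform 1 gets the full section plus every subsampled region
    (mirroring how the sampling experiments reuse one platform's output);
    platform 2 gets the full section only.  Biopsy placement draws from a
    dedicated substream of the pipeline seed, one child per case.
    """
    config = config or PipelineConfig()
    if subsample_regions is None:
        subsample_regions = list(REGION_LABELS)
    rows = []
    case_ids = cohort.case_ids
    biopsy_ss = np.random.SeedSequence((config.rng_seed, 1337)).spawn(len(case_ids))
    for cid, ss in zip(case_ids, biopsy_ss):
        rng = np.random.default_rng(ss)
        rows.append(
            region_metrics(
                cohort.cells["platform1"][cid], config, rng=rng, regions=subsample_regions
            )
        )
        rows.append(
            pd.DataFrame([metrics_row(cohort.cells["platform2"][cid], "full", config)])
        )
    return pd.concat(rows, ignore_index=True)


def marker_table(metrics: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Wide per-case table: one column per marker × platform × region.

    Column names look like ``ki67_platform1_full`` or
    ``entropy_platform1_biopsy2``; clinical covariates are merged in.
    """
    wide = metrics.pivot_table(
        index="case_id",
        columns=["platform_id", "region"],
        values=["ki67_pct", "entropy"],
        aggfunc="first",
    )
    wide.columns = [
        f"{'ki67' if m == 'ki67_pct' else m}_{p}_{r}" for m, p, r in wide.columns
    ]
    wide = wide.reset_index()
    return clinical.merge(wide, on="case_id", how="inner")


def agreement_table(
    metrics: pd.DataFrame,
    config: PipelineConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """The agreement battery for every platform/sampling comparison.

    Rows: platform1-vs-platform2 (full section) and full-vs-region within
    platform 1, for both Ki67% and entropy.
    """
    config = config or PipelineConfig()
    rng = rng or np.random.default_rng(config.rng_seed)
    wide = metrics.pivot_table(
        index="case_id",
        columns=["platform_id", "region"],
        values=["ki67_pct", "entropy"],
        aggfunc="first",
    )
    rows = []
    for marker in ("ki67_pct", "entropy"):
        comparisons = [("platform1_vs_platform2", ("platform1", "full"), ("platform2", "full"))]
        p1_regions = [
            r
            for (p, r) in {(p, r) for (_, p, r) in wide.columns}
            if p == "platform1" and r != "full"
        ]
        for r in sorted(p1_regions):
            comparisons.append((f"full_vs_{r}", ("platform1", "full"), ("platform1", r)))
        for label, a, b in comparisons:
            if (marker, *a) not in wide.columns or (marker, *b) not in wide.columns:
                continue
            pair = wide[[(marker, *a), (marker, *b)]].dropna()
            if len(pair) < 5:
                continue
            rep = compute_agreement(
                pair.iloc[:, 0].to_numpy(),
                pair.iloc[:, 1].to_numpy(),
                n_boot=config.n_bootstrap,
                rng=rng,
            )
            rows.append({"marker": marker, "comparison": label, **rep.as_dict()})
    return pd.DataFrame(rows)


def univariate_table(data: pd.DataFrame, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Univariate Cox regressions for every binary and continuous indicator.

    Continuous markers are dichotomized at their optimized log-rank cutoff
    on the full cohort (so these rows carry the same selection optimism as
    any optimized-cutoff analysis); binary covariates enter directly.
    """
    config = config or PipelineConfig()
    times = data["time_months"].to_numpy()
    events = data["event"].to_numpy(dtype=bool)
    rows = []
    binary = [c for c in ("node_positive", "grade_g3") if c in data.columns]
    continuous = [
        c
        for c in data.columns
        if c.startswith(("ki67_", "entropy_")) or c == "visual_ki67"
    ]
    for col in binary + continuous:
        try:
            if col in binary:
                x = data[col].astype(float)
                cutoff = np.nan
            else:
                cut = find_cutoff(
                    data[col].to_numpy(), times, events,
                    min_group_frac=config.min_group_frac, variable=col,
                )
                x = (data[col] > cut.cutoff).astype(float)
                cutoff = cut.cutoff
            fit = cox_fit(pd.DataFrame({col: x}), times, events)
            rows.append(
                {
                    "indicator": col,
                    "cutoff": cutoff,
                    "hr": fit.hr[0],
                    "ci_lower": fit.ci_lower[0],
                    "ci_upper": fit.ci_upper[0],
                    "p": fit.wald_p[0],
                }
            )
        except Exception as exc:
            rows.append(
                {
                    "indicator": col,
                    "cutoff": np.nan,
                    "hr": np.nan,
                    "ci_lower": np.nan,
                    "ci_upper": np.nan,
                    "p": np.nan,
                    "flags": f"{type(exc).__name__}",
                }
            )
    return pd.DataFrame(rows)


def summarize_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-indicator summary: mean, sd, median, quartiles, min, max.

    Quartiles use linear interpolation between order statistics.  One row
    per platform × region × indicator.
    """
    rows = []
    for (platform, region), grp in metrics.groupby(["platform_id", "region"]):
        for col in INDICATOR_COLUMNS:
            v = grp[col].dropna().to_numpy()
            if v.size == 0:
                continue
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            rows.append(
                {
                    "platform_id": platform,
                    "region": region,
                    "indicator": col,
                    "n": v.size,
                    "mean": v.mean(),
                    "sd": v.std(ddof=1) if v.size > 1 else 0.0,
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "min": v.min(),
                    "max": v.max(),
                }
            )
    return pd.DataFrame(rows)


def _default_model_specs(data: pd.DataFrame) -> list[tuple[str, str | None]]:
    specs: list[tuple[str, str | None]] = [
        ("clinicopathologic", None),
        ("visual_ki67", "visual_ki67"),
    ]
    for col in data.columns:
        if col.startswith(("ki67_platform", "entropy_platform")):
            specs.append((col, col))
    return specs


def run_full(
    spec: SyntheticCohortSpec,
    config: PipelineConfig | None = None,
    out_dir: str | Path = "hexki67_out",
    model_specs: list[tuple[str, str | None]] | None = None,
) -> dict[str, Path]:
    """Execute the whole pipeline on a synthetic cohort and write artifacts.

    Emits ``metrics.csv``, ``summary.csv``, ``agreement.csv``,
    ``univariate.csv``, ``models.csv`` (+ ``model_covariates.csv``) and
    ``manifest.json`` under ``out_dir`` and returns the path map.
    """
    config = config or PipelineConfig(rng_seed=spec.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(spec, config)
    metrics = compute_cohort_metrics(cohort, config)
    data = marker_table(metrics, cohort.clinical)
    agreement = agreement_table(metrics, config)
    univariate = univariate_table(data, config)
    models, covars = fit_model_suite(
        data, model_specs or _default_model_specs(data), config, seed=config.rng_seed
    )
    paths = {
        "metrics": out / "metrics.csv",
        "summary": out / "summary.csv",
        "agreement": out / "agreement.csv",
        "univariate": out / "univariate.csv",
        "models": out / "models.csv",
        "model_covariates": out / "model_covariates.csv",
        "manifest": out / "manifest.json",
    }
    write_metrics(metrics, paths["metrics"])
    summarize_metrics(metrics).to_csv(paths["summary"], index=False)
    agreement.to_csv(paths["agreement"], index=False)
    univariate.to_csv(paths["univariate"], index=False)
    models.to_csv(paths["models"], index=False)
    covars.to_csv(paths["model_covariates"], index=False)
    manifest = {
        "package_version": __version__,
        "python": _platform.python_version(),
        "seed": spec.seed,
        "config": dataclasses.asdict(config),
        "cohort_spec": dataclasses.asdict(spec),
        "n_cases": len(cohort.clinical),
        "n_events": int(cohort.clinical["event"].sum()),
        "output_sha256": {
            k: hashlib.sha256(p.read_bytes()).hexdigest()
            for k, p in paths.items()
            if k != "manifest"
        },
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, default=str))
    return paths
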