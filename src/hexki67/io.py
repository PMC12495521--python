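"""Domain types, file readers/writers and pipeline configuration.

The pipeline's atomic input is a per-case, per-platform table of tumor-cell
centroids with a binary Ki67 classification, as exported by digital image
analysis (DIA) platforms such as HALO or Aiforia.  Coordinates are stored
internally in micrometres with the origin at each case's bounding-box
minimum, so that grids and biopsy rectangles are scanner-independent.

All delimited files are comma-separated UTF-8 with a header row, matching
typical DIA object-data exports.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CellTable",
    "PipelineConfig",
    "LoadError",
    "read_cell_tables",
    "read_clinical_table",
    "apply_administrative_censoring",
    "write_metrics",
    "read_metrics",
    "read_config",
    "write_config",
    "METRICS_COLUMNS",
    "CLINICAL_COLUMNS",
]

#: follow-up horizon in months (administrative censoring at 10 years)
FOLLOWUP_HORIZON_MONTHS = 120.0

CELL_COLUMNS = ["case_id", "x_um", "y_um", "ki67_positive"]
CLINICAL_COLUMNS = [
    "case_id",
    "age",
    "grade",
    "node_positive",
    "time_months",
    "event",
    "visual_ki67",
]
METRICS_COLUMNS = [
    "case_id",
    "platform_id",
    "region",
    "ki67_pct",
    "entropy",
    "homogeneity",
    "contrast",
    "dissimilarity",
    "energy",
    "ashman_d",
    "n_valid_tiles",
    "n_pairs",
    "flags",
]


class LoadError(ValueError):
    """Raised when an input file violates the expected schema."""


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters shared by all pipeline stages.

    Parameters
    ----------
    hex_side
        Side length of the hexagonal grid elements, µm.
    min_cells
        Minimum cell count for a hexagon to enter the texture analysis;
        sparser tiles are considered insufficiently sampled and excluded.
    n_bins
        Number of equal-width positivity intervals (10 gives the classic
        0–10%, >10–20%, ... binning).
    log_base
        Base of the entropy logarithm.  Locked to 2: a 10-bin co-occurrence
        matrix then bounds entropy by log2(100) ≈ 6.64 bits.
    biopsy_width, biopsy_length
        Simulated core-needle biopsy dimensions, µm.
    n_bootstrap
        Bootstrap replicates for concordance-correlation confidence
        intervals.
    min_group_frac
        Smallest admissible group fraction when scanning survival cutoffs.
    rng_seed
        Seed for every stochastic step of a pipeline run.
    """

    hex_side: float = 262.5
    min_cells: int = 50
    n_bins: int = 10
    log_base: int = 2
    biopsy_width: float = 1200.0
    biopsy_length: float = 12000.0
    n_bootstrap: int = 1000
    min_group_frac: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.hex_side <= 0:
            raise ValueError("hex_side must be positive")
        if self.min_cells < 1:
            raise ValueError("min_cells must be >= 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.log_base != 2:
            raise ValueError("log_base is locked to 2")


@dataclass
class CellTable:
    """One case/platform's tumor cells as coordinate + Ki67-status arrays."""

    case_id: str
    platform_id: str
    x: np.ndarray
    y: np.ndarray
    positive: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.positive = np.asarray(self.positive, dtype=bool)
        if self.x.size == 0:
            raise ValueError(f"case {self.case_id}: empty cell table")
        if not (self.x.size == self.y.size == self.positive.size):
            raise ValueError(f"case {self.case_id}: ragged columns")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError(f"case {self.case_id}: non-finite coordinate")

    @property
    def n_cells(self) -> int:
        return int(self.x.size)

    @property
    def n_pos(self) -> int:
        return int(self.positive.sum())

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        """Tight bounding box (x_min, y_min, x_max, y_max) in µm."""
        return (
            float(self.x.min()),
            float(self.y.min()),
            float(self.x.max()),
            float(self.y.max()),
        )

    def normalized(self) -> "CellTable":
        """Shift coordinates so the bounding-box minimum sits at the origin."""
        x0, y0, _, _ = self.bbox
        return CellTable(
            self.case_id, self.platform_id, self.x - x0, self.y - y0, self.positive
        )

    def subset(self, mask: np.ndarray) -> "CellTable":
        """Row-subset preserving order (raises on an empty selection)."""
        mask = np.asarray(mask, dtype=bool)
        return CellTable(
            self.case_id, self.platform_id, self.x[mask], self.y[mask], self.positive[mask]
        )


def read_cell_tables(
    path: str | Path,
    platform_id: str,
    units: str = "um",
    microns_per_pixel: float | None = None,
) -> dict[str, CellTable]:
    """Read a DIA per-cell export into one :class:`CellTable` per case.

    The file must contain columns ``case_id, x_um, y_um, ki67_positive``.
    With ``units="px"`` coordinates are converted to µm via
    ``microns_per_pixel``.  Row order is preserved; coordinates are
    normalized to each case's bounding-box minimum.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise LoadError(f"{path}: empty file") from exc
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing column(s) {missing}")
    if df.empty:
        raise LoadError(f"{path}: no data rows")
    for col in ("x_um", "y_um"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise LoadError(f"{path}: non-numeric {col} at data row {row}")
        df[col] = coerced
    if units == "px":
        if microns_per_pixel is None or microns_per_pixel <= 0:
            raise LoadError("pixel units require a positive microns_per_pixel")
        df["x_um"] = df["x_um"] * microns_per_pixel
        df["y_um"] = df["y_um"] * microns_per_pixel
    elif units != "um":
        raise LoadError(f"unknown units {units!r} (use 'um' or 'px')")

    tables: dict[str, CellTable] = {}
    for case_id, grp in df.groupby("case_id", sort=False):
        tables[str(case_id)] = CellTable(
            str(case_id),
            platform_id,
            grp["x_um"].to_numpy(),
            grp["y_um"].to_numpy(),
            grp["ki67_positive"].to_numpy().astype(bool),
        ).normalized()
    return tables


def write_cell_tables(tables: dict[str, CellTable], path: str | Path) -> None:
    """Write cell tables back to the CSV schema accepted by the reader."""
    frames = []
    for case_id, t in tables.items():
        frames.append(
            pd.DataFrame(
                {
                    "case_id": case_id,
                    "x_um": t.x,
                    "y_um": t.y,
                    "ki67_positive": t.positive.astype(int),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def apply_administrative_censoring(df: pd.DataFrame) -> pd.DataFrame:
    """Truncate follow-up at 120 months, censoring events past the horizon.

    Idempotent: applying it twice equals applying it once.
    """
    out = df.copy()
    over = out["time_months"] > FOLLOWUP_HORIZON_MONTHS
    out.loc[over, "time_months"] = FOLLOWUP_HORIZON_MONTHS
    out.loc[over, "event"] = False
    out["event"] = out["event"].astype(bool)
    return out


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read the clinical table, applying the 10-year censoring rule.

    Expects columns ``case_id, age, grade, node_positive, time_months,
    event, visual_ki67``; grade is one of G1/G2/G3.  A derived boolean
    column ``grade_g3`` (the G1-2 vs G3 modeling contrast) is appended.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise LoadError(f"{path}: empty file") from exc
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing column(s) {missing}")
    if df["case_id"].duplicated().any():
        dup = df.loc[df["case_id"].duplicated(), "case_id"].iloc[0]
        raise LoadError(f"{path}: duplicate case_id {dup!r}")
    if (df["time_months"] <= 0).any():
        raise LoadError(f"{path}: non-positive follow-up time")
    bad_grade = ~df["grade"].isin(["G1", "G2", "G3"])
    if bad_grade.any():
        raise LoadError(f"{path}: grade must be G1/G2/G3")
    if ((df["visual_ki67"] < 0) | (df["visual_ki67"] > 100)).any():
        raise LoadError(f"{path}: visual_ki67 outside [0, 100]")
    df["node_positive"] = df["node_positive"].astype(bool)
    df["event"] = df["event"].astype(bool)
    df = apply_administrative_censoring(df)
    df["grade_g3"] = df["grade"] == "G3"
    return df


def write_metrics(metrics: pd.DataFrame, path: str | Path) -> None:
    """Write per case × platform × region metrics as CSV (stable columns)."""
    if metrics is None or len(metrics) == 0:
        raise ValueError("refusing to write an empty metrics table")
    missing = [c for c in METRICS_COLUMNS if c not in metrics.columns]
    if missing:
        raise ValueError(f"metrics table missing column(s) {missing}")
    metrics[METRICS_COLUMNS].to_csv(path, index=False)


def read_metrics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=True)
    missing = [c for c in METRICS_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing column(s) {missing}")
    df["flags"] = df["flags"].fillna("").astype(str)
    return df[METRICS_COLUMNS]


def read_config(path: str | Path) -> PipelineConfig:
    """Load a flat TOML key-value file mirroring :class:`PipelineConfig`."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise LoadError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return PipelineConfig(**raw)


def write_config(config: PipelineConfig, path: str | Path) -> None:
    lines = []
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        lines.append(f"{f.name} = {v}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
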