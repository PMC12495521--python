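"""Tissue-sampling simulation: halves, quadrants and core-needle biopsies.

A resected tumor section is rarely what the clinic sees first; these
operations cut a case's cell table into the smaller specimens a pathologist
might receive — geometric halves, quadrants, or a simulated core biopsy
strip (1.2 mm wide, up to 12 mm long, vertical to emulate random tissue
orientation) — so the stability of Ki67% and Haralick entropy under
reduced sampling can be quantified.

Halves and quadrants split at the bounding-box midpoint; cells exactly on
a split line go to the lower/left part, so the parts always partition the
original multiset.  Region metrics re-anchor the hexagonal grid to each
region's own bounding box: a real biopsy would be tiled on its own, and
entropy must not depend on the discarded remainder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hexgrid import global_ki67_pct
from .io import CellTable, PipelineConfig
from .texture import case_texture

__all__ = [
    "RegionMask",
    "split_halves",
    "split_quadrants",
    "simulate_biopsy",
    "BiopsyError",
    "metrics_row",
    "region_metrics",
    "REGION_LABELS",
]

REGION_LABELS = [
    "full",
    "top_half",
    "bottom_half",
    "left_half",
    "right_half",
    "nw",
    "ne",
    "sw",
    "se",
    "biopsy1",
    "biopsy2",
]


class BiopsyError(RuntimeError):
    """Raised when no biopsy strip with enough cells can be placed."""


@dataclass(frozen=True)
class RegionMask:
    kind: str
    rect: tuple[float, float, float, float]  # x_lo, y_lo, x_hi, y_hi (µm)
    label: str

    def __post_init__(self) -> None:
        x_lo, y_lo, x_hi, y_hi = self.rect
        if x_hi < x_lo or y_hi < y_lo:
            raise ValueError("rect must be well-ordered")


def split_halves(cells: CellTable, axis: str = "horizontal") -> tuple[CellTable, CellTable]:
    """Split at the bbox midpoint.

    ``axis="horizontal"`` splits along a horizontal line into
    (bottom, top); ``axis="vertical"`` along a vertical line into
    (left, right).  Boundary cells go to the first (lower/left) part.
    """
    x0, y0, x1, y1 = cells.bbox
    if axis == "horizontal":
        mid = (y0 + y1) / 2.0
        lower = cells.y <= mid
    elif axis == "vertical":
        mid = (x0 + x1) / 2.0
        lower = cells.x <= mid
    else:
        raise ValueError("axis must be 'horizontal' or 'vertical'")
    return cells.subset(lower), cells.subset(~lower)


def split_quadrants(cells: CellTable) -> dict[str, CellTable]:
    """Bbox-midpoint split on both axes into nw/ne/sw/se quadrants.

    North = upper y half; boundary cells go south/west, so the quadrants
    partition the table.  Quadrants with no cells are omitted.
    """
    x0, y0, x1, y1 = cells.bbox
    xm = (x0 + x1) / 2.0
    ym = (y0 + y1) / 2.0
    west = cells.x <= xm
    south = cells.y <= ym
    out: dict[str, CellTable] = {}
    for label, mask in {
        "nw": west & ~south,
        "ne": ~west & ~south,
        "sw": west & south,
        "se": ~west & south,
    }.items():
        if mask.any():
            out[label] = cells.subset(mask)
    return out


def simulate_biopsy(
    cells: CellTable,
    config: PipelineConfig,
    rng: np.random.Generator,
    max_attempts: int = 20,
) -> tuple[CellTable, RegionMask]:
    """Cut a vertical core-biopsy strip from the section.

    The strip is ``biopsy_width`` wide with a uniformly random x-centre;
    its height is the smaller of the bbox height and ``biopsy_length``,
    centred on the cell-mass y-centroid (clipped into the bbox).  The
    x-position is redrawn (up to ``max_attempts`` times) until the strip
    holds at least one valid hexagon's worth of cells.
    """
    x0, y0, x1, y1 = cells.bbox
    w = config.biopsy_width
    if x1 - x0 <= w:
        raise BiopsyError("section narrower than the biopsy width")
    height = min(y1 - y0, config.biopsy_length)
    yc = float(np.clip(cells.y.mean(), y0 + height / 2.0, y1 - height / 2.0))
    y_lo, y_hi = yc - height / 2.0, yc + height / 2.0
    for _ in range(max_attempts):
        xc = rng.uniform(x0 + w / 2.0, x1 - w / 2.0)
        x_lo, x_hi = xc - w / 2.0, xc + w / 2.0
        mask = (cells.x >= x_lo) & (cells.x <= x_hi) & (cells.y >= y_lo) & (cells.y <= y_hi)
        if mask.sum() >= config.min_cells:
            return cells.subset(mask), RegionMask("biopsy", (x_lo, y_lo, x_hi, y_hi), "biopsy")
    raise BiopsyError(f"no strip with >= {config.min_cells} cells in {max_attempts} attempts")


def metrics_row(
    cells: CellTable | None, region: str, config: PipelineConfig
) -> dict[str, object]:
    """One CaseMetrics row (Ki67% + texture) for a region's cell set.

    ``cells=None`` (an empty region) yields a row flagged ``missing`` with
    NaN metrics rather than zeros.
    """
    if cells is None or cells.n_cells == 0:
        return {
            "case_id": "" if cells is None else cells.case_id,
            "platform_id": "" if cells is None else cells.platform_id,
            "region": region,
            "ki67_pct": np.nan,
            "entropy": np.nan,
            "homogeneity": np.nan,
            "contrast": np.nan,
            "dissimilarity": np.nan,
            "energy": np.nan,
            "ashman_d": np.nan,
            "n_valid_tiles": 0,
            "n_pairs": 0,
            "flags": "missing",
        }
    # normalize so the grid re-anchors to this region's own bbox
    local = cells.normalized()
    tf = case_texture(local, config)
    return {
        "case_id": cells.case_id,
        "platform_id": cells.platform_id,
        "region": region,
        "ki67_pct": global_ki67_pct(cells),
        "entropy": tf.entropy,
        "homogeneity": tf.homogeneity,
        "contrast": tf.contrast,
        "dissimilarity": tf.dissimilarity,
        "energy": tf.energy,
        "ashman_d": tf.ashman_d,
        "n_valid_tiles": tf.n_valid_tiles,
        "n_pairs": tf.n_pairs,
        "flags": ";".join(tf.flags),
    }


def region_metrics(
    cells: CellTable,
    config: PipelineConfig,
    rng: np.random.Generator | None = None,
    regions: list[str] | None = None,
) -> pd.DataFrame:
    """Metrics for the full section and each requested subsampled region.

    ``regions`` defaults to every label in :data:`REGION_LABELS`; biopsies
    need ``rng``.  The ``full`` row equals the unrestricted pipeline
    output.
    """
    regions = regions or list(REGION_LABELS)
    rows = []
    bottom, top = split_halves(cells, "horizontal")
    left, right = split_halves(cells, "vertical")
    quads = split_quadrants(cells)
    derived: dict[str, CellTable | None] = {
        "full": cells,
        "top_half": top,
        "bottom_half": bottom,
        "left_half": left,
        "right_half": right,
        **{k: quads.get(k) for k in ("nw", "ne", "sw", "se")},
    }
    for label in regions:
        if label.startswith("biopsy"):
            if rng is None:
                raise ValueError("biopsy regions require an rng")
            try:
                strip, _ = simulate_biopsy(cells, config, rng)
            except BiopsyError:
                rows.append(metrics_row(None, label, config))
                continue
            rows.append(metrics_row(strip, label, config))
        else:
            rows.append(metrics_row(derived.get(label), label, config))
    df = pd.DataFrame(rows)
    df["case_id"] = cells.case_id
    df["platform_id"] = cells.platform_id
    return df
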