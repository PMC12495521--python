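"""Haralick texture features and Ashman's D on the hexagonal tile graph.

Per-tile Ki67 positivity percentages are ranked into equal-width intervals
(by default ten: 0–10%, >10–20%, ..., >90–100%) and every unordered pair of
axially adjacent *valid* tiles contributes a symmetric increment to a
co-occurrence matrix of bin pairs.  Haralick features summarise that
matrix; entropy — the headline heterogeneity metric — is computed in bits
(base-2 logarithm), bounding a 10-bin matrix by log2(100) ≈ 6.644.

Pairs touching an invalid (under-sampled) tile are wholly excluded rather
than bridged.  Degenerate inputs (fewer than two valid tiles, or no
adjacent valid pair) yield entropy 0 with an explanatory flag, mirroring
how a tumor too small to tile scores the minimum heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .hexgrid import build_tiles
from .io import CellTable, PipelineConfig

__all__ = [
    "bin_percentage",
    "CoOccurrenceMatrix",
    "build_cooccurrence",
    "haralick_entropy",
    "haralick_features",
    "ashman_d",
    "TextureFeatures",
    "case_texture",
]

#: axial offsets of the 6-neighborhood; the first three enumerate each
#: unordered adjacent pair exactly once
AXIAL_NEIGHBORS = [(1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1)]


def bin_percentage(pct, n_bins: int = 10):
    """Map positivity percentages to interval ranks 1..n_bins.

    Bin 1 covers [0, w]; bin k covers (w*(k-1), w*k] with w = 100/n_bins,
    so 10% falls in bin 1 and 10.01% in bin 2 for the default ten bins.
    """
    pct_arr = np.asarray(pct, dtype=float)
    if np.any((pct_arr < 0) | (pct_arr > 100)):
        raise ValueError("percentage outside [0, 100]")
    width = 100.0 / n_bins
    # tiny tolerance so ratios that print as bin edges (e.g. 30.000000004)
    # land in the closed-upper-edge bin
    b = np.ceil((pct_arr - 1e-9) / width).astype(np.int64)
    b = np.clip(b, 1, n_bins)
    return b if b.ndim else int(b)


@dataclass
class CoOccurrenceMatrix:
    """Symmetric bin-pair counts over adjacent valid tiles."""

    counts: np.ndarray  # (n_bins, n_bins) int
    n_pairs: int

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def probs(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total


def build_cooccurrence(tiles: pd.DataFrame, n_bins: int = 10) -> CoOccurrenceMatrix:
    """Co-occurrence matrix of positivity bins over adjacent valid tiles.

    ``tiles`` is the output of :func:`hexki67.hexgrid.build_tiles`.  For
    every unordered pair of axially adjacent valid tiles with bins
    (b_i, b_j), both ``counts[b_i-1, b_j-1]`` and ``counts[b_j-1, b_i-1]``
    are incremented, so equal-bin pairs add 2 to the diagonal and the
    matrix is symmetric by construction.
    """
    valid = tiles[tiles["valid"]]
    counts = np.zeros((n_bins, n_bins), dtype=np.int64)
    if len(valid) < 2:
        return CoOccurrenceMatrix(counts, 0)
    bins = bin_percentage(valid["pct_pos"].to_numpy(), n_bins)
    bin_of = {
        (int(q), int(r)): int(b)
        for q, r, b in zip(valid["q"].to_numpy(), valid["r"].to_numpy(), bins)
    }
    n_pairs = 0
    for (q, r), bi in bin_of.items():
        for dq, dr in AXIAL_NEIGHBORS[:3]:
            bj = bin_of.get((q + dq, r + dr))
            if bj is None:
                continue
            counts[bi - 1, bj - 1] += 1
            counts[bj - 1, bi - 1] += 1
            n_pairs += 1
    return CoOccurrenceMatrix(counts, n_pairs)


def haralick_entropy(m: CoOccurrenceMatrix) -> float:
    """Entropy −Σ p·log2(p) of the co-occurrence distribution, in bits."""
    p = m.probs
    nz = p[p > 0]
    if nz.size == 0:
        return 0.0
    return float(-(nz * np.log2(nz)).sum())


def haralick_features(m: CoOccurrenceMatrix) -> dict[str, float]:
    """Energy, contrast, dissimilarity and homogeneity of the matrix.

    Bin distance |i−j| is measured in bin units on the 1..n_bins ranks.
    """
    p = m.probs
    n = m.n_bins
    i, j = np.meshgrid(np.arange(1, n + 1), np.arange(1, n + 1), indexing="ij")
    d = np.abs(i - j)
    return {
        "energy": float((p**2).sum()),
        "contrast": float((d.astype(float) ** 2 * p).sum()),
        "dissimilarity": float((d * p).sum()),
        "homogeneity": float((p / (1.0 + d.astype(float) ** 2)).sum()),
    }


def ashman_d(pcts, random_state: int = 0) -> float:
    """Ashman's bimodality index from a 2-component Gaussian mixture.

    Fits a two-component mixture by EM (5 seeded restarts, variance floor
    to guard against component collapse) and returns
    D = |μ1 − μ2| / sqrt((σ1² + σ2²) / 2).
    """
    x = np.asarray(pcts, dtype=float).reshape(-1, 1)
    if x.shape[0] < 2:
        raise ValueError("Ashman's D needs at least 2 tile values")
    if np.ptp(x) == 0:
        return 0.0
    gm = GaussianMixture(
        n_components=2,
        n_init=5,
        reg_covar=1e-4,
        random_state=random_state,
        max_iter=500,
    ).fit(x)
    mu = gm.means_.ravel()
    var = gm.covariances_.ravel()
    return float(abs(mu[0] - mu[1]) / np.sqrt((var[0] + var[1]) / 2.0))


@dataclass
class TextureFeatures:
    """Per-case texture summary of the valid-tile positivity pattern."""

    entropy: float
    homogeneity: float
    contrast: float
    dissimilarity: float
    energy: float
    ashman_d: float
    n_valid_tiles: int
    n_pairs: int
    flags: list[str] = field(default_factory=list)

    @property
    def degenerate(self) -> bool:
        return "degenerate" in self.flags


def case_texture(
    cells: CellTable,
    config: PipelineConfig | None = None,
    compute_ashman: bool = True,
) -> TextureFeatures:
    """Full texture pipeline for one case: tile → filter → bin → features.

    Degenerate layouts (no adjacent pair of valid tiles) return entropy 0
    and carry a ``"degenerate"`` flag; Ashman's D is NaN when fewer than
    two valid tiles exist (or when ``compute_ashman=False`` skips the
    mixture fit, the single expensive step, for entropy-only callers).
    """
    config = config or PipelineConfig()
    tiles = build_tiles(cells, side=config.hex_side, min_cells=config.min_cells)
    valid = tiles[tiles["valid"]]
    m = build_cooccurrence(tiles, n_bins=config.n_bins)
    feats = haralick_features(m)
    flags: list[str] = []
    if m.n_pairs == 0:
        flags.append("degenerate")
    if not compute_ashman:
        d = float("nan")
    elif len(valid) >= 2:
        d = ashman_d(valid["pct_pos"].to_numpy(), random_state=config.rng_seed)
    else:
        d = float("nan")
        flags.append("too_few_tiles")
    return TextureFeatures(
        entropy=haralick_entropy(m),
        homogeneity=feats["homogeneity"],
        contrast=feats["contrast"],
        dissimilarity=feats["dissimilarity"],
        energy=feats["energy"],
        ashman_d=d,
        n_valid_tiles=int(len(valid)),
        n_pairs=m.n_pairs,
        flags=flags,
    )
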