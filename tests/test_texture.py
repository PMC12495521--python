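import numpy as np
import pandas as pd
import pytest

from hexki67.hexgrid import axial_to_xy
from hexki67.io import CellTable, PipelineConfig
from hexki67.texture import (
    CoOccurrenceMatrix,
    ashman_d,
    bin_percentage,
    build_cooccurrence,
    case_texture,
    haralick_entropy,
    haralick_features,
)


def tiles_frame(entries, valid=None):
    """Build a tiles DataFrame from [(q, r, pct_pos), ...]."""
    df = pd.DataFrame(entries, columns=["q", "r", "pct_pos"])
    df["n_cells"] = 100
    df["n_pos"] = (df["pct_pos"] * 100 / 100).astype(int)
    df["valid"] = True if valid is None else valid
    return df


def brute_force_cooccurrence(df, n_bins=10):
    """All-pairs enumeration at unit axial distance (cube metric)."""
    valid = df[df["valid"]].reset_index(drop=True)
    counts = np.zeros((n_bins, n_bins), dtype=int)
    n_pairs = 0
    b = bin_percentage(valid["pct_pos"].to_numpy(), n_bins)
    for i in range(len(valid)):
        for j in range(i + 1, len(valid)):
            dq = valid.loc[i, "q"] - valid.loc[j, "q"]
            dr = valid.loc[i, "r"] - valid.loc[j, "r"]
            dist = (abs(dq) + abs(dr) + abs(dq + dr)) / 2
            if dist == 1:
                counts[b[i] - 1, b[j] - 1] += 1
                counts[b[j] - 1, b[i] - 1] += 1
                n_pairs += 1
    return counts, n_pairs


@pytest.mark.parametrize(
    "pct, expected",
    [(0, 1), (10, 1), (10.01, 2), (55, 6), (100, 10), (30.000000000000004, 3)],
)
def test_bin_percentage_interval_convention(pct, expected):
    assert bin_percentage(pct) == expected


def test_bin_percentage_rejects_out_of_range():
    with pytest.raises(ValueError):
        bin_percentage(-0.1)
    with pytest.raises(ValueError):
        bin_percentage(100.1)


def test_three_collinear_tiles_worked_example():
    # bins [1, 1, 2] along a row: pairs (1,1) and (1,2)
    df = tiles_frame([(0, 0, 5.0), (1, 0, 5.0), (2, 0, 15.0)])
    m = build_cooccurrence(df)
    assert m.n_pairs == 2
    assert m.counts[0, 0] == 2 and m.counts[0, 1] == 1 and m.counts[1, 0] == 1
    probs = m.probs
    assert probs[0, 0] == pytest.approx(0.5)
    assert probs[0, 1] == pytest.approx(0.25)
    # frozen hand values for the full feature set on this matrix
    assert haralick_entropy(m) == pytest.approx(1.5)
    f = haralick_features(m)
    assert f["energy"] == pytest.approx(0.375)
    assert f["contrast"] == pytest.approx(0.5)
    assert f["dissimilarity"] == pytest.approx(0.5)
    assert f["homogeneity"] == pytest.approx(0.75)


def test_uniform_bin_puts_all_mass_on_diagonal():
    df = tiles_frame([(q, 0, 25.0) for q in range(4)])
    m = build_cooccurrence(df)
    assert m.probs[2, 2] == pytest.approx(1.0)
    f = haralick_features(m)
    assert f["contrast"] == 0.0 and f["dissimilarity"] == 0.0
    assert f["homogeneity"] == pytest.approx(1.0)


def test_single_or_invalid_tiles_give_empty_matrix():
    assert build_cooccurrence(tiles_frame([(0, 0, 40.0)])).n_pairs == 0
    # invalid neighbor breaks the pair entirely
    df = tiles_frame([(0, 0, 5.0), (1, 0, 95.0)], valid=[True, False])
    m = build_cooccurrence(df)
    assert m.n_pairs == 0 and haralick_entropy(m) == 0.0


def test_cooccurrence_matches_brute_force_on_random_layouts(rng):
    for _ in range(120):
        n_tiles = rng.integers(2, 26)
        qs = rng.integers(0, 5, n_tiles)
        rs = rng.integers(0, 5, n_tiles)
        seen = set()
        entries, valid = [], []
        for q, r in zip(qs, rs):
            if (q, r) in seen:
                continue
            seen.add((q, r))
            entries.append((q, r, rng.uniform(0, 100)))
            valid.append(rng.random() < 0.8)
        df = tiles_frame(entries, valid=valid)
        m = build_cooccurrence(df)
        ref_counts, ref_pairs = brute_force_cooccurrence(df)
        assert np.array_equal(m.counts, ref_counts)
        assert m.n_pairs == ref_pairs


def test_entropy_bounds_and_degenerate_cases():
    n = 10
    uniform = CoOccurrenceMatrix(np.ones((n, n), dtype=int), n * n // 2)
    assert haralick_entropy(uniform) == pytest.approx(np.log2(100), abs=1e-6)
    point = np.zeros((n, n), dtype=int)
    point[3, 3] = 7
    m = CoOccurrenceMatrix(point, 7)
    assert haralick_entropy(m) == 0.0
    assert haralick_features(m)["energy"] == pytest.approx(1.0)
    empty = CoOccurrenceMatrix(np.zeros((n, n), dtype=int), 0)
    assert haralick_entropy(empty) == 0.0


def test_entropy_invariant_under_simultaneous_bin_relabeling(rng):
    counts = rng.integers(0, 9, (10, 10))
    counts = counts + counts.T  # symmetrize
    perm = rng.permutation(10)
    m1 = CoOccurrenceMatrix(counts, int(counts.sum() // 2))
    m2 = CoOccurrenceMatrix(counts[np.ix_(perm, perm)], m1.n_pairs)
    assert haralick_entropy(m1) == pytest.approx(haralick_entropy(m2))


def test_ashman_d_formula_and_recovery(rng):
    # analytic: equal-width components 60 apart with sd 10 give D = 6
    x = np.concatenate([rng.normal(20, 10, 4000), rng.normal(80, 10, 4000)])
    assert ashman_d(np.clip(x, 0, 100)) == pytest.approx(6.0, rel=0.08)
    # mixture recovery: components (20, 5) and (70, 5) -> D = 10
    y = np.concatenate([rng.normal(20, 5, 250), rng.normal(70, 5, 250)])
    assert ashman_d(y) == pytest.approx(10.0, rel=0.10)
    # identical components collapse to D ~ 0 via the constant guard
    assert ashman_d(np.full(50, 42.0)) == 0.0
    with pytest.raises(ValueError):
        ashman_d([1.0])


def checkerboard_case(side=262.5, half=6, cells_per_tile=400, seed=0):
    """Cells on a hex lattice whose tiles alternate 5% / 95% positivity."""
    rng = np.random.default_rng(seed)
    xs, ys, ps = [], [], []
    for q in range(-half, half):
        for r in range(-half, half):
            cx, cy = axial_to_xy(np.array([q]), np.array([r]), side)
            theta = rng.uniform(0, 2 * np.pi, cells_per_tile)
            rad = rng.uniform(0, side * 0.45, cells_per_tile)
            xs.append(cx[0] + rad * np.cos(theta))
            ys.append(cy[0] + rad * np.sin(theta))
            pct = 0.05 if (q + r) % 2 == 0 else 0.95
            ps.append(rng.random(cells_per_tile) < pct)
    return CellTable("cb", "p", np.concatenate(xs), np.concatenate(ys), np.concatenate(ps))


def test_checkerboard_field_has_high_entropy():
    tf = case_texture(checkerboard_case(), PipelineConfig())
    assert tf.entropy >= 1.5
    assert tf.n_valid_tiles >= 100


def test_case_texture_degenerate_input_flags(rng):
    # all cells in one hexagon -> no adjacency, entropy 0, flagged
    cells = CellTable("c", "p", rng.uniform(0, 40, 200), rng.uniform(0, 40, 200), rng.random(200) < 0.5)
    tf = case_texture(cells, PipelineConfig())
    assert tf.entropy == 0.0 and tf.degenerate
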