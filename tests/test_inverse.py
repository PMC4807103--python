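"""Inverse-solution checks: prior structure, regularization behaviour,
localization, window averaging, and voxel-wise contrasts."""

import numpy as np
import pytest

from erpfield.dataset import Erp
from erpfield.inverse import (
    build_laura_inverse,
    estimate_window_activity,
    laura_prior,
    voxelwise_contrast,
)
from erpfield.sourcespace import SourceGrid


@pytest.fixture(scope="module")
def inverse(lead110):
    return build_laura_inverse(lead110)


def test_prior_rows_annihilate_constants(grid1000):
    A = laura_prior(grid1000, 2)
    # each row: 1 at the diagonal, neighbour weights summing to -1
    assert np.allclose(A.sum(axis=1), 0.0, atol=1e-12)
    assert np.allclose(np.diag(A), 1.0)
    with pytest.raises(ValueError):
        laura_prior(grid1000, 4)


def test_disconnected_grid_point_rejected():
    pts = np.array([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]])
    grid = SourceGrid(points=pts, spacing=0.1, neighbors=((), ()))
    with pytest.raises(ValueError, match="neighbour"):
        laura_prior(grid)


def test_zero_sensor_data_gives_zero_estimate(inverse):
    est = inverse.estimate(np.zeros(110))
    assert np.all(est.values == 0.0)


def test_estimate_is_strength_equivariant(inverse, rng):
    x = rng.normal(size=110)
    lam = inverse.mid_lambda()
    v1 = inverse.estimate(x, lam=lam).values
    v3 = inverse.estimate(3.0 * x, lam=lam).values
    assert np.allclose(v3, 3.0 * v1, rtol=1e-10)


def test_estimate_energy_shrinks_monotonically_with_lambda(inverse, rng):
    x = rng.normal(size=110)
    lams = inverse._s.max() ** 2 * np.logspace(-6, 2, 12)
    energies = [np.sum(inverse.estimate(x, lam=l).values ** 2) for l in lams]
    assert all(a > b for a, b in zip(energies, energies[1:]))
    assert energies[-1] < 1e-3 * energies[0]


def test_single_source_localization(lead110, grid1000, inverse, rng):
    """Noiseless single grid-point sources under the electrode cap: the
    magnitude peak lands within one lattice step (<= sqrt(3) spacings) of the
    true point for at least 90% of 50 random superficial sources."""
    r = np.linalg.norm(grid1000.points, axis=1)
    candidates = np.flatnonzero((r >= 0.55) & (grid1000.points[:, 2] > 0))
    picks = rng.choice(candidates, 50, replace=False)
    op = inverse.operator(inverse.mid_lambda())
    hits = 0
    for idx in picks:
        moment = rng.normal(size=3)
        moment /= np.linalg.norm(moment)
        x = lead110.matrix[:, 3 * idx : 3 * idx + 3] @ moment
        mag = np.linalg.norm((op @ x).reshape(-1, 3), axis=1)
        d = np.linalg.norm(grid1000.points[np.argmax(mag)] - grid1000.points[idx])
        hits += d <= np.sqrt(3) * grid1000.spacing * 1.001
    assert hits >= 45


def test_gcv_lambda_prefers_more_smoothing_for_noisier_data(lead110, inverse, rng):
    idx = inverse.lead_field.grid.nearest([0.0, 0.2, 0.5])
    clean = lead110.matrix[:, 3 * idx : 3 * idx + 3] @ np.array([0.0, 0.0, 1.0])
    lam_clean = inverse.gcv_lambda(clean)
    noisy = clean + rng.normal(scale=0.3 * np.abs(clean).max(), size=110)
    lam_noisy = inverse.gcv_lambda(noisy)
    assert lam_noisy > lam_clean


def test_lambda_modes(lead110):
    with pytest.raises(ValueError):
        build_laura_inverse(lead110, "bogus")
    with pytest.raises(ValueError):
        build_laura_inverse(lead110, -1.0)
    inv = build_laura_inverse(lead110, "mid")
    assert inv.resolve_lambda() == inv.mid_lambda()
    with pytest.raises(ValueError, match="GCV"):
        build_laura_inverse(lead110, "gcv").resolve_lambda()


def _erp(data):
    return Erp(
        data=data, sampling_rate=500.0, epoch_window=(-200.0, 1000.0), n_trials=90
    )


def test_window_activity_single_sample_equals_map_inversion(inverse, rng):
    data = rng.normal(size=(110, 600))
    erp = _erp(data)
    t0 = erp.times[320]
    act = estimate_window_activity(inverse, erp, (t0, t0))
    direct = inverse.estimate(data[:, 320]).values
    assert np.allclose(act, direct)


def test_window_activity_constant_erp_window_invariant(inverse):
    data = np.tile(np.random.default_rng(2).normal(size=(110, 1)), (1, 600))
    erp = _erp(data)
    a = estimate_window_activity(inverse, erp, (0.0, 100.0))
    b = estimate_window_activity(inverse, erp, (400.0, 900.0))
    assert np.allclose(a, b)


def test_window_average_then_invert_equals_invert_then_average(inverse, rng):
    """By linearity, averaging maps then inverting equals inverting each
    sample and averaging the moment vectors."""
    data = rng.normal(size=(110, 30))
    lam = inverse.mid_lambda()
    avg_then_inv, _ = inverse.moments(data.mean(axis=1), lam=lam)
    per_sample, _ = inverse.moments(data, lam=lam)
    assert np.allclose(avg_then_inv, per_sample.mean(axis=2), atol=1e-10)


def test_empty_window_rejected(inverse):
    erp = _erp(np.zeros((110, 600)))
    with pytest.raises(ValueError, match="window"):
        estimate_window_activity(inverse, erp, (2000.0, 2100.0))


# -- voxel-wise contrast -----------------------------------------------------

def _connected_points(grid, k, start_at=None):
    start = grid.nearest(start_at if start_at is not None else [0.3, 0.2, 0.3])
    chain = [start]
    frontier = [start]
    while len(chain) < k and frontier:
        i = frontier.pop(0)
        for j in grid.neighbors[i]:
            if j not in chain:
                chain.append(j)
                frontier.append(j)
                if len(chain) == k:
                    break
    return chain[:k]


def _activities_with_effect(grid, points, n=15, delta=1.0, seed=0):
    rng = np.random.default_rng(seed)
    base = np.abs(rng.normal(5.0, 0.1, size=(n, grid.n_points)))
    eff = base.copy()
    eff[:, points] += delta + rng.normal(0.0, 0.1, size=(n, len(points)))
    return eff, base


@pytest.mark.parametrize("k,expected_clusters", [(9, 0), (10, 1)])
def test_cluster_extent_threshold_boundary(grid1000, k, expected_clusters):
    pts = _connected_points(grid1000, k)
    A, B = _activities_with_effect(grid1000, pts)
    con = voxelwise_contrast(A, B, grid1000, cluster_min=10)
    real = [c for c in con.clusters if set(c["members"]) & set(pts)]
    assert len(real) == expected_clusters
    if expected_clusters:
        assert real[0]["n_points"] >= 10
        assert real[0]["sign"] == 1


def test_identical_conditions_give_no_clusters(grid1000, rng):
    A = np.abs(rng.normal(5.0, 0.5, size=(15, grid1000.n_points)))
    con = voxelwise_contrast(A, A.copy(), grid1000)
    assert con.clusters == []
    assert not con.significant.any()


def test_positive_and_negative_clusters_disjoint(grid1000):
    up = _connected_points(grid1000, 12, [0.3, 0.2, 0.3])
    down = _connected_points(grid1000, 12, [-0.3, -0.2, 0.3])
    A, B = _activities_with_effect(grid1000, up, seed=3)
    B2 = B.copy()
    B2[:, down] += 1.0 + np.random.default_rng(4).normal(0.0, 0.1, (15, len(down)))
    con = voxelwise_contrast(A, B2, grid1000)
    pos = {i for c in con.clusters if c["sign"] > 0 for i in c["members"]}
    neg = {i for c in con.clusters if c["sign"] < 0 for i in c["members"]}
    assert pos and neg and not (pos & neg)
    # labels partition significant points
    assert set(np.flatnonzero(con.cluster_labels > 0)) == pos | neg
    assert int(con.significant.sum()) == len(pos | neg)


def test_contrast_critical_value_matches_df14(grid1000):
    """With 15 subjects, significance before clustering is |t| > 2.14."""
    A = np.abs(np.random.default_rng(1).normal(5.0, 0.5, (15, grid1000.n_points)))
    con = voxelwise_contrast(A, A + 0.1, grid1000)
    raw_sig = con.p_values < 0.05
    assert np.array_equal(raw_sig, np.abs(np.nan_to_num(con.t_values)) > 2.144786)
    assert con.df == 14


def test_contrast_subject_mismatch_rejected(grid1000):
    with pytest.raises(ValueError):
        voxelwise_contrast(
            np.zeros((5, grid1000.n_points)),
            np.zeros((6, grid1000.n_points)),
            grid1000,
        )
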