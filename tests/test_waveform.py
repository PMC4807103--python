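"""Mass-univariate statistics: paired t oracle, persistence criteria, and
brute-force connected-component oracles."""

import numpy as np
import pytest
from scipy import stats

from erpfield._criteria import find_runs
from erpfield.waveform import (
    apply_spatial_criterion,
    apply_temporal_criterion,
    pointwise_paired_t,
    waveform_analysis,
)


# -- paired t ----------------------------------------------------------------

def test_paired_t_matches_scipy(rng):
    A = rng.normal(size=(12, 6, 20))
    B = rng.normal(size=(12, 6, 20))
    t, p = pointwise_paired_t(A, B)
    ref = stats.ttest_rel(A, B, axis=0)
    assert np.allclose(t, ref.statistic, atol=1e-10)
    assert np.allclose(p, ref.pvalue, atol=1e-10)


def test_identical_conditions_give_p_one():
    A = np.random.default_rng(0).normal(size=(8, 4, 10))
    t, p = pointwise_paired_t(A, A.copy())
    assert np.all(np.isnan(t))
    assert np.all(p == 1.0)


def test_global_sign_flip_negates_t(rng):
    A = rng.normal(size=(10, 3, 8))
    B = rng.normal(size=(10, 3, 8))
    t1, _ = pointwise_paired_t(A, B)
    t2, _ = pointwise_paired_t(-A, -B)
    t3, _ = pointwise_paired_t(B, A)
    assert np.allclose(t2, -t1)
    assert np.allclose(t3, -t1)


def test_significance_boundary_at_critical_t():
    """At n=15 the two-tailed .05 boundary sits at |t| = 2.1448: a sample
    t just above it is significant, just below is not."""
    n = 15
    z = np.arange(n, dtype=float)
    z = (z - z.mean()) / z.std(ddof=1)  # exactly mean 0, sd 1
    for target, sig in [(2.2, True), (2.1, False)]:
        d = target / np.sqrt(n) + z  # sample mean/sd give t == target
        t, p = pointwise_paired_t(d[:, None, None], np.zeros((n, 1, 1)))
        assert t[0, 0] == pytest.approx(target)
        assert bool(p[0, 0] < 0.05) == sig


def test_subject_mismatch_rejected(rng):
    with pytest.raises(ValueError):
        pointwise_paired_t(rng.normal(size=(5, 3, 4)), rng.normal(size=(6, 3, 4)))


# -- temporal criterion ------------------------------------------------------

def _mask_with_run(length, start, run):
    m = np.zeros((1, length), dtype=bool)
    m[0, start : start + run] = True
    return m


@pytest.mark.parametrize("run,kept", [(9, False), (10, True), (15, True)])
def test_temporal_criterion_run_boundary(run, kept):
    out = apply_temporal_criterion(_mask_with_run(60, 20, run), 10)
    assert out.sum() == (run if kept else 0)


def test_temporal_criterion_all_true_unchanged():
    m = np.ones((3, 30), dtype=bool)
    assert np.array_equal(apply_temporal_criterion(m, 10), m)


def test_temporal_criterion_against_bruteforce_oracle(rng):
    """Random masks: every surviving run has length >= 10, every cleared run
    had length < 10, checked with an independent scan."""
    for _ in range(50):
        m = rng.random((4, 80)) < 0.55
        out = apply_temporal_criterion(m, 10)
        assert not np.any(out & ~m)  # only removes
        for row_in, row_out in zip(m, out):
            runs = find_runs(row_in)
            expect = np.zeros_like(row_in)
            for a, b in runs:
                if b - a >= 10:
                    expect[a:b] = True
            assert np.array_equal(row_out, expect)


def test_temporal_criterion_commutes_with_channel_relabeling(rng):
    m = rng.random((8, 40)) < 0.5
    perm = rng.permutation(8)
    assert np.array_equal(
        apply_temporal_criterion(m, 10)[perm], apply_temporal_criterion(m[perm], 10)
    )


# -- spatial criterion -------------------------------------------------------

def _connected_chain(montage, cluster, k):
    """k adjacency-connected electrodes inside one named cluster."""
    members = set(montage.clusters[cluster])
    start = next(iter(sorted(members)))
    chain = [start]
    frontier = [start]
    while len(chain) < k and frontier:
        i = frontier.pop(0)
        for j in montage.neighbors[i]:
            if j in members and j not in chain:
                chain.append(j)
                frontier.append(j)
                if len(chain) == k:
                    break
    assert len(chain) == k, "cluster too small for the requested chain"
    return chain


@pytest.mark.parametrize("k,kept", [(4, False), (5, True)])
def test_spatial_criterion_group_size_boundary(montage110, k, kept):
    mask = np.zeros((110, 3), dtype=bool)
    mask[_connected_chain(montage110, "AM", k), 1] = True
    out = apply_spatial_criterion(mask, montage110, 5)
    assert out[:, 1].sum() == (k if kept else 0)
    assert out[:, [0, 2]].sum() == 0


def test_spatial_criterion_does_not_pool_across_clusters(montage110):
    """Three significant electrodes in each of two clusters never make a
    five-electrode group, even if the six are globally connected."""
    mask = np.zeros((110, 1), dtype=bool)
    mask[_connected_chain(montage110, "AM", 3), 0] = True
    mask[_connected_chain(montage110, "CM", 3), 0] = True
    out = apply_spatial_criterion(mask, montage110, 5)
    assert out.sum() == 0


def test_spatial_criterion_against_networkx_oracle(montage110, rng):
    """Random masks vs an independent connected-components implementation."""
    nx = pytest.importorskip("networkx")
    G = nx.Graph()
    G.add_nodes_from(range(110))
    for i, nbrs in enumerate(montage110.neighbors):
        G.add_edges_from((i, j) for j in nbrs)
    for _ in range(20):
        mask = rng.random((110, 2)) < 0.3
        out = apply_spatial_criterion(mask, montage110, 5)
        for s in range(2):
            expect = np.zeros(110, dtype=bool)
            active = set(np.flatnonzero(mask[:, s]).tolist())
            for members in montage110.clusters.values():
                sub = G.subgraph(active & set(members))
                for comp in nx.connected_components(sub):
                    if len(comp) >= 5:
                        expect[list(comp)] = True
            assert np.array_equal(out[:, s], expect)


def test_spatial_criterion_commutes_with_sample_relabeling(montage110, rng):
    mask = rng.random((110, 6)) < 0.25
    perm = rng.permutation(6)
    a = apply_spatial_criterion(mask, montage110, 5)[:, perm]
    b = apply_spatial_criterion(mask[:, perm], montage110, 5)
    assert np.array_equal(a, b)


# -- combined analysis -------------------------------------------------------

def test_filtering_only_removes_significance(montage110, rng):
    A = rng.normal(size=(10, 110, 60))
    B = A + rng.normal(scale=0.5, size=A.shape)
    res = waveform_analysis(A, B, montage110)
    raw = res.p_values < res.alpha
    assert not np.any(res.significant & ~raw)


def test_null_familywise_rate_reduced_by_criteria(montage32):
    """Across null replicates, datasets with any surviving cell after both
    criteria are rarer than datasets with any raw point-wise hit."""
    rng = np.random.default_rng(99)
    any_raw = any_filtered = 0
    for _ in range(40):
        A = rng.normal(size=(8, 32, 60))
        B = rng.normal(size=(8, 32, 60))
        res = waveform_analysis(A, B, montage32)
        any_raw += (res.p_values < res.alpha).any()
        any_filtered += res.significant.any()
    assert any_raw >= 39  # point-wise testing fires almost always
    assert any_filtered < any_raw
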