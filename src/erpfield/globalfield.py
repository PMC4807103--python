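"""Reference-independent global electric-field statistics and their tests.

Two scalar descriptors summarize a scalp map at one time point:

* **GFP** (global field power) — the spatial standard deviation of the
  average-referenced potentials: ``sqrt(mean_e v_e**2)``.  Reference-free
  index of field strength.
* **DISS** (global dissimilarity) — the root-mean-square difference between
  two maps after each is scaled to unit GFP.  Strength-independent index of
  topographic difference; ranges 0 (identical configurations) to 2 (inverted
  maps) and satisfies ``DISS**2 = 2 * (1 - r)`` with r the spatial Pearson
  correlation of the maps.

Differences between paired conditions are tested point-wise in time with
randomization statistics: the within-subject condition labels are permuted
(1000 permutations by default), the group statistic is recomputed per
permutation, and p is the inclusive proportion ``(b + 1) / (n_perm + 1)`` of
permuted statistics at least as large as the observed one.  Applied to GFP
this tests strength modulation; applied to DISS between the GFP-normalized
group-average maps it is the topographic analysis of variance (TANOVA).
Significant samples must persist for a minimum run (20 ms at 500 Hz).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from ._criteria import enforce_min_run, find_runs
from .dataset import Erp

__all__ = [
    "gfp",
    "diss",
    "GlobalFieldResult",
    "gfp_randomization_test",
    "tanova",
    "plot_global_field",
]

logger = logging.getLogger("erpfield.globalfield")


def gfp(scalp_map: np.ndarray, *, channel_axis: int = 0) -> np.ndarray:
    """Global field power: spatial SD of the average-referenced map.

    Works on a single map (returns a scalar) or any array with a channel
    axis (returns the per-slice GFP).  The channel mean is subtracted
    internally, so the result is identical for any recording reference.
    """
    v = np.asarray(scalp_map, dtype=float)
    if v.shape[channel_axis] < 2:
        raise ValueError("GFP requires at least 2 channels")
    v = v - v.mean(axis=channel_axis, keepdims=True)
    return np.sqrt(np.mean(v**2, axis=channel_axis))


def diss(map_u: np.ndarray, map_v: np.ndarray) -> float:
    """Global dissimilarity between two scalp maps (0 to 2).

    Each map is average-referenced and scaled to unit GFP before the RMS
    difference is taken.  Raises if either map has zero GFP.
    """
    u = np.asarray(map_u, dtype=float)
    v = np.asarray(map_v, dtype=float)
    u = u - u.mean()
    v = v - v.mean()
    gu, gv = gfp(u), gfp(v)
    if gu == 0 or gv == 0:
        raise ValueError(
            f"DISS undefined for a zero-GFP map (GFP_u={gu}, GFP_v={gv})"
        )
    return float(np.sqrt(np.mean((u / gu - v / gv) ** 2)))


@dataclass
class GlobalFieldResult:
    """Point-wise randomization-test output for GFP or TANOVA."""

    statistic: str  # "gfp" | "tanova"
    observed: np.ndarray  # per-sample observed statistic
    gfp_a: np.ndarray
    gfp_b: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    significant_windows: list[tuple[float, float]]
    times_ms: np.ndarray
    n_permutations: int
    alpha: float
    min_run_samples: int
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "statistic": self.statistic,
                "n_permutations": self.n_permutations,
                "alpha": self.alpha,
                "min_run_samples": self.min_run_samples,
                "seed": self.seed,
                "significant_windows_ms": [list(w) for w in self.significant_windows],
            },
            indent=2,
            sort_keys=True,
        )


def _stack(erps) -> np.ndarray:
    if isinstance(erps, np.ndarray):
        return erps
    return np.stack([e.data if isinstance(e, Erp) else np.asarray(e) for e in erps])


def _times(erps, times_ms, n_samples) -> np.ndarray:
    if times_ms is not None:
        return np.asarray(times_ms, dtype=float)
    first = erps[0]
    if isinstance(first, Erp):
        return first.times
    return np.arange(n_samples, dtype=float)


def _windows(
    significant: np.ndarray, times: np.ndarray
) -> list[tuple[float, float]]:
    return [
        (float(times[a]), float(times[b - 1])) for a, b in find_runs(significant)
    ]


def _check_pairing(A: np.ndarray, B: np.ndarray, n_perm: int) -> None:
    if A.shape != B.shape:
        raise ValueError(f"paired conditions differ in shape: {A.shape} vs {B.shape}")
    if A.shape[0] < 2:
        raise ValueError("at least 2 subjects are required")
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")


def gfp_randomization_test(
    erps_a,
    erps_b,
    n_perm: int = 1000,
    alpha: float = 0.05,
    min_run_samples: int = 10,
    seed: int = 0,
    *,
    times_ms=None,
) -> GlobalFieldResult:
    """Point-wise paired randomization test on subject GFP between conditions.

    The observed statistic at each sample is the absolute group-mean
    difference of single-subject GFP.  The null flips each subject's
    condition assignment independently per permutation.
    """
    A, B = _stack(erps_a), _stack(erps_b)
    _check_pairing(A, B, n_perm)
    n = A.shape[0]
    ga = gfp(A, channel_axis=1)  # (n, T)
    gb = gfp(B, channel_axis=1)
    d = ga - gb
    observed = np.abs(d.mean(axis=0))
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
    perm_stats = np.abs(signs @ d) / n  # (n_perm, T)
    p = (1.0 + (perm_stats >= observed[None, :]).sum(axis=0)) / (n_perm + 1.0)
    sig = enforce_min_run(p < alpha, min_run_samples)
    times = _times(erps_a, times_ms, A.shape[2])
    return GlobalFieldResult(
        statistic="gfp",
        observed=observed,
        gfp_a=gfp(A.mean(axis=0), channel_axis=0),
        gfp_b=gfp(B.mean(axis=0), channel_axis=0),
        p_values=p,
        significant=sig,
        significant_windows=_windows(sig, times),
        times_ms=times,
        n_permutations=n_perm,
        alpha=alpha,
        min_run_samples=min_run_samples,
        seed=seed,
    )


def _diss_series(maps_a: np.ndarray, maps_b: np.ndarray) -> np.ndarray:
    """DISS per sample between two (..., channels, T) map series.

    Samples where either map has zero GFP yield NaN (callers convert these
    to p = 1 and log).
    """
    a = maps_a - maps_a.mean(axis=-2, keepdims=True)
    b = maps_b - maps_b.mean(axis=-2, keepdims=True)
    ga = np.sqrt(np.mean(a**2, axis=-2, keepdims=True))
    gb = np.sqrt(np.mean(b**2, axis=-2, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(np.mean((a / ga - b / gb) ** 2, axis=-2))
    return out


def tanova(
    erps_a,
    erps_b,
    n_perm: int = 1000,
    alpha: float = 0.05,
    min_run_samples: int = 10,
    seed: int = 0,
    *,
    times_ms=None,
    statistic_on: str = "group_map",
    perm_chunk: int = 100,
) -> GlobalFieldResult:
    """Topographic analysis of variance: randomization test on DISS.

    The observed statistic at each sample is, by default, the DISS between
    the two GFP-normalized group-average maps; the null permutes the
    within-subject condition labels and recomputes the group maps per
    permutation.  ``statistic_on='subject_mean'`` instead averages the
    per-subject DISS values (both conventions are found in practice; the
    group-map form is the default).
    """
    if statistic_on not in ("group_map", "subject_mean"):
        raise ValueError(f"unknown statistic_on {statistic_on!r}")
    A, B = _stack(erps_a), _stack(erps_b)
    _check_pairing(A, B, n_perm)
    n, n_ch, n_t = A.shape

    def stat(mean_a, mean_b, per_subj_a=None, per_subj_b=None):
        if statistic_on == "group_map":
            return _diss_series(mean_a, mean_b)
        return _diss_series(per_subj_a, per_subj_b).mean(axis=-2)

    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    if statistic_on == "group_map":
        observed = _diss_series(mean_a, mean_b)
    else:
        observed = _diss_series(A, B).mean(axis=0)
    degenerate = ~np.isfinite(observed)
    if degenerate.any():
        logger.info(
            "%d samples with zero-GFP group map; p set to 1", int(degenerate.sum())
        )
    rng = np.random.default_rng(seed)
    count = np.zeros(n_t)
    D = (B - A).reshape(n, -1)  # swap direction per subject
    for start in range(0, n_perm, perm_chunk):
        m = min(perm_chunk, n_perm - start)
        Z = rng.integers(0, 2, size=(m, n)).astype(float)
        delta = (Z @ D).reshape(m, n_ch, n_t) / n
        if statistic_on == "group_map":
            perm_stat = _diss_series(mean_a + delta, mean_b - delta)
        else:
            zmask = Z[:, :, None, None].astype(bool)
            pa = np.where(zmask, B[None], A[None])
            pb = np.where(zmask, A[None], B[None])
            perm_stat = _diss_series(pa, pb).mean(axis=1)
        with np.errstate(invalid="ignore"):
            count += np.nansum(perm_stat >= observed[None, :], axis=0)
    p = (1.0 + count) / (n_perm + 1.0)
    p[degenerate] = 1.0
    sig = enforce_min_run(p < alpha, min_run_samples)
    times = _times(erps_a, times_ms, n_t)
    return GlobalFieldResult(
        statistic="tanova",
        observed=np.where(degenerate, np.nan, observed),
        gfp_a=gfp(mean_a, channel_axis=0),
        gfp_b=gfp(mean_b, channel_axis=0),
        p_values=p,
        significant=sig,
        significant_windows=_windows(sig, times),
        times_ms=times,
        n_permutations=n_perm,
        alpha=alpha,
        min_run_samples=min_run_samples,
        seed=seed,
    )


def plot_global_field(
    result_gfp: GlobalFieldResult, result_tanova: GlobalFieldResult, path
) -> None:
    """Two-panel summary: group GFP traces and DISS, with significant windows
    shaded."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(9, 5), sharex=True)
    t = result_gfp.times_ms
    axes[0].plot(t, result_gfp.gfp_a, "k", label="condition A")
    axes[0].plot(t, result_gfp.gfp_b, "r", label="condition B")
    axes[0].set_ylabel("GFP (μV)")
    axes[0].legend(loc="upper right", frameon=False)
    for a, b in result_gfp.significant_windows:
        axes[0].axvspan(a, b, color="0.8")
    axes[1].plot(result_tanova.times_ms, result_tanova.observed, "b")
    axes[1].set_ylabel("DISS")
    axes[1].set_xlabel("time (ms)")
    for a, b in result_tanova.significant_windows:
        axes[1].axvspan(a, b, color="0.8")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
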