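"""Mass-univariate waveform statistics on subject ERP amplitudes.

Point-wise paired t-tests are computed at every electrode and time point
between two within-subject conditions, then filtered by two persistence
criteria: a temporal criterion (significant runs must last a minimum number
of contiguous samples, 10 at 500 Hz = 20 ms by default) and a spatial
criterion (at each sample, significant electrodes must form a group of at
least five adjacency-contiguous electrodes within one of the nine named
scalp clusters).  No further multiple-comparison adjustment is applied; the
persistence criteria are the only protection, which is a deliberate, known
limitation of the protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._criteria import connected_components, enforce_min_run, find_runs
from .dataset import Erp
from .montage import Montage

__all__ = [
    "SignificanceMask",
    "pointwise_paired_t",
    "apply_temporal_criterion",
    "apply_spatial_criterion",
    "waveform_analysis",
    "significant_intervals",
    "write_intervals",
]

logger = logging.getLogger("erpfield.waveform")


@dataclass
class SignificanceMask:
    """Electrode x time significance map with the test metadata behind it."""

    t_values: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    alpha: float
    min_run_samples: int
    min_electrodes: int
    clusters_used: tuple[str, ...]


def _stack(erps) -> np.ndarray:
    if isinstance(erps, np.ndarray):
        return erps
    return np.stack([e.data if isinstance(e, Erp) else np.asarray(e) for e in erps])


def pointwise_paired_t(erps_a, erps_b) -> tuple[np.ndarray, np.ndarray]:
    """Paired t and two-tailed p per electrode and sample.

    Parameters
    ----------
    erps_a, erps_b : sequence of Erp or ndarray (n_subjects, channels, samples)
        Same subjects, same order, identical axes.

    Returns
    -------
    (t_values, p_values) : ndarrays, shape (channels, samples)
        Where the subject differences have exactly zero variance, t is NaN
        and p is set to 1 (logged).
    """
    A, B = _stack(erps_a), _stack(erps_b)
    if A.shape != B.shape:
        raise ValueError(f"condition arrays differ in shape: {A.shape} vs {B.shape}")
    n = A.shape[0]
    if n < 2:
        raise ValueError("paired t-test requires at least 2 subjects")
    d = A - B
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = sd == 0
    t[degenerate] = np.nan
    p = np.where(
        degenerate, 1.0, 2.0 * stats.t.sf(np.abs(np.nan_to_num(t)), df=n - 1)
    )
    if degenerate.any():
        logger.info(
            "%d electrode/sample cells had zero-variance differences; p set to 1",
            int(degenerate.sum()),
        )
    return t, p


def apply_temporal_criterion(
    significant: np.ndarray, min_run_samples: int = 10
) -> np.ndarray:
    """Clear per-electrode significant runs shorter than ``min_run_samples``."""
    return enforce_min_run(significant, min_run_samples, axis=-1)


def apply_spatial_criterion(
    significant: np.ndarray,
    montage: Montage,
    min_electrodes: int = 5,
    *,
    within_clusters: bool = True,
) -> np.ndarray:
    """Keep, per sample, only groups of >= ``min_electrodes`` contiguous
    significant electrodes.

    Contiguity is adjacency in the montage graph.  With ``within_clusters``
    (default) the grouping is evaluated separately inside each of the nine
    named scalp clusters, the literal reading of "contiguous electrodes
    within nine clusters"; set it False to allow groups to span clusters.
    """
    if within_clusters and not montage.clusters:
        raise ValueError("montage has no named clusters")
    sig = np.asarray(significant, dtype=bool)
    out = np.zeros_like(sig)
    groups = (
        list(montage.clusters.values())
        if within_clusters
        else [tuple(range(montage.n_channels))]
    )
    for s in range(sig.shape[1]):
        active = np.flatnonzero(sig[:, s])
        if active.size < min_electrodes:
            continue
        active_set = set(active.tolist())
        for members in groups:
            sub = active_set.intersection(members)
            if len(sub) < min_electrodes:
                continue
            for comp in connected_components(sub, montage.neighbors):
                if len(comp) >= min_electrodes:
                    out[comp, s] = True
    return out


def waveform_analysis(
    erps_a,
    erps_b,
    montage: Montage,
    *,
    alpha: float = 0.05,
    min_run_samples: int = 10,
    min_electrodes: int = 5,
    order: tuple[str, str] = ("temporal", "spatial"),
    within_clusters: bool = True,
) -> SignificanceMask:
    """Full mass-univariate analysis: paired t, then both persistence criteria.

    ``order`` controls which criterion is applied first; the default applies
    the temporal criterion and then the spatial one.
    """
    t, p = pointwise_paired_t(erps_a, erps_b)
    sig = p < alpha
    for step in order:
        if step == "temporal":
            sig = apply_temporal_criterion(sig, min_run_samples)
        elif step == "spatial":
            sig = apply_spatial_criterion(
                sig, montage, min_electrodes, within_clusters=within_clusters
            )
        else:
            raise ValueError(f"unknown criterion {step!r}")
    logger.info("criteria order %s; %d significant cells", order, int(sig.sum()))
    return SignificanceMask(
        t_values=t,
        p_values=p,
        significant=sig,
        alpha=alpha,
        min_run_samples=min_run_samples,
        min_electrodes=min_electrodes,
        clusters_used=tuple(montage.clusters),
    )


def significant_intervals(
    mask: SignificanceMask, montage: Montage, times_ms: np.ndarray
) -> list[dict]:
    """Per-electrode significant intervals with peak t, for tabular export."""
    rows = []
    for ch in range(mask.significant.shape[0]):
        for start, stop in find_runs(mask.significant[ch]):
            seg_t = mask.t_values[ch, start:stop]
            peak = start + int(np.nanargmax(np.abs(seg_t)))
            rows.append(
                {
                    "electrode": montage.labels[ch],
                    "start_ms": float(times_ms[start]),
                    "end_ms": float(times_ms[stop - 1]),
                    "peak_t": float(mask.t_values[ch, peak]),
                }
            )
    return rows


def write_intervals(path, rows: list[dict]) -> None:
    """Write intervals as tab-delimited text: electrode, start, end, peak t."""
    with open(path, "w") as fh:
        fh.write("electrode\tstart_ms\tend_ms\tpeak_t\n")
        for r in rows:
            fh.write(
                f"{r['electrode']}\t{r['start_ms']:.1f}\t{r['end_ms']:.1f}"
                f"\t{r['peak_t']:.4f}\n"
            )
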