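"""ERP preprocessing: filtering, referencing, rejection, interpolation, averaging.

The canonical order, enforced by :func:`preprocess_subject`, is

    band-pass filter -> average reference -> amplitude rejection ->
    bad-channel interpolation -> trial averaging

with the 80-trial floor checked before a subject/session enters group
analysis.  Each stage is also available as a standalone function operating on
plain arrays or :class:`~erpfield.dataset.EpochSet` objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .dataset import EpochSet, Erp
from .montage import Montage
from .spline import spherical_spline_interpolate

__all__ = [
    "bandpass",
    "bandpass_epochs",
    "rereference_average",
    "reject_amplitude",
    "FloorReport",
    "enforce_trial_floor",
    "average_trials",
    "average_subjects",
    "PreprocessResult",
    "preprocess_subject",
]

logger = logging.getLogger("erpfield.preprocess")


def _bandpass_sos(sampling_rate: float, low_hz: float, high_hz: float, order: int):
    nyq = sampling_rate / 2.0
    if high_hz >= nyq:
        raise ValueError(
            f"high cutoff {high_hz} Hz must be below Nyquist ({nyq} Hz)"
        )
    if not 0 < low_hz < high_hz:
        raise ValueError("require 0 < low_hz < high_hz")
    return sps.butter(order, [low_hz / nyq, high_hz / nyq], btype="band", output="sos")


def bandpass(
    data: np.ndarray,
    sampling_rate: float,
    low_hz: float = 1.0,
    high_hz: float = 30.0,
    *,
    order: int = 4,
    axis: int = -1,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward, no group delay).

    ``order`` is the per-direction passband design order; the effective
    attenuation is doubled by the second pass.
    """
    sos = _bandpass_sos(sampling_rate, low_hz, high_hz, order)
    return sps.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=axis)


def bandpass_epochs(
    epochs: EpochSet, low_hz: float = 1.0, high_hz: float = 30.0, *, order: int = 4
) -> EpochSet:
    """Filter every trial of an :class:`EpochSet` along the time axis."""
    out = epochs.copy()
    out.data = bandpass(
        epochs.data, epochs.sampling_rate, low_hz, high_hz, order=order, axis=1
    )
    return out


def rereference_average(data: np.ndarray, *, channel_axis: int = 0) -> np.ndarray:
    """Re-express potentials against the average reference.

    Subtracts the instantaneous mean over channels; inter-channel differences
    are unchanged and the operation is idempotent.
    """
    data = np.asarray(data, dtype=float)
    if data.shape[channel_axis] < 2:
        raise ValueError("average reference requires at least 2 channels")
    return data - data.mean(axis=channel_axis, keepdims=True)


def reject_amplitude(epochs: EpochSet, threshold_uv: float = 65.0) -> EpochSet:
    """Flag trials whose absolute voltage exceeds ``threshold_uv`` anywhere.

    A trial is marked ``amplitude_rejected`` iff any channel/sample exceeds
    the threshold in absolute value.  Trials already excluded for other
    reasons keep their flag.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    out = epochs.copy()
    peak = np.abs(out.data).max(axis=(0, 1))
    hit = peak > threshold_uv
    for tr in np.flatnonzero(hit):
        if out.trial_flags[tr] == "accepted":
            out.trial_flags[tr] = "amplitude_rejected"
    return out


@dataclass(frozen=True)
class FloorReport:
    """Accept/usable verdict for one subject/session."""

    n_accepted: int
    min_trials: int

    @property
    def usable(self) -> bool:
        return self.n_accepted >= self.min_trials


def enforce_trial_floor(epochs: EpochSet, min_trials: int = 80) -> FloorReport:
    """Check the artifact-free trial-count floor for a subject/session."""
    return FloorReport(n_accepted=int(epochs.accepted.sum()), min_trials=min_trials)


def average_trials(epochs: EpochSet) -> Erp:
    """Average the accepted trials into a subject-level ERP."""
    mask = epochs.accepted
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no accepted trials to average")
    return Erp(
        data=epochs.data[:, :, mask].mean(axis=2),
        sampling_rate=epochs.sampling_rate,
        epoch_window=epochs.epoch_window,
        n_trials=n,
        level="subject",
    )


def average_subjects(erps: list[Erp]) -> Erp:
    """Average subject ERPs into a group-level ERP."""
    if not erps:
        raise ValueError("no subject ERPs to average")
    shapes = {e.data.shape for e in erps}
    if len(shapes) != 1:
        raise ValueError(f"subject ERPs have inconsistent shapes: {shapes}")
    return Erp(
        data=np.mean([e.data for e in erps], axis=0),
        sampling_rate=erps[0].sampling_rate,
        epoch_window=erps[0].epoch_window,
        n_trials=len(erps),
        level="group",
    )


@dataclass
class PreprocessResult:
    """Subject-level preprocessing output with a stage log."""

    erp: Erp | None
    floor: FloorReport
    n_rejected: int
    bad_channels: tuple = ()
    steps: list[str] = field(default_factory=list)

    @property
    def usable(self) -> bool:
        return self.floor.usable


def preprocess_subject(
    epochs: EpochSet,
    montage: Montage,
    *,
    low_hz: float = 1.0,
    high_hz: float = 30.0,
    reject_uv: float = 65.0,
    min_trials: int = 80,
    bad_channels=(),
    baseline_correct: bool = False,
) -> PreprocessResult:
    """Run the full per-subject chain in the canonical order.

    Returns a :class:`PreprocessResult`; ``erp`` is None when the session
    falls below the trial floor.  ``baseline_correct`` (off by default)
    subtracts the mean of the pre-cue segment per channel before averaging.
    """
    steps: list[str] = []
    es = bandpass_epochs(epochs, low_hz, high_hz)
    steps.append(f"bandpass {low_hz}-{high_hz} Hz (zero-phase)")
    es.data = rereference_average(es.data, channel_axis=0)
    steps.append("average reference")
    n_before = int(es.accepted.sum())
    es = reject_amplitude(es, reject_uv)
    n_rejected = n_before - int(es.accepted.sum())
    steps.append(f"amplitude rejection at {reject_uv} μV: {n_rejected} trials")
    if bad_channels:
        es.data = spherical_spline_interpolate(es.data, bad_channels, montage)
        es.data = rereference_average(es.data, channel_axis=0)
        steps.append(f"spherical-spline interpolation of {list(bad_channels)}")
    floor = enforce_trial_floor(es, min_trials)
    steps.append(f"trial floor {min_trials}: {floor.n_accepted} accepted")
    erp = None
    if floor.usable:
        if baseline_correct:
            pre = es.times < 0
            es.data = es.data - es.data[:, pre, :].mean(axis=1, keepdims=True)
            steps.append("baseline correction (pre-cue mean)")
        erp = average_trials(es)
        steps.append(f"averaged {erp.n_trials} trials")
    for s in steps:
        logger.info(s)
    return PreprocessResult(
        erp=erp,
        floor=floor,
        n_rejected=n_rejected,
        bad_channels=tuple(bad_channels),
        steps=steps,
    )
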