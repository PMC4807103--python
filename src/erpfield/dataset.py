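"""Epoched-EEG and ERP containers with HDF5 persistence.

An :class:`EpochSet` holds one subject/session's epoched voltages
(channels x samples x trials, μV) together with the sampling rate, the epoch
window relative to cue onset, and a per-trial status flag.  An :class:`Erp`
is a trial- or subject-averaged voltage matrix (channels x samples).

Datasets are persisted as a single HDF5 file with the hierarchy::

    /montage/labels, /montage/positions
    /subjects/s01/A/data   (channels x samples x trials, float64, μV)
    /subjects/s01/A/trial_flags
    ...

with ``sampling_rate`` (Hz) and ``epoch_window`` (ms) as root attributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from .montage import Montage

__all__ = [
    "TRIAL_FLAGS",
    "EpochSet",
    "Erp",
    "time_axis",
    "save_dataset",
    "load_dataset",
    "save_erp_txt",
    "load_erp_txt",
]

#: Valid per-trial status values.  ``accepted`` trials enter the average;
#: the three exclusion categories are mutually exclusive and sticky.
TRIAL_FLAGS = ("accepted", "amplitude_rejected", "emg_excluded", "error_trial")


def time_axis(epoch_window: tuple[float, float], sampling_rate: float) -> np.ndarray:
    """Sample times in ms for an epoch window, cue onset at 0 ms.

    The number of samples is ``round(span * rate)``; the window start is the
    first sample.
    """
    t0, t1 = epoch_window
    n = int(round((t1 - t0) / 1000.0 * sampling_rate))
    return t0 + np.arange(n) * 1000.0 / sampling_rate


@dataclass
class EpochSet:
    """Epoched voltages for one subject/session.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples, n_trials)
        Voltages in μV.
    sampling_rate : float, Hz
    epoch_window : (float, float), ms relative to cue onset
    trial_flags : ndarray of str, shape (n_trials,)
        One status from :data:`TRIAL_FLAGS` per trial.
    montage_ref : str
        Identity of the montage the channels refer to.
    """

    data: np.ndarray
    sampling_rate: float
    epoch_window: tuple[float, float]
    trial_flags: np.ndarray = field(default=None)  # type: ignore[assignment]
    montage_ref: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("EpochSet.data must be channels x samples x trials")
        if self.trial_flags is None:
            self.trial_flags = np.full(self.data.shape[2], "accepted", dtype=object)
        self.trial_flags = np.asarray(self.trial_flags, dtype=object)
        if len(self.trial_flags) != self.data.shape[2]:
            raise ValueError("one flag per trial is required")
        bad = set(self.trial_flags) - set(TRIAL_FLAGS)
        if bad:
            raise ValueError(f"unknown trial flags: {sorted(bad)}")
        n_expected = len(time_axis(self.epoch_window, self.sampling_rate))
        if abs(self.data.shape[1] - n_expected) > 1:
            raise ValueError(
                f"{self.data.shape[1]} samples inconsistent with window "
                f"{self.epoch_window} ms at {self.sampling_rate} Hz"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return time_axis(self.epoch_window, self.sampling_rate)[: self.data.shape[1]]

    @property
    def accepted(self) -> np.ndarray:
        """Boolean mask of trials currently flagged ``accepted``."""
        return self.trial_flags == "accepted"

    def copy(self) -> "EpochSet":
        return replace(self, data=self.data.copy(), trial_flags=self.trial_flags.copy())


@dataclass
class Erp:
    """A trial- or subject-averaged ERP (channels x samples, μV)."""

    data: np.ndarray
    sampling_rate: float
    epoch_window: tuple[float, float]
    n_trials: int
    level: str = "subject"  # "subject" | "group"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Erp.data must be channels x samples")
        if self.level not in ("subject", "group"):
            raise ValueError(f"unknown ERP level {self.level!r}")

    @property
    def times(self) -> np.ndarray:
        return time_axis(self.epoch_window, self.sampling_rate)[: self.data.shape[1]]

    def window_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        t = self.times
        return (t >= window_ms[0]) & (t <= window_ms[1])


def save_dataset(
    path,
    epochs: dict[tuple[int, str], EpochSet],
    montage: Montage | None = None,
) -> None:
    """Write a ``{(subject_index, condition): EpochSet}`` mapping to HDF5."""
    first = next(iter(epochs.values()))
    with h5py.File(path, "w") as f:
        f.attrs["sampling_rate"] = first.sampling_rate
        f.attrs["epoch_window"] = first.epoch_window
        if montage is not None:
            g = f.create_group("montage")
            g.create_dataset("labels", data=np.array(montage.labels, dtype="S"))
            g.create_dataset("positions", data=montage.positions)
            g.attrs["head_radius"] = montage.head_radius
        for (subject, condition), es in epochs.items():
            g = f.create_group(f"subjects/s{subject:02d}/{condition}")
            g.create_dataset("data", data=es.data)
            g.create_dataset(
                "trial_flags", data=np.array(list(es.trial_flags), dtype="S")
            )
            g.attrs["montage_ref"] = es.montage_ref


def load_dataset(path) -> dict[tuple[int, str], EpochSet]:
    """Read a dataset written by :func:`save_dataset`."""
    out: dict[tuple[int, str], EpochSet] = {}
    with h5py.File(path, "r") as f:
        rate = float(f.attrs["sampling_rate"])
        window = tuple(float(v) for v in f.attrs["epoch_window"])
        for sname, sgroup in f["subjects"].items():
            subject = int(sname[1:])
            for condition, g in sgroup.items():
                out[(subject, condition)] = EpochSet(
                    data=g["data"][()],
                    sampling_rate=rate,
                    epoch_window=window,  # type: ignore[arg-type]
                    trial_flags=np.array(
                        [v.decode() for v in g["trial_flags"][()]], dtype=object
                    ),
                    montage_ref=str(g.attrs.get("montage_ref", "")),
                )
    return out


def save_erp_txt(path, erp: Erp) -> None:
    """Export an ERP as delimited text: rows = channels, columns = time (ms)."""
    header = "time_ms\t" + "\t".join(f"{t:.3f}" for t in erp.times)
    np.savetxt(path, erp.data, delimiter="\t", header=header, comments="# ")


def load_erp_txt(path, sampling_rate: float, epoch_window, n_trials: int = 0) -> Erp:
    data = np.loadtxt(path, delimiter="\t")
    return Erp(
        data=np.atleast_2d(data),
        sampling_rate=sampling_rate,
        epoch_window=tuple(epoch_window),
        n_trials=n_trials,
    )
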