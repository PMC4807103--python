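"""Synthetic two-session Go/NoGo-style ERP experiments with known ground truth.

The generator emulates the study conditions the downstream statistics are
built for: 15 subjects recorded in two sessions (conditions "A" and "B"),
~110 scalp channels at 500 Hz, epochs from -200 to 1000 ms around cue onset.
Each dataset is the lead-field projection of a small set of dipolar source
components with Gaussian-windowed timecourses, plus spatially correlated
sensor noise and occasional high-amplitude artifact trials.

Between-session effects are injected in two distinct ways, mirroring the two
neurophysiological mechanisms the global field statistics disentangle:

* **strength effects** — per-condition gain multipliers on a component's
  amplitude (same generators, different strength → GFP differences with
  identical normalized topography);
* **topography effects** — per-condition alternative source locations
  (different generator configuration → DISS/TANOVA differences).

Randomness is fully determined by a single integer seed: subject-level draws
use the substream ``SeedSequence([seed, subject])`` and per-session draws use
``SeedSequence([seed, subject, condition_index])``, so any subject/session can
be regenerated in isolation, bit-for-bit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .dataset import EpochSet, time_axis
from .headmodel import HeadModel, dipole_gain
from .montage import Montage, build_montage

__all__ = [
    "CONDITIONS",
    "SourceComponent",
    "SimDesign",
    "GroundTruth",
    "SimulatedExperiment",
    "default_components",
    "scalp_pattern",
    "signal_erp",
    "simulate_epochset",
    "iter_subject_sessions",
    "simulate_experiment",
    "simulate_null_subject_erps",
]

#: The two experimental sessions.
CONDITIONS = ("A", "B")

#: Temporal FWHM of injected artifact transients (ms).  Broad enough to
#: survive 1-30 Hz band-pass filtering essentially unattenuated.
ARTIFACT_FWHM_MS = 100.0

_FWHM_TO_SD = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SourceComponent:
    """One dipolar ERP generator.

    Parameters
    ----------
    name : str
    location : tuple of float
        Dipole position in normalized head units, inside the brain sphere.
    orientation : tuple of float
        Unit moment direction (normalized on construction).
    peak_ms, fwhm_ms : float
        Center and full width at half maximum of the Gaussian-windowed
        timecourse.
    amplitude : float
        Peak moment in nominal source units (chosen so that typical scalp
        deflections are a few μV).
    condition_gains : tuple of float
        Per-condition amplitude multipliers (strength effects).
    condition_locations : dict, optional
        Condition name -> alternative location (topography effects).
    active_window : (float, float), optional
        The timecourse is zeroed outside this window (ms).
    """

    name: str
    location: tuple[float, float, float]
    orientation: tuple[float, float, float]
    peak_ms: float
    fwhm_ms: float
    amplitude: float
    condition_gains: tuple[float, ...] = (1.0, 1.0)
    condition_locations: dict[str, tuple[float, float, float]] | None = None
    active_window: tuple[float, float] | None = None

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("component amplitude must be >= 0")
        o = np.asarray(self.orientation, dtype=float)
        nrm = np.linalg.norm(o)
        if nrm == 0:
            raise ValueError("orientation must be a non-zero vector")
        object.__setattr__(self, "orientation", tuple(o / nrm))

    def location_for(self, condition: str) -> tuple[float, float, float]:
        if self.condition_locations and condition in self.condition_locations:
            return self.condition_locations[condition]
        return self.location

    def gain_for(self, condition: str) -> float:
        return self.condition_gains[CONDITIONS.index(condition)]

    def timecourse(self, times_ms: np.ndarray) -> np.ndarray:
        """Unit-peak Gaussian-windowed waveform sampled at ``times_ms``."""
        sd = self.fwhm_ms * _FWHM_TO_SD
        w = np.exp(-0.5 * ((times_ms - self.peak_ms) / sd) ** 2)
        if self.active_window is not None:
            w = np.where(
                (times_ms >= self.active_window[0])
                & (times_ms <= self.active_window[1]),
                w,
                0.0,
            )
        return w


def _radial(loc) -> tuple[float, float, float]:
    v = np.asarray(loc, dtype=float)
    return tuple(v / np.linalg.norm(v))


def default_components() -> list[SourceComponent]:
    """The default generator set: five components emulating a cued task.

    An early posterior visual response and a sustained central preparatory
    component carry strength (gain) effects; three mid-latency components —
    sensorimotor, parietal/prefrontal and a prefrontal pair standing in for
    the pre-SMA vs right-inferior-frontal dissociation — carry topography
    (location) effects in successive latency windows.
    """
    return [
        SourceComponent(
            name="visual",
            location=(0.0, -0.55, 0.35),
            orientation=_radial((0.0, -0.55, 0.35)),
            peak_ms=120.0,
            fwhm_ms=60.0,
            amplitude=14.0,
            condition_gains=(1.25, 1.0),
        ),
        SourceComponent(
            name="sensorimotor",
            location=(-0.35, -0.10, 0.50),
            orientation=_radial((-0.35, -0.10, 0.50)),
            peak_ms=205.0,
            fwhm_ms=40.0,
            amplitude=10.0,
            condition_locations={"B": (-0.10, -0.40, 0.52)},
        ),
        SourceComponent(
            name="parietal_prefrontal",
            location=(0.20, -0.45, 0.45),
            orientation=_radial((0.20, -0.45, 0.45)),
            peak_ms=282.0,
            fwhm_ms=50.0,
            amplitude=10.0,
            condition_locations={"B": (0.45, 0.15, -0.10)},
        ),
        SourceComponent(
            name="preparatory",
            location=(0.0, -0.05, 0.60),
            orientation=_radial((0.0, -0.05, 0.60)),
            peak_ms=480.0,
            fwhm_ms=200.0,
            amplitude=12.0,
            condition_gains=(1.5, 1.0),
        ),
        SourceComponent(
            name="prefrontal_inhibition",
            location=(-0.05, 0.25, 0.62),
            orientation=_radial((-0.05, 0.25, 0.62)),
            peak_ms=455.0,
            fwhm_ms=40.0,
            amplitude=10.0,
            condition_locations={"B": (0.50, 0.35, 0.15)},
        ),
    ]


@dataclass(frozen=True)
class SimDesign:
    """Full specification of a synthetic two-session experiment.

    Defaults are the emulated study conditions: 15 subjects, 100 trials per
    session, 110 channels at 500 Hz, epochs -200..1000 ms.  ``noise_sd`` is
    the per-trial white noise amplitude before any filtering (12 μV; 1-30 Hz
    band-pass filtering leaves roughly half of it, and averaging ~95 accepted
    trials leaves well under 1 μV in subject ERPs).  ``noise_spatial_corr``
    is the inter-channel noise correlation at one head-radius separation,
    decaying exponentially with electrode distance.

    Between-subject variability has two components: a lognormal global
    amplitude gain (``subject_gain_sd``) and a per-subject, per-component
    source-location offset (``subject_location_jitter_sd``, in head units;
    the default 0.04 corresponds to roughly 4 mm of anatomical/functional
    variability on a 9 cm head).  Both are fixed per subject across
    conditions, as anatomy is.  Without the location jitter every subject
    would share bit-identical generator geometry, making inverse-solution
    leakage patterns perfectly correlated across subjects and group-level
    source statistics unrealistically large.
    """

    n_subjects: int = 15
    n_trials_per_condition: int = 100
    n_channels: int = 110
    sampling_rate: float = 500.0
    epoch_window: tuple[float, float] = (-200.0, 1000.0)
    components: tuple[SourceComponent, ...] = field(
        default_factory=lambda: tuple(default_components())
    )
    noise_sd: float = 12.0
    noise_spatial_corr: float = 0.5
    artifact_rate: float = 0.05
    artifact_amplitude: float = 120.0
    subject_gain_sd: float = 0.2
    subject_location_jitter_sd: float = 0.04
    min_trial_floor: int = 80
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "components", tuple(self.components))
        self.validate()

    def validate(self) -> None:
        t0, t1 = self.epoch_window
        if not (t0 < 0.0 < t1):
            raise ValueError("epoch window must span cue onset (0 ms)")
        if self.artifact_rate > 0 and self.artifact_amplitude <= 65.0:
            raise ValueError(
                "artifact_amplitude must exceed the 65 μV rejection threshold "
                "when artifact trials are injected"
            )
        if not 0.0 <= self.noise_spatial_corr < 1.0:
            raise ValueError("noise_spatial_corr must be in [0, 1)")
        expected_clean = self.n_trials_per_condition * (1.0 - self.artifact_rate)
        if expected_clean < self.min_trial_floor:
            warnings.warn(
                f"design flagged: expected {expected_clean:.0f} artifact-free "
                f"trials is below the {self.min_trial_floor}-trial floor",
                UserWarning,
                stacklevel=2,
            )

    @property
    def times(self) -> np.ndarray:
        return time_axis(self.epoch_window, self.sampling_rate)


@dataclass
class GroundTruth:
    """Everything injected into a simulated experiment, for oracle checks."""

    components: tuple[SourceComponent, ...]
    subject_gains: np.ndarray
    subject_location_jitters: np.ndarray  # (n_subjects, n_components, 3)
    artifact_trials: dict[tuple[int, str], tuple[int, ...]]
    seed: int

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "subject_gains": [float(g) for g in self.subject_gains],
            "subject_location_jitters": self.subject_location_jitters.tolist(),
            "artifact_trials": {
                f"s{s:02d}/{c}": list(idx)
                for (s, c), idx in sorted(self.artifact_trials.items())
            },
            "components": [
                {
                    "name": c.name,
                    "location": list(c.location),
                    "orientation": list(c.orientation),
                    "peak_ms": c.peak_ms,
                    "fwhm_ms": c.fwhm_ms,
                    "amplitude": c.amplitude,
                    "condition_gains": list(c.condition_gains),
                    "condition_locations": (
                        {k: list(v) for k, v in c.condition_locations.items()}
                        if c.condition_locations
                        else None
                    ),
                    "active_window": (
                        list(c.active_window) if c.active_window else None
                    ),
                }
                for c in self.components
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class SimulatedExperiment:
    epochs: dict[tuple[int, str], EpochSet]
    montage: Montage
    head: HeadModel
    truth: GroundTruth


def scalp_pattern(
    component: SourceComponent,
    condition: str,
    montage: Montage,
    head: HeadModel,
) -> np.ndarray:
    """Average-referenced unit-moment scalp map of a component in a condition."""
    loc = component.location_for(condition)
    gain = dipole_gain(head, np.asarray(loc), montage.positions)[0]  # (3, e)
    return np.asarray(component.orientation) @ gain


def _noise_chol(design: SimDesign, montage: Montage) -> np.ndarray:
    """Cholesky factor of the spatial noise covariance (unit variance)."""
    if design.noise_spatial_corr == 0.0:
        return np.eye(montage.n_channels)
    d = np.linalg.norm(
        montage.positions[:, None, :] - montage.positions[None, :, :], axis=2
    )
    corr = design.noise_spatial_corr ** (d / montage.head_radius)
    return np.linalg.cholesky(corr + 1e-10 * np.eye(len(corr)))


def _subject_params(design: SimDesign, subject: int) -> tuple[float, np.ndarray]:
    """Subject-level draws: global gain and per-component location offsets.

    Drawn from the subject substream ``SeedSequence([seed, subject])`` so
    they are identical across this subject's sessions.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, subject]))
    gain = float(np.exp(rng.normal(0.0, design.subject_gain_sd)))
    jitter = rng.normal(
        0.0, design.subject_location_jitter_sd, size=(len(design.components), 3)
    )
    return gain, jitter


def _inside_brain(loc: np.ndarray, head: HeadModel, margin: float = 0.02) -> np.ndarray:
    """Pull a (possibly jittered) location back inside the brain sphere."""
    r = np.linalg.norm(loc)
    r_max = head.brain_radius - margin
    return loc if r < r_max else loc * (r_max / r)


def signal_erp(
    design: SimDesign,
    condition: str,
    montage: Montage,
    head: HeadModel,
    subject_gain: float = 1.0,
    subject_jitter: np.ndarray | None = None,
) -> np.ndarray:
    """Noiseless signal (channels x samples) for one condition.

    ``subject_jitter`` is an optional (n_components, 3) array of location
    offsets (head units) applied on top of each component's per-condition
    location.
    """
    times = design.times
    out = np.zeros((montage.n_channels, len(times)))
    for k, comp in enumerate(design.components):
        if subject_jitter is None:
            pattern = scalp_pattern(comp, condition, montage, head)
        else:
            loc = np.asarray(comp.location_for(condition)) + subject_jitter[k]
            loc = _inside_brain(loc, head)
            gain3 = dipole_gain(head, loc, montage.positions)[0]
            pattern = np.asarray(comp.orientation) @ gain3
        amp = comp.amplitude * comp.gain_for(condition) * subject_gain
        out += np.outer(pattern, amp * comp.timecourse(times))
    return out


def simulate_epochset(
    design: SimDesign,
    subject: int,
    condition: str,
    montage: Montage,
    head: HeadModel,
    *,
    noise_chol: np.ndarray | None = None,
) -> tuple[EpochSet, tuple[int, ...]]:
    """Simulate one subject/session; returns the epochs and the true artifact
    trial indices."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    times = design.times
    n_ch, n_t, n_tr = montage.n_channels, len(times), design.n_trials_per_condition
    chol = _noise_chol(design, montage) if noise_chol is None else noise_chol
    gain, jitter = _subject_params(design, subject)
    signal = signal_erp(
        design, condition, montage, head, subject_gain=gain, subject_jitter=jitter
    )
    rng = np.random.default_rng(
        np.random.SeedSequence([design.seed, subject, CONDITIONS.index(condition)])
    )
    data = np.empty((n_ch, n_t, n_tr))
    white = rng.standard_normal(size=(n_tr * n_t, n_ch))
    noise = (design.noise_sd * (white @ chol.T)).reshape(n_tr, n_t, n_ch)
    data[:] = signal[:, :, None] + noise.transpose(2, 1, 0)
    artifact_idx: list[int] = []
    if design.artifact_rate > 0:
        hit = rng.random(n_tr) < design.artifact_rate
        sd = ARTIFACT_FWHM_MS * _FWHM_TO_SD
        for tr in np.flatnonzero(hit):
            ch = rng.integers(n_ch)
            center = rng.uniform(times[0] + sd, times[-1] - sd)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            pulse = design.artifact_amplitude * np.exp(
                -0.5 * ((times - center) / sd) ** 2
            )
            data[ch, :, tr] += sign * pulse
            artifact_idx.append(int(tr))
    es = EpochSet(
        data=data,
        sampling_rate=design.sampling_rate,
        epoch_window=design.epoch_window,
        montage_ref=f"cap{n_ch}",
    )
    return es, tuple(artifact_idx)


def iter_subject_sessions(
    design: SimDesign,
    montage: Montage | None = None,
    head: HeadModel | None = None,
) -> Iterator[tuple[int, str, EpochSet, tuple[int, ...]]]:
    """Yield ``(subject, condition, epochs, artifact_indices)`` lazily.

    Memory-friendly alternative to :func:`simulate_experiment` for large
    designs: each subject/session is generated on demand and can be reduced
    to an ERP before the next one is drawn.
    """
    montage = montage or build_montage(design.n_channels)
    head = head or HeadModel()
    chol = _noise_chol(design, montage)
    for subject in range(design.n_subjects):
        for condition in CONDITIONS:
            es, arts = simulate_epochset(
                design, subject, condition, montage, head, noise_chol=chol
            )
            yield subject, condition, es, arts


def simulate_experiment(
    design: SimDesign,
    montage: Montage | None = None,
    head: HeadModel | None = None,
) -> SimulatedExperiment:
    """Simulate the full experiment and return data plus ground truth.

    Holds every subject/session in memory (~1.6 GB at the default design);
    use :func:`iter_subject_sessions` to stream instead.
    """
    montage = montage or build_montage(design.n_channels)
    head = head or HeadModel()
    for comp in design.components:
        for cond in CONDITIONS:
            loc = np.asarray(comp.location_for(cond))
            if np.linalg.norm(loc) >= head.brain_radius:
                raise ValueError(
                    f"component {comp.name!r} lies outside the brain sphere "
                    f"in condition {cond}"
                )
    epochs: dict[tuple[int, str], EpochSet] = {}
    artifacts: dict[tuple[int, str], tuple[int, ...]] = {}
    for subject, condition, es, arts in iter_subject_sessions(design, montage, head):
        epochs[(subject, condition)] = es
        artifacts[(subject, condition)] = arts
    params = [_subject_params(design, s) for s in range(design.n_subjects)]
    truth = GroundTruth(
        components=design.components,
        subject_gains=np.array([g for g, _ in params]),
        subject_location_jitters=(
            np.stack([j for _, j in params])
            if design.components
            else np.zeros((design.n_subjects, 0, 3))
        ),
        artifact_trials=artifacts,
        seed=design.seed,
    )
    return SimulatedExperiment(epochs=epochs, montage=montage, head=head, truth=truth)


def simulate_null_subject_erps(
    n_subjects: int,
    montage: Montage,
    n_samples: int,
    erp_noise_sd: float,
    spatial_corr: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw paired null subject ERPs (no condition effect) for calibration.

    Both conditions share the generating distribution: spatially correlated
    Gaussian noise at subject-ERP level (``erp_noise_sd`` is the per-channel
    standard deviation after trial averaging).  Returns two arrays of shape
    (n_subjects, n_channels, n_samples).

    This is the fast path for Monte-Carlo validity studies of the permutation
    tests, where simulating individual trials adds nothing: averaging
    zero-mean trial noise yields exactly this distribution.
    """
    design = SimDesign(
        n_subjects=n_subjects,
        n_channels=montage.n_channels,
        components=(),
        noise_spatial_corr=spatial_corr,
        artifact_rate=0.0,
        seed=seed,
    )
    chol = _noise_chol(design, montage)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9999]))
    n_ch = montage.n_channels
    white = rng.standard_normal(size=(2, n_subjects, n_samples, n_ch))
    noise = erp_noise_sd * (white @ chol.T)
    both = noise.transpose(0, 1, 3, 2)
    return both[0].copy(), both[1].copy()
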