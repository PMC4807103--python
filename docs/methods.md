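# Methods

`erpfield` implements the electrical-neuroimaging analysis chain for
two-session event-related-potential (ERP) experiments — preprocessing,
mass-univariate waveform statistics, reference-free global field statistics
with randomization tests, and distributed source estimation with voxel-wise
parametric mapping — together with a synthetic data generator that makes
every stage verifiable against known ground truth.  This note documents the
models, the defaults and why they were chosen, the numerical decisions, and
what the synthetic validation does and does not establish.

## Head model and forward solution

The volume conductor is an analytic three-shell concentric-spheres model
(brain/skull/scalp), radii 0.87 / 0.92 / 1.0 in normalized head units and
relative conductivities 1 : 1/80 : 1 (the conventional brain-to-skull
ratio).  The scalp potential of a current dipole is the classical Legendre
series: the primary potential is expanded in solid harmonics, homogeneous
solutions are added per shell, and the continuity/no-outflow boundary
conditions reduce, per harmonic degree, to one 5×5 linear solve whose
solution depends only on the geometry.  Eighty series terms keep relative
truncation error below 1e-6 for sources up to 0.82 head units off-center
(the deepest grid points used are at 0.82).  With equal shell
conductivities the transfer factors collapse to the textbook
homogeneous-sphere coefficients, which is a unit test; the full three-shell
solution is cross-checked in the test suite against an independently
implemented sphere model (MNE's Berg approximation) and agrees to ~0.2%.

Units are deliberately relative: potentials are "μV" when source moments
are in nominal units, and the absolute scale is carried by the simulator's
component amplitudes.  Nothing downstream depends on the absolute scale —
the statistics are either scale-free (DISS, TANOVA, t) or compare scaled
quantities between conditions.

## Electrode montage

Electrodes are placed on the upper spherical cap (polar half-angle 120°,
matching a dense geodesic net with its artifact-prone outermost belt
removed) by a Fibonacci spiral, which gives quasi-uniform coverage for any
channel count without depending on a proprietary sensor geometry.  The
default is 110 channels.  Adjacency ("contiguous electrodes") is a
symmetrized 6-nearest-neighbour graph.  The nine named scalp regions — AL,
AM, AR, CL, CM, CR, PL, PM, PR (anterior/central/posterior ×
left/midline/right) — are assigned by terciles of the anterior coordinate,
then terciles of the lateral coordinate within each band.  Terciles
guarantee nine non-empty clusters for any montage of ≥ 16 channels and are
insensitive to the cap's exact extent; the cost is that the "midline" bands
are as wide as the lateral ones, which only matters for the spatial
persistence criterion and is conservative there (groups are harder, not
easier, to split across clusters).

## Synthetic two-session experiments

The generator emulates the study conditions the statistics are designed
for: 15 subjects × 2 sessions, 100 trials per session, 110 channels at
500 Hz, epochs −200..1000 ms around cue onset.  Each dataset is the
lead-field projection of a small set of dipolar components with
Gaussian-windowed timecourses (peak latency, FWHM, amplitude), plus noise
and artifacts:

* **Sensor noise** — temporally white per trial with standard deviation
  12 μV, spatially correlated with an exponential kernel (correlation 0.5
  at one head-radius separation).  After the pipeline's own 1–30 Hz
  band-pass, roughly half of this amplitude survives, and averaging ~95
  accepted trials leaves ~0.6 μV in subject ERPs — a realistic ERP
  signal-to-noise regime for component amplitudes of a few μV.
* **Artifacts** — each trial is independently contaminated with
  probability 0.05 by a 120 μV Gaussian transient (FWHM 100 ms, so it
  survives band-pass filtering) on one random channel.  With 100 trials
  this leaves ~95 artifact-free trials per session, matching the accepted
  trial counts the protocol reports, and comfortably above the 80-trial
  floor.
* **Between-subject variability** — a lognormal global gain (σ = 0.2) and
  a per-subject, per-component source-location offset (σ = 0.04 head units
  ≈ 4 mm), both fixed across a subject's two sessions, as anatomy is.
  Without the location jitter every simulated subject would share
  bit-identical generator geometry; inverse-solution leakage would then be
  perfectly correlated across subjects and group-level voxel statistics
  would become arbitrarily large.

Between-session effects are injected in the two mechanistically distinct
ways the global field statistics are designed to separate: per-condition
amplitude gains (strength effects: GFP changes, identical normalized
topography) and per-condition source locations (topography effects: DISS
changes).  The default component set emulates a cued task's structure — an
early posterior visual response and a sustained central preparatory
component carrying gain effects, and three mid-latency components
(~205 ms, ~282 ms, ~455 ms) carrying location effects.

Randomness is governed by one integer seed through documented substreams:
`SeedSequence([seed, subject])` for subject-level draws and
`SeedSequence([seed, subject, condition_index])` for per-session noise and
artifacts, so any subject/session regenerates bit-identically in
isolation.

**What the generator does not emulate:** overlapping epochs and slow
inter-trial dependencies (epochs are independent), ocular/muscular
artifact morphology (only amplitude is realistic), latency jitter between
trials, realistic anatomy (spherical head, no tissue anisotropy), and the
full heterogeneity of real subjects (shared component set, moderate
amplitude/position variability).  Consequences for interpretation: passing
the recovery tests shows the chain is correct and sensitive under
idealized conditions; it does not certify sensitivity on real data, where
between-subject variance is larger — synthetic voxel-wise t values run
noticeably higher than the t(14) ≈ 2.3–4.4 range typical of real
group contrasts of this size.

## Preprocessing

Canonical order, enforced and logged: zero-phase band-pass (4th-order
Butterworth, 1–30 Hz, forward-backward so attenuation doubles and group
delay cancels) → average reference → amplitude rejection → bad-channel
interpolation → trial averaging, with an 80-trial usability floor per
subject/session.

* **Rejection semantics** — a trial is rejected iff any channel/sample
  exceeds the threshold (65 μV) in absolute value after filtering.
  Absolute rather than peak-to-peak was chosen as the common
  automated-rejection convention; the threshold is a parameter.
  Exclusions for other causes (EMG, response errors) enter as input flags
  and are never overwritten.
* **Baseline correction** — off by default (the protocol specifies none);
  available as an opt-in flag that subtracts the pre-cue mean.
* **Spherical-spline interpolation** — Perrin-style: kernel
  g(x) = (1/4π) Σ (2n+1)/(nᵐ(n+1)ᵐ) Pₙ(x) with stiffness m = 4, 50
  Legendre terms, smoothing 1e-5 on the kernel diagonal, and the zero-sum
  side condition solved in a bordered system.  Reconstruction of a deleted
  channel from forward-modeled maps has median error well under 10% of the
  map maximum at 110 channels, and error shrinks with montage density.
  The operator agrees with an independent implementation (MNE's) to ~2%.
* After interpolation the average reference is re-applied, since replacing
  a channel perturbs the instantaneous mean; ERPs therefore satisfy the
  zero-mean invariant to 1e-9.

## Waveform statistics

Point-wise paired t-tests on subject ERP amplitudes at every electrode and
sample (two-tailed, df = n−1; cells with exactly zero-variance differences
get p = 1 and are logged).  Two persistence criteria filter the α = .05
map: significant runs shorter than 10 samples (20 ms at 500 Hz) are
cleared per electrode, then, per sample, significant electrodes must form
an adjacency-connected group of ≥ 5 inside one named cluster.  Temporal
first, spatial second (the order is configurable and logged); whether the
five-electrode requirement applies per sample (default) or per run is also
configurable, per-sample being the stricter literal reading.  No further
multiple-comparison correction is applied — fidelity to the protocol — and
this is a known limitation: under band-limited noise the persistence
criteria reduce, but do not control, the family-wise error rate (see
*Limitations*).

## Global field statistics

GFP is the spatial standard deviation of the average-referenced map; DISS
between two maps is the RMS difference after each is scaled to unit GFP,
with the identity DISS² = 2(1−r) (r = spatial Pearson correlation) tested
to 1e-10.  Both are reference-free.

Point-wise paired randomization tests (1000 permutations by default):

* **GFP test** — observed statistic |mean over subjects of (GFP_A −
  GFP_B)| per sample; null generated by independently swapping each
  subject's condition labels.
* **TANOVA** — observed statistic is the DISS between the two
  GFP-normalized group-average maps; each permutation swaps labels within
  subjects and recomputes the group maps.  The alternative convention
  (mean of per-subject DISS) is implemented behind a flag; the group-map
  form is the default.  Samples with a zero-GFP group map get p = 1 and
  are logged.

p-values are inclusive, (b+1)/(n_perm+1), which guarantees validity at
finite permutation counts: with 200 permutations the attainable rate just
below α = .05 is 10/201 ≈ 0.0498, and the Monte-Carlo calibration
(15 subjects, no effects, 500 replicates) lands within [0.035, 0.065] for
both tests.  The 20 ms persistence criterion is applied to the p < .05
series, and significant windows are reported in ms.  Permutation draws are
seeded; identical inputs and seed give identical p-series.

## Source estimation and voxel-wise mapping

The solution space is a cubic lattice of ~1000 points (configurable; 3001
reproduces the protocol's density) strictly inside the brain sphere, with
26-neighbourhood contiguity (≤ √3 × spacing).  The inverse is a weighted
minimum norm with a local autoregressive prior: the penalty is
‖(A + small ridge) u‖² with A = I − B, B the inverse-squared-distance
neighbour weights (rows normalized; exponent configurable 2 or 3), acting
on sensitivity-normalized sources u = N s, where N scales each point by
the Frobenius norm of its three lead-field columns.  Two elements deserve
justification:

* **Sensitivity (depth) normalization** — without it, minimum-norm
  solutions systematically mislocalize toward the scalp; with it, 95%+ of
  noiseless single-point sources under the electrode cap are recovered
  within one lattice step of the truth.  Sources outside the cap's
  coverage (inferior brain) localize worse — a physical limitation of any
  EEG montage, not of the solver.
* **The ridge (β = 0.3)** — A alone annihilates spatially constant source
  fields, so the pure autoregressive prior is improper and admits
  arbitrarily large smooth patterns; the ridge makes the prior proper.
  Localization is insensitive to β over 0.1–1.

The solve is done in the prior-whitened domain via one SVD, so the
operator for any regularization strength is a diagonal rescaling.  The
default strength is the fixed middle of a 13-step geometric ladder
(1e-6..1e-1 relative to the largest squared singular value), the
convention of fixed mid-range regularization; generalized cross-validation
is implemented as an alternative and is useful for map reconstruction, but
it under-regularizes the window-averaged magnitude maps used in group
contrasts.

For each analysis window (taken automatically from the significant TANOVA
intervals, with manual override), each subject's ERP is averaged over the
window first and inverted second — by linearity identical to inverting
every sample and averaging moments, which is tested.  Activity is the
Euclidean norm of the free-orientation moment ("current density").
Between-condition contrasts are paired t-tests per solution point,
thresholded two-tailed at α = .05 (|t| > 2.14 at 14 df), clustered by
lattice contiguity separately for positive and negative t, and clusters
smaller than 10 points are cleared.  Each surviving cluster is reported at
the solution point with the maximum absolute group-mean activity
difference, with the t and p values there (plus the cluster's maximum |t|
as an extra field).  The difference peak, not the |t| peak, is the
location summary: the |t| maximum is attracted to low-variance points
where estimation leakage is systematic but tiny, and on synthetic
displaced-source experiments it misses the true location by a median of
~2.2 lattice steps where the difference peak misses by ~1.5.

## Numerical and degenerate-input decisions

* Zero-variance difference cells (waveform t, voxel t): t undefined → p
  set to 1 and logged, never treated as infinitely significant.
* Zero-GFP maps: DISS raises on direct calls with a diagnostic; inside
  TANOVA the affected samples get p = 1 and are logged.
* Dipoles at the sphere center: the degree-1 term survives (b⁰ = 1);
  radial/tangential frames fall back to fixed axes.
* Jittered component locations are radially pulled back to 0.02 inside
  the brain-sphere surface.
* The interpolation solve is a dense bordered system; with ≥ 8 good
  channels it is well-conditioned at smoothing 1e-5.
* All Monte-Carlo machinery uses `numpy.random.Generator` with explicit
  seeds; permutation tests chunk their permutation blocks (default 100)
  to bound memory at ~50 MB per block on full-length epochs.

## Problem sizes used in validation

The test suite and the acceptance script size their simulations to run on
one CPU in minutes, as a deliberate choice of desk-scale validation:
the null calibration uses 500 replicates × 200 permutations on 100-sample
epochs (tests) and 200 replicates in the acceptance script; effect
recovery runs 10 seeded full experiments (15 subjects × 2 sessions × 100
trials × 110 channels × 600 samples) in the tests and 5 in the script;
the source grid is ~1000 points rather than 3001 (the dense grid is one
configuration flag away and is exercised for its geometry in tests).

## Limitations

* The persistence criterion is liberal under temporally smooth noise: the
  1–30 Hz band-pass gives subject-ERP noise a lag-1 autocorrelation of
  ~0.98 at 500 Hz, so 10-sample runs of p < .05 occur under the null in
  roughly a third of full-length epochs even though the per-sample rate
  is exactly calibrated.  Windows near the detection threshold should be
  interpreted accordingly; the per-sample calibration, not the
  window-level family-wise rate, is the guaranteed property.
* No multiple-comparison correction beyond the persistence criteria, by
  design fidelity.
* The spherical head model and normalized coordinates mean source
  locations are not anatomically labeled; cluster coordinates are in head
  units.
* Synthetic subjects are more homogeneous than real ones; group-level
  effect sizes (and voxel t values) are correspondingly optimistic.
* EEG cannot localize sources far from the sensor cap; recovery
  guarantees apply to cap-covered (cortical-like) sources.
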