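# Methods

This note documents the models, algorithms and design choices behind
`sleepreplay`, in the order the pipeline runs them. Everything described
here is implemented in `src/sleepreplay/` and exercised by the test suite;
no empirical claim below goes beyond what the tests and
`scripts/acceptance.py` compute.

## Scope and data model

The package analyzes endogenous memory reactivation in nap EEG: it detects
slow oscillations (SOs), sleep spindles and SO-spindle complexes in NREM
sleep, quantifies the SO phase at which spindles peak (circular statistics),
trains a category classifier on wake "localizer" epochs and tests it on
downstate-locked sleep epochs (temporal generalization), and relates the
resulting reactivation strength to coupling phase and to behavioral memory
retention.

Signals are microvolts; time is continuous seconds with 0-based sample
indices (`index = round(t·sfreq)`); epoch windows are endpoint-inclusive
(`n = round((t1−t0)·sfreq)+1` samples, symmetric around the lock sample).
Sleep staging is consumed as a per-sample mask (standard 30-s scored
hypnograms are expanded on load); only movement-free N2/N3 samples enter
event detection. EDF and BrainVision recordings are read through MNE; EDF
writing uses a compact EDF+ writer (16-bit, 1-s records) because no EDF
writer library is assumed available.

## Event detection

**Slow oscillations.** The linked-mastoid signal at the target channel
(default Cz) is band-passed 0.3–1.25 Hz with a zero-phase FIR filter whose
length is three cycles of the low cut-off (Hamming window, applied forward
and backward). Candidates span successive positive-to-negative zero
crossings, must contain a trough followed by a peak, and are kept iff their
duration lies in [0.8, 2] s. No amplitude criterion is applied by default.

**Spindles.** The signal is band-passed 12–18 Hz (same FIR recipe); its RMS
is computed in a centred 200-ms moving window; the amplitude criterion is
the 75th percentile (linear interpolation between order statistics) of the
RMS distribution over movement-free N2/N3 samples of that recording.
Supra-threshold runs lasting more than 0.5 s but less than 3 s (strict)
become events; the trough is the minimum of the band-passed signal within
the run and the envelope peak is the RMS maximum.

**Optional amplitude criteria and ground-truth validation.** A broadband
1/f background *necessarily* produces SO-band cycles that pass the duration
window and spindle-band RMS runs that skirt the percentile threshold; these
are correct detections under the definitional criteria but are not planted
events. Validation against simulated ground truth therefore enables the
detectors' optional amplitude criteria, in self-calibrating form: SO troughs
must exceed 3× the robust noise SD of the band-passed N2/N3 signal
(`median(|x|)/0.6745` — robust because a plain SD is inflated by the events
themselves), and spindle RMS peaks must reach 2× the percentile threshold.
With these, recall and precision against planted events exceed 0.9 across
seeds. Both criteria default to off.

**Pairing.** An SO and a spindle form a complex when the spindle's anchor
falls within (downstate, downstate + 1.5 s]. The anchor is configurable
(onset, trough, or envelope peak; default onset — "a spindle detected
following the SO" read as its start). The simulation-validation pipeline
anchors on the envelope peak: the coupling phase is defined at that same
feature, and onset-anchored pairing censors spindles peaking near the
downstate, which measurably biases participant preferred phases toward the
upstate. When several spindles qualify, the earliest is paired; each
spindle pairs at most once, so complexes ≤ min(#SO, #spindles). Unpaired
events are kept as solitary SOs/spindles for control analyses.

**Time–frequency maps.** Sliding-window Fourier power with a Hanning taper,
window length five cycles per frequency, 1–30 Hz in 1-Hz steps, 50-ms time
steps, averaged over events and z-scored across time per frequency. A
perfectly stationary input has zero temporal variance, making the z-scored
map degenerate; `zscore=False` returns raw power for such checks.

## SO-spindle coupling

Downstate-locked ±2.5-s epochs are band-passed (two-pass Butterworth,
2nd order per pass) in the SO band for instantaneous phase and in the
spindle band for instantaneous amplitude (Hilbert transform); the coupling
phase is the SO phase at the sample of maximal spindle amplitude, with the
search restricted to ±1.5 s. Phase convention: upstate 0, downstate ±π,
down-to-up transition −π/2; angles wrapped to (−π, π].

Epochs are reflection-extended by one epoch length per side before
filtering and the Hilbert transform. Without this, finite-epoch edge
transients bias the extracted phase by up to ~0.13 rad (measured against
the closed-form phase of a planted sinusoidal SO); with it, the planted
von Mises location (κ=5) is recovered within 0.05 rad over 10⁴ events.

Circular statistics follow the standard formulas: mean direction
arg Σe^{iθ}, resultant length R = |Σe^{iθ}|/n, Rayleigh z = nR² with
p = exp(√(1+4n+4(n²−(nR)²)) − (1+2n)), circular–linear correlation

    r = √((r_cx² + r_sx² − 2 r_cx r_sx r_cs) / (1 − r_cs²)),  p: χ²(2) at n·r²,

and the partial variant residualizes x, cos θ and sin θ on the covariate
(least squares, with intercept) before applying the same formula
(residualizing only x is available as an option; the "all" scheme is the
default and documented as an assumption). These implementations are
cross-checked against pingouin's circular routines in the test suite.

## Decoding

Preprocessing, in order: whole-trial baseline correction; z-scoring per
channel × time point across trials (sample SD; zero-variance features map
to 0); PCA fitted on the pooled wake+sleep channel-space samples with the
first 30 components retained; 150-ms running-average smoothing in component
space (window forced odd — 31 samples at 200 Hz — with shrinking edge
windows). The implemented order is asserted by a provenance-log test.

The classifier is linear discriminant analysis with the pooled within-class
covariance shrunk toward (trace/p)·I by γ=0.01. The default path fits all
time points in one batched solve (`lda_weights_multi`); it is verified
against scikit-learn's `LinearDiscriminantAnalysis(solver="lsqr",
shrinkage=0.01)` and exists because surrogate analyses refit the classifier
hundreds of thousands of times. Any sklearn-style estimator can be injected
instead.

AUC is computed by the rank-sum identity (average ranks, so ties count one
half) and is invariant under monotone transforms of the decision scores
(property-tested). Localizer decoding uses stratified fivefold
cross-validation repeated five times with re-randomized folds. Wake→sleep
decoding trains one classifier per localizer time point and tests it on
every sleep time point — no cross-validation, as the sets are independent
recordings; sleep test labels are the category learned in that epoch's
session, so AUC > 0.5 signals reactivation of the just-learned category.
Surrogate baselines shuffle the *training* labels (250 times by default)
and average the resulting AUC maps.

The searchlight repeats the temporal-generalization analysis per channel
neighborhood after back-projecting components to sensor space. Neighborhoods
are centre + channels within a global radius (the median 7th-nearest
neighbour distance), clamped to 5–9 channels with distance ties broken by
channel-name order.

## Group statistics and behavior

**Cluster permutation.** Per map point, a dependent-samples t against the
surrogate baseline; points with two-sided p < 0.05 are clustered by
contiguity (adjacency in 1-D, 4-connectivity in 2-D); the cluster statistic
is the sum of t values (maxsum). The null distribution is built from
participant-wise sign flips of the difference maps — the map-wide maximum
|maxsum| per permutation — giving family-wise control by the max-statistic
construction; Monte-Carlo p values include the observed statistic,
p = (b+1)/(m+1), with 1000 randomizations by default. For ≤12 participants
(when 2ⁿ does not exceed the randomization budget) all 2ⁿ sign patterns are
enumerated instead. Calibration: across 500 null cohorts (n=20), the
family-wise error is 0.05 ± 0.02 (asserted in the acceptance suite).

**Behavior.** d′ = z(hit rate) − z(false-alarm rate) with extreme
proportions replaced by 1/(2N) and 1−1/(2N); cued recall as percent of
recognition hits; retention index = (post recall-of-hits % / pre
recall-of-hits %) × 100, collapsed across sessions by averaging, with
zero-denominator sessions flagged missing. Spearman correlations use
average ranks; the partial Spearman is a Pearson partial correlation on
ranks (t approximation, df = n−3), cross-checked against pingouin. The
comparison of two dependent correlations sharing one variable is provided
as Steiger's z (the specific variant used historically for this comparison
is not documented; this is an assumption).

**Reactivation strength** is the per-participant mean AUC over the
significant *positive* cluster (or an explicit train×test window).
Whole-trial baselining induces genuine below-chance stripes in
generalization maps — classifiers trained on pre-stimulus localizer samples
carry the inverted pattern — so negative clusters are excluded from the
strength mask.

## Synthetic-data generator

The generator emulates the two-session, within-participant study design:
per session, a nap recording plus a 200-trial two-class localizer; sessions
are counterbalanced (`(participant+session) % 2`), and participant-level
traits (preferred coupling phase, category templates) come from
session-independent random streams. All randomness derives from one master
seed through hierarchical per-participant, per-purpose seed sequences;
identical configurations are bit-identical.

Components and defaults (units in `SimConfig` docstrings):

* **Background**: per-channel 1/f (α=1) Gaussian noise, 15 µV RMS, plus a
  spatially correlated 1/f component at half weight. The spectrum is
  flattened below 0.5 Hz.
* **Hypnogram**: wake/N1 onset, then alternating N2/N3 blocks (4–10 scored
  epochs each) with occasional arousals; ~3% of NREM epochs flagged as
  movement artifact.
* **Channels**: 64 positions on the unit sphere from a standard 10-10
  montage; Cz and the mastoid proxies TP9/TP10 are always included, so
  reduced layouts remain analyzable.
* **SOs**: one biphasic sine cycle (duration 1/so_freq clipped to
  [0.8, 2] s), trough 75 µV and peak 40 µV at the best channel, a
  fronto-central topography whose mastoid weights are ≈0 (so amplitudes
  hold under the linked-mastoid reference), Poisson times at 5/min within
  valid NREM, ≥3 s apart.
* **Spindles**: 13.5-Hz carrier under a Hann envelope (duration 0.8–1.3 s),
  25 µV envelope peak at Cz, central topography. 60% of SOs carry a
  spindle whose envelope peak is placed where the SO phase equals a von
  Mises draw: event-level κ=0.75 (event-level resultant length ≈0.35,
  matching participant-level coupling dispersion reported for real naps)
  around the participant's preferred phase, itself von Mises around the
  group phase −0.642 rad (−36.78°) with κ=6 (across-participant R ≈ 0.91).
  Solitary spindles occur at 2/min away from SOs.
* **Reactivation**: half of the SO-spindle complexes receive a
  category-specific spatial pattern (posterior Gaussian bumps, unit norm,
  shared with the localizer) under a Hann envelope 0.8–1.2 s after the
  downstate, scaled by `reactivation_snr` (default 1.0) × noise RMS ×
  a phase-precision factor that falls linearly with the participant's
  |preferred phase|, reaching zero at π/2 (`reactivation_phase_link`,
  default 1). This factor is the generative link behind "tighter coupling →
  stronger reactivation".
* **Localizer**: balanced classes, same spatial templates, ERP-like
  envelope (gamma-shaped, onset 150 ms, peak ≈400 ms), amplitude
  `reactivation_snr` × noise RMS.
* **Behavior**: 60 old/60 new recognition trials per session with hit rate
  ≈0.85 pre / 0.80 post and false-alarm rate ≈0.10/0.12; recall-of-hits
  64% pre-sleep; expected retention is 1.2 for a perfectly coupled
  participant and falls linearly with the circular distance of the
  preferred phase from the upstate (`behavior_link_strength`, default 1.5,
  plus 5% Gaussian jitter), clipped to [0.2, 1.2]. The defaults give a
  cohort-mean retention index near 90% with a between-participant SD of
  ~15–20 points — the dispersion scale reported for real nap cohorts of
  20 participants; a substantially smaller dispersion would be
  undetectable through the binomial noise of ~50 recall trials.

What the generator does **not** emulate: full-night sleep architecture and
REM cycling, ocular/muscle artifacts, volume conduction from a head model,
across-event variability in SO shape, non-stationary spindle frequency, or
1/f slope differences between stages. Passing tests therefore demonstrate
that the pipeline recovers the planted structure under realistic amplitudes
and rates — not that it is robust to every artifact of real recordings.

## Validation experiments and problem sizes

The acceptance suite runs, at fixed seeds:

1. surrogate-null calibration (200 noise epochs, 30 channels, 250 shuffles,
   decoding every 50 ms): mean surrogate AUC within 0.5 ± 0.01;
2. the spindle threshold against an independently computed 75th percentile;
3. detector recovery on a 30-min nap: recall/precision ≥ 0.9;
4. coupling recovery: planted μ within 0.05 rad (κ=5, 10⁴ events, in
   batches of 1000) and a group Rayleigh rejection across 20 participants
   at event-level κ=1;
5. the closed-form identities (z = nR², r=1 for x=cos θ, d′=0 at equal
   rates, retention=100 at equal recall);
6. cluster-permutation calibration (500 null cohorts, n=20, 1000
   randomizations) and exact-enumeration agreement at n=8;
7. a full simulated cohort (20 participants, 60-min naps, 160 localizer
   trials, decode steps 50/25 ms, 40 shuffles): a significant cluster at
   the planted lag, strength tracking planted amplitude, the phase–strength
   association, and the strength–retention correlation.

Sixty-minute naps are used for the cohort (the emulated design allows 120
minutes): each participant then contributes a few hundred complexes, enough
for stable per-participant AUC; with 30-minute naps the across-participant
correlations are dominated by AUC estimation noise.

## Known limitations

* The coupling-phase estimator retains a residual bias ≤ ~0.04 rad from
  finite-epoch analytic-signal estimation; the recovery tolerance (0.05
  rad) sits just above it.
* Cluster-level inference controls family-wise error for the max cluster
  statistic; secondary clusters' p values are conservative.
* The EDF writer pads the final data record with zeros when the recording
  is not a whole number of seconds and requires an integer sampling rate.
* The searchlight reports observed AUC only; its spatial inference (a
  cluster test across channels) is not implemented.
* Percentile conventions matter: thresholds use linear interpolation
  between order statistics; other dialects shift the spindle threshold
  slightly.
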