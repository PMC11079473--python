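# Methods

This note documents the models, operational definitions, defaults, and
known limitations of the package. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Recording model and conventions

A recording is a uniform-rate multichannel matrix in µV: a modified 10-20
scalp subset (F3/F4/C3/C4 omitted, as they typically conflict with the
post-operative head bandage) plus two 4-contact DBS leads, `LTh0-3` and
`RTh0-3`, numbered from the deepest contact (clinical aliases `RTh8-11`
are accepted for the right lead). Time is seconds from record start,
sample indexing 0-based, intervals half-open. Annotations label sleep,
awake, and seizure intervals; sleep/awake may not overlap.

Montages are derived channels (minuend − subtrahend): bipolar DBS =
adjacent contact pairs (three per lead); bipolar scalp = longitudinal
chains (Fp1-F7-T3-T5-O1 and the right homologue); monopolar = as-recorded
against the common extracranial reference, or re-referenced to any channel.

**Analysis segments.** 20 minutes per state by default, earliest-first,
non-contiguous allowed, every sample ≥ 2 h from any seizure annotation.
Selection is deterministic and idempotent; an explicit error names the
shortfall when the recording cannot supply the requested minutes.

**EDF.** Plain 16-bit EDF with a fixed anonymized header date, so equal
data give byte-identical files; annotations travel in a sidecar CSV. The
per-channel physical range is symmetric and covers the data, bounding the
round-trip error by one digital step.

## Synthetic data: the stated world

`simulate_recording` produces two segments per state (awake/sleep
interleaved), default 10 min each, at 2048 Hz (tests and the acceptance
script scale `fs` and durations down; the statistics scale, the code path
does not).

- **Background**: Gaussian 1/f^α noise, α = 1.5, SD 10 µV, independently
  per channel; an optional sinusoid mixture (0.5–2 Hz) can be added to
  sleep segments on scalp channels (off by default).
- **Templates**: the fast component is a Hann lobe whose FWHM equals
  `fast_duration_ms` (default 30 ms, amplitude 100 µV scalp / 80 µV
  thalamus), immediately followed by an opposite-polarity Hann slow wave
  (150 ms). A shallow recovery tail zeroes the integral without touching
  the lobe shapes; with the default amplitudes the areas already balance
  and the tail vanishes. Amplitudes are free parameters: no published
  amplitude statistics exist for TIEDs, so defaults were chosen to sit
  within the usual intracranial/scalp IED range and are never tuned
  against detector behaviour.
- **Events**: per-site, per-state homogeneous Poisson processes thinned to
  ≥ 1 s same-site separation (keeps triggered-average epochs free of
  neighbouring events). Default rates (events/min): thalamus 0.33 sleep /
  0.13 awake, scalp 0.26 sleep / 0.13 awake. The awake scalp rate needs a
  word: the reported cohort *median* for awake scalp discharges is 0/min,
  which cannot serve as a single-recording generator rate (it would leave
  every awake scalp-triggered condition empty by construction, while such
  conditions are analysed in practice); the awake thalamic value stands in.
- **Spatial spread**: scalp events project onto the primary chain channel
  and its neighbours with weights (1, 0.6, 0.3); thalamic spikes onto the
  primary contact and adjacent contacts with weights (1, 0.5), which
  produces the bipolar phase reversal a local generator should show. Sharp
  transients are injected as a monotone far-field gradient
  (1, 0.5, 0.2, 0.05) from beyond the deepest contact — visible in the
  bipolar montage but without sign reversal.
- **Coupling**: each scalp event is echoed in the same-side thalamus with
  probability `coupling_probability` (default 0.55) after a truncated
  normal lag, mean 51 ms, SD 30 ms, bounds [2, 180] ms. Only mean and
  range of the lag distribution are reported clinically; the SD and the
  truncated-normal shape are this package's choice.
- **Determinism**: one RNG stream per recording keyed by the seed;
  per-patient seeds derive from (base seed, patient index) so any patient
  regenerates alone.

What the generator does **not** emulate: realistic head-model forward
projection, artifacts, sleep architecture beyond a binary label, seizures,
and non-stationary rates. A green signal-path test therefore establishes
that the algorithms recover what they are defined to recover under the
stated noise model — not that they would perform identically on clinical
recordings.

## Detection

Detection runs on band-passed signals (zero-phase Butterworth, 2–45 Hz by
default): the 1/f background concentrates its variance below 2 Hz where a
raw-amplitude criterion would be meaningless, while both IED components
(fast lobe, slow wave) lie inside the band.

- **Prominence**: |x| ≥ 6 × σ̂, σ̂ = MAD × 1.4826 computed blockwise over
  60 s windows, floored at 0.5 µV (amplifier/quantization floor; without a
  floor, numerically silent test data would make everything "prominent").
  The threshold is a parameter and is reported alongside results — the
  clinical criterion ("prominent amplitude") is qualitative.
- **Merging**: cross-channel candidates are merged by non-maximum
  suppression in prominence order with a 200 ms radius. NMS (rather than
  chain grouping) makes the candidate count provably monotone in the
  threshold: whether a hit survives depends only on stronger hits.
- **Fast-component duration**: full width at half prominence around the
  detected peak, with linear interpolation of the half-crossings
  (sub-sample accuracy; at 512 Hz a nominal 51 ms template genuinely
  renders at 49.8 ms, so duration-boundary checks need ≥ 1 kHz).
- **Spike vs sharp transient** (thalamic only): spike requires fast
  component < 50 ms AND slow wave AND bipolar phase reversal AND monopolar
  prominence; a prominent candidate failing any of the last three — or the
  duration bound — is a sharp transient. Slow wave := opposite-polarity
  area in the 80–400 ms post-peak window exceeding 0.25 × the fast lobe
  area. Phase reversal := opposite-signed deflections ≥ half the candidate
  amplitude on adjacent bipolar channels within ±20 ms. Scalp events are
  detected on the bipolar scalp montage and not subclassified.
- **Peak contact**: monopolar channel with maximal |amplitude| within
  ±25 ms; ties break toward the deepest contact.

## Triggered averaging and connection classification

Epochs are ±500 ms around trigger peaks (trigger sample = 0 ms; length
fs + 1 samples); triggers closer than 500 ms to a record edge are dropped
and counted. The IED-TP peak is the maximal-absolute extremum of the
average exceeding 4 × the baseline SD (−500…−250 ms of the average),
excluding ±2 ms around zero. 4× replaces the original visual judgement
and is a parameter. The ±2 ms exclusion (`min_lag`, the smallest lag the
classification should resolve) routes near-zero latencies to
`not_evaluable` instead of letting sign noise pick follower vs preceder.

The target channel is the target site's bipolar channel with the largest
averaged excursion; channel choice at the target is not specified
clinically, and the largest-deflection rule is the natural surrogate.

Conditions are independent units: 2 sides × 2 states × 2 directions, minus
those with a missed lead or no triggers (`not_evaluable`, excluded from
all denominators). The two directions of the same (side, state) may
disagree; both are reported.

## Anatomy

The imaging pipeline (MRI/CT fusion, visual consensus) is replaced by
patient-space coordinates plus a box atlas — the visual localization step
is not reproducible from text, the downstream logic is. Boxes are closed
(boundary points belong to the region) and may not overlap; the packaged
synthetic atlas keeps 0.5 mm gaps between adjacent regions. ANT
subdivisions are a sagittal-plane parcellation (ventral/dorsal/posterior),
deliberately not the cytoarchitectonic subnuclei. Hit := ≥ 1 contact in
any ANT subregion; MD contacts do not make a hit.

Region-occurrence bookkeeping deduplicates contacts to one unit per
(patient, side, region); duplicating a contact within a region of one
lead never changes counts. Units are per-side: per-patient dedup cannot
satisfy the published per-region occurrence and the per-patient TIED
counts simultaneously, per-side dedup satisfies both.

## Outcome statistics

- SR = 100·(pre − post)/pre; pre = 0 is an explicit error. Responder is
  strict: SR = 50.0 exactly is a non-responder.
- Percentages round half-up to integer percent (55/120 → 46 %).
- OR = ad/bc; zero off-diagonal cells give +∞ unless the
  Haldane–Anscombe +0.5 correction is requested.
- Fisher exact (two-sided, sum of tables with probability ≤ observed),
  Wilcoxon signed-rank (zero differences dropped, exact when possible),
  rank-sum with mid-ranks, and pooled-variance t-tests are delegated to
  scipy.stats behind this module's interface; the test suite cross-checks
  Fisher against a full hypergeometric enumeration for every table with
  N ≤ 30 and the signed-rank test against a 2⁶ sign enumeration.
- "TIED present" in the outcome association means spike-class TIEDs; a
  flag widens it to any TIED. For bilateral seizure-focus laterality,
  "focus-side TIED" means a spike-class TIED on either hit side.

## The paper15 cohort fixture

Per-patient raw data exist only in an unavailable clinical supplement, so
`thalied.fixtures` reconstructs the *minimal synthetic cohort* consistent
with every published aggregate simultaneously: 6/15 responders; 9
bilateral- and 6 unilateral-hit patients (24/30 leads, 55/120 ANT
contacts); 11 focus-side hits; 10 patients with spike TIEDs (all 6
responders + 4/9 non-responders); 13 patients with any TIED, 7 bilateral;
41 sampled region units with spikes in 5/10 MD, 12/13 ANT-V, 6/10 ANT-D
and sharp transients in 3/10 ANT-D, 2/8 ANT-P; and 60 evaluable
conditions splitting 33/3/24 with follower lags spanning 2–180 ms, mean
exactly 51 ms, and sleep-state splits of 88 %/6 % (responders) vs
38 %/57 % (non-responders). Two published lag summaries are mutually
inconsistent at the printed precision (no three preceder lags with range
15–25 ms can average 18.0; the fixture uses {15, 15, 25}, mean 18.33,
which prints as 18), and the responder/non-responder mean follower lags
can only be approximated (50.0 and 52.75 here). Flags and summaries are
never hard-coded: they are computed from fixture primitives (coordinates,
per-contact events, signed latencies, seizure counts) by the same code
paths real data would take, and `verify_paper15` raises on any violated
aggregate.

## Limitations

- The detector substitutes quantitative surrogates (6 × σ̂ prominence,
  area-ratio slow-wave rule, 4 × baseline-SD IED-TP threshold) for expert
  visual judgement; thresholds are parameters, not clinical ground truth.
- The synthetic background is stationary Gaussian 1/f^α; real EEG has
  artifacts, spindles, and state-dependent spectra that will lower
  detector specificity relative to the simulated figures.
- Trajectory-wise hit ratios and laterality-subgroup response rates are
  stored pass-through only; their published denominators are not
  reconstructible.
- Conditions with a single trigger produce legitimate but fragile
  averages; `n_triggers` is carried in every result so downstream users
  can filter.
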