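# thalied

Analysis toolkit for **intrathalamic interictal epileptiform discharges
(TIEDs)** recorded from externalized anterior-thalamus (ANT) DBS leads,
together with scalp EEG, in drug-resistant epilepsy patients.

Between implantation and generator placement, the four-contact DBS leads can
be connected to the EEG amplifier like stereo-EEG electrodes. The questions
this package operationalizes: do interictal discharges occur inside the ANT;
how do they relate in time to scalp discharges; and does their presence —
especially on the side of the epileptic focus — predict the response to
subsequent ANT stimulation?

## What it computes

- **IED detection** (`thalied.detect`). Discharges are detected on the
  bipolar montage as local extrema with amplitude ≥ *k*·σ̂, where σ̂ is a
  robust background SD (MAD × 1.4826 over a sliding window; *k* = 6 by
  default). Thalamic candidates are refined into **spikes** — fast component
  < 50 ms (full width at half prominence), bipolar phase reversal, monopolar
  prominence, and a following slow wave — versus **sharp transients (ST)**,
  which are outstanding in the bipolar montage but lack phase reversal or
  monopolar prominence, regardless of duration.
- **IED-triggered average potentials** (`thalied.averaging`). For each of
  ≤ 8 conditions per patient (2 sides × {sleep, awake} × 2 averaging
  directions), the target site's signal is averaged in a ±500 ms window
  around the trigger site's IED peaks. A peak of the average exceeding
  4 × the pre-trigger baseline SD is the IED-TP; its signed latency τ
  classifies the ANT as **follower** (scalp→thal with τ > 0, or thal→scalp
  with τ < 0), **preceder** (converse signs), or **no connection** (no
  suprathreshold peak). Lags are reported as |τ| in ms.
- **Anatomy** (`thalied.anatomy`). Contacts are assigned to ANT-V/ANT-D/
  ANT-P (a sagittal-plane parcellation of the ANT) or MD through an
  axis-aligned box atlas; a lead **hits** when ≥ 1 contact lies in the ANT.
  Patient-level flags: bilateral hit, focus-side hit, focus-side spike-TIED.
- **Outcome statistics** (`thalied.stats`). Responder := seizure reduction
  SR = 100·(pre − post)/pre strictly > 50 %. Response rates per subgroup,
  odds ratios OR = ad/bc from 2×2 tables, two-sided Fisher exact tests,
  Wilcoxon signed-rank / rank-sum, and independent t-tests on lags.
- **Synthetic recordings** (`thalied.synth`). Ground-truthed scalp+thalamic
  sessions: 1/f^α Gaussian background, Hann-lobe spike-and-slow-wave
  templates, state-dependent Poisson event rates, and probabilistic
  scalp→thalamus coupling with truncated-normal lags.
- **Cohort fixture** (`thalied.fixtures`). A synthetic 15-patient cohort
  (`paper15`) whose primitives — coordinates, per-contact events,
  per-condition latencies, seizure counts — jointly reproduce the published
  cohort aggregates when pushed through the pipeline.

## Worked example

```python
from thalied import pipeline

report = pipeline.run_fixture_pipeline()
print(report["response_rate_pct"])
# {'overall': 40, 'bilateral_hit': 44, 'unilateral_hit': 33,
#  'focus_side_hit': 45, 'focus_side_spike_tied': 71}
print(report["odds_ratios"])
# {'bilateral_hit': 1.6, 'focus_side_hit': 2.5, 'focus_side_spike_tied': 17.5}
print(report["connections"]["follower_pct"],
      report["connections"]["mean_follower_lag_ms"])
# 55 51.0
```

Read: 40 % of the cohort responded (> 50 % seizure reduction at 1 year);
the response rate climbs to 71 % among patients with spike-type TIEDs on
the focus side, and the odds ratio for a good outcome rises from 1.6
(bilateral anatomical hit) through 2.5 (focus-side hit) to 17.5 (focus-side
TIEDs) — anatomical placement matters less than electrophysiological
confirmation. Across 60 evaluable triggered-average conditions the ANT
followed the scalp in 55 % with a mean lag of 51 ms.

The full signal path on simulated data:

```bash
thalied simulate --n-patients 1 --seed 7 --out out/
thalied detect --edf out/P01.edf --out out/events.csv
thalied summarize --out out/report
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes both stages from scratch: the fixture cohort through the
bookkeeping pipeline (response rates, odds ratios, contact/lead hit
percentages, connection fractions and lags, region occurrence), and a
scaled-down simulated cohort through the signal pipeline (simulation,
detection against ground truth, triggered-average classification),
printing the resulting numbers and writing the JSON result object.
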