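"""End-to-end orchestration: simulate → detect → average → classify →
summarize, with per-stage outputs that can be reloaded individually.

Two entry points: :func:`run_fixture_pipeline` summarizes the packaged
15-patient bookkeeping fixture (anatomy hit logic, connection accounting,
outcome association); :func:`run_signal_pipeline` exercises the full
signal path on simulated recordings with ground truth.  Both are
deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import averaging, detect, fixtures, stats, synth
from .recording import (DBS_LEFT, DBS_RIGHT, SCALP_CHAINS, Recording,
                        make_bipolar, make_monopolar, select_segments)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def site_views(rec: Recording) -> dict:
    """Per-site bipolar views plus per-side thalamic monopolar views."""
    pairs = {
        "scalp-left": list(zip(SCALP_CHAINS["left"], SCALP_CHAINS["left"][1:])),
        "scalp-right": list(zip(SCALP_CHAINS["right"],
                                SCALP_CHAINS["right"][1:])),
        "thal-left": list(zip(DBS_LEFT, DBS_LEFT[1:])),
        "thal-right": list(zip(DBS_RIGHT, DBS_RIGHT[1:])),
    }
    views = {site: make_bipolar(rec, p) for site, p in pairs.items()}
    mono = {
        "thal-left": make_monopolar(rec, labels=DBS_LEFT),
        "thal-right": make_monopolar(rec, labels=DBS_RIGHT),
    }
    return {"bipolar": views, "monopolar": mono}


def analyze_patient(rec: Recording, params: detect.DetectionParams,
                    analysis_minutes: float,
                    side_hit: dict | None = None,
                    peak_threshold: float = 4.0,
                    band=(2.0, 45.0)) -> dict:
    """Detect IEDs per site/state, run the 8-condition triggered-average
    classification, and return events + conditions + rates.

    The recording is band-passed (``band`` Hz, zero-phase) before detection
    and averaging; pass ``band=None`` to analyse broadband."""
    if band is not None:
        rec = detect.preprocess_recording(rec, *band)
    views = site_views(rec)
    side_hit = side_hit or {"left": True, "right": True}
    try:
        segments = {state: select_segments(rec, state,
                                           minutes=analysis_minutes)
                    for state in ("sleep", "awake")}
    except Exception as exc:
        raise StageError(f"segment-selection: {exc}") from exc

    events: list[detect.IEDEvent] = []
    trigger_times: dict[tuple, np.ndarray] = {}
    try:
        for site, bip in views["bipolar"].items():
            is_thal = site.startswith("thal")
            mono = views["monopolar"].get(site)
            for state in ("sleep", "awake"):
                evs = detect.detect_site(bip, mono, segments[state], site,
                                         state, params, classify=is_thal)
                events.extend(evs)
                trigger_times[(site, state)] = np.array(
                    [e.time_s for e in evs])
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"detection: {exc}") from exc

    try:
        conditions = averaging.enumerate_conditions(
            trigger_times, views["bipolar"], side_hit, segments,
            peak_threshold=peak_threshold)
    except Exception as exc:
        raise StageError(f"averaging: {exc}") from exc

    rates = {}
    for (site, state), times in trigger_times.items():
        rates[f"{site}/{state}"] = detect.ied_rate(times, analysis_minutes)
    return {"events": events, "conditions": conditions, "rates": rates,
            "segments": segments}


def events_frame(events, patient_id: str) -> pd.DataFrame:
    rows = [dict(patient=patient_id, site=e.site, state=e.state,
                 time_s=e.time_s, klass=e.klass, peak_contact=e.peak_contact,
                 prominence=e.prominence,
                 fast_duration_ms=e.fast_duration_ms) for e in events]
    return pd.DataFrame(rows)


def conditions_frame(conditions, patient_id: str) -> pd.DataFrame:
    rows = [dict(patient=patient_id, side=r.side, state=r.state,
                 direction=r.direction, category=r.category, lag_ms=r.lag_ms,
                 latency_ms=r.latency_ms, n_triggers=r.n_triggers,
                 reason=r.reason) for r in conditions]
    return pd.DataFrame(rows)


def run_signal_pipeline(config: synth.SimulationConfig, n_patients: int = 1,
                        params: detect.DetectionParams | None = None,
                        analysis_minutes: float | None = None,
                        out_dir=None) -> dict:
    """Simulate ``n_patients`` sessions and run the full analysis on each.

    ``analysis_minutes`` defaults to the full simulated per-state duration
    (two segments per state).  Returns a JSON-serializable report; per-stage
    CSVs are written when ``out_dir`` is given.
    """
    params = params or detect.DetectionParams()
    if analysis_minutes is None:
        analysis_minutes = 2 * config.segment_minutes
    try:
        cohort = synth.simulate_cohort(n_patients, config, out_dir=out_dir)
    except Exception as exc:
        raise StageError(f"simulation: {exc}") from exc

    all_events, all_conditions = [], []
    patients = []
    for i, (rec, gt) in enumerate(cohort):
        pid = rec.patient_id
        res = analyze_patient(rec, params, analysis_minutes)
        ef = events_frame(res["events"], pid)
        cf = conditions_frame(res["conditions"], pid)
        all_events.append(ef)
        all_conditions.append(cf)
        matched = n_det = n_true = 0
        for site in ("scalp-left", "scalp-right", "thal-left", "thal-right"):
            m, d, t = detect.match_events(
                [e.time_s for e in res["events"] if e.site == site],
                gt.times(site=site))
            matched, n_det, n_true = matched + m, n_det + d, n_true + t
        patients.append({
            "patient": pid,
            "n_true_events": n_true,
            "n_detected": n_det,
            "sensitivity": matched / n_true if n_true else None,
            "precision": matched / n_det if n_det else None,
            "rates_per_min": res["rates"],
        })
    events_df = pd.concat(all_events, ignore_index=True)
    cond_df = pd.concat(all_conditions, ignore_index=True)
    summary = averaging.summarize_conditions(
        r for df in [cond_df] for r in _frame_to_results(df))
    report = {
        "stage": "signal",
        "seed": config.seed,
        "n_patients": n_patients,
        "patients": patients,
        "connections": {
            "n_evaluable": summary.n_evaluable,
            "n_follower": summary.n_follower,
            "n_preceder": summary.n_preceder,
            "n_no_connection": summary.n_no_connection,
            "mean_follower_lag_ms": summary.mean_follower_lag_ms,
        },
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        events_df.to_csv(out / "events.csv", index=False)
        cond_df.to_csv(out / "conditions.csv", index=False)
        (out / "report.json").write_text(
            json.dumps(_jsonable(report), indent=2, sort_keys=True))
    return _jsonable(report)


def _frame_to_results(df: pd.DataFrame):
    for _, row in df.iterrows():
        yield averaging.ConnectionResult(
            side=row["side"], state=row["state"], direction=row["direction"],
            category=row["category"],
            lag_ms=None if pd.isna(row["lag_ms"]) else float(row["lag_ms"]),
            latency_ms=None if pd.isna(row["latency_ms"])
            else float(row["latency_ms"]))


def run_fixture_pipeline(out_dir=None, haldane: bool = False) -> dict:
    """Summarize the packaged 15-patient fixture through the full
    bookkeeping path: hit logic from coordinates, connection classification
    from latencies, outcome association from the cohort table."""
    try:
        bundle = fixtures.paper15_bundle()
        aggregates = fixtures.verify_paper15(bundle)
    except fixtures.FixtureError:
        raise
    except Exception as exc:
        raise StageError(f"fixture-build: {exc}") from exc

    cohort = bundle["cohort"]
    report = stats.cohort_report(cohort, bundle["summary"],
                                 bundle["sleep_summary"], haldane=haldane)
    occ = stats.region_occurrence(bundle["contact_events"])
    report["region_occurrence"] = {
        region: {"n_sampled": int(row["n_sampled"]),
                 "spike_pct": int(row["spike_pct"]),
                 "st_pct": int(row["st_pct"])}
        for region, row in occ.iterrows()
    }
    n_contacts = sum(len(l.contacts) for l in bundle["lead_maps"])
    report["localization"] = {
        "n_contacts": n_contacts,
        "n_ant_contacts": aggregates["n_ant_contacts"],
        "ant_contact_pct": stats.percent(aggregates["n_ant_contacts"],
                                         n_contacts),
        "n_leads": aggregates["n_leads"],
        "n_hit_leads": aggregates["n_hit_leads"],
        "hit_lead_pct": stats.percent(aggregates["n_hit_leads"],
                                      aggregates["n_leads"]),
    }
    report["stage"] = "fixture"
    report = _jsonable(report)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(out / "cohort.csv")
        bundle["contact_events"].to_csv(out / "contact_events.csv",
                                        index=False)
        conditions_frame(bundle["conditions"], "paper15").to_csv(
            out / "conditions.csv", index=False)
        occ.to_csv(out / "region_occurrence.csv")
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
    return report


def run_pipeline(config: dict) -> dict:
    """Dispatch on ``config['mode']``: ``fixture`` or ``signal``.

    Signal-mode keys: ``simulation`` (SimulationConfig fields), ``detection``
    (DetectionParams fields), ``n_patients``, ``analysis_minutes``,
    ``out_dir``, ``seed``.
    """
    mode = config.get("mode", "fixture")
    out_dir = config.get("out_dir")
    if mode == "fixture":
        return run_fixture_pipeline(out_dir=out_dir,
                                    haldane=config.get("haldane", False))
    if mode != "signal":
        raise ValueError(f"unknown pipeline mode {mode!r}")
    sim_kw = dict(config.get("simulation", {}))
    if "seed" in config:
        sim_kw.setdefault("seed", config["seed"])
    if "rates" in sim_kw:
        sim_kw["rates"] = {
            (site, state): v
            for (site, state), v in _parse_rates(sim_kw["rates"]).items()}
    sim = synth.SimulationConfig(**sim_kw)
    det = detect.DetectionParams(**config.get("detection", {}))
    return run_signal_pipeline(sim, n_patients=config.get("n_patients", 1),
                               params=det,
                               analysis_minutes=config.get("analysis_minutes"),
                               out_dir=out_dir)


def _parse_rates(rates) -> dict:
    """YAML rates come as 'site/state': value."""
    out = {}
    for key, v in rates.items():
        if isinstance(key, tuple):
            out[key] = float(v)
        else:
            site, state = key.split("/")
            out[(site, state)] = float(v)
    return out
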