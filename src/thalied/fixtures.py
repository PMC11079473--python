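"""Reference 15-patient cohort fixture ("paper15").

A synthetic reconstruction of a 15-patient ANT-DBS cohort whose aggregate
bookkeeping satisfies, simultaneously, the published cohort-level numbers
this package's analysis reproduces: 6/15 responders (overall response rate
40%), 9 bilateral-hit and 6 unilateral-hit patients (24/30 leads hit, 55/120
contacts in the ANT = 46%), 11 focus-side-hit patients, 7 patients with
spike-type TIEDs on the focus side, 41 sampled thalamic region units with
the stated spike/sharp-transient occurrence per region, and 60 evaluable
triggered-average conditions splitting 33/3/24 into follower/preceder/
no-connection with follower lags spanning 2-180 ms (mean 51 ms).

All per-patient rows here are synthetic: the real per-patient data live only
in an unavailable clinical supplementary table, so this fixture is the
minimal world consistent with every printed aggregate.  Flags and summaries
are *computed* from the primitive rows (coordinates, per-contact events,
per-condition latencies) by the same code paths real data would take.
"""

from __future__ import annotations

import pandas as pd

from .anatomy import LeadMap, Contact, RegionAtlas, default_atlas, \
    lead_hit, patient_hit_summary, ANT_REGIONS
from .averaging import classify_connection, summarize_conditions
from .stats import seizure_reduction, is_responder

S2T, T2S = "scalp->thal", "thal->scalp"

#: per-patient fixture rows.  ``leads[side]`` is None for a missed
#: (intraventricular) lead, else (trajectory, [(region, n_contacts, events)])
#: with events "spike" / "st" / None; contacts not covered by region units
#: are outside the atlas.  ``conditions`` are (side, state, direction,
#: signed IED-TP latency in ms or None for no detectable peak).
PAPER15 = [
    dict(id="P01", laterality="right", pre=30, post=3,
         leads=dict(
             left=("frontal", [("ANT-V", 2, "spike"), ("MD", 2, "spike")]),
             right=("frontal", [("ANT-V", 2, "spike"), ("ANT-D", 1, "spike"),
                                ("ANT-P", 1, None)])),
         rates=(0.60, 0.25, 0.40, 0.05),
         conditions=[
             ("left", "sleep", S2T, +6), ("left", "sleep", T2S, -10),
             ("right", "sleep", S2T, +14), ("right", "sleep", T2S, -18),
             ("left", "awake", S2T, +20), ("left", "awake", T2S, -22),
             ("right", "awake", S2T, +28), ("right", "awake", T2S, +25)]),
    dict(id="P02", laterality="right", pre=20, post=4,
         leads=dict(
             left=("frontal", [("ANT-V", 1, "spike"), ("ANT-D", 1, "spike"),
                               ("MD", 2, "spike")]),
             right=("frontal", [("ANT-V", 2, "spike"), ("ANT-P", 2, None)])),
         rates=(0.50, 0.20, 0.30, 0.00),
         conditions=[
             ("left", "sleep", S2T, +30), ("left", "sleep", T2S, -32),
             ("right", "sleep", S2T, +35), ("right", "sleep", T2S, -40),
             ("right", "awake", S2T, +42), ("right", "awake", T2S, -48)]),
    dict(id="P03", laterality="right", pre=12, post=2,
         leads=dict(
             left=("frontal", [("ANT-D", 4, "spike")]),
             right=("frontal", [("ANT-V", 2, "spike"), ("MD", 2, "spike")])),
         rates=(0.45, 0.15, 0.26, 0.10),
         conditions=[
             ("left", "sleep", S2T, +50), ("left", "sleep", T2S, -55),
             ("right", "sleep", S2T, +60), ("right", "sleep", T2S, -70),
             ("right", "awake", S2T, +80), ("right", "awake", T2S, None)]),
    dict(id="P04", laterality="bilateral", pre=10, post=4,
         leads=dict(
             left=("frontal", [("ANT-V", 4, "spike")]),
             right=("lateral", [("ANT-V", 2, "spike"), ("MD", 2, None)])),
         rates=(0.40, 0.13, 0.20, 0.00),
         conditions=[
             ("left", "sleep", S2T, +90), ("left", "sleep", T2S, +15),
             ("right", "awake", S2T, +140), ("right", "awake", T2S, None)]),
    dict(id="P05", laterality="right", pre=16, post=6,
         leads=dict(
             left=None,
             right=("frontal", [("ANT-V", 2, "spike"), ("MD", 2, None)])),
         rates=(0.55, 0.20, 0.35, 0.08),
         conditions=[
             ("right", "sleep", S2T, +160), ("right", "awake", S2T, None)]),
    dict(id="P06", laterality="left", pre=9, post=4,
         leads=dict(
             left=None,
             right=("frontal", [("ANT-V", 2, "spike"), ("MD", 2, None)])),
         rates=(0.35, 0.10, 0.25, 0.00),
         conditions=[
             ("right", "sleep", S2T, None), ("right", "awake", T2S, None)]),
    dict(id="P07", laterality="left", pre=10, post=5,
         leads=dict(
             left=("frontal", [("ANT-V", 2, "spike"), ("ANT-P", 1, None)]),
             right=("frontal", [("ANT-D", 2, "spike"), ("MD", 2, "spike")])),
         rates=(0.33, 0.13, 0.30, 0.05),
         conditions=[
             ("left", "sleep", S2T, +2), ("left", "sleep", T2S, -4),
             ("right", "sleep", S2T, -15), ("right", "sleep", T2S, None),
             ("left", "awake", S2T, +8), ("right", "awake", S2T, None)]),
    dict(id="P08", laterality="left", pre=12, post=8,
         leads=dict(
             left=("frontal", [("ANT-V", 2, "spike"), ("ANT-P", 1, None)]),
             right=("frontal", [("ANT-D", 2, "spike"), ("MD", 2, "spike")])),
         rates=(0.25, 0.10, 0.26, 0.00),
         conditions=[
             ("left", "sleep", S2T, +12), ("left", "sleep", T2S, -16),
             ("right", "sleep", S2T, None),
             ("left", "awake", S2T, +25), ("right", "awake", S2T, None)]),
    dict(id="P09", laterality="left", pre=8, post=6,
         leads=dict(
             left=("parietal", [("ANT-D", 1, "st"), ("MD", 3, None)]),
             right=("parietal", [("ANT-V", 3, "spike")])),
         rates=(0.20, 0.05, 0.22, 0.12),
         conditions=[
             ("right", "sleep", S2T, +38), ("left", "sleep", S2T, None),
             ("left", "sleep", T2S, None),
             ("right", "awake", S2T, +45), ("right", "awake", T2S, None)]),
    dict(id="P10", laterality="bilateral", pre=20, post=15,
         leads=dict(
             left=("parietal", [("ANT-D", 3, "st")]),
             right=("parietal", [("ANT-P", 1, None)])),
         rates=(0.10, 0.05, 0.15, 0.00),
         conditions=[
             ("left", "sleep", S2T, +65), ("left", "sleep", T2S, None),
             ("right", "sleep", S2T, None), ("left", "awake", S2T, None)]),
    dict(id="P11", laterality="bilateral", pre=10, post=9,
         leads=dict(
             left=("parietal", [("ANT-P", 1, None)]),
             right=("lateral", [("ANT-D", 1, "st"), ("ANT-P", 1, "st")])),
         rates=(0.15, 0.05, 0.18, 0.00),
         conditions=[
             ("right", "sleep", S2T, +100), ("right", "sleep", T2S, None),
             ("left", "sleep", S2T, None), ("right", "awake", S2T, None)]),
    dict(id="P12", laterality="left", pre=15, post=14,
         leads=dict(
             left=("parietal", [("ANT-P", 1, "st"), ("MD", 2, None)]),
             right=None),
         rates=(0.05, 0.00, 0.00, 0.00),
         conditions=[
             ("left", "sleep", S2T, None), ("left", "sleep", T2S, None)]),
    dict(id="P13", laterality="left", pre=10, post=10,
         leads=dict(
             left=None,
             right=("parietal", [("ANT-D", 3, "spike")])),
         rates=(0.30, 0.10, 0.28, 0.06),
         conditions=[
             ("right", "sleep", S2T, +138), ("right", "awake", S2T, +180)]),
    dict(id="P14", laterality="left", pre=10, post=12,
         leads=dict(
             left=None,
             right=("parietal", [("ANT-V", 1, None)])),
         rates=(0.00, 0.00, 0.20, 0.05),
         conditions=[
             ("right", "sleep", S2T, None), ("right", "awake", S2T, None)]),
    dict(id="P15", laterality="right", pre=6, post=5,
         leads=dict(
             left=("parietal", [("ANT-D", 1, None)]),
             right=None),
         rates=(0.00, 0.00, 0.10, 0.00),
         conditions=[
             ("left", "sleep", S2T, None), ("left", "awake", S2T, None)]),
]

#: trajectories of the six missed (intraventricular) leads
MISS_TRAJECTORIES = {
    ("P05", "left"): "frontal", ("P06", "left"): "frontal",
    ("P12", "right"): "parietal", ("P13", "left"): "frontal",
    ("P14", "left"): "frontal", ("P15", "right"): "frontal",
}

_OUTSIDE_XYZ = (1.0, 2.0, 10.0)  # near-midline, intraventricular


def build_lead_maps(atlas: RegionAtlas | None = None) -> list[LeadMap]:
    """Materialize all 30 leads as coordinate lists and resolve their
    regions through the box atlas (so the hit logic runs on geometry, not on
    pre-assigned labels)."""
    atlas = atlas or default_atlas()
    leads = []
    for row in PAPER15:
        for side, spec in row["leads"].items():
            sign = -1.0 if side == "left" else 1.0
            contacts = []
            if spec is None:
                traj = MISS_TRAJECTORIES[(row["id"], side)]
                for k in range(4):
                    x, y, z = _OUTSIDE_XYZ
                    contacts.append(Contact(label=f"c{k}",
                                            coordinate=(sign * x, y,
                                                        z + 0.5 * k)))
            else:
                traj, units = spec
                k = 0
                for region, n, _events in units:
                    cx, cy, cz = atlas.center(side, region)
                    for j in range(n):
                        contacts.append(Contact(
                            label=f"c{k}",
                            coordinate=(cx, cy, cz - 0.5 + 0.5 * j)))
                        k += 1
                while k < 4:
                    x, y, z = _OUTSIDE_XYZ
                    contacts.append(Contact(label=f"c{k}",
                                            coordinate=(sign * x, y,
                                                        z + 0.5 * k)))
                    k += 1
            lead = LeadMap(patient_id=row["id"], side=side,
                           contacts=contacts, trajectory=traj)
            lead.assign_regions(atlas)
            leads.append(lead)
    return leads


def contact_event_records() -> pd.DataFrame:
    """One row per intrathalamic contact: patient, side, region, and whether
    that contact's region unit showed spikes / sharp transients."""
    rows = []
    for row in PAPER15:
        for side, spec in row["leads"].items():
            if spec is None:
                continue
            _traj, units = spec
            for region, n, events in units:
                for _ in range(n):
                    rows.append(dict(patient=row["id"], side=side,
                                     region=region,
                                     has_spike=events == "spike",
                                     has_st=events == "st"))
    return pd.DataFrame(rows)


def condition_results(patient_id: str | None = None):
    """ConnectionResults for all evaluable fixture conditions, obtained by
    running the sign-convention classifier on the stored signed latencies."""
    out = []
    for row in PAPER15:
        if patient_id is not None and row["id"] != patient_id:
            continue
        for side, state, direction, latency in row["conditions"]:
            r = classify_connection(direction, latency, side=side, state=state)
            r.patient_id = row["id"]  # type: ignore[attr-defined]
            out.append(r)
    return out


def _spike_sides(row) -> set:
    sides = set()
    for side, spec in row["leads"].items():
        if spec is None:
            continue
        for region, _n, events in spec[1]:
            if region in ANT_REGIONS and events == "spike":
                sides.add(side)
    return sides


def _tied_sides(row) -> set:
    sides = set()
    for side, spec in row["leads"].items():
        if spec is None:
            continue
        for region, _n, events in spec[1]:
            if region in ANT_REGIONS and events in ("spike", "st"):
                sides.add(side)
    return sides


def build_cohort_table(atlas: RegionAtlas | None = None) -> pd.DataFrame:
    """Per-patient cohort table with outcome and flags, all derived from the
    fixture primitives through the library's own logic."""
    atlas = atlas or default_atlas()
    leads = build_lead_maps(atlas)
    by_patient: dict[str, list[LeadMap]] = {}
    for lead in leads:
        by_patient.setdefault(lead.patient_id, []).append(lead)

    rows = []
    for row in PAPER15:
        sr = seizure_reduction(row["pre"], row["post"])
        resp = is_responder(sr)
        hits = patient_hit_summary(by_patient[row["id"]], row["laterality"])
        spike_sides = _spike_sides(row)
        tied_sides = _tied_sides(row)
        if row["laterality"] == "bilateral":
            focus_spike = bool(spike_sides)
        else:
            focus_spike = row["laterality"] in spike_sides
        t_s, t_a, s_s, s_a = row["rates"]
        rows.append(dict(
            patient=row["id"], laterality=row["laterality"],
            seizures_pre=row["pre"], seizures_post=row["post"],
            sr_percent=sr, responder=resp,
            engel="III" if resp else "IV",
            bilateral_hit=hits["bilateral_hit"],
            unilateral_hit=hits["unilateral_hit"],
            focus_side_hit=hits["focus_side_hit"],
            any_ant_spike_tied=bool(spike_sides),
            any_ant_tied=bool(tied_sides),
            focus_side_spike_tied=focus_spike,
            tied_rate_sleep=t_s, tied_rate_awake=t_a,
            sied_rate_sleep=s_s, sied_rate_awake=s_a,
        ))
    return pd.DataFrame(rows).set_index("patient")


def paper15_bundle(atlas: RegionAtlas | None = None) -> dict:
    """Everything the summary stage consumes: cohort table, lead maps,
    contact event records, and connection results (pooled + sleep-only)."""
    atlas = atlas or default_atlas()
    cohort = build_cohort_table(atlas)
    results = condition_results()
    sleep = [r for r in results if r.state == "sleep"]
    return dict(
        atlas=atlas,
        cohort=cohort,
        lead_maps=build_lead_maps(atlas),
        contact_events=contact_event_records(),
        conditions=results,
        summary=summarize_conditions(results),
        sleep_summary=summarize_conditions(sleep),
    )


class FixtureError(ValueError):
    """The fixture violates one of its stated aggregate constraints."""


def verify_paper15(bundle: dict | None = None) -> dict:
    """Self-check the fixture's aggregate constraints; returns the checked
    aggregates, raises :class:`FixtureError` on any violation."""
    b = bundle or paper15_bundle()
    cohort, leads = b["cohort"], b["lead_maps"]
    n_hit = sum(lead_hit(l) for l in leads)
    n_ant = sum(1 for l in leads for r in l.regions if r in ANT_REGIONS)
    s = b["summary"]
    checks = {
        "n_patients": (len(cohort), 15),
        "n_responders": (int(cohort["responder"].sum()), 6),
        "n_leads": (len(leads), 30),
        "n_hit_leads": (n_hit, 24),
        "n_ant_contacts": (n_ant, 55),
        "n_bilateral_hit": (int(cohort["bilateral_hit"].sum()), 9),
        "n_focus_side_hit": (int(cohort["focus_side_hit"].sum()), 11),
        "n_focus_side_spike_tied":
            (int(cohort["focus_side_spike_tied"].sum()), 7),
        "n_evaluable_conditions": (s.n_evaluable, 60),
        "n_followers": (s.n_follower, 33),
        "n_preceders": (s.n_preceder, 3),
        "n_no_connection": (s.n_no_connection, 24),
    }
    bad = {k: v for k, v in checks.items() if v[0] != v[1]}
    if bad:
        raise FixtureError(f"inconsistent fixture aggregates: {bad}")
    return {k: v[0] for k, v in checks.items()}
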