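"""Contact-to-region assignment and lead/patient hit logic.

The imaging pipeline (MRI/CT fusion and visual consensus localization) is
replaced by patient-space contact coordinates plus a box atlas: each thalamic
subregion — anterior nucleus ventral/dorsal/posterior parts (ANT-V, ANT-D,
ANT-P, a sagittal-plane parcellation) and the mediodorsal nucleus (MD) — is
an axis-aligned closed box per side.  A lead *hits* when at least one of its
four contacts lies in an ANT subregion; otherwise it missed the target
(intraventricular).
"""

from __future__ import annotations

from dataclasses import dataclass

ANT_REGIONS = ("ANT-V", "ANT-D", "ANT-P")
REGIONS = ANT_REGIONS + ("MD",)
OUTSIDE = "outside"
TRAJECTORIES = ("frontal", "parietal", "lateral")


@dataclass(frozen=True)
class Box:
    """Closed axis-aligned box, mm bounds: boundary points belong to it."""

    lo: tuple
    hi: tuple

    def __post_init__(self):
        if len(self.lo) != 3 or len(self.hi) != 3:
            raise ValueError("box bounds must be 3-D")
        if any(a > b for a, b in zip(self.lo, self.hi)):
            raise ValueError(f"inverted box bounds {self.lo} > {self.hi}")

    def contains(self, p) -> bool:
        return all(a <= x <= b for a, x, b in zip(self.lo, p, self.hi))

    @property
    def center(self):
        return tuple((a + b) / 2.0 for a, b in zip(self.lo, self.hi))

    def overlaps(self, other: "Box") -> bool:
        return all(a0 <= b1 and a1 <= b0
                   for a0, b0, a1, b1 in zip(self.lo, self.hi,
                                             other.lo, other.hi))


@dataclass
class RegionAtlas:
    """Named closed boxes per (side, region); regions may not overlap."""

    boxes: dict  # (side, region) -> Box

    def __post_init__(self):
        keys = list(self.boxes)
        for (side, region) in keys:
            if region not in REGIONS:
                raise ValueError(f"unknown region {region!r}")
        for i, k1 in enumerate(keys):
            for k2 in keys[i + 1:]:
                if k1[0] == k2[0] and self.boxes[k1].overlaps(self.boxes[k2]):
                    raise ValueError(f"atlas boxes {k1} and {k2} overlap")

    def assign(self, coordinate, side: str) -> str:
        for (s, region), box in self.boxes.items():
            if s == side and box.contains(coordinate):
                return region
        return OUTSIDE

    def center(self, side: str, region: str):
        return self.boxes[(side, region)].center


def default_atlas() -> RegionAtlas:
    """Synthetic plausibility-envelope atlas (mm, AC-centred patient space).

    Stand-in geometry for the visual/imaging localization step: the ANT sits
    superior-anterior near the third ventricle (parcellated only in the
    sagittal plane into ventral, dorsal, and posterior parts), MD posterior
    and inferior to it.  Left is x < 0, right x > 0; gaps of 0.5 mm keep the
    closed boxes disjoint.
    """
    def sided(x0, x1, y0, y1, z0, z1):
        return (Box((x0, y0, z0), (x1, y1, z1)),          # right
                Box((-x1, y0, z0), (-x0, y1, z1)))        # left
    boxes = {}
    specs = {
        "ANT-V": (3.0, 9.0, -1.0, 5.0, 8.0, 11.5),
        "ANT-D": (3.0, 9.0, -1.0, 5.0, 12.0, 15.0),
        "ANT-P": (3.0, 9.0, -5.5, -1.5, 8.0, 15.0),
        "MD": (3.0, 9.0, -12.0, -6.0, 4.0, 12.0),
    }
    for region, (x0, x1, y0, y1, z0, z1) in specs.items():
        r, l = sided(x0, x1, y0, y1, z0, z1)
        boxes[("right", region)] = r
        boxes[("left", region)] = l
    return RegionAtlas(boxes)


@dataclass
class Contact:
    label: str
    coordinate: tuple
    region: str = OUTSIDE


@dataclass
class LeadMap:
    """One implanted 4-contact lead with atlas-resolved regions."""

    patient_id: str
    side: str                      # "left" | "right"
    contacts: list                 # list[Contact], deepest first
    trajectory: str = "frontal"

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError("side must be left or right")
        if len(self.contacts) != 4:
            raise ValueError("a DBS lead carries exactly 4 contacts")
        if self.trajectory not in TRAJECTORIES:
            raise ValueError(f"unknown trajectory {self.trajectory!r}")

    def assign_regions(self, atlas: RegionAtlas) -> None:
        for c in self.contacts:
            c.region = atlas.assign(c.coordinate, self.side)

    @property
    def regions(self) -> list[str]:
        return [c.region for c in self.contacts]


def assign_region(coordinate, atlas: RegionAtlas, side: str) -> str:
    """Region label of the containing closed box, else ``outside``."""
    return atlas.assign(coordinate, side)


def lead_hit(lead: LeadMap) -> bool:
    """Hit iff at least one contact lies in an ANT subregion."""
    return any(r in ANT_REGIONS for r in lead.regions)


def patient_hit_summary(leads, focus_laterality: str) -> dict:
    """Per-patient hit flags.

    ``bilateral_hit``: both leads hit.  ``focus_side_hit``: for one-sided
    laterality, the lead on that side hit; for bilateral laterality, both
    did.  ``unilateral_hit``: exactly one lead hit.
    """
    if focus_laterality not in ("left", "right", "bilateral"):
        raise ValueError(f"unknown laterality {focus_laterality!r}")
    hits = {lead.side: lead_hit(lead) for lead in leads}
    n_hit = sum(hits.values())
    bilateral = len(hits) == 2 and all(hits.values())
    if focus_laterality == "bilateral":
        focus = bilateral
    else:
        focus = hits.get(focus_laterality, False)
    return {"bilateral_hit": bilateral,
            "unilateral_hit": n_hit == 1,
            "any_hit": n_hit >= 1,
            "focus_side_hit": focus}


def ant_contact_count(leads) -> int:
    return sum(1 for lead in leads for r in lead.regions if r in ANT_REGIONS)


def region_units(leads) -> list[tuple]:
    """Deduplicated sampled-region units: one per (patient, side, region)
    with at least one intrathalamic contact.  Multiple contacts within the
    same region (same patient and lead) count once."""
    seen = set()
    out = []
    for lead in leads:
        for r in lead.regions:
            if r == OUTSIDE:
                continue
            key = (lead.patient_id, lead.side, r)
            if key not in seen:
                seen.add(key)
                out.append(key)
    return out
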