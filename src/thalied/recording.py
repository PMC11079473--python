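"""Recording data model, montage construction, and analysis-segment selection.

A :class:`Recording` bundles a multichannel scalp-EEG + thalamic-LFP signal
matrix with its sampling rate and state annotations (sleep / awake / seizure
intervals).  Montages are expressed as :class:`MontageView` objects holding
derived channels (minuend minus subtrahend), so bipolar and monopolar views
share one code path.

Conventions: time is in seconds from record start, sample indexing is
0-based, and all intervals are half-open ``[start, end)``.  DBS contacts are
numbered from the deepest contact (0 = most distal).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: scalp channels used by default (modified 10-20; F3/F4/C3/C4 are typically
#: sacrificed to the head bandage and therefore omitted)
SCALP_CHANNELS = ["Fp1", "Fp2", "F7", "F8", "T3", "T4", "T5", "T6", "O1", "O2"]
LEFT_SCALP = ["Fp1", "F7", "T3", "T5", "O1"]
RIGHT_SCALP = ["Fp2", "F8", "T4", "T6", "O2"]

#: longitudinal scalp chains used for the bipolar scalp montage
SCALP_CHAINS = {
    "left": ["Fp1", "F7", "T3", "T5", "O1"],
    "right": ["Fp2", "F8", "T4", "T6", "O2"],
}

DBS_LEFT = ["LTh0", "LTh1", "LTh2", "LTh3"]
DBS_RIGHT = ["RTh0", "RTh1", "RTh2", "RTh3"]

#: numeric aliases for right-lead contacts 8-11 (clinical numbering carries on
#: across leads: left 0-3, right 8-11)
CONTACT_ALIASES = {f"RTh{8 + i}": f"RTh{i}" for i in range(4)}

STATES = ("sleep", "awake")
SITES = ("scalp-left", "scalp-right", "thal-left", "thal-right")


def channel_kind(label: str) -> str:
    """Classify a channel label as scalp / dbs-left / dbs-right."""
    if label.startswith("LTh"):
        return "dbs-left"
    if label.startswith("RTh"):
        return "dbs-right"
    return "scalp"


@dataclass(frozen=True)
class Annotation:
    """A labelled time interval, ``[start_s, end_s)`` seconds."""

    label: str  # sleep | awake | seizure
    start_s: float
    end_s: float

    def __post_init__(self):
        if self.end_s < self.start_s:
            raise ValueError(f"annotation ends before it starts: {self}")


@dataclass
class Recording:
    """Multichannel recording: samples in microvolt, one row per channel."""

    labels: list[str]
    data: np.ndarray  # shape (n_channels, n_samples), µV
    fs: float
    annotations: list[Annotation] = field(default_factory=list)
    patient_id: str = "P00"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channel rows"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate channel labels")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        dur = self.duration_s
        for ann in self.annotations:
            if ann.start_s < 0 or ann.end_s > dur + 1e-9:
                raise ValueError(f"annotation {ann} outside record [0, {dur:.3f}s)")
        self._check_state_overlap()

    def _check_state_overlap(self):
        ivals = sorted(
            (a.start_s, a.end_s) for a in self.annotations if a.label in STATES
        )
        for (s0, e0), (s1, _) in zip(ivals, ivals[1:]):
            if s1 < e0 - 1e-9:
                raise ValueError("sleep/awake annotations overlap")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    @property
    def kinds(self) -> list[str]:
        return [channel_kind(lb) for lb in self.labels]

    def index(self, label: str) -> int:
        label = CONTACT_ALIASES.get(label, label)
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.index(label)]

    def state_intervals(self, state: str) -> list[tuple[float, float]]:
        return [
            (a.start_s, a.end_s) for a in self.annotations if a.label == state
        ]

    def with_data(self, data: np.ndarray) -> "Recording":
        return replace(self, data=data)


@dataclass(frozen=True)
class DerivedChannel:
    """name = minuend - subtrahend; subtrahend None means as-recorded."""

    name: str
    minuend: str
    subtrahend: str | None = None


@dataclass
class MontageView:
    """A set of derived channels over a recording (bipolar or monopolar)."""

    recording: Recording
    channels: list[DerivedChannel]
    mode: str  # "bipolar" | "monopolar"

    def __post_init__(self):
        for ch in self.channels:
            self.recording.index(ch.minuend)
            if ch.subtrahend is not None:
                self.recording.index(ch.subtrahend)

    @property
    def labels(self) -> list[str]:
        return [ch.name for ch in self.channels]

    @property
    def fs(self) -> float:
        return self.recording.fs

    def signal(self, name: str) -> np.ndarray:
        for ch in self.channels:
            if ch.name == name:
                x = self.recording.channel(ch.minuend)
                if ch.subtrahend is None:
                    return x
                return x - self.recording.channel(ch.subtrahend)
        raise KeyError(f"derived channel {name!r} not in montage")

    def matrix(self) -> np.ndarray:
        return np.vstack([self.signal(name) for name in self.labels])

    def subset(self, names: list[str]) -> "MontageView":
        keep = [ch for ch in self.channels if ch.name in names]
        return MontageView(self.recording, keep, self.mode)


def _adjacent_pairs(chain: list[str]) -> list[tuple[str, str]]:
    return list(zip(chain, chain[1:]))


def make_bipolar(rec: Recording, scheme: str = "dbs-adjacent") -> MontageView:
    """Build a bipolar montage.

    ``scheme`` is ``"dbs-adjacent"`` (contacts 0-1, 1-2, 2-3 per lead — three
    derived channels per 4-contact lead), ``"scalp-longitudinal"`` (the
    fronto-temporo-occipital chains), or an explicit list of
    ``(minuend, subtrahend)`` label pairs.
    """
    pairs: list[tuple[str, str]] = []
    if scheme == "dbs-adjacent":
        for lead in (DBS_LEFT, DBS_RIGHT):
            present = [lb for lb in lead if lb in rec.labels]
            pairs += _adjacent_pairs(present)
    elif scheme == "scalp-longitudinal":
        for chain in SCALP_CHAINS.values():
            present = [lb for lb in chain if lb in rec.labels]
            pairs += _adjacent_pairs(present)
    else:
        pairs = [(a, b) for a, b in scheme]
    if not pairs:
        raise ValueError(f"no channels available for bipolar scheme {scheme!r}")
    chans = [DerivedChannel(f"{a}-{b}", a, b) for a, b in pairs]
    return MontageView(rec, chans, "bipolar")


def make_monopolar(rec: Recording, reference: str = "as-recorded",
                   labels: list[str] | None = None) -> MontageView:
    """Build a monopolar montage against ``reference``.

    ``"as-recorded"`` keeps the acquisition reference (extracranial G2);
    any channel label re-references every channel to it.
    """
    use = labels if labels is not None else rec.labels
    if reference == "as-recorded":
        chans = [DerivedChannel(lb, lb) for lb in use]
    else:
        rec.index(reference)  # raises if missing
        chans = [DerivedChannel(lb, lb, reference) for lb in use]
    return MontageView(rec, chans, "monopolar")


def _subtract_intervals(ival: tuple[float, float],
                        forbidden: list[tuple[float, float]]):
    """Yield the parts of ``ival`` not covered by any forbidden interval."""
    segs = [ival]
    for f0, f1 in forbidden:
        out = []
        for s0, s1 in segs:
            if f1 <= s0 or f0 >= s1:
                out.append((s0, s1))
                continue
            if f0 > s0:
                out.append((s0, f0))
            if f1 < s1:
                out.append((f1, s1))
        segs = out
    return segs


class InsufficientDataError(RuntimeError):
    """Raised when a recording cannot supply the requested analysis minutes."""


def select_segments(rec: Recording, state: str, minutes: float = 20.0,
                    seizure_gap_hours: float = 2.0) -> list[tuple[float, float]]:
    """Pick intervals of ``state`` totalling exactly ``minutes``.

    Every selected sample is at least ``seizure_gap_hours`` away from any
    seizure annotation; intervals are taken earliest-first and the last one is
    trimmed so the total is exact.
    """
    if state not in STATES:
        raise ValueError(f"state must be one of {STATES}")
    want = minutes * 60.0
    gap = seizure_gap_hours * 3600.0
    forbidden = [
        (a.start_s - gap, a.end_s + gap)
        for a in rec.annotations
        if a.label == "seizure"
    ]
    eligible: list[tuple[float, float]] = []
    for ival in sorted(rec.state_intervals(state)):
        eligible += _subtract_intervals(ival, forbidden)

    picked: list[tuple[float, float]] = []
    total = 0.0
    for s0, s1 in eligible:
        if total >= want:
            break
        take = min(s1 - s0, want - total)
        if take > 0:
            picked.append((s0, s0 + take))
            total += take
    if total < want - 1e-9:
        raise InsufficientDataError(
            f"only {total / 60.0:.2f} min of eligible {state} data, "
            f"need {minutes:.2f} min (short by {(want - total) / 60.0:.2f} min)"
        )
    return picked


def amplitude_artifact_mask(rec: Recording, threshold_uv: float,
                            pad_s: float = 0.25) -> np.ndarray:
    """Boolean per-sample mask of samples within ``pad_s`` of any
    suprathreshold excursion on any channel.  Optional helper for real data;
    the simulator produces artifact-free records."""
    bad = np.any(np.abs(rec.data) > threshold_uv, axis=0)
    if not bad.any():
        return bad
    pad = int(round(pad_s * rec.fs))
    idx = np.flatnonzero(bad)
    mask = np.zeros(rec.n_samples, dtype=bool)
    for i in idx:
        mask[max(0, i - pad):i + pad + 1] = True
    return mask
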