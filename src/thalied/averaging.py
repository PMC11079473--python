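"""IED-triggered average potentials (IED-TP) and connection classification.

For each of the eight per-patient conditions (2 sides x 2 states x 2
directions), the target site's signal is averaged in a ±500 ms window
time-locked to the trigger site's IED peaks (trigger peak = 0 ms).  A
suprathreshold extremum of the average is the IED-TP peak; its signed
latency classifies the anterior-thalamus side as *follower* (scalp→thal
average with positive latency, or thal→scalp with negative latency),
*preceder* (the converse signs), or *no connection* (no detectable peak).
Reported lags are absolute ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

WINDOW_MS = 500.0
BASELINE_MS = (-500.0, -250.0)

DIRECTIONS = ("scalp->thal", "thal->scalp")


@dataclass
class TriggeredAverage:
    """Average target waveform(s) around trigger events."""

    waveforms: dict            # channel label -> µV array, length fs+1
    fs: float
    n_triggers: int
    trigger_site: str = ""
    trigger_state: str = ""
    target_site: str = ""
    n_dropped: int = 0         # triggers too close to the record edges

    @property
    def time_ms(self) -> np.ndarray:
        n = next(iter(self.waveforms.values())).size
        return (np.arange(n) - (n - 1) / 2) / self.fs * 1000.0

    def baseline_sd(self, channel: str) -> float:
        w = self.waveforms[channel]
        t = self.time_ms
        m = (t >= BASELINE_MS[0]) & (t <= BASELINE_MS[1])
        return float(np.std(w[m]))

    def best_channel(self) -> str:
        """Channel with the largest absolute excursion."""
        return max(self.waveforms,
                   key=lambda ch: float(np.max(np.abs(self.waveforms[ch]))))


@dataclass
class ConnectionResult:
    """Outcome of one (side, state, direction) condition."""

    side: str                  # "left" | "right"
    state: str                 # "sleep" | "awake"
    direction: str             # "scalp->thal" | "thal->scalp"
    category: str              # follower | preceder | no_connection | not_evaluable
    lag_ms: float | None = None   # absolute
    latency_ms: float | None = None  # signed, as measured on the average
    n_triggers: int = 0
    reason: str = ""           # why not_evaluable

    def __post_init__(self):
        if self.category in ("follower", "preceder"):
            assert self.lag_ms is not None and self.lag_ms <= WINDOW_MS


def extract_epochs(signal: np.ndarray, fs: float, trigger_times_s,
                   window_ms: float = WINDOW_MS):
    """Epoch matrix around triggers; the trigger sample is the centre (0 ms).

    Triggers closer than the window to either record edge are dropped and
    counted.  Returns ``(epochs, n_dropped)``; raises if nothing is usable.
    """
    half = int(round(window_ms / 1000.0 * fs))
    rows = []
    dropped = 0
    for t in trigger_times_s:
        c = int(round(t * fs))
        if c - half < 0 or c + half >= signal.size:
            dropped += 1
            continue
        rows.append(signal[c - half: c + half + 1])
    if not rows:
        raise ValueError(
            f"no usable triggers ({dropped} dropped at the record edges)")
    return np.vstack(rows), dropped


def average_epochs(epochs: np.ndarray, fs: float, **meta) -> TriggeredAverage:
    """Pointwise mean across epochs (single channel)."""
    epochs = np.atleast_2d(epochs)
    return TriggeredAverage(waveforms={"avg": epochs.mean(axis=0)}, fs=fs,
                            n_triggers=epochs.shape[0], **meta)


def average_channels(channel_epochs: dict, fs: float, **meta) -> TriggeredAverage:
    """Pointwise mean per channel for multichannel targets."""
    waves = {ch: np.atleast_2d(ep).mean(axis=0)
             for ch, ep in channel_epochs.items()}
    n = np.atleast_2d(next(iter(channel_epochs.values()))).shape[0]
    return TriggeredAverage(waveforms=waves, fs=fs, n_triggers=n, **meta)


def find_iedtp_peak(avg: TriggeredAverage, channel: str | None = None,
                    peak_threshold: float = 4.0,
                    min_lag_ms: float = 2.0) -> float | None:
    """Signed latency (ms) of the maximal-absolute extremum of the average
    exceeding ``peak_threshold`` x the pre-trigger baseline SD, excluding
    ±``min_lag_ms`` around 0; ``None`` when no suprathreshold peak exists."""
    if channel is None:
        channel = avg.best_channel()
    w = avg.waveforms[channel]
    t = avg.time_ms
    sd = avg.baseline_sd(channel)
    m = np.abs(t) >= min_lag_ms
    idx = np.flatnonzero(m)
    k = idx[np.argmax(np.abs(w[idx]))]
    if np.abs(w[k]) < peak_threshold * sd:
        return None
    return float(t[k])


def classify_connection(direction: str, latency_ms: float | None,
                        side: str = "", state: str = "",
                        min_lag_ms: float = 2.0,
                        n_triggers: int = 0) -> ConnectionResult:
    """Map a signed IED-TP latency to follower / preceder / no_connection.

    scalp→thal with positive latency or thal→scalp with negative latency
    means the thalamus follows the scalp; the converse signs make it a
    preceder.  ``|latency| < min_lag_ms`` is ambiguous sign-noise around 0
    and yields ``not_evaluable``.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    kw = dict(side=side, state=state, direction=direction,
              n_triggers=n_triggers)
    if latency_ms is None:
        return ConnectionResult(category="no_connection", **kw)
    if abs(latency_ms) < min_lag_ms:
        return ConnectionResult(category="not_evaluable",
                                latency_ms=latency_ms,
                                reason="latency below minimum lag", **kw)
    thal_later = (latency_ms > 0) == (direction == "scalp->thal")
    cat = "follower" if thal_later else "preceder"
    return ConnectionResult(category=cat, lag_ms=abs(latency_ms),
                            latency_ms=latency_ms, **kw)


@dataclass
class ConditionSummary:
    """Category bookkeeping over evaluable conditions."""

    n_evaluable: int = 0
    n_follower: int = 0
    n_preceder: int = 0
    n_no_connection: int = 0
    follower_lags: list = field(default_factory=list)
    preceder_lags: list = field(default_factory=list)

    @property
    def fractions(self) -> dict:
        n = self.n_evaluable
        if n == 0:
            return {"follower": np.nan, "preceder": np.nan,
                    "no_connection": np.nan}
        return {"follower": self.n_follower / n,
                "preceder": self.n_preceder / n,
                "no_connection": self.n_no_connection / n}

    @property
    def mean_follower_lag_ms(self) -> float:
        return float(np.mean(self.follower_lags)) if self.follower_lags else np.nan

    @property
    def mean_preceder_lag_ms(self) -> float:
        return float(np.mean(self.preceder_lags)) if self.preceder_lags else np.nan


def summarize_conditions(results) -> ConditionSummary:
    """Aggregate connection results; ``not_evaluable`` is excluded from the
    denominator."""
    s = ConditionSummary()
    for r in results:
        if r.category == "not_evaluable":
            continue
        s.n_evaluable += 1
        if r.category == "follower":
            s.n_follower += 1
            s.follower_lags.append(r.lag_ms)
        elif r.category == "preceder":
            s.n_preceder += 1
            s.preceder_lags.append(r.lag_ms)
        elif r.category == "no_connection":
            s.n_no_connection += 1
        else:
            raise ValueError(f"unknown category {r.category!r}")
    return s


def enumerate_conditions(trigger_times: dict, target_views: dict,
                         side_hit: dict, segments: dict,
                         peak_threshold: float = 4.0,
                         min_lag_ms: float = 2.0) -> list[ConnectionResult]:
    """Evaluate the ≤8 conditions of one patient from signals.

    ``trigger_times[(site, state)]`` are detected IED peak times (s);
    ``target_views[site]`` is the MontageView whose channels are averaged when
    that site is the *target*; ``side_hit[side]`` flags an intranuclear lead;
    ``segments[state]`` are the analysis intervals (unused beyond bookkeeping,
    triggers are assumed to come from them).  Conditions with a missed lead or
    with no triggers are ``not_evaluable``.
    """
    results = []
    for side in ("left", "right"):
        for state in ("sleep", "awake"):
            for direction in DIRECTIONS:
                kw = dict(side=side, state=state, direction=direction)
                if not side_hit.get(side, False):
                    results.append(ConnectionResult(
                        category="not_evaluable", reason="missing ANT hit",
                        **kw))
                    continue
                src = ("scalp" if direction == "scalp->thal" else "thal")
                dst = "thal" if src == "scalp" else "scalp"
                trig = trigger_times.get((f"{src}-{side}", state), [])
                if len(trig) == 0:
                    results.append(ConnectionResult(
                        category="not_evaluable", reason="missing IEDs", **kw))
                    continue
                view = target_views[f"{dst}-{side}"]
                chan_epochs = {}
                dropped = 0
                try:
                    for ch in view.labels:
                        ep, dropped = extract_epochs(view.signal(ch), view.fs,
                                                     trig)
                        chan_epochs[ch] = ep
                except ValueError:
                    results.append(ConnectionResult(
                        category="not_evaluable",
                        reason="all triggers at record edges", **kw))
                    continue
                avg = average_channels(chan_epochs, view.fs,
                                       trigger_site=f"{src}-{side}",
                                       trigger_state=state,
                                       target_site=f"{dst}-{side}",
                                       n_dropped=dropped)
                lat = find_iedtp_peak(avg, peak_threshold=peak_threshold,
                                      min_lag_ms=min_lag_ms)
                results.append(classify_connection(
                    direction, lat, side=side, state=state,
                    min_lag_ms=min_lag_ms, n_triggers=avg.n_triggers))
    return results
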