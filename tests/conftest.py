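"""Shared fixtures: tiny synthetic recordings built programmatically."""

import numpy as np
import pytest

from thalied.recording import Annotation, Recording, DBS_LEFT, DBS_RIGHT
from thalied.synth import SimulationConfig, SpikeTemplate, make_spike_template


@pytest.fixture
def fs():
    return 512.0


@pytest.fixture
def lead_recording(fs):
    """60 s silent recording with the two DBS leads only (all-sleep)."""
    n = int(60 * fs)
    labels = DBS_LEFT + DBS_RIGHT
    data = np.zeros((len(labels), n))
    ann = [Annotation("sleep", 0.0, 60.0)]
    return Recording(labels=labels, data=data, fs=fs, annotations=ann)


def insert_template(rec, label, t, template=None, weight=1.0):
    """Add a spike template so its fast-component peak lands at ``t`` s."""
    from thalied.synth import template_peak_offset
    template = template or SpikeTemplate()
    w = make_spike_template(template, rec.fs) * weight
    off = template_peak_offset(template, rec.fs)
    i0 = int(round(t * rec.fs)) - off
    rec.data[rec.index(label), i0:i0 + w.size] += w
    return rec


@pytest.fixture
def quiet_config(fs):
    """Short, silent simulation config (all rates zero)."""
    rates = {(site, state): 0.0
             for site in ("scalp-left", "scalp-right", "thal-left",
                          "thal-right")
             for state in ("sleep", "awake")}
    return SimulationConfig(rates=rates, segment_minutes=0.5, fs=fs, seed=11)
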