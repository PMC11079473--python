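"""Minimal EDF (European Data Format) reader/writer.

Plain 16-bit EDF with one uniform sampling rate across channels, which is all
the acquisition setup here produces (scalp EEG and thalamic LFP sampled
together).  Annotations travel in a sidecar CSV (``label,start_s,end_s``)
next to the EDF rather than as EDF+ TALs, keeping the binary layout to the
1992 base spec.

The header date/time are fixed (anonymized) so that writing the same
recording twice yields byte-identical files.
"""

from __future__ import annotations

import csv
import math
import os

import numpy as np

from .recording import Annotation, Recording

DIG_MIN = -32768
DIG_MAX = 32767
_HDR_DATE = "01.01.85"
_HDR_TIME = "00.00.00"
_NSAMP_TAG = "NS="  # true sample count, stored in the reserved header field


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _fmt_float(x: float, width: int = 8) -> str:
    """Format a float into an EDF 8-char ASCII field."""
    for fmt in (f"{x:.6g}", f"{x:.4g}", f"{x:.2g}"):
        if len(fmt) <= width:
            return fmt
    raise ValueError(f"cannot format {x} in {width} chars")


def write_edf(rec: Recording, path: str | os.PathLike,
              record_duration_s: float = 1.0) -> None:
    """Write ``rec`` as a 16-bit EDF file plus a sidecar annotation CSV.

    Samples are scaled per channel to a symmetric physical range covering the
    data, so the quantization error is at most half a digital unit step.
    """
    n_ch, n_samp = rec.data.shape
    if n_ch == 0:
        raise ValueError("cannot write an EDF with zero channels")
    spr = int(round(record_duration_s * rec.fs))
    if spr <= 0 or abs(spr - record_duration_s * rec.fs) > 1e-6:
        raise ValueError(
            f"record duration {record_duration_s}s is not an integer number "
            f"of samples at fs={rec.fs}"
        )
    n_rec = math.ceil(n_samp / spr) if n_samp else 0
    if n_rec == 0:
        raise ValueError("cannot write an EDF with zero samples")

    # symmetric physical range per channel; EDF fields are 8-char ASCII so
    # round the bound up to 4 significant digits
    pmaxs = []
    for i in range(n_ch):
        amax = float(np.max(np.abs(rec.data[i]))) if n_samp else 0.0
        if amax == 0.0:
            amax = 1.0
        exp = math.floor(math.log10(amax))
        bound = math.ceil(amax / 10 ** (exp - 3)) * 10 ** (exp - 3)
        pmaxs.append(float(bound))

    header = bytearray()
    header += _field("0", 8)
    header += _field(rec.patient_id, 80)
    header += _field("thalied simulated recording", 80)
    header += _field(_HDR_DATE, 8)
    header += _field(_HDR_TIME, 8)
    header += _field(256 * (1 + n_ch), 8)
    header += _field(f"{_NSAMP_TAG}{n_samp}", 44)
    header += _field(n_rec, 8)
    header += _field(_fmt_float(record_duration_s), 8)
    header += _field(n_ch, 4)
    for lb in rec.labels:
        header += _field(lb, 16)
    for _ in range(n_ch):
        header += _field("", 80)  # transducer
    for _ in range(n_ch):
        header += _field("uV", 8)
    for p in pmaxs:
        header += _field(_fmt_float(-p), 8)
    for p in pmaxs:
        header += _field(_fmt_float(p), 8)
    header += _field(DIG_MIN, 8) * n_ch
    header += _field(DIG_MAX, 8) * n_ch
    for _ in range(n_ch):
        header += _field("", 80)  # prefilter
    header += _field(spr, 8) * n_ch
    header += _field("", 32) * n_ch

    # digitize; physical bound strings round-trip through ASCII, so recompute
    # the gains from the formatted values
    gains = [
        (float(_fmt_float(p)) - float(_fmt_float(-p))) / (DIG_MAX - DIG_MIN)
        for p in pmaxs
    ]
    offsets = [float(_fmt_float(-p)) - DIG_MIN * g for p, g in zip(pmaxs, gains)]
    dig = np.empty((n_ch, n_rec * spr), dtype="<i2")
    for i in range(n_ch):
        x = np.zeros(n_rec * spr)
        x[:n_samp] = rec.data[i]
        d = np.rint((x - offsets[i]) / gains[i])
        dig[i] = np.clip(d, DIG_MIN, DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        # record-major, signal-blocked layout
        blocks = dig.reshape(n_ch, n_rec, spr)
        fh.write(np.ascontiguousarray(blocks.transpose(1, 0, 2)).tobytes())

    write_annotations_csv(rec.annotations, _sidecar_path(path))


def _sidecar_path(path) -> str:
    return f"{os.fspath(path)}.annotations.csv"


def write_annotations_csv(annotations, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "start_s", "end_s"])
        for a in annotations:
            w.writerow([a.label, f"{a.start_s:.6f}", f"{a.end_s:.6f}"])


def read_annotations_csv(path) -> list[Annotation]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(Annotation(row["label"], float(row["start_s"]),
                                  float(row["end_s"])))
    return out


def read_edf(path: str | os.PathLike) -> Recording:
    """Read a plain 16-bit EDF written by :func:`write_edf` (or compatible).

    Raises ``ValueError`` on malformed headers or mixed per-channel sampling
    rates (unsupported here).
    """
    with open(path, "rb") as fh:
        fixed = fh.read(256)
        if len(fixed) < 256:
            raise ValueError("truncated EDF header")
        try:
            patient = fixed[8:88].decode("ascii").strip()
            reserved = fixed[192:236].decode("ascii").strip()
            n_rec = int(fixed[236:244])
            rec_dur = float(fixed[244:252])
            n_ch = int(fixed[252:256])
        except (UnicodeDecodeError, ValueError) as exc:
            raise ValueError(f"malformed EDF header: {exc}") from None
        if n_ch <= 0:
            raise ValueError("EDF declares no signals")

        sig = fh.read(256 * n_ch)
        if len(sig) < 256 * n_ch:
            raise ValueError("truncated EDF signal header")

        # field offsets within the signal header block:
        # label16, transducer80, dim8, pmin8, pmax8, dmin8, dmax8,
        # prefilter80, spr8, reserved32 — each field stored for all signals
        # before the next field starts
        offs = {}
        cur = 0
        for name, width in [("label", 16), ("transducer", 80), ("dim", 8),
                            ("pmin", 8), ("pmax", 8), ("dmin", 8),
                            ("dmax", 8), ("prefilter", 80), ("spr", 8),
                            ("reserved", 32)]:
            offs[name] = (cur, width)
            cur += width * n_ch

        def fieldvals(name):
            start, width = offs[name]
            return [
                sig[start + i * width: start + (i + 1) * width]
                .decode("ascii").strip()
                for i in range(n_ch)
            ]

        labels = fieldvals("label")
        pmin = [float(v) for v in fieldvals("pmin")]
        pmax = [float(v) for v in fieldvals("pmax")]
        dmin = [int(v) for v in fieldvals("dmin")]
        dmax = [int(v) for v in fieldvals("dmax")]
        spr = [int(v) for v in fieldvals("spr")]
        if len(set(spr)) != 1:
            raise ValueError("mixed per-channel sampling rates are unsupported")
        spr0 = spr[0]
        fs = spr0 / rec_dur

        raw = np.frombuffer(fh.read(), dtype="<i2")

    expect = n_rec * n_ch * spr0
    if raw.size < expect:
        raise ValueError("EDF data shorter than header declares")
    raw = raw[:expect].reshape(n_rec, n_ch, spr0)
    gains = np.array([(pb - pa) / (db - da)
                      for pa, pb, da, db in zip(pmin, pmax, dmin, dmax)])
    offsets = np.array([pa - da * g for pa, da, g in zip(pmin, dmin, gains)])
    data = raw.transpose(1, 0, 2).reshape(n_ch, -1).astype(float)
    data = data * gains[:, None] + offsets[:, None]

    n_samp = n_rec * spr0
    if reserved.startswith(_NSAMP_TAG):
        n_samp = min(n_samp, int(reserved[len(_NSAMP_TAG):]))
    data = data[:, :n_samp]

    annotations = []
    sidecar = _sidecar_path(path)
    if os.path.exists(sidecar):
        annotations = read_annotations_csv(sidecar)
    return Recording(labels=labels, data=data, fs=fs,
                     annotations=annotations, patient_id=patient or "P00")
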