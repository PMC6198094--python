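"""Readers and writers: EDF signals, hypnogram CSV, model checkpoints.

EDF reading goes through MNE.  Writing uses a small built-in EDF encoder
(16-bit samples, standard 256-byte headers) so synthetic recordings can be
exported without any external writer; the MNE reader doubles as an
independent check of the encoder in the test suite.

Hypnograms travel as plain CSV ``epoch,stage`` with tokens
W/N1/N2/N3/R/U and the R&K aliases S3/S4 (both mapped to N3).

Checkpoints use a deterministic binary container (JSON header + raw
little-endian arrays) so saving the same model twice is byte-identical.
"""

from __future__ import annotations

import io as _io
import json
import struct
from pathlib import Path

import numpy as np

from .config import StagerConfig, load_demographics
from .core import STAGE_TO_TOKEN, STAGE_TOKENS, EegRecording, Hypnogram, SleepStage


class FormatError(ValueError):
    """Unreadable or malformed file content."""


class ChannelNotFoundError(KeyError):
    """Requested channel label is absent from the file."""


class CheckpointError(ValueError):
    """Checkpoint does not match the expected model configuration."""


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_EDF_HDR = 256  # bytes, fixed part and per-signal part


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise FormatError(f"EDF header field too long: {text!r} > {width}")
    return b.ljust(width)


def write_recording(recording: EegRecording, path: str | Path) -> None:
    """Write a single-channel recording as 16-bit EDF.

    Uses 1-second data records when the sample count divides evenly by the
    rate, otherwise a single data record spanning the whole signal, so the
    sample count is always preserved exactly.
    """
    x = np.asarray(recording.samples, dtype=np.float64)
    rate = recording.rate
    n = len(x)
    if n == 0:
        raise FormatError("cannot write an empty recording")
    if float(rate).is_integer() and n % int(rate) == 0:
        spr = int(rate)
        n_records = n // spr
        duration = "1"
    else:
        spr = n
        n_records = 1
        duration = f"{n / rate:.6g}"
        if len(duration) > 8:
            raise FormatError("recording duration does not fit an EDF header")

    amp = float(np.max(np.abs(x))) if n else 0.0
    phys_max = max(amp, 1e-6) * 1.000001  # avoid phys_min == phys_max
    phys_min = -phys_max
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((x - phys_min) * scale + dig_min).astype("<i2")

    label = recording.channel_label or "EEG"
    patient = recording.subject_id or "X"
    header = b"".join(
        [
            _pad("0", 8),
            _pad(patient, 80),
            _pad("Startdate 01-JAN-2000", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(_EDF_HDR * 2), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad(duration, 8),
            _pad("1", 4),
        ]
    )
    sig_header = b"".join(
        [
            _pad(label, 16),
            _pad("", 80),
            _pad("uV", 8),
            _pad(f"{phys_min:.6g}", 8),
            _pad(f"{phys_max:.6g}", 8),
            _pad(str(dig_min), 8),
            _pad(str(dig_max), 8),
            _pad("", 80),
            _pad(str(spr), 8),
            _pad("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        fh.write(digital.tobytes())


def read_recording(
    path: str | Path,
    channel: str | None = None,
    demographics: str | Path | dict | None = None,
) -> EegRecording:
    """Read one EEG channel from an EDF/EDF+ file (or ``.txt`` fallback).

    Samples are returned in microvolts; ``demographics`` may be a sidecar
    YAML path or a pre-loaded ``{subject_id: {age, gender}}`` mapping.
    """
    path = Path(path)
    if path.suffix == ".txt":
        rec = _read_txt_recording(path)
    else:
        rec = _read_edf_recording(path, channel)
    if demographics is not None:
        table = (
            demographics
            if isinstance(demographics, dict)
            else load_demographics(demographics)
        )
        entry = table.get(rec.subject_id)
        if entry:
            rec.age = entry.get("age", rec.age)
            rec.gender = entry.get("gender", rec.gender)
    return rec


def _read_edf_recording(path: Path, channel: str | None) -> EegRecording:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted errors on bad headers
        raise FormatError(f"unreadable EDF file {path}: {exc}") from exc
    names = raw.ch_names
    if channel is None:
        name = names[0]
    elif channel in names:
        name = channel
    else:
        raise ChannelNotFoundError(
            f"channel {channel!r} not in {path} (has {names})"
        )
    data = raw.get_data(picks=[name])[0] * 1e6  # volts -> microvolts
    subject = (raw.info.get("subject_info") or {}).get("his_id", "") or ""
    return EegRecording(
        samples=np.asarray(data, dtype=np.float64),
        rate=float(raw.info["sfreq"]),
        subject_id=subject,
        channel_label=name,
    )


def _read_txt_recording(path: Path) -> EegRecording:
    """Plain numeric format: ``key=value`` header line, one sample per line."""
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(kv.split("=", 1) for kv in header.split() if "=" in kv)
        if "rate" not in meta:
            raise FormatError(f"{path}: first line must contain rate=<Hz>")
        samples = np.loadtxt(fh, dtype=np.float64, ndmin=1)
    return EegRecording(
        samples=samples,
        rate=float(meta["rate"]),
        subject_id=meta.get("subject", ""),
        channel_label=meta.get("channel", "FPz-M2"),
    )


def write_txt_recording(recording: EegRecording, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"rate={recording.rate:g} subject={recording.subject_id} "
            f"channel={recording.channel_label}\n"
        )
        np.savetxt(fh, recording.samples, fmt="%.9g")


# ---------------------------------------------------------------------------
# Hypnogram CSV
# ---------------------------------------------------------------------------


def read_hypnogram(path: str | Path, trim_unknown_edges: bool = False) -> Hypnogram:
    """Read a plain ``epoch,stage`` CSV into a Hypnogram.

    Epoch indices must be contiguous from 0.  ``trim_unknown_edges`` drops
    leading/trailing runs of UNKNOWN epochs (how edge epochs of a night are
    handled is a scoring-house convention, so it is exposed as an option).
    """
    stages: list[SleepStage] = []
    expected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.lower().startswith("epoch"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'epoch,stage'")
            try:
                idx = int(parts[0])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad epoch index") from exc
            if idx != expected:
                raise FormatError(
                    f"{path}:{lineno}: non-contiguous epoch index "
                    f"{idx} (expected {expected})"
                )
            token = parts[1].upper()
            if token not in STAGE_TOKENS:
                raise FormatError(f"{path}:{lineno}: unknown stage token {token!r}")
            stages.append(STAGE_TOKENS[token])
            expected += 1
    if trim_unknown_edges:
        lo, hi = 0, len(stages)
        while lo < hi and stages[lo] is SleepStage.UNKNOWN:
            lo += 1
        while hi > lo and stages[hi - 1] is SleepStage.UNKNOWN:
            hi -= 1
        stages = stages[lo:hi]
    return Hypnogram(stages=stages)


def write_hypnogram(hypnogram: Hypnogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("epoch,stage\n")
        for i, stage in enumerate(hypnogram.stages):
            fh.write(f"{i},{STAGE_TO_TOKEN[stage]}\n")


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

_CKPT_MAGIC = b"STAGERNET1"


def save_model(model, path: str | Path) -> None:
    """Serialize a StagerModel (config + parameters) deterministically."""
    names = sorted(model.params)
    specs = []
    payload = _io.BytesIO()
    offset = 0
    for name in names:
        arr = np.ascontiguousarray(model.params[name], dtype="<f8")
        specs.append({"name": name, "shape": list(arr.shape), "offset": offset})
        raw = arr.tobytes()
        payload.write(raw)
        offset += len(raw)
    header = json.dumps(
        {"config": model.config.to_dict(), "params": specs},
        sort_keys=True,
        separators=(",", ":"),
    ).encode()
    with open(path, "wb") as fh:
        fh.write(_CKPT_MAGIC)
        fh.write(struct.pack("<Q", len(header)))
        fh.write(header)
        fh.write(payload.getvalue())


def load_model(path: str | Path, expected_config: StagerConfig | None = None):
    """Load a checkpoint; raise CheckpointError on config mismatch."""
    from .architecture import StagerModel

    with open(path, "rb") as fh:
        magic = fh.read(len(_CKPT_MAGIC))
        if magic != _CKPT_MAGIC:
            raise CheckpointError(f"{path} is not a stager checkpoint")
        (hlen,) = struct.unpack("<Q", fh.read(8))
        header = json.loads(fh.read(hlen))
        blob = fh.read()
    config = StagerConfig.from_dict(header["config"])
    if expected_config is not None and config.to_dict() != expected_config.to_dict():
        raise CheckpointError("checkpoint config does not match expected config")
    model = StagerModel(config, seed=0)
    for spec in header["params"]:
        name, shape, off = spec["name"], tuple(spec["shape"]), spec["offset"]
        if name not in model.params or tuple(model.params[name].shape) != shape:
            raise CheckpointError(f"parameter {name} missing or wrong shape")
        count = int(np.prod(shape)) if shape else 1
        arr = np.frombuffer(blob, dtype="<f8", count=count, offset=off)
        model.params[name] = arr.reshape(shape).astype(np.float64).copy()
    return model
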