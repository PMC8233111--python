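"""File I/O: EDF signals, hypnogram CSV, YAML/JSON configuration.

Reading EDF goes through :func:`mne.io.read_raw_edf`.  Writing uses a minimal
16-bit EDF writer implemented here (one data record per second, one physical
range per channel in microvolts).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .recording import Recording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field too long: {s!r} (max {width})")
    return s.ljust(width).encode("ascii")


def _fmt_phys(v: float) -> str:
    """Format a physical min/max so it round-trips within 8 ASCII chars."""
    for fmt in ("%.6g", "%.5g", "%.4g", "%.3g"):
        s = fmt % v
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot format {v} in 8 chars")


def write_edf(recording: Recording, path) -> None:
    """Write a recording to a 16-bit EDF file.

    The signal is stored in microvolts with a symmetric physical range per
    channel; round-tripping reproduces samples to within one quantization
    step of that range.  The recording duration must be a whole number of
    seconds and the sampling rate an integer.
    """
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_samp = recording.data.shape
    if n_samp % fs != 0:
        raise ValueError("EDF writer requires a whole number of seconds of data")
    n_rec = n_samp // fs

    data_uv = recording.data * 1e6
    # symmetric physical range per channel, padded so extremes stay in range
    pmax = np.maximum(np.max(np.abs(data_uv), axis=1) * 1.0001, 1e-3)

    start = recording.clock_start
    header = b"".join([
        _ascii_field("0", 8),
        _ascii_field("X X X X", 80),
        _ascii_field("Startdate X X X X", 80),
        _ascii_field(start.strftime("%d.%m.%y"), 8),
        _ascii_field(start.strftime("%H.%M.%S"), 8),
        _ascii_field(256 * (1 + n_ch), 8),
        _ascii_field("", 44),
        _ascii_field(n_rec, 8),
        _ascii_field(1, 8),
        _ascii_field(n_ch, 4),
    ])
    fields = [
        [_ascii_field(lab[:16], 16) for lab in recording.labels],
        [_ascii_field("", 80)] * n_ch,
        [_ascii_field("uV", 8)] * n_ch,
        [_ascii_field(_fmt_phys(-p), 8) for p in pmax],
        [_ascii_field(_fmt_phys(p), 8) for p in pmax],
        [_ascii_field(_DIG_MIN, 8)] * n_ch,
        [_ascii_field(_DIG_MAX, 8)] * n_ch,
        [_ascii_field("", 80)] * n_ch,
        [_ascii_field(fs, 8)] * n_ch,
        [_ascii_field("", 32)] * n_ch,
    ]
    header += b"".join(b"".join(col) for col in fields)

    # re-read the formatted physical range so quantization matches the header
    pmax_hdr = np.array([float(_fmt_phys(p)) for p in pmax])
    scale = (pmax_hdr - (-pmax_hdr)) / (_DIG_MAX - _DIG_MIN)
    dig = np.round((data_uv - (-pmax_hdr[:, None])) / scale[:, None]) + _DIG_MIN
    dig = np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        # records: for each second, each channel's fs samples in sequence
        blocks = dig.reshape(n_ch, n_rec, fs).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(blocks).tobytes())


def read_edf(path) -> Recording:
    """Read an EDF file into a :class:`Recording` (via MNE)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    meas = raw.info["meas_date"]
    clock = meas.replace(tzinfo=None) if meas is not None else None
    kwargs = {} if clock is None else {"clock_start": clock}
    return Recording(data=raw.get_data(), fs=float(raw.info["sfreq"]),
                     labels=list(raw.ch_names), **kwargs)


def load_config(path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError("configuration file must contain a mapping")
    return cfg


def dump_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))
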