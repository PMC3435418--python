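"""EDF and sidecar-file IO.

Recordings travel as 16-bit EDF (physical units µV) plus a tab-separated
events file.  Writing uses a small self-contained EDF encoder (plain EDF,
one-second data records); reading goes through :mod:`mne`, which doubles as
an independent check on the writer in the round-trip tests.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EVENT_COLUMNS, ContinuousRecording

__all__ = ["write_edf", "read_edf", "write_events_tsv", "read_events_tsv"]

logger = logging.getLogger(__name__)

_DIG_MAX = 32767


def _phys_str(v: float) -> str:
    """Shortest %g rendering of v that fits an 8-byte EDF header field."""
    for prec in range(6, 0, -1):
        s = f"{v:.{prec}g}"
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot encode physical bound {v} in 8 bytes")


def _ascii(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(recording: ContinuousRecording, path) -> None:
    """Write a recording as plain 16-bit EDF (µV physical units).

    Uses one-second data records; the sample rate must therefore be a whole
    number of samples per second.  The last record is zero-padded.
    """
    fs = recording.sample_rate_hz
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9 or spr < 1:
        raise ValueError("EDF writer requires an integer number of samples per second")
    data = recording.data
    n_ch, n_samp = data.shape
    n_records = int(np.ceil(n_samp / spr))

    # per-channel symmetric physical range, one quantization step of headroom
    absmax = np.maximum(np.abs(data).max(axis=1), 1e-6)
    pmax = absmax * (1 + 1.0 / _DIG_MAX)
    pmin = -pmax

    header = b"".join([
        _ascii(0, 8),
        _ascii("X X X X", 80),
        _ascii("Startdate X X X X", 80),
        _ascii("01.01.01", 8),
        _ascii("00.00.00", 8),
        _ascii(256 * (n_ch + 1), 8),
        _ascii("", 44),
        _ascii(n_records, 8),
        _ascii(1, 8),
        _ascii(n_ch, 4),
    ])
    fields = [
        ("label", 16, list(recording.labels)),
        ("transducer", 80, ["AgAgCl electrode"] * n_ch),
        ("dim", 8, ["uV"] * n_ch),
        ("pmin", 8, [_phys_str(v) for v in pmin]),
        ("pmax", 8, [_phys_str(v) for v in pmax]),
        ("dmin", 8, [-_DIG_MAX] * n_ch),
        ("dmax", 8, [_DIG_MAX] * n_ch),
        ("prefilter", 80, [""] * n_ch),
        ("spr", 8, [spr] * n_ch),
        ("reserved", 32, [""] * n_ch),
    ]
    sig_header = b"".join(
        b"".join(_ascii(v, width) for v in values) for _, width, values in fields
    )
    # re-parse the physical range exactly as written so scaling matches
    pmin_w = np.array([float(_phys_str(v)) for v in pmin])
    pmax_w = np.array([float(_phys_str(v)) for v in pmax])
    gain = (pmax_w - pmin_w) / (2 * _DIG_MAX)

    padded = np.zeros((n_ch, n_records * spr))
    padded[:, :n_samp] = data
    digital = np.clip(
        np.round(padded / gain[:, None]), -_DIG_MAX, _DIG_MAX
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for rec in range(n_records):
            chunk = digital[:, rec * spr:(rec + 1) * spr]
            fh.write(chunk.tobytes())
    logger.info("wrote EDF %s (%d ch, %d records)", path, n_ch, n_records)


def read_edf(path, events: pd.DataFrame | None = None) -> ContinuousRecording:
    """Read an EDF file into a :class:`ContinuousRecording` (µV).

    ``events`` may be supplied directly or is looked for next to the file as
    ``<stem>_events.tsv``.
    """
    import mne  # deferred: mne import is slow

    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
    except Exception as err:  # pragma: no cover - mne error text varies
        raise ValueError(f"could not read EDF file {path}: {err}") from err
    data = raw.get_data() * 1e6  # volts -> µV
    if events is None:
        sidecar = path.with_name(path.stem + "_events.tsv")
        if not sidecar.exists():
            raise FileNotFoundError(
                f"events file {sidecar} not found; pass events= explicitly"
            )
        events = read_events_tsv(sidecar)
    return ContinuousRecording(data, raw.info["sfreq"], tuple(raw.ch_names), events)


def write_events_tsv(events: pd.DataFrame, path) -> None:
    """Write the event table as TSV (onset_s, duration_s, label + structure)."""
    df = events.copy()
    df["label"] = (
        df["kind"].astype(str) + "/" + df["condition"].astype(str)
    )
    cols = ["onset_s", "duration_s", "label", "kind", "condition", "block", "sequence", "trial"]
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"events file {path} missing columns {sorted(missing)}")
    return df[list(EVENT_COLUMNS)]
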