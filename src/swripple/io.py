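"""File interfaces: EDF, stage/artifact annotations, configs, tables.

Signals travel as EDF (16-bit, physical unit uV) or plain delimited
text; sleep stages as two-column text (epoch_index, stage); artifact
intervals as three-column text (channel, start_s, end_s); generator
configs as flat YAML mirroring the ``SynthConfig`` field names; ground
truth as JSON.  EDF reading goes through :mod:`mne`; writing uses a
small EDF encoder sufficient for continuous multichannel recordings.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .synth import GroundTruth, SynthConfig

__all__ = [
    "write_edf",
    "read_edf",
    "write_signals_text",
    "read_signals_text",
    "write_stages",
    "read_stages",
    "write_artifact_intervals",
    "write_synth_config",
    "read_synth_config",
    "write_ground_truth",
]


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(path: str | Path, channels: dict[str, np.ndarray],
              fs: float) -> None:
    """Write channels to an EDF file (1-s records, 16-bit, unit uV).

    The final partial second, if any, is zero-padded to a whole record.
    """
    path = Path(path)
    labels = list(channels)
    ns = len(labels)
    spr = int(round(fs))  # samples per record (1-s records)
    n = max(len(v) for v in channels.values())
    n_rec = int(np.ceil(n / spr))
    data = np.zeros((ns, n_rec * spr))
    for i, lab in enumerate(labels):
        x = np.asarray(channels[lab], dtype=float)
        data[i, :len(x)] = x
    pmin = np.floor(data.min(axis=1))
    pmax = np.ceil(data.max(axis=1))
    pmax = np.where(pmax <= pmin, pmin + 1, pmax)
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(np.round((data - pmin[:, None]) * scale[:, None])
                      + dmin, dmin, dmax).astype("<i2")

    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate X X X X", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (1 + ns)), 8),
        _pad("", 44),
        _pad(str(n_rec), 8),
        _pad("1", 8),
        _pad(str(ns), 4),
    ])
    fields = [
        [_pad(lab, 16) for lab in labels],
        [_pad("", 80)] * ns,
        [_pad("uV", 8)] * ns,
        [_pad(f"{v:g}"[:8], 8) for v in pmin],
        [_pad(f"{v:g}"[:8], 8) for v in pmax],
        [_pad(str(dmin), 8)] * ns,
        [_pad(str(dmax), 8)] * ns,
        [_pad("", 80)] * ns,
        [_pad(str(spr), 8)] * ns,
        [_pad("", 32)] * ns,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for field in fields:
            fh.write(b"".join(field))
        # interleave: per record, all samples of signal 1, then signal 2, ...
        records = digital.reshape(ns, n_rec, spr).transpose(1, 0, 2)
        fh.write(records.tobytes())


def read_edf(path: str | Path) -> tuple[dict[str, np.ndarray], float]:
    """Read an EDF file into (channel dict in uV, sampling rate)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data(units="uV")
    channels = {ch: data[i] for i, ch in enumerate(raw.ch_names)}
    return channels, float(raw.info["sfreq"])


def write_signals_text(path: str | Path, channels: dict[str, np.ndarray],
                       fs: float) -> None:
    """Plain delimited text: time_s, then one column per channel."""
    labels = list(channels)
    n = len(next(iter(channels.values())))
    t = np.arange(n) / fs
    arr = np.column_stack([t] + [channels[c] for c in labels])
    np.savetxt(path, arr, fmt="%.6f", delimiter="\t",
               header="time_s\t" + "\t".join(labels), comments="")


def read_signals_text(path: str | Path) -> tuple[dict[str, np.ndarray],
                                                 float]:
    with open(path) as fh:
        labels = fh.readline().split()[1:]
    arr = np.loadtxt(path, skiprows=1)
    fs = 1.0 / np.median(np.diff(arr[:, 0]))
    return {lab: arr[:, i + 1] for i, lab in enumerate(labels)}, float(fs)


def write_stages(path: str | Path, stages: list[str]) -> None:
    """Two-column text: 20-s epoch index and stage label."""
    with open(path, "w") as fh:
        fh.write("epoch_index\tstage\n")
        for i, s in enumerate(stages):
            fh.write(f"{i}\t{s}\n")


def read_stages(path: str | Path) -> list[str]:
    stages = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            if line.strip():
                stages.append(line.split()[1])
    return stages


def write_artifact_intervals(path: str | Path,
                             intervals: dict[str, list[tuple[float, float]]]
                             ) -> None:
    """Three-column text: channel, start_s, end_s."""
    with open(path, "w") as fh:
        fh.write("channel\tstart_s\tend_s\n")
        for ch, spans in intervals.items():
            for a, b in spans:
                fh.write(f"{ch}\t{a:.4f}\t{b:.4f}\n")


def write_synth_config(path: str | Path, config: SynthConfig) -> None:
    """Flat YAML key-value file mirroring SynthConfig field names."""
    d = {}
    for k, v in vars(config).items():
        d[k] = list(v) if isinstance(v, tuple) else v
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def read_synth_config(path: str | Path) -> SynthConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    tuple_fields = {"ripple_rate_per_min", "ripple_amp_uv", "spw_freq_hz"}
    for k in tuple_fields & set(d):
        d[k] = tuple(d[k])
    return SynthConfig(**d)


def write_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)
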