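"""Reading and writing of recordings and analysis artifacts.

EEG trials are written as EDF (16-bit) or BDF (24-bit) with a delimited
events sidecar; EMG and all derived matrices are delimited text with a
header row.  EDF/BDF reading goes through MNE.  A JSON manifest records
every generated path together with the seed and configuration hash.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EEG, EMG, Recording

_EDF_HEADER = 256


def _ascii(value: str, width: int) -> bytes:
    s = value[:width].ljust(width)
    return s.encode("ascii")


def _num(value: float, width: int) -> bytes:
    s = f"{value:.10g}"[:width].ljust(width)
    return s.encode("ascii")


def _write_edf_like(rec: Recording, path: Path, bdf: bool) -> None:
    """Minimal single-record EDF/BDF writer (events go to a sidecar)."""
    n_sig = rec.n_channels
    n_samples = rec.n_samples
    data = rec.data
    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6) * 1.000001
    dig_max = 8388607 if bdf else 32767
    dig_min = -8388608 if bdf else -32768

    with open(path, "wb") as fh:
        if bdf:
            fh.write(b"\xffBIOSEMI")
        else:
            fh.write(_ascii("0", 8))
        fh.write(_ascii("X X X X", 80))                 # patient id
        fh.write(_ascii("Startdate X X X X", 80))       # recording id
        fh.write(_ascii("01.01.00", 8))
        fh.write(_ascii("00.00.00", 8))
        fh.write(_num(_EDF_HEADER * (1 + n_sig), 8))
        fh.write(_ascii("24BIT" if bdf else "", 44))
        fh.write(_num(1, 8))                            # one data record
        fh.write(_num(n_samples / rec.rate, 8))         # record duration (s)
        fh.write(_num(n_sig, 4))
        for lab in rec.labels:
            fh.write(_ascii(lab, 16))
        fh.write(_ascii("", 80) * n_sig)                # transducer
        fh.write(_ascii("uV", 8) * n_sig)
        for a in phys_max:
            fh.write(_num(-a, 8))
        for a in phys_max:
            fh.write(_num(a, 8))
        fh.write(_num(dig_min, 8) * n_sig)
        fh.write(_num(dig_max, 8) * n_sig)
        fh.write(_ascii("", 80) * n_sig)                # prefiltering
        fh.write(_num(n_samples, 8) * n_sig)
        fh.write(_ascii("", 32) * n_sig)
        for ch in range(n_sig):
            scaled = np.round(data[ch] / phys_max[ch] * dig_max)
            scaled = np.clip(scaled, dig_min, dig_max).astype(np.int32)
            if bdf:
                as32 = scaled.astype("<i4").tobytes()
                fh.write(np.frombuffer(as32, dtype=np.uint8)
                         .reshape(-1, 4)[:, :3].tobytes())
            else:
                fh.write(scaled.astype("<i2").tobytes())


def write_edf(rec: Recording, path: str | Path) -> Path:
    path = Path(path)
    _write_edf_like(rec, path, bdf=False)
    _write_events_sidecar(rec, path)
    return path


def write_bdf(rec: Recording, path: str | Path) -> Path:
    path = Path(path)
    _write_edf_like(rec, path, bdf=True)
    _write_events_sidecar(rec, path)
    return path


def _events_sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + "_events.csv")


def _write_events_sidecar(rec: Recording, path: Path) -> None:
    if rec.events:
        write_events(rec.events, _events_sidecar_path(path))


def write_events(events: list[tuple[int, str]], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(events, columns=["sample", "label"]).to_csv(path, index=False)
    return path


def read_events(path: str | Path) -> list[tuple[int, str]]:
    df = pd.read_csv(path)
    return [(int(r.sample), str(r.label)) for r in df.itertuples()]


def write_delimited(rec: Recording, path: str | Path) -> Path:
    """Samples x channels TSV with a channel-label header row."""
    path = Path(path)
    pd.DataFrame(rec.data.T, columns=rec.labels).to_csv(path, sep="\t",
                                                        index=False)
    _write_events_sidecar(rec, path)
    return path


def write_matrix(values: np.ndarray, path: str | Path,
                 header: list[str] | None = None) -> Path:
    path = Path(path)
    arr = np.atleast_2d(np.asarray(values))
    cols = header if header is not None else [f"c{i}" for i in range(arr.shape[1])]
    pd.DataFrame(arr, columns=cols).to_csv(path, sep="\t", index=False)
    return path


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def _read_delimited_recording(path: Path, rate: float,
                              modality: str) -> Recording:
    with open(path) as fh:
        first = fh.readline().strip()
    tokens = first.replace(",", "\t").split("\t")
    numeric = True
    for tok in tokens:
        try:
            float(tok)
        except ValueError:
            numeric = False
            break
    if numeric:
        raise ValueError(f"{path}: delimited matrix must start with a "
                         "channel-label header row")
    sep = "\t" if "\t" in first else ","
    df = pd.read_csv(path, sep=sep)
    events_path = _events_sidecar_path(path)
    events = read_events(events_path) if events_path.exists() else []
    return Recording(data=df.to_numpy(dtype=float).T, rate=rate,
                     labels=[str(c) for c in df.columns], modality=modality,
                     events=events)


def read_recording(path: str | Path, fmt: str | None = None,
                   rate: float | None = None, modality: str = EEG) -> Recording:
    """Read an EDF/BDF/delimited recording (events from a sidecar table).

    ``rate`` is required for delimited matrices (they carry no rate).
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt in ("edf", "bdf"):
        import mne
        reader = mne.io.read_raw_edf if fmt == "edf" else mne.io.read_raw_bdf
        raw = reader(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6              # MNE returns volts; stored uV
        events_path = _events_sidecar_path(path)
        events = read_events(events_path) if events_path.exists() else []
        return Recording(data=data, rate=float(raw.info["sfreq"]),
                         labels=list(raw.ch_names), modality=modality,
                         events=events)
    if fmt in ("csv", "tsv", "txt"):
        if rate is None:
            raise ValueError("rate is required for delimited matrices")
        return _read_delimited_recording(path, rate, modality)
    raise ValueError(f"unknown recording format: {fmt!r}")


def write_manifest(entries: dict[str, object], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True, default=str)
    return path
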