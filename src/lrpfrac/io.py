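"""Continuous-EEG container and BrainVision triplet I/O.

The recording container deliberately stays minimal: a channels x samples
float array in microvolts, a sampling rate, and a flat list of event
markers (stimulus / left response / right response, each tagged with the
trial it belongs to).  The BrainVision format (.vhdr/.vmrk/.eeg) is the
native format of the acquisition system this pipeline targets; data are
written as IEEE float32, multiplexed, one value per channel per sample.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

MARKER_KINDS = ("stimulus", "response_left", "response_right")


@dataclass
class Marker:
    """One event on the recording timeline (sample index, 0-based)."""

    sample: int
    kind: str  # stimulus | response_left | response_right
    trial_index: int

    def __post_init__(self) -> None:
        if self.kind not in MARKER_KINDS:
            raise ValueError(f"unknown marker kind {self.kind!r}")


@dataclass
class EEGRecording:
    """Continuous multichannel EEG in microvolts with event markers."""

    channel_labels: list[str]
    sampling_rate: float
    data: np.ndarray  # (n_channels, n_samples), microvolts
    markers: list[Marker] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.channel_labels)} channel labels"
            )
        samples = [m.sample for m in self.markers]
        if any(b <= a for a, b in zip(samples, samples[1:])):
            raise ValueError("marker sample indices must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not present; have {self.channel_labels}"
            ) from None

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def copy(self) -> "EEGRecording":
        return replace(
            self,
            data=self.data.copy(),
            channel_labels=list(self.channel_labels),
            markers=list(self.markers),
        )


# ---------------------------------------------------------------------------
# BrainVision writing

_VHDR_TEMPLATE = """\
BrainVision Data Exchange Header File Version 1.0
; Written by lrpfrac

[Common Infos]
Codepage=UTF-8
DataFile={datafile}
MarkerFile={markerfile}
DataFormat=BINARY
; Data orientation: MULTIPLEXED=ch1,pt1, ch2,pt1 ...
DataOrientation=MULTIPLEXED
NumberOfChannels={nchan}
; Sampling interval in microseconds
SamplingInterval={sampint}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
; Each entry: Ch<Channel number>=<Name>,<Reference channel name>,
; <Resolution in "Unit">,<Unit>
{channels}
"""

_VMRK_TEMPLATE = """\
BrainVision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={datafile}

[Marker Infos]
; Each entry: Mk<Marker number>=<Type>,<Description>,<Position in data points>,
; <Size in data points>, <Channel number (0 = marker is related to all channels)>
{markers}
"""

# marker descriptions: stimulus -> "S<trial>", responses -> "R1"/"R2" with the
# trial recovered from the preceding stimulus on read
_RESPONSE_CODE = {"response_left": "R  1", "response_right": "R  2"}
_RESPONSE_KIND = {v: k for k, v in _RESPONSE_CODE.items()}


def write_brainvision(recording: EEGRecording, basename: str | Path) -> Path:
    """Write a .vhdr/.vmrk/.eeg triplet; returns the header path.

    ``basename`` may carry any of the three extensions or none.
    """
    base = Path(basename)
    if base.suffix in {".vhdr", ".vmrk", ".eeg"}:
        base = base.with_suffix("")
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))

    chan_lines = "\n".join(
        f"Ch{i + 1}={label},,1,µV" for i, label in enumerate(recording.channel_labels)
    )
    samp_int_us = 1e6 / recording.sampling_rate
    samp_repr = f"{samp_int_us:.6f}".rstrip("0").rstrip(".")
    vhdr.write_text(
        _VHDR_TEMPLATE.format(
            datafile=eeg.name,
            markerfile=vmrk.name,
            nchan=len(recording.channel_labels),
            sampint=samp_repr,
            channels=chan_lines,
        ),
        encoding="utf-8",
    )

    stamp = datetime.datetime(2000, 1, 1).strftime("%Y%m%d%H%M%S%f")
    mk_lines = [f"Mk1=New Segment,,1,1,0,{stamp}"]
    for i, m in enumerate(recording.markers, start=2):
        if m.kind == "stimulus":
            mtype, desc = "Stimulus", f"S{m.trial_index + 1}"
        else:
            mtype, desc = "Response", _RESPONSE_CODE[m.kind]
        # BrainVision positions are 1-based
        mk_lines.append(f"Mk{i}={mtype},{desc},{m.sample + 1},1,0")
    vmrk.write_text(
        _VMRK_TEMPLATE.format(datafile=eeg.name, markers="\n".join(mk_lines)),
        encoding="utf-8",
    )

    recording.data.T.astype("<f4").tofile(eeg)
    return vhdr


# ---------------------------------------------------------------------------
# BrainVision reading


def _parse_ini(text: str) -> dict[str, dict[str, str]]:
    sections: dict[str, dict[str, str]] = {}
    current: dict[str, str] | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(";"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = sections.setdefault(line[1:-1], {})
        elif "=" in line:
            if current is None:
                continue  # preamble line such as the version banner
            key, _, value = line.partition("=")
            current[key.strip()] = value.strip()
        elif current is not None:
            raise ValueError(f"malformed header line {lineno}: {raw!r}")
    return sections


def read_brainvision(header_path: str | Path) -> EEGRecording:
    """Read a BrainVision triplet written by :func:`write_brainvision`.

    Supports the subset of the format this package writes: binary
    IEEE_FLOAT_32 or INT_16, multiplexed orientation.
    """
    vhdr = Path(header_path)
    if not vhdr.exists():
        raise FileNotFoundError(f"missing header file: {vhdr}")
    sections = _parse_ini(vhdr.read_text(encoding="utf-8"))
    try:
        common = sections["Common Infos"]
        nchan = int(common["NumberOfChannels"])
        samp_int_us = float(common["SamplingInterval"])
        datafile = vhdr.with_name(common["DataFile"])
        markerfile = vhdr.with_name(common["MarkerFile"])
    except KeyError as exc:
        raise ValueError(f"header {vhdr} missing required field: {exc}") from exc
    if common.get("DataFormat", "BINARY") != "BINARY":
        raise ValueError("only BINARY DataFormat is supported")
    if common.get("DataOrientation", "MULTIPLEXED") != "MULTIPLEXED":
        raise ValueError("only MULTIPLEXED orientation is supported")
    fmt = sections.get("Binary Infos", {}).get("BinaryFormat", "IEEE_FLOAT_32")
    dtype = {"IEEE_FLOAT_32": "<f4", "INT_16": "<i2"}.get(fmt)
    if dtype is None:
        raise ValueError(f"unsupported BinaryFormat {fmt!r}")

    labels, resolutions = [], []
    chinfo = sections.get("Channel Infos", {})
    for i in range(1, nchan + 1):
        try:
            entry = chinfo[f"Ch{i}"]
        except KeyError:
            raise ValueError(f"header {vhdr} missing Channel Infos entry Ch{i}")
        parts = entry.split(",")
        labels.append(parts[0])
        resolutions.append(float(parts[2]) if len(parts) > 2 and parts[2] else 1.0)

    if not datafile.exists():
        raise FileNotFoundError(f"missing data file: {datafile}")
    raw = np.fromfile(datafile, dtype=dtype)
    if raw.size % nchan:
        raise ValueError(
            f"data file {datafile} holds {raw.size} values, not divisible by "
            f"{nchan} channels declared in the header"
        )
    data = raw.reshape(-1, nchan).T.astype(float) * np.asarray(resolutions)[:, None]

    if not markerfile.exists():
        raise FileNotFoundError(f"missing marker file: {markerfile}")
    msect = _parse_ini(markerfile.read_text(encoding="utf-8")).get("Marker Infos", {})
    markers: list[Marker] = []
    last_trial = -1
    for key in sorted(msect, key=lambda k: int(k[2:])):
        parts = msect[key].split(",")
        mtype, desc, pos = parts[0], parts[1], int(parts[2]) - 1
        if mtype == "Stimulus" and desc.startswith("S"):
            last_trial = int(desc[1:].strip()) - 1
            markers.append(Marker(pos, "stimulus", last_trial))
        elif mtype == "Response":
            kind = _RESPONSE_KIND.get(desc)
            if kind is not None:
                markers.append(Marker(pos, kind, last_trial))
        # "New Segment" and foreign marker types are ignored

    return EEGRecording(
        channel_labels=labels,
        sampling_rate=1e6 / samp_int_us,
        data=data,
        markers=markers,
    )


# ---------------------------------------------------------------------------
# epochs container (HDF5)


def write_epochs_h5(epochs, path) -> None:
    """Persist an EpochSet as an HDF5 container (data + metadata table)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
        f.attrs["lock"] = epochs.lock
        f.attrs["window_ms"] = epochs.window_ms
        f.attrs["baseline_ms"] = epochs.baseline_ms
        f.attrs["sampling_rate"] = epochs.sampling_rate
        f.attrs["channel_labels"] = [str(c) for c in epochs.channel_labels]
        meta = epochs.trial_meta
        g = f.create_group("trial_meta")
        for col in meta.columns:
            values = meta[col].to_numpy()
            if values.dtype == object or str(values.dtype).startswith("str"):
                values = np.asarray([str(v) for v in values], dtype="S")
            g.create_dataset(col, data=values)


def read_epochs_h5(path):
    """Read an EpochSet written by :func:`write_epochs_h5`."""
    import h5py
    import pandas as pd

    from .preprocess import EpochSet

    with h5py.File(path, "r") as f:
        data = f["data"][...]
        meta = {}
        for col, ds in f["trial_meta"].items():
            values = ds[...]
            if values.dtype.kind == "S":
                values = values.astype(str)
            meta[col] = values
        return EpochSet(
            lock=str(f.attrs["lock"]),
            window_ms=tuple(float(v) for v in f.attrs["window_ms"]),
            baseline_ms=tuple(float(v) for v in f.attrs["baseline_ms"]),
            data=data,
            channel_labels=[str(c) for c in f.attrs["channel_labels"]],
            sampling_rate=float(f.attrs["sampling_rate"]),
            trial_meta=pd.DataFrame(meta),
        )
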