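"""Readers and writers for the package's on-disk formats.

Everything is plain text: delimited tables with small JSON/YAML sidecars.
An HDF5 exporter/reader with an SNIRF-style layout is provided for
interoperability with optical-imaging tools.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .datatypes import ChannelInfo, RawRecording, ROITimeSeries

__all__ = [
    "write_roi_series",
    "read_roi_series",
    "write_raw_recording",
    "read_raw_recording",
    "write_snirf",
    "read_snirf",
    "write_design_yaml",
]

PathLike = Union[str, Path]


def write_roi_series(series: ROITimeSeries, path: PathLike) -> None:
    """ROI oxyhemoglobin series as a tab-separated table; the header comment
    carries the sampling rate and units."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={series.sampling_rate_hz} units=uM\n")
        pd.DataFrame(series.values, columns=list(series.roi_labels)).to_csv(
            fh, sep="\t", index=False
        )


def read_roi_series(path: PathLike) -> ROITimeSeries:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing metadata header line")
        meta = dict(item.split("=") for item in header[1:].split())
        df = pd.read_csv(fh, sep="\t")
    return ROITimeSeries(float(meta["sampling_rate_hz"]), df.to_numpy(), tuple(df.columns))


def _channel_sidecar(raw: RawRecording) -> dict:
    return {
        "sampling_rate_hz": raw.sampling_rate_hz,
        "wavelengths_nm": list(raw.wavelengths_nm),
        "baseline_s": list(raw.baseline_s),
        "channels": [
            {
                "channel_id": c.channel_id,
                "source_detector_distance_mm": c.source_detector_distance_mm,
                "roi_label": c.roi_label,
            }
            for c in raw.channels
        ],
    }


def write_raw_recording(raw: RawRecording, path: PathLike) -> None:
    """Raw intensities as a tab-separated table (columns ``channel@wl``),
    with channel metadata in a ``.json`` sidecar next to the table."""
    path = Path(path)
    cols = {}
    for i, ch in enumerate(raw.channels):
        for w, wl in enumerate(raw.wavelengths_nm):
            cols[f"{ch.channel_id}@{wl:.0f}"] = raw.intensity[:, i, w]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(_channel_sidecar(raw), fh, indent=1)


def read_raw_recording(path: PathLike) -> RawRecording:
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        meta = json.load(fh)
    df = pd.read_csv(path, sep="\t")
    channels = [
        ChannelInfo(c["channel_id"], c["source_detector_distance_mm"], c["roi_label"])
        for c in meta["channels"]
    ]
    wls = tuple(meta["wavelengths_nm"])
    T = len(df)
    intensity = np.empty((T, len(channels), 2))
    for i, ch in enumerate(channels):
        for w, wl in enumerate(wls):
            intensity[:, i, w] = df[f"{ch.channel_id}@{wl:.0f}"].to_numpy()
    return RawRecording(
        sampling_rate_hz=meta["sampling_rate_hz"],
        channels=channels,
        intensity=intensity,
        wavelengths_nm=wls,
        baseline_s=tuple(meta.get("baseline_s", (0.0, 60.0))),
    )


def write_snirf(raw: RawRecording, path: PathLike) -> None:
    """HDF5 export with an SNIRF-style layout (``/nirs/data1`` time series
    plus measurement-list entries); continuous-wave amplitude only."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        T, nch, _ = raw.intensity.shape
        flat = raw.intensity.reshape(T, nch * 2)
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset("time", data=np.arange(T) / raw.sampling_rate_hz)
        for i, ch in enumerate(raw.channels):
            for w, wl in enumerate(raw.wavelengths_nm):
                ml = data.create_group(f"measurementList{i * 2 + w + 1}")
                ml.create_dataset("wavelengthActual", data=float(wl))
                ml.create_dataset("sourceIndex", data=i + 1)
                ml.create_dataset("detectorIndex", data=i + 1)
                ml.create_dataset("dataType", data=1)  # CW amplitude
                ml.attrs["channel_id"] = ch.channel_id
                ml.attrs["distance_mm"] = ch.source_detector_distance_mm
                ml.attrs["roi_label"] = ch.roi_label or ""


def read_snirf(path: PathLike) -> RawRecording:
    import h5py

    with h5py.File(path, "r") as f:
        data = f["nirs/data1"]
        t = np.asarray(data["time"])
        fs = float(np.round(1.0 / np.median(np.diff(t)), 9))
        flat = np.asarray(data["dataTimeSeries"])
        nch = flat.shape[1] // 2
        channels = []
        wls = []
        for i in range(nch):
            ml = data[f"measurementList{i * 2 + 1}"]
            channels.append(
                ChannelInfo(
                    ml.attrs["channel_id"],
                    float(ml.attrs["distance_mm"]),
                    (ml.attrs["roi_label"] or None) if ml.attrs["roi_label"] else None,
                )
            )
        for w in range(2):
            wls.append(float(np.asarray(data[f"measurementList{w + 1}"]["wavelengthActual"])))
    intensity = flat.reshape(len(t), nch, 2)
    return RawRecording(float(fs), channels, intensity, tuple(wls))


def write_design_yaml(design, path: PathLike) -> None:
    """Study-design parameters as a YAML document (scalars and mappings
    only; the base network is recorded by its coupling matrix)."""
    import dataclasses

    import yaml

    d = dataclasses.asdict(design)
    net = d.pop("base_network", None)
    if net is not None:
        d["base_network"] = {
            "rois": list(net["rois"]),
            "coupling": np.asarray(net["coupling"]).tolist(),
            "noise_cov": np.asarray(net["noise_cov"]).tolist(),
            "slow_rate_hz": net["slow_rate_hz"],
        }
    if d.get("artifacts") is not None:
        d["artifacts"] = dict(d["artifacts"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
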