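"""Readers and writers for the formats the package touches.

The canonical container is an HDF5 file with datasets ``/data``
(channels × samples, float64), ``/fs`` (scalar Hz), ``/labels`` (channel
names) and optional ``/events/<kind>`` (sorted sample indices). Small
fixtures use delimited text (one row per channel, optional ``#``-prefixed
header of labels); event series are plain text, one sample index per line.
GroundTruth objects are written as JSON (parameters) plus HDF5 (source
signals and mixing).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .containers import EventSeries, GroundTruth, Recording

__all__ = [
    "write_recording", "read_recording",
    "write_events", "read_events",
    "write_ground_truth", "read_ground_truth",
    "write_ged_result",
]


def write_recording(
    path: str | Path,
    rec: Recording,
    events: dict[str, EventSeries] | None = None,
) -> None:
    """Write a Recording (and optional event series) to HDF5 or text.

    Format is chosen by extension: ``.h5``/``.hdf5`` → HDF5 container,
    anything else → tab-delimited text (events not supported there).
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=rec.data)
            f.create_dataset("fs", data=float(rec.fs))
            f.create_dataset(
                "labels", data=np.array(rec.labels, dtype=h5py.string_dtype()))
            if events:
                g = f.create_group("events")
                for kind, ev in events.items():
                    g.create_dataset(kind, data=ev.samples)
    else:
        if events:
            raise ValueError("events are only supported in the HDF5 container")
        header = "# " + "\t".join(rec.labels) + f"\n# fs={rec.fs}\n"
        with open(path, "w") as f:
            f.write(header)
            np.savetxt(f, rec.data, delimiter="\t")


def read_recording(
    path: str | Path, fs: float | None = None
) -> tuple[Recording, dict[str, EventSeries]]:
    """Read a Recording (HDF5 or delimited text).

    Returns ``(recording, events)``; ``events`` is empty for text files.
    Text files may carry labels and fs in ``#``-prefixed header lines; an
    explicit ``fs`` argument overrides. Channels × samples orientation is
    enforced: if the parsed matrix has fewer columns than rows it is
    transposed with a warning (recordings are long in time).
    """
    import warnings

    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            fs_read = float(f["fs"][()])
            labels = [s.decode() if isinstance(s, bytes) else str(s)
                      for s in f["labels"][()]]
            events = {}
            if "events" in f:
                for kind in f["events"]:
                    events[kind] = EventSeries(f["events"][kind][()], kind=kind)
        return Recording(data, fs if fs is not None else fs_read, labels), events

    labels: list[str] = []
    fs_header: float | None = None
    with open(path) as f:
        head = []
        for line in f:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if stripped.startswith("fs="):
                    fs_header = float(stripped[3:])
                elif stripped:
                    labels = stripped.split("\t")
            else:
                head.append(line)
                break
        body = head + f.readlines()
    try:
        data = np.loadtxt(body, delimiter="\t", ndmin=2)
    except ValueError as err:
        raise ValueError(f"non-numeric cell in {path}: {err}") from err
    if data.shape[0] > data.shape[1]:
        warnings.warn("more rows than columns: transposing to "
                      "channels x samples", stacklevel=2)
        data = data.T
        if labels and len(labels) != data.shape[0]:
            labels = []
    fs_eff = fs if fs is not None else fs_header
    if fs_eff is None:
        raise ValueError("sampling rate not found in file; pass fs=")
    return Recording(data, fs_eff, labels), {}


def write_events(path: str | Path, events: EventSeries) -> None:
    """One sample index per line."""
    np.savetxt(path, events.samples, fmt="%d")


def read_events(path: str | Path, kind: str = "custom") -> EventSeries:
    samples = np.atleast_1d(np.loadtxt(path, dtype=np.int64))
    return EventSeries(np.sort(samples), kind=kind)


def write_ground_truth(prefix: str | Path, gt: GroundTruth) -> None:
    """JSON parameter file ``<prefix>.json`` + HDF5 arrays ``<prefix>.h5``."""
    prefix = Path(prefix)
    meta = {
        "driver_freq": gt.driver_freq,
        "modulated_freqs": gt.modulated_freqs,
        "distractor_freqs": gt.distractor_freqs,
        "event_times": gt.event_times.tolist(),
        "seed": gt.seed,
        "fs": gt.fs,
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    with h5py.File(prefix.with_suffix(".h5"), "w") as f:
        f.create_dataset("source_signals", data=gt.source_signals)
        f.create_dataset("mixing", data=gt.mixing)
        for key, val in gt.extras.items():
            arr = np.asarray(val)
            if arr.dtype.kind in "fiub":
                f.create_dataset(f"extras/{key}", data=arr)


def read_ground_truth(prefix: str | Path) -> GroundTruth:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    with h5py.File(prefix.with_suffix(".h5"), "r") as f:
        sources = f["source_signals"][()]
        mixing = f["mixing"][()]
        extras = {}
        if "extras" in f:
            for key in f["extras"]:
                extras[key] = f["extras"][key][()]
    return GroundTruth(
        source_signals=sources, mixing=mixing,
        driver_freq=meta["driver_freq"],
        modulated_freqs=meta["modulated_freqs"],
        distractor_freqs=meta["distractor_freqs"],
        event_times=np.array(meta["event_times"], dtype=np.int64),
        seed=meta["seed"], fs=meta["fs"], extras=extras,
    )


def write_ged_result(path: str | Path, result, provenance: dict | None = None) -> None:
    """Serialize a GEDResult (+ provenance: event kind, window, γ, seed)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("eigenvalues", data=result.eigenvalues)
        f.create_dataset("eigenvectors", data=result.eigenvectors)
        f.create_dataset("forward_models", data=result.forward_models)
        for key, val in (provenance or {}).items():
            f.attrs[key] = val
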