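"""Movie and recording containers on disk.

Two formats are supported:

* multi-page TIFF (one page per frame) with a JSON sidecar
  (``<stem>.json``) carrying the mandatory metadata;
* an HDF5 container with datasets ``/vm``, ``/cai``, ``/pseudo_ecg``,
  ``/stimulus_log`` and root attributes ``frame_interval_ms`` and
  ``pixel_pitch_mm`` (per-dataset attributes carry channel/polarity).

Both round-trip losslessly.  Metadata is never defaulted on read: a file
missing ``frame_interval`` is an error naming the field.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .movie import MetadataError, MovieError, OpticalMovie

_REQUIRED_META = ("frame_interval", "pixel_pitch", "channel", "polarity")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_movie(movie: OpticalMovie, path: str | Path, format: str | None = None) -> Path:
    """Write a movie; format inferred from suffix unless given.

    ``tiff_stack`` writes ``path`` plus a ``path.json`` sidecar;
    ``hdf5_container`` writes a single HDF5 file.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "tiff_stack":
        # float64 pages: lossless round-trip matters more than file size here
        tifffile.imwrite(path, movie.data, photometric="minisblack")
        meta = {
            "frame_interval": movie.frame_interval,
            "pixel_pitch": movie.pixel_pitch,
            "channel": movie.channel,
            "polarity": movie.polarity,
            "metadata": _jsonable(movie.metadata),
        }
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    elif fmt == "hdf5_container":
        with h5py.File(path, "w") as f:
            f.attrs["frame_interval_ms"] = movie.frame_interval
            f.attrs["pixel_pitch_mm"] = movie.pixel_pitch
            d = f.create_dataset(movie.channel, data=movie.data, track_times=False)
            d.attrs["channel"] = movie.channel
            d.attrs["polarity"] = movie.polarity
            d.attrs["metadata_json"] = json.dumps(_jsonable(movie.metadata))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_movie(path: str | Path, format: str | None = None, channel: str | None = None) -> OpticalMovie:
    """Read a movie written by :func:`write_movie`.

    Raises :class:`MetadataError` naming the first missing metadata
    field; raises :class:`MovieError` on shape problems.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "tiff_stack":
        data = np.asarray(tifffile.imread(path))
        if data.ndim == 2:
            data = data[None]
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise MetadataError(f"missing metadata sidecar {sidecar.name}")
        meta = json.loads(sidecar.read_text())
        for fieldname in _REQUIRED_META:
            if fieldname not in meta or meta[fieldname] is None:
                raise MetadataError(f"metadata field {fieldname!r} absent in {sidecar.name}")
        return OpticalMovie(
            data=data.astype(np.float64),
            frame_interval=float(meta["frame_interval"]),
            pixel_pitch=float(meta["pixel_pitch"]),
            channel=meta["channel"],
            polarity=meta["polarity"],
            metadata=meta.get("metadata", {}),
        )
    if fmt == "hdf5_container":
        with h5py.File(path, "r") as f:
            for attr in ("frame_interval_ms", "pixel_pitch_mm"):
                if attr not in f.attrs:
                    raise MetadataError(f"metadata field {attr!r} absent in {path.name}")
            if channel is None:
                channels = [k for k in ("vm", "cai") if k in f]
                if len(channels) != 1:
                    raise MovieError(
                        f"container holds channels {channels}; pass channel= to choose"
                    )
                channel = channels[0]
            if channel not in f:
                raise MovieError(f"channel {channel!r} not in {path.name}")
            d = f[channel]
            if "polarity" not in d.attrs:
                raise MetadataError(f"metadata field 'polarity' absent for /{channel}")
            return OpticalMovie(
                data=np.asarray(d, dtype=np.float64),
                frame_interval=float(f.attrs["frame_interval_ms"]),
                pixel_pitch=float(f.attrs["pixel_pitch_mm"]),
                channel=channel,
                polarity=str(d.attrs["polarity"]),
                metadata=json.loads(d.attrs.get("metadata_json", "{}")),
            )
    raise ValueError(f"unknown format {fmt!r}")


def write_recording(path: str | Path, vm: OpticalMovie | None = None,
                    cai: OpticalMovie | None = None,
                    pseudo_ecg: np.ndarray | None = None,
                    stimulus_log: list | None = None) -> Path:
    """Write a full dual-channel recording to one HDF5 container."""
    path = Path(path)
    ref = vm or cai
    if ref is None:
        raise ValueError("at least one channel required")
    with h5py.File(path, "w") as f:
        f.attrs["frame_interval_ms"] = ref.frame_interval
        f.attrs["pixel_pitch_mm"] = ref.pixel_pitch
        for mov in (vm, cai):
            if mov is None:
                continue
            d = f.create_dataset(mov.channel, data=mov.data, track_times=False)
            d.attrs["channel"] = mov.channel
            d.attrs["polarity"] = mov.polarity
            d.attrs["metadata_json"] = json.dumps(_jsonable(mov.metadata))
        if pseudo_ecg is not None:
            f.create_dataset("pseudo_ecg", data=np.asarray(pseudo_ecg, dtype=np.float64),
                             track_times=False)
        if stimulus_log is not None:
            arr = np.array(
                [(t, r, c, bool(cap)) for (t, (r, c), cap) in stimulus_log],
                dtype=[("time_ms", "f8"), ("row", "i4"), ("col", "i4"), ("captured", "?")],
            )
            f.create_dataset("stimulus_log", data=arr, track_times=False)
    return path


def read_recording(path: str | Path) -> dict:
    """Read a container written by :func:`write_recording`."""
    path = Path(path)
    out: dict = {"vm": None, "cai": None, "pseudo_ecg": None, "stimulus_log": None}
    with h5py.File(path, "r") as f:
        for ch in ("vm", "cai"):
            if ch in f:
                out[ch] = read_movie(path, format="hdf5_container", channel=ch)
        if "pseudo_ecg" in f:
            out["pseudo_ecg"] = np.asarray(f["pseudo_ecg"])
        if "stimulus_log" in f:
            arr = np.asarray(f["stimulus_log"])
            out["stimulus_log"] = [
                (float(r["time_ms"]), (int(r["row"]), int(r["col"])), bool(r["captured"]))
                for r in arr
            ]
    return out


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff_stack"
    if suffix in (".h5", ".hdf5", ".hdf"):
        return "hdf5_container"
    raise ValueError(f"cannot infer container format from suffix {suffix!r}")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
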