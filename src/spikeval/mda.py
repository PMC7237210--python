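"""MDA binary arrays, firings event lists, recording manifests, and sha1:// URIs.

The MDA dialect used throughout extracellular benchmarking pipelines is a raw
little-endian header of 32-bit signed integers ``[type_code, bytes_per_element,
ndim, dim_1, ..., dim_n]`` followed by the dense payload in column-major
(Fortran) element order.  Supported type codes follow the MountainSort
convention (see ``TYPE_CODES``).

Firings matrices are 3 x L: row 1 is the primary channel (1-based, 0 when
unknown), row 2 the event time in (possibly fractional) 1-based sample units,
row 3 the positive integer unit label.
"""

from __future__ import annotations

import csv
import hashlib
import json
import shutil
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MdaFormatError",
    "TYPE_CODES",
    "read_mda",
    "write_mda",
    "sha1_uri",
    "sha1_of_file",
    "ContentStore",
    "Firings",
    "Recording",
]


class MdaFormatError(ValueError):
    """Raised for malformed or unsupported MDA content."""


#: MountainSort-convention type codes -> numpy dtypes (all little-endian).
TYPE_CODES: dict[int, np.dtype] = {
    -3: np.dtype("<f4"),
    -4: np.dtype("<i2"),
    -5: np.dtype("<i4"),
    -6: np.dtype("<u2"),
    -7: np.dtype("<f8"),
    -8: np.dtype("<u4"),
}

_DTYPE_TO_CODE = {dt: code for code, dt in TYPE_CODES.items()}


def read_mda(path: str | Path) -> np.ndarray:
    """Read an MDA file into a numpy array (column-major element order).

    Raises
    ------
    MdaFormatError
        If the type code is unknown, the bytes-per-element field is
        inconsistent, or the payload is shorter than the declared dims.
    """
    path = Path(path)
    with open(path, "rb") as f:
        head = f.read(12)
        if len(head) < 12:
            raise MdaFormatError(f"{path}: file too short for an MDA header")
        code, bpe, ndim = struct.unpack("<3i", head)
        if code not in TYPE_CODES:
            raise MdaFormatError(f"{path}: unknown MDA type code {code}")
        dtype = TYPE_CODES[code]
        if bpe != dtype.itemsize:
            raise MdaFormatError(
                f"{path}: bytes-per-element {bpe} inconsistent with type code {code}"
            )
        if ndim < 1 or ndim > 32:
            raise MdaFormatError(f"{path}: implausible ndim {ndim}")
        dim_bytes = f.read(4 * ndim)
        if len(dim_bytes) < 4 * ndim:
            raise MdaFormatError(f"{path}: truncated dims")
        dims = struct.unpack(f"<{ndim}i", dim_bytes)
        if any(d <= 0 for d in dims):
            raise MdaFormatError(f"{path}: non-positive dimension in {dims}")
        n = int(np.prod(dims))
        payload = f.read(n * dtype.itemsize)
    if len(payload) < n * dtype.itemsize:
        raise MdaFormatError(
            f"{path}: payload has {len(payload)} bytes, expected {n * dtype.itemsize}"
        )
    flat = np.frombuffer(payload, dtype=dtype, count=n)
    return flat.reshape(dims, order="F")


def write_mda(array: np.ndarray, path: str | Path) -> Path:
    """Write ``array`` as MDA.  Deterministic: identical arrays give identical bytes."""
    path = Path(path)
    array = np.asarray(array)
    if array.ndim == 0:
        raise MdaFormatError("cannot write a zero-dimensional array")
    dtype = array.dtype.newbyteorder("<")
    if dtype not in _DTYPE_TO_CODE:
        raise MdaFormatError(f"unsupported dtype {array.dtype} for MDA")
    code = _DTYPE_TO_CODE[dtype]
    with open(path, "wb") as f:
        f.write(struct.pack("<3i", code, dtype.itemsize, array.ndim))
        f.write(struct.pack(f"<{array.ndim}i", *array.shape))
        f.write(np.ascontiguousarray(array.T).astype(dtype, copy=False).tobytes())
    return path


def sha1_of_file(path: str | Path) -> str:
    h = hashlib.sha1()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def sha1_uri(path: str | Path) -> str:
    """Content URI ``sha1://<digest>/<basename>`` of a file's bytes."""
    path = Path(path)
    return f"sha1://{sha1_of_file(path)}/{path.name}"


class ContentStore:
    """Local content-addressable file registry keyed by SHA-1 digest."""

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)

    def add(self, path: str | Path) -> str:
        path = Path(path)
        uri = sha1_uri(path)
        digest = uri.split("/")[2]
        dest = self.directory / digest
        if not dest.exists():
            shutil.copyfile(path, dest)
        return uri

    def resolve(self, uri: str) -> Path:
        if not uri.startswith("sha1://"):
            raise ValueError(f"not a sha1 URI: {uri}")
        digest = uri[len("sha1://") :].split("/")[0]
        dest = self.directory / digest
        if not dest.exists():
            raise KeyError(f"digest {digest} not present in store {self.directory}")
        return dest


def _validate_firings(channels, times, labels):
    if not (len(channels) == len(times) == len(labels)):
        raise ValueError("firings rows must have equal length")
    if len(labels) and np.any(np.asarray(labels) < 1):
        raise ValueError("unit labels must be positive integers")


@dataclass
class Firings:
    """Labeled spike events: primary channel, sample time, unit label."""

    channels: np.ndarray
    times: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        _validate_firings(self.channels, self.times, self.labels)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def unit_labels(self) -> np.ndarray:
        return np.unique(self.labels)

    def times_for(self, label: int) -> np.ndarray:
        """Event times of one unit, sorted ascending."""
        return np.sort(self.times[self.labels == label])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "Firings":
        arr = np.asarray(arr)
        if arr.ndim != 2 or arr.shape[0] != 3:
            raise ValueError(f"firings matrix must be 3 x L, got {arr.shape}")
        return cls(arr[0], arr[1], arr[2].astype(np.int64))

    def to_array(self) -> np.ndarray:
        return np.vstack([self.channels, self.times, self.labels.astype(np.float64)])

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        if path.suffix == ".csv":
            with open(path, "w", newline="") as f:
                w = csv.writer(f)
                w.writerow(["channel", "sample", "label"])
                for c, t, l in zip(self.channels, self.times, self.labels):
                    w.writerow([int(c) if float(c).is_integer() else c,
                                int(t) if float(t).is_integer() else t, int(l)])
        else:
            write_mda(self.to_array(), path)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "Firings":
        path = Path(path)
        if path.suffix == ".csv":
            rows = []
            with open(path, newline="") as f:
                r = csv.reader(f)
                header = next(r)
                if [h.strip() for h in header] != ["channel", "sample", "label"]:
                    raise MdaFormatError(f"{path}: expected header channel,sample,label")
                for row in r:
                    rows.append([float(x) for x in row])
            arr = np.array(rows, dtype=np.float64).reshape(-1, 3).T
            if arr.size == 0:
                arr = np.empty((3, 0))
            return cls.from_array(arr)
        return cls.from_array(read_mda(path))


@dataclass
class Recording:
    """Multichannel extracellular timeseries in microvolts.

    ``traces`` is channels x samples; ``geometry`` holds per-channel electrode
    coordinates in micrometers (2 or 3 columns).
    """

    traces: np.ndarray
    sample_rate: float
    geometry: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.traces = np.atleast_2d(np.asarray(self.traces))
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.geometry is None:
            self.geometry = np.column_stack(
                [np.zeros(self.num_channels), 20.0 * np.arange(self.num_channels)]
            )
        self.geometry = np.atleast_2d(np.asarray(self.geometry, dtype=np.float64))
        if self.geometry.shape[0] != self.num_channels:
            raise ValueError(
                f"geometry has {self.geometry.shape[0]} rows for "
                f"{self.num_channels} channels"
            )
        if self.geometry.shape[1] not in (2, 3):
            raise ValueError("geometry needs 2 or 3 coordinate columns")

    @property
    def num_channels(self) -> int:
        return self.traces.shape[0]

    @property
    def num_samples(self) -> int:
        return self.traces.shape[1]

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.num_samples / self.sample_rate

    def save(self, directory: str | Path, name: str = "recording") -> Path:
        """Write ``<name>.mda`` (float32) plus a JSON manifest; returns manifest path."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        mda_path = directory / f"{name}.mda"
        write_mda(self.traces.astype(np.float32), mda_path)
        manifest = {
            "sample_rate": float(self.sample_rate),
            "geometry": self.geometry.tolist(),
            "timeseries_uri": mda_path.name,
            "timeseries_sha1": sha1_uri(mda_path),
            "duration_samples": int(self.num_samples),
        }
        manifest_path = directory / f"{name}.json"
        manifest_path.write_text(json.dumps(manifest, indent=2))
        return manifest_path

    @classmethod
    def load(cls, manifest_path: str | Path, store: ContentStore | None = None) -> "Recording":
        manifest_path = Path(manifest_path)
        manifest = json.loads(manifest_path.read_text())
        uri = manifest["timeseries_uri"]
        if uri.startswith("sha1://"):
            if store is None:
                raise ValueError("sha1 URI manifest requires a ContentStore")
            ts_path = store.resolve(uri)
        else:
            ts_path = manifest_path.parent / uri
        traces = read_mda(ts_path)
        rec = cls(
            traces=traces,
            sample_rate=float(manifest["sample_rate"]),
            geometry=np.asarray(manifest["geometry"], dtype=np.float64),
        )
        if rec.num_samples != int(manifest["duration_samples"]):
            raise MdaFormatError(
                f"{ts_path}: manifest declares {manifest['duration_samples']} samples, "
                f"file has {rec.num_samples}"
            )
        return rec
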