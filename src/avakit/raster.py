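"""Core data containers for population calcium-imaging analysis.

The central object is the :class:`SpikeRaster`: per-neuron, per-frame
nonnegative spike-rate estimates ``lam`` (the deconvolved rate, written
lambda throughout the docs) together with a binary activity ``mask``.
The invariant ``mask == (lam > 0)`` is enforced on construction, so the
mask is always derivable from the rates; it is stored explicitly because
several analyses (event synchronization, bursts) operate on events only.

Containers read and write two on-disk layouts:

* HDF5 with datasets ``lambda``, ``mask`` and scalar ``frame_rate``;
* delimited text, neurons x frames, with a header row of frame indices.

ROI centroid tables are plain CSV with columns ``roi_id,x_um,y_um``.
"""

from __future__ import annotations

from dataclasses import InitVar, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = ["SpikeRaster", "FluorescenceTraces", "ROIMap"]


def _as_2d(values, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype not in (np.float32, np.float64):
        arr = arr.astype(float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D (neurons x frames), got shape {arr.shape}")
    return arr


@dataclass
class SpikeRaster:
    """Per-neuron, per-frame spike-rate estimates with a binary activity mask.

    Parameters
    ----------
    lam : ndarray, shape (n_neurons, n_frames)
        Nonnegative spike-rate estimate per neuron and frame (arbitrary
        rate units; a frame with ``lam > 0`` is an event).
    mask : ndarray of bool, same shape
        Binary activity mask; must equal ``lam > 0``.
    frame_rate : float
        Acquisition rate in Hz.
    check : bool
        Validate the invariants on construction (default). Internal
        producers that build ``lam`` themselves skip the full-array
        scans on very large simulations.
    """

    lam: np.ndarray
    mask: np.ndarray
    frame_rate: float = 15.0
    check: InitVar[bool] = True

    def __post_init__(self, check: bool = True) -> None:
        self.lam = _as_2d(self.lam, "lam")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.lam.shape:
            raise ValueError("mask and lam must have identical shapes")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not check:
            return
        if not np.isfinite(self.lam).all():
            raise ValueError("lam must be finite")
        if (self.lam < 0).any():
            raise ValueError("lam must be nonnegative")
        if not np.array_equal(self.mask, self.lam > 0):
            raise ValueError("mask must equal (lam > 0)")

    @classmethod
    def from_lambda(cls, lam, frame_rate: float = 15.0, check: bool = True) -> "SpikeRaster":
        lam = _as_2d(lam, "lam")
        return cls(lam=lam, mask=lam > 0, frame_rate=frame_rate, check=check)

    @property
    def n_neurons(self) -> int:
        return self.lam.shape[0]

    @property
    def n_frames(self) -> int:
        return self.lam.shape[1]

    def copy(self) -> "SpikeRaster":
        return SpikeRaster(self.lam.copy(), self.mask.copy(), self.frame_rate)

    # ------------------------------------------------------------------ I/O
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("lambda", data=self.lam)
            f.create_dataset("mask", data=self.mask.astype(np.uint8))
            f.create_dataset("frame_rate", data=float(self.frame_rate))

    @classmethod
    def from_hdf5(cls, path) -> "SpikeRaster":
        with h5py.File(path, "r") as f:
            lam = f["lambda"][...]
            frame_rate = float(f["frame_rate"][()])
        return cls.from_lambda(lam, frame_rate=frame_rate)

    def to_csv(self, path, frame_rate_in_header: bool = True) -> None:
        header = ",".join(str(t) for t in range(self.n_frames))
        comments = f"# frame_rate_hz={self.frame_rate}\n" if frame_rate_in_header else ""
        with open(path, "w") as fh:
            fh.write(comments)
            fh.write(header + "\n")
            np.savetxt(fh, self.lam, delimiter=",", fmt="%.10g")

    @classmethod
    def from_csv(cls, path, frame_rate: float | None = None) -> "SpikeRaster":
        path = Path(path)
        with open(path) as fh:
            first = fh.readline()
        rate = frame_rate
        skip = 1
        if first.startswith("#"):
            skip = 2
            if rate is None and "frame_rate_hz=" in first:
                rate = float(first.strip().split("frame_rate_hz=")[1])
        if rate is None:
            rate = 15.0
        lam = np.loadtxt(path, delimiter=",", skiprows=skip, ndmin=2)
        return cls.from_lambda(lam, frame_rate=rate)


@dataclass
class FluorescenceTraces:
    """Normalized fluorescence (dF/F) per neuron per frame."""

    values: np.ndarray
    frame_rate: float = 15.0

    def __post_init__(self) -> None:
        self.values = _as_2d(self.values, "values")
        if not np.isfinite(self.values).all():
            raise ValueError("fluorescence values must be finite")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("dff", data=self.values)
            f.create_dataset("frame_rate", data=float(self.frame_rate))

    @classmethod
    def from_hdf5(cls, path) -> "FluorescenceTraces":
        with h5py.File(path, "r") as f:
            values = f["dff"][...]
            frame_rate = float(f["frame_rate"][()])
        return cls(values=values, frame_rate=frame_rate)


@dataclass
class ROIMap:
    """ROI centroid positions (micrometres) within a square imaging field."""

    x: np.ndarray
    y: np.ndarray
    field_size: float = 557.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same length")
        if self.field_size <= 0:
            raise ValueError("field_size must be positive")
        for c in (self.x, self.y):
            if ((c < 0) | (c > self.field_size)).any():
                raise ValueError("centroids must lie within [0, field_size]")

    @property
    def n_rois(self) -> int:
        return self.x.size

    def distances(self) -> np.ndarray:
        """Full symmetric Euclidean distance matrix (um)."""
        dx = self.x[:, None] - self.x[None, :]
        dy = self.y[:, None] - self.y[None, :]
        return np.hypot(dx, dy)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"roi_id": np.arange(self.n_rois), "x_um": self.x, "y_um": self.y}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, field_size: float = 557.0) -> "ROIMap":
        df = pd.read_csv(path)
        return cls(x=df["x_um"].to_numpy(), y=df["y_um"].to_numpy(), field_size=field_size)
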