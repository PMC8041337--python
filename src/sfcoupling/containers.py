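"""Core data containers shared across the pipeline.

The pipeline moves three kinds of objects around: labelled multichannel
time series (MEG-like sensor arrays plus an intracranial reference
channel), 3D scalar volumes with a voxel-to-world affine (coherence
images, tract-density images, masks, statistic maps), and streamline
sets (polylines in world millimetre coordinates).  NIfTI and TRK
round-trips are delegated to :mod:`nibabel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "TimeSeriesRecording",
    "VolumeImage",
    "StreamlineSet",
]


@dataclass
class TimeSeriesRecording:
    """A labelled multichannel signal block with sampling rate.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal values, one row per channel.
    fs : float
        Sampling rate in Hz.
    channel_names : sequence of str
        One label per row of ``data``.
    metadata : dict
        Free-form provenance (e.g. realized coherences, source grid
        indices, seeds).
    """

    data: np.ndarray
    fs: float
    channel_names: Sequence[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2D (n_channels, n_samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def index_of(self, name: str) -> int:
        try:
            return list(self.channel_names).index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None

    def pick(self, names: Sequence[str]) -> "TimeSeriesRecording":
        """Sub-recording containing ``names`` in the given order."""
        idx = [self.index_of(n) for n in names]
        return TimeSeriesRecording(
            self.data[idx].copy(), self.fs, list(names), dict(self.metadata)
        )

    def time_reversed(self) -> "TimeSeriesRecording":
        """Same channels with the sample order reversed."""
        return TimeSeriesRecording(
            self.data[:, ::-1].copy(), self.fs, list(self.channel_names),
            dict(self.metadata),
        )


@dataclass
class VolumeImage:
    """3D scalar array with a voxel-to-world affine (mm)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def voxel_size(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (continuous) voxel indices, shape (..., 3), to world mm."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm coordinates to continuous voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def world_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centres along each axis.

        Requires an axis-aligned affine (diagonal rotation/zoom part up
        to sign).
        """
        R = self.affine[:3, :3]
        if np.any(np.abs(R - np.diag(np.diag(R))) > 1e-9):
            raise ValueError("affine is not axis-aligned")
        out = []
        for ax in range(3):
            n = self.data.shape[ax]
            out.append(self.affine[ax, ax] * np.arange(n) + self.affine[ax, 3])
        return tuple(out)

    def copy_with(self, data: np.ndarray) -> "VolumeImage":
        return VolumeImage(np.asarray(data), self.affine.copy())

    def same_space(self, other: "VolumeImage", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.affine, other.affine, atol=atol)
        )

    # --- NIfTI round-trip -------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data), self.affine)

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image) -> "VolumeImage":
        return cls(np.asanyarray(img.dataobj), img.affine)


class StreamlineSet:
    """A collection of polylines in world millimetre coordinates.

    Each streamline is an ``(n_vertices, 3)`` float array.  Identity is
    positional (index into the list); the class is a thin sequence
    wrapper so that filtering operations preserve order.
    """

    def __init__(self, streamlines: Sequence[np.ndarray]):
        self._lines = [np.asarray(s, dtype=float).reshape(-1, 3)
                       for s in streamlines]

    def __len__(self) -> int:
        return len(self._lines)

    def __iter__(self):
        return iter(self._lines)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return StreamlineSet(self._lines[i])
        return self._lines[i]

    @property
    def total_vertices(self) -> int:
        return sum(len(s) for s in self._lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"StreamlineSet(n={len(self)}, vertices={self.total_vertices})"
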