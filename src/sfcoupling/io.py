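"""Readers and writers for the formats the pipeline touches.

Volumes go to NIfTI-1, streamlines to TRK (both via nibabel),
recordings to a flat binary array with a JSON sidecar carrying channel
names and sampling rate, cross-spectra to an ``.npz`` container, and
tables to CSV.  Configuration is plain-text YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .containers import StreamlineSet, TimeSeriesRecording, VolumeImage
from .spectral import CrossSpectrum

__all__ = [
    "read_nifti", "write_nifti",
    "read_trk", "write_trk",
    "save_recording", "load_recording",
    "save_csd", "load_csd",
    "PipelineConfig",
    "sha256_of",
]


# --- NIfTI ---------------------------------------------------------------

def write_nifti(img: VolumeImage, path) -> Path:
    path = Path(path)
    nib.save(img.to_nifti(), str(path))
    return path


def read_nifti(path) -> VolumeImage:
    path = Path(path)
    try:
        nii = nib.load(str(path))
        data = np.asanyarray(nii.dataobj)  # eager: surfaces truncation now
    except Exception as exc:
        raise ValueError(f"cannot parse NIfTI file {path}: {exc}") from exc
    if data.ndim != 3:
        raise ValueError(f"{path} is not a 3D volume (ndim={data.ndim})")
    return VolumeImage(data, nii.affine)


# --- TRK -----------------------------------------------------------------

def write_trk(s: StreamlineSet, path) -> Path:
    path = Path(path)
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(line, dtype=np.float32) for line in s],
        affine_to_rasmm=np.eye(4),
    )
    nib.streamlines.save(tractogram, str(path))
    return path


def read_trk(path) -> StreamlineSet:
    path = Path(path)
    try:
        trk = nib.streamlines.load(str(path))
    except Exception as exc:
        raise ValueError(f"cannot parse TRK file {path}: {exc}") from exc
    declared = trk.header.get("nb_streamlines")
    lines = list(trk.streamlines)  # already in world (RAS mm) coordinates
    if declared not in (None, 0) and declared != len(lines):
        raise ValueError(
            f"{path}: header declares {declared} streamlines, file holds "
            f"{len(lines)}"
        )
    return StreamlineSet(lines)


# --- recordings ----------------------------------------------------------

def save_recording(rec: TimeSeriesRecording, prefix) -> tuple:
    """Write ``<prefix>.npy`` (float64 array) + ``<prefix>.json`` sidecar."""
    prefix = Path(prefix)
    npy = prefix.with_suffix(".npy")
    meta = prefix.with_suffix(".json")
    np.save(npy, rec.data)
    payload = {
        "fs": rec.fs,
        "channel_names": list(rec.channel_names),
        "metadata": _jsonable(rec.metadata),
    }
    meta.write_text(json.dumps(payload, sort_keys=True, indent=1))
    return npy, meta


def load_recording(prefix) -> TimeSeriesRecording:
    prefix = Path(prefix)
    data = np.load(prefix.with_suffix(".npy"))
    payload = json.loads(prefix.with_suffix(".json").read_text())
    return TimeSeriesRecording(data, payload["fs"], payload["channel_names"],
                               payload.get("metadata", {}))


# --- cross-spectra -------------------------------------------------------

def save_csd(csd: CrossSpectrum, path) -> Path:
    path = Path(path)
    np.savez(
        path, freqs=csd.freqs, S=csd.S, n_avg=csd.n_avg, fs=csd.fs,
        channel_labels=np.array(list(csd.channel_labels)),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_csd(path) -> CrossSpectrum:
    with np.load(path, allow_pickle=False) as z:
        return CrossSpectrum(
            z["freqs"], z["S"], int(z["n_avg"]),
            [str(c) for c in z["channel_labels"]], float(z["fs"]),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# --- configuration -------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (plain-text YAML)."""

    output_dir: str = "sfcoupling_out"
    seed: int = 0
    n_subjects: int = 5
    n_hemispheres_per_subject: int = 2
    duration_s: float = 60.0
    fs: float = 200.0
    sensor_snr: float = 2.0
    n_sensors: int = 16
    space_shape: tuple = (16, 16, 16)
    voxel_mm: float = 2.0
    grid_spacing_mm: float = 5.0
    regularization: float = 0.05
    band: str = "low_beta"
    coherence_range: tuple = (0.2, 0.8)
    coupling_lag: int = 4
    seed_radius_mm: float = 3.0
    sfc_slope: float = 12.0
    target_density: float = 8.0
    density_noise_sd: float = 1.0
    forming_p: float = 0.01
    n_perm: int = 200
    fwe_alpha: float = 0.01

    def __post_init__(self) -> None:
        self.space_shape = tuple(int(v) for v in self.space_shape)
        self.coherence_range = tuple(float(v) for v in self.coherence_range)
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if not 0 < self.forming_p < 1:
            raise ValueError("forming_p must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file {path} does not exist")
        raw = yaml.safe_load(path.read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path
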