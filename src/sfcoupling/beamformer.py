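"""DICS beamforming: reference-coherence imaging on a source grid.

Dynamic Imaging of Coherent Sources builds, for every point of a 5 mm
source grid, a spatial filter ``w = C^-1 l / (l' C^-1 l)`` from the
(regularized, band-averaged, real-part) sensor cross-spectral matrix C
and the leadfield column l of that point.  The filter has unit gain at
its own location.  Source-reference magnitude-squared coherence is then

    coh(g) = |w' S_xr|^2 / ((w' S_xx w) * S_rr)

with all blocks of the complex band-averaged CSD, and the grid values
are trilinearly interpolated onto a 2 mm voxel image restricted to the
brain mask.

The forward model here is scalar (orientation-free), matching the toy
leadfield of :mod:`sfcoupling.synthetic`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .containers import VolumeImage
from .spectral import CrossSpectrum, FrequencyBand

__all__ = [
    "SourceGrid",
    "build_source_grid",
    "dics_filters",
    "coherence_image",
    "flip_midsagittal",
]


@dataclass
class SourceGrid:
    """Regular source lattice inside a brain mask.

    ``points`` are world-mm coordinates ordered consistently with the
    leadfield rows; ``axes`` are the lattice coordinates per axis and
    ``lattice_index`` maps each point to its (i, j, k) on the lattice
    (used for interpolation back to voxel space).  The lattice is
    symmetric about the world plane x=0 so that mid-sagittal flipping
    maps grid points onto grid points.
    """

    points: np.ndarray
    spacing: float
    mask: VolumeImage
    axes: tuple
    lattice_index: np.ndarray

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def build_source_grid(mask: VolumeImage, spacing: float = 5.0) -> SourceGrid:
    """5 mm (default) lattice of points whose containing mask voxel is
    nonzero, mirror-symmetrized about world x=0."""
    data = np.asarray(mask.data)
    # world extent of the mask volume
    corners = np.array([[i, j, k] for i in (0, data.shape[0] - 1)
                        for j in (0, data.shape[1] - 1)
                        for k in (0, data.shape[2] - 1)], dtype=float)
    world = mask.voxel_to_world(corners)
    lo, hi = world.min(axis=0), world.max(axis=0)

    # x placed symmetrically about 0: +-s/2, +-3s/2, ...
    nx = int(np.floor((hi[0] - spacing / 2.0) / spacing)) + 1
    xs_pos = spacing / 2.0 + spacing * np.arange(max(nx, 0))
    xs = np.sort(np.concatenate([-xs_pos[::-1], xs_pos]))
    ys = np.arange(lo[1], hi[1] + 1e-9, spacing)
    zs = np.arange(lo[2], hi[2] + 1e-9, spacing)

    pts, idx = [], []
    inside = np.zeros((xs.size, ys.size, zs.size), dtype=bool)
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            for k, z in enumerate(zs):
                v = np.rint(mask.world_to_voxel([x, y, z])).astype(int)
                if np.all(v >= 0) and np.all(v < data.shape) and data[tuple(v)]:
                    inside[i, j, k] = True
    # mirror-symmetrize in x so flipping maps grid points to grid points
    inside &= inside[::-1, :, :]
    for i, j, k in np.argwhere(inside):
        pts.append([xs[i], ys[j], zs[k]])
        idx.append([i, j, k])
    if not pts:
        raise ValueError("no grid points fall inside the mask")
    return SourceGrid(np.asarray(pts, dtype=float), spacing, mask,
                      (xs, ys, zs), np.asarray(idx, dtype=int))


def dics_filters(
    csd: CrossSpectrum,
    leadfield: np.ndarray,
    grid: SourceGrid,
    band: FrequencyBand,
    regularization: float = 0.05,
) -> np.ndarray:
    """Per-grid-point DICS sensor weights, shape (n_grid, n_sensors).

    ``csd`` must be restricted to the sensor channels (reference
    excluded).  C is the real part of the band-averaged CSD plus
    ``regularization * mean(diag(C))`` on the diagonal.  Each filter
    satisfies the unit-gain property w'l = 1.
    """
    leadfield = np.asarray(leadfield, dtype=float)
    if leadfield.shape[0] != grid.n_points:
        raise ValueError("leadfield rows must match grid points")
    if leadfield.shape[1] != csd.n_channels:
        raise ValueError("leadfield columns must match CSD channels")
    if csd.n_channels < 2:
        raise ValueError("need at least 2 sensors")
    if regularization < 0:
        raise ValueError("regularization must be >= 0")
    C = csd.band_matrix(band).real
    lam = regularization * np.mean(np.diag(C))
    Creg = C + lam * np.eye(C.shape[0])
    try:
        Cinv_Lt = np.linalg.solve(Creg, leadfield.T)  # (n_sens, n_grid)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "regularized CSD matrix is singular; increase the "
            "regularization fraction"
        ) from None
    denom = np.einsum("gs,sg->g", leadfield, Cinv_Lt)
    if np.any(np.abs(denom) < 1e-30):
        raise np.linalg.LinAlgError(
            "degenerate leadfield projection; increase the regularization "
            "fraction"
        )
    return (Cinv_Lt / denom[None, :]).T


def coherence_image(
    csd: CrossSpectrum,
    filters: np.ndarray,
    grid: SourceGrid,
    band: FrequencyBand,
    reference: str = "LFP",
) -> VolumeImage:
    """Source-reference coherence image on the mask's voxel space.

    ``csd`` must include the reference channel; the filters must have
    been computed from the sensor-only CSD.  Grid coherences are
    trilinearly interpolated to the mask voxel grid (non-mask lattice
    points contribute 0); voxels outside the mask are NaN.
    """
    ref = csd.index_of(reference)
    sens = [i for i in range(csd.n_channels) if i != ref]
    if filters.shape != (grid.n_points, len(sens)):
        raise ValueError("filters do not match grid/sensor dimensions")
    Sb = csd.band_matrix(band)
    Srr = Sb[ref, ref].real
    if Srr <= 0:
        raise ValueError("reference auto-spectrum is zero in the band")
    Sss = Sb[np.ix_(sens, sens)]
    Ssr = Sb[np.ix_(sens, [ref])][:, 0]
    num = np.abs(filters.conj() @ Ssr) ** 2
    den = np.einsum("gs,st,gt->g", filters.conj(), Sss, filters).real * Srr
    coh = np.clip(num / np.maximum(den, 1e-300), 0.0, 1.0)

    # scatter grid values onto the regular lattice, 0 where no grid point
    xs, ys, zs = grid.axes
    lattice = np.zeros((xs.size, ys.size, zs.size))
    li = grid.lattice_index
    lattice[li[:, 0], li[:, 1], li[:, 2]] = coh
    interp = RegularGridInterpolator(
        (xs, ys, zs), lattice, method="linear", bounds_error=False,
        fill_value=0.0,
    )
    mask = grid.mask
    shape = mask.shape
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    centers = mask.voxel_to_world(
        np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    )
    vals = interp(centers).reshape(shape)
    vals = np.clip(vals, 0.0, 1.0)
    out = np.where(np.asarray(mask.data) > 0, vals, np.nan)
    return mask.copy_with(out.astype(float))


def flip_midsagittal(img: VolumeImage) -> VolumeImage:
    """Mirror a volume across the world plane x=0.

    The world point (x, y, z) takes the value formerly at (-x, y, z).
    Requires an axis-aligned affine whose voxel centres are symmetric
    about x=0 (as produced by
    :func:`sfcoupling.synthetic.make_symmetric_space`), in which case
    the flip is exact and an involution.
    """
    xs, _, _ = img.world_axes()
    if abs(xs[0] + xs[-1]) > 1e-6:
        raise ValueError(
            "voxel grid is not symmetric about world x=0; exact "
            "mid-sagittal flipping is undefined for this affine"
        )
    return img.copy_with(np.asarray(img.data)[::-1, :, :].copy())
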