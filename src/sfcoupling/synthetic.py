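"""Synthetic cohort generation with known ground truth.

Everything downstream of raw data acquisition is testable against this
module: it fabricates (a) multichannel sensor recordings in which
band-limited cortical sources have controlled magnitude-squared
coherence and a controlled Granger direction relative to an
intracranial reference channel, projected through a toy forward model
with additive sensor noise, and (b) streamline sets whose voxel-wise
density is, at chosen voxels, a linear function of each subject's
assigned coherence level — the planted structure-function coupling the
statistics modules are meant to recover.

Sources are band-limited filtered-noise processes tied to the
reference through a shared innovation plus a sample lag: this makes
the in-band coherence analytically controllable (coherence equals the
squared shared-amplitude) and fixes the Granger direction by which
side receives the delayed copy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .containers import StreamlineSet, TimeSeriesRecording, VolumeImage
from .spectral import FrequencyBand

__all__ = [
    "SourceSpec",
    "CohortSpec",
    "StreamlineCohort",
    "simulate_var_sources",
    "make_toy_leadfield",
    "generate_subject_recording",
    "generate_streamline_cohort",
    "make_symmetric_space",
    "make_ellipsoid_mask",
    "make_sensor_shell",
]

DIRECTIONS = ("source_drives_ref", "ref_drives_source", "bidirectional", "none")


@dataclass(frozen=True)
class SourceSpec:
    """One simulated cortical source coupled to the reference channel.

    Parameters
    ----------
    location : int
        Grid index of the source (row of the leadfield).
    band : FrequencyBand
        Frequency band carrying the coupling.
    coherence_target : float
        Intended magnitude-squared coherence with the reference, in
        [0, 1].
    direction : str
        One of ``source_drives_ref``, ``ref_drives_source``,
        ``bidirectional``, ``none``.
    coupling_lag : int
        Coupling delay in samples (>= 1 unless direction is ``none``).
    """

    location: int
    band: FrequencyBand
    coherence_target: float
    direction: str = "source_drives_ref"
    coupling_lag: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.coherence_target <= 1.0:
            raise ValueError("coherence_target must be in [0, 1]")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.direction != "none" and self.coupling_lag < 1:
            raise ValueError("coupling_lag must be >= 1 for directed coupling")


@dataclass
class CohortSpec:
    """Across-subject design of the synthetic cohort.

    ``sfc_voxels`` are voxel indices where, across observations, the
    expected tract density is ``target + sfc_slope * coherence_level``,
    i.e. where structure predicts function by construction.
    """

    n_subjects: int
    n_hemispheres_per_subject: int = 2
    sfc_voxels: tuple = ()
    sfc_slope: float = 10.0
    coherence_range: tuple = (0.2, 0.8)
    nuisance_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")
        if self.n_hemispheres_per_subject < 1:
            raise ValueError("need at least 1 hemisphere per subject")

    @property
    def n_observations(self) -> int:
        return self.n_subjects * self.n_hemispheres_per_subject

    def observation_table(self) -> pd.DataFrame:
        rows = []
        sides = ["right", "left"]
        for s in range(self.n_subjects):
            for h in range(self.n_hemispheres_per_subject):
                rows.append(
                    dict(observation_id=f"sub{s:02d}_{sides[h % 2]}",
                         subject=f"sub{s:02d}", side=sides[h % 2])
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# VAR simulation (oracle substrate for the Granger machinery)
# ---------------------------------------------------------------------------

def var_companion(coeffs: np.ndarray) -> np.ndarray:
    """Companion matrix of a VAR(p) coefficient stack, shape (pk, pk)."""
    coeffs = np.asarray(coeffs, dtype=float)
    p, k, k2 = coeffs.shape
    if k != k2:
        raise ValueError("coefficient matrices must be square")
    comp = np.zeros((p * k, p * k))
    comp[:k] = np.concatenate(coeffs, axis=1)
    if p > 1:
        comp[k:, :-k] = np.eye((p - 1) * k)
    return comp


def simulate_var_sources(
    coeffs: np.ndarray,
    noise_cov: np.ndarray,
    n_samples: int,
    seed: int,
    fs: float = 1.0,
    channel_prefix: str = "ch",
) -> TimeSeriesRecording:
    """Simulate a stationary vector-autoregressive process.

    Parameters
    ----------
    coeffs : ndarray, shape (order, k, k)
        ``coeffs[m]`` multiplies the state ``m + 1`` steps back.
    noise_cov : ndarray, shape (k, k)
        Innovation covariance; must be symmetric positive definite.
    n_samples : int
        Length of the returned realization (after burn-in removal).
    seed : int
        RNG seed; fixed seed gives identical output.
    fs : float
        Nominal sampling rate attached to the recording (Hz).

    Raises
    ------
    ValueError
        If the VAR is unstable (companion spectral radius >= 1) or
        ``noise_cov`` is not symmetric positive definite.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.ndim != 3:
        raise ValueError("coeffs must have shape (order, k, k)")
    p, k, _ = coeffs.shape
    noise_cov = np.asarray(noise_cov, dtype=float)
    if noise_cov.shape != (k, k) or not np.allclose(noise_cov, noise_cov.T,
                                                    atol=1e-10):
        raise ValueError("noise_cov must be a symmetric (k, k) matrix")
    try:
        chol = np.linalg.cholesky(noise_cov)
    except np.linalg.LinAlgError:
        raise ValueError("noise_cov is not positive definite") from None
    radius = np.max(np.abs(np.linalg.eigvals(var_companion(coeffs))))
    if radius >= 1.0:
        raise ValueError(
            f"unstable VAR: companion spectral radius {radius:.4f} >= 1"
        )
    burn = max(10 * p, 200)
    total = n_samples + burn
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((total, k)) @ chol.T
    x = np.zeros((total, k))
    for t in range(p, total):
        acc = eps[t]
        for m in range(p):
            acc = acc + coeffs[m] @ x[t - 1 - m]
        x[t] = acc
    data = x[burn:].T.copy()
    names = [f"{channel_prefix}{i}" for i in range(k)]
    return TimeSeriesRecording(data, fs, names, {"seed": seed})


# ---------------------------------------------------------------------------
# Toy forward model
# ---------------------------------------------------------------------------

def make_toy_leadfield(grid_points: np.ndarray,
                       sensor_positions: np.ndarray) -> np.ndarray:
    """Inverse-distance toy leadfield, shape (n_grid, n_sensors).

    Each row is the gain pattern of a unit source at one grid point:
    g_ij = 1 / ||grid_i - sensor_j||, normalized to unit row norm.  A
    smooth, full-row-rank stand-in for a physical forward model.
    """
    grid_points = np.asarray(grid_points, dtype=float).reshape(-1, 3)
    sensor_positions = np.asarray(sensor_positions, dtype=float).reshape(-1, 3)
    if sensor_positions.shape[0] < 8:
        raise ValueError("need at least 8 sensors")
    d = np.linalg.norm(
        grid_points[:, None, :] - sensor_positions[None, :, :], axis=2
    )
    if np.any(d < 1e-9):
        raise ValueError("a grid point coincides with a sensor")
    # distinct grid points
    gd = np.linalg.norm(grid_points[:, None] - grid_points[None, :], axis=2)
    np.fill_diagonal(gd, np.inf)
    if np.any(gd < 1e-9):
        raise ValueError("grid points are not distinct")
    lf = 1.0 / d
    lf /= np.linalg.norm(lf, axis=1, keepdims=True)
    return lf


# ---------------------------------------------------------------------------
# Recording generation
# ---------------------------------------------------------------------------

def _band_noise(rng: np.random.Generator, n: int, band: FrequencyBand,
                fs: float) -> np.ndarray:
    """Unit-variance zero-phase band-limited Gaussian noise of length n."""
    pad = int(round(4 * fs))
    sos = butter(4, [band.lo, band.hi], btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n + 2 * pad))[pad:-pad]
    return x / x.std()


def generate_subject_recording(
    source_specs: list,
    leadfield: np.ndarray,
    duration_s: float = 180.0,
    fs: float = 300.0,
    sensor_snr: float = 1.0,
    seed: int = 0,
    ref_noise_power: float = 0.05,
) -> TimeSeriesRecording:
    """Generate one subject's sensor + reference recording.

    Sensors carry the leadfield projection of the band-limited sources
    plus independent Gaussian noise scaled so that the RMS
    signal-to-noise ratio equals ``sensor_snr`` (``np.inf`` disables
    noise).  The reference channel (label ``"LFP"``) carries the shared
    band-limited components demanded by each :class:`SourceSpec`, a
    small broadband noise floor (``ref_noise_power``, relative to the
    unit-variance shared components), and is high-pass filtered at
    1 Hz with a 4th-order zero-phase Butterworth, mirroring hardware
    high-pass filtering without the phase distortion that would corrupt
    the directionality ground truth.

    The realized in-band source-reference coherence of each source
    (computed on the noiseless sources at generation time) is stored in
    ``metadata["realized_coherence"]``.
    """
    leadfield = np.asarray(leadfield, dtype=float)
    n_grid, n_sensors = leadfield.shape
    n = int(round(duration_s * fs))
    nyq = fs / 2.0
    rng = np.random.default_rng(seed)

    ref = np.zeros(n)
    sources = []
    for spec in source_specs:
        if spec.band.hi >= nyq:
            raise ValueError(
                f"band {spec.band.name} upper edge {spec.band.hi} Hz is at or "
                f"above Nyquist {nyq} Hz"
            )
        if not 0 <= spec.location < n_grid:
            raise ValueError(f"source location {spec.location} outside grid")
        lag = spec.coupling_lag if spec.direction != "none" else 0
        z = _band_noise(rng, n + lag, spec.band, fs)
        z_now, z_del = z[lag:lag + n], z[:n]  # z_del[t] = z_now[t - lag]
        if spec.direction == "source_drives_ref":
            shared_src, ref_comp = z_now, z_del
        elif spec.direction == "ref_drives_source":
            shared_src, ref_comp = z_del, z_now
        elif spec.direction == "bidirectional":
            w = _band_noise(rng, n + lag, spec.band, fs)
            w_now, w_del = w[lag:lag + n], w[:n]
            shared_src = (z_del + w_now) / np.sqrt(2.0)
            ref_comp = (z_now + w_del) / np.sqrt(2.0)
        else:  # none: zero-lag shared component
            shared_src, ref_comp = z_now, z_del
        a = np.sqrt(spec.coherence_target)
        private = _band_noise(rng, n, spec.band, fs)
        src = a * shared_src + np.sqrt(1.0 - spec.coherence_target) * private
        sources.append(src / src.std() if src.std() > 0 else src)
        ref = ref + ref_comp

    ref = ref + np.sqrt(ref_noise_power) * rng.standard_normal(n)
    hp = butter(4, 1.0, btype="highpass", fs=fs, output="sos")
    ref = sosfiltfilt(hp, ref)

    if sources:
        src_arr = np.asarray(sources)
        rows = leadfield[[s.location for s in source_specs]]
        sensors = rows.T @ src_arr  # (n_sensors, n)
    else:
        sensors = np.zeros((n_sensors, n))
    if np.isfinite(sensor_snr):
        sig_rms = np.sqrt(np.mean(sensors ** 2))
        noise_sd = (sig_rms / sensor_snr) if sig_rms > 0 else 1.0
        sensors = sensors + noise_sd * rng.standard_normal(sensors.shape)

    # realized coherence check on the noiseless sources
    from .spectral import band_average, coherence, compute_csd  # local: cycle
    realized = []
    for spec, src in zip(source_specs, sources):
        pair = TimeSeriesRecording(np.vstack([src, ref]), fs, ["src", "ref"])
        csd = compute_csd(pair)
        realized.append(
            band_average(csd.freqs, coherence(csd, 0, 1), spec.band)
        )
        if abs(realized[-1] - spec.coherence_target) > 0.1:
            warnings.warn(
                f"realized coherence {realized[-1]:.3f} deviates from target "
                f"{spec.coherence_target:.3f} by more than 0.1",
                stacklevel=2,
            )

    names = [f"MEG{i:03d}" for i in range(n_sensors)] + ["LFP"]
    data = np.vstack([sensors, ref])
    meta = {
        "seed": seed,
        "source_locations": [s.location for s in source_specs],
        "realized_coherence": realized,
        "sensor_snr": sensor_snr,
    }
    return TimeSeriesRecording(data, fs, names, meta)


# ---------------------------------------------------------------------------
# Toy anatomical space and streamline cohorts
# ---------------------------------------------------------------------------

def make_symmetric_space(shape=(24, 24, 24), voxel: float = 2.0) -> VolumeImage:
    """Blank image whose voxel centres are symmetric about world x=0.

    The affine places voxel centres at ``voxel * (i - (n-1)/2)`` along
    each axis, so the mid-sagittal plane x=0 lies exactly between (even
    n) or on (odd n) voxel centres and mirror voxels map onto voxels.
    """
    affine = np.eye(4)
    for ax, n in enumerate(shape):
        affine[ax, ax] = voxel
        affine[ax, 3] = -voxel * (n - 1) / 2.0
    return VolumeImage(np.zeros(shape, dtype=float), affine)


def make_ellipsoid_mask(space: VolumeImage, semiaxes=None) -> VolumeImage:
    """Binary ellipsoid 'brain' mask centred at world origin."""
    shape = space.shape
    if semiaxes is None:
        ext = [space.voxel_size()[ax] * shape[ax] / 2.0 for ax in range(3)]
        semiaxes = [0.9 * e for e in ext]
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    pts = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    xyz = space.voxel_to_world(pts).reshape(shape + (3,))
    r2 = sum((xyz[..., ax] / semiaxes[ax]) ** 2 for ax in range(3))
    return space.copy_with((r2 <= 1.0).astype(np.int16))


def make_sensor_shell(n_sensors: int = 24, radius: float = 40.0,
                      seed: int = 7) -> np.ndarray:
    """Quasi-uniform sensor positions on a sphere (Fibonacci lattice)."""
    i = np.arange(n_sensors) + 0.5
    phi = np.arccos(1 - 2 * i / n_sensors)
    theta = np.pi * (1 + 5 ** 0.5) * i
    pts = np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta),
         np.cos(phi)], axis=1
    )
    return radius * pts


@dataclass
class StreamlineCohort:
    """Per-observation streamline sets with the planted coherence levels."""

    streamline_sets: list
    coherence_levels: np.ndarray
    table: pd.DataFrame
    seed_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    seed_radius: float = 3.0


def _random_point_in_sphere(rng, center, radius):
    while True:
        p = rng.uniform(-1.0, 1.0, size=3)
        if p @ p <= 1.0:
            return center + radius * p


def _polyline(p0: np.ndarray, p1: np.ndarray, step: float = 1.0) -> np.ndarray:
    """Straight polyline from p0 to p1 with ~``step`` mm vertex spacing."""
    length = np.linalg.norm(p1 - p0)
    n = max(2, int(np.ceil(length / step)) + 1)
    t = np.linspace(0.0, 1.0, n)
    return p0[None, :] + t[:, None] * (p1 - p0)[None, :]


def generate_streamline_cohort(
    cohort: CohortSpec,
    seed_center,
    seed_radius: float,
    target_map: VolumeImage,
    noise_sd: float = 0.0,
    coherence_levels: np.ndarray = None,
) -> StreamlineCohort:
    """Generate per-observation streamline sets around a seed sphere.

    For every nonzero voxel ``v`` of ``target_map`` the generator emits
    ``round(mean_v + noise)`` straight 1 mm-spaced polylines from a
    random point inside the seed sphere to a random point inside voxel
    ``v``, where ``mean_v`` is the target density plus, at the cohort's
    ``sfc_voxels``, ``sfc_slope`` times the observation's coherence
    level (plus any subject/side nuisance offsets).  Every streamline
    therefore passes through the seed sphere; the voxel-wise density at
    ``v`` recovers ``mean_v`` up to counting noise and any corridor
    density contributed by streamlines headed past ``v``.
    """
    seed_center = np.asarray(seed_center, dtype=float)
    target = np.asarray(target_map.data, dtype=float)
    if np.any(target < 0):
        raise ValueError("target_map must be nonnegative")
    rng = np.random.default_rng(cohort.seed)
    table = cohort.observation_table()
    n_obs = len(table)
    if coherence_levels is None:
        levels = rng.uniform(*cohort.coherence_range, size=n_obs)
    else:
        levels = np.asarray(coherence_levels, dtype=float)
        if levels.size != n_obs:
            raise ValueError("coherence_levels must have one entry per "
                             "observation")
    subj_off = {s: rng.normal(0.0, cohort.nuisance_sd)
                for s in table["subject"].unique()}
    side_off = {"right": 0.0, "left": rng.normal(0.0, cohort.nuisance_sd)}

    nz = np.argwhere(target > 0)
    sfc = {tuple(v) for v in cohort.sfc_voxels}
    for v in sfc:
        if not all(0 <= v[ax] < target.shape[ax] for ax in range(3)):
            raise ValueError(f"sfc voxel {v} outside the volume")
    if nz.size == 0 and not sfc:
        warnings.warn("all-zero target_map: emitting empty streamline sets",
                      stacklevel=2)
        empty = [StreamlineSet([]) for _ in range(n_obs)]
        return StreamlineCohort(empty, levels, table,
                                seed_center, seed_radius)
    voxels = {tuple(v) for v in nz} | sfc
    half = target_map.voxel_size() / 2.0

    sets = []
    for o in range(n_obs):
        lines = []
        base_off = (subj_off[table.loc[o, "subject"]]
                    + side_off[table.loc[o, "side"]])
        for v in sorted(voxels):
            mean = target[v] + base_off
            if v in sfc:
                mean += cohort.sfc_slope * levels[o]
            if noise_sd > 0:
                mean += noise_sd * rng.normal()
            count = int(round(max(0.0, mean)))
            center = target_map.voxel_to_world(np.asarray(v, dtype=float))
            for _ in range(count):
                p0 = _random_point_in_sphere(rng, seed_center, seed_radius)
                p1 = center + rng.uniform(-1.0, 1.0, size=3) * half * 0.98
                lines.append(_polyline(p0, p1, step=1.0))
        sets.append(StreamlineSet(lines))
    return StreamlineCohort(sets, levels, table, seed_center, seed_radius)
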