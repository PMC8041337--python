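"""End-to-end synthetic pipeline: simulate -> spectra -> DICS ->
density -> flip -> GLM -> clusters -> Granger, with an artifact
manifest.

Every stage writes its outputs under ``config.output_dir`` and records
them (with SHA-256 content hashes) in ``manifest.json``; a rerun with
the same configuration and seed reproduces every artifact
byte-identically.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import beamformer, granger, sfc, synthetic, tracts
from .containers import VolumeImage
from .io import (PipelineConfig, save_csd, save_recording, sha256_of,
                 write_nifti, write_trk)
from .spectral import CANONICAL_BANDS, compute_csd

logger = logging.getLogger("sfcoupling")

STAGES = ("simulate", "spectra", "dics", "density", "glm", "granger")


def _band_by_name(name: str):
    for band in CANONICAL_BANDS:
        if band.name == name:
            return band
    raise ValueError(f"unknown band {name!r}; choose from "
                     f"{[b.name for b in CANONICAL_BANDS]}")


def run_pipeline(config: PipelineConfig, stop_after: str = "granger") -> dict:
    """Run the synthetic cohort pipeline up to ``stop_after``.

    Returns the manifest dictionary (also written to
    ``<output_dir>/manifest.json``).
    """
    if stop_after not in STAGES:
        raise ValueError(f"stop_after must be one of {STAGES}")
    stop_idx = STAGES.index(stop_after)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    band = _band_by_name(config.band)
    rng = np.random.default_rng(config.seed)
    artifacts: list[Path] = []

    # ---- geometry shared by all stages ---------------------------------
    space = synthetic.make_symmetric_space(config.space_shape, config.voxel_mm)
    mask = synthetic.make_ellipsoid_mask(space)
    grid = beamformer.build_source_grid(mask, config.grid_spacing_mm)
    sensors = synthetic.make_sensor_shell(
        config.n_sensors,
        radius=1.4 * max(space.voxel_size()[0] * s for s in space.shape),
    )
    leadfield = synthetic.make_toy_leadfield(grid.points, sensors)

    # source locations: a right-hemisphere grid point and its mirror
    right_pts = grid.points[grid.points[:, 0] > 0]
    target = right_pts[np.argmin(np.linalg.norm(
        right_pts - np.array([right_pts[:, 0].mean(), 0.0, 0.0]), axis=1))]
    loc_right = int(np.argmin(np.linalg.norm(grid.points - target, axis=1)))
    mirror = target * np.array([-1.0, 1.0, 1.0])
    loc_left = int(np.argmin(np.linalg.norm(grid.points - mirror, axis=1)))

    cohort = synthetic.CohortSpec(
        n_subjects=config.n_subjects,
        n_hemispheres_per_subject=config.n_hemispheres_per_subject,
        sfc_slope=config.sfc_slope,
        coherence_range=config.coherence_range,
        seed=config.seed,
    )
    table = cohort.observation_table()
    n_obs = len(table)
    levels = rng.uniform(*config.coherence_range, size=n_obs)

    # ---- stage: simulate ------------------------------------------------
    logger.info("stage simulate: %d observations", n_obs)
    recordings = []
    for o in range(n_obs):
        side = table.loc[o, "side"]
        loc = loc_right if side == "right" else loc_left
        spec = synthetic.SourceSpec(
            location=loc, band=band, coherence_target=levels[o],
            direction="source_drives_ref", coupling_lag=config.coupling_lag,
        )
        rec = synthetic.generate_subject_recording(
            [spec], leadfield, duration_s=config.duration_s, fs=config.fs,
            sensor_snr=config.sensor_snr,
            seed=int(rng.integers(2 ** 31 - 1)),
        )
        recordings.append(rec)
        artifacts.extend(save_recording(
            rec, out / f"recording_{table.loc[o, 'observation_id']}"
        ))
    table_path = out / "cohort.csv"
    pd.concat(
        [table, pd.Series(levels, name="coherence_level")], axis=1
    ).to_csv(table_path, index=False)
    artifacts.append(table_path)
    artifacts.append(write_nifti(mask, out / "brain_mask.nii"))
    if stop_idx < 1:
        return _finish(out, config, artifacts)

    # ---- stage: spectra --------------------------------------------------
    logger.info("stage spectra")
    csds = [compute_csd(rec) for rec in recordings]
    for o, csd in enumerate(csds):
        artifacts.append(save_csd(
            csd, out / f"csd_{table.loc[o, 'observation_id']}.npz"
        ))
    if stop_idx < 2:
        return _finish(out, config, artifacts)

    # ---- stage: dics -----------------------------------------------------
    logger.info("stage dics")
    sensor_names = [n for n in recordings[0].channel_names if n != "LFP"]
    filters = []
    coh_imgs = []
    for o, csd in enumerate(csds):
        w = beamformer.dics_filters(
            csd.pick(sensor_names), leadfield, grid, band,
            regularization=config.regularization,
        )
        filters.append(w)
        img = beamformer.coherence_image(csd, w, grid, band, reference="LFP")
        if table.loc[o, "side"] == "left":
            img = beamformer.flip_midsagittal(img)
        coh_imgs.append(img)
        artifacts.append(write_nifti(
            img, out / f"coherence_{table.loc[o, 'observation_id']}.nii"
        ))
    if stop_idx < 3:
        return _finish(out, config, artifacts)

    # ---- stage: density --------------------------------------------------
    logger.info("stage density")
    # planted structure-function blob around the right-hemisphere source
    blob_center = np.rint(mask.world_to_voxel(target)).astype(int)
    sfc_voxels = []
    for d in np.ndindex(2, 2, 2):
        v = tuple(blob_center + np.array(d))
        if all(0 <= v[ax] < mask.shape[ax] for ax in range(3)):
            sfc_voxels.append(v)
    target_map = mask.copy_with(np.zeros(mask.shape))
    for v in sfc_voxels:
        target_map.data[v] = config.target_density
    cohort.sfc_voxels = tuple(sfc_voxels)

    seed_center_r = target + np.array([config.grid_spacing_mm, 0.0, 0.0])
    roi_mask = _sphere_mask(mask, seed_center_r, 2.0 * config.seed_radius_mm)
    sl_cohort = synthetic.generate_streamline_cohort(
        cohort, seed_center_r, config.seed_radius_mm, target_map,
        noise_sd=config.density_noise_sd, coherence_levels=levels,
    )
    dens_imgs = []
    for o, sset in enumerate(sl_cohort.streamline_sets):
        side = table.loc[o, "side"]
        if side == "left":
            sset = _mirror_streamlines(sset)
            roi = tracts.SeedROI(seed_center_r * np.array([-1, 1, 1]),
                                 config.seed_radius_mm,
                                 beamformer.flip_midsagittal(roi_mask))
        else:
            roi = tracts.SeedROI(seed_center_r, config.seed_radius_mm,
                                 roi_mask)
        kept = tracts.filter_streamlines(sset, roi)
        artifacts.append(write_trk(
            kept, out / f"streamlines_{table.loc[o, 'observation_id']}.trk"
        ))
        dimg = tracts.density_image(kept, mask)
        if side == "left":
            dimg = beamformer.flip_midsagittal(dimg)
        dens_imgs.append(dimg)
        artifacts.append(write_nifti(
            VolumeImage(np.asarray(dimg.data, dtype=np.int32), dimg.affine),
            out / f"density_{table.loc[o, 'observation_id']}.nii",
        ))
    if stop_idx < 4:
        return _finish(out, config, artifacts)

    # ---- stage: glm ------------------------------------------------------
    logger.info("stage glm")
    model = sfc.StructureFunctionModel(coh_imgs, dens_imgs, mask=mask)
    results = model.fit()
    clusters = results.cluster_permutation(
        forming_p=config.forming_p, n_perm=config.n_perm, seed=config.seed,
    )
    fmap = results.F_image
    artifacts.append(write_nifti(
        VolumeImage(np.asarray(fmap.data, dtype=np.float32), fmap.affine),
        out / "sfc_F.nii",
    ))
    artifacts.append(write_nifti(clusters.labels, out / "sfc_clusters.nii"))
    cl_path = out / "sfc_clusters.csv"
    clusters.table().to_csv(cl_path, index=False)
    artifacts.append(cl_path)
    if stop_idx < 5:
        return _finish(out, config, artifacts)

    # ---- stage: granger --------------------------------------------------
    logger.info("stage granger")
    # peak-F coordinate -> nearest grid point -> DICS source time series
    Fdata = np.asarray(fmap.data)
    if np.isfinite(Fdata).any():
        peak_ijk = np.unravel_index(np.nanargmax(Fdata), Fdata.shape)
        peak_world = mask.voxel_to_world(np.asarray(peak_ijk, dtype=float))
    else:
        peak_world = target
    gpt = int(np.argmin(np.linalg.norm(grid.points - peak_world, axis=1)))
    gpt_mirror = int(np.argmin(np.linalg.norm(
        grid.points - peak_world * np.array([-1, 1, 1]), axis=1)))
    pair_recs = []
    for o, rec in enumerate(recordings):
        g = gpt if table.loc[o, "side"] == "right" else gpt_mirror
        sens = rec.pick(sensor_names).data
        src = filters[o][g] @ sens
        lfp = rec.data[rec.index_of("LFP")]
        pair_recs.append(synthetic.TimeSeriesRecording(
            np.vstack([src, lfp]), rec.fs, ["source", "LFP"],
        ))
    trt = granger.time_reversal_test(pair_recs, band)
    report = trt.to_dict()
    report["peak_world_mm"] = [float(v) for v in peak_world]
    gr_path = out / "granger_report.json"
    gr_path.write_text(json.dumps(report, sort_keys=True, indent=1))
    artifacts.append(gr_path)
    csv_path = out / "granger_directions.csv"
    trt.direction_stats().to_csv(csv_path, index=False)
    artifacts.append(csv_path)
    return _finish(out, config, artifacts)


def _sphere_mask(space: VolumeImage, center, radius) -> VolumeImage:
    shape = space.shape
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    xyz = space.voxel_to_world(
        np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    ).reshape(shape + (3,))
    d = np.linalg.norm(xyz - np.asarray(center, dtype=float), axis=-1)
    return space.copy_with((d <= radius).astype(np.int16))


def _mirror_streamlines(sset):
    from .containers import StreamlineSet
    return StreamlineSet([line * np.array([-1.0, 1.0, 1.0])
                          for line in sset])


def _finish(out: Path, config: PipelineConfig, artifacts: list) -> dict:
    manifest = {
        "seed": config.seed,
        "outputs": {
            str(p.relative_to(out)): sha256_of(p) for p in sorted(artifacts)
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1)
    )
    return manifest
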