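"""Streamline filtering, density counting and the 2x2 ANOVA."""

import numpy as np
import pandas as pd
import pytest

from sfcoupling.beamformer import flip_midsagittal
from sfcoupling.containers import StreamlineSet
from sfcoupling.synthetic import make_symmetric_space
from sfcoupling.tracts import (SeedROI, TractDensityANOVA, density_image,
                               densify_vertices, filter_streamlines)


@pytest.fixture
def space():
    return make_symmetric_space((12, 12, 12), 2.0)


def _sphere_mask(space, center, radius):
    shape = space.shape
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape],
                               indexing="ij"), axis=-1).reshape(-1, 3)
    xyz = space.voxel_to_world(idx)
    d = np.linalg.norm(xyz - np.asarray(center, dtype=float), axis=1)
    return space.copy_with(
        (d <= radius).astype(np.int16).reshape(shape))


class TestFilter:
    def test_through_center_and_mask_retained(self, space):
        roi = SeedROI(np.zeros(3), 3.0, _sphere_mask(space, [0, 0, 0], 4.0))
        line = np.array([[-8.0, 0, 0], [8.0, 0, 0]])
        kept = filter_streamlines(StreamlineSet([line]), roi)
        assert len(kept) == 1

    def test_missing_structure_mask_dropped(self, space):
        # passes the sphere but the mask lives elsewhere
        roi = SeedROI(np.zeros(3), 3.0, _sphere_mask(space, [9, 9, 9], 2.0))
        line = np.array([[-8.0, 0, 0], [8.0, 0, 0]])
        assert len(filter_streamlines(StreamlineSet([line]), roi)) == 0

    def test_distance_boundary_against_bruteforce(self, space):
        # closest densified vertex at radius + 0.1 -> dropped
        roi = SeedROI(np.zeros(3), 3.0, _sphere_mask(space, [0, 0, 0], 9.0))
        line_out = np.array([[-8.0, 3.1, 0], [8.0, 3.1, 0]])
        line_in = np.array([[-8.0, 2.9, 0], [8.0, 2.9, 0]])
        # brute-force point-to-segment distances confirm the geometry
        for line, expected in ((line_out, 3.1), (line_in, 2.9)):
            verts = densify_vertices(line, 0.01)
            d = np.linalg.norm(verts, axis=1).min()
            assert d == pytest.approx(expected, abs=0.01)
        kept = filter_streamlines(StreamlineSet([line_out, line_in]), roi)
        assert len(kept) == 1
        assert np.array_equal(kept[0], line_in)

    def test_empty_input_warns(self, space):
        roi = SeedROI(np.zeros(3), 3.0, _sphere_mask(space, [0, 0, 0], 4.0))
        with pytest.warns(UserWarning, match="empty"):
            out = filter_streamlines(StreamlineSet([]), roi)
        assert len(out) == 0


class TestDensity:
    def test_straight_segment_counts_five_voxels(self, space):
        start = space.voxel_to_world(np.array([3.0, 6.0, 6.0]))
        start = start - np.array([1.0, 0.0, 0.0])  # on a voxel face
        line = np.array([start, start + [10.0, 0.0, 0.0]])
        img = density_image(StreamlineSet([line]), space)
        assert (np.asarray(img.data) > 0).sum() == 5
        assert img.data.max() == 1

    def test_duplicated_streamline_counts_twice(self, space):
        line = np.array([[-5.0, 1.0, 1.0], [5.0, 1.0, 1.0]])
        img = density_image(StreamlineSet([line, line.copy()]), space)
        assert img.data.max() == 2

    def test_loop_counts_once_per_voxel(self, space):
        # out and back through the same voxels: binary per streamline
        fwd = np.array([[-5.0, 1.0, 1.0], [5.0, 1.0, 1.0]])
        loop = np.vstack([fwd, fwd[::-1] + [0.0, 0.3, 0.0]])
        img_loop = density_image(StreamlineSet([loop]), space)
        img_fwd = density_image(StreamlineSet([fwd]), space)
        assert img_loop.data.max() == 1
        # brute-force voxel-visit oracle at fine sampling
        t = np.linspace(0, 1, 20001)
        visited = set()
        for a, b in zip(loop[:-1], loop[1:]):
            pts = a[None] + t[:, None] * (b - a)[None]
            vox = np.floor(space.world_to_voxel(pts) + 0.5).astype(int)
            visited |= {tuple(v) for v in vox}
        got = {tuple(v) for v in np.argwhere(np.asarray(img_loop.data) > 0)}
        assert got == visited
        assert set(map(tuple, np.argwhere(np.asarray(img_fwd.data) > 0))) \
            <= got

    def test_order_invariance_and_additivity(self, space):
        rng = np.random.default_rng(0)
        lines = [rng.uniform(-10, 10, size=(5, 3)) for _ in range(6)]
        full = density_image(StreamlineSet(lines), space)
        perm = density_image(StreamlineSet(lines[::-1]), space)
        assert np.array_equal(full.data, perm.data)
        a = density_image(StreamlineSet(lines[:3]), space)
        b = density_image(StreamlineSet(lines[3:]), space)
        assert np.array_equal(full.data, a.data + b.data)

    def test_flip_commutes_with_mirrored_counting(self, space):
        rng = np.random.default_rng(1)
        lines = [rng.uniform(-10, 10, size=(4, 3)) for _ in range(5)]
        mirrored = [l * np.array([-1.0, 1.0, 1.0]) for l in lines]
        count_then_flip = flip_midsagittal(
            density_image(StreamlineSet(lines), space))
        flip_then_count = density_image(StreamlineSet(mirrored), space)
        assert np.array_equal(count_then_flip.data, flip_then_count.data)


def _anova_cohort(space, seed, location_effect=0.0, blob=None):
    rng = np.random.default_rng(seed)
    rows, images = [], []
    for s in range(6):
        disease = "PDD" if s < 3 else "DLB"
        for side in ("right", "left"):
            for loc in ("NBM", "GP"):
                d = rng.poisson(6.0, size=space.shape).astype(float)
                if blob is not None and loc == "NBM":
                    d[blob] += location_effect
                images.append(space.copy_with(d))
                rows.append(dict(observation_id=f"s{s}_{side}_{loc}",
                                 subject=f"s{s}", side=side, location=loc,
                                 disease=disease))
    return images, pd.DataFrame(rows)


class TestDensityAnova:
    def test_contrast_antisymmetry_under_label_swap(self, space):
        images, table = _anova_cohort(space, 0, location_effect=3.0,
                                      blob=(slice(5, 7),) * 3)
        res = TractDensityANOVA(images, table).fit(n_perm=100, seed=0)
        swapped = table.copy()
        swapped["location"] = swapped["location"].map(
            {"NBM": "GP", "GP": "NBM"})
        res2 = TractDensityANOVA(images, swapped).fit(n_perm=100, seed=0)
        t1 = np.nan_to_num(res["location"]["t_image"].data)
        t2 = np.nan_to_num(res2["location"]["t_image"].data)
        assert np.allclose(t1, -t2, atol=1e-8)

    def test_planted_location_effect_recovered(self, space):
        blob = (slice(5, 7),) * 3
        images, table = _anova_cohort(space, 1, location_effect=6.0,
                                      blob=blob)
        res = TractDensityANOVA(images, table).fit(
            forming_p=0.01, n_perm=200, seed=1)
        cl = res["location"]["clusters"]
        sig = cl.significant(alpha=0.05)
        assert sig.size >= 1
        labels = np.asarray(cl.labels.data)
        blob_mask = np.zeros(space.shape, dtype=bool)
        blob_mask[blob] = True
        assert any(np.all(labels[blob_mask] == s) for s in sig)

    def test_rank_deficient_design_reports_aliased_columns(self, space):
        images, table = _anova_cohort(space, 2)
        # disease is constant within subject; making location constant
        # per subject aliases it with the subject indicators
        table = table[table["location"] == "NBM"].reset_index(drop=True)
        images = images[::2]
        table["location"] = ["NBM", "GP"] * (len(table) // 2)
        table["location"] = np.where(table["subject"].isin(["s0", "s1", "s2"]),
                                     "NBM", "GP")
        with pytest.raises(ValueError, match="aliased|two levels"):
            TractDensityANOVA(images, table).fit(n_perm=100)
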