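"""Colocalization statistics, co-moving tracks, ROI intensity ratios."""

import numpy as np
import pandas as pd
import pytest

from mirtrack.quantification import (
    ColocalizationResult,
    RegionMasks,
    colocalization_stats,
    extract_cotrajectories,
    region_intensity_ratio,
    retention_ratio,
)
from mirtrack.synthetic import simulate_two_channel_detections
from mirtrack.tracks import Trajectory


def dets(points):
    df = pd.DataFrame(points, columns=["frame", "x_um", "y_um"])
    df["quality"] = 1.0
    df["channel"] = "A"
    return df


class TestColocalization:
    def test_percentage_arithmetic_on_printed_counts(self):
        res = ColocalizationResult(n_total_A=59811, n_coloc=11364, radius=0.3, n_frames=9600)
        assert round(res.percentage) == 19
        res2 = ColocalizationResult(n_total_A=61693, n_coloc=1452, radius=0.3, n_frames=9600)
        assert np.floor(res2.percentage * 10) / 10 == 2.3

    def test_identical_sets_fully_colocalize(self, rng):
        d = dets([(f, x, y) for f in range(3) for x, y in rng.uniform(0, 10, (5, 2))])
        assert colocalization_stats(d, d.copy(), radius=0.01).percentage == 100.0

    def test_distant_clusters_do_not_colocalize(self):
        a = dets([(0, 1.0, 1.0), (0, 1.2, 1.1)])
        b = dets([(0, 50.0, 50.0)])
        assert colocalization_stats(a, b, radius=0.3).percentage == 0.0

    def test_monotone_in_radius(self, rng):
        a = dets([(f, x, y) for f in range(5) for x, y in rng.uniform(0, 10, (20, 2))])
        b = dets([(f, x, y) for f in range(5) for x, y in rng.uniform(0, 10, (20, 2))])
        pct = [colocalization_stats(a, b, r).percentage for r in (0.1, 0.3, 1.0, 3.0)]
        assert pct == sorted(pct)

    def test_planted_fraction_recovered_sparse(self):
        # 10^4 A-detections spread thin: chance pairing is negligible
        da, db = simulate_two_channel_detections(
            200, 50, 50, 0.19, jitter_sd=0.05, fov=(100.0, 100.0), seed=5
        )
        res = colocalization_stats(da, db, radius=0.3)
        assert res.n_total_A == 10_000
        assert res.percentage == pytest.approx(19.0, abs=2.0)

    def test_empty_channel_a_rejected(self):
        with pytest.raises(ValueError):
            colocalization_stats(dets([]), dets([(0, 1.0, 1.0)]), 0.3)


class TestCotrajectories:
    def make_track(self, tid, offset=0.0, frames=None):
        frames = np.arange(20) if frames is None else frames
        pos = np.column_stack([0.1 * frames + offset, np.ones(len(frames))])
        return Trajectory(tid, frames, pos, dt=0.05)

    def test_self_pair_selected_with_zero_distance(self):
        a = self.make_track("a")
        pairs = extract_cotrajectories([a], [self.make_track("b")], radius=0.3, min_overlap=5)
        assert len(pairs) == 1
        assert pairs[0].median_distance == 0.0
        assert pairs[0].n_overlap == 20

    def test_shifted_copy_beyond_radius_not_paired(self):
        a = self.make_track("a")
        b = self.make_track("b", offset=0.6)  # 2x radius
        assert extract_cotrajectories([a], [b], radius=0.3) == []

    def test_insufficient_overlap_not_paired(self):
        a = self.make_track("a")
        b = self.make_track("b", frames=np.arange(18, 22))
        assert extract_cotrajectories([a], [b], radius=0.3, min_overlap=5) == []

    def test_planted_pairs_recovered_without_spurious(self, rng):
        tracks_a, tracks_b = [], []
        for i in range(6):
            frames = np.arange(30)
            pos = np.cumsum(rng.normal(0, 0.05, (30, 2)), axis=0) + [5.0 * i, 0.0]
            tracks_a.append(Trajectory(f"a{i}", frames, pos, dt=0.05))
            if i < 3:  # only half get a co-moving partner
                jitter = rng.normal(0, 0.05, (30, 2))
                tracks_b.append(Trajectory(f"b{i}", frames, pos + jitter, dt=0.05))
            else:
                far = np.cumsum(rng.normal(0, 0.05, (30, 2)), axis=0) + [5.0 * i, 20.0]
                tracks_b.append(Trajectory(f"b{i}", frames, far, dt=0.05))
        pairs = extract_cotrajectories(tracks_a, tracks_b, radius=0.3, min_overlap=10)
        assert sorted((p.id_a, p.id_b) for p in pairs) == [(f"a{i}", f"b{i}") for i in range(3)]


def make_masks(shape=(60, 60)):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    cell = (xx - 30) ** 2 + (yy - 30) ** 2 <= 25**2
    nucleus = (xx - 30) ** 2 + (yy - 30) ** 2 <= 10**2
    pnr = ((xx - 30) ** 2 + (yy - 30) ** 2 <= 15**2) & ~nucleus
    background = ~((xx - 30) ** 2 + (yy - 30) ** 2 <= 28**2)
    return RegionMasks(
        {"cell": cell, "nucleus": nucleus, "perinuclear": pnr, "background": background}
    )


class TestRegionRatios:
    def test_uniform_image_gives_area_ratio(self):
        masks = RegionMasks(
            {
                "cell": np.ones((20, 20), bool),
                "quarter": np.pad(np.ones((10, 10), bool), ((0, 10), (0, 10))),
                "background": np.zeros((20, 20), bool),
            }
        )
        masks.masks["background"][0, 0] = True
        masks.masks["cell"][0, 0] = False
        masks.masks["quarter"][0, 0] = False
        img = np.full((20, 20), 50.0)
        img[0, 0] = 10.0  # background pixel
        ratio = region_intensity_ratio(img, masks, "quarter", "cell")
        assert ratio == pytest.approx(99 / 399, rel=1e-9)  # exact area ratio

    def test_flat_image_flags_empty_denominator(self):
        masks = make_masks()
        with pytest.raises(ValueError):
            region_intensity_ratio(np.full((60, 60), 3.0), masks, "perinuclear", "cell")

    def test_offset_invariance(self, rng):
        masks = make_masks()
        img = rng.poisson(20.0, size=(60, 60)).astype(float)
        img[masks["perinuclear"]] += 100
        r0 = region_intensity_ratio(img, masks, "perinuclear", "cell")
        r1 = region_intensity_ratio(img + 37.0, masks, "perinuclear", "cell")
        assert r0 == pytest.approx(r1, rel=1e-12)

    def test_planted_photon_budget_recovered(self):
        masks = make_masks()
        ratios = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            img = rng.poisson(5.0, size=(60, 60)).astype(float)
            pnr_idx = np.argwhere(masks["perinuclear"])
            rest_idx = np.argwhere(masks["cell"] & ~masks["perinuclear"])
            # plant 40% of 200k photons in the PNR, 60% elsewhere in the cell
            for idx, n in ((pnr_idx, 80_000), (rest_idx, 120_000)):
                hits = rng.integers(0, len(idx), size=n)
                np.add.at(img, tuple(idx[hits].T), 1.0)
            ratios.append(region_intensity_ratio(img, masks, "perinuclear", "cell"))
        assert np.mean(ratios) == pytest.approx(0.40, abs=0.02)

    def test_nucleus_outside_cell_rejected(self):
        with pytest.raises(ValueError):
            RegionMasks(
                {"cell": np.zeros((5, 5), bool), "nucleus": np.ones((5, 5), bool)}
            )

    def test_cytoplasm_derived_as_cell_minus_nucleus(self):
        masks = make_masks()
        assert "cytoplasm" in masks
        assert not np.any(masks["cytoplasm"] & masks["nucleus"])


class TestRetention:
    def test_identical_images_give_unity(self, rng):
        masks = make_masks()
        img = rng.poisson(30.0, size=(60, 60)).astype(float)
        img[masks["cell"]] += 50
        assert retention_ratio(img, img.copy(), masks) == pytest.approx(1.0)

    def test_background_only_late_image_gives_zero(self, rng):
        masks = make_masks()
        early = np.full((60, 60), 5.0)
        early[masks["cell"]] += 100
        late = np.full((60, 60), 5.0)
        assert retention_ratio(early, late, masks) == pytest.approx(0.0, abs=1e-6)

    def test_planted_retention_recovered(self):
        masks = make_masks()
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            cyt_idx = np.argwhere(masks["cytoplasm"])
            def image(n_photons):
                img = rng.poisson(5.0, size=(60, 60)).astype(float)
                hits = rng.integers(0, len(cyt_idx), size=n_photons)
                np.add.at(img, tuple(cyt_idx[hits].T), 1.0)
                return img
            vals.append(retention_ratio(image(200_000), image(110_000), masks))
        assert np.mean(vals) == pytest.approx(0.55, abs=0.02)
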