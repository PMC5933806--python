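"""Occlusion-based receptive-field mapping, unit selection, clustering."""

import numpy as np
import pytest

from navaff.receptive import (
    DiscrepancyMap,
    embed_and_cluster_units,
    map_discrepancy,
    segment_receptive_field,
    select_units,
)


class RegionUnit:
    """Adapter-contract provider: unit 0 averages a known 20x20 region."""

    input_size = (64, 64)

    def __init__(self, r0=20, c0=25):
        self.r0, self.c0 = r0, c0

    def forward(self, images):
        images = np.asarray(images, dtype=float)
        if images.ndim == 2:
            images = images[None]
        act = images[:, self.r0: self.r0 + 20,
                     self.c0: self.c0 + 20].mean(axis=(1, 2))
        return {"unit": act[:, None]}


class TestMapDiscrepancy:
    def test_zero_outside_unit_support(self):
        provider = RegionUnit(0, 0)  # region rows/cols 0..19
        img = np.random.default_rng(0).uniform(0, 0.2, (64, 64))
        maps = map_discrepancy(provider, img, "unit", [0], patch_size=11,
                               stride=3, seed=0)
        m = maps[0].values
        # occluders starting at row >= 20 never touch the region
        assert np.all(m[31:, 31:] == 0.0)
        assert m[:20, :20].max() > 0

    def test_grid_arithmetic(self):
        provider = RegionUnit()
        img = np.zeros((64, 64))
        maps = map_discrepancy(provider, img, "unit", [0], patch_size=11,
                               stride=3, seed=0)
        n_axis = (64 - 11) // 3 + 1
        assert maps[0].grid.shape == (n_axis**2, 2)

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            map_discrepancy(RegionUnit(), np.zeros((64, 64)), "unit", [3],
                            seed=0)

    def test_planted_region_recovered(self):
        provider = RegionUnit()
        rng = np.random.default_rng(1)
        hits = 0
        for i in range(20):
            img = rng.uniform(0.0, 0.15, (64, 64))
            m = map_discrepancy(provider, img, "unit", [0], patch_size=11,
                                stride=3, seed=i)[0]
            pr, pc = np.unravel_index(np.argmax(m.values), m.values.shape)
            hits += (20 <= pr < 40) and (25 <= pc < 45)
        assert hits >= 19


class TestSelectUnits:
    def test_planted_readout_ranks_first(self, battery):
        rng = np.random.default_rng(0)
        base = np.stack([h.normalized for h in battery["histograms"]])
        target = battery["affordance_rdm"]
        # unit 7 is a noiseless linear readout of the histograms
        acts = rng.standard_normal((base.shape[0], 12))
        readout = base @ rng.standard_normal(base.shape[1])
        acts[:, 7] = readout
        sel = select_units(acts, target, target, n=3)
        assert sel.unit_ids[0] == 7

    def test_full_selection_is_identity(self, battery):
        rng = np.random.default_rng(1)
        target = battery["affordance_rdm"]
        acts = rng.standard_normal((target.n_conditions, 6))
        sel = select_units(acts, target, target, n=6)
        assert sorted(sel.unit_ids.tolist()) == list(range(6))

    def test_constant_units_ranked_last(self, battery):
        rng = np.random.default_rng(2)
        target = battery["affordance_rdm"]
        acts = rng.standard_normal((target.n_conditions, 5))
        acts[:, 2] = 1.0
        sel = select_units(acts, target, target, n=5)
        assert sel.unit_ids[-1] == 2


class TestSegmentation:
    def test_gaussian_bump_mask_is_connected_superlevel_set(self):
        r, c = np.mgrid[0:60, 0:60]
        bump = np.exp(-((r - 30) ** 2 + (c - 35) ** 2) / 40.0)
        m = DiscrepancyMap(values=bump, unit_id=0)
        seg, _ = segment_receptive_field(m, smooth=5)
        from scipy.ndimage import label

        n_components = label(seg.mask)[1]
        assert n_components == 1
        pr, pc = np.unravel_index(np.argmax(m.smoothed(5)), bump.shape)
        assert seg.mask[pr, pc]

    def test_threshold_boundary_inclusive(self):
        vals = np.zeros((40, 40))
        vals[10, 10] = 1.0
        m = DiscrepancyMap(values=vals, unit_id=0)
        seg, _ = segment_receptive_field(m, smooth=1)
        # the raw map has a single pixel at peak; with no smoothing, only
        # pixels >= 10% of the peak are kept, and the peak itself qualifies
        assert seg.mask[10, 10]
        assert seg.threshold_value == pytest.approx(0.1)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, (30, 30))
        m1 = DiscrepancyMap(values=vals, unit_id=0)
        m2 = DiscrepancyMap(values=vals * 37.5, unit_id=0)
        s1, _ = segment_receptive_field(m1)
        s2, _ = segment_receptive_field(m2)
        assert np.array_equal(s1.mask, s2.mask)

    def test_all_zero_map_flagged_empty(self):
        m = DiscrepancyMap(values=np.zeros((20, 20)), unit_id=0)
        seg, composite = segment_receptive_field(m)
        assert seg.empty
        assert not seg.mask.any()

    def test_composite_darkens_outside_mask(self):
        rng = np.random.default_rng(1)
        vals = np.zeros((40, 40))
        vals[15:25, 15:25] = 1.0
        m = DiscrepancyMap(values=vals, unit_id=0)
        img = np.full((40, 40), 0.8)
        seg, composite = segment_receptive_field(m, image=img, smooth=3)
        outside = ~seg.mask & ~seg.outline
        assert np.all(composite[outside] < 0.5)
        assert np.all(composite[seg.outline] == (1.0, 0.0, 0.0))


class _PatternProvider:
    """Responds to the mean intensity pattern; used for cluster planting."""

    input_size = (64, 64)

    def forward(self, images):
        arrs = [np.asarray(getattr(im, "pixels", im), dtype=float)
                for im in (images if isinstance(images, (list, tuple))
                           else list(images))]
        feats = []
        for a in arrs:
            h, w = a.shape
            feats.append([
                a[: h // 2].mean(), a[h // 2:].mean(),
                a[:, : w // 2].mean(), a[:, w // 2:].mean(),
            ])
        return {"feat": np.asarray(feats)}


class TestEmbedAndCluster:
    def _maps_for(self, peaks, shape=(64, 64)):
        maps = []
        for i, (pr, pc) in enumerate(peaks):
            vals = np.zeros(shape)
            vals[pr, pc] = 1.0
            m = DiscrepancyMap(values=vals, unit_id=0)
            m.image_id = i
            maps.append(m)
        return maps

    def test_two_planted_families_recovered(self):
        # family A units respond to bright-top content, family B to
        # bright-bottom content; per-unit peak jitter keeps the response
        # vectors distinct within a family
        rng = np.random.default_rng(0)
        images = []
        for i in range(6):
            img = rng.uniform(0.0, 0.1, (64, 64))
            if i < 3:
                img[:32] += 0.9  # bright top
            else:
                img[32:] += 0.9  # bright bottom
            images.append(img)
        unit_maps = {}
        for u in range(6):
            img_ids = (0, 1, 2) if u < 3 else (3, 4, 5)
            base_peak = (14 + u, 28 + 2 * u) if u < 3 else (47 + (u - 3),
                                                            30 + 2 * u)
            maps = []
            for img_id in img_ids:
                vals = np.zeros((64, 64))
                vals[base_peak] = 1.0
                m = DiscrepancyMap(values=vals, unit_id=u)
                m.image_id = img_id
                maps.append(m)
            unit_maps[u] = maps
        out = embed_and_cluster_units(unit_maps, images, _PatternProvider(),
                                      "feat", patch=33, k_range=range(2, 5),
                                      seed=0)
        assert out.k == 2
        labels = out.labels
        assert len(set(labels[:3])) == 1
        assert len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_identical_units_flagged_degenerate(self):
        img = np.full((64, 64), 0.5)
        unit_maps = {}
        for u in range(4):
            maps = self._maps_for([(10, 10)] * 3)
            unit_maps[u] = maps
        out = embed_and_cluster_units(unit_maps, [img, img, img],
                                      _PatternProvider(), "feat", patch=33,
                                      seed=0)
        assert out.degenerate
        assert out.k == 1

    def test_too_few_maps_rejected(self):
        unit_maps = {0: self._maps_for([(1, 1)]),
                     1: self._maps_for([(1, 1)] * 3),
                     2: self._maps_for([(1, 1)] * 3)}
        with pytest.raises(ValueError, match="at least 3"):
            embed_and_cluster_units(unit_maps, [np.zeros((64, 64))] * 3,
                                    _PatternProvider(), "feat")
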