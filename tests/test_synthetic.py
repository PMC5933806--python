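"""Generators: scene rendering, rater paths, cohorts, labeled activations."""

import numpy as np
import pytest

from navaff.affordance import bin_paths
from navaff.rdm import compute_rdm, normalize_fmri
from navaff.inference import spearman_rsa
from navaff.synthetic import (
    SceneSpec,
    generate_cohort,
    generate_labeled_activations,
    render_scene,
    simulate_rater_paths,
)


class TestRenderScene:
    def test_deterministic(self):
        spec = SceneSpec(image_size=(101, 101), opening_azimuths=(70.0,))
        a, b = render_scene(spec), render_scene(spec)
        assert np.array_equal(a.pixels, b.pixels)

    def test_mirror_commutes(self):
        spec = SceneSpec(
            image_size=(101, 101), opening_azimuths=(60.0, 120.0),
            opening_widths=(16.0, 20.0),
        )
        img = render_scene(spec).pixels
        mirrored = render_scene(spec.mirrored()).pixels
        assert np.array_equal(img[:, ::-1], mirrored)

    def test_centered_doorway_is_symmetric(self):
        spec = SceneSpec(image_size=(101, 101), opening_azimuths=(90.0,))
        img = render_scene(spec).pixels
        assert np.array_equal(img, img[:, ::-1])

    def test_ground_truth_returned_verbatim(self):
        spec = SceneSpec(opening_azimuths=(45.0, 135.0), image_size=(101, 101))
        assert render_scene(spec).azimuths == (45.0, 135.0)

    def test_overlapping_openings_rejected_with_azimuths(self):
        spec = SceneSpec(
            image_size=(227, 227), opening_azimuths=(88.0, 92.0),
            opening_widths=30.0,
        )
        with pytest.raises(ValueError, match="88.*92|92.*88"):
            render_scene(spec)

    def test_doorway_brightens_wall(self):
        with_door = render_scene(SceneSpec(image_size=(101, 101),
                                           opening_azimuths=(90.0,)))
        # door pixels should be the brightest region in the image
        assert with_door.pixels.max() == pytest.approx(
            with_door.spec.door_luminance, abs=0.01)


class TestRaterPaths:
    def test_straight_ahead_stays_on_origin_column(self):
        hm = simulate_rater_paths([90.0], 5, 0.0, (64, 64), seed=0,
                                  blur_sigma=0)
        col_mass = hm.values.sum(axis=0)
        assert col_mass[32] == pytest.approx(hm.values.sum())

    def test_unit_mass_per_rater(self):
        # mass conservation: total equals n_raters x per-path mass (1.0)
        hm = simulate_rater_paths([60.0, 120.0], 10, 0.0, (64, 64), seed=0,
                                  blur_sigma=0)
        assert hm.values.sum() == pytest.approx(10.0)

    def test_even_raters_split_mass_between_two_rays(self):
        hm = simulate_rater_paths([45.0, 135.0], 8, 0.0, (81, 81), seed=0,
                                  blur_sigma=0)
        left = hm.values[:, : 40].sum()
        right = hm.values[:, 41:].sum()
        assert left == pytest.approx(right)

    def test_histogram_peaks_near_truth(self):
        # Monte-Carlo with the generator itself: at 5-degree rater noise and
        # 100 raters, the peak of a 1-degree-binned 50-draw sample wobbles by
        # a few degrees; the smoothed top-2 peaks stay within 4 degrees of
        # the true azimuths in >= 95% of replicates
        from navaff.affordance import histogram_from_map

        hits = 0
        reps = 40
        for seed in range(reps):
            hm = simulate_rater_paths([60.0, 130.0], 100, 5.0, (227, 227),
                                      seed=seed)
            sm = histogram_from_map(hm.values).smoothed.copy()
            top2 = []
            for _ in range(2):
                b = int(np.argmax(sm))
                top2.append(b + 0.5)
                sm[max(0, b - 15): b + 15] = -np.inf  # suppress found peak
            errs = [min(abs(t - a) for a in (60.0, 130.0)) for t in top2]
            hits += max(errs) <= 4.0
        assert hits / reps >= 0.95

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            simulate_rater_paths([], 5, 0.0, (64, 64), seed=0)

    def test_deterministic(self):
        a = simulate_rater_paths([80.0], 20, 5.0, (64, 64), seed=7)
        b = simulate_rater_paths([80.0], 20, 5.0, (64, 64), seed=7)
        assert np.array_equal(a.values, b.values)


class TestCohort:
    def test_zero_noise_reconstructs_target(self, battery):
        target = battery["affordance_rdm"]
        labels = battery["labels"]
        cohort = generate_cohort(target, 2, 2, 64, 0.0, seed=0)
        for s in range(2):
            avg = cohort.patterns[s].mean(axis=0)
            rec = compute_rdm(avg, labels)
            scale = (rec.vector() @ target.vector()) / (
                target.vector() @ target.vector())
            assert scale > 0
            dev = np.abs(rec.values - scale * target.values).max()
            assert dev < 1e-6 * target.values.max()

    def test_zero_noise_subjects_identical(self, battery):
        cohort = generate_cohort(battery["affordance_rdm"], 2, 1, 64, 0.0,
                                 seed=3)
        assert np.array_equal(cohort.patterns[0], cohort.patterns[1])

    @pytest.mark.parametrize("voxel_map", ["qr", "hadamard"])
    def test_voxel_map_is_isometry(self, battery, voxel_map):
        target = battery["affordance_rdm"]
        cohort = generate_cohort(target, 1, 1, 64, 0.0, seed=1,
                                 voxel_map=voxel_map)
        rec = compute_rdm(cohort.patterns[0, 0], battery["labels"])
        assert np.allclose(rec.values, target.values, atol=1e-8)

    def test_non_embeddable_rdm_reports_eigenvalue(self):
        # violate the triangle inequality strongly enough to break PSD
        from navaff.rdm import RDM

        d = np.array([
            [0.0, 1.0, 1.0, 25.0],
            [1.0, 0.0, 1.0, 1.0],
            [1.0, 1.0, 0.0, 1.0],
            [25.0, 1.0, 1.0, 0.0],
        ])
        bad = RDM(d, ["a", "b", "c", "d"])
        with pytest.raises(ValueError, match="eigenvalue"):
            generate_cohort(bad, 1, 1, 8, 0.0, seed=0)

    def test_recovery_degrades_with_noise(self, battery):
        target = battery["affordance_rdm"]
        labels = battery["labels"]
        mean_rho = []
        for noise in (0.0, 1.0, 3.0):
            rhos = []
            for seed in range(10):
                cohort = generate_cohort(target, 2, 2, 64, noise, seed=seed)
                grp = np.mean([
                    compute_rdm(cohort.patterns[s].mean(axis=0), labels).values
                    for s in range(2)
                ], axis=0)
                from navaff.rdm import RDM

                rhos.append(spearman_rsa(RDM(grp, labels), target))
            mean_rho.append(np.mean(rhos))
        assert mean_rho[0] > mean_rho[1] > mean_rho[2]


class TestLabeledActivations:
    def test_deterministic(self):
        a = generate_labeled_activations(seed=5)
        b = generate_labeled_activations(seed=5)
        assert np.array_equal(a.activations, b.activations)
        assert a.labels.equals(b.labels)

    def test_balanced_classes(self):
        lab = generate_labeled_activations(100, 200, 20, 2.0, n_properties=3,
                                           seed=0)
        for col in lab.labels:
            counts = lab.labels[col].value_counts()
            assert counts["low"] == counts["high"] == 50

    def test_odd_image_count_rejected(self):
        with pytest.raises(ValueError, match="balanced"):
            generate_labeled_activations(n_images=99)

    def test_informative_subset_within_range(self):
        lab = generate_labeled_activations(50, 100, 10, 1.0, seed=2)
        assert lab.informative_units.size == 10
        assert lab.informative_units.max() < 100

    def test_too_many_informative_rejected(self):
        with pytest.raises(ValueError):
            generate_labeled_activations(n_units=10, n_informative=11)
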