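"""RSA statistics: correlation, resampling, permutation, commonality."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from navaff.rdm import RDM, compute_rdm
from navaff.inference import (
    bonferroni,
    bootstrap_se,
    bootstrap_sv_contrast,
    commonality,
    noise_ceiling,
    permutation_test,
    regression_rsa,
    spearman_rsa,
)


def _rdm_from(values, labels=None):
    n = values.shape[0]
    labels = labels or [f"c{i}" for i in range(n)]
    return RDM(values, labels)


class TestSpearman:
    def test_self_correlation_is_one(self, random_rdm_pair):
        a, _ = random_rdm_pair(0)
        assert spearman_rsa(a, a) == pytest.approx(1.0)

    def test_monotone_invariance(self, random_rdm_pair):
        a, _ = random_rdm_pair(1)
        exp = _rdm_from(np.exp(a.values) - 1.0, list(a.labels))
        assert spearman_rsa(a, exp) == pytest.approx(1.0)

    def test_four_condition_hand_ranked_pair(self):
        # upper triangles: a -> (1, 2, 3, 4, 5, 6); b -> (2, 1, 3, 4, 6, 5)
        def build(vec):
            m = np.zeros((4, 4))
            m[np.triu_indices(4, 1)] = vec
            return _rdm_from(m + m.T)

        a = build(np.array([1.0, 2, 3, 4, 5, 6]))
        b = build(np.array([2.0, 1, 3, 4, 6, 5]))
        # hand computation: rank displacement d = (1,-1,0,0,1,-1)
        # rho = 1 - 6*sum(d^2)/(6*35) = 1 - 24/210
        assert spearman_rsa(a, b) == pytest.approx(1 - 24 / 210)

    def test_constant_rdm_flagged_nan(self):
        const = _rdm_from(np.ones((5, 5)) - np.eye(5))
        rng = np.random.default_rng(0)
        other = compute_rdm(rng.standard_normal((5, 3)),
                            [f"c{i}" for i in range(5)])
        assert np.isnan(spearman_rsa(const, other))


class TestBootstrap:
    def test_identical_rdms_zero_se(self, random_rdm_pair):
        a, _ = random_rdm_pair(0)
        assert bootstrap_se(a, a, n_iterations=50, seed=0) == 0.0

    def test_full_fraction_degenerate_zero_se(self, random_rdm_pair):
        a, b = random_rdm_pair(1)
        assert bootstrap_se(a, b, n_iterations=50, fraction=1.0, seed=0) == 0.0

    def test_se_shrinks_with_condition_count(self):
        rng = np.random.default_rng(0)
        ses = []
        for n in (10, 50):
            labels = [f"c{i}" for i in range(n)]
            base = rng.standard_normal((n, 12))
            a = compute_rdm(base, labels)
            b = compute_rdm(base + 0.6 * rng.standard_normal(base.shape),
                            labels)
            ses.append(bootstrap_se(a, b, n_iterations=300, seed=1))
        assert ses[1] < ses[0]

    def test_too_small_subset_rejected(self, random_rdm_pair):
        a, b = random_rdm_pair(2)
        with pytest.raises(ValueError):
            bootstrap_se(a.subset(np.arange(4)), b.subset(np.arange(4)),
                         fraction=0.5)


class TestPermutation:
    def test_minimum_p_at_formula_floor(self, battery):
        # a strong true effect beats every permutation: p = 1/(N+1)
        target = battery["affordance_rdm"]
        res = permutation_test(target, target, n_iterations=200, seed=0)
        assert res.p_value == pytest.approx(1 / 201)

    def test_deterministic_under_seed(self, random_rdm_pair):
        a, b = random_rdm_pair(3)
        p1 = permutation_test(a, b, 100, seed=9).p_value
        p2 = permutation_test(a, b, 100, seed=9).p_value
        assert p1 == p2

    def test_small_rdm_rejected(self):
        tiny = _rdm_from(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            permutation_test(tiny, tiny)


class TestBonferroni:
    @pytest.mark.parametrize("p, m, expected", [
        (0.01, 5, 0.05),
        (0.5, 4, 1.0),
        (0.2, 1, 0.2),
    ])
    def test_values(self, p, m, expected):
        assert bonferroni([p], m) == [pytest.approx(expected)]

    def test_m_smaller_than_list_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], m=1)


class TestNoiseCeiling:
    def test_identical_subjects_ceiling_one(self, random_rdm_pair):
        a, _ = random_rdm_pair(0)
        nc = noise_ceiling([a, a, a])
        assert nc.value == pytest.approx(1.0)

    def test_two_subject_hand_example(self, random_rdm_pair):
        a, b = random_rdm_pair(1)
        nc = noise_ceiling([a, b])
        from navaff.rdm import group_rdm

        grp = group_rdm([a, b])
        expected = 0.5 * (spearman_rsa(a, grp) + spearman_rsa(b, grp))
        assert nc.value == pytest.approx(expected)
        assert nc.value == pytest.approx(float(np.mean(nc.per_subject)))

    def test_ceiling_decreases_with_noise(self, battery):
        from navaff.rdm import normalize_fmri
        from navaff.synthetic import generate_cohort

        target = battery["affordance_rdm"]
        labels = battery["labels"]
        vals = []
        for noise in (0.2, 1.0, 3.0):
            per = []
            for seed in range(5):
                cohort = generate_cohort(target, 4, 2, 64, noise, seed=seed)
                subj = [
                    compute_rdm(normalize_fmri(cohort.subject_runs(s)), labels)
                    for s in range(4)
                ]
                per.append(noise_ceiling(subj).value)
            vals.append(np.mean(per))
        assert vals[0] > vals[1] > vals[2]

    def test_single_subject_rejected(self, random_rdm_pair):
        a, _ = random_rdm_pair(2)
        with pytest.raises(ValueError):
            noise_ceiling([a])


class TestRegressionRSA:
    def test_single_predictor_r2_is_squared_pearson(self, random_rdm_pair):
        a, b = random_rdm_pair(0)
        res = regression_rsa(a, [b])
        r = np.corrcoef(a.vector(), b.vector())[0, 1]
        assert res.r2 == pytest.approx(r**2, abs=1e-12)

    def test_exact_affine_relation(self, random_rdm_pair):
        a, _ = random_rdm_pair(1)
        target = _rdm_from(2.0 * a.values + 3.0 * (1 - np.eye(a.n_conditions)),
                           list(a.labels))
        res = regression_rsa(target, [a])
        assert res.r2 == pytest.approx(1.0)
        assert res.coefficients[0] == pytest.approx(2.0)
        assert res.coefficients[1] == pytest.approx(3.0)

    def test_orthogonal_predictors_add_r2(self):
        rng = np.random.default_rng(0)
        n = 10
        labels = [f"c{i}" for i in range(n)]
        a = compute_rdm(rng.standard_normal((n, 6)), labels)
        b = compute_rdm(rng.standard_normal((n, 6)), labels)
        # orthogonalize b's vector against a's (centered)
        va = a.vector() - a.vector().mean()
        vb = b.vector() - b.vector().mean()
        vb = vb - (vb @ va) / (va @ va) * va
        m = np.zeros((n, n))
        m[np.triu_indices(n, 1)] = vb - vb.min() + 1.0
        b_orth = _rdm_from(m + m.T, labels)
        y = compute_rdm(rng.standard_normal((n, 6)), labels)
        r2_a = regression_rsa(y, [a]).r2
        r2_b = regression_rsa(y, [b_orth]).r2
        r2_ab = regression_rsa(y, [a, b_orth]).r2
        assert r2_ab == pytest.approx(r2_a + r2_b, abs=1e-10)

    def test_collinear_predictors_rejected(self, random_rdm_pair):
        a, b = random_rdm_pair(2)
        dup = _rdm_from(2.0 * b.values, list(b.labels))
        with pytest.raises(ValueError, match="collinear"):
            regression_rsa(a, [b, dup])


class TestCommonality:
    def test_identity_on_random_triples(self, random_rdm_pair):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            labels = [f"c{i}" for i in range(8)]
            t, x1, x2 = (compute_rdm(rng.standard_normal((8, 5)), labels)
                         for _ in range(3))
            res = commonality(t, x1, x2)
            assert res.gamma1 + res.gamma2 + res.gamma12 == pytest.approx(
                res.r2_full, abs=1e-10)
            assert res.gamma1 == pytest.approx(res.r2_full - res.r2_x2,
                                               abs=1e-12)
            assert res.gamma12 == pytest.approx(
                res.r2_x1 + res.r2_x2 - res.r2_full, abs=1e-12)

    def test_duplicate_predictor_sv_100(self, random_rdm_pair):
        t, x = random_rdm_pair(0)
        res = commonality(t, x, x)
        assert res.gamma1 == pytest.approx(0.0, abs=1e-12)
        assert res.shared_variance_pct == pytest.approx(100.0)

    def test_orthogonal_predictor_sv_near_zero(self):
        rng = np.random.default_rng(1)
        n = 12
        labels = [f"c{i}" for i in range(n)]
        x1 = compute_rdm(rng.standard_normal((n, 6)), labels)
        t = compute_rdm(rng.standard_normal((n, 6)), labels)
        v1 = x1.vector() - x1.vector().mean()
        v2 = rng.standard_normal(v1.size)
        v2 -= (v2 @ v1) / (v1 @ v1) * v1
        # also orthogonalize against the target so gamma12 ~ 0
        vt = t.vector() - t.vector().mean()
        v2 -= (v2 @ vt) / (vt @ vt) * vt
        m = np.zeros((n, n))
        m[np.triu_indices(n, 1)] = v2 - v2.min() + 1.0
        x2 = _rdm_from(m + m.T, labels)
        res = commonality(t, x1, x2)
        assert abs(res.shared_variance_pct) < 5.0

    def test_worked_numeric_decomposition(self):
        # R2_12 = 0.60, R2_1 = 0.50, R2_2 = 0.30
        g1 = 0.60 - 0.30
        g12 = 0.50 + 0.30 - 0.60
        assert g1 == pytest.approx(0.30)
        assert g12 == pytest.approx(0.20)
        assert 100 * g12 / (g12 + g1) == pytest.approx(40.0)

    def test_useless_x1_flagged_undefined(self):
        rng = np.random.default_rng(2)
        n = 8
        labels = [f"c{i}" for i in range(n)]
        t = compute_rdm(rng.standard_normal((n, 4)), labels)
        const = _rdm_from(np.ones((n, n)) - np.eye(n), labels)
        res = commonality(t, const, const)
        assert not res.sv_defined
        assert np.isnan(res.shared_variance_pct)


class TestSVContrast:
    def test_identical_contenders_degenerate_at_zero(self, random_rdm_pair):
        t, x1 = random_rdm_pair(0)
        _, x2 = random_rdm_pair(1)
        out = bootstrap_sv_contrast(t, x1, x2, x2, n_iterations=50, seed=0)
        assert out["lower_95_one_tailed"] == 0.0
        assert not out["significant"]

    def test_planted_contrast_positive(self):
        rng = np.random.default_rng(3)
        n = 16
        labels = [f"c{i}" for i in range(n)]
        base = rng.standard_normal((n, 8))
        t = compute_rdm(base, labels)
        x1 = compute_rdm(base + 0.2 * rng.standard_normal(base.shape), labels)
        matched = compute_rdm(base + 0.2 * rng.standard_normal(base.shape),
                              labels)
        unrelated = compute_rdm(rng.standard_normal((n, 8)), labels)
        out = bootstrap_sv_contrast(t, x1, matched, unrelated,
                                    n_iterations=200, seed=0)
        assert out["lower_95_one_tailed"] > 0
        assert out["significant"]

    def test_deterministic(self, random_rdm_pair):
        t, x1 = random_rdm_pair(4)
        a, b = random_rdm_pair(5)
        o1 = bootstrap_sv_contrast(t, x1, a, b, n_iterations=80, seed=2)
        o2 = bootstrap_sv_contrast(t, x1, a, b, n_iterations=80, seed=2)
        assert o1["lower_95_one_tailed"] == o2["lower_95_one_tailed"]


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_commonality_identity_property(seed):
    """gamma1 + gamma2 + gamma12 == R^2_full for arbitrary RDM triples."""
    rng = np.random.default_rng(seed)
    labels = [f"c{i}" for i in range(7)]
    t, x1, x2 = (compute_rdm(rng.standard_normal((7, 4)), labels)
                 for _ in range(3))
    res = commonality(t, x1, x2)
    assert res.gamma1 + res.gamma2 + res.gamma12 == pytest.approx(
        res.r2_full, abs=1e-10)
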