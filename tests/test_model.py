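from fractions import Fraction

import numpy as np
import pytest

from pctpoly.binning import BinGrid, build_bin_grid, fill_empty_bins
from pctpoly.model import (
    InterpolationModel,
    PolynomialModel,
    RegionModelSet,
    evaluate_model,
    fit_polynomial,
    monomial_exponents,
    predict_pct,
    predict_pct_per_bin,
    train_region_models,
)
from pctpoly.synthetic import PhantomSpec, generate_phantom
from pctpoly.volumes import SOFT, ImageVolume, RegionLabelMap


def _full_grid(nbin, axis_max, value_fn, counts=None):
    """Grid with every bin filled: mean = value_fn(center1, center2)."""
    c1 = (np.arange(nbin) + 0.5) * axis_max[0] / nbin
    c2 = (np.arange(nbin) + 0.5) * axis_max[1] / nbin
    cc1, cc2 = np.meshgrid(c1, c2, indexing="ij")
    mean_ct = value_fn(cc1, cc2)
    if counts is None:
        counts = np.ones((nbin, nbin), dtype=int)
    return BinGrid(
        nbin=nbin,
        axis_max=axis_max,
        counts=counts,
        mean_ct=mean_ct.astype(float),
        filled=counts > 0,
        weights=counts.astype(float),
        imputed=True,
    )


class TestMonomials:
    def test_count(self):
        for n in (0, 1, 2, 5, 30):
            assert len(monomial_exponents(n)) == (n + 1) * (n + 2) // 2

    def test_lexicographic(self):
        assert monomial_exponents(2) == [(0, 0), (0, 1), (0, 2), (1, 0), (1, 1), (2, 0)]


class TestFitPolynomial:
    def test_constant_grid(self):
        g = _full_grid(10, (100.0, 100.0), lambda a, b: np.full_like(a, 40.0))
        for degree in (0, 3, 8):
            m = fit_polynomial(g, degree)
            q = np.linspace(0, 100, 13)
            qq1, qq2 = np.meshgrid(q, q)
            assert np.max(np.abs(m.evaluate(qq1, qq2) - 40.0)) < 1e-6

    def test_plane_exact(self):
        s1max, s2max = 200.0, 50.0
        g = _full_grid(12, (s1max, s2max), lambda a, b: 100 * a / s1max + 50 * b / s2max)
        m = fit_polynomial(g, 1)
        c1, c2 = np.meshgrid(g.centers(0), g.centers(1), indexing="ij")
        assert np.mean(np.abs(m.evaluate(c1, c2) - g.mean_ct)) < 1e-6

    def test_quadratic_matches_exact_normal_equations(self):
        # oracle: normal equations solved in exact rational arithmetic
        rng = np.random.default_rng(11)
        nbin = 20
        counts = rng.integers(1, 100, (nbin, nbin))
        g = _full_grid(
            nbin,
            (1.0, 1.0),
            lambda a, b: 500 - 300 * a + 200 * b + 150 * a * b - 80 * a**2 + 40 * b**2
            + rng.normal(0, 5, (nbin, nbin)),
            counts=counts,
        )
        degree = 2
        m = fit_polynomial(g, degree)

        exps = monomial_exponents(degree)
        u = [(Fraction(i) + Fraction(1, 2)) / nbin for i in range(nbin)]
        rows, targets, weights = [], [], []
        for i in range(nbin):
            for j in range(nbin):
                rows.append([u[i] ** a * u[j] ** b for a, b in exps])
                targets.append(Fraction(g.mean_ct[i, j]))
                weights.append(Fraction(int(counts[i, j])))
        k = len(exps)
        ata = [[sum(w * r[a] * r[b] for w, r in zip(weights, rows)) for b in range(k)] for a in range(k)]
        atb = [sum(w * r[a] * t for w, r, t in zip(weights, rows, targets)) for a in range(k)]
        coeffs = _solve_exact(ata, atb)

        c1, c2 = np.meshgrid(g.centers(0), g.centers(1), indexing="ij")
        fitted = m.evaluate(c1, c2)
        oracle = np.zeros((nbin, nbin))
        for (a, b), c in zip(exps, coeffs):
            oracle += float(c) * (c1**a) * (c2**b)
        np.testing.assert_allclose(fitted, oracle, rtol=1e-8)

    def test_residual_non_increasing_in_degree(self, rng):
        g = _full_grid(15, (1.0, 1.0), lambda a, b: np.sin(3 * a) * 100 + 50 * b**3)
        prev = np.inf
        for degree in range(0, 7):
            m = fit_polynomial(g, degree)
            c1, c2 = np.meshgrid(g.centers(0), g.centers(1), indexing="ij")
            res = float(np.sum((m.evaluate(c1, c2) - g.mean_ct) ** 2))
            assert res <= prev + 1e-8
            prev = res

    def test_unimputed_grid_rejected(self, rng):
        g = build_bin_grid(s1=rng.uniform(0, 1, 50), s2=rng.uniform(0, 1, 50),
                           ct=rng.normal(size=50), nbin=20, axis_max=(1.0, 1.0))
        with pytest.raises(ValueError, match="fill_empty_bins"):
            fit_polynomial(g, 2)

    def test_all_zero_weights_rejected(self):
        g = _full_grid(4, (1.0, 1.0), lambda a, b: a + b)
        g.weights = np.zeros_like(g.weights)
        with pytest.raises(ValueError, match="weight"):
            fit_polynomial(g, 1)


def _solve_exact(ata, atb):
    """Gaussian elimination over Fractions (extended-precision oracle)."""
    n = len(atb)
    aug = [row[:] + [atb[i]] for i, row in enumerate(ata)]
    for col in range(n):
        piv = max(range(col, n), key=lambda r: abs(aug[r][col]))
        aug[col], aug[piv] = aug[piv], aug[col]
        for r in range(n):
            if r != col and aug[r][col] != 0:
                f = aug[r][col] / aug[col][col]
                aug[r] = [x - f * y for x, y in zip(aug[r], aug[col])]
    return [aug[i][n] / aug[i][i] for i in range(n)]


class TestEvaluateModel:
    def test_clamp_high(self):
        m = PolynomialModel(degree=0, coeffs=[2500.0], input_scale=(1.0, 1.0))
        assert evaluate_model(m, 0.5, 0.5) == 2000.0

    def test_clamp_low(self):
        m = PolynomialModel(degree=0, coeffs=[-1500.0], input_scale=(1.0, 1.0))
        assert evaluate_model(m, 0.5, 0.5) == -1000.0

    def test_interpolation_at_bin_center(self, rng):
        g = fill_empty_bins(
            build_bin_grid(
                s1=rng.uniform(0, 1, 2000), s2=rng.uniform(0, 1, 2000),
                ct=rng.normal(100, 200, 2000), nbin=6, axis_max=(1.0, 1.0),
            )
        )
        m = InterpolationModel(grid=g)
        for i in (0, 2, 5):
            for j in (1, 3, 4):
                c1 = g.centers(0)[i]
                c2 = g.centers(1)[j]
                assert m.evaluate(c1, c2) == pytest.approx(
                    np.clip(g.mean_ct[i, j], -1000, 2000), rel=1e-12
                )

    def test_interpolation_clamps_to_hull(self, rng):
        g = fill_empty_bins(
            build_bin_grid(
                s1=rng.uniform(0, 1, 500), s2=rng.uniform(0, 1, 500),
                ct=rng.normal(0, 100, 500), nbin=4, axis_max=(1.0, 1.0),
            )
        )
        m = InterpolationModel(grid=g)
        assert m.evaluate(0.0, 0.0) == pytest.approx(float(np.clip(g.mean_ct[0, 0], -1000, 2000)))
        assert m.evaluate(5.0, 5.0) == pytest.approx(float(np.clip(g.mean_ct[3, 3], -1000, 2000)))


def _uniform_patient(shape=(8, 8, 4), ct_value=40.0):
    labels = RegionLabelMap(labels=np.full(shape, SOFT))
    mr1 = ImageVolume(data=np.random.default_rng(0).uniform(10, 100, shape), spacing=(1, 1, 1))
    mr2 = ImageVolume(data=np.random.default_rng(1).uniform(10, 100, shape), spacing=(1, 1, 1))
    ct = ImageVolume(data=np.full(shape, ct_value), spacing=(1, 1, 1))
    return (mr1, mr2, ct, labels)


class TestTrainRegionModels:
    def test_constant_soft_patient(self):
        patient = _uniform_patient()
        models = train_region_models([patient], nbin=10, degree=3)
        pct = predict_pct(models, patient[0], patient[1], patient[3])
        assert np.max(np.abs(pct.data - 40.0)) < 1e-6

    def test_excluded_voxels_never_train(self, small_spec):
        p = generate_phantom(small_spec, 0)
        rng = np.random.default_rng(5)
        excl = p.labels.body_mask & (rng.random(p.labels.shape) < 0.5)
        ct_bad = p.ct.data.copy()
        ct_bad[excl] += 5000.0  # corrupted where excluded
        corrupted = (p.mr1, p.mr2, p.ct.with_data(ct_bad), RegionLabelMap(p.labels.labels.copy(), excl))

        # reference: the same voxels removed from the body entirely
        labels_clean = p.labels.labels.copy()
        labels_clean[excl] = 0
        clean = (p.mr1, p.mr2, p.ct, RegionLabelMap(labels_clean))

        kw = dict(nbin=12, degree=2, axis_max=(2000.0, 40000.0))
        m_corrupt = train_region_models([corrupted], **kw)
        m_clean = train_region_models([clean], **kw)
        for name in m_corrupt.models:
            np.testing.assert_array_equal(
                m_corrupt.models[name].coeffs, m_clean.models[name].coeffs
            )

    def test_duplicated_patient_equals_doubled_counts(self, small_spec):
        p = generate_phantom(small_spec, 0)
        patient = (p.mr1, p.mr2, p.ct, p.labels)
        kw = dict(nbin=12, degree=3, axis_max=(2000.0, 40000.0))
        m1 = train_region_models([patient], **kw)
        m2 = train_region_models([patient, patient], **kw)
        for name in m1.models:
            np.testing.assert_allclose(
                m1.models[name].coeffs, m2.models[name].coeffs, rtol=1e-8, atol=1e-10
            )

    def test_zero_voxel_region_fails_in_pooled_mode(self):
        mr1, mr2, ct, _ = _uniform_patient()
        labels = RegionLabelMap(labels=np.zeros(mr1.shape, dtype=int))  # all outside
        with pytest.raises(ValueError):
            train_region_models([(mr1, mr2, ct, labels)], nbin=5, degree=1, segmentation=False)


class TestPredictPct:
    def test_all_outside(self):
        mr1, mr2, ct, _ = _uniform_patient()
        labels = RegionLabelMap(labels=np.zeros(mr1.shape, dtype=int))
        models = train_region_models([_uniform_patient()], nbin=5, degree=1)
        pct = predict_pct(models, mr1, mr2, labels)
        assert np.all(pct.data == -1000.0)

    def test_matches_voxel_loop_oracle(self, small_spec):
        p = generate_phantom(small_spec, 0)
        models = train_region_models([(p.mr1, p.mr2, p.ct, p.labels)], nbin=10, degree=3)
        pct = predict_pct(models, p.mr1, p.mr2, p.labels)
        sub = np.argwhere(p.labels.body_mask)[::97]  # spot-check a voxel sample
        from pctpoly.volumes import REGION_NAMES

        for x, y, z in sub:
            model = models.region_model(REGION_NAMES[int(p.labels.labels[x, y, z])])
            expected = float(model.evaluate(p.mr1.data[x, y, z], p.mr2.data[x, y, z]))
            assert pct.data[x, y, z] == pytest.approx(expected, rel=1e-12)

    def test_output_range_invariant(self, small_cohort):
        p = small_cohort[0]
        models = train_region_models([(p.mr1, p.mr2, p.ct, p.labels)], nbin=10, degree=3)
        pct = predict_pct(models, p.mr1, p.mr2, p.labels)
        assert pct.data.min() >= -1000.0
        assert pct.data.max() <= 2000.0
        assert np.all(pct.data[~p.labels.body_mask] == -1000.0)

    def test_per_bin_prediction_piecewise_constant(self, small_spec):
        p = generate_phantom(small_spec, 0)
        models = train_region_models([(p.mr1, p.mr2, p.ct, p.labels)], nbin=8, degree=2)
        pct_bin = predict_pct_per_bin(models, p.mr1, p.mr2, p.labels)
        # voxels sharing (region, bin) share a prediction
        from pctpoly.binning import bin_index

        body = p.labels.body_mask
        i = bin_index(p.mr1.data[body], models.axis_max[0], models.nbin)
        j = bin_index(p.mr2.data[body], models.axis_max[1], models.nbin)
        key = p.labels.labels[body] * models.nbin**2 + np.asarray(i) * models.nbin + np.asarray(j)
        vals = pct_bin.data[body]
        for k in np.unique(key)[::7]:
            assert np.ptp(vals[key == k]) == 0.0


class TestRecoveryProperties:
    def test_noiseless_polynomial_recovery(self):
        # ground truth of degree 2, every bin filled -> near-exact recovery
        rng = np.random.default_rng(3)
        nbin = 15

        def truth(a, b):
            return 100 + 300 * a - 150 * b + 80 * a * b - 50 * b**2

        g = _full_grid(nbin, (1.0, 1.0), lambda a, b: truth(a, b))
        m = fit_polynomial(g, 3)
        q1, q2 = rng.uniform(0.03, 0.97, 400), rng.uniform(0.03, 0.97, 400)
        assert np.mean(np.abs(m.evaluate(q1, q2) - truth(q1, q2))) < 0.1

    def test_polynomial_vs_interpolation_agreement(self, small_spec):
        from dataclasses import replace as dreplace

        spec = dreplace(small_spec, shape=(40, 40, 20), ct_noise_sd=0.0)
        p = generate_phantom(spec, 0)
        patient = (p.mr1, p.mr2, p.ct, p.labels)
        kw = dict(nbin=20, degree=4)
        m_poly = train_region_models([patient], model_type="polynomial", **kw)
        m_interp = train_region_models([patient], model_type="interpolation", **kw)
        from pctpoly.evaluation import mae

        body = p.labels.body_mask
        mae_poly = mae(predict_pct(m_poly, *patient[:2], patient[3]), p.ct, body)
        mae_interp = mae(predict_pct(m_interp, *patient[:2], patient[3]), p.ct, body)
        assert abs(mae_poly - mae_interp) < 0.05 * max(mae_poly, mae_interp, 1e-9)


class TestPersistence:
    def test_polynomial_round_trip(self, tmp_path, small_spec):
        p = generate_phantom(small_spec, 0)
        models = train_region_models([(p.mr1, p.mr2, p.ct, p.labels)], nbin=8, degree=3)
        models.save(tmp_path / "m.json")
        back = RegionModelSet.load(tmp_path / "m.json")
        assert back.nbin == models.nbin
        assert back.axis_max == tuple(models.axis_max)
        pct_a = predict_pct(models, p.mr1, p.mr2, p.labels)
        pct_b = predict_pct(back, p.mr1, p.mr2, p.labels)
        np.testing.assert_array_equal(pct_a.data, pct_b.data)

    def test_interpolation_round_trip(self, tmp_path, small_spec):
        p = generate_phantom(small_spec, 0)
        models = train_region_models(
            [(p.mr1, p.mr2, p.ct, p.labels)], nbin=8, degree=3, model_type="interpolation"
        )
        models.save(tmp_path / "m.json")
        back = RegionModelSet.load(tmp_path / "m.json")
        pct_a = predict_pct(models, p.mr1, p.mr2, p.labels)
        pct_b = predict_pct(back, p.mr1, p.mr2, p.labels)
        np.testing.assert_array_equal(pct_a.data, pct_b.data)

    def test_missing_model_file(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="m.json"):
            RegionModelSet.load(tmp_path / "m.json")
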