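import numpy as np
import pytest

from nirscal.model_selection import (
    calibrate,
    cross_validate,
    global_h,
    grid_search,
    t_outliers,
    validate,
)
from nirscal.mpls import mpls_fit
from nirscal.pretreatment import PretreatmentSpec, parse_treatment_code
from nirscal.spectra_io import SpectraSet, average_duplicates, split_cal_val

from .oracles import loo_secv

RAW = PretreatmentSpec(0, 0, 1, 1)


def _linear_spectra(n, w, rank, noise_frac, seed, grid_start=1100.0):
    """Spectra with a known low-rank linear y-relationship.

    The reference noise is uniform (bounded at sqrt(3) SDs), so studentized
    residuals of genuine samples stay well below the T threshold and the
    outlier tests probe the detector, not the tails of the noise.
    """
    rng = np.random.default_rng(seed)
    grid = np.arange(grid_start, grid_start + 2 * w, 2.0)
    latent = rng.normal(size=(n, rank))
    basis = rng.normal(size=(rank, w))
    X = latent @ basis + 0.3
    coefs = rng.normal(size=rank)
    y = latent @ coefs
    half = np.sqrt(3.0) * noise_frac * y.std()
    y = y + rng.uniform(-half, half, size=n)
    s = SpectraSet(grid, X, [f"s{i}" for i in range(n)])
    return s, y


class TestCrossValidate:
    def test_recovers_rank_of_synthetic_data(self):
        # rank-3 signal with 1 % noise: the SECV minimum should sit at 3
        # factors for most seeds
        hits = 0
        for seed in range(10):
            s, y = _linear_spectra(60, 30, rank=3, noise_frac=0.01, seed=seed)
            cv = cross_validate(s, y, RAW, max_factors=8, n_groups=6, seed=seed,
                                standardize_residuals=False)
            hits += cv.opt_factors == 3
        assert hits >= 6

    def test_loo_matches_brute_force_oracle(self):
        s, y = _linear_spectra(15, 12, rank=2, noise_frac=0.2, seed=1)
        p = 3
        cv = cross_validate(s, y, RAW, max_factors=p, n_groups=15, seed=0,
                            standardize_residuals=False)
        oracle = loo_secv(s.absorbance, y, p)
        assert cv.secv[p - 1] == pytest.approx(oracle, abs=1e-10)

    def test_same_seed_same_curve(self):
        s, y = _linear_spectra(40, 20, rank=2, noise_frac=0.1, seed=4)
        a = cross_validate(s, y, RAW, 5, seed=9)
        b = cross_validate(s, y, RAW, 5, seed=9)
        np.testing.assert_array_equal(a.secv, b.secv)
        np.testing.assert_array_equal(a.groups, b.groups)

    def test_too_many_groups_rejected(self):
        s, y = _linear_spectra(10, 8, rank=1, noise_frac=0.1, seed=0)
        with pytest.raises(ValueError, match="n_groups"):
            cross_validate(s, y, RAW, 3, n_groups=11)


class TestGlobalH:
    @pytest.fixture
    def fitted(self):
        s, y = _linear_spectra(50, 25, rank=3, noise_frac=0.05, seed=2)
        m = mpls_fit(s.absorbance, y, 3)
        return s, y, m

    def test_score_centroid_has_zero_gh(self, fitted):
        s, _, m = fitted
        # a synthetic spectrum whose scores sit at the calibration centroid
        gh = global_h(m, s.absorbance)
        centroid_spectrum = s.absorbance.mean(axis=0, keepdims=True)
        assert global_h(m, centroid_spectrum)[0] < gh.mean() * 0.2

    def test_calibration_mean_gh_near_one(self, fitted):
        s, _, m = fitted
        gh = global_h(m, s.absorbance)
        # empirical Mahalanobis distances average (n-1)/n per dimension
        assert 0.9 <= gh.mean() <= 1.1

    def test_amplified_spectrum_is_flagged(self, fitted):
        s, _, m = fitted
        outlier = s.absorbance[:1] * 100.0
        assert global_h(m, outlier)[0] >= 10.0


class TestTOutliers:
    def test_zero_residuals_no_flags(self):
        s, y = _linear_spectra(30, 15, rank=2, noise_frac=0.0, seed=3)
        m = mpls_fit(s.absorbance, y, 2)
        y_exact = m.predict(s.absorbance)  # residuals exactly zero, SEC = 0
        assert not t_outliers(m, s.absorbance, y_exact).any()

    def test_implanted_residual_flagged(self):
        s, y = _linear_spectra(40, 20, rank=2, noise_frac=0.05, seed=5)
        m = mpls_fit(s.absorbance, y, 2)
        from nirscal.stats import sec

        resid = y - m.predict(s.absorbance)
        y_bad = y.copy()
        y_bad[7] += 10 * sec(resid, 2)
        m_bad = mpls_fit(s.absorbance, y_bad, 2)
        flags = t_outliers(m_bad, s.absorbance, y_bad)
        assert flags[7]

    def test_boundary_is_strict(self):
        # a sample sitting exactly at T == threshold is not flagged ("> 2.5")
        from nirscal.stats import sec

        s, y = _linear_spectra(30, 15, rank=2, noise_frac=0.0, seed=6)
        m = mpls_fit(s.absorbance, y, 2)
        e = np.zeros(30)
        e[0] = 1.0
        y_test = m.predict(s.absorbance) + e  # residuals are exactly e
        boundary = abs(e[0]) / sec(e, 2)
        assert not t_outliers(m, s.absorbance, y_test, threshold=boundary).any()
        assert t_outliers(m, s.absorbance, y_test, threshold=boundary * 0.999)[0]


class TestCalibrate:
    def test_clean_data_no_removals(self):
        s, y = _linear_spectra(40, 25, rank=3, noise_frac=0.02, seed=7)
        res = calibrate(s, y, RAW, max_factors=5, seed=7)
        assert res.n_used == 40 and res.removed == [] and res.passes == 0

    def test_implanted_outliers_removed_within_two_passes(self):
        hits = 0
        for seed in range(10):
            s, y = _linear_spectra(88, 30, rank=3, noise_frac=0.03, seed=seed)
            y_bad = y.copy()
            spread = y.std()
            y_bad[10] += 6 * spread
            y_bad[50] -= 6 * spread
            res = calibrate(s, y_bad, RAW, max_factors=6, seed=seed)
            removed_ids = {r["sample_id"] for r in res.removed}
            if res.n_used == 86 and removed_ids == {"s10", "s50"}:
                hits += 1
        assert hits >= 8

    def test_pass_budget_is_respected(self):
        s, y = _linear_spectra(40, 20, rank=2, noise_frac=0.5, seed=8)
        res = calibrate(s, y, RAW, max_factors=4, seed=8, t_threshold=1.2)
        assert res.passes <= 2

    def test_too_few_samples_rejected(self):
        s, y = _linear_spectra(15, 10, rank=2, noise_frac=0.1, seed=9)
        with pytest.raises(ValueError, match=">= 20"):
            calibrate(s, y, RAW)

    def test_excessive_removal_aborts(self):
        s, y = _linear_spectra(30, 15, rank=1, noise_frac=2.0, seed=10)
        with pytest.raises(RuntimeError, match="half"):
            calibrate(s, y, RAW, max_factors=3, seed=10, t_threshold=0.3)


class TestGridSearchAndValidate:
    def test_leaderboard_has_one_row_per_cell(self):
        s, y = _linear_spectra(40, 40, rank=3, noise_frac=0.05, seed=11)
        grid = [RAW, PretreatmentSpec(1, 2, 2, 1), PretreatmentSpec(2, 2, 2, 1, "SNV")]
        gs = grid_search(s, y, grid=grid, max_factors=4, seed=11)
        assert len(gs.leaderboard) == 3
        assert gs.leaderboard["secv"].iloc[0] == gs.leaderboard["secv"].min()

    def test_winner_deterministic_given_seed(self):
        s, y = _linear_spectra(40, 40, rank=3, noise_frac=0.05, seed=12)
        grid = [RAW, PretreatmentSpec(1, 2, 2, 1, "SNV")]
        a = grid_search(s, y, grid=grid, max_factors=4, seed=3)
        b = grid_search(s, y, grid=grid, max_factors=4, seed=3)
        assert a.best.pretreatment.label == b.best.pretreatment.label
        assert a.best.stats.secv == b.best.stats.secv

    def test_scatter_correction_wins_on_scatter_perturbed_data(self, small_dataset):
        # paired comparison: with multiplicative scatter in the simulator, the
        # best scatter-corrected cell should beat the same derivative with no
        # correction for most seeds
        from nirscal.synthetic import SimConfig, make_dataset

        wins = 0
        for seed in range(10):
            cfg = SimConfig(n_samples=40)
            cfg.wavelengths = np.arange(1400.0, 2400.0, 4.0)
            cfg.scatter_mult_sd = 0.10
            spectra, ref = make_dataset(cfg, seed=seed)
            s = average_duplicates(spectra)
            y = ref.values("de_c", s.sample_ids)
            code = "2,4,4,1"
            plain = calibrate(s, y, parse_treatment_code(code), max_factors=5, seed=seed)
            snv = calibrate(s, y, parse_treatment_code(code, "SNV"), max_factors=5, seed=seed)
            wins += snv.stats.secv < plain.stats.secv
        assert wins >= 7

    def test_validating_on_calibration_set_reproduces_fit(self):
        s, y = _linear_spectra(40, 25, rank=3, noise_frac=0.05, seed=13)
        res = calibrate(s, y, RAW, max_factors=4, seed=13)
        kept = [s.sample_ids.index(i) for i in res.kept_ids]
        stats = validate(res, s.subset(kept), y[kept])
        # SEP over the training residuals = RMS of fitted residuals
        resid = y[kept] - res.model.predict(s.subset(kept).absorbance)
        assert stats.sep == pytest.approx(np.sqrt(np.mean(resid**2)), rel=1e-10)

    def test_rpd_consistency_between_cv_and_heldout(self):
        # with no distribution shift and no outlier trimming, validation RPD
        # tracks cross-validation RPD; majority over seeds within 20 %
        from nirscal.synthetic import SimConfig, make_dataset

        hits = 0
        for seed in range(5):
            cfg = SimConfig(n_samples=60)
            cfg.wavelengths = np.arange(1400.0, 2400.0, 4.0)
            spectra, ref = make_dataset(cfg, seed=100 + seed)
            s = average_duplicates(spectra)
            cal, val = split_cal_val(s.sample_ids, 15, seed)
            y_cal = ref.values("de_d", cal)
            y_val = ref.values("de_d", val)
            res = calibrate(
                s.select_samples(cal), y_cal,
                parse_treatment_code("2,4,4,1", "SNV"),
                max_factors=6, seed=seed, max_passes=0,
            )
            vs = validate(res, s.select_samples(val), y_val)
            hits += abs(vs.rpd_v - res.stats.rpd_cv) <= 0.2 * res.stats.rpd_cv
        assert hits >= 3

    def test_empty_validation_set_rejected(self):
        s, y = _linear_spectra(40, 25, rank=2, noise_frac=0.05, seed=14)
        res = calibrate(s, y, RAW, max_factors=3, seed=14)
        with pytest.raises(ValueError, match="empty"):
            validate(res, s.subset([]), np.array([]))
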