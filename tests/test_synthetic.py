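import numpy as np
import pytest
from scipy import stats

from netsynchrony._seeds import derive_seed
from netsynchrony.spectral import decompose, match_components
from netsynchrony.synthetic import (
    MeasureSpec,
    draw_subject_spectra,
    generate_behavior,
    generate_connectivity,
    generate_time_series,
    make_cohort,
    make_truth,
    truth_from_dict,
    truth_to_dict,
)


class TestMakeTruth:
    def test_single_component_degenerate_case(self):
        truth = make_truth(
            n_regions=10, n_components=1, group_spectrum=[2.0],
            subject_spectrum_sd=[0.1], behavior_coefficients={}, seed=0,
        )
        assert truth.loadings.shape == (10, 1)
        assert np.linalg.norm(truth.loadings[:, 0]) == pytest.approx(1.0)

    def test_seed_determinism_bitwise(self):
        a = make_truth(n_regions=40, n_components=6, behavior_coefficients={}, seed=9,
                       group_spectrum=6.0 * 0.8 ** np.arange(6),
                       subject_spectrum_sd=[0.1] * 6)
        b = make_truth(n_regions=40, n_components=6, behavior_coefficients={}, seed=9,
                       group_spectrum=6.0 * 0.8 ** np.arange(6),
                       subject_spectrum_sd=[0.1] * 6)
        assert np.array_equal(a.loadings, b.loadings)

    def test_loadings_gram_is_identity(self):
        truth = make_truth(n_regions=50, n_components=5, behavior_coefficients={},
                           group_spectrum=[5, 4, 3, 2, 1],
                           subject_spectrum_sd=[0.1] * 5, seed=3)
        gram = truth.loadings.T @ truth.loadings
        assert np.max(np.abs(gram - np.eye(5))) < 1e-10

    def test_loadings_overlap_across_components(self):
        # one-to-many: most regions carry non-negligible weight on >1 component
        truth = make_truth(n_regions=60, n_subjects=5, seed=1)
        big = np.abs(truth.loadings) > 0.05
        assert (big.sum(axis=1) > 1).mean() > 0.5

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_regions": 3, "n_components": 5},
            {"group_spectrum": [1.0, 2.0]},     # not decreasing
            {"group_spectrum": [2.0, -1.0]},    # not positive
            {"bogus_key": 1},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        base = dict(n_regions=20, n_components=2, behavior_coefficients={},
                    group_spectrum=[2.0, 1.0], subject_spectrum_sd=[0.1, 0.1])
        base.update(kwargs)
        with pytest.raises(ValueError):
            make_truth(**base, seed=0)


class TestSubjectSpectra:
    def test_zero_variance_reduces_to_group_spectrum(self):
        truth = make_truth(n_regions=20, n_components=3, n_subjects=7,
                           group_spectrum=[3, 2, 1], subject_spectrum_sd=[0, 0, 0],
                           behavior_coefficients={}, seed=5)
        lam = draw_subject_spectra(truth)
        assert np.allclose(lam, np.tile([3, 2, 1], (7, 1)))

    def test_log_mean_matches_group_value(self):
        truth = make_truth(n_regions=20, n_components=3, n_subjects=2000,
                           group_spectrum=[3, 2, 1], subject_spectrum_sd=[0.2] * 3,
                           behavior_coefficients={}, seed=6)
        lam = draw_subject_spectra(truth)
        se = 0.2 / np.sqrt(2000)
        for k in range(3):
            assert abs(np.mean(np.log(lam[:, k])) - np.log(truth.group_spectrum[k])) < 3 * se

    def test_determinism_and_positivity(self):
        truth = make_truth(n_regions=20, n_components=2, n_subjects=30,
                           group_spectrum=[2.0, 1.0], subject_spectrum_sd=[0.3, 0.3],
                           behavior_coefficients={}, seed=7)
        assert np.array_equal(draw_subject_spectra(truth), draw_subject_spectra(truth))
        assert (draw_subject_spectra(truth) > 0).all()


class TestGenerateConnectivity:
    def test_rank_one_eigen_oracle(self):
        truth = make_truth(n_regions=10, n_components=1, group_spectrum=[2.0],
                           subject_spectrum_sd=[0.0], noise_sd=0.0,
                           behavior_coefficients={}, seed=8)
        cm = generate_connectivity(truth, np.array([2.0]), 0)
        w = truth.loadings[:, 0]
        dense = 2.0 * np.outer(w, w)
        np.fill_diagonal(dense, 0.0)
        assert np.allclose(cm.values, dense)
        lead = decompose(cm, 1).singular_values[0]
        oracle = np.max(np.abs(np.linalg.eigvalsh(dense)))
        assert lead == pytest.approx(oracle, rel=1e-12)
        assert lead < 2.0  # diagonal deflation pulls the eigenvalue down

    def test_symmetry(self, small_truth):
        lam = draw_subject_spectra(small_truth)[0]
        cm = generate_connectivity(small_truth, lam, 3)
        assert np.array_equal(cm.values, cm.values.T)

    def test_noise_free_recovery_within_two_percent(self):
        truth = make_truth(n_regions=400, n_components=3, n_subjects=4, noise_sd=0.0,
                           group_spectrum=[5.0, 4.0, 3.2], subject_spectrum_sd=[0.05] * 3,
                           behavior_coefficients={}, seed=21)
        lam = draw_subject_spectra(truth)
        group = decompose(generate_connectivity(truth, truth.group_spectrum, 0), 3, "g")
        for i in range(4):
            prof = decompose(generate_connectivity(truth, lam[i], 0), 3, str(i))
            matched = match_components(prof, group)
            planted = np.sort(lam[i])[::-1]
            assert np.max(np.abs(matched.eigenvalue - planted) / planted) < 0.02
            cos = np.abs(np.sum(matched.aligned_loadings * group.components, axis=0))
            assert (cos > 0.99).all()


class TestGenerateTimeSeries:
    def test_dimensions_and_run_separation(self, small_truth):
        lam = draw_subject_spectra(small_truth)[0]
        runs = generate_time_series(small_truth, lam, 4)
        assert len(runs) == small_truth.n_runs
        assert runs[0].values.shape == (30, 80)
        assert not np.array_equal(runs[0].values, runs[1].values)

    def test_sample_covariance_converges(self):
        truth = make_truth(n_regions=30, n_components=3, n_timepoints=100_000,
                           n_runs=1, noise_sd=0.0, group_spectrum=[4.0, 2.0, 1.0],
                           subject_spectrum_sd=[0.0] * 3, behavior_coefficients={}, seed=13)
        X = generate_time_series(truth, truth.group_spectrum, 1)[0].values
        target = (truth.loadings * truth.group_spectrum) @ truth.loadings.T
        sample = (X @ X.T) / X.shape[1]
        rel_err = np.linalg.norm(sample - target) / np.linalg.norm(target)
        assert rel_err < 0.02  # O(1/sqrt(T)) at T=1e5


class TestGenerateBehavior:
    def test_noiseless_single_weight_perfect_rank_correlation(self):
        truth = make_truth(
            n_regions=20, n_components=3, n_subjects=50,
            group_spectrum=[3, 2, 1], subject_spectrum_sd=[0.2] * 3,
            behavior_coefficients={"m": MeasureSpec(linear={3: 1.0}, residual_sd=0.0)},
            seed=14,
        )
        lam = draw_subject_spectra(truth)
        y = generate_behavior(truth, lam)["m"].to_numpy()
        assert stats.spearmanr(y, lam[:, 2]).statistic == pytest.approx(1.0, abs=1e-12)

    def test_unknown_component_rejected(self):
        with pytest.raises(ValueError, match="unknown components"):
            make_truth(
                n_regions=20, n_components=2, group_spectrum=[2, 1],
                subject_spectrum_sd=[0.1, 0.1],
                behavior_coefficients={"m": MeasureSpec(linear={5: 1.0})}, seed=0,
            )

    def test_null_measure_spearman_calibration(self):
        # all-zero weights: the per-component false-positive rate of the
        # plain alpha=.05 Spearman test stays at its nominal level
        # (pooled over 100 cohorts x 10 components)
        hits = total = 0
        for rep in range(100):
            truth = make_truth(
                n_regions=20, n_subjects=200, n_components=10,
                behavior_coefficients={"null": MeasureSpec(residual_sd=1.0)},
                seed=derive_seed(15, "null", rep),
            )
            lam = draw_subject_spectra(truth)
            y = generate_behavior(truth, lam)["null"].to_numpy()
            for k in range(10):
                total += 1
                hits += stats.spearmanr(lam[:, k], y).pvalue < 0.05
        assert hits / total <= 0.074  # 0.05 + 3.5 binomial sigmas at n=1000

    def test_planted_product_beats_singletons(self):
        from netsynchrony.synthetic import plant_product_measure

        truth = make_truth(n_regions=30, n_subjects=600, behavior_coefficients={}, seed=16)
        truth.behavior_coefficients = {"m": plant_product_measure(truth, (4, 8), 2.0, 3.0)}
        lam = draw_subject_spectra(truth)
        y = generate_behavior(truth, lam)["m"].to_numpy()
        product = lam[:, 3] * lam[:, 7]
        r_product = abs(stats.spearmanr(product, y).statistic)
        r_singletons = max(
            abs(stats.spearmanr(lam[:, k], y).statistic) for k in range(10)
        )
        assert r_product > r_singletons


class TestCohort:
    def test_cohort_invariants_and_roundtrip(self, small_truth, tmp_path):
        cohort = make_cohort(small_truth, kind="connectivity")
        assert (cohort.subject_spectra.to_numpy() > 0).all()
        assert not cohort.behavior.isna().any().any()
        assert len(cohort.connectivity) == small_truth.n_subjects
        assert len(cohort.connectivity[cohort.subject_ids[0]]) == small_truth.n_runs
        back = truth_from_dict(truth_to_dict(small_truth))
        assert np.array_equal(back.loadings, small_truth.loadings)
        assert back.behavior_coefficients == small_truth.behavior_coefficients

    def test_timeseries_cohort(self, small_truth):
        cohort = make_cohort(small_truth, kind="timeseries")
        runs = cohort.time_series[cohort.subject_ids[0]]
        assert len(runs) == small_truth.n_runs
        assert runs[0].values.shape == (30, 80)
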