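"""Metrics, fold bookkeeping, and cross-validated decoding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ecodec as ec
from ecodec.errors import LeakageError, ParameterError


def brute_force_cc(a, b):
    n = len(a)
    ma, mb = sum(a) / n, sum(b) / n
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    da = sum((x - ma) ** 2 for x in a) ** 0.5
    db = sum((y - mb) ** 2 for y in b) ** 0.5
    return num / (da * db)


def brute_force_nrmse(a, b):
    n = len(a)
    mse = sum((y - x) ** 2 for x, y in zip(a, b)) / n
    return mse ** 0.5 / (max(a) - min(a))


class TestMetrics:
    def test_identity_gives_unit_cc_and_zero_error(self, rng):
        y = rng.random(50)
        assert ec.correlation(y, y) == pytest.approx(1.0)
        assert ec.nrmse(y, y) == 0.0

    def test_affine_invariance_of_cc(self, rng):
        y = rng.random(50)
        assert ec.correlation(y, 2 * y + 3) == pytest.approx(1.0)

    def test_exact_anticorrelation(self):
        assert ec.correlation([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_nrmse_hand_example(self):
        # constant prediction at 0.5 of a 0/1 square: RMSE 0.5, range 1
        assert ec.nrmse([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == pytest.approx(0.5)

    def test_nrmse_scale_invariant(self, rng):
        a, b = rng.random(40), rng.random(40)
        assert ec.nrmse(10 * a, 10 * b) == pytest.approx(ec.nrmse(a, b))

    def test_flat_actual_returns_nan(self):
        assert np.isnan(ec.nrmse(np.ones(5), np.zeros(5)))
        assert np.isnan(ec.correlation(np.ones(5), np.arange(5.0)))

    def test_agreement_with_brute_force_on_random_pairs(self):
        # independent loop-based oracle, 1000 random vector pairs
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = rng.integers(2, 40)
            a = rng.standard_normal(n)
            b = rng.standard_normal(n)
            if a.max() == a.min():
                continue
            assert ec.correlation(a, b) == pytest.approx(
                brute_force_cc(list(a), list(b)), abs=1e-12)
            assert ec.nrmse(a, b) == pytest.approx(
                brute_force_nrmse(list(a), list(b)), abs=1e-12)


class TestKfoldSplit:
    @pytest.mark.parametrize("n,k,size", [(240, 10, 24), (120, 10, 12)])
    def test_equal_fold_sizes(self, n, k, size):
        labels = ec.kfold_split(np.arange(n), k, seed=0)
        counts = np.bincount(labels, minlength=k)
        assert (counts == size).all()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(n=st.integers(12, 300), k=st.integers(2, 10), seed=st.integers(0, 99))
    def test_partition_and_near_equal_sizes(self, n, k, seed):
        labels = ec.kfold_split(np.arange(n), k, seed)
        counts = np.bincount(labels, minlength=k)
        assert counts.sum() == n
        assert counts.max() - counts.min() <= 1

    def test_deterministic_per_seed(self):
        a = ec.kfold_split(np.arange(100), 10, seed=5)
        b = ec.kfold_split(np.arange(100), 10, seed=5)
        c = ec.kfold_split(np.arange(100), 10, seed=6)
        np.testing.assert_array_equal(a, b)
        assert (a != c).any()

    def test_more_folds_than_trials_rejected(self):
        with pytest.raises(ParameterError):
            ec.kfold_split(np.arange(5), 10, seed=0)


class TestCrossValidation:
    def test_every_trial_in_exactly_one_test_fold(self, small_cv, small_pipeline):
        trials = small_pipeline["trials"]
        tm = small_cv.trial_metrics
        seen = tm.groupby("trial")["fold"].nunique()
        assert (seen == 1).all()
        assert set(tm["trial"].unique()) == set(range(trials.n_trials))

    def test_decode_recovers_synthetic_targets(self, small_cv):
        cc = small_cv.grand_mean_cc()
        assert (cc >= 0.7).all(), cc.to_dict()

    def test_report_ranges(self, small_cv):
        tm = small_cv.trial_metrics
        assert tm["cc"].between(-1, 1).all()
        assert (tm["nrmse"] >= 0).all()

    def test_aggregation_identities(self, small_cv):
        # grand mean == mean of fold means; SEM == SD(fold means)/sqrt(k)
        tm = small_cv.trial_metrics
        fold_means = tm.groupby(["fold", "muscle"])["cc"].mean()
        ms = small_cv.muscle_summary()
        for m in small_cv.muscle_names:
            fm = fold_means.xs(m, level="muscle")
            assert ms.loc[m, ("cc", "grand_mean")] == pytest.approx(fm.mean())
            assert ms.loc[m, ("cc", "sem")] == pytest.approx(
                fm.std(ddof=1) / np.sqrt(small_cv.k))

    def test_no_leakage_refit_equality(self, small_pipeline, small_cv):
        """Fitting explicitly on the training rows only reproduces the fold
        model bit-for-bit: held-out rows cannot have influenced it."""
        p = small_pipeline
        design, emg, trials, cfg = (p["design"], p["emg"], p["trials"], p["cfg"])
        labels = small_cv.fold_assignment
        f = 0
        train_trials = np.flatnonzero(labels != f)
        rows = (trials.starts[train_trials][:, None]
                + np.arange(0, trials.n_rows_per_trial,
                            cfg.fit_row_decimation)[None, :]).ravel()
        Y = emg.activity.T[design.row0:design.row0 + design.n_rows]
        refit = ec.fit_slir(design, Y, cfg.ard, rows=rows,
                            muscle_names=emg.muscle_names)
        fold_model = small_cv.models[f]
        np.testing.assert_array_equal(refit.active_mask, fold_model.active_mask)
        np.testing.assert_array_equal(refit.weights, fold_model.weights)
        np.testing.assert_array_equal(refit.bias, fold_model.bias)

    def test_random_segment_control_collapses_to_chance(self, small_pipeline):
        # refilling trial windows with random-phase EMG removes all
        # decodable structure: cross-validated CC drops to chance
        p = small_pipeline
        cfg = p["cfg"].replace(fit_row_decimation=10)
        shifted = ec.random_segment_control(p["emg"], p["trials"],
                                            p["design"], seed=41)
        rep = ec.cross_validate(p["design"], shifted, p["trials"], cfg,
                                seed=3, keep_models=False)
        assert np.abs(rep.grand_mean_cc()).max() < 0.2

    def test_trial_permutation_bounds_stereotypy_ceiling(self, small_pipeline,
                                                         small_cv):
        # swapping onset-aligned trial contents leaves the across-trial
        # template decodable: accuracy stays high but below the true decode
        p = small_pipeline
        cfg = p["cfg"].replace(fit_row_decimation=10)
        shuffled = ec.permute_trial_blocks(p["emg"], p["trials"], p["design"],
                                           seed=77)
        rep = ec.cross_validate(p["design"], shuffled, p["trials"], cfg,
                                seed=3, keep_models=False)
        ceiling = rep.grand_mean_cc().mean()
        assert 0.3 < ceiling < small_cv.grand_mean_cc().mean()

    def test_report_table_layout(self, small_cv):
        table = small_cv.to_table()
        k = small_cv.k
        assert len(table) == 2 * (k + 1)  # CC and nRMSE blocks with Avg. rows
        assert set(small_cv.muscle_names) <= set(table.columns)


class TestContinuousEvaluate:
    def test_holdout_stream_scores(self, small_pipeline):
        p = small_pipeline
        cfg = p["cfg"]
        design, emg, trials = p["design"], p["emg"], p["trials"]
        Y = emg.activity.T[design.row0:design.row0 + design.n_rows]
        rows = trials.all_rows(cfg.fit_row_decimation)
        model = ec.fit_slir(design, Y, cfg.ard, rows=rows,
                            muscle_names=emg.muscle_names,
                            train_span=("train", 0.0, p["session"].duration))
        spec2 = ec.make_subject_spec("B", seed=11)  # same true weights
        spec2.n_trials = 12
        sess2, _ = ec.generate_session(spec2, seed=555)
        src2 = ec.extract_band_sources(sess2, cfg)
        d2 = ec.build_design_matrix(src2, cfg)
        emg2 = ec.emg_envelope(sess2.emg, sess2.rate_emg, cfg, sess2.muscle_names)
        out = ec.continuous_evaluate(model, d2, emg2, (5.0, 55.0),
                                     session_id="holdout")
        assert (out["cc"] >= 0.6).all(), out["cc"].to_dict()

    def test_overlap_with_training_raises(self, small_pipeline):
        p = small_pipeline
        design, emg = p["design"], p["emg"]
        Y = emg.activity.T[design.row0:design.row0 + design.n_rows]
        model = ec.fit_slir(design, Y[:3000], p["cfg"].ard,
                            rows=np.arange(3000),
                            muscle_names=emg.muscle_names,
                            train_span=("sess", 0.0, 30.0))
        with pytest.raises(LeakageError):
            ec.continuous_evaluate(model, design, emg, (10.0, 60.0),
                                   session_id="sess")

    def test_zero_length_span_rejected(self, small_pipeline):
        p = small_pipeline
        design, emg = p["design"], p["emg"]
        Y = emg.activity.T[design.row0:design.row0 + design.n_rows]
        m = ec.fit_slir(design, Y[:2000], p["cfg"].ard, rows=np.arange(2000),
                        muscle_names=emg.muscle_names)
        with pytest.raises(ParameterError):
            ec.continuous_evaluate(m, design, emg, (10.0, 10.0))
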