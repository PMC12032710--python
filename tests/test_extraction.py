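"""NMF, R², cross-validation, model selection, compactness arithmetic."""

import numpy as np
import pytest

from synergykit.datatypes import ProcessedTrial, TrialMeta
from synergykit.extraction import (
    DegenerateInputError,
    FoldError,
    SelectionError,
    UndefinedRSquaredError,
    best_pairing_cosine,
    build_strategy_dataset,
    compactness_summary,
    compare_model_counts,
    compute_r_squared,
    cross_validated_curve,
    extract_synergies,
    fit_fixed_factors,
    make_folds,
    nmf_extract,
    select_n_knee,
    select_n_star,
)
from synergykit.synthetic import (
    NoiseModel,
    generate_envelope_trial,
    make_ground_truth,
)

from conftest import LABEL, gaussian_bump, single_strategy_config

# Temporal/spatial model orders selected across the ten strategy datasets
# (two movements x two floors), used for the count-difference statistic.
COUNT_PAIRS = [
    (7, 15), (6, 12), (6, 16), (10, 11), (8, 13),
    (8, 16), (8, 13), (8, 13), (7, 12), (7, 12),
]


def _trials(envs, supports=None):
    supports = supports or ["UA"] * len(envs)
    return [
        ProcessedTrial(
            envelope=e, events=None,
            meta=TrialMeta(1, "sit_to_stand", "non_challenging", s, i + 1, "a"),
        )
        for i, (e, s) in enumerate(zip(envs, supports))
    ]


class TestStrategyDataset:
    def test_concatenation_shapes(self):
        rng = np.random.default_rng(0)
        ds = build_strategy_dataset(_trials([rng.random((101, 30)) for _ in range(2)]))
        assert ds.temporal_matrix.shape == (101, 60)
        assert ds.spatial_matrix.shape == (30, 202)

    def test_round_trip_is_lossless_and_ordered(self):
        rng = np.random.default_rng(1)
        envs = [rng.random((101, 30)) for _ in range(3)]
        ds = build_strategy_dataset(_trials(envs, ["UA", "LT", "FS"]))
        blocks = ds.split_columns(ds.temporal_matrix, "temporal")
        for e, b in zip(envs, blocks):
            assert np.array_equal(e, b)
        sblocks = ds.split_columns(ds.spatial_matrix, "spatial")
        for e, b in zip(envs, sblocks):
            assert np.array_equal(e.T, b)
        assert [t.meta.support for t in ds.trials] == ["UA", "LT", "FS"]


class TestRSquared:
    def test_perfect_reconstruction_is_one(self):
        x = np.random.default_rng(0).random((10, 7))
        assert compute_r_squared(x, x) == pytest.approx(1.0)

    def test_row_mean_reconstruction_is_zero(self):
        x = np.random.default_rng(1).random((10, 7))
        recon = np.tile(x.mean(axis=1, keepdims=True), (1, 7))
        assert compute_r_squared(x, recon) == pytest.approx(0.0)

    def test_hand_computed_toy(self):
        data = np.array([[1.0, 2.0, 3.0], [2.0, 2.0, 2.0]])
        recon = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        # SSE = 0 + 2; SST about row means (2, 2) = 2 + 0 -> R² = 0
        assert compute_r_squared(data, recon) == pytest.approx(0.0)

    def test_constant_data_undefined(self):
        with pytest.raises(UndefinedRSquaredError):
            compute_r_squared(np.ones((4, 4)), np.ones((4, 4)))


class TestNMF:
    def test_rank_one_exact(self):
        c = gaussian_bump(40, 8)
        w = np.random.default_rng(0).random(30)
        V = np.outer(c, w)
        A, B, obj, _ = nmf_extract(V, 1, restarts=3, max_iter=500, seed=0)
        assert compute_r_squared(V, A @ B) >= 1 - 1e-6

    def test_noiseless_rank3_ground_truth_recovery(self, noiseless_gt):
        C = noiseless_gt.strategies[LABEL].profiles()
        V = np.hstack(
            [generate_envelope_trial(noiseless_gt, LABEL, "UA", s)[0] for s in range(6)]
        )
        A, B, obj, _ = nmf_extract(V, 3, restarts=5, max_iter=2000, seed=0)
        assert best_pairing_cosine(C, A).min() > 0.99

    def test_determinism(self):
        V = np.random.default_rng(2).random((40, 25))
        a1 = nmf_extract(V, 3, restarts=3, max_iter=200, seed=5)
        a2 = nmf_extract(V, 3, restarts=3, max_iter=200, seed=5)
        assert np.array_equal(a1[0], a2[0]) and np.array_equal(a1[1], a2[1])

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(DegenerateInputError):
            nmf_extract(np.zeros((10, 10)), 2)

    def test_objective_trace_non_increasing(self):
        rng = np.random.default_rng(3)
        for seed in range(3):
            V = rng.random((50, 40))
            *_, trace = nmf_extract(V, 4, restarts=2, max_iter=300, seed=seed)
            assert np.all(np.diff(trace) <= 1e-9 * trace[0])

    def test_train_r2_non_decreasing_in_n(self, noisy_envelope_trials):
        ds = build_strategy_dataset(noisy_envelope_trials[:8])
        r2s = [
            extract_synergies(ds, "temporal", n, restarts=2, max_iter=400, seed=0).r2_train
            for n in range(1, 6)
        ]
        assert np.all(np.diff(r2s) >= -1e-6)

    def test_unit_max_renormalization_preserves_reconstruction(self):
        V = np.random.default_rng(4).random((30, 20))
        A, B, obj, _ = nmf_extract(V, 3, restarts=2, max_iter=300, seed=1)
        assert A.max(axis=0) == pytest.approx(np.ones(3))
        # objective equals the reconstruction error of the returned factors
        assert obj == pytest.approx(np.sum((V - A @ B) ** 2), rel=1e-10)

    def test_matches_sklearn_objective(self):
        """Independent cross-check: our best objective is no worse than 1.05x
        scikit-learn's NMF on the same problem."""
        from sklearn.decomposition import NMF

        V = np.random.default_rng(5).random((60, 45))
        _, _, obj, _ = nmf_extract(V, 4, restarts=5, max_iter=1000, seed=0)
        sk = NMF(4, init="random", solver="mu", max_iter=1000, random_state=0, tol=1e-7)
        Wsk = sk.fit_transform(V)
        obj_sk = np.sum((V - Wsk @ sk.components_) ** 2)
        assert obj <= 1.05 * obj_sk


class TestFixedFactorFit:
    def test_consistent_trial_reaches_r2_one(self, noiseless_gt):
        C = noiseless_gt.strategies[LABEL].profiles()
        env, _ = generate_envelope_trial(noiseless_gt, LABEL, "UA", 9)
        _, r2 = fit_fixed_factors(C, env)
        assert r2 >= 1 - 1e-6

    def test_disjoint_support_gives_nonpositive_r2(self):
        c = np.zeros(101)
        c[:30] = gaussian_bump(15, 5)[:30]
        data = np.zeros((101, 4))
        data[70:, :] = np.random.default_rng(0).random((31, 4))
        H, r2 = fit_fixed_factors(c[:, None], data)
        assert np.allclose(H, 0.0)
        assert r2 <= 0.0

    def test_single_profile_closed_form(self):
        c = gaussian_bump(50, 8)
        m = 0.7 * c + 0.1
        H, _ = fit_fixed_factors(c[:, None], m[:, None])
        expected = max(0.0, float(c @ m) / float(c @ c))
        assert H[0, 0] == pytest.approx(expected, rel=1e-10)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            fit_fixed_factors(np.ones((10, 2)), np.ones((11, 3)))


class TestCrossValidation:
    def test_folds_partition_trials(self, noisy_envelope_trials):
        ds = build_strategy_dataset(noisy_envelope_trials)
        folds = make_folds(ds, 5, seed=0)
        seen = np.concatenate(folds)
        assert sorted(seen) == list(range(ds.n_trials))

    def test_too_few_trials_raises(self, noisy_envelope_trials):
        ds = build_strategy_dataset(noisy_envelope_trials[:4])
        with pytest.raises(FoldError):
            make_folds(ds, 5, seed=0)

    def test_noiseless_curve_saturates_at_true_order(self, noiseless_gt):
        envs = [
            generate_envelope_trial(noiseless_gt, LABEL, "UA", s)[0] for s in range(6)
        ]
        # noiseless + jitter-free trials are identical; add support variety
        envs += [
            generate_envelope_trial(noiseless_gt, LABEL, "FS", s)[0] for s in range(3)
        ]
        ds = build_strategy_dataset(_trials(envs, ["UA"] * 6 + ["FS"] * 3))
        curve = cross_validated_curve(
            ds, "temporal", n_values=np.arange(1, 5), n_folds=5,
            restarts=2, max_iter=500, seed=0,
        )
        assert curve.r2_mean[2] >= 0.99  # n = 3 = true order
        assert curve.r2_cv.shape == (5, 4)

    def test_mean_curve_non_decreasing_within_noise(self, noisy_envelope_trials):
        ds = build_strategy_dataset(noisy_envelope_trials)
        curve = cross_validated_curve(
            ds, "temporal", n_values=np.arange(1, 6), n_folds=5,
            restarts=2, max_iter=400, seed=3,
        )
        assert np.all(np.diff(curve.r2_mean) >= -0.02)


class TestModelSelection:
    @staticmethod
    def _piecewise(n_max=30, breakpoint=6, s1=0.1, s2=0.001):
        n = np.arange(1, n_max + 1)
        y = np.where(
            n <= breakpoint,
            s1 * (n - breakpoint),
            s2 * (n - breakpoint),
        )
        return n, y + 0.9

    def test_knee_finds_exact_breakpoint(self):
        n, y = self._piecewise()
        assert select_n_knee(n, y).n_knee == 6

    def test_perfectly_linear_curve_gives_one(self):
        n = np.arange(1, 31)
        assert select_n_knee(n, 0.01 * n + 0.5).n_knee == 1

    def test_offset_invariance(self):
        n, y = self._piecewise(breakpoint=9)
        assert select_n_knee(n, y).n_knee == select_n_knee(n, y + 0.3).n_knee == 9

    def test_n_star_on_slow_rise(self):
        # global criterion first met at n = 8 (0.91), with a small local
        # increment there; below 8 the curve sits under 0.9
        n = np.arange(1, 31)
        y = np.minimum(0.91 + 0.004 * (n - 8), 0.99)
        y[n == 7] = 0.899
        y[n < 7] = 0.5 + 0.05 * n[n < 7]
        assert select_n_star(n, y).n_star == 8

    def test_n_star_flat_high_curve_uses_order_zero_convention(self):
        # R² jumps from the defined 0 at order 0 to 0.95 at order 1: the
        # local criterion fails there, so the first admissible order is 2
        n = np.arange(1, 31)
        assert select_n_star(n, np.full(30, 0.95)).n_star == 2

    def test_n_star_unreachable_global(self):
        n = np.arange(1, 31)
        with pytest.raises(SelectionError):
            select_n_star(n, np.full(30, 0.85))


class TestCompactness:
    @pytest.mark.parametrize(
        "nt, ns, expected",
        [
            (7, 15, dict(tit=707, tdt=210, st=917, ss=1965)),
            (6, 16, dict(tit=606, tdt=180, st=786, ss=2096)),
            (1, 1, dict(tit=101, tdt=30, st=131, ss=131)),
        ],
    )
    def test_parameter_count_arithmetic(self, nt, ns, expected):
        c = compactness_summary(nt, ns)
        assert c.trial_independent_temporal == expected["tit"]
        assert c.trial_dependent_temporal == expected["tdt"]
        assert c.sum_temporal == expected["st"]
        assert c.sum_spatial == expected["ss"]

    def test_temporal_more_compact_for_all_observed_pairs(self):
        for nt, ns in COUNT_PAIRS:
            c = compactness_summary(nt, ns)
            assert c.sum_temporal < c.sum_spatial

    def test_count_difference_statistics(self):
        mean, sd = compare_model_counts(COUNT_PAIRS)
        assert round(mean, 1) == 5.8
        assert round(sd, 1) == 2.4
        assert compare_model_counts([(3, 3), (5, 5)]) == (0.0, 0.0)
        mean2, sd2 = compare_model_counts([(4, 8), (4, 10)])
        assert mean2 == pytest.approx(5.0)
        assert sd2 == pytest.approx(np.sqrt(2.0))
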