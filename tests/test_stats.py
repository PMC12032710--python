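"""Mixed-model support statistics: coding, identities, diagnostics."""

import numpy as np
import pytest

from synergykit.datatypes import TrialMeta
from synergykit.muscles import MUSCLE16_NAMES
from synergykit.stats import (
    SingleParticipantError,
    adjust_alpha,
    average_bilateral,
    build_observation_table,
    fit_muscle_interaction_lmm,
    fit_support_lmm,
    residual_diagnostics,
    run_support_analysis,
)


def meta(p=1, support="UA", rep=1):
    return TrialMeta(p, "sit_to_stand", "non_challenging", support, rep, "a")


def simulate_observations(
    rng, participants=10, reps_per_support=2, fs_effect=0.0, lt_effect=0.0,
    participant_sd=0.1, noise_sd=0.15, fs_muscle_scale=None,
):
    """Weighting vectors with a participant random intercept and optional
    planted support effects (additive, or multiplicative per channel)."""
    obs = []
    for p in range(1, participants + 1):
        u = rng.normal(0, participant_sd)
        for rep in range(1, reps_per_support + 1):
            for sup in ("UA", "LT", "FS"):
                base = 0.5 + u + rng.normal(0, noise_sd, 30)
                if sup == "FS":
                    base = base + fs_effect
                    if fs_muscle_scale is not None:
                        base = base * fs_muscle_scale
                if sup == "LT":
                    base = base + lt_effect
                obs.append((meta(p, sup, rep), np.clip(base, 0, None)))
    return obs


class TestBilateralAveraging:
    def test_pair_mean(self):
        w = np.zeros(30)
        w[0], w[1] = 0.4, 0.6  # Pec left/right
        assert average_bilateral(w)[0] == pytest.approx(0.5)

    def test_constant_passthrough(self):
        assert np.allclose(average_bilateral(np.full(30, 0.7)), 0.7)

    def test_matches_brute_force_pairing(self):
        rng = np.random.default_rng(0)
        w = rng.random(30)
        expected = [(w[2 * i] + w[2 * i + 1]) / 2 for i in range(14)] + [w[28], w[29]]
        assert np.allclose(average_bilateral(w), expected)

    def test_ra_is_last(self):
        assert MUSCLE16_NAMES[-1] == "RA"


class TestObservationTable:
    def test_row_count_and_support_columns(self):
        rng = np.random.default_rng(1)
        obs = simulate_observations(rng, participants=5, reps_per_support=2)[:10]
        table = build_observation_table(obs)
        assert len(table) == 160
        for tid, (m, _) in enumerate(obs):
            rows = table[table["trial"] == tid]
            assert (rows["support"] == m.support).all()
            assert len(rows) == 16

    def test_round_trip_unstack(self):
        rng = np.random.default_rng(2)
        obs = simulate_observations(rng, participants=2, reps_per_support=1)
        table = build_observation_table(obs)
        for tid, (_, w30) in enumerate(obs):
            got = table[table["trial"] == tid]["response"].to_numpy()
            assert np.allclose(got, average_bilateral(w30))


class TestSupportLMM:
    def test_reference_swap_reparameterization_identity(self):
        rng = np.random.default_rng(3)
        table = build_observation_table(simulate_observations(rng, fs_effect=0.15))
        f_ua = fit_support_lmm(table, "UA")
        f_lt = fit_support_lmm(table, "LT")
        lhs = f_lt.params["sup_FS"]
        rhs = f_ua.params["sup_FS"] - f_ua.params["sup_LT"]
        assert abs(lhs - rhs) < 1e-6

    def test_planted_fs_effect_estimated(self):
        rng = np.random.default_rng(4)
        table = build_observation_table(simulate_observations(rng, fs_effect=0.2))
        fit = fit_support_lmm(table, "UA")
        assert fit.params["sup_FS"] == pytest.approx(0.2, abs=0.05)
        assert fit.pvalues["sup_FS"] < 0.001

    def test_single_participant_rejected(self):
        rng = np.random.default_rng(5)
        obs = [o for o in simulate_observations(rng) if o[0].participant == 1]
        with pytest.raises(SingleParticipantError):
            fit_support_lmm(build_observation_table(obs))

    def test_single_support_level_rejected(self):
        rng = np.random.default_rng(6)
        obs = [o for o in simulate_observations(rng) if o[0].support == "UA"]
        with pytest.raises(ValueError):
            fit_support_lmm(build_observation_table(obs))


class TestInteractionLMM:
    def test_effect_coding_reference_muscle_absent_and_sum_identity(self):
        rng = np.random.default_rng(7)
        table = build_observation_table(simulate_observations(rng))
        fit = fit_muscle_interaction_lmm(table)
        main = [ix for ix in fit.params.index
                if ix.startswith("C(muscle") and ":" not in ix]
        assert len(main) == 15
        assert not any("[S.RA]" in ix for ix in fit.params.index)
        # effect coding: the implied RA coefficient is minus the sum of the
        # other 15, so the 16 muscle deviations sum to zero by construction
        implied_ra = -fit.params[main].sum()
        assert abs(fit.params[main].sum() + implied_ra) < 1e-8

    def test_planted_interaction_flags_scaled_muscles(self):
        rng = np.random.default_rng(8)
        scale = np.ones(30)
        scale[8:12] = 1.8  # both sides of Bic and Tri
        table = build_observation_table(
            simulate_observations(rng, participants=12, reps_per_support=3,
                                  fs_muscle_scale=scale)
        )
        fit = fit_muscle_interaction_lmm(table)
        flagged = [
            ix for ix in fit.pvalues.index
            if ix.startswith("sup_FS:") and fit.pvalues[ix] < 0.05 / 3
        ]
        assert any("[S.Bic]" in ix for ix in flagged)
        assert any("[S.Tri]" in ix for ix in flagged)


class TestAlphaAndDiagnostics:
    def test_bonferroni_values(self):
        assert adjust_alpha(0.05, 14) == pytest.approx(0.05 / 14)
        assert adjust_alpha(0.05, 1) == 0.05
        assert adjust_alpha(0.05, 3) == pytest.approx(0.0166666, abs=1e-6)
        with pytest.raises(ValueError):
            adjust_alpha(0.05, 0)

    def test_gaussian_residuals_pass_normality(self):
        rng = np.random.default_rng(9)
        table = build_observation_table(
            simulate_observations(rng, participants=12, noise_sd=0.05)
        )
        fit = fit_support_lmm(table)
        d = residual_diagnostics(fit)
        assert d.normality_p > 0.01
        assert abs(d.skewness) < 0.5

    def test_heteroscedasticity_flagged(self):
        rng = np.random.default_rng(10)
        obs = []
        for p in range(1, 11):
            for rep in (1, 2):
                for sup in ("UA", "LT", "FS"):
                    mean = {"UA": 0.3, "LT": 0.6, "FS": 1.2}[sup]
                    w = np.clip(mean + rng.normal(0, mean * 0.4, 30), 0, None)
                    obs.append((meta(p, sup, rep), w))
        fit = fit_support_lmm(build_observation_table(obs))
        d = residual_diagnostics(fit)
        assert d.hetero_p < 0.05 and d.hetero_spearman_rho > 0


class TestPlantedSupportShift:
    def test_seat_transition_synergy_flags_both_muscle_groups(self):
        """End-to-end: with the generator's planted upper-body-up /
        lower-limb-down full-support effect, the two-stage procedure flags at
        least one upper-body and one lower-limb muscle for the
        seat-transition synergy in >= 80 % of 25 replicate cohorts."""
        import warnings

        from synergykit.datatypes import ProcessedTrial
        from synergykit.extraction import build_strategy_dataset, extract_synergies
        from synergykit.muscles import LOWER_LIMB, UPPER_BODY
        from synergykit.preprocessing import normalize_amplitude
        from synergykit.synthetic import (
            GeneratorConfig,
            generate_cohort,
            make_ground_truth,
        )
        from synergykit.timing import find_main_peak

        label = "sit_to_stand|non_challenging|a"
        P, n_rep, hits = 12, 25, 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for rep in range(n_rep):
                cfg = GeneratorConfig(
                    synergy_counts={label: 3},
                    strategy_profiles={label: ([10, 50, 90], [6, 5, 6])},
                    task_strategies={("sit_to_stand", "non_challenging"): ["a"]},
                    movements=("sit_to_stand",),
                    floors=("non_challenging",),
                    participants=P,
                    weighting_seed=rep,
                )
                gt = make_ground_truth(cfg)
                trials, _ = generate_cohort(cfg, seed=rep, level="envelope", gt=gt)
                pts = []
                for p in range(1, P + 1):
                    sub = [
                        ProcessedTrial(envelope=t["envelope"], events=None, meta=t["meta"])
                        for t in trials if t["meta"].participant == p
                    ]
                    norm, _, _ = normalize_amplitude(sub)
                    pts.extend(norm)
                ds = build_strategy_dataset(pts)
                model = extract_synergies(
                    ds, "temporal", 3, restarts=2, max_iter=400, seed=rep
                )
                obs = [
                    [(t.meta, model.trial_dependent[i][s, :]) for i, t in enumerate(ds.trials)]
                    for s in range(3)
                ]
                results = run_support_analysis(obs)
                peaks = [find_main_peak(model.trial_independent[:, s])[0] for s in range(3)]
                seat = int(np.argmin(np.abs(np.array(peaks) - 50)))
                r = results[seat]
                if r.stage2:
                    fit = r.stage2["UA"]
                    flagged = [
                        ix.split("[S.")[1][:-1]
                        for ix in fit.pvalues.index
                        if ix.startswith("sup_FS:") and fit.pvalues[ix] < r.alpha_stage2
                    ]
                    hits += any(m in UPPER_BODY for m in flagged) and any(
                        m in LOWER_LIMB for m in flagged
                    )
        assert hits >= 20


class TestTwoStageProcedure:
    def test_bonferroni_count_and_gating(self):
        rng = np.random.default_rng(11)
        per_syn = [
            simulate_observations(rng, participants=8, fs_effect=0.3),  # strong
            simulate_observations(rng, participants=8, fs_effect=0.0),  # null
        ]
        results = run_support_analysis(per_syn, base_alpha=0.05)
        assert all(r.alpha_stage1 == pytest.approx(0.05 / 4) for r in results)
        assert results[0].significant and results[0].stage2
        assert results[0].alpha_stage2 == pytest.approx(0.05 / 3)
        if not results[1].significant:
            assert results[1].stage2 == {}
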