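import numpy as np
import pytest
from scipy import stats

from speechcoh.nulls import coherence_with_baseline, envelope_coherence_test
from speechcoh.spectral import coherence, fit_one_over_f, trial_csd
from speechcoh.synthetic import (DEFAULT_GROUPS, GroupSpec, SyntheticConfig,
                                 generate_av_envelope_pair,
                                 generate_behavioral_cohort,
                                 generate_envelope_trials, generate_recording,
                                 generate_subject, grid_adjacency, jitter_config)


class TestEnvelopePairs:
    def test_deterministic_given_trial_seed(self):
        cfg = SyntheticConfig()
        a1, v1 = generate_av_envelope_pair(cfg, trial_seed=42)
        a2, v2 = generate_av_envelope_pair(cfg, trial_seed=42)
        assert np.array_equal(a1.samples, a2.samples)
        assert np.array_equal(v1.samples, v2.samples)

    def test_nonnegative_and_finite(self):
        cfg = SyntheticConfig()
        a, v = generate_av_envelope_pair(cfg, trial_seed=3)
        for env in (a, v):
            assert np.all(env.samples >= 0)
            assert np.all(np.isfinite(env.samples))
            assert env.fs == cfg.fs and len(env) == cfg.n_samples

    def test_band_coherence_exceeds_out_of_band(self):
        cfg = SyntheticConfig(av_env_coherence=0.5)
        aud, vis = generate_envelope_trials(cfg, n_trials=200, seed=5)
        grid = np.arange(1.0, 20.0, 1.0)
        cm = coherence(trial_csd(aud, vis, cfg.fs, grid))
        vals = cm.values[0]
        in_band = vals[(grid >= 2) & (grid <= 8)].mean()
        out_band = vals[(grid >= 12) & (grid <= 19)].mean()
        assert in_band / out_band >= 3
        # shared-component weight sqrt(lambda) puts the asymptotic magnitude
        # coherence at lambda; taper leakage attenuates it slightly
        assert in_band == pytest.approx(0.5, rel=0.15)

    def test_zero_target_coherence_is_chance(self):
        cfg = SyntheticConfig(av_env_coherence=0.0)
        aud, vis = generate_envelope_trials(cfg, n_trials=40, seed=9)
        res = envelope_coherence_test(aud, vis, cfg.fs,
                                      freq_grid=np.arange(1.0, 20.0),
                                      n_perm=500, seed=2)
        assert res.significant.sum() <= 1

    def test_one_over_f_spectrum(self):
        cfg = SyntheticConfig()
        aud, _ = generate_envelope_trials(cfg, n_trials=30, seed=11)
        grid = np.arange(1.0, 30.0)
        est = trial_csd(aud, aud, cfg.fs, grid)
        slope, _, _ = fit_one_over_f(est.auto_x[0], grid)
        assert slope < -0.5

    def test_unit_av_coherence_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(av_env_coherence=1.0)


class TestRecordings:
    def test_shapes_groups_adjacency(self):
        cfg = SyntheticConfig(n_trials_per_condition=6)
        aud, vis = generate_envelope_trials(cfg, seed=0)
        rec = generate_recording(cfg, aud, vis, "AV_high", seed=1)
        assert rec.data.shape == (6, 27, cfg.n_samples)
        assert set(rec.groups) == {"STG", "occipital", "other"}
        assert rec.adjacency.sum() > 0
        assert rec.condition == "AV_high"

    def test_unknown_condition_rejected(self):
        cfg = SyntheticConfig(n_trials_per_condition=4)
        aud, vis = generate_envelope_trials(cfg, seed=0)
        with pytest.raises(ValueError):
            generate_recording(cfg, aud, vis, "AV_medium")

    def test_zero_gain_recording_shows_no_coupling(self):
        groups = {"flat": GroupSpec(n_channels=4)}
        cfg = SyntheticConfig(n_trials_per_condition=20, channel_groups=groups)
        effects = []
        for s in range(8):
            aud, vis = generate_envelope_trials(cfg, seed=100 + s)
            rec = generate_recording(cfg, aud, vis, "AV_low", seed=s)
            cm = coherence_with_baseline(rec, aud, cfg.fs, np.arange(2.0, 9.0),
                                         n_perm=10, seed=s)
            effects.append(cm.effect.mean())
        t, p = stats.ttest_1samp(effects, 0.0)
        assert p > 0.01

    def test_coupling_gain_monotonically_increases_effect(self):
        """True-minus-baseline coherence grows with the generating gain."""
        gains = [0.0, 0.15, 0.3, 0.6, 1.2]
        means = []
        for g in gains:
            cfg = SyntheticConfig(
                n_trials_per_condition=20,
                channel_groups={"g": GroupSpec(n_channels=2, gain_auditory=g)})
            eff = []
            for s in range(3):
                aud, vis = generate_envelope_trials(cfg, seed=500 + s)
                rec = generate_recording(cfg, aud, vis, "AO_high", seed=s)
                cm = coherence_with_baseline(rec, aud, cfg.fs, np.arange(2.0, 9.0),
                                             n_perm=10, seed=s)
                eff.append(cm.effect.mean())
            means.append(np.mean(eff))
        rho = stats.spearmanr(gains, means).statistic
        assert rho > 0.9

    def test_vo_condition_carries_no_direct_auditory_drive(self):
        """In visual-only trials the auditory envelope couples to visual
        channels only through the AV envelope correlation."""
        cfg = SyntheticConfig(
            n_trials_per_condition=30, av_env_coherence=0.6,
            channel_groups={"occ": GroupSpec(n_channels=3, gain_visual=0.8)})
        ord_eff, par_eff = [], []
        for s in range(6):
            aud, vis = generate_envelope_trials(cfg, seed=900 + s)
            rec = generate_recording(cfg, aud, vis, "VO", seed=s)
            grid = np.arange(2.0, 9.0)
            co = coherence_with_baseline(rec, aud, cfg.fs, grid, n_perm=15, seed=s)
            pa = coherence_with_baseline(rec, aud, cfg.fs, grid, n_perm=15, seed=s,
                                         z_trials=vis, estimator="partial_coherence")
            ord_eff.append(co.effect.mean())
            par_eff.append(pa.effect.mean())
        t_ord, p_ord = stats.ttest_1samp(ord_eff, 0.0, alternative="greater")
        t_par, p_par = stats.ttest_1samp(par_eff, 0.0, alternative="greater")
        assert p_ord < 0.01          # leaked auditory coherence present
        assert p_par > 0.05          # removed by partialling the visual envelope

    def test_deterministic_given_seed(self):
        cfg = SyntheticConfig(n_trials_per_condition=4)
        aud, vis = generate_envelope_trials(cfg, seed=1)
        r1 = generate_recording(cfg, aud, vis, "AO_low", seed=2)
        r2 = generate_recording(cfg, aud, vis, "AO_low", seed=2)
        assert np.array_equal(r1.data, r2.data)


class TestLayoutAndSubjects:
    def test_grid_adjacency_is_blockwise_symmetric(self):
        names, adj, groups = grid_adjacency(DEFAULT_GROUPS)
        assert len(names) == sum(g.n_channels for g in DEFAULT_GROUPS.values())
        assert np.array_equal(adj, adj.T) and not np.any(np.diag(adj))
        stg = [names.index(c) for c in groups["STG"]]
        occ = [names.index(c) for c in groups["occipital"]]
        assert not adj[np.ix_(stg, occ)].any()

    def test_jitter_preserves_zero_gains(self, rng):
        cfg = SyntheticConfig()
        jit = jitter_config(cfg, rng)
        assert jit.channel_groups["STG"].gain_visual == 0.0
        assert jit.channel_groups["STG"].gain_auditory > 0.0
        assert jit.channel_groups["STG"].gain_auditory != cfg.channel_groups["STG"].gain_auditory

    def test_generate_subject_covers_conditions(self):
        cfg = SyntheticConfig(n_trials_per_condition=3)
        out = generate_subject(cfg, conditions=("AV_low", "VO"), seed=4)
        assert set(out) == {"AV_low", "VO"}
        assert out["AV_low"]["recording"].condition == "AV_low"


class TestBehavioralCohort:
    def test_target_correlation_high(self):
        df = generate_behavioral_cohort(200, benefit_lipreading_r=1.0, seed=0)
        r = np.corrcoef(df["lip_reading"], df["av_benefit"])[0, 1]
        assert r > 0.95

    def test_zero_target_correlation_within_critical_bounds(self):
        crit = stats.t.ppf(0.975, 198) / np.sqrt(198 + stats.t.ppf(0.975, 198) ** 2)
        inside = 0
        for s in range(40):
            df = generate_behavioral_cohort(200, benefit_lipreading_r=0.0, seed=s)
            r = np.corrcoef(df["lip_reading"], df["av_benefit"])[0, 1]
            inside += abs(r) < crit
        assert inside >= 33   # ~95% expected

    def test_bounded_and_reproducible(self):
        a = generate_behavioral_cohort(14, 0.9, seed=3)
        b = generate_behavioral_cohort(14, 0.9, seed=3)
        assert a.equals(b)
        for c in ("AO_high", "AO_low", "AV_high", "AV_low", "VO"):
            assert a[c].between(0, 100).all()

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            generate_behavioral_cohort(10, benefit_lipreading_r=1.5)
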