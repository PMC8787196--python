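"""Semi-Markov generator: determinism, dwell laws, parameter recovery,
progression, optogenetic windows."""

import numpy as np
import pytest

from groomsyntax import synthetic as syn
from groomsyntax.ethogram import ANTERIOR, GROOMING, LABELS, LABEL_INDEX, to_bouts
from groomsyntax.features import anterior_proportion, syntax_vector
from helpers import stationary_distribution, truncated_lognormal_mean_frames


def flat_config(frames: int) -> syn.GeneratorConfig:
    M = syn.dust_base_config().early_matrix
    return syn.GeneratorConfig(early_matrix=M, late_matrix=M.copy(),
                               recording_frames=frames)


class TestConfigValidation:
    def test_rejects_nonzero_diagonal(self):
        M = syn.dust_base_config().early_matrix.copy()
        M[0, 0] = 0.1
        with pytest.raises(ValueError, match="zero diagonal"):
            syn.GeneratorConfig(early_matrix=M, late_matrix=M)

    def test_rejects_non_stochastic_rows(self):
        M = syn.dust_base_config().early_matrix.copy()
        M[2] *= 0.5
        with pytest.raises(ValueError, match="sum to 1"):
            syn.GeneratorConfig(early_matrix=syn.dust_base_config().early_matrix,
                                late_matrix=M)

    def test_degenerate_row_errors(self):
        M = np.zeros((7, 7))
        M[:, 0] = 1.0
        M[0, :] = 0.0  # F row has no mass anywhere
        with pytest.raises(ValueError, match="degenerate"):
            syn.matrix_from_dict({})  # fully empty matrix
        with pytest.raises(ValueError):
            syn._normalize_rows(M)

    def test_phase_interpolation_row_stochastic(self):
        cfg = syn.dust_base_config()
        for t in (0.0, 300.0, 400.0, 1500.0):
            P = syn.transition_matrix_at(cfg, t)
            assert np.allclose(P.sum(axis=1), 1.0)
            assert np.allclose(np.diag(P), 0.0)


class TestSimulateEthogram:
    def test_seeded_determinism_and_length(self):
        cfg = syn.dust_base_config(recording_frames=5000)
        a = syn.simulate_ethogram(cfg, seed=9)
        b = syn.simulate_ethogram(cfg, seed=9)
        assert np.array_equal(a.labels, b.labels)
        assert a.n_frames == 5000
        c = syn.simulate_ethogram(cfg, seed=10)
        assert not np.array_equal(a.labels, c.labels)

    def test_deterministic_two_state_chain_alternates(self):
        rows = {s: ({"H": 1.0} if s != "H" else {"F": 1.0}) for s in LABELS}
        M = syn.matrix_from_dict(rows)
        cfg = syn.GeneratorConfig(early_matrix=M, late_matrix=M.copy(),
                                  recording_frames=3000)
        e = syn.simulate_ethogram(cfg, seed=4)
        actions = [b.action for b in to_bouts(e)]
        assert set(actions) <= {"F", "H"}
        assert all(x != y for x, y in zip(actions, actions[1:]))

    def test_parameter_recovery_long_run(self):
        cfg = flat_config(1_200_000)  # ~30k bouts
        sv = syntax_vector(to_bouts(syn.simulate_ethogram(cfg, seed=11)))
        assert np.abs(sv.probs - cfg.early_matrix).max() < 0.03

    def test_recovery_error_shrinks_with_length(self):
        errs = []
        for frames in (30_000, 150_000, 900_000):
            cfg = flat_config(frames)
            sv = syntax_vector(to_bouts(syn.simulate_ethogram(cfg, seed=21)))
            errs.append(np.abs(sv.probs - cfg.early_matrix).max())
        # monotone in expectation; allow slack on the middle point
        assert errs[2] < errs[0]
        assert errs[1] < errs[0] * 1.5

    def test_grooming_dwell_mode_500_to_750_ms(self):
        cfg = syn.dust_base_config(recording_frames=200_000)
        e = syn.simulate_ethogram(cfg, seed=1)
        durs = [b.n_frames for b in to_bouts(e) if b.action in GROOMING]
        modal = np.bincount(durs).argmax()
        assert 0.5 <= modal / 30.0 <= 0.75

    def test_no_bout_below_cutoff(self):
        e = syn.simulate_ethogram(syn.dust_base_config(recording_frames=20_000), seed=2)
        bouts = to_bouts(e)
        assert all(b.duration_s >= 0.150 for b in bouts[:-1])  # last may be truncated

    def test_anterior_proportion_declines(self):
        cfg = syn.dust_base_config(recording_frames=50_000)
        for seed in (1, 2, 3):
            e = syn.simulate_ethogram(cfg, seed=seed)
            assert anterior_proportion(e, 0.0, 0.1) > anterior_proportion(e, 0.9, 1.0)


class TestPopulations:
    def test_population_determinism_and_ids(self):
        tpl = syn.GroupTemplate("gX", syn.dust_base_config(recording_frames=2000))
        a = syn.simulate_population(tpl, 3, seed=5)
        b = syn.simulate_population(tpl, 3, seed=5)
        assert [x.fly_id for x in a] == ["gX_f00", "gX_f01", "gX_f02"]
        for x, y in zip(a, b):
            assert np.array_equal(x.labels, y.labels)
        with pytest.raises(ValueError):
            syn.simulate_population(tpl, 0, seed=5)

    def test_pooled_syntax_converges_without_jitter(self):
        tpl = syn.GroupTemplate(
            "nz", flat_config(240_000), jitter_concentration=None
        )
        pop = syn.simulate_population(tpl, 10, seed=8)
        counts = np.zeros((7, 7))
        for e in pop:
            counts += syntax_vector(to_bouts(e)).counts
        pooled = counts / counts.sum(axis=1, keepdims=True)
        assert np.abs(pooled - tpl.config.early_matrix).max() < 0.025

    def test_divergence_moves_target_probability(self):
        base = syn.dust_base_config()
        M = syn.apply_divergence(
            base.early_matrix,
            {("F", "H"): -0.15, ("F", "Wk"): 0.075, ("F", "S"): 0.075},
        )
        i, j = LABEL_INDEX["F"], LABEL_INDEX["H"]
        assert M[i, j] == pytest.approx(base.early_matrix[i, j] - 0.15)
        assert np.allclose(M.sum(axis=1), 1.0)

    def test_jitter_preserves_row_stochasticity_and_support(self):
        rng = np.random.default_rng(0)
        M = syn.dust_base_config().early_matrix
        J = syn.jitter_matrix(M, 50.0, rng)
        assert np.allclose(J.sum(axis=1), 1.0)
        assert np.allclose(np.diag(J), 0.0)
        assert ((M == 0) >= (J == 0)).all() or np.array_equal(M == 0, J == 0)

    def test_individual_sessions_share_fly_matrix(self):
        tpl = syn.GroupTemplate("cs", syn.dust_base_config(recording_frames=2000))
        ethos = syn.simulate_individual_sessions(tpl, 2, 3, seed=3)
        assert len(ethos) == 6
        ids = {(e.fly_id, e.session_id) for e in ethos}
        assert ("cs_f00", "day1") in ids and ("cs_f01", "day3") in ids
        # same fly, different day: different realization
        d1 = next(e for e in ethos if e.fly_id == "cs_f00" and e.session_id == "day1")
        d2 = next(e for e in ethos if e.fly_id == "cs_f00" and e.session_id == "day2")
        assert not np.array_equal(d1.labels, d2.labels)


class TestOptoSessions:
    def test_in_window_frames_mostly_anterior(self, opto_session):
        fps = opto_session.frame_rate_hz
        inw = np.concatenate([
            opto_session.labels[int(s * fps):int(t * fps)]
            for s, t in syn.DEFAULT_OPTO_WINDOWS
        ])
        assert np.isin(inw, list(ANTERIOR)).mean() >= 0.90

    def test_empty_window_list_matches_plain_simulation(self):
        cfg = syn.opto_config(recording_frames=4000)
        a = syn.simulate_opto_session(cfg, windows=[], seed=6)
        b = syn.simulate_ethogram(cfg, seed=6)
        assert np.array_equal(a.labels, b.labels)

    def test_overlapping_windows_rejected(self):
        cfg = syn.opto_config(recording_frames=20_000)
        with pytest.raises(ValueError, match="overlap"):
            syn.simulate_opto_session(cfg, windows=[(0, 200), (100, 300)], seed=1)

    def test_full_coverage_matches_stationary_oracle(self):
        cfg = syn.opto_config(recording_frames=120_000)
        total_s = 120_000 / 30.0
        e = syn.simulate_opto_session(cfg, windows=[(0.0, total_s)], seed=13)
        A = syn.anterior_dominant_matrix()
        pi = stationary_distribution(A)
        mean_frames = np.array([
            truncated_lognormal_mean_frames(*cfg.duration_params[a], cfg.min_bout_s, 30.0)
            for a in LABELS
        ])
        expected = (pi * mean_frames) / (pi * mean_frames).sum()
        ant_expected = expected[LABEL_INDEX["F"]] + expected[LABEL_INDEX["H"]]
        ant_observed = anterior_proportion(e)
        assert ant_observed == pytest.approx(ant_expected, abs=0.05)
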