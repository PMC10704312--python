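import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.special import expit

from actema.accelerometry import process_raw
from actema.linkage import build_dataset
from actema.simulate import (DEFAULT_ITEM_PARAMS, HurdleParams, ItemParams,
                             SyntheticConfig, gen_item_scores, gen_model_frame,
                             gen_outcome_minutes, gen_participants, simulate)


def _config(**kw):
    kw.setdefault("n_participants", 10)
    kw.setdefault("n_days", 2)
    return SyntheticConfig(**kw)


class TestConfig:
    @pytest.mark.parametrize("bad", [
        {"response_prob": 1.2},
        {"truncation_mode": "sometimes"},
        {"prompts_per_day": 20},  # 20 x 60 min do not fit in 13 h
        {"windows": (30, 15)},
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            _config(**bad)

    def test_negative_item_sd_rejected(self):
        with pytest.raises(ValueError):
            ItemParams(mu=4, tau=-1, sigma=1)

    def test_nonpositive_theta_rejected(self):
        with pytest.raises(ValueError):
            HurdleParams(theta=0.0)


class TestParticipants:
    def test_zero_between_sd_gives_zero_intercepts(self):
        items = {"intention": ItemParams(mu=4, tau=0.0, sigma=1.0)}
        cfg = _config(item_params=items, driver_item="intention")
        _, truth = gen_participants(cfg)
        assert (truth.item_intercepts["intention"] == 0).all()

    def test_same_seed_identical_rosters(self):
        cfg = _config(seed=42)
        r1, t1 = gen_participants(cfg)
        r2, t2 = gen_participants(cfg)
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(t1.item_intercepts, t2.item_intercepts)

    def test_intercept_sd_matches_tau_at_large_n(self):
        items = {"intention": ItemParams(mu=4, tau=1.5, sigma=1.0)}
        cfg = SyntheticConfig(n_participants=2000, item_params=items,
                              driver_item="intention", seed=5)
        _, truth = gen_participants(cfg)
        sd = truth.item_intercepts["intention"].std(ddof=1)
        assert abs(sd - 1.5) / 1.5 < 0.05


class TestItemScores:
    def _scores(self, cfg):
        rng = np.random.default_rng(cfg.seed)
        roster, truth = gen_participants(cfg, rng)
        n = cfg.n_participants * 4
        prompts = pd.DataFrame({
            "participant_id": np.repeat(roster["participant_id"], 4),
            "status": "completed",
        })
        return gen_item_scores(roster, prompts, cfg, truth, rng)

    def test_degenerate_variances_give_constant(self):
        items = {"intention": ItemParams(mu=4, tau=0.0, sigma=0.0)}
        cfg = _config(item_params=items, driver_item="intention",
                      likert_mode="continuous")
        scores = self._scores(cfg)
        assert (scores["intention"] == 4.0).all()

    def test_discrete_scores_on_likert_scale(self):
        cfg = _config(likert_mode="discrete", seed=8)
        scores = self._scores(cfg)
        for col in cfg.item_params:
            vals = scores[col].dropna()
            assert vals.isin(range(1, 8)).all()

    def test_within_share_of_variance(self):
        # tau=0.8, sigma=1.2: within share = 1.44/(1.44+0.64) ~ 0.692
        items = {"intention": ItemParams(mu=4, tau=0.8, sigma=1.2)}
        cfg = SyntheticConfig(n_participants=200, n_days=5, prompts_per_day=6,
                              item_params=items, driver_item="intention",
                              likert_mode="continuous", seed=17)
        rng = np.random.default_rng(cfg.seed)
        roster, truth = gen_participants(cfg, rng)
        prompts = pd.DataFrame({
            "participant_id": np.repeat(roster["participant_id"], 30),
            "status": "completed",
        })
        scores = gen_item_scores(roster, prompts, cfg, truth, rng)
        g = scores.groupby("participant_id")["intention"]
        between_var = g.mean().var(ddof=1)
        within_var = g.transform(lambda s: s - s.mean()).var(ddof=1)
        share = within_var / (within_var + between_var)
        assert abs(share - 0.692) < 0.05


class TestOutcome:
    def _frame(self, hurdle, n=64, per=30, seed=3):
        cfg = SyntheticConfig(
            n_participants=n, n_days=per // 6, prompts_per_day=6,
            response_prob=1.0, likert_mode="continuous",
            hurdle_params={"lpa": hurdle}, windows=(120,), seed=seed)
        return gen_model_frame(cfg, "lpa")

    def test_closed_hurdle_gives_all_zero(self):
        hp = HurdleParams(alpha0=-30.0, omega_a=0.0, beta_w=0.0, beta_b=0.0)
        df = self._frame(hp)
        assert (df["y"] == 0).all()

    def test_nb_mean_identity_on_open_hurdle(self):
        hp = HurdleParams(alpha0=30.0, omega_a=0.0, beta_w=0.0, beta_b=0.0,
                          gamma0=np.log(5.0), omega_c=0.0, delta_w=0.0,
                          delta_b=0.0, theta=1e6)
        df = self._frame(hp, n=100, per=30)
        assert df["y"].mean() == pytest.approx(5.0, rel=0.05)

    def test_counts_capped_at_window(self):
        hp = HurdleParams(alpha0=30.0, omega_a=0.0, gamma0=np.log(200.0),
                          theta=5.0, beta_w=0, beta_b=0, delta_w=0, delta_b=0,
                          omega_c=0.0)
        df = self._frame(hp, n=10, per=6)
        assert (df["y"] <= 120).all()

    def test_mean_overflow_names_prompt(self):
        hp = HurdleParams(gamma0=50.0)
        cfg = SyntheticConfig(n_participants=2, n_days=1, response_prob=1.0,
                              hurdle_params={"lpa": hp}, windows=(120,), seed=1)
        with pytest.raises(RuntimeError, match="participant"):
            gen_model_frame(cfg, "lpa")

    def test_zero_fraction_matches_numeric_integration(self):
        # effects = 0: P(y=0) = E_u[1 - invlogit(alpha0 + u)]
        hp = HurdleParams(alpha0=0.7, omega_a=0.9, beta_w=0.0, beta_b=0.0)
        df = self._frame(hp, n=400, per=30, seed=10)
        expected = integrate.quad(
            lambda u: (1 - expit(0.7 + u))
            * np.exp(-0.5 * (u / 0.9) ** 2) / (0.9 * np.sqrt(2 * np.pi)),
            -8, 8)[0]
        assert (df["y"] == 0).mean() == pytest.approx(expected, abs=0.02)


class TestTraceAndRaw:
    def test_full_determinism(self):
        cfg = dict(n_participants=5, n_days=2, signal_level="minute", seed=99)
        a = simulate(SyntheticConfig(**cfg))
        b = simulate(SyntheticConfig(**cfg))
        pd.testing.assert_frame_equal(a.observations, b.observations)
        pd.testing.assert_frame_equal(a.minutes, b.minutes)
        pd.testing.assert_frame_equal(a.prompts, b.prompts)

    def test_nested_window_monotonicity(self, small_minute_sim):
        obs = small_minute_sim.observations
        for k in ("lpa", "mvpa", "tpa"):
            assert (obs[f"{k}_15"] <= obs[f"{k}_30"]).all()
            assert (obs[f"{k}_30"] <= obs[f"{k}_60"]).all()
            assert (obs[f"{k}_60"] <= obs[f"{k}_120"]).all()

    def test_minute_trace_round_trip(self, small_minute_sim):
        sim = small_minute_sim
        ds = build_dataset(sim.prompts, sim.minutes)
        for d in (15, 30, 60, 120):
            for k in ("lpa", "mvpa"):
                np.testing.assert_array_equal(
                    ds[f"{k}_{d}"].to_numpy(),
                    sim.observations[f"{k}_{d}"].to_numpy(dtype=float))

    def test_enmo_bands_match_classes(self, small_minute_sim):
        m = small_minute_sim.minutes
        assert (m.loc[m["intensity"] == "SED", "enmo_mg"] < 57).all()
        lpa = m.loc[m["intensity"] == "LPA", "enmo_mg"]
        assert ((lpa > 57) & (lpa < 104)).all()
        assert (m.loc[m["intensity"] == "MVPA", "enmo_mg"] > 104).all()

    def test_raw_round_trip_within_1mg(self):
        cfg = SyntheticConfig(n_participants=1, n_days=1, prompts_per_day=2,
                              signal_level="raw", sample_rate_hz=10, seed=5)
        sim = simulate(cfg)
        assert len(sim.raw) == len(sim.minutes) * 600  # 60 s x 10 Hz
        processed = process_raw(sim.raw)
        merged = sim.minutes.merge(processed, on=["participant_id",
                                                  "minute_start"])
        err = np.abs(merged["enmo_mg_x"] - merged["enmo_mg_y"])
        assert err.max() < 1.0

    def test_zero_target_gives_resting_gravity(self):
        from actema.simulate import gen_raw_signal
        minutes = pd.DataFrame({
            "participant_id": ["P001"],
            "minute_start": [pd.Timestamp("2020-01-06 09:00")],
            "enmo_mg": [0.0], "intensity": ["SED"],
        })
        cfg = SyntheticConfig(n_participants=1, n_days=1, sample_rate_hz=5)
        raw = gen_raw_signal(minutes, cfg, np.random.default_rng(0))
        assert np.allclose(raw[["x_g", "y_g"]], 0.0) and (raw["z_g"] == 1).all()


def test_default_item_panel_majority_within_variance():
    for p in DEFAULT_ITEM_PARAMS.values():
        assert p.sigma**2 / (p.sigma**2 + p.tau**2) > 0.5
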