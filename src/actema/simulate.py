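"""Synthetic EMA + accelerometer study generator with known ground truth.

Emulates a time-based EMA study in older adults: 64 participants carry a
smartphone for 7 days and are prompted 6 times per day inside predefined
one-hour frames between 09:00 and 22:00, answering 7 momentary items on
1-7 Likert scales, while a wrist accelerometer records their activity.
Every quantity the downstream pipeline estimates is generated from an
explicit parametric model, so estimator correctness can be checked by
parameter recovery rather than against non-deposited study data.

Generative model
----------------
Items:      x_ijk = mu_k + u_ik + e_ijk,  u_ik ~ N(0, tau_k^2),
            e_ijk ~ N(0, sigma_k^2); optionally rounded and clamped to
            the 1-7 scale (``likert_mode="discrete"``).
Activity:   a two-part (hurdle) process per outcome (LPA / MVPA) for the
            longest prospective window after each answered prompt:
            z ~ Bernoulli(invlogit(alpha0 + a_i + beta_w (x - xbar_i)
                                   + beta_b xbar_i)),
            and, given z = 1, minutes ~ NB2(mean exp(gamma0 + c_i
            + delta_w (x - xbar_i) + delta_b xbar_i), dispersion theta),
            zero-truncated by rejection (``truncation_mode="truncated"``)
            or with zeros replaced by 1 (``"untruncated"``, a small
            documented bias).  Counts are capped at the window length
            (logged when it happens).
Nesting:    active minutes are placed uniformly at random inside the
            longest window, so shorter nested windows (15 in 30 in 60 in
            120) are thinned subsets of one latent trace and count
            monotonicity holds by construction.

Three output levels: ``observation`` (linked table only), ``minute``
(adds a classified per-minute ENMO trace), ``raw`` (adds triaxial
samples whose processed ENMO reproduces the minute trace).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import accelerometry as acc
from . import ema

__all__ = [
    "ItemParams",
    "HurdleParams",
    "SyntheticConfig",
    "GroundTruth",
    "SimulationResult",
    "DEFAULT_ITEM_PARAMS",
    "gen_participants",
    "gen_prompts",
    "gen_item_scores",
    "gen_outcome_minutes",
    "gen_minute_trace",
    "gen_raw_signal",
    "simulate",
]

logger = logging.getLogger(__name__)


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ItemParams:
    """Likert-item parameters: grand mean, between- and within-person SD."""

    mu: float
    tau: float  # between-person SD
    sigma: float  # within-person (momentary) SD

    def __post_init__(self):
        if self.tau < 0 or self.sigma < 0:
            raise ValueError("item SDs must be non-negative")


@dataclass(frozen=True)
class HurdleParams:
    """Two-part outcome parameters for one activity intensity.

    Logistic part: intercept ``alpha0``, random-intercept SD ``omega_a``,
    within effect ``beta_w``, between effect ``beta_b``.  Count part (log
    scale): intercept ``gamma0``, random-intercept SD ``omega_c``, within
    ``delta_w``, between ``delta_b``, NB2 dispersion ``theta``.
    """

    alpha0: float = 0.0
    omega_a: float = 0.8
    beta_w: float = 0.3
    beta_b: float = 0.1
    gamma0: float = 2.3
    omega_c: float = 0.5
    delta_w: float = 0.2
    delta_b: float = 0.05
    theta: float = 1.5

    def __post_init__(self):
        if self.omega_a < 0 or self.omega_c < 0:
            raise ValueError("random-intercept SDs must be non-negative")
        if self.theta <= 0:
            raise ValueError("NB dispersion theta must be positive")


# Grand means and total SDs shaped like a typical older-adult EMA panel;
# the split gives every item ~60% within-person variance, matching the
# selection rule (>50% within share) that retained these 7 items.
def _split(mu, sd, within_share=0.6):
    return ItemParams(mu=mu, tau=sd * np.sqrt(1 - within_share),
                      sigma=sd * np.sqrt(within_share))


DEFAULT_ITEM_PARAMS = {
    "relax": _split(4.7, 1.5),
    "satisf": _split(4.8, 1.4),
    "irrit": _split(1.5, 1.0),
    "down": _split(1.3, 0.8),
    "fatigue": _split(1.9, 1.1),
    "intention": _split(3.7, 2.1),
    "selfeff": _split(4.2, 2.1),
}

# Plausible study-scale hurdle defaults for the 120-minute window,
# anchored at light-activity prevalence ~90% and MVPA prevalence ~56%
# with means near the descriptive magnitudes of such cohorts.
DEFAULT_HURDLE_PARAMS = {
    "lpa": HurdleParams(alpha0=2.0, omega_a=0.8, beta_w=0.38, beta_b=0.10,
                        gamma0=2.40, omega_c=0.5, delta_w=0.21, delta_b=0.05,
                        theta=1.5),
    "mvpa": HurdleParams(alpha0=0.2, omega_a=0.8, beta_w=0.39, beta_b=0.10,
                         gamma0=1.90, omega_c=0.5, delta_w=0.25, delta_b=0.05,
                         theta=1.2),
}


@dataclass
class SyntheticConfig:
    """Full description of one simulated study."""

    n_participants: int = 64
    n_days: int = 7
    prompts_per_day: int = 6
    day_window: tuple = ("09:00", "22:00")
    frame_duration: int = 60
    item_params: dict = field(default_factory=lambda: dict(DEFAULT_ITEM_PARAMS))
    response_prob: float = 0.7733
    hurdle_params: dict = field(
        default_factory=lambda: dict(DEFAULT_HURDLE_PARAMS))
    driver_item: str = "intention"
    windows: tuple = (15, 30, 60, 120)
    truncation_mode: str = "truncated"
    likert_mode: str = "discrete"
    signal_level: str = "observation"
    sample_rate_hz: float = 25.0
    start_date: str = "2020-01-06"
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.response_prob <= 1:
            raise ValueError("response_prob must lie in [0, 1]")
        if self.truncation_mode not in ("truncated", "untruncated"):
            raise ValueError("truncation_mode must be truncated|untruncated")
        if self.likert_mode not in ("discrete", "continuous"):
            raise ValueError("likert_mode must be discrete|continuous")
        if self.signal_level not in ("observation", "minute", "raw"):
            raise ValueError("signal_level must be observation|minute|raw")
        if self.driver_item not in self.item_params:
            raise ValueError(f"driver_item {self.driver_item!r} has no item params")
        w0 = ema._parse_clock(self.day_window[0])
        w1 = ema._parse_clock(self.day_window[1])
        if self.prompts_per_day * self.frame_duration > w1 - w0:
            raise ValueError("prompt frames do not fit inside the day window")
        if tuple(sorted(self.windows)) != tuple(self.windows) or min(self.windows) <= 0:
            raise ValueError("windows must be strictly increasing and positive")

    @property
    def model_window(self) -> int:
        """The longest prospective window; the hurdle model is defined on it."""
        return max(self.windows)


@dataclass
class GroundTruth:
    """Everything needed to verify recovery: intercepts, predictors, config."""

    item_intercepts: pd.DataFrame  # participants x items (u_ik)
    hurdle_intercepts: pd.DataFrame  # a_i / c_i per outcome
    config: SyntheticConfig
    linear_predictors: pd.DataFrame | None = None  # per answered prompt

    def to_json(self, path) -> None:
        payload = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(self.config).items()},
            "item_intercepts": self.item_intercepts.to_dict(),
            "hurdle_intercepts": self.hurdle_intercepts.to_dict(),
        }
        if self.linear_predictors is not None:
            payload["linear_predictors"] = self.linear_predictors.to_dict("list")
        with open(path, "w") as fh:
            json.dump(payload, fh, default=float, indent=1)


def _participant_ids(n):
    return [f"P{i + 1:03d}" for i in range(n)]


def gen_participants(config: SyntheticConfig,
                     rng: np.random.Generator | None = None):
    """Draw the participant roster and all person-level random intercepts.

    Item intercepts u_ik ~ N(0, tau_k^2); hurdle intercepts a_i ~
    N(0, omega_a^2) and c_i ~ N(0, omega_c^2) per outcome.  Deterministic
    given ``config.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pids = _participant_ids(config.n_participants)
    items = {k: rng.normal(0.0, p.tau, config.n_participants)
             for k, p in config.item_params.items()}
    item_df = pd.DataFrame(items, index=pids)
    hurdle = {}
    for out, hp in config.hurdle_params.items():
        hurdle[f"a_{out}"] = rng.normal(0.0, hp.omega_a, config.n_participants)
        hurdle[f"c_{out}"] = rng.normal(0.0, hp.omega_c, config.n_participants)
    hurdle_df = pd.DataFrame(hurdle, index=pids)
    roster = pd.DataFrame({"participant_id": pids})
    truth = GroundTruth(item_intercepts=item_df, hurdle_intercepts=hurdle_df,
                        config=config)
    return roster, truth


def gen_prompts(roster: pd.DataFrame, config: SyntheticConfig,
                rng: np.random.Generator) -> pd.DataFrame:
    """Simulate the prompting protocol: triggers, response status, latency.

    Non-response is Bernoulli(1 - response_prob), independent of state.
    Latency is zero for most answered prompts with an exponential tail
    clipped at the 20-minute expiry; completion duration is lognormal
    around ~1.8 min.
    """
    schedule = ema.build_frames(config.day_window, config.prompts_per_day,
                                config.frame_duration)
    start = pd.Timestamp(config.start_date)
    rows = []
    for pid in roster["participant_id"]:
        for day in range(config.n_days):
            date = start + pd.Timedelta(days=day)
            for fi, frame in enumerate(schedule.frames):
                t = ema.draw_trigger(frame, date, rng)
                answered = rng.uniform() < config.response_prob
                if answered:
                    latency = 0.0 if rng.uniform() < 0.55 else min(
                        rng.exponential(5.0), ema.EXPIRY_MIN)
                    duration = float(np.exp(rng.normal(0.58, 0.36)))
                else:
                    latency = np.nan
                    duration = np.nan
                rows.append({
                    "participant_id": pid,
                    "day": day,
                    "frame_index": fi,
                    "trigger_time": t["trigger_time"],
                    "reminder1": t["reminder1"],
                    "reminder2": t["reminder2"],
                    "expiry_time": t["expiry_time"],
                    "status": "completed" if answered else "missed",
                    "latency_min": round(latency, 2) if answered else np.nan,
                    "completion_duration_min": (round(duration, 2)
                                                if answered else np.nan),
                })
    return pd.DataFrame(rows)


def gen_item_scores(roster: pd.DataFrame, prompts: pd.DataFrame,
                    config: SyntheticConfig, truth: GroundTruth,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Attach item scores to answered prompts.

    Latent x_ijk = mu_k + u_ik + e_ijk; in ``discrete`` mode rounded and
    clamped to [1, 7], in ``continuous`` mode the latent value itself
    (used by unbiased recovery tests).
    """
    out = prompts.copy()
    answered = out["status"] == "completed"
    n = len(out)
    for k, p in config.item_params.items():
        u = truth.item_intercepts[k].reindex(out["participant_id"]).to_numpy()
        latent = p.mu + u + rng.normal(0.0, p.sigma, n)
        if config.likert_mode == "discrete":
            vals = np.clip(np.round(latent), 1, 7)
        else:
            vals = latent
        vals = np.where(answered, vals, np.nan)
        out[k] = vals
    return out


def _draw_nb(rng, mu, theta):
    """NB2 draws with mean mu, dispersion theta (variance mu + mu^2/theta)."""
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p)


def gen_outcome_minutes(scores: pd.DataFrame, config: SyntheticConfig,
                        truth: GroundTruth, duration: int,
                        rng: np.random.Generator,
                        outcome: str = "lpa") -> np.ndarray:
    """Hurdle draws of active minutes in a window, one per answered prompt.

    Uses the realized person mean of the driver item for centering, i.e.
    exactly the decomposition the downstream model refits.  Returns NaN
    for unanswered prompts.
    """
    hp = config.hurdle_params[outcome]
    answered = (scores["status"] == "completed").to_numpy()
    x = scores[config.driver_item].to_numpy(dtype=float)
    pid = scores["participant_id"]
    xbar = pd.Series(x).groupby(pid.to_numpy()).transform("mean").to_numpy()
    xw = x - xbar
    a = truth.hurdle_intercepts[f"a_{outcome}"].reindex(pid).to_numpy()
    c = truth.hurdle_intercepts[f"c_{outcome}"].reindex(pid).to_numpy()

    eta_z = hp.alpha0 + a + hp.beta_w * xw + hp.beta_b * xbar
    eta_c = hp.gamma0 + c + hp.delta_w * xw + hp.delta_b * xbar
    counts = np.full(len(scores), np.nan)
    idx = np.flatnonzero(answered)
    if np.any(eta_c[idx] > 20):
        bad = idx[np.argmax(eta_c[idx] > 20)]
        raise GenerationError(
            f"count mean overflow (eta={eta_c[bad]:.1f}) at prompt index {bad} "
            f"for participant {pid.iloc[bad]}")
    z = rng.uniform(size=len(idx)) < 1.0 / (1.0 + np.exp(-eta_z[idx]))
    drawn = np.zeros(len(idx), dtype=float)
    pos = np.flatnonzero(z)
    mu = np.exp(eta_c[idx][pos])
    vals = _draw_nb(rng, mu, hp.theta).astype(float)
    if config.truncation_mode == "truncated":
        redo = np.flatnonzero(vals == 0)
        guard = 0
        while redo.size and guard < 1000:
            vals[redo] = _draw_nb(rng, mu[redo], hp.theta)
            redo = redo[vals[redo] == 0]
            guard += 1
        vals[vals == 0] = 1.0  # pathological means only
    else:
        vals[vals == 0] = 1.0  # documented bias of the untruncated mode
    capped = vals > duration
    if np.any(capped):
        logger.warning("%d %s draws capped at the %d-min window length",
                       int(capped.sum()), outcome, duration)
        vals = np.minimum(vals, duration)
    drawn[pos] = vals
    counts[idx] = drawn
    return counts


def _nest_positions(rng, count_lpa, count_mvpa, duration):
    """Place LPA/MVPA minutes uniformly among the window's minute slots."""
    total = int(count_lpa + count_mvpa)
    slots = rng.permutation(duration)[:total]
    return slots[: int(count_lpa)], slots[int(count_lpa):]


def _build_observations(scores, config, truth, rng):
    """Observation-level linked table with nested per-window counts."""
    D = config.model_window
    answered = scores[scores["status"] == "completed"].reset_index(drop=True)
    counts = {}
    positions = {}
    for outcome in ("lpa", "mvpa"):
        full = gen_outcome_minutes(scores, config, truth, D, rng, outcome)
        counts[outcome] = full[(scores["status"] == "completed").to_numpy()]
    # joint placement inside the longest window drives all nested windows
    pos_l, pos_m = [], []
    for cl, cm in zip(counts["lpa"], counts["mvpa"]):
        cl, cm = int(cl), int(cm)
        if cl + cm > D:  # cap the later-drawn outcome to fit the window
            logger.warning("joint LPA+MVPA target %d exceeds window %d; capped",
                           cl + cm, D)
            cm = D - cl
        pl, pm = _nest_positions(rng, cl, cm, D)
        pos_l.append(pl)
        pos_m.append(pm)
    positions["lpa"], positions["mvpa"] = pos_l, pos_m

    obs = answered[["participant_id", "trigger_time"]].copy()
    for k in config.item_params:
        obs[k] = answered[k].to_numpy()
    for d in config.windows:
        lpa_d = np.array([(p < d).sum() for p in pos_l])
        mvpa_d = np.array([(p < d).sum() for p in pos_m])
        obs[f"lpa_{d}"] = lpa_d
        obs[f"mvpa_{d}"] = mvpa_d
        obs[f"tpa_{d}"] = lpa_d + mvpa_d
        for intensity in ("lpa", "mvpa", "tpa"):
            obs[f"any_{intensity}_{d}"] = (obs[f"{intensity}_{d}"] >= 1).astype(int)
        obs[f"coverage_{d}"] = 1.0
    return obs, positions


def gen_minute_trace(observations: pd.DataFrame, positions: dict,
                     config: SyntheticConfig,
                     rng: np.random.Generator):
    """Per-minute ENMO/intensity trace consistent with the linked counts.

    Covers each participant's study span continuously (midnight of day 1
    to 2 h past the last day's end).  Window minutes carry the classes
    placed by the observation-level generator; everything else is
    sedentary.  ENMO is drawn inside the class band: sedentary uniform on
    [0, 57), LPA uniform on (57, 104), MVPA lognormal shifted above 104.

    Consecutive 120-min windows can overlap (prompts may be less than
    2 h apart); minutes claimed by an earlier window are not reassigned.
    The trace is therefore the authoritative record: the function also
    returns the *realized* per-window counts read back off its own class
    array, which the simulation adopts as the observation-level ground
    truth in minute/raw mode.
    """
    start = pd.Timestamp(config.start_date).normalize()
    end = (start + pd.Timedelta(days=config.n_days)
           + pd.Timedelta(minutes=config.model_window))
    index = pd.date_range(start, end, freq="1min", inclusive="left")
    n_min = len(index)
    frames = []
    realized = {f"{k}_{d}": np.zeros(len(observations), dtype=int)
                for k in ("lpa", "mvpa") for d in config.windows}
    for pid, grp in observations.groupby("participant_id", sort=True):
        cls = np.zeros(n_min, dtype=np.int8)  # 0 SED, 1 LPA, 2 MVPA
        claimed = np.zeros(n_min, dtype=bool)
        bases = {}
        for ridx in grp.index:
            trigger = pd.Timestamp(grp.loc[ridx, "trigger_time"])
            w0 = trigger.floor("min") + pd.Timedelta(minutes=1)
            base = int((w0 - start).total_seconds() // 60)
            bases[ridx] = base
            for code, pos in ((1, positions["lpa"][ridx]),
                              (2, positions["mvpa"][ridx])):
                tgt = base + np.asarray(pos, dtype=int)
                tgt = tgt[(tgt >= 0) & (tgt < n_min)]
                free = ~claimed[tgt]
                cls[tgt[free]] = code
            claimed[base: base + config.model_window] = True
        # read the realized counts back off the class array
        for ridx, base in bases.items():
            for d in config.windows:
                seg = cls[base: base + d]
                realized[f"lpa_{d}"][ridx] = int((seg == 1).sum())
                realized[f"mvpa_{d}"][ridx] = int((seg == 2).sum())
        enmo = np.empty(n_min)
        sed = cls == 0
        lpa = cls == 1
        mvpa = cls == 2
        enmo[sed] = rng.uniform(0.0, 57.0, sed.sum())
        enmo[lpa] = rng.uniform(57.0 + 1e-6, 104.0 - 1e-6, lpa.sum())
        enmo[mvpa] = 104.0 + rng.lognormal(3.0, 0.7, mvpa.sum())
        frames.append(pd.DataFrame({
            "participant_id": pid,
            "minute_start": index,
            "enmo_mg": enmo,
            "intensity": np.array([acc.SED, acc.LPA, acc.MVPA])[cls],
        }))
    return pd.concat(frames, ignore_index=True), pd.DataFrame(realized)


def gen_raw_signal(minutes: pd.DataFrame, config: SyntheticConfig,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Triaxial samples whose processed ENMO reproduces the minute trace.

    Per minute the device sees unit gravity on z plus a horizontal
    circular oscillation of amplitude A = sqrt((1 + e/1000)^2 - 1), which
    makes every sample's vector norm exactly 1 + e/1000 g: the per-sample
    ENMO equals the minute target e (mg) identically, so the 1 s -> 60 s
    averaging chain returns e to within floating-point error.
    """
    fs = config.sample_rate_hz
    n_per_min = int(round(60 * fs))
    targets = minutes["enmo_mg"].to_numpy(dtype=float)
    if np.any(targets < 0):
        raise GenerationError("negative minute ENMO target")
    frames = []
    k = np.arange(n_per_min)
    phase_step = 2.0 * np.pi * 1.0 / fs  # 1 Hz oscillation
    for (pid, m0, e) in zip(minutes["participant_id"], minutes["minute_start"],
                            targets):
        amp = np.sqrt((1.0 + e / 1000.0) ** 2 - 1.0)
        phi = rng.uniform(0, 2 * np.pi)
        ts = pd.Timestamp(m0) + pd.to_timedelta(k / fs, unit="s")
        frames.append(pd.DataFrame({
            "participant_id": pid,
            "timestamp": ts,
            "x_g": amp * np.sin(phase_step * k + phi),
            "y_g": amp * np.cos(phase_step * k + phi),
            "z_g": np.ones(n_per_min),
        }))
    return pd.concat(frames, ignore_index=True)


def gen_model_frame(config: SyntheticConfig, outcome: str = "lpa",
                    duration: int | None = None,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Minimal per-prompt modelling frame for estimator studies.

    Skips the prompting-protocol plumbing (every prompt answered, no
    timestamps) and returns one row per prompt with the driver item
    score ``x``, the outcome count ``y`` for one window, and
    ``participant_id`` — exactly the data a single hurdle cell models.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if duration is None:
        duration = config.model_window
    roster, truth = gen_participants(config, rng)
    n_per = config.n_days * config.prompts_per_day
    frame = pd.DataFrame({
        "participant_id": np.repeat(roster["participant_id"].to_numpy(), n_per),
        "status": "completed",
    })
    frame = gen_item_scores(roster, frame, config, truth, rng)
    y = gen_outcome_minutes(frame, config, truth, duration, rng, outcome)
    out = pd.DataFrame({
        "participant_id": frame["participant_id"],
        "x": frame[config.driver_item],
        "y": y,
    })
    out["any"] = (out["y"] >= 1).astype(int)
    return out


@dataclass
class SimulationResult:
    """All artefacts of one simulated study."""

    config: SyntheticConfig
    roster: pd.DataFrame
    truth: GroundTruth
    prompts: pd.DataFrame  # EMA table incl. item scores
    observations: pd.DataFrame  # linked-observation table (ground truth)
    minutes: pd.DataFrame | None = None
    raw: pd.DataFrame | None = None

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        emacols = (["participant_id", "trigger_time", "status", "latency_min",
                    "completion_duration_min"] + list(self.config.item_params))
        self.prompts[emacols].to_csv(out / "ema.csv", index=False)
        self.observations.to_csv(out / "observations.csv", index=False)
        self.truth.to_json(out / "ground_truth.json")
        if self.minutes is not None:
            self.minutes.to_csv(out / "minutes.csv", index=False)
        if self.raw is not None:
            self.raw.to_csv(out / "raw.csv", index=False)


def simulate(config: SyntheticConfig | None = None,
             seed: int | None = None) -> SimulationResult:
    """Run the full generator at the configured signal level."""
    if config is None:
        config = SyntheticConfig()
    if seed is not None:
        config.seed = seed
    rng = np.random.default_rng(config.seed)
    roster, truth = gen_participants(config, rng)
    prompts = gen_prompts(roster, config, rng)
    prompts = gen_item_scores(roster, prompts, config, truth, rng)
    observations, positions = _build_observations(prompts, config, truth, rng)
    minutes = raw = None
    if config.signal_level in ("minute", "raw"):
        minutes, realized = gen_minute_trace(observations, positions, config, rng)
        # the trace is authoritative where overlapping windows collide
        for d in config.windows:
            observations[f"lpa_{d}"] = realized[f"lpa_{d}"].to_numpy()
            observations[f"mvpa_{d}"] = realized[f"mvpa_{d}"].to_numpy()
            observations[f"tpa_{d}"] = (observations[f"lpa_{d}"]
                                        + observations[f"mvpa_{d}"])
            for intensity in ("lpa", "mvpa", "tpa"):
                observations[f"any_{intensity}_{d}"] = (
                    observations[f"{intensity}_{d}"] >= 1).astype(int)
    if config.signal_level == "raw":
        raw = gen_raw_signal(minutes, config, rng)
    return SimulationResult(config=config, roster=roster, truth=truth,
                            prompts=prompts, observations=observations,
                            minutes=minutes, raw=raw)
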