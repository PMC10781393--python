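"""Closed-loop training-load control against a simulated athlete.

A proportional feedback law (the degenerate-horizon member of the
model-predictive-control family) adapts session intensity i and duration d
to hold an observed fatigue indicator at a setpoint while rewarding spare
stamina:

    i' = clamp(i - alpha*k_f*(I_fatigue - setpoint)
                 + alpha*k_s*(I_stamina - 0.5), i_min, i_max)

and analogously for duration with a per-parameter gain scale (minutes per
unit error).  The learning rate alpha caps the per-session adjustment
magnitude, and hard bounds keep prescriptions physiologically sane.

The simulated athlete is a stable first-order plant: latent fatigue carries
over with factor rho < 1 and accumulates in proportion to the imposed load
i*d; stamina is the complementary headroom 1 - Fat/Fat_scale.  For the
noise-free plant with fixed duration the closed loop is a coupled linear
recurrence whose fixed point puts the fatigue observation exactly at the
setpoint; it contracts when alpha*k_f*beta*d < 2*(1 - rho).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bias import correct_predictions, estimate_bias
from .exceptions import ConfigError

@dataclass
class TrainingParams:
    """A session prescription: duration in minutes, intensity in [0, 1]."""

    duration_min: float = 45.0
    intensity: float = 0.5


@dataclass
class ControlConfig:
    fatigue_setpoint: float = 0.5
    k_f: float = 0.5               # intensity gain on fatigue error
    k_s: float = 0.0               # intensity gain on stamina surplus
    alpha: float = 0.5             # learning rate in (0, 1]
    duration_gain_scale: float = 0.0   # minutes adjusted per unit error
    d_bounds: tuple[float, float] = (10.0, 120.0)
    i_bounds: tuple[float, float] = (0.05, 1.0)
    max_sessions: int = 100
    bias_window: int = 10          # rolling sessions for bias estimation

    def validate(self) -> "ControlConfig":
        if not 0 < self.alpha <= 1:
            raise ConfigError("alpha must lie in (0, 1]")
        if self.k_f < 0 or self.k_s < 0:
            raise ConfigError("gains must be non-negative")
        if self.d_bounds[0] >= self.d_bounds[1] or self.i_bounds[0] >= self.i_bounds[1]:
            raise ConfigError("bounds must satisfy min < max")
        if self.max_sessions < 1:
            raise ConfigError("max_sessions must be >= 1")
        return self


@dataclass
class AthleteState:
    """Latent state of the simulated athlete (first-order load response)."""

    fatigue: float = 0.0           # latent accumulated fatigue, >= 0
    stamina: float = 1.0           # latent headroom in [0, 1]
    carryover: float = 0.6         # rho, fraction of fatigue retained, < 1
    load_sensitivity: float = 0.02 # beta, fatigue per (intensity * minute)
    fatigue_scale: float = 1.0     # maps fatigue to the stamina headroom
    process_noise_sd: float = 0.0
    observation_noise_sd: float = 0.0
    observation_bias: float = 0.0  # systematic sensor offset, removed by the
                                   # rolling bias correction in the loop

    def validate(self) -> "AthleteState":
        if not 0 <= self.carryover < 1:
            raise ConfigError("carryover rho must lie in [0, 1)")
        if not self.load_sensitivity > 0:
            raise ConfigError("load_sensitivity beta must be positive")
        if self.process_noise_sd < 0 or self.observation_noise_sd < 0:
            raise ConfigError("noise sds must be non-negative")
        return self


def _clamp(x: float, lo: float, hi: float) -> float:
    return min(max(x, lo), hi)


def control_session(i_fatigue: float, i_stamina: float,
                    params: TrainingParams, cfg: ControlConfig) -> TrainingParams:
    """One proportional update of the training prescription.

    Fatigue above the setpoint pushes intensity (and duration, scaled by
    ``duration_gain_scale``) down; stamina above the 0.5 reference pushes
    them up.  Outputs are always clamped to the configured bounds.
    """
    cfg.validate()
    f_err = i_fatigue - cfg.fatigue_setpoint
    s_err = i_stamina - 0.5
    step = -cfg.alpha * cfg.k_f * f_err + cfg.alpha * cfg.k_s * s_err
    i_new = _clamp(params.intensity + step, *cfg.i_bounds)
    d_new = _clamp(params.duration_min + cfg.duration_gain_scale * step,
                   *cfg.d_bounds)
    return TrainingParams(d_new, i_new)


def simulate_athlete_session(state: AthleteState, params: TrainingParams,
                             seed: int) -> tuple[AthleteState, float, float]:
    """Advance the plant one session and observe it.

    Fat' = rho*Fat + beta*i*d + process noise;
    Sta' = clamp(1 - Fat'/Fat_scale, 0, 1);
    observations are the latents plus observation noise.  Deterministic
    given the seed.
    """
    state.validate()
    rng = np.random.default_rng(seed)
    fat = (state.carryover * state.fatigue
           + state.load_sensitivity * params.intensity * params.duration_min)
    if state.process_noise_sd > 0:
        fat += rng.normal(0.0, state.process_noise_sd)
    fat = max(fat, 0.0)
    sta = _clamp(1.0 - fat / state.fatigue_scale, 0.0, 1.0)
    new_state = replace(state, fatigue=fat, stamina=sta)
    obs_f = fat + state.observation_bias + (
        rng.normal(0.0, state.observation_noise_sd)
        if state.observation_noise_sd > 0 else 0.0)
    obs_s = sta + state.observation_bias + (
        rng.normal(0.0, state.observation_noise_sd)
        if state.observation_noise_sd > 0 else 0.0)
    return new_state, float(obs_f), float(obs_s)


def optimize_training_loop(initial: TrainingParams, state: AthleteState,
                           cfg: ControlConfig, n_sessions: int | None = None,
                           seed: int = 0) -> pd.DataFrame:
    """Run the full session loop: simulate -> bias-correct -> control.

    Observed fatigue/stamina are corrected with a rolling-window bias
    estimate against the plant's latent truths (the one setting where the
    truths exist), then fed to the proportional controller.  Returns the
    per-session trajectory as a DataFrame with columns::

        session, duration_min, intensity, fatigue_latent, stamina_latent,
        fatigue_observed, stamina_observed, fatigue_corrected,
        stamina_corrected

    Deterministic given the seed (per-session sub-seeds are drawn from one
    generator).
    """
    cfg.validate()
    state.validate()
    n_sessions = cfg.max_sessions if n_sessions is None else n_sessions
    rng = np.random.default_rng(seed)
    params = replace(initial)
    rows = []
    obs_f_hist: list[float] = []
    tru_f_hist: list[float] = []
    obs_s_hist: list[float] = []
    tru_s_hist: list[float] = []
    for t in range(n_sessions):
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        state, obs_f, obs_s = simulate_athlete_session(state, params, sub_seed)
        obs_f_hist.append(obs_f)
        tru_f_hist.append(state.fatigue)
        obs_s_hist.append(obs_s)
        tru_s_hist.append(state.stamina)
        w = cfg.bias_window
        b_f = estimate_bias(obs_f_hist[-w:], tru_f_hist[-w:])
        b_s = estimate_bias(obs_s_hist[-w:], tru_s_hist[-w:])
        corr_f = float(correct_predictions([obs_f], b_f)[0])
        corr_s = float(correct_predictions([obs_s], b_s)[0])
        rows.append({
            "session": t, "duration_min": params.duration_min,
            "intensity": params.intensity,
            "fatigue_latent": state.fatigue, "stamina_latent": state.stamina,
            "fatigue_observed": obs_f, "stamina_observed": obs_s,
            "fatigue_corrected": corr_f, "stamina_corrected": corr_s,
        })
        params = control_session(corr_f, corr_s, params, cfg)
    return pd.DataFrame(rows)


def closed_loop_fixed_point(cfg: ControlConfig, state: AthleteState,
                            duration_min: float) -> dict[str, float]:
    """Fixed point of the noise-free loop with fixed duration and k_s = 0.

    At equilibrium the controller holds fatigue at the setpoint, so the
    implied intensity is i* = setpoint*(1 - rho)/(beta*d) — the inversion of
    Fat* = beta*i*d/(1 - rho)."""
    i_star = (cfg.fatigue_setpoint * (1.0 - state.carryover)
              / (state.load_sensitivity * duration_min))
    return {"fatigue": cfg.fatigue_setpoint,
            "intensity": _clamp(i_star, *cfg.i_bounds)}


def stability_margin(cfg: ControlConfig, state: AthleteState,
                     duration_min: float) -> float:
    """Contraction margin of the 1-D loop: positive when
    alpha*k_f*beta*d < 2*(1 - rho)."""
    return (2.0 * (1.0 - state.carryover)
            - cfg.alpha * cfg.k_f * state.load_sensitivity * duration_min)
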