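"""Synthetic two-alternative forced-choice trajectory generator.

Emulates the statistical structure the analyses assume: an N-back
matching task where each trial is a Match with probability 0.33, and
the response is a hand movement sampled at 90 Hz along the signed
box axis (positive toward the Match box), from a neutral start to one
of two boxes at +/- the total distance (default 0.20 m).

A trial unfolds as: hold at zero for a shifted-lognormal initiation
delay; move at constant condition speed toward a first target side
(with some probability the first leg heads toward the Match box
regardless of the truth -- the early match bias); if the first leg does
not aim at the final landing side, or a spurious self-correction fires,
the direction reverses at a random switch distance; per-sample
hesitation pauses freeze the hand in place for a random duration.  The
trial completes when a box is reached; final accuracy compares the
landing side with the trial type (an error probability picks the wrong
landing side).  Every latent draw (delay, bias flag, switch distance,
pause count, error flag) is recorded in a manifest for recovery tests.

Reproducibility: one root seed; each trial draws from its own
``default_rng([seed, trial_counter])`` substream, so results do not
depend on generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .io import Dataset, TRIAL_COLUMNS, TRAJECTORY_COLUMNS

__all__ = ["LevelParams", "GeneratorConfig", "generate_trial", "generate_dataset"]


@dataclass
class LevelParams:
    """Per-N-back-level movement parameters.

    delay: shifted lognormal, ``shift + exp(Normal(mu, sigma))`` ms.
    ``speed_m_s`` is the constant hand speed while moving;
    ``hesitation_pause_prob`` is the per-sample probability of starting
    a pause of duration uniform in ``pause_ms_range``;
    ``self_correction_prob`` injects a wrong-way excursion even when the
    first leg would otherwise be straight;
    ``early_match_bias_prob`` sends the first leg toward the Match box
    regardless of the correct answer;
    ``error_prob`` makes the trial land at the wrong box.
    """

    delay_shift_ms: float = 100.0
    delay_mu: float = math.log(600.0)
    delay_sigma: float = 0.55
    speed_m_s: float = 0.30
    hesitation_pause_prob: float = 0.01
    pause_ms_range: tuple = (100.0, 400.0)
    self_correction_prob: float = 0.05
    early_match_bias_prob: float = 0.10
    error_prob: float = 0.05

    def __post_init__(self) -> None:
        for p in (self.hesitation_pause_prob, self.self_correction_prob,
                  self.early_match_bias_prob, self.error_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.speed_m_s <= 0:
            raise ValueError("speed must be > 0")


def _default_levels() -> dict:
    # harder N: later initiation, slower movement, more hesitation,
    # self-correction, early match bias and errors
    return {
        1: LevelParams(),
        2: LevelParams(delay_mu=math.log(900.0), delay_sigma=0.65,
                       speed_m_s=0.25, hesitation_pause_prob=0.02,
                       self_correction_prob=0.10, early_match_bias_prob=0.20,
                       error_prob=0.10),
        3: LevelParams(delay_mu=math.log(1300.0), delay_sigma=0.75,
                       speed_m_s=0.20, hesitation_pause_prob=0.03,
                       self_correction_prob=0.15, early_match_bias_prob=0.30,
                       error_prob=0.15),
    }


@dataclass
class GeneratorConfig:
    """Study-level configuration; defaults mirror the study design.

    19 analysed participants, 76 trials per participant x N-back cell
    (so 4332 trials per device), Match probability 0.33, 90 Hz
    sampling, boxes at +/-0.20 m.  ``devices`` controls whether the
    key-press (``classical``) arm, the tracked (``vr``) arm, or both
    are generated; classical trials carry RT and accuracy but no
    trajectory, with the motor leg compressed to a fraction of the
    tracked movement time.
    """

    seed: int = 0
    n_participants: int = 19
    trials_per_condition: int = 76   # per participant x n_back cell
    match_prob: float = 0.33
    sample_rate_hz: float = 90.0
    total_distance_m: float = 0.20
    devices: tuple = ("classical", "vr")
    classical_motor_fraction: float = 0.7
    participant_delay_sd: float = 0.15
    participant_speed_sd: float = 0.10
    max_trial_ms: float = 30000.0
    levels: dict = field(default_factory=_default_levels)

    def __post_init__(self) -> None:
        if not 0.0 <= self.match_prob <= 1.0:
            raise ValueError("match_prob must be in [0, 1]")
        if self.sample_rate_hz <= 0 or self.total_distance_m <= 0:
            raise ValueError("sample_rate and total_distance must be > 0")
        self.levels = {int(k): (v if isinstance(v, LevelParams) else LevelParams(**v))
                       for k, v in self.levels.items()}

    # -- YAML round-trip (CLI config files) ----------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["devices"] = list(self.devices)
        d["levels"] = {k: asdict(v) for k, v in self.levels.items()}
        for lv in d["levels"].values():
            lv["pause_ms_range"] = list(lv["pause_ms_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "devices" in d:
            d["devices"] = tuple(d["devices"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def generate_trial(config: GeneratorConfig, condition: tuple, device: str,
                   index: int, delay_mult: float = 1.0,
                   speed_mult: float = 1.0):
    """Generate one trial; deterministic in ``(config.seed, index)``.

    Parameters
    ----------
    condition : (n_back, trial_type)
    device : ``"classical"`` or ``"vr"``
    index : int
        Trial counter keying the RNG substream.
    delay_mult, speed_mult : float
        Participant-level multipliers on the stochastic delay component
        and movement speed (individual slowness/quickness); drawn once
        per participant by :func:`generate_dataset`.

    Returns
    -------
    (trial, trajectory, latents)
        ``trial`` is a dict of trial-table fields (without id columns);
        ``trajectory`` is ``(t_ms, x_m)`` arrays or ``None`` for the
        classical device; ``latents`` records the ground-truth draws.
    """
    n_back, trial_type = condition
    params: LevelParams = config.levels[int(n_back)]
    if speed_mult != 1.0:
        params = LevelParams(**{**asdict(params),
                                "speed_m_s": params.speed_m_s * speed_mult})
    rng = np.random.default_rng([config.seed, index])

    delay_ms = params.delay_shift_ms + delay_mult * float(
        rng.lognormal(params.delay_mu, params.delay_sigma))
    error = bool(rng.random() < params.error_prob)
    biased = bool(rng.random() < params.early_match_bias_prob)
    self_corr = bool(rng.random() < params.self_correction_prob)

    correct_side = 1 if trial_type == "match" else -1
    end_side = -correct_side if error else correct_side
    if biased:
        first_side = 1                      # toward the Match box, regardless
    elif self_corr:
        first_side = -end_side              # spurious wrong-way excursion
    else:
        first_side = end_side
    needs_switch = first_side != end_side
    switch_dist = (float(rng.uniform(0.3, 0.8)) * config.total_distance_m
                   if needs_switch else math.nan)

    latents = {
        "delay_mult": delay_mult, "speed_mult": speed_mult,
        "delay_ms": delay_ms, "error": error, "biased": biased,
        "self_corrected": self_corr and not biased,
        "first_side": first_side, "end_side": end_side,
        "switch_dist_m": switch_dist, "n_pauses": 0,
    }

    accuracy = 0.0 if error else 1.0

    if device == "classical":
        # key press: no trajectory, motor leg compressed
        move_ms = 1000.0 * config.total_distance_m / params.speed_m_s
        rt = delay_ms + config.classical_motor_fraction * move_ms
        trial = {"device": device, "n_back": int(n_back),
                 "trial_type": trial_type, "rt_ms": rt, "accuracy": accuracy}
        return trial, None, latents

    dt = 1000.0 / config.sample_rate_hz
    step = params.speed_m_s * dt / 1000.0   # meters per sample while moving
    D = config.total_distance_m
    t_list, x_list = [], []
    t, x = 0.0, 0.0
    direction = first_side
    switched = not needs_switch
    pause_until = -1.0
    n_pauses = 0
    t_list.append(t); x_list.append(x)
    rt = math.nan
    while t < config.max_trial_ms:
        t += dt
        moving = t > delay_ms and t > pause_until
        if moving:
            if params.hesitation_pause_prob and rng.random() < params.hesitation_pause_prob:
                pause_until = t + float(rng.uniform(*params.pause_ms_range))
                n_pauses += 1
            else:
                x += direction * step
                if not switched and abs(x) >= switch_dist:
                    direction = end_side
                    switched = True
        done = switched and (x * end_side >= D)
        if done:
            x = end_side * D
        t_list.append(t); x_list.append(x)
        if done:
            rt = t
            break
    latents["n_pauses"] = n_pauses

    finished = math.isfinite(rt)
    trial = {"device": device, "n_back": int(n_back), "trial_type": trial_type,
             "rt_ms": rt if finished else math.nan,
             "accuracy": accuracy if finished else math.nan}
    traj = (np.asarray(t_list), np.asarray(x_list))
    return trial, traj, latents


def generate_dataset(config: GeneratorConfig | None = None):
    """Generate a full balanced dataset plus its ground-truth manifest.

    The design is balanced over participants x N-back (x device);
    within each cell every trial is independently a Match with
    probability ``match_prob``.  Returns ``(Dataset, manifest)`` where
    the manifest is a DataFrame with one row per trial holding every
    latent variable, aligned with the dataset by ``trial_id``.
    """
    config = config or GeneratorConfig()
    trial_rows, traj_t, traj_x, traj_ids, manifest_rows = [], [], [], [], []
    index = 0
    for p in range(1, config.n_participants + 1):
        participant = f"P{p:02d}"
        rng_p = np.random.default_rng([config.seed, 1000003, p])
        delay_mult = float(rng_p.lognormal(0.0, config.participant_delay_sd))
        speed_mult = float(rng_p.lognormal(0.0, config.participant_speed_sd))
        for device in config.devices:
            for n_back in sorted(config.levels):
                for _ in range(config.trials_per_condition):
                    rng_tt = np.random.default_rng([config.seed, index, 7])
                    trial_type = ("match" if rng_tt.random() < config.match_prob
                                  else "nonmatch")
                    trial, traj, latents = generate_trial(
                        config, (n_back, trial_type), device, index,
                        delay_mult, speed_mult)
                    trial_id = f"T{index:06d}"
                    trial_rows.append({"trial_id": trial_id,
                                       "participant": participant, **trial})
                    if traj is not None:
                        traj_ids.append(np.full(len(traj[0]), trial_id, dtype=object))
                        traj_t.append(traj[0])
                        traj_x.append(traj[1])
                    manifest_rows.append({"trial_id": trial_id,
                                          "participant": participant,
                                          "device": device, "n_back": n_back,
                                          "trial_type": trial_type, **latents})
                    index += 1
    trials = pd.DataFrame(trial_rows, columns=TRIAL_COLUMNS)
    if traj_t:
        trajectories = pd.DataFrame({
            "trial_id": np.concatenate(traj_ids),
            "t_ms": np.concatenate(traj_t),
            "x_m": np.concatenate(traj_x),
        })
    else:
        trajectories = pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    manifest = pd.DataFrame(manifest_rows)
    ds = Dataset(trials, trajectories,
                 metadata={"generator": config.to_dict(), "seed": config.seed})
    return ds.validate(), manifest
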