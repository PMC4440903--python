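"""Synthetic two-session rating experiments with controllable RTM and conformity.

The generator emulates the paradigm's data-generating situation: every
participant carries a stable latent value for each item; each session's
rating is that latent value plus occasion-specific noise, which is what
produces regression toward the mean (RTM).  In the experimental group the
second-session rating is additionally shifted by a participant-specific
conformity weight times the presented group deviation; in the control
group the deviation is drawn and reflected identically but never enters
the second rating.

With occasion noise variance ``noise_sd**2`` and latent spread
``latent_sd**2`` the population slope of rating change on the centered
first rating is ``-noise_sd**2 / (latent_sd**2 + noise_sd**2)``; the
default calibration puts that slope at -0.374.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .paradigm import (
    DEFAULT_SCALE,
    N_ITEMS,
    SCHEDULE_COUNTS,
    RatingScale,
    reflect_deviations,
)

__all__ = ["GeneratorConfig", "generate_experiment", "RTM_SLOPE_DEFAULT"]

#: magnitude of the continuous-mode RTM slope the default noise level implies
RTM_SLOPE_DEFAULT = 0.374


def _noise_sd_for_slope(slope_magnitude: float, latent_sd: float) -> float:
    """Noise sd giving RTM slope ``-slope_magnitude`` for a given latent sd."""
    if not 0.0 < slope_magnitude < 1.0:
        raise ValueError("slope magnitude must be in (0, 1)")
    return latent_sd * math.sqrt(slope_magnitude / (1.0 - slope_magnitude))


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic experiment.

    Defaults reproduce the study's design scale: two groups of 27
    participants rating 180 items twice on a 1-6 Likert scale, with the
    occasion noise calibrated so the continuous-mode RTM slope is -0.374
    and a small positive conformity effect (0.15 rating units per unit of
    presented deviation, between-participant sd 0.05) in the experimental
    group.
    """

    n_per_group: int = 27
    n_items: int = N_ITEMS
    latent_mean: float = 3.5
    latent_sd: float = 1.0
    noise_sd: float = _noise_sd_for_slope(RTM_SLOPE_DEFAULT, 1.0)
    conformity_weight_mean: float = 0.15
    conformity_weight_sd: float = 0.05
    discretize: bool = True
    shared_items: bool = False
    scale: RatingScale = field(default=DEFAULT_SCALE)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 participants per group")
        if self.n_items < 2:
            raise ValueError("need at least 2 items")
        if self.latent_sd <= 0:
            raise ValueError("latent_sd must be positive")
        if self.noise_sd < 0 or self.conformity_weight_sd < 0:
            raise ValueError("standard deviations must be nonnegative")

    @property
    def rtm_slope(self) -> float:
        """Population slope of rating change on centered first rating in
        continuous mode (negative; 0 when there is no occasion noise)."""
        total = self.latent_sd**2 + self.noise_sd**2
        return -self.noise_sd**2 / total

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


def _schedule_values(n_items: int, rng: np.random.Generator) -> np.ndarray:
    """Random permutation of the fixed deviation multiset, rescaled to
    ``n_items`` (counts in the 30/30/60/30/30 proportion, remainders filled
    by sampling the multiset without replacement)."""
    values = np.repeat(
        list(SCHEDULE_COUNTS.keys()), list(SCHEDULE_COUNTS.values())
    )
    reps, extra = divmod(n_items, values.size)
    pool = np.tile(values, reps)
    if extra:
        pool = np.concatenate([pool, rng.choice(values, extra, replace=False)])
    return rng.permutation(pool)


def _discretize(x: np.ndarray, scale: RatingScale) -> np.ndarray:
    # round half away from zero, then clamp to the scale
    rounded = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return scale.clamp(rounded)


def generate_experiment(config: GeneratorConfig | None = None, **overrides) -> pd.DataFrame:
    """Simulate a complete two-group, two-session experiment.

    Returns a trial table with one row per (participant, item):
    ``participant_id, group, item_id, rating_1, drawn_deviation,
    presented_deviation, rating_2``.

    Randomness is organised as one substream per (group, participant)
    spawned from the master seed, so enlarging ``n_per_group`` extends the
    table without reshuffling existing participants.  Identical config
    (including seed) gives a byte-identical table.
    """
    config = (config or GeneratorConfig()).with_(**overrides) if overrides else (
        config or GeneratorConfig()
    )
    scale = config.scale
    frames: list[pd.DataFrame] = []
    shared_latent = None
    if config.shared_items:
        item_rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(99,))
        )
        shared_latent = config.latent_mean + config.latent_sd * item_rng.standard_normal(
            config.n_items
        )
    for g_index, group in enumerate(("experimental", "control")):
        for j in range(config.n_per_group):
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(g_index, j))
            )
            latent = (
                shared_latent
                if shared_latent is not None
                else config.latent_mean
                + config.latent_sd * rng.standard_normal(config.n_items)
            )
            weight = rng.normal(
                config.conformity_weight_mean, config.conformity_weight_sd
            )
            e1 = config.noise_sd * rng.standard_normal(config.n_items)
            e2 = config.noise_sd * rng.standard_normal(config.n_items)
            drawn = _schedule_values(config.n_items, rng)

            y1 = latent + e1
            rating_1 = _discretize(y1, scale) if config.discretize else y1
            presented = reflect_deviations(rating_1, drawn, scale)

            y2 = latent + e2
            if group == "experimental":
                y2 = y2 + weight * presented
            rating_2 = _discretize(y2, scale) if config.discretize else y2

            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": f"{group[0]}{j + 1:02d}",
                        "group": group,
                        "item_id": np.arange(1, config.n_items + 1),
                        "rating_1": rating_1,
                        "drawn_deviation": drawn.astype(np.int64),
                        "presented_deviation": presented.astype(np.int64),
                        "rating_2": rating_2,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
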