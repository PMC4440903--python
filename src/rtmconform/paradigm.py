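"""Design constants of the deviance-based conformity paradigm.

In the paradigm, a participant rates each of 180 items on a 1-6 Likert
scale and is then shown an ostensible group judgment that deviates from
their own rating by a scheduled amount in {-2, -1, 0, +1, +2}.  The
schedule contains each nonzero deviation 30 times and zero 60 times, in
random order.  When adding the drawn deviation to the participant's
rating would leave the scale, the deviation's sign is flipped so that the
presented group judgment always stays on the scale (boundary reflection).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RatingScale",
    "DEFAULT_SCALE",
    "DeviationSchedule",
    "PresentedFeedback",
    "SCHEDULE_COUNTS",
    "N_ITEMS",
    "make_deviation_schedule",
    "apply_reflection",
    "reflect_deviations",
]


@dataclass(frozen=True)
class RatingScale:
    """Closed integer rating scale; all ratings and presented group
    judgments must lie within ``[minimum, maximum]``."""

    minimum: int = 1
    maximum: int = 6

    def __post_init__(self) -> None:
        if self.minimum >= self.maximum:
            raise ValueError("scale minimum must be below maximum")

    def contains(self, value: float) -> bool:
        return self.minimum <= value <= self.maximum

    def clamp(self, value: np.ndarray) -> np.ndarray:
        return np.clip(value, self.minimum, self.maximum)


DEFAULT_SCALE = RatingScale(1, 6)

#: deviation value -> number of occurrences per 180-trial session
SCHEDULE_COUNTS: dict[int, int] = {-2: 30, -1: 30, 0: 60, 1: 30, 2: 30}
N_ITEMS: int = sum(SCHEDULE_COUNTS.values())


@dataclass(frozen=True)
class DeviationSchedule:
    """Randomized order of the fixed deviation multiset for one session."""

    drawn_deviations: tuple[int, ...]

    def __post_init__(self) -> None:
        values, counts = np.unique(self.drawn_deviations, return_counts=True)
        observed = dict(zip(values.tolist(), counts.tolist()))
        if observed != SCHEDULE_COUNTS:
            raise ValueError(
                f"schedule multiset {observed} != required {SCHEDULE_COUNTS}"
            )

    def __len__(self) -> int:
        return len(self.drawn_deviations)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.drawn_deviations, dtype=np.int64)


@dataclass(frozen=True)
class PresentedFeedback:
    """Group judgment actually shown (or, for the control group, silently
    determined) on one trial."""

    presented_deviation: int
    group_judgment: float
    scale: RatingScale = field(default=DEFAULT_SCALE, repr=False)

    def __post_init__(self) -> None:
        if not self.scale.contains(self.group_judgment):
            raise ValueError("group judgment falls outside the rating scale")


def make_deviation_schedule(
    seed: int | np.random.Generator,
) -> DeviationSchedule:
    """Draw a uniformly random permutation of the fixed deviation multiset.

    Parameters
    ----------
    seed
        Seed or ``numpy`` Generator.  The same seed always yields the same
        schedule.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    values = np.repeat(
        list(SCHEDULE_COUNTS.keys()), list(SCHEDULE_COUNTS.values())
    )
    return DeviationSchedule(tuple(rng.permutation(values).tolist()))


def apply_reflection(
    initial_rating: float,
    drawn_deviation: int,
    scale: RatingScale = DEFAULT_SCALE,
) -> PresentedFeedback:
    """Apply the boundary-reflection rule to one trial.

    If ``initial_rating + drawn_deviation`` stays on the scale the drawn
    deviation is presented unchanged; otherwise its sign is flipped.  On
    the 1-6 scale with ``|deviation| <= 2`` the flipped judgment is always
    in bounds (a rating that cannot absorb +2 can always absorb -2), so no
    further fallback exists.
    """
    if not scale.contains(initial_rating):
        raise ValueError(
            f"initial rating {initial_rating} outside scale "
            f"[{scale.minimum}, {scale.maximum}]"
        )
    presented = drawn_deviation
    if not scale.contains(initial_rating + presented):
        presented = -presented
    judgment = initial_rating + presented
    # guaranteed by the scale geometry; a violation is a programming error
    assert scale.contains(judgment)
    return PresentedFeedback(presented, judgment, scale)


def reflect_deviations(
    initial_ratings: np.ndarray,
    drawn_deviations: np.ndarray,
    scale: RatingScale = DEFAULT_SCALE,
) -> np.ndarray:
    """Vectorized sign-flip rule: flip each deviation whose sum with the
    rating leaves the scale.

    Unlike :func:`apply_reflection` this does not validate the ratings, so
    it also serves continuous-mode simulations whose real-valued ratings
    may themselves fall outside the nominal scale (there the rule remains
    a pure sign flip and the implied judgment may stay out of bounds).
    """
    r = np.asarray(initial_ratings, dtype=float)
    d = np.asarray(drawn_deviations, dtype=np.int64)
    out_of_bounds = (r + d < scale.minimum) | (r + d > scale.maximum)
    return np.where(out_of_bounds, -d, d)
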