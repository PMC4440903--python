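"""Mean-centering, rating changes, and deviation binning.

All ratings are centered separately per participant and per session
(session mean subtracted), which removes session-level displacement and
fixes every participant's mean rating change at zero — the justification
for the fixed zero intercept of the RTM model downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "mean_center",
    "compute_rating_changes",
    "bin_deviation",
    "preprocess",
]

CONDITIONS = ("peers_lower", "peers_equal", "peers_higher")

#: tolerance for "per-participant centered mean is zero" assertions
CENTER_TOL = 1e-9


def mean_center(
    ratings: pd.Series, participant: pd.Series | np.ndarray
) -> pd.Series:
    """Center one session's ratings within participant.

    Raises if any participant has no rating in the session.
    """
    ratings = pd.Series(ratings).astype(float)
    if ratings.isna().any():
        raise ValueError("missing rating encountered while centering")
    return ratings - ratings.groupby(np.asarray(participant)).transform("mean")


def bin_deviation(presented_deviation):
    """Collapse the five presented-deviation levels into the 3-level
    Deviation factor: -2/-1 -> peers_lower, 0 -> peers_equal,
    +1/+2 -> peers_higher.  Accepts a scalar or an array-like.
    """
    d = np.asarray(presented_deviation)
    if not np.isin(d, (-2, -1, 0, 1, 2)).all():
        raise ValueError("presented deviation outside {-2..+2}")
    out = np.where(d < 0, CONDITIONS[0], np.where(d == 0, CONDITIONS[1], CONDITIONS[2]))
    return out.item() if np.isscalar(presented_deviation) else out


def compute_rating_changes(
    centered_1: pd.Series, centered_2: pd.Series, keys: pd.DataFrame
) -> pd.Series:
    """Per-item rating change c = centered second rating minus centered
    first rating, for sessions already aligned on (participant, item)."""
    if len(centered_1) != len(centered_2):
        raise ValueError("sessions are not aligned")
    if keys.duplicated().any():
        raise ValueError("duplicate (participant, item) keys")
    return centered_2.to_numpy() - centered_1.to_numpy()


def preprocess(trials: pd.DataFrame) -> pd.DataFrame:
    """Add the analysis columns to a trial table.

    ``r`` is the mean-centered first rating, ``c`` the rating change
    (centered second minus centered first), ``condition`` the 3-level
    Deviation factor from the presented deviation.  Within each
    participant both r and c average to zero.
    """
    required = {"participant_id", "item_id", "rating_1", "rating_2", "presented_deviation"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table lacks columns {sorted(missing)}")
    if trials.duplicated(["participant_id", "item_id"]).any():
        raise ValueError("duplicate (participant, item) rows")

    out = trials.copy()
    out["r"] = mean_center(out["rating_1"], out["participant_id"])
    centered_2 = mean_center(out["rating_2"], out["participant_id"])
    out["c"] = centered_2.to_numpy() - out["r"].to_numpy()
    out["condition"] = bin_deviation(out["presented_deviation"].to_numpy())

    check = out.groupby("participant_id")[["r", "c"]].mean().abs()
    assert (check < CENTER_TOL).all().all()
    return out
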