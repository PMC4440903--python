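"""Subtract the predicted RTM component from each rating change.

Given the average control-group slope ``gamma10``, the corrected rating
change of item ``i`` in participant ``x`` is::

    s_hat_ix = c_ix - gamma10 * r_ix

which attributes to social influence only the part of the observed
change not predicted by the initial rating's distance from the
participant's mean.  Only the fixed average slope is used — never
participant-specific slope predictions — so the same correction rule
applies to every participant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["correct_rating_changes"]


def correct_rating_changes(
    items: pd.DataFrame,
    gamma10: float,
    change_col: str = "c",
    rating_col: str = "r",
    out_col: str = "s_hat",
) -> pd.DataFrame:
    """Return ``items`` with the RTM-corrected change column added.

    Row count and order are preserved.  Because ``r`` is centered within
    participant, each participant's mean corrected change remains zero.
    """
    if not np.isfinite(gamma10):
        raise ValueError("gamma10 must be finite")
    out = items.copy()
    out[out_col] = out[change_col] - gamma10 * out[rating_col]
    return out
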