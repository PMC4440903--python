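"""Per-participant conformity scores.

A participant's conformity score is the Pearson correlation, across
their items, between the presented group deviation (five raw levels,
-2..+2) and the item's rating change — either the observed change ``c``
(uncorrected score) or the RTM-corrected change ``s_hat`` (corrected
score).  Correlations are Fisher-z transformed (``z = arctanh(r)``) so
participant scores are approximately normal and comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConformityScore", "conformity_score", "score_participants"]

#: |r| is clamped to 1 - _R_CLAMP before arctanh so z stays finite (~14.2)
_R_CLAMP = 1e-12


@dataclass(frozen=True)
class ConformityScore:
    participant_id: str
    r: float
    z: float
    defined: bool


def _pearson_z(deviation: np.ndarray, change: np.ndarray) -> tuple[float, float, bool]:
    if deviation.size < 3:
        raise ValueError("need at least 3 items per participant")
    sd_d = deviation.std()
    sd_c = change.std()
    if sd_d == 0 or sd_c == 0:
        warnings.warn("zero variance: conformity score undefined")
        return np.nan, np.nan, False
    r = float(np.corrcoef(deviation, change)[0, 1])
    if abs(r) >= 1.0 - _R_CLAMP:
        warnings.warn("|r| = 1 clamped before Fisher-z transform")
        r = np.sign(r) * (1.0 - _R_CLAMP)
    return r, float(np.arctanh(r)), True


def conformity_score(
    items: pd.DataFrame,
    change_field: str = "c",
    deviation_field: str = "presented_deviation",
    participant_id: str | None = None,
) -> ConformityScore:
    """Score one participant's items (Pearson r and its Fisher-z)."""
    d = items[deviation_field].to_numpy(float)
    c = items[change_field].to_numpy(float)
    r, z, ok = _pearson_z(d, c)
    pid = participant_id or str(items["participant_id"].iloc[0])
    return ConformityScore(pid, r, z, ok)


def score_participants(
    items: pd.DataFrame,
    corrected_field: str = "s_hat",
    deviation_field: str = "presented_deviation",
) -> pd.DataFrame:
    """Uncorrected and corrected scores for every participant.

    Returns one row per participant: ``r_raw, z_raw, r_corrected,
    z_corrected``.  Participants with an undefined score carry NaN and
    should be excluded from aggregates (warned at computation time).
    """
    rows = []
    for pid, sub in items.groupby("participant_id", sort=True):
        raw = conformity_score(sub, "c", deviation_field, str(pid))
        row = {"participant_id": str(pid), "r_raw": raw.r, "z_raw": raw.z}
        if corrected_field in sub.columns:
            cor = conformity_score(sub, corrected_field, deviation_field, str(pid))
            row.update({"r_corrected": cor.r, "z_corrected": cor.z})
        rows.append(row)
    return pd.DataFrame(rows)
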