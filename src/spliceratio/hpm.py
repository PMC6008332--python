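"""Proteome-microarray candidate filter.

GenePix-style spot statistics (foreground F635 and local background B635)
are reduced to three per-protein quantities:

* SNR per spot: ``(F635_mean - B635_mean) / B635_sd``,
* fold change per spot: ``F635_median / B635_median``,
* CV across the two duplicate spots: sample s.d. / mean of the
  background-subtracted mean signals.

A protein passes with SNR >= 3 and fold >= 5 on both spots (per-spot by
default — stricter than filtering on the duplicate mean, which is exposed
as an option) and duplicate CV < 0.15.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass

import pandas as pd

__all__ = ["SpotStats", "compute_spot_stats", "filter_candidates"]

SNR_MIN = 3.0
FOLD_MIN = 5.0
CV_MAX = 0.15


@dataclass(frozen=True, slots=True)
class SpotStats:
    """Per-protein spot statistics and filter outcome."""

    protein_id: str
    snr: tuple[float, float]
    fold: tuple[float, float]
    cv: float
    pass_flag: bool
    reason: str  # "" when passing; first failed rule otherwise


def compute_spot_stats(
    spots: pd.DataFrame,
    snr_min: float = SNR_MIN,
    fold_min: float = FOLD_MIN,
    cv_max: float = CV_MAX,
    per_spot: bool = True,
) -> SpotStats:
    """Reduce one protein's two duplicate spots to filter statistics.

    ``per_spot=False`` applies the SNR/fold cutoffs to the duplicate means
    instead of each spot.  Zero background s.d. or median excludes the
    protein with a reason code.
    """
    if len(spots) != 2:
        raise ValueError(
            f"{spots['protein_id'].iloc[0] if len(spots) else '?'}: "
            f"expected exactly 2 duplicate spots, got {len(spots)}"
        )
    protein_id = str(spots["protein_id"].iloc[0])
    if (spots["B635_sd"] <= 0).any() or (spots["B635_median"] <= 0).any():
        return SpotStats(protein_id, (math.nan, math.nan), (math.nan, math.nan),
                         math.nan, False, "degenerate_background")
    signal = (spots["F635_mean"] - spots["B635_mean"]).to_numpy(dtype=float)
    snr = tuple(signal / spots["B635_sd"].to_numpy(dtype=float))
    fold = tuple(
        (spots["F635_median"] / spots["B635_median"]).to_numpy(dtype=float)
    )
    mean_signal = float(signal.mean())
    if mean_signal == 0:
        return SpotStats(protein_id, snr, fold, math.nan, False, "zero_signal")
    cv = abs(statistics.stdev(signal) / mean_signal)

    if per_spot:
        snr_ok = min(snr) >= snr_min
        fold_ok = min(fold) >= fold_min
    else:
        snr_ok = (snr[0] + snr[1]) / 2 >= snr_min
        fold_ok = (fold[0] + fold[1]) / 2 >= fold_min
    reason = "" if snr_ok else "snr"
    if not reason and not fold_ok:
        reason = "fold"
    if not reason and not cv < cv_max:
        reason = "cv"
    return SpotStats(protein_id, snr, fold, cv, reason == "", reason)


def filter_candidates(
    spot_table: pd.DataFrame,
    snr_min: float = SNR_MIN,
    fold_min: float = FOLD_MIN,
    cv_max: float = CV_MAX,
    per_spot: bool = True,
) -> pd.DataFrame:
    """Apply the spot filter to a whole spot table.

    Returns one row per protein, sorted by protein id: snr1, snr2, fold1,
    fold2, cv, pass flag and failure reason.  Candidates are the rows with
    ``passed`` true.
    """
    rows = []
    for protein_id, spots in spot_table.groupby("protein_id", sort=True):
        st = compute_spot_stats(
            spots.sort_values("replicate_index"),
            snr_min=snr_min, fold_min=fold_min, cv_max=cv_max, per_spot=per_spot,
        )
        rows.append(
            {
                "protein_id": st.protein_id,
                "snr1": st.snr[0],
                "snr2": st.snr[1],
                "fold1": st.fold[0],
                "fold2": st.fold[1],
                "cv": st.cv,
                "passed": st.pass_flag,
                "reason": st.reason,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "snr1", "snr2", "fold1", "fold2", "cv", "passed", "reason"],
    )
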