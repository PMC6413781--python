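"""Change-from-baseline summaries for hair melanin chemical markers.

PTCA (pyrrole-2,3,5-tricarboxylic acid) is an oxidation product
proportional to eumelanin; 4-AHP (4-amino-3-hydroxyphenylalanine) a
hydrolysis product proportional to pheomelanin. Both are reported in
ng per mg of hair. Change is computed against each participant's earliest
visit on record; the spread is the sample (n-1) standard deviation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MARKERS = ("ptca", "ahp4")
HAIR_COLUMNS = ["participant", "visit_month", "ptca", "ahp4"]


def validate_hair_table(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(HAIR_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"hair table missing columns: {sorted(missing)}")
    for m in MARKERS:
        vals = records[m].to_numpy(float)
        if np.any(vals[np.isfinite(vals)] < 0):
            raise ValueError(f"negative concentrations in column {m!r}")
    return records


def marker_ratio(records: pd.DataFrame) -> pd.DataFrame:
    """Convenience eumelanin:pheomelanin marker ratio (PTCA / 4-AHP) per
    record; NaN where 4-AHP is zero. Not part of the trial's own tables."""
    out = records.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(out["ahp4"] > 0, out["ptca"] / out["ahp4"], np.nan)
    out["ptca_ahp4_ratio"] = ratio
    return out


def marker_change_summary(records: pd.DataFrame, target_visit: int) -> pd.DataFrame:
    """Per-marker n, mean and sample SD of change from baseline.

    Baseline is each participant's earliest visit with data for the marker.
    Participants lacking a baseline or the target visit are excluded with a
    logged warning. With a single participant the SD is undefined and
    reported as NaN.
    """
    validate_hair_table(records)
    rows = []
    for marker in MARKERS:
        sub = records.dropna(subset=[marker])
        changes = []
        for pid, grp in sub.groupby("participant", sort=True):
            grp = grp.sort_values("visit_month")
            baseline_month = grp["visit_month"].iloc[0]
            tgt = grp[grp["visit_month"] == target_visit]
            if tgt.empty:
                logger.warning(
                    "participant %s lacks %s at month %s; excluded", pid, marker, target_visit
                )
                continue
            if baseline_month == target_visit:
                logger.warning(
                    "participant %s has no visit before month %s for %s; excluded",
                    pid, target_visit, marker,
                )
                continue
            baseline = grp[grp["visit_month"] == baseline_month][marker].iloc[0]
            changes.append(float(tgt[marker].iloc[0] - baseline))
        n = len(changes)
        if n == 0:
            raise ValueError(f"no participant has both baseline and month {target_visit}")
        arr = np.asarray(changes)
        rows.append(
            {
                "marker": marker,
                "visit_month": target_visit,
                "n": n,
                "mean_change": float(arr.mean()),
                "sd_change": float(arr.std(ddof=1)) if n > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
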