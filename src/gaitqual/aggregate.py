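"""Weekly median aggregation of epoch-level gait characteristics.

A subject's gait quality for a measurement week is summarized as the
median over all valid epochs of that week, one value per characteristic.
Cells backed by fewer than a configurable number of valid epochs are set
to missing, and downstream two-week analyses use complete cases only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: columns that label rather than measure an epoch
ID_COLUMNS = ("subject", "week", "day", "epoch", "valid", "invalid_reason")


def feature_columns(epoch_rows: pd.DataFrame) -> list[str]:
    return [c for c in epoch_rows.columns if c not in ID_COLUMNS]


def weekly_median_table(epoch_rows: pd.DataFrame,
                        min_epochs: int = 10) -> pd.DataFrame:
    """Per-(subject, week) medians over valid epochs.

    Each characteristic is aggregated independently: its cell is the median
    of non-missing values among valid epochs, or missing when fewer than
    ``min_epochs`` such values exist. ``n_epochs_<name>`` columns record
    the count behind each cell.
    """
    cols = feature_columns(epoch_rows)
    if epoch_rows.empty or not cols:
        return pd.DataFrame(columns=["subject", "week"])
    valid = epoch_rows[epoch_rows["valid"].astype(bool)] \
        if "valid" in epoch_rows.columns else epoch_rows
    out_rows = []
    for (subj, week), grp in valid.groupby(["subject", "week"], sort=True):
        row: dict = {"subject": subj, "week": week}
        for c in cols:
            vals = grp[c].dropna()
            row[f"n_epochs_{c}"] = len(vals)
            row[c] = float(np.median(vals)) if len(vals) >= min_epochs else np.nan
        out_rows.append(row)
    table = pd.DataFrame(out_rows)
    ordered = ["subject", "week"] + cols + [f"n_epochs_{c}" for c in cols]
    return table[[c for c in ordered if c in table.columns]]


def paired_weeks(table: pd.DataFrame, characteristic: str,
                 weeks: tuple[int, int] = (1, 2),
                 ) -> tuple[np.ndarray, np.ndarray, list]:
    """Complete-case week-1/week-2 value pairs for one characteristic.

    Subjects missing the characteristic in either week are dropped; the
    retained subject ids are returned for accounting.
    """
    wide = table.pivot_table(index="subject", columns="week",
                             values=characteristic, aggfunc="first")
    for w in weeks:
        if w not in wide.columns:
            return np.array([]), np.array([]), []
    wide = wide[list(weeks)].dropna()
    return (wide[weeks[0]].to_numpy(), wide[weeks[1]].to_numpy(),
            list(wide.index))
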