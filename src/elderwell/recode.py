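"""Categorical recoding that prepares scored survey data for MCA, trees and
regression.

The rules, applied per respondent:

* each wellbeing index is discretized into sample quartiles Q1 (worst) to Q4
  (best) using linear-interpolation percentiles; values exactly on a
  breakpoint fall into the lower quartile;
* number of children is banded into "no child" / "1-3 children" /
  "more than 3 children";
* class_total / places_total count the distinct activity flags set, and the
  binarized versions indicate two or more activities;
* work status collapses to yes (working, part-time, ad-hoc or freelance) /
  no; health to good ("good" or "very good") / not good; family and friends
  relationships to good ("good" or "excellent") / not good; education to
  "more than secondary" / "secondary or less".

Rows with a missing learning attitude are retained; each downstream stage
applies its own complete-case rule.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .codebook import CLASS_FLAGS, PLACE_FLAGS, WORKING_LEVELS

QUARTILE_LEVELS = ("Q1", "Q2", "Q3", "Q4")
CHILD_BANDS = ("no child", "1-3 children", "more than 3 children")
MORE_THAN_SECONDARY = ("post-secondary", "tertiary")
GOOD_HEALTH = ("good", "very good")
GOOD_REL = ("good", "excellent")

QUARTILE_COLUMNS = {
    "MWI_Quality": "quality_r",
    "MWI_Satisfaction": "satisfaction_r",
    "MWI_Psychological": "psychological_r",
}


class DegenerateQuartiles(UserWarning):
    """All scores identical: the quartile partition collapses to Q1."""


def quartile_bin(scores) -> pd.Categorical:
    """Assign Q1..Q4 by the 25/50/75 sample percentiles of the scores.

    Breakpoints use linear-interpolation percentiles over the non-missing
    values; a value equal to a breakpoint goes to the lower bin.  Missing
    stays missing.  Requires at least 4 non-missing scores.
    """
    s = pd.Series(np.asarray(scores, dtype=float))
    obs = s.dropna().to_numpy()
    if obs.size < 4:
        raise ValueError(f"need >= 4 non-missing scores to form quartiles, got {obs.size}")
    breaks = np.percentile(obs, [25, 50, 75], method="linear")
    if breaks[0] == breaks[2]:
        warnings.warn(
            "all quartile breakpoints coincide; assigning every score to Q1",
            DegenerateQuartiles,
        )
    idx = np.searchsorted(breaks, s.to_numpy(), side="left")
    codes = np.where(s.isna(), -1, idx)
    return pd.Categorical.from_codes(codes, categories=list(QUARTILE_LEVELS))


def recode_children(n_children) -> pd.Categorical:
    """Band a child count: 0 -> no child, 1-3, >=4 -> more than 3 children."""
    n = pd.Series(np.asarray(n_children, dtype=float))
    if (n.dropna() < 0).any():
        raise ValueError("negative child count")
    codes = np.select(
        [n.isna(), n == 0, n <= 3], [-1, 0, 1], default=2
    )
    return pd.Categorical.from_codes(codes, categories=list(CHILD_BANDS))


def binarize_activity(total, threshold: int = 2):
    """1 iff the respondent did `threshold` or more distinct activities."""
    t = np.asarray(total, dtype=float)
    if np.any(t[~np.isnan(t)] < 0):
        raise ValueError("negative activity count")
    out = np.where(np.isnan(t), np.nan, (t >= threshold).astype(float))
    return out if out.ndim else float(out)


def _good_flag(col: pd.Series, good_levels) -> pd.Categorical:
    vals = np.where(col.isna(), None, np.where(col.isin(good_levels), "good", "not good"))
    return pd.Categorical(vals, categories=["not good", "good"])


def collapse_levels(table: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Build the coded table: quartile tags, bands, counts and collapsed flags.

    Parameters
    ----------
    table : DataFrame
        Validated survey table (one row per respondent).
    scores : DataFrame
        MWI columns aligned with ``table`` (from :func:`~elderwell.index.score_table`).

    Returns
    -------
    DataFrame with one row per input row, carrying both the raw activity
    counts (used by the regressions) and their binarized versions (used by
    the MCA), plus all collapsed categorical fields.
    """
    if "health_good" in table.columns and "health" not in table.columns:
        # already coded: the collapse is idempotent and never drops rows
        return table.copy()

    needed = {"marital", "no_children", "education", "work", "gender", "health",
              "disability", "mobility", "family_rel", "friends_rel", "learn_elderly"}
    absent = sorted(needed - set(table.columns))
    if absent:
        raise KeyError(f"survey table lacks column(s): {absent}")

    out = pd.DataFrame(index=table.index)
    out["respondent_id"] = table["respondent_id"].values

    for mwi_col, coded_col in QUARTILE_COLUMNS.items():
        out[coded_col] = quartile_bin(scores[mwi_col])

    out["no_children"] = table["no_children"].to_numpy(dtype=float)
    out["children_band"] = recode_children(table["no_children"])
    class_total = table[list(CLASS_FLAGS)].sum(axis=1, skipna=False)
    places_total = table[list(PLACE_FLAGS)].sum(axis=1, skipna=False)
    out["class_total"] = class_total.to_numpy(dtype=float)
    out["places_total"] = places_total.to_numpy(dtype=float)
    out["class_total_bin"] = binarize_activity(class_total)
    out["places_total_bin"] = binarize_activity(places_total)

    work = table["work"]
    out["working"] = pd.Categorical(
        np.where(work.isna(), None, np.where(work.isin(WORKING_LEVELS), "yes", "no")),
        categories=["no", "yes"],
    )
    out["retired"] = (work == "retired").astype(float).where(work.notna())
    out["health_good"] = _good_flag(table["health"], GOOD_HEALTH)
    out["family_good"] = _good_flag(table["family_rel"], GOOD_REL)
    out["friends_good"] = _good_flag(table["friends_rel"], GOOD_REL)
    out["education_band"] = pd.Categorical(
        np.where(
            table["education"].isna(),
            None,
            np.where(
                table["education"].isin(MORE_THAN_SECONDARY),
                "more than secondary",
                "secondary or less",
            ),
        ),
        categories=["secondary or less", "more than secondary"],
    )
    out["learn_elderly"] = pd.Categorical(
        table["learn_elderly"], categories=["no", "yes"]
    )
    out["disability"] = table["disability"].to_numpy(dtype=float)
    out["mobility"] = table["mobility"].to_numpy(dtype=float)
    out["female"] = (table["gender"] == "female").astype(float).where(table["gender"].notna())
    out["married"] = (table["marital"] == "married").astype(float).where(table["marital"].notna())
    return out
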