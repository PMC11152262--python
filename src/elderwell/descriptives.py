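"""Exploratory summaries: frequency profiles, activity participation,
index cross-correlations and wellbeing distributions by learning attitude."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .codebook import CLASS_FLAGS, PLACE_FLAGS


@dataclass
class FrequencyReport:
    """Category counts for one field, plus the missing count and base n."""

    field: str
    counts: pd.Series
    n_missing: int
    n: int

    def to_frame(self) -> pd.DataFrame:
        df = self.counts.rename("count").rename_axis("category").reset_index()
        df.insert(0, "field", self.field)
        return df


def frequency_counts(table: pd.DataFrame, field: str) -> FrequencyReport:
    """Per-category counts of one field; never invents empty categories
    beyond those declared on a categorical dtype."""
    if field not in table.columns:
        raise KeyError(f"unknown field {field!r}")
    col = table[field]
    counts = col.value_counts(dropna=True).sort_index()
    counts = counts[counts.index.notna() & (counts > 0)]
    return FrequencyReport(
        field=field,
        counts=counts,
        n_missing=int(col.isna().sum()),
        n=int(len(col)),
    )


def activity_distribution(table: pd.DataFrame) -> pd.DataFrame:
    """Counts of respondents with 0 / 1 / >=2 activities, classes and places.

    Returns a two-row frame (family x {none, one, two_or_more}).
    """
    rows = {}
    for family, flags in (("classes", CLASS_FLAGS), ("places", PLACE_FLAGS)):
        total = table[list(flags)].sum(axis=1)
        rows[family] = {
            "none": int((total == 0).sum()),
            "one": int((total == 1).sum()),
            "two_or_more": int((total >= 2).sum()),
        }
    return pd.DataFrame(rows).T[["none", "one", "two_or_more"]]


def mwi_correlations(scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations of the three indices (complete cases)."""
    obs = scores.dropna()
    if len(obs) < 3:
        raise ValueError("need at least 3 complete score rows")
    zero_var = [c for c in obs.columns if obs[c].std() == 0]
    corr = obs.corr(method="pearson")
    for c in zero_var:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
        corr.loc[c, c] = 1.0
    return corr


def grouped_distribution(
    scores: pd.DataFrame, group: pd.Series
) -> pd.DataFrame:
    """Per-group mean, quartiles and sample skewness of each index.

    Skewness is the adjusted Fisher-Pearson estimator.  Groups with fewer
    than 2 members get NaN summaries; missing group labels are skipped.
    """
    rows = []
    obs_group = group.dropna()
    for level, idx in obs_group.groupby(obs_group, observed=True).groups.items():
        sub = scores.loc[idx]
        for col in scores.columns:
            vals = sub[col].dropna().to_numpy()
            ok = vals.size >= 2
            rows.append(
                {
                    "group": level,
                    "score": col,
                    "n": vals.size,
                    "mean": vals.mean() if ok else np.nan,
                    "q25": np.percentile(vals, 25) if ok else np.nan,
                    "median": np.percentile(vals, 50) if ok else np.nan,
                    "q75": np.percentile(vals, 75) if ok else np.nan,
                    "skewness": stats.skew(vals, bias=False) if vals.size >= 3 else np.nan,
                }
            )
    return pd.DataFrame(rows)
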