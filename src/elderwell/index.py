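"""The Multidimensional Wellbeing Index (MWI).

Each wellbeing instrument (CASP-19 quality of life, Satisfaction with Life,
WHO-5 psychological wellbeing) is summarized per respondent by a normalized
Euclidean-distance index rather than a raw sum.  Item responses are first
rescaled to the unit interval,

    d_j = (A_j - m_j) / (M_j - m_j)          (reflected for reverse-keyed items)

and the k normalized responses of a scale are aggregated as

    MWI = 1/2 * [ ||d||_2 / sqrt(k)  +  (1 - ||1 - d||_2 / sqrt(k)) ]

i.e. the average of (i) the normalized distance from the worst point 0 and
(ii) one minus the normalized distance from the ideal point 1.  The index is
unit-free, bounded in [0, 1] (0 = worst, 1 = best possible wellbeing),
strictly monotone in every dimension, and invariant to affine rescaling of
the raw response grid.  It also satisfies the complement symmetry
MWI(d) + MWI(1 - d) = 1.

This construction follows the distance-based composite-index tradition used
for financial-inclusion indices; unlike a mean score it penalizes uneven
profiles symmetrically from both the floor and the ceiling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .codebook import (
    HIGHER_IS_BETTER,
    LOWER_IS_BETTER,
    Codebook,
    ScaleDefinition,
    SchemaError,
    default_codebook,
)

SCORE_COLUMNS = {
    "quality": "MWI_Quality",
    "satisfaction": "MWI_Satisfaction",
    "psychological": "MWI_Psychological",
}


def normalize_response(A, m: float, M: float, orientation: str = HIGHER_IS_BETTER):
    """Map a raw response in [m, M] onto [0, 1] with 1 = best wellbeing.

    Scalar or array ``A``; NaN propagates.  Raises on degenerate bounds or
    out-of-range values.
    """
    if M <= m:
        raise ValueError(f"upper bound {M} must exceed lower bound {m}")
    A = np.asarray(A, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((A < m) | (A > M)):
            raise ValueError(f"response outside [{m}, {M}]")
    if orientation == HIGHER_IS_BETTER:
        d = (A - m) / (M - m)
    elif orientation == LOWER_IS_BETTER:
        d = (M - A) / (M - m)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return d if d.ndim else float(d)


def normalize_table(table: pd.DataFrame, scale: ScaleDefinition, codebook: Codebook | None = None) -> pd.DataFrame:
    """Normalized response matrix (respondents x items) for one scale."""
    missing = [it for it in scale.items if it not in table.columns]
    if missing:
        raise SchemaError(f"scale {scale.scale_id!r}: missing item column(s) {missing}")
    cols = {}
    for j, item in enumerate(scale.items):
        cols[item] = normalize_response(
            table[item].to_numpy(dtype=float), scale.m[j], scale.M[j], scale.orientation[j]
        )
    return pd.DataFrame(cols, index=table.index)


def compute_mwi(d) -> float:
    """Aggregate one respondent's normalized responses into the index.

    ``d`` is a length-k vector with entries in [0, 1] and no missing values.
    Returns a score in [0, 1]; exactly 0 at the all-worst corner and exactly
    1 at the all-best corner.
    """
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValueError("empty response vector")
    if np.any(np.isnan(d)):
        raise ValueError("missing values in response vector; apply a missing policy first")
    if np.any((d < 0) | (d > 1)):
        raise ValueError("normalized responses must lie in [0, 1]")
    k = d.size
    lower = np.linalg.norm(d) / np.sqrt(k)
    upper = np.linalg.norm(1.0 - d) / np.sqrt(k)
    return float(0.5 * (lower + 1.0 - upper))


def _mwi_rows(d: np.ndarray) -> np.ndarray:
    """Row-wise index over a matrix; rows containing NaN yield NaN."""
    k = d.shape[1]
    with np.errstate(invalid="ignore"):
        lower = np.sqrt(np.sum(d**2, axis=1) / k)
        upper = np.sqrt(np.sum((1.0 - d) ** 2, axis=1) / k)
    return 0.5 * (lower + 1.0 - upper)


class MWIScorer(TransformerMixin, BaseEstimator):
    """Transformer computing the three wellbeing indices from item responses.

    Parameters
    ----------
    codebook : Codebook or None
        Scale definitions to score against; default instrument when None.
    policy : {"strict", "rescale"}
        Missing-item handling.  ``strict`` (default): any missing item makes
        that scale's score missing, keeping k fixed at the instrument length.
        ``rescale``: score over the observed items with k = observed count.

    Attributes
    ----------
    scales_ : dict
        Scale definitions used, keyed by scale id.
    feature_names_out_ : list of str
        Output columns: MWI_Quality, MWI_Satisfaction, MWI_Psychological.
    """

    def __init__(self, codebook: Codebook | None = None, policy: str = "strict"):
        self.codebook = codebook
        self.policy = policy

    def fit(self, X: pd.DataFrame, y=None) -> "MWIScorer":
        if self.policy not in ("strict", "rescale"):
            raise ValueError(f"unknown missing policy {self.policy!r}")
        cb = self.codebook or default_codebook()
        for scale in cb.scales.values():
            absent = [it for it in scale.items if it not in X.columns]
            if absent:
                raise SchemaError(
                    f"scale {scale.scale_id!r}: missing item column(s) {absent}"
                )
        self.scales_ = dict(cb.scales)
        self.feature_names_out_ = [SCORE_COLUMNS[s] for s in self.scales_]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "scales_"):
            self.fit(X)
        out = {}
        for scale_id, scale in self.scales_.items():
            d = normalize_table(X, scale).to_numpy()
            if self.policy == "strict":
                scores = _mwi_rows(d)
            else:
                scores = np.full(len(d), np.nan)
                for i, row in enumerate(d):
                    obs = row[~np.isnan(row)]
                    if obs.size:
                        scores[i] = compute_mwi(obs)
            out[SCORE_COLUMNS[scale_id]] = scores
        return pd.DataFrame(out, index=X.index)


def score_table(
    table: pd.DataFrame,
    codebook: Codebook | None = None,
    policy: str = "strict",
) -> pd.DataFrame:
    """Score a validated survey table; returns the three MWI columns."""
    return MWIScorer(codebook=codebook, policy=policy).fit(table).transform(table)
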