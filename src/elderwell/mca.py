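"""Multiple Correspondence Analysis of the coded survey table.

MCA is correspondence analysis applied to the cases-by-categories indicator
matrix Z (one binary column per category, exactly one 1 per variable per
row).  With P = Z / n_total, row masses r, column masses c, the standardized
residual matrix is

    S = D_r^{-1/2} (P - r c^T) D_c^{-1/2},      S = U Sigma V^T  (SVD)

Principal inertias are the squared singular values; their total equals
(J - Q)/Q for an indicator matrix with J categories over Q variables.
Category principal coordinates are D_c^{-1/2} V Sigma and individual
(respondent) principal coordinates are D_r^{-1/2} U Sigma; the two are
linked by the usual CA transition formulas, which :meth:`MCA.transform`
uses to project new respondents.

Raw inertia proportions understate the structure of indicator MCA, so the
Benzecri-adjusted proportions are also computed; the raw figures are the
default report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

#: default active variables: (coded-table column, display name) pairs.  The
#: binarized activity totals are displayed under their count names so that
#: category labels read class_total_1, places_total_1.
DEFAULT_ACTIVE_VARS: tuple[tuple[str, str], ...] = (
    ("quality_r", "quality_r"),
    ("satisfaction_r", "satisfaction_r"),
    ("psychological_r", "psychological_r"),
    ("learn_elderly", "learn_elderly"),
    ("class_total_bin", "class_total"),
    ("places_total_bin", "places_total"),
    ("health_good", "health_good"),
    ("family_good", "family_good"),
    ("friends_good", "friends_good"),
    ("working", "working"),
    ("education_band", "education"),
    ("children_band", "children"),
    ("disability", "disability"),
    ("mobility", "mobility"),
    ("female", "female"),
    ("married", "married"),
)

VARIABLE_GROUPS = {
    "quality_r": "wellbeing",
    "satisfaction_r": "wellbeing",
    "psychological_r": "wellbeing",
    "learn_elderly": "learning",
    "class_total": "learning",
    "places_total": "learning",
}


@dataclass
class IndicatorMatrix:
    """One-hot indicator matrix with bookkeeping.

    Each row sums to Q (one category per active variable); J is the total
    category count.  ``index`` carries the respondent ids of retained
    (complete-case) rows; ``n_dropped`` the rows excluded for missing an
    active category.
    """

    Z: np.ndarray
    columns: list[str]
    var_of_column: list[str]
    Q: int
    J: int
    index: pd.Index
    n_dropped: int = 0


def _flag_to_level(v) -> str:
    if isinstance(v, str):
        return v
    f = float(v)
    return str(int(f)) if f == int(f) else str(f)


def one_hot(
    coded: pd.DataFrame,
    active_vars=None,
) -> IndicatorMatrix:
    """Build the indicator matrix over the active variables (complete cases).

    ``active_vars`` is a sequence of column names or (column, display-name)
    pairs; category labels follow the ``variable_level`` convention
    (``learn_elderly_no``, ``class_total_1``, ...).  Rows missing any active
    variable are dropped and counted.  A variable with fewer than two
    observed levels raises (its categories carry no variance).
    """
    if active_vars is None:
        active_vars = [p for p in DEFAULT_ACTIVE_VARS if p[0] in coded.columns]
    pairs = [(v, v) if isinstance(v, str) else tuple(v) for v in active_vars]
    missing = [c for c, _ in pairs if c not in coded.columns]
    if missing:
        raise KeyError(f"active variable(s) not in coded table: {missing}")

    sub = coded[[c for c, _ in pairs]]
    complete = sub.notna().all(axis=1)
    sub = sub.loc[complete]
    n_dropped = int((~complete).sum())
    if len(sub) == 0:
        raise ValueError("no complete cases over the active variables")

    blocks, columns, var_of_column = [], [], []
    for col, name in pairs:
        levels = [_flag_to_level(v) for v in sub[col]]
        uniq = sorted(set(levels))
        if len(uniq) < 2:
            raise ValueError(
                f"active variable {name!r} has a single observed level {uniq}; "
                "zero-variance category set"
            )
        arr = np.zeros((len(sub), len(uniq)))
        pos = {u: j for j, u in enumerate(uniq)}
        for i, lv in enumerate(levels):
            arr[i, pos[lv]] = 1.0
        blocks.append(arr)
        columns.extend(f"{name}_{u}" for u in uniq)
        var_of_column.extend([name] * len(uniq))

    Z = np.hstack(blocks)
    idx = (
        pd.Index(coded.loc[complete, "respondent_id"])
        if "respondent_id" in coded.columns
        else sub.index
    )
    return IndicatorMatrix(
        Z=Z,
        columns=columns,
        var_of_column=var_of_column,
        Q=len(pairs),
        J=Z.shape[1],
        index=idx,
        n_dropped=n_dropped,
    )


@dataclass
class MCAResult:
    """Inertias plus category and individual coordinates."""

    eigenvalues: np.ndarray          # principal inertias, non-increasing
    explained_inertia: np.ndarray    # raw proportions over ALL dimensions
    adjusted_inertia: np.ndarray     # Benzecri-adjusted proportions
    total_inertia: float
    column_coordinates: pd.DataFrame
    row_coordinates: pd.DataFrame
    column_contributions: pd.DataFrame
    column_masses: pd.Series
    singular_values: np.ndarray
    Q: int
    J: int


def fit_mca(Z: IndicatorMatrix, n_dims: int | None = None) -> MCAResult:
    """Correspondence analysis of an indicator matrix.

    Dimensions are ordered by inertia.  The SVD sign ambiguity is resolved
    by orienting each dimension so that its highest-contribution category
    has a positive coordinate.
    """
    X = Z.Z
    n, J = X.shape
    max_dims = min(J - Z.Q, n - 1)
    if n_dims is None:
        n_dims = max_dims
    if n_dims > max_dims:
        raise ValueError(f"n_dims={n_dims} exceeds the rank bound {max_dims}")

    P = X / X.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    sv = sv[:max_dims]
    U = U[:, :max_dims]
    V = Vt[:max_dims].T
    if max_dims == 0 or sv[0] <= 1e-12:
        raise ValueError("degenerate indicator matrix: residual has rank 0")

    eig = sv**2
    total = float(eig.sum())
    explained = eig / total

    # Benzecri adjustment: only dimensions with inertia > 1/Q carry signal
    thr = 1.0 / Z.Q
    adj = np.where(eig > thr, (Z.Q / (Z.Q - 1.0) * (eig - thr)) ** 2, 0.0)
    adj_total = adj.sum()
    adjusted = adj / adj_total if adj_total > 0 else np.zeros_like(adj)

    col_coords = (V * sv) / np.sqrt(c)[:, None]
    row_coords = (U * sv) / np.sqrt(r)[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = (c[:, None] * col_coords**2) / eig[None, :]

    # sign convention: top-contribution category positive on each dimension
    for s in range(len(sv)):
        lead = int(np.argmax(contrib[:, s]))
        if col_coords[lead, s] < 0:
            col_coords[:, s] *= -1
            row_coords[:, s] *= -1

    dims = [f"dim_{s + 1}" for s in range(n_dims)]
    return MCAResult(
        eigenvalues=eig[:n_dims],
        explained_inertia=explained,
        adjusted_inertia=adjusted,
        total_inertia=total,
        column_coordinates=pd.DataFrame(col_coords[:, :n_dims], index=Z.columns, columns=dims),
        row_coordinates=pd.DataFrame(row_coords[:, :n_dims], index=Z.index, columns=dims),
        column_contributions=pd.DataFrame(contrib[:, :n_dims], index=Z.columns, columns=dims),
        column_masses=pd.Series(c, index=Z.columns),
        singular_values=sv[:n_dims],
        Q=Z.Q,
        J=Z.J,
    )


def factor_table(
    result: MCAResult,
    dims: tuple[int, int] = (1, 2),
    learn_labels: pd.Series | None = None,
) -> pd.DataFrame:
    """Long-format coordinates for the two requested dimensions.

    Categories carry a group tag (wellbeing / learning / demographic);
    individuals optionally carry their learning-attitude label, matching the
    colouring of the individual factor map.
    """
    d1, d2 = dims
    for d in dims:
        if not 1 <= d <= result.column_coordinates.shape[1]:
            raise IndexError(f"dimension {d} not retained in result")
    c1, c2 = f"dim_{d1}", f"dim_{d2}"

    cat = pd.DataFrame(
        {
            "point": result.column_coordinates.index,
            "kind": "category",
            "group": [
                VARIABLE_GROUPS.get(_var_of(label), "demographic")
                for label in result.column_coordinates.index
            ],
            "x": result.column_coordinates[c1].to_numpy(),
            "y": result.column_coordinates[c2].to_numpy(),
        }
    )
    ind = pd.DataFrame(
        {
            "point": result.row_coordinates.index.astype(str),
            "kind": "individual",
            "group": (
                learn_labels.reindex(result.row_coordinates.index).astype(str).to_numpy()
                if learn_labels is not None
                else "individual"
            ),
            "x": result.row_coordinates[c1].to_numpy(),
            "y": result.row_coordinates[c2].to_numpy(),
        }
    )
    return pd.concat([cat, ind], ignore_index=True)


def _var_of(label: str) -> str:
    for var in VARIABLE_GROUPS:
        if label.startswith(var + "_"):
            return var
    return label.rsplit("_", 1)[0]


class MCA(TransformerMixin, BaseEstimator):
    """Multiple correspondence analysis as an sklearn-style transformer.

    Parameters
    ----------
    n_components : int or None
        Number of dimensions to retain (all non-trivial ones when None).
    active_vars : sequence or None
        Columns (or (column, display-name) pairs) of the coded table to use
        as active variables; defaults to the full coded categorical set.

    Attributes
    ----------
    eigenvalues_ : ndarray — principal inertias per retained dimension.
    explained_inertia_ : ndarray — raw proportions (all dimensions).
    adjusted_inertia_ : ndarray — Benzecri-adjusted proportions.
    total_inertia_ : float — equals (J - Q)/Q.
    column_coordinates_, row_coordinates_ : DataFrame — principal coordinates.
    result_ : MCAResult — full fitted result.
    """

    def __init__(self, n_components: int | None = None, active_vars=None):
        self.n_components = n_components
        self.active_vars = active_vars

    def fit(self, X: pd.DataFrame, y=None) -> "MCA":
        Z = one_hot(X, self.active_vars)
        res = fit_mca(Z, self.n_components)
        self.indicator_ = Z
        self.result_ = res
        self.eigenvalues_ = res.eigenvalues
        self.explained_inertia_ = res.explained_inertia
        self.adjusted_inertia_ = res.adjusted_inertia
        self.total_inertia_ = res.total_inertia
        self.column_coordinates_ = res.column_coordinates
        self.row_coordinates_ = res.row_coordinates
        self.n_dropped_ = Z.n_dropped
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Project respondents via the CA transition formula.

        row coordinate = (row profile) . (category principal coords) / sigma
        """
        if not hasattr(self, "result_"):
            raise RuntimeError("MCA instance is not fitted yet")
        pairs = [(v, v) if isinstance(v, str) else tuple(v) for v in (
            self.active_vars
            if self.active_vars is not None
            else [p for p in DEFAULT_ACTIVE_VARS if p[0] in X.columns]
        )]
        fitted_cols = list(self.result_.column_coordinates.index)
        blocks = []
        for col, name in pairs:
            levels = [_flag_to_level(v) for v in X[col]]
            arr = np.zeros((len(X), len(fitted_cols)))
            for i, lv in enumerate(levels):
                label = f"{name}_{lv}"
                if label in fitted_cols:
                    arr[i, fitted_cols.index(label)] = 1.0
            blocks.append(arr)
        Znew = sum(blocks)
        profile = Znew / Znew.sum(axis=1, keepdims=True)
        G = self.result_.column_coordinates.to_numpy()
        coords = profile @ G / self.result_.singular_values[None, :]
        return pd.DataFrame(coords, index=X.index, columns=self.result_.column_coordinates.columns)
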