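"""MCA machinery: indicator construction, inertia identities, coordinates.

The independent oracle used throughout is a from-scratch correspondence
analysis via eigendecomposition of SᵀS with explicit loops — a different
numerical route from the production SVD implementation.
"""

import numpy as np
import pandas as pd
import pytest

from elderwell.mca import MCA, IndicatorMatrix, factor_table, fit_mca, one_hot


def reference_ca(Z, Q):
    """Independent correspondence analysis: eigen-decomposition of SᵀS.

    Returns (eigenvalues desc, category principal coordinates) computed by
    explicit summation, no SVD.
    """
    Z = np.asarray(Z, dtype=float)
    n, J = Z.shape
    total = Z.sum()
    P = Z / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = np.empty((n, J))
    for i in range(n):
        for j in range(J):
            S[i, j] = (P[i, j] - r[i] * c[j]) / np.sqrt(r[i] * c[j])
    StS = S.T @ S
    w, V = np.linalg.eigh(StS)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    w = np.clip(w, 0, None)
    coords = V * np.sqrt(w)[None, :] / np.sqrt(c)[:, None]
    return w, coords


def indicator_from_frame(df):
    return one_hot(df)


class TestOneHot:
    def test_column_count_and_row_sums(self):
        df = pd.DataFrame({"a": ["x", "y", "x", "y"], "b": ["p", "q", "r", "p"]})
        Z = one_hot(df, ["a", "b"])
        assert Z.J == 5
        assert Z.Q == 2
        assert (Z.Z.sum(axis=1) == 2).all()
        assert Z.columns == ["a_x", "a_y", "b_p", "b_q", "b_r"]

    def test_column_sums_are_category_frequencies(self):
        df = pd.DataFrame({"a": ["x", "x", "y"], "b": ["p", "q", "q"]})
        Z = one_hot(df, ["a", "b"])
        assert dict(zip(Z.columns, Z.Z.sum(axis=0))) == {
            "a_x": 2, "a_y": 1, "b_p": 1, "b_q": 2,
        }

    def test_incomplete_rows_dropped_and_counted(self):
        df = pd.DataFrame({"a": ["x", None, "y", "x"], "b": ["p", "q", "q", "p"]})
        Z = one_hot(df, ["a", "b"])
        assert Z.n_dropped == 1
        assert Z.Z.shape[0] == 3

    def test_single_level_variable_rejected(self):
        df = pd.DataFrame({"a": ["x", "x"], "b": ["p", "q"]})
        with pytest.raises(ValueError, match="single observed level"):
            one_hot(df, ["a", "b"])

    def test_display_rename_drives_labels(self):
        df = pd.DataFrame({"class_total_bin": [0.0, 1.0, 1.0, 0.0], "b": list("pqpq")})
        Z = one_hot(df, [("class_total_bin", "class_total"), "b"])
        assert "class_total_1" in Z.columns and "class_total_0" in Z.columns


class TestFitMca:
    def test_duplicated_binary_variables_give_inertias_one_zero(self):
        # two identical binary variables: phi = 1, eigenvalues (1±1)/2
        x = ["a", "b", "a", "b", "a", "b"]
        Z = one_hot(pd.DataFrame({"v1": x, "v2": x}), ["v1", "v2"])
        res = fit_mca(Z)
        assert res.eigenvalues[0] == pytest.approx(1.0, abs=1e-12)
        assert res.total_inertia == pytest.approx(1.0, abs=1e-12)

    def test_two_binary_closed_form_phi(self):
        """Indicator MCA of two binaries has eigenvalues (1±phi)/2."""
        rng = np.random.default_rng(11)
        x = rng.integers(0, 2, 400)
        y = np.where(rng.random(400) < 0.8, x, 1 - x)  # correlated copy
        df = pd.DataFrame({"x": x.astype(str), "y": y.astype(str)})
        phi = abs(np.corrcoef(x, y)[0, 1])
        res = fit_mca(one_hot(df, ["x", "y"]))
        assert res.eigenvalues[0] == pytest.approx((1 + phi) / 2, abs=1e-10)

    def test_total_inertia_identity_random_matrices(self):
        """Sum of principal inertias equals (J - Q)/Q, against the
        explicit-summation trace oracle."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            nvar = rng.integers(2, 5)
            df = pd.DataFrame(
                {
                    f"v{q}": rng.choice(list("abcd")[: rng.integers(2, 4)], size=40)
                    for q in range(nvar)
                }
            )
            Z = one_hot(df, list(df.columns))
            res = fit_mca(Z)
            w, _ = reference_ca(Z.Z, Z.Q)
            assert res.total_inertia == pytest.approx((Z.J - Z.Q) / Z.Q, abs=1e-10)
            assert res.total_inertia == pytest.approx(w.sum(), abs=1e-10)

    def test_independent_variables_leading_inertia_near_1_over_q(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {"a": rng.choice(["x", "y"], 4000), "b": rng.choice(["p", "q"], 4000)}
        )
        res = fit_mca(one_hot(df, ["a", "b"]))
        assert res.eigenvalues[0] == pytest.approx(0.5, abs=0.05)

    def test_oracle_equivalence_on_fixture(self, paper_like_coded):
        """Inertias and |coordinates| match the independent eigen-route."""
        sub = paper_like_coded.head(60)
        Z = one_hot(sub, ["learn_elderly", "health_good", "working", "children_band"])
        res = fit_mca(Z)
        w, coords = reference_ca(Z.Z, Z.Q)
        k = len(res.eigenvalues)
        assert np.allclose(res.eigenvalues, w[:k], atol=1e-6)
        assert np.allclose(
            np.abs(res.column_coordinates.to_numpy()), np.abs(coords[:, :k]), atol=1e-6
        )

    def test_orthogonality_mass_weighted(self, paper_like_coded):
        res = MCA(n_components=4).fit(paper_like_coded).result_
        F = res.row_coordinates.to_numpy()
        r = np.full(len(F), 1.0 / len(F))
        G = (F * r[:, None]).T @ F
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-10

    def test_transition_formula_consistency(self, paper_like_coded):
        """Row coordinates recompute from category coordinates via the CA
        transition formula."""
        est = MCA(n_components=4).fit(paper_like_coded)
        Z = est.indicator_
        profile = Z.Z / Z.Z.sum(axis=1, keepdims=True)
        recon = profile @ est.column_coordinates_.to_numpy() / est.result_.singular_values[None, :]
        assert np.allclose(recon, est.row_coordinates_.to_numpy(), atol=1e-8)

    def test_inertias_non_increasing_and_proportions_sum_to_one(self, paper_like_coded):
        est = MCA().fit(paper_like_coded)
        assert (np.diff(est.eigenvalues_) <= 1e-12).all()
        assert (est.eigenvalues_ >= -1e-12).all()
        assert est.explained_inertia_.sum() == pytest.approx(1.0, abs=1e-10)

    def test_n_dims_bound_enforced(self):
        df = pd.DataFrame({"a": list("xyxy"), "b": list("pqqp")})
        with pytest.raises(ValueError, match="n_dims"):
            fit_mca(one_hot(df, ["a", "b"]), n_dims=99)


class TestFactorTable:
    def test_every_category_once_with_groups(self, paper_like_coded):
        est = MCA(n_components=3).fit(paper_like_coded)
        labels = paper_like_coded.set_index("respondent_id")["learn_elderly"]
        tab = factor_table(est.result_, (1, 2), learn_labels=labels)
        cats = tab[tab["kind"] == "category"]
        assert sorted(cats["point"]) == sorted(est.column_coordinates_.index)
        assert set(cats["group"]) <= {"wellbeing", "learning", "demographic"}
        inds = tab[tab["kind"] == "individual"]
        assert len(inds) == len(est.row_coordinates_)
        assert {"yes", "no"} <= set(inds["group"])

    def test_out_of_range_dimension_rejected(self, paper_like_coded):
        est = MCA(n_components=2).fit(paper_like_coded)
        with pytest.raises(IndexError):
            factor_table(est.result_, (1, 9))

    def test_transform_matches_fitted_rows(self, paper_like_coded):
        est = MCA(n_components=3).fit(paper_like_coded)
        complete = paper_like_coded.dropna(subset=["learn_elderly"])
        proj = est.transform(complete)
        fitted = est.row_coordinates_
        assert np.allclose(proj.to_numpy(), fitted.to_numpy(), atol=1e-8)
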