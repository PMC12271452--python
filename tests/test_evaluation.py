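"""c-DF-IPF weights, association tests, observed/expected, similarities."""

import numpy as np
import pandas as pd
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ehrclust.evaluation import (
    CDFIPFMatrix,
    DiseaseMatrix,
    cdfipf,
    chi2_one_vs_all,
    comorbidity_similarity,
    crossgender_similarity,
    dfipf,
    observed_expected_exclusivity,
    ttest_one_vs_all,
    z_symbol,
)


def matrix_from(values, conditions=None):
    values = np.asarray(values)
    conditions = conditions or [f"d{j}" for j in range(values.shape[1])]
    ids = [f"p{i}" for i in range(values.shape[0])]
    return DiseaseMatrix(values, ids, conditions)


def brute_force_dfipf(X):
    """Independent direct evaluation of the patient-level weight formula."""
    n, D = X.shape
    out = np.zeros((n, D))
    for i in range(n):
        row_total = X[i].sum()
        for j in range(D):
            carriers = sum(X[k, j] for k in range(n))
            if X[i, j] and row_total and carriers:
                out[i, j] = (X[i, j] / row_total) * np.log(n / carriers)
    return out


def brute_force_cdfipf(dfipf_vals, assign, K):
    n, D = dfipf_vals.shape
    out = np.zeros((K, D))
    for j in range(D):
        with_d = len({assign[i] for i in range(n) if dfipf_vals[i, j] > 0})
        if with_d == 0:
            continue
        for c in range(K):
            members = [i for i in range(n) if assign[i] == c]
            if members:
                avg = np.mean([dfipf_vals[i, j] for i in members])
                out[c, j] = avg * np.log(K / with_d)
    return out


class TestDFIPF:
    def test_ubiquitous_disease_scores_zero(self):
        m = matrix_from(np.ones((5, 1), dtype=int))
        assert (dfipf(m).to_numpy() == 0).all()

    def test_hand_evaluated_case(self):
        # 4 patients; d0 only in p0 who has 2 diseases -> (1/2) ln 4
        X = np.array([[1, 1], [0, 1], [0, 1], [0, 1]])
        w = dfipf(matrix_from(X))
        assert np.isclose(w.iloc[0, 0], 0.5 * np.log(4))  # ~0.6931

    def test_patient_with_single_disease_present_once(self):
        X = np.zeros((6, 1), dtype=int)
        X[0, 0] = 1
        w = dfipf(matrix_from(X))
        assert np.isclose(w.iloc[0, 0], np.log(6))

    def test_empty_columns_are_excluded(self):
        X = np.array([[1, 0], [1, 0]])
        w = dfipf(matrix_from(X))
        assert list(w.columns) == ["d0"]

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(25):
            X = (rng.random((20, 10)) < 0.3).astype(int)
            X[X.sum(axis=1) == 0, 0] = 1  # every patient has >= 1 disease
            w = dfipf(matrix_from(X))
            brute = brute_force_dfipf(X.astype(float))
            kept = [j for j in range(10) if X[:, j].sum() > 0]
            assert np.abs(w.to_numpy() - brute[:, kept]).max() < 1e-12


class TestCDFIPF:
    def test_single_cluster_weights_all_zero(self):
        X = np.array([[1, 0], [0, 1]])
        w = dfipf(matrix_from(X))
        c = cdfipf(w, np.zeros(2, dtype=int), n_clusters=1)
        assert (c.weights.to_numpy() == 0).all()

    def test_condition_in_every_cluster_scores_zero(self):
        X = np.ones((4, 1), dtype=int)
        # ubiquitous disease: DF-IPF already 0, and ln(K/K) = 0 regardless
        X2 = np.array([[1, 1], [1, 0], [1, 1], [1, 0]])
        w = dfipf(matrix_from(X2))
        c = cdfipf(w, np.array([0, 0, 1, 1]), n_clusters=2)
        assert np.allclose(c.weights["d0"], 0.0)

    def test_hand_evaluated_two_cluster_case(self):
        # condition only in cluster 0 with mean DF-IPF 0.5 -> 0.5 ln 2 there
        dfipf_vals = pd.DataFrame(
            {"d0": [0.4, 0.6, 0.0, 0.0], "d1": [0.2, 0.2, 0.2, 0.2]},
            index=[f"p{i}" for i in range(4)],
        )
        c = cdfipf(dfipf_vals, np.array([0, 0, 1, 1]), n_clusters=2)
        assert np.isclose(c.weights.loc[0, "d0"], 0.5 * np.log(2))  # ~0.3466
        assert c.weights.loc[1, "d0"] == 0.0

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(25):
            X = (rng.random((20, 10)) < 0.3).astype(int)
            X[X.sum(axis=1) == 0, 0] = 1
            assign = rng.integers(0, 3, size=20)
            w = dfipf(matrix_from(X))
            got = cdfipf(w, assign, n_clusters=3)
            full = np.zeros((20, 10))
            kept = [j for j in range(10) if X[:, j].sum() > 0]
            full[:, kept] = w.to_numpy()
            brute = brute_force_cdfipf(full, assign, 3)
            kept2 = [j for j, c in enumerate(matrix_from(X).conditions) if c in got.weights.columns]
            assert np.abs(got.weights.to_numpy() - brute[:, kept2]).max() < 1e-12


class TestChi2OneVsAll:
    def test_observed_equals_expected_gives_zero_z(self):
        variable = np.tile([1, 0], 50)
        assignments = np.repeat([0, 1], 50)
        rep = chi2_one_vs_all(variable, assignments).table
        assert np.allclose(rep["z"], 0.0)
        assert (rep["symbol"] == "").all()

    def test_matches_independent_contingency_formula(self):
        # cluster of 100 with 30 cases vs rest of 900 with 90 cases
        variable = np.r_[np.ones(30), np.zeros(70), np.ones(90), np.zeros(810)]
        assignments = np.r_[np.zeros(100), np.ones(900)]
        rep = chi2_one_vs_all(variable, assignments).table.set_index("cluster")
        a, b, c, d = 30.0, 70.0, 90.0, 810.0
        n = a + b + c + d
        chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert np.isclose(rep.loc[0, "chi2"], chi2)
        assert np.isclose(rep.loc[0, "z"], np.sqrt(chi2))  # over-represented

    def test_symbol_thresholds_are_exact(self):
        assert z_symbol(50.0) == "++"
        assert z_symbol(49.999) == "+"
        assert z_symbol(10.0) == "+"
        assert z_symbol(9.999) == ""
        assert z_symbol(-9.999) == ""
        assert z_symbol(-10.0) == "-"
        assert z_symbol(-49.999) == "-"
        assert z_symbol(-50.0) == "--"

    def test_zero_margin_tables_flagged(self):
        variable = np.zeros(40)
        assignments = np.repeat([0, 1], 20)
        rep = chi2_one_vs_all(variable, assignments).table
        assert rep["degenerate"].all()
        assert np.allclose(rep["z"], 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.integers(1, 40), st.integers(1, 40), st.integers(1, 40), st.integers(1, 40)
    )
    def test_z_squared_equals_chi_square_statistic(self, a, b, c, d):
        variable = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        assignments = np.r_[np.zeros(a + b), np.ones(c + d)]
        rep = chi2_one_vs_all(variable, assignments).table
        expected = stats.chi2_contingency(
            np.array([[a, b], [c, d]]), correction=False
        )[0]
        assert np.allclose(rep["z"] ** 2, expected, atol=1e-9)


class TestTTestOneVsAll:
    def test_identical_distributions_give_near_zero_t(self, rng):
        x = rng.normal(size=200)
        rep = ttest_one_vs_all(x, np.tile([0, 1], 100))
        assert np.abs(rep["t"]).max() < 2.5  # no systematic shift

    def test_shift_grows_with_sample_size(self, rng):
        ts = []
        for n in (50, 200, 800):
            x = np.r_[rng.normal(size=n) + 1.0, rng.normal(size=n)]
            assign = np.r_[np.zeros(n), np.ones(n)]
            rep = ttest_one_vs_all(x, assign).set_index("cluster")
            ts.append(rep.loc[0, "t"])
        assert ts[0] > 0 and ts[0] < ts[1] < ts[2]

    def test_matches_textbook_welch_computation(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        rep = ttest_one_vs_all(np.r_[a, b], np.r_[np.zeros(5), np.ones(5)])
        va, vb = a.var(ddof=1) / 5, b.var(ddof=1) / 5
        t_manual = (a.mean() - b.mean()) / np.sqrt(va + vb)
        assert np.isclose(rep.set_index("cluster").loc[0, "t"], t_manual)

    def test_zero_variance_both_sides_flagged(self):
        x = np.ones(40)
        rep = ttest_one_vs_all(x, np.repeat([0, 1], 20))
        assert rep["degenerate"].all()


class TestObservedExpectedExclusivity:
    def test_uniform_prevalence_gives_unit_ratio(self):
        X = np.tile([1, 0], (30, 1))
        assign = np.repeat([0, 1, 2], 10)
        rep = observed_expected_exclusivity(matrix_from(X), assign)
        assert np.allclose(rep["observed_expected"], 1.0)

    def test_all_carriers_in_one_cluster(self):
        X = np.zeros((30, 1), dtype=int)
        X[:10, 0] = 1
        assign = np.repeat([0, 1, 2], 10)
        rep = observed_expected_exclusivity(matrix_from(X), assign).set_index("cluster")
        assert rep.loc[0, "exclusivity"] == 1.0
        assert rep.loc[1, "exclusivity"] == 0.0

    def test_counting_fixture_and_invariants(self, rng):
        X = (rng.random((60, 4)) < 0.4).astype(int)
        X[:, 0] = 1  # guarantee occupancy
        assign = rng.integers(0, 3, size=60)
        rep = observed_expected_exclusivity(matrix_from(X), assign)
        for cond, grp in rep.groupby("condition"):
            assert np.isclose(grp["exclusivity"].sum(), 1.0)
            # cluster-size-weighted O/E averages to 1
            sizes = np.array([np.sum(assign == c) for c in grp["cluster"]])
            weighted = (grp["observed_expected"] * sizes).sum() / sizes.sum()
            assert np.isclose(weighted, 1.0)


class TestSimilarities:
    def test_self_pair_similarity_is_one(self, rng):
        vecs = rng.normal(size=(4, 8))
        res = comorbidity_similarity(["a", "b", "c", "d"], vecs, [("a", "a")])
        assert np.isclose(res["median"], 1.0)

    def test_orthogonal_vectors_similarity_zero(self):
        vecs = np.eye(3)
        res = comorbidity_similarity(["a", "b", "c"], vecs, [("a", "b")], n_random_couples=0)
        assert np.isclose(res["median"], 0.0)

    def test_missing_tokens_are_skipped(self, rng):
        vecs = rng.normal(size=(2, 4))
        res = comorbidity_similarity(["a", "b"], vecs, [("a", "zzz"), ("a", "b")])
        assert len(res["pairs"]) == 1

    def test_crossgender_identity_and_negation(self):
        prof = pd.DataFrame([[0.1, 0.5, 0.2, 0.9, 0.3]], columns=list("abcde"))
        f = CDFIPFMatrix(weights=prof)
        m_same = CDFIPFMatrix(weights=prof.copy())
        m_neg = CDFIPFMatrix(weights=-prof)
        assert np.isclose(crossgender_similarity(f, m_same).iloc[0, 0], 1.0)
        assert np.isclose(crossgender_similarity(f, m_neg).iloc[0, 0], -1.0)

    def test_crossgender_matches_manual_pearson(self):
        a = np.array([0.1, 0.4, 0.2, 0.8, 0.3])
        b = np.array([0.2, 0.1, 0.5, 0.6, 0.4])
        f = CDFIPFMatrix(weights=pd.DataFrame([a], columns=list("abcde")))
        m = CDFIPFMatrix(weights=pd.DataFrame([b], columns=list("abcde")))
        r = crossgender_similarity(f, m).iloc[0, 0]
        manual = ((a - a.mean()) * (b - b.mean())).sum() / (
            np.sqrt(((a - a.mean()) ** 2).sum()) * np.sqrt(((b - b.mean()) ** 2).sum())
        )
        assert np.isclose(r, manual)
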