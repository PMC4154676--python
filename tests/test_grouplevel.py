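"""Edge-wise GLM correctness against the normal-equations oracle and an
independent statsmodels GLM (Gaussian/IWLS) cross-check, plus F-test, VIF,
FDR and SPN machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rdiconn.grouplevel import (
    PhenotypeTable,
    build_design_matrix,
    build_spn,
    fdr_control,
    fit_edge_glm,
    ftest_rdi,
    pooled_rdi_model,
    vif_of_interest,
)


def make_pheno(n, rng, n_regions=5):
    frame = pd.DataFrame(
        {
            "subject": [f"s{i}" for i in range(n)],
            "group": np.repeat([0, 1], [n - n // 2, n // 2]),
            "age": rng.uniform(7, 35, n),
            "iq": rng.normal(110, 15, n),
            "gender": rng.integers(0, 2, n),
            "mean_fd": np.abs(rng.normal(0.07, 0.03, n)),
        }
    )
    drd = rng.normal(0, 0.01, (n, n_regions))
    return PhenotypeTable(frame, drd)


class TestFitEdgeGlm:
    def test_noiseless_group_effect_recovered_exactly(self, rng):
        pheno = make_pheno(30, rng)
        grp = pheno.frame["group"].to_numpy(float)
        z = (0.3 + 0.5 * grp)[:, None]
        res = fit_edge_glm(z, [(0, 1)], pheno, "STD")
        assert np.isclose(res.table["beta"].iloc[0], 0.5, atol=1e-10)
        assert res.table["rss"].iloc[0] < 1e-20
        assert res.table["degenerate"].iloc[0]
        assert res.table["p"].iloc[0] == 0.0

    @pytest.mark.parametrize("model", ["STD", "STD+RDI"])
    def test_coefficients_match_normal_equations_oracle(self, model, rng):
        pheno = make_pheno(40, rng)
        pairs = [(0, 1), (2, 3), (1, 4)]
        z = rng.normal(size=(40, 3))
        res = fit_edge_glm(z, pairs, pheno, model)
        for e, pair in enumerate(pairs):
            X, _ = build_design_matrix(pheno, model, pair)
            beta = np.linalg.solve(X.T @ X, X.T @ z[:, e])
            assert np.allclose(res.coefs[e], beta, atol=1e-8)

    @pytest.mark.parametrize("model", ["STD", "STD+RDI"])
    def test_matches_statsmodels_gaussian_glm(self, model, rng):
        """Independent cross-check: a Gaussian GLM fitted by IWLS must agree
        with the closed-form fit in coefficients, t and p."""
        import statsmodels.api as sm

        pheno = make_pheno(35, rng)
        z = rng.normal(size=(35, 1))
        pair = (1, 3)
        res = fit_edge_glm(z, [pair], pheno, model)
        X, labels = build_design_matrix(pheno, model, pair)
        glm = sm.GLM(z[:, 0], X, family=sm.families.Gaussian()).fit()
        assert np.allclose(res.coefs[0], glm.params, atol=1e-8)
        j = labels.index("grp")
        assert np.isclose(res.table["t"].iloc[0], glm.tvalues[j], atol=1e-6)
        # statsmodels GLM uses the normal approx for p; recompute from t
        p_t = 2 * stats.t.sf(abs(glm.tvalues[j]), res.table["dof"].iloc[0])
        assert np.isclose(res.table["p"].iloc[0], p_t, atol=1e-10)

    def test_interaction_recovery_simulation(self):
        """Planted RDI interaction beta = 0.4 recovered without bias."""
        rng = np.random.default_rng(7)
        n, reps = 200, 100
        est = []
        for _ in range(reps):
            pheno = make_pheno(n, rng)
            da = pheno.delta_rd[:, 0]
            db = pheno.delta_rd[:, 1]
            z = (0.4 * da * db + rng.normal(0, 0.2, n))[:, None]
            res = fit_edge_glm(z, [(0, 1)], pheno, "STD+RDI")
            jj = res.columns.index("drd_ab")
            est.append(res.coefs[0, jj])
        assert abs(np.mean(est) - 0.4) < 0.05 * 0.4 + 3 * np.std(est) / np.sqrt(reps)

    def test_rank_deficient_design_names_columns(self, rng):
        pheno = make_pheno(20, rng)
        pheno.frame["iq"] = pheno.frame["age"] * 2.0
        z = rng.normal(size=(20, 1))
        with pytest.raises(ValueError, match="iq"):
            fit_edge_glm(z, [(0, 1)], pheno, "STD")

    def test_more_params_than_subjects_rejected(self, rng):
        pheno = make_pheno(6, rng)
        with pytest.raises(ValueError, match="subjects"):
            fit_edge_glm(rng.normal(size=(6, 1)), [(0, 1)], pheno, "STD")

    def test_null_type_one_error_calibrated(self):
        """Per-edge group t-test rejects ~5% at alpha = 0.05 under the null."""
        rng = np.random.default_rng(42)
        n, n_edges = 60, 1000
        pheno = make_pheno(n, rng)
        z = rng.normal(size=(n, n_edges))
        res = fit_edge_glm(z, [(0, 1)] * n_edges, pheno, "STD")
        rate = (res.table["p"] < 0.05).mean()
        assert 0.03 < rate < 0.07


class TestFtest:
    def test_null_f_pvalues_uniform(self):
        rng = np.random.default_rng(1)
        n, n_edges = 80, 400
        pheno = make_pheno(n, rng)
        z = rng.normal(size=(n, n_edges))
        pairs = [tuple(rng.choice(5, 2, replace=False)) for _ in range(n_edges)]
        out = ftest_rdi(z, pairs, pheno)
        ks = stats.kstest(out["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_power_against_planted_interaction(self):
        rng = np.random.default_rng(2)
        n, reps = 200, 60
        rejections = 0
        for _ in range(reps):
            pheno = make_pheno(n, rng)
            da, db = pheno.delta_rd[:, 0], pheno.delta_rd[:, 1]
            da = da / da.std() * 1.0
            db = db / db.std() * 1.0
            z = (0.4 * da * db + rng.normal(0, 0.2, n))[:, None]
            pheno.delta_rd[:, 0] = da
            pheno.delta_rd[:, 1] = db
            out = ftest_rdi(z, [(0, 1)], pheno)
            rejections += out["p"].iloc[0] < 0.05
        assert rejections / reps > 0.8

    def test_exact_interpolation_flagged(self, rng):
        pheno = make_pheno(8, rng)
        z = rng.normal(size=(8, 1))    # 8 params, 8 rows: exact interpolation
        out = ftest_rdi(z, [(0, 1)], pheno)
        assert out["degenerate"].iloc[0]
        assert out["p"].iloc[0] == 0.0


class TestPooledModel:
    def test_row_count(self, rng):
        pheno = make_pheno(3, rng)
        z = rng.normal(size=(3, 2))
        out = pooled_rdi_model(z, [(0, 1), (2, 3)], pheno)
        assert out["n_rows"] == 6

    def test_recovers_common_interaction(self):
        rng = np.random.default_rng(3)
        n, n_edges = 100, 12
        pheno = make_pheno(n, rng, n_regions=8)
        pairs = [(a, b) for a in range(4) for b in range(4, 7)]
        beta_int = 50.0     # large slope: dRD products are tiny (~1e-4)
        z = np.empty((n, n_edges))
        for e, (a, b) in enumerate(pairs):
            z[:, e] = beta_int * pheno.delta_rd[:, a] * pheno.delta_rd[:, b] \
                + rng.normal(0, 0.1, n)
        out = pooled_rdi_model(z, pairs, pheno)
        se = out["result"].bse[out["columns"].index("drd_ab")]
        assert abs(out["beta_interaction"] - beta_int) < 2 * se
        assert out["surface_z"].shape == (21, 21)

    def test_row_cap_guard(self, rng):
        pheno = make_pheno(10, rng)
        z = rng.normal(size=(10, 5))
        with pytest.raises(MemoryError, match="subsample"):
            pooled_rdi_model(z, [(0, 1)] * 5, pheno, row_cap=10)


class TestVif:
    def test_orthogonal_grouping_gives_unit_vif(self):
        X = np.column_stack([np.ones(8),
                             [1, -1] * 4,
                             [1, 1, -1, -1] * 2])
        assert np.isclose(vif_of_interest(X, 1), 1.0, atol=1e-12)

    def test_constructed_r2_gives_vif_four(self, rng):
        n = 4000
        w = rng.normal(size=n)
        e = rng.normal(size=n)
        # y = w + e/sqrt(3): R^2 of y on w is 0.75 exactly in expectation
        y = w + e * np.sqrt(1 / 3)
        X = np.column_stack([np.ones(n), y, w])
        assert abs(vif_of_interest(X, 1) - 4.0) < 0.3

    def test_duplicate_of_grouping_is_infinite(self):
        g = np.array([0, 1, 0, 1, 1, 0], float)
        X = np.column_stack([np.ones(6), g, g.copy()])
        with pytest.warns(UserWarning, match="collinearity"):
            assert np.isinf(vif_of_interest(X, 1))


class TestFdrAndSpn:
    def test_all_small_p_all_significant(self):
        q, mask = fdr_control(np.full(100, 0.001), 0.05)
        assert mask.all()
        assert np.allclose(q, 0.001)

    def test_single_p_is_its_own_q(self):
        q, mask = fdr_control(np.array([0.04]), 0.05)
        assert np.isclose(q[0], 0.04)
        assert mask[0]

    def test_uniform_null_rarely_significant(self):
        rng = np.random.default_rng(9)
        hits = []
        for _ in range(200):
            p = rng.uniform(size=3828)
            _, mask = fdr_control(p, 0.05)
            hits.append(mask.sum())
        assert np.quantile(hits, 0.95) <= 2

    def test_empty_p_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fdr_control(np.array([]))

    def test_spn_thresholding(self, rng):
        table = pd.DataFrame(
            {
                "region_a": np.arange(20),
                "region_b": np.arange(20) + 1,
                "t": rng.normal(size=20),
                "p": np.concatenate([np.full(10, 1e-8), np.full(10, 0.9)]),
            }
        )
        spn_all = build_spn(table, rule="p", alpha=1.0)
        assert spn_all.n_significant == 20
        spn_none = build_spn(table.assign(p=1.0), rule="p", alpha=0.01)
        assert spn_none.n_significant == 0
        spn_q = build_spn(table, rule="q", alpha=0.05)
        assert spn_q.n_significant == 10
        assert set(spn_q.edges["sign"]) <= {-1.0, 1.0}

    def test_spn_exports(self, tmp_path, rng):
        table = pd.DataFrame(
            {"region_a": [1, 2], "region_b": [3, 4],
             "t": [2.5, -3.0], "p": [0.001, 0.002]})
        spn = build_spn(table, rule="p", alpha=0.01)
        spn.to_tsv(tmp_path / "spn.tsv")
        spn.to_graphml(tmp_path / "spn.graphml")
        assert (tmp_path / "spn.tsv").exists()
        back = pd.read_csv(tmp_path / "spn.tsv", sep="\t")
        assert len(back) == 2


class TestPhenotypeValidation:
    def test_missing_covariates_rejected(self, rng):
        pheno = make_pheno(10, rng)
        frame = pheno.frame.copy()
        frame.loc[0, "age"] = np.nan
        with pytest.raises(ValueError, match="missing values"):
            PhenotypeTable(frame, pheno.delta_rd)

    def test_single_group_rejected(self, rng):
        pheno = make_pheno(10, rng)
        frame = pheno.frame.copy()
        frame["group"] = 0
        with pytest.raises(ValueError, match="2 levels"):
            PhenotypeTable(frame, pheno.delta_rd)
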