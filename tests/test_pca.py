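import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import transcompr as tc
from transcompr.pca import ProjectionError, retained_components
from transcompr.preprocess import ModelError

from conftest import make_metadata, make_study


def _zscored_study(rng, n_genes=60, n_samples=10, **meta):
    study = make_study(rng.normal(size=(n_genes, n_samples)), **meta)
    return tc.zscore_genes(study)


class TestRetentionRule:
    def test_cumulative_rule_binds(self):
        assert retained_components([0.50, 0.30, 0.15, 0.04, 0.01]) == 3

    def test_individual_rule_binds(self):
        assert retained_components([0.96, 0.02, 0.02]) == 1

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=30)
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_naive_recomputation(self, raw):
        fr = np.sort(np.asarray(raw))[::-1]
        fr = fr / fr.sum()
        k_cum = next(i + 1 for i in range(len(fr)) if fr[: i + 1].sum() >= 0.95 - 1e-12)
        k_each = int(np.sum(fr >= 0.01 - 1e-12))
        assert retained_components(fr) == min(k_cum, k_each)


class TestFitPCA:
    def test_model_invariants(self, rng):
        model = tc.fit_pca(_zscored_study(rng))
        k = model.n_components
        gram = model.loadings.T @ model.loadings
        assert np.allclose(gram, np.eye(k), atol=1e-8)
        assert np.all(np.diff(model.full_fractions) <= 1e-12)
        assert model.full_fractions.sum() == pytest.approx(1.0, abs=1e-9)
        assert retained_components(model.full_fractions) == k

    def test_reconstruction_error_equals_discarded_variance(self, rng):
        study = _zscored_study(rng, n_genes=40, n_samples=12)
        model = tc.fit_pca(study, var_cum=0.8, var_each=0.0)
        A = study.values.to_numpy().T
        recon = model.sample_scores.to_numpy() @ model.loadings.T
        rel_sq_err = np.sum((A - recon) ** 2) / np.sum(A**2)
        assert rel_sq_err == pytest.approx(
            1.0 - model.explained_fraction.sum(), abs=1e-6
        )

    def test_sign_convention_and_determinism(self, rng):
        study = _zscored_study(rng)
        m1 = tc.fit_pca(study)
        m2 = tc.fit_pca(study)
        assert np.array_equal(m1.loadings, m2.loadings)
        for j in range(m1.n_components):
            col = m1.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0


class TestProjection:
    def test_self_projection_identity(self, rng):
        for _ in range(3):
            study = _zscored_study(rng, n_genes=50, n_samples=8)
            model = tc.fit_pca(study)
            proj = tc.project(model, study, tc.HomologMap.identity(study.gene_ids))
            assert np.max(np.abs(proj.scores.to_numpy() - model.sample_scores.to_numpy())) < 1e-8

    def test_scores_match_triple_loop_product(self, rng):
        human = _zscored_study(rng, n_genes=200, n_samples=10)
        model = tc.fit_pca(human)
        mouse_vals = rng.normal(size=(200, 12))
        mouse = make_study(
            pd.DataFrame(mouse_vals, index=[f"m{g}" for g in human.gene_ids]),
            species="mouse",
            labels=["WT"] * 6 + ["HO"] * 6,
        )
        hmap = tc.HomologMap.from_pairs(human.gene_ids, mouse.gene_ids)
        proj = tc.project(model, mouse, hmap)
        for s in range(12):
            for j in range(model.n_components):
                expected = 0.0
                for g in range(200):
                    expected += mouse_vals[g, s] * model.loadings[g, j]
                assert proj.scores.iloc[s, j] == pytest.approx(expected, abs=1e-10)

    def test_projected_variance_sums_to_one_and_sample_order_invariant(self, rng):
        human = _zscored_study(rng, n_genes=80, n_samples=9)
        model = tc.fit_pca(human)
        vals = rng.normal(size=(80, 10))
        ids = [f"m{g}" for g in human.gene_ids]
        hmap = tc.HomologMap.from_pairs(human.gene_ids, ids)
        mouse = make_study(
            pd.DataFrame(vals, index=ids), species="mouse", labels=["WT"] * 10
        )
        perm = rng.permutation(10)
        mouse_perm = make_study(
            pd.DataFrame(vals[:, perm], index=ids), species="mouse", labels=["WT"] * 10
        )
        p1 = tc.project(model, mouse, hmap)
        p2 = tc.project(model, mouse_perm, hmap)
        assert p1.projected_variance_fraction.sum() == pytest.approx(1.0)
        assert np.allclose(
            p1.projected_variance_fraction, p2.projected_variance_fraction
        )

    def test_single_loading_profile_concentrates_mass(self, rng):
        human = _zscored_study(rng, n_genes=50, n_samples=8)
        model = tc.fit_pca(human)
        profile = model.loadings[:, 1]
        mouse = make_study(
            pd.DataFrame(
                np.tile(profile, (4, 1)).T, index=human.gene_ids.tolist()
            ),
            species="mouse",
            labels=["WT"] * 4,
        )
        proj = tc.project(model, mouse, tc.HomologMap.identity(human.gene_ids))
        assert proj.projected_variance_fraction.iloc[1] == pytest.approx(1.0, abs=1e-10)

    def test_missing_partner_listed(self, rng):
        human = _zscored_study(rng, n_genes=20, n_samples=8)
        model = tc.fit_pca(human)
        mouse = make_study(
            pd.DataFrame(rng.normal(size=(10, 4)), index=[f"m{i}" for i in range(10)]),
            species="mouse",
            labels=["WT"] * 4,
        )
        hmap = tc.HomologMap.from_pairs(human.gene_ids, [f"m{i}" for i in range(20)])
        with pytest.raises(ProjectionError, match="lack a mouse partner"):
            tc.project(model, mouse, hmap)


class TestPhenotypeRegression:
    @staticmethod
    def _model_with_scores(scores: pd.DataFrame) -> tc.PCAModel:
        g = 5
        return tc.PCAModel(
            gene_order=pd.Index([f"g{i}" for i in range(g)]),
            loadings=np.eye(g)[:, : scores.shape[1]],
            explained_fraction=np.ones(scores.shape[1]) / scores.shape[1],
            full_fractions=np.ones(scores.shape[1]) / scores.shape[1],
            sample_scores=scores,
        )

    def test_planted_age_component(self, rng):
        n = 24
        age = rng.integers(60, 90, n).astype(float)
        meta = make_metadata(
            [f"s{i}" for i in range(n)],
            age=age,
            sex=rng.choice(["M", "F"], n),
            labels=rng.choice(["control", "AD"], n),
        )
        scores = pd.DataFrame({"PC1": age}, index=meta.index)
        res = tc.phenotype_regression(self._model_with_scores(scores), meta)
        assert res.loc["PC1", "p_age"] < 1e-10
        assert res.loc["PC1", "p_disease"] > 0.5

    def test_tvalues_match_normal_equations_oracle(self, rng):
        n = 8
        age = np.array([61.0, 72, 65, 80, 70, 68, 77, 63])
        sex = ["M", "F", "M", "F", "M", "F", "M", "F"]
        labels = ["control"] * 4 + ["AD"] * 4
        meta = make_metadata(
            [f"s{i}" for i in range(n)], age=age, sex=sex, labels=labels
        )
        y = rng.normal(size=n)
        scores = pd.DataFrame({"PC1": y}, index=meta.index)
        res = tc.phenotype_regression(self._model_with_scores(scores), meta)

        X = np.column_stack(
            [
                np.ones(n),
                age,
                [1.0 if s == "M" else 0.0 for s in sex],
                [0.0] * 4 + [1.0] * 4,
            ]
        )
        beta = np.linalg.inv(X.T @ X) @ X.T @ y
        resid = y - X @ beta
        sigma2 = resid @ resid / (n - 4)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        t = beta / se
        assert res.loc["PC1", "t_age"] == pytest.approx(t[1], abs=1e-10)
        assert res.loc["PC1", "t_sex"] == pytest.approx(t[2], abs=1e-10)
        assert res.loc["PC1", "t_disease"] == pytest.approx(t[3], abs=1e-10)

    def test_consistent_sample_permutation_invariance(self, rng):
        n = 16
        meta = make_metadata(
            [f"s{i}" for i in range(n)],
            age=rng.integers(60, 90, n).astype(float),
            sex=rng.choice(["M", "F"], n),
            labels=rng.choice(["control", "AD"], n),
        )
        scores = pd.DataFrame(rng.normal(size=(n, 2)), index=meta.index, columns=["PC1", "PC2"])
        perm = rng.permutation(n)
        res1 = tc.phenotype_regression(self._model_with_scores(scores), meta)
        res2 = tc.phenotype_regression(
            self._model_with_scores(scores.iloc[perm]), meta.iloc[perm]
        )
        pd.testing.assert_frame_equal(res1, res2, check_exact=False, atol=1e-10)

    def test_categorical_disease_uses_omnibus_p(self, rng):
        n = 24
        meta = make_metadata(
            [f"s{i}" for i in range(n)],
            age=rng.integers(60, 90, n).astype(float),
            sex=rng.choice(["M", "F"], n),
            labels=list(np.tile(["control", "incipient", "moderate", "severe"], n // 4)),
        )
        scores = pd.DataFrame({"PC1": rng.normal(size=n)}, index=meta.index)
        res = tc.phenotype_regression(self._model_with_scores(scores), meta)
        assert np.isnan(res.loc["PC1", "t_disease"])
        assert 0 < res.loc["PC1", "p_disease"] <= 1

    def test_rank_deficient_design_is_error(self, rng):
        n = 12
        sex = ["M", "F"] * 6
        labels = ["AD" if s == "M" else "control" for s in sex]
        meta = make_metadata(
            [f"s{i}" for i in range(n)],
            age=rng.integers(60, 90, n).astype(float),
            sex=sex,
            labels=labels,
        )
        scores = pd.DataFrame({"PC1": rng.normal(size=n)}, index=meta.index)
        with pytest.raises(ModelError, match="rank"):
            tc.phenotype_regression(self._model_with_scores(scores), meta)
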