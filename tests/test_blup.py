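"""Mixed-model machinery: design construction, Henderson equations vs a
direct GLS/BLUP oracle, EM-REML properties, corrected phenotypes."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from crossblup.blup import (
    GBLUP,
    SireModel,
    VarianceComponents,
    build_design,
    reml_estimate,
    reml_loglik,
    solve_mme,
)
from crossblup.grm import GRMatrix


def _phenotypes(n, rng, n_batches=2, n_dams=4, ids=None):
    return pd.DataFrame(
        {
            "animal_id": ids if ids is not None else [f"a{i}" for i in range(n)],
            "trait": "T",
            "value": rng.normal(size=n),
            "batch": rng.choice([f"b{k}" for k in range(n_batches)], n),
            "pen": "p1",
            "sex": rng.choice(["M", "F"], n),
            "age": 7,
            "dam_id": rng.choice([f"d{k}" for k in range(n_dams)], n),
        }
    )


def _random_psd_grm(n_total, rng, rank=None):
    ids = [f"a{i}" for i in range(n_total)]
    w = rng.normal(size=(n_total, rank or max(4, n_total // 2)))
    G = w @ w.T / w.shape[1] + 0.05 * np.eye(n_total)
    return GRMatrix(G, ids, "single")


class TestBuildDesign:
    def test_single_combination_gives_intercept_column(self):
        rng = np.random.default_rng(0)
        ph = _phenotypes(6, rng, n_batches=1)
        ph["sex"] = "M"
        d = build_design(ph, grm_ids=ph["animal_id"].tolist(), model="animal")
        assert d.X.shape[1] == 1
        assert np.all(d.X == 1.0)

    def test_crossed_factors_give_product_levels(self):
        ph = pd.DataFrame(
            {
                "animal_id": list("abcd"),
                "value": [1.0, 2.0, 3.0, 4.0],
                "batch": ["b1", "b1", "b2", "b2"],
                "pen": "p1",
                "sex": ["M", "F", "M", "F"],
                "age": 7,
                "dam_id": "d1",
            }
        )
        d = build_design(ph, grm_ids=list("abcd"), model="animal")
        assert d.X.shape[1] == 4  # 2 batches x 2 sexes fully crossed

    def test_single_offspring_dam_still_gets_level(self):
        rng = np.random.default_rng(1)
        ph = _phenotypes(5, rng, n_dams=5)
        ph["dam_id"] = [f"d{i}" for i in range(5)]
        d = build_design(ph, grm_ids=ph["animal_id"].tolist(), model="animal")
        assert len(d.dam_levels) == 5

    def test_record_missing_from_grm_raises(self):
        rng = np.random.default_rng(2)
        ph = _phenotypes(4, rng)
        with pytest.raises(ValueError, match="missing from the GRM"):
            build_design(ph, grm_ids=["a0", "a1"], model="animal")


class TestSolveMME:
    def test_matches_gls_blup_oracle_with_candidates(self):
        """Henderson solutions equal direct GLS fixed effects and
        sigma2_a G Z' V^-1 (y - X b) BLUP, including unphenotyped
        candidates, on a 150-record fixture."""
        rng = np.random.default_rng(5)
        n, extra = 150, 12
        grm = _random_psd_grm(n + extra, rng)
        ph = _phenotypes(n, rng, n_batches=3, n_dams=10)
        d = build_design(ph, grm_ids=grm.ids, model="animal")
        vc = VarianceComponents(sigma2_a=0.4, sigma2_m=0.1, sigma2_e=0.6)
        sol = solve_mme(d, grm, vc, epsilon=0.0)

        X = d.X
        Z = np.zeros((n, n + extra))
        Z[np.arange(n), d.animal_index] = 1.0
        L = np.zeros((n, len(d.dam_levels)))
        L[np.arange(n), d.dam_index] = 1.0
        y = d.y
        V = 0.4 * Z @ grm.values @ Z.T + 0.1 * L @ L.T + 0.6 * np.eye(n)
        Vi = np.linalg.inv(V)
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        a_hat = 0.4 * grm.values @ Z.T @ Vi @ (y - X @ b)
        m_hat = 0.1 * L.T @ Vi @ (y - X @ b)
        assert np.abs(sol.fixed.to_numpy() - b).max() < 1e-8
        assert np.abs(sol.gebv.to_numpy() - a_hat).max() < 1e-8
        assert np.abs(sol.maternal.to_numpy() - m_hat).max() < 1e-8

    def test_candidate_gebv_equals_projection_of_reference_gebv(self):
        """Joint-solve GEBV of unphenotyped candidates equal the genomic
        projection G_cand,ref (G_ref,ref)^-1 a_ref of the reference GEBV."""
        rng = np.random.default_rng(6)
        n, extra = 60, 6
        grm = _random_psd_grm(n + extra, rng, rank=n + extra)
        ph = _phenotypes(n, rng)
        d = build_design(ph, grm_ids=grm.ids, model="animal")
        vc = VarianceComponents(sigma2_a=0.5, sigma2_m=0.05, sigma2_e=0.5)
        sol = solve_mme(d, grm, vc, epsilon=0.0)
        ref_ids = ph["animal_id"].tolist()
        cand_ids = [i for i in grm.ids if i not in set(ref_ids)]
        g_rr = grm.submatrix(ref_ids)
        idx_c = grm.index_of(cand_ids)
        idx_r = grm.index_of(ref_ids)
        g_cr = grm.values[np.ix_(idx_c, idx_r)]
        projected = g_cr @ np.linalg.solve(g_rr, sol.gebv.loc[ref_ids].to_numpy())
        assert np.abs(sol.gebv.loc[cand_ids].to_numpy() - projected).max() < 1e-8

    def test_identity_grm_equals_ridge_regression(self):
        """With G = I and no maternal term, GEBV are ridge coefficients with
        penalty sigma2_e / sigma2_a (5-record closed form)."""
        rng = np.random.default_rng(7)
        n = 5
        ids = [f"a{i}" for i in range(n)]
        ph = _phenotypes(n, rng, n_batches=1, n_dams=1)
        ph["sex"] = "M"
        grm = GRMatrix(np.eye(n), ids, "single")
        vc = VarianceComponents(sigma2_a=0.3, sigma2_m=0.0, sigma2_e=0.7)
        d = build_design(ph, grm_ids=ids, model="animal")
        sol = solve_mme(d, grm, vc, epsilon=0.0)
        lam = 0.7 / 0.3
        X = np.ones((n, 1))
        Z = np.eye(n)
        # direct inverse of the 2x2-block mixed-model equations
        C = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + lam * np.eye(n)]])
        s = np.linalg.solve(C, np.concatenate([X.T @ d.y, d.y]))
        assert np.abs(sol.gebv.to_numpy() - s[1:]).max() < 1e-10

    def test_vanishing_additive_variance_shrinks_gebv_to_zero(self):
        rng = np.random.default_rng(8)
        grm = _random_psd_grm(20, rng)
        ph = _phenotypes(20, rng, ids=grm.ids)
        d = build_design(ph, grm_ids=grm.ids, model="animal")
        vc = VarianceComponents(sigma2_a=1e-10, sigma2_m=0.1, sigma2_e=1.0)
        sol = solve_mme(d, grm, vc, epsilon=0.0)
        assert np.abs(sol.gebv.to_numpy()).max() < 1e-6

    def test_gebv_invariant_to_batch_level_shift(self):
        rng = np.random.default_rng(9)
        grm = _random_psd_grm(40, rng)
        ph = _phenotypes(40, rng, ids=grm.ids, n_batches=2)
        d1 = build_design(ph, grm_ids=grm.ids, model="animal")
        shifted = ph.copy()
        shifted.loc[shifted["batch"] == "b0", "value"] += 5.0
        d2 = build_design(shifted, grm_ids=grm.ids, model="animal")
        vc = VarianceComponents(sigma2_a=0.4, sigma2_m=0.1, sigma2_e=0.6)
        s1 = solve_mme(d1, grm, vc)
        s2 = solve_mme(d2, grm, vc)
        assert np.allclose(s1.gebv.to_numpy(), s2.gebv.to_numpy(), atol=1e-8)


def _simulated_records(rng, n=120, n_dams=20, sigma_a=0.4, sigma_m=0.1, sigma_e=0.5):
    grm = _random_psd_grm(n, rng, rank=n)
    chol = np.linalg.cholesky(grm.values + 1e-10 * np.eye(n))
    a = chol @ rng.normal(size=n) * np.sqrt(sigma_a)
    dam_idx = rng.integers(n_dams, size=n)
    m = rng.normal(size=n_dams) * np.sqrt(sigma_m)
    y = 1.0 + a + m[dam_idx] + rng.normal(size=n) * np.sqrt(sigma_e)
    ph = pd.DataFrame(
        {
            "animal_id": grm.ids,
            "value": y,
            "batch": "b1", "pen": "p1", "sex": "M", "age": 7,
            "dam_id": [f"d{k}" for k in dam_idx],
        }
    )
    return ph, grm


class TestREML:
    def test_likelihood_monotone_nondecreasing(self):
        rng = np.random.default_rng(10)
        ph, grm = _simulated_records(rng)
        d = build_design(ph, grm_ids=grm.ids, model="animal")
        vc = reml_estimate(d, grm, max_iter=60, tol=0.0)
        trace = np.array(vc.loglik_trace)
        assert len(trace) >= 50
        assert np.all(np.diff(trace) > -1e-8)

    def test_em_fixed_point_matches_direct_likelihood_maximum(self):
        """Independent oracle: Nelder-Mead maximisation of the restricted
        likelihood reaches the same components as EM."""
        rng = np.random.default_rng(11)
        ph, grm = _simulated_records(rng, n=100)
        d = build_design(ph, grm_ids=grm.ids, model="animal")
        em = reml_estimate(d, grm, max_iter=2000, tol=1e-10)

        def nll(logs):
            c = VarianceComponents(
                sigma2_a=np.exp(logs[0]), sigma2_m=np.exp(logs[1]), sigma2_e=np.exp(logs[2])
            )
            return -reml_loglik(d, grm, c)

        opt = minimize(
            nll, np.log([0.3, 0.1, 0.5]), method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 3000},
        )
        # the optimiser can be at most marginally better than the EM iterate
        assert -opt.fun >= em.loglik - 1e-6
        assert em.loglik == pytest.approx(-opt.fun, abs=0.01)
        assert em.sigma2_a == pytest.approx(np.exp(opt.x[0]), abs=0.03)
        assert em.sigma2_e == pytest.approx(np.exp(opt.x[2]), abs=0.03)

    def test_zero_maternal_variance_estimated_at_boundary(self):
        rng = np.random.default_rng(12)
        ph, grm = _simulated_records(rng, n=150, sigma_m=0.0)
        d = build_design(ph, grm_ids=grm.ids, model="animal")
        vc = reml_estimate(d, grm, max_iter=800, tol=1e-9)
        assert vc.sigma2_m < 0.03

    def test_nonconvergence_warns_and_flags(self):
        rng = np.random.default_rng(13)
        ph, grm = _simulated_records(rng, n=60)
        d = build_design(ph, grm_ids=grm.ids, model="animal")
        with pytest.warns(UserWarning, match="did not converge"):
            vc = reml_estimate(d, grm, max_iter=3, tol=1e-12)
        assert not vc.converged


class TestCorrectedPhenotypes:
    def _cb_records(self, rng, n=100, n_sires=8, n_dams=25):
        sires = [f"S{i}" for i in range(n_sires)]
        s_idx = rng.integers(n_sires, size=n)
        d_idx = rng.integers(n_dams, size=n)
        s_eff = rng.normal(size=n_sires) * 0.4
        ph = pd.DataFrame(
            {
                "animal_id": [f"x{i}" for i in range(n)],
                "trait": "T",
                "value": s_eff[s_idx] + rng.normal(size=n),
                "batch": rng.choice(["b1", "b2"], n),
                "pen": "p1",
                "sex": rng.choice(["M", "F"], n),
                "age": 7,
                "dam_id": [f"d{k}" for k in d_idx],
                "genetic_group": "CB",
            }
        )
        ped = pd.DataFrame(
            {
                "animal_id": ph["animal_id"],
                "sire_id": [sires[k] for k in s_idx],
                "dam_id": ph["dam_id"],
                "genetic_group": "CB",
            }
        )
        return ph, ped

    def test_batch_shift_absorbed(self):
        rng = np.random.default_rng(14)
        ph, ped = self._cb_records(rng)
        res1 = SireModel(ph, ped).fit(
            components=VarianceComponents(sigma2_s=0.2, sigma2_m=0.05, sigma2_e=1.0)
        )
        shifted = ph.copy()
        shifted.loc[shifted["batch"] == "b1", "value"] += 7.0
        res2 = SireModel(shifted, ped).fit(
            components=VarianceComponents(sigma2_s=0.2, sigma2_m=0.05, sigma2_e=1.0)
        )
        yc1 = res1.corrected_phenotypes()["y_corrected"].to_numpy()
        yc2 = res2.corrected_phenotypes()["y_corrected"].to_numpy()
        assert np.allclose(yc1, yc2, atol=1e-8)

    def test_sire_means_track_sire_solutions(self):
        """Within-sire averages of corrected phenotypes correlate strongly
        with the estimated (shrunken) sire effects."""
        rng = np.random.default_rng(15)
        ph, ped = self._cb_records(rng, n=400, n_sires=10)
        res = SireModel(ph, ped).fit(
            components=VarianceComponents(sigma2_s=0.15, sigma2_m=0.05, sigma2_e=1.0)
        )
        yc = res.corrected_phenotypes()
        means = yc.groupby("sire_id")["y_corrected"].mean()
        shat = res.solution.sire.loc[means.index]
        assert np.corrcoef(means, shat)[0, 1] > 0.97

    def test_gblup_summary_mentions_components(self):
        rng = np.random.default_rng(16)
        ph, grm = _simulated_records(rng, n=50)
        ph["trait"] = "T"
        res = GBLUP(ph, grm).fit(
            components=VarianceComponents(sigma2_a=0.4, sigma2_m=0.1, sigma2_e=0.6)
        )
        text = res.summary()
        assert "sigma2_a" in text and "h2" in text
        assert res.gebv.index.tolist() == grm.ids
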