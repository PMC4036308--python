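import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lactpath.lmm import (
    TraitParams,
    bull_weight,
    cow_weight,
    effect_correlations,
    fit_null_model,
    genomic_control_lambda,
    record_weights,
    snp_association,
    standardise_records,
)
from lactpath.pipeline import gwas_inputs, run_gwas
from lactpath.relatedness import build_a_matrix
from lactpath.reml import REMLError, SpectralREML
from lactpath.simulate import SimulationConfig, simulate_dataset

from .conftest import as_dataset
from .oracles import direct_reml, ols_t_stats, random_pedigree


class TestStandardisation:
    def test_closed_form(self):
        got = standardise_records([1.0, 2.0, 3.0], ["a"] * 3)
        assert np.allclose(got, [-1.0, 0.0, 1.0])

    def test_breeds_are_independent(self, rng):
        vals = rng.normal(5, 3, 40)
        breeds = np.repeat(["x", "y"], 20)
        got = standardise_records(vals, breeds)
        for b in ("x", "y"):
            assert got[breeds == b].mean() == pytest.approx(0, abs=1e-12)
            assert got[breeds == b].std(ddof=1) == pytest.approx(1)

    def test_idempotent(self, rng):
        vals = standardise_records(rng.normal(size=30), ["a"] * 30)
        again = standardise_records(vals, ["a"] * 30)
        assert np.allclose(vals, again)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            standardise_records([1.0, 1.0, 1.0], ["a"] * 3)

    def test_singleton_breed_errors(self):
        with pytest.raises(ValueError, match=">= 2"):
            standardise_records([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestWeights:
    def test_bull_weight_examples(self):
        assert bull_weight(0.33, 100) == pytest.approx(0.6463, abs=1e-4)
        assert bull_weight(0.5, 1) == pytest.approx(0.5 / 4.5)
        assert bull_weight(0.33, 1e9) == pytest.approx(0.67, abs=1e-6)

    def test_cow_weight_examples(self):
        assert cow_weight(0.33, 0.56, 1) == pytest.approx(0.67)
        assert cow_weight(0.33, 0.56, 3) == pytest.approx(0.67 / (1 + 0.56 * 2 / 3))
        assert cow_weight(0.33, 0.56, 1e9) == pytest.approx(0.67 / 1.56, abs=1e-6)

    @given(
        h2=st.floats(0.05, 0.95),
        r2=st.floats(0.0, 1.0),
        n=st.integers(1, 10_000),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounds_and_monotonicity(self, h2, r2, n):
        r2 = max(r2, h2)
        wb = bull_weight(h2, n)
        wc = cow_weight(h2, r2, n)
        assert 0 < wb <= 1 - h2
        assert 0 < wc <= 1 - h2
        assert bull_weight(h2, n + 1) > wb  # more daughters, more information
        if r2 > 0 and n > 1:
            assert cow_weight(h2, r2, n) < cow_weight(h2, r2, n - 1)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bull_weight(1.2, 10)
        with pytest.raises(ValueError):
            bull_weight(0.3, 0)
        with pytest.raises(ValueError):
            cow_weight(0.3, 0.56, 0)
        with pytest.raises(ValueError):
            cow_weight(0.3, 1.5, 2)

    def test_percentage_traits_can_skip_bull_weighting(self):
        import pandas as pd

        rec = pd.DataFrame(
            {"sex": ["bull", "cow"], "n": [50, 3]}
        )
        t = TraitParams("fat_pct", h2=0.5, r2=0.56, weight_bulls=False)
        w = record_weights(rec, t)
        assert w[0] == 1.0
        assert w[1] == pytest.approx(cow_weight(0.5, 0.56, 3))


class TestRemlEngine:
    def _simulate(self, rng, n=80, sg2=0.4, se2=0.6):
        ped = random_pedigree(10, n, seed=3)
        A = build_a_matrix(ped).values
        L = np.linalg.cholesky(A + 1e-9 * np.eye(n))
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [1.0, 0.5] + np.sqrt(sg2) * (L @ rng.normal(size=n))
        y = y + np.sqrt(se2) * rng.normal(size=n)
        return y, X, A

    def test_matches_direct_restricted_likelihood(self, rng):
        y, X, A = self._simulate(rng)
        fit = SpectralREML(y, X, A).fit()
        sg2, se2, ll = direct_reml(y, X, A)
        assert fit.sigma_g2 == pytest.approx(sg2, rel=0.05, abs=0.01)
        assert fit.sigma_e2 == pytest.approx(se2, rel=0.05, abs=0.01)
        assert fit.loglik == pytest.approx(ll, abs=1e-3)

    def test_matches_direct_reml_with_weights(self, rng):
        y, X, A = self._simulate(rng)
        w = rng.uniform(0.3, 1.0, size=len(y))
        fit = SpectralREML(y, X, A, weights=w).fit()
        sg2, se2, _ = direct_reml(y, X, A, weights=w)
        assert fit.sigma_g2 == pytest.approx(sg2, rel=0.08, abs=0.02)
        assert fit.sigma_e2 == pytest.approx(se2, rel=0.08, abs=0.02)

    def test_constant_response_is_an_error(self):
        with pytest.raises(REMLError, match="variance"):
            SpectralREML(np.ones(10), np.ones((10, 1)), np.eye(10))

    def test_rank_deficient_design_is_an_error(self):
        X = np.ones((10, 2))
        with pytest.raises(REMLError, match="rank"):
            SpectralREML(np.arange(10.0), X, np.eye(10))

    def test_identity_kinship_flags_flat_profile(self, rng):
        y = rng.normal(size=60)
        X = np.ones((60, 1))
        with pytest.warns(RuntimeWarning, match="flat"):
            fit = SpectralREML(y, X, np.eye(60)).fit()
        assert not fit.identifiable
        # only the total variance is identified; it matches the sample var
        assert fit.sigma_g2 + fit.sigma_e2 == pytest.approx(
            y.var(ddof=1), rel=0.05
        )


class TestAssociation:
    def test_collapses_to_ols_with_identity_kinship(self, rng):
        n = 120
        X = np.ones((n, 1))
        w = rng.binomial(2, 0.4, n).astype(float)
        y = rng.normal(size=n) + 0.3 * w
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            null = fit_null_model(y, X, np.eye(n))
            res = snp_association(w, y, X, np.eye(n), null=null, mode="fast")
        b_ols, z_ols = ols_t_stats(y, X, w)
        assert res.beta[0] == pytest.approx(b_ols, rel=1e-6)
        assert res.pvalue[0] == pytest.approx(2 * stats.norm.sf(abs(z_ols)), rel=1e-4)

    def test_allele_flip_changes_sign_not_pvalue(self, tiny_dataset):
        rec, y, X, w, W = gwas_inputs(tiny_dataset, "milk")
        A = build_a_matrix(tiny_dataset.pedigree).submatrix(rec["animal"])
        null = fit_null_model(y, X, A, w)
        sub = W[:, :30]
        res = snp_association(sub, y, X, A, w, null=null, mode="fast")
        res_flip = snp_association(2.0 - sub, y, X, A, w, null=null, mode="fast")
        ok = (res.status == "ok").to_numpy()
        assert np.allclose(res.beta[ok], -res_flip.beta[ok], rtol=1e-6)
        assert np.allclose(res.pvalue[ok], res_flip.pvalue[ok], rtol=1e-6)

    def test_monomorphic_and_collinear_snps_are_flagged(self, tiny_dataset):
        rec, y, X, w, W = gwas_inputs(tiny_dataset, "milk")
        A = build_a_matrix(tiny_dataset.pedigree).submatrix(rec["animal"])
        null = fit_null_model(y, X, A, w)
        n = len(y)
        snps = np.column_stack([np.full(n, 2.0), X[:, 1] * 2.0, W[:, 0]])
        res = snp_association(snps, y, X, A, w, null=null, mode="fast")
        assert res.status.tolist()[:2] == ["monomorphic", "collinear"]
        assert np.isnan(res.beta[0]) and np.isnan(res.beta[1])

    def test_run_gwas_reports_every_snp(self, tiny_dataset):
        res = run_gwas(tiny_dataset, "milk")
        assert len(res) == len(tiny_dataset.genotypes.snp_ids)
        assert {"snp_id", "chrom", "pos", "beta", "se", "pvalue", "status"} <= set(
            res.columns
        )

    def test_unknown_trait_is_an_error(self, tiny_dataset):
        with pytest.raises(ValueError, match="unknown trait"):
            gwas_inputs(tiny_dataset, "yield_of_gold")


class TestEffectCorrelations:
    def _frames(self, rng, r):
        cov = np.array([[1.0, r], [r, 1.0]])
        b = rng.multivariate_normal(np.zeros(2), cov, size=400)
        import pandas as pd

        ids = [f"s{i}" for i in range(400)]
        return {
            "t1": pd.DataFrame({"snp_id": ids, "beta": b[:, 0]}),
            "t2": pd.DataFrame({"snp_id": ids, "beta": b[:, 1]}),
        }

    def test_self_and_negated(self, rng):
        frames = self._frames(rng, 0.5)
        frames["t2"] = frames["t1"].assign(beta=-frames["t1"].beta)
        corr = effect_correlations(frames)
        assert corr.loc["t1", "t1"] == 1.0
        assert corr.loc["t1", "t2"] == pytest.approx(-1.0)

    def test_recovers_generated_correlation(self, rng):
        corr = effect_correlations(self._frames(rng, 0.7))
        assert corr.loc["t1", "t2"] == pytest.approx(0.7, abs=0.1)

    def test_too_few_shared_snps_is_an_error(self, rng):
        import pandas as pd

        frames = {
            "t1": pd.DataFrame({"snp_id": ["a", "b"], "beta": [1.0, 2.0]}),
            "t2": pd.DataFrame({"snp_id": ["a", "b"], "beta": [1.0, 2.0]}),
        }
        with pytest.raises(ValueError, match="shared"):
            effect_correlations(frames)

    def test_independent_architectures_are_uncorrelated(self):
        cfg = SimulationConfig(
            seed=77,
            n_animals=500,
            n_founders=120,
            n_snps=2_000,
            n_genes=400,
            n_chromosomes=4,
            chrom_length_bp=15_000_000,
            traits=(
                TraitParams("t1", h2=0.3, r2=0.56),
                TraitParams("t2", h2=0.3, r2=0.56),
            ),
            n_causal=30,
        )
        ds = as_dataset(simulate_dataset(cfg))
        results = {t: run_gwas(ds, t) for t in ("t1", "t2")}
        corr = effect_correlations(results)
        assert abs(corr.loc["t1", "t2"]) < 0.1


def test_genomic_control_lambda_on_uniform_pvalues(rng):
    p = rng.uniform(size=20_000)
    assert genomic_control_lambda(p) == pytest.approx(1.0, abs=0.05)
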