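import numpy as np
import pandas as pd
import pytest

from hybridgp import (
    Kernel, ModelData, blup_oracle, fit_gibbs, linear_kernel,
    make_model_data, predict,
)
from conftest import random_psd_kernel


def _single_env_data(y, K, mask=None):
    J = len(y)
    return ModelData(
        y=np.asarray(y, float),
        line_index=np.arange(J),
        kernels=[K],
        line_ids=K.line_ids,
        mask=np.zeros(J, bool) if mask is None else np.asarray(mask, bool),
    )


class TestModelData:
    def test_requires_an_unmasked_observation(self, rng):
        K = random_psd_kernel(rng, 10, "G")
        with pytest.raises(ValueError, match="unmasked"):
            _single_env_data(np.ones(10), K, mask=np.ones(10, bool))

    def test_rejects_label_mismatch(self, rng):
        K1 = random_psd_kernel(rng, 5, "G")
        K2 = Kernel(K1.values, [f"X{i}" for i in range(5)], "H")
        with pytest.raises(ValueError, match="mismatched"):
            ModelData(np.ones(5), np.arange(5), [K1, K2], K1.line_ids,
                      np.zeros(5, bool))

    def test_make_model_data_masks_all_envs_of_test_lines(self, rng):
        K = random_psd_kernel(rng, 6, "G")
        ph = pd.DataFrame({
            "line": ["L0", "L0", "L1", "L2"],
            "environment": ["E0", "E1", "E0", "E1"],
            "trait": "GY", "value": [1.0, 1.1, 2.0, 0.5],
        })
        data = make_model_data(ph, [K], test_lines=["L0"])
        assert data.mask.tolist() == [True, True, False, False]

    def test_unknown_phenotype_line_rejected(self, rng):
        K = random_psd_kernel(rng, 3, "G")
        ph = pd.DataFrame({"line": ["L9"], "environment": ["E0"],
                           "trait": "GY", "value": [1.0]})
        with pytest.raises(ValueError, match="L9"):
            make_model_data(ph, [K])


class TestGibbsSampler:
    def test_constant_response_degenerates_gracefully(self, rng):
        K = random_psd_kernel(rng, 15, "G")
        y = np.full(15, 7.0)
        fit = fit_gibbs(_single_env_data(y, K), n_iter=1500, burn_in=300, seed=0)
        assert fit.mu_mean == pytest.approx(7.0, abs=0.05)
        assert fit.sigma2_mean < 0.05
        assert (fit.sigma2_samples > 0).all()
        assert all((s > 0).all() for s in fit.kernel_variance_samples.values())

    def test_matches_closed_form_blup_with_fixed_variances(self, rng):
        J = 80
        X = rng.normal(size=(J, 60))
        X = (X - X.mean(0)) / X.std(0)
        G = linear_kernel(pd.DataFrame(X, index=[f"L{i}" for i in range(J)]), "G")
        y = 2 + rng.multivariate_normal(np.zeros(J), G.values) + rng.normal(0, 0.7, J)
        fit = fit_gibbs(
            _single_env_data(y, G), n_iter=8000, burn_in=1000, thin=2, seed=3,
            fixed_kernel_variances=[1.0], fixed_residual_variance=0.49,
            fix_mu=float(y.mean()),
        )
        u_hat = blup_oracle(G.values, np.arange(J), y, 1.0, 0.49)
        dev = np.abs(fit.u_means["G"].to_numpy() - u_hat).max()
        assert dev < 0.02 * y.std()

    def test_bit_identical_chains_for_identical_seeds(self, rng):
        K = random_psd_kernel(rng, 12, "G")
        y = rng.normal(size=12)
        data = _single_env_data(y, K)
        f1 = fit_gibbs(data, n_iter=400, burn_in=100, seed=9)
        f2 = fit_gibbs(data, n_iter=400, burn_in=100, seed=9)
        np.testing.assert_array_equal(f1.sigma2_samples, f2.sigma2_samples)
        np.testing.assert_array_equal(
            f1.u_means["G"].to_numpy(), f2.u_means["G"].to_numpy()
        )

    def test_masked_twin_line_predicted_from_its_duplicate(self, rng):
        # two lines with identical kernel rows are exchangeable: masking one
        # of them must predict (approximately) the observed twin's value
        J = 12
        A = rng.normal(size=(J, 20))
        A[1] = A[0]
        K = linear_kernel(pd.DataFrame(A, index=[f"L{i}" for i in range(J)]), "K")
        g = rng.multivariate_normal(np.zeros(J), K.values + 1e-10 * np.eye(J))
        y = g.copy()
        mask = np.zeros(J, bool)
        mask[1] = True
        fit = fit_gibbs(
            _single_env_data(y, K, mask), n_iter=8000, burn_in=1000, thin=2,
            seed=5, fixed_kernel_variances=[1.0],
            fixed_residual_variance=1e-4,
        )
        pred = fit.predictions.iloc[0]
        assert pred == pytest.approx(y[0], abs=0.1)

    def test_additional_kernels_keep_the_sampler_finite(self, rng):
        J = 20
        G = random_psd_kernel(rng, J, "G")
        H = Kernel(random_psd_kernel(rng, J, "H").values, G.line_ids, "H")
        y = rng.normal(size=J)
        for kernels in ([G], [H, G]):
            data = ModelData(y, np.arange(J), kernels, G.line_ids,
                             np.zeros(J, bool))
            fit = fit_gibbs(data, n_iter=800, burn_in=200, seed=2)
            assert np.isfinite(fit.sigma2_mean)
            assert all(np.isfinite(v) for v in fit.kernel_variance_means.values())

    def test_permuting_lines_permutes_posterior_means(self, rng):
        J = 25
        X = rng.normal(size=(J, 30))
        X = (X - X.mean(0)) / X.std(0)
        ids = [f"L{i}" for i in range(J)]
        G = linear_kernel(pd.DataFrame(X, index=ids), "G")
        y = rng.multivariate_normal(np.zeros(J), G.values) + rng.normal(0, 0.5, J)
        perm = rng.permutation(J)
        Gp = Kernel(G.values[np.ix_(perm, perm)], [ids[i] for i in perm], "G")
        kw = dict(n_iter=12000, burn_in=2000, thin=2,
                  fixed_kernel_variances=[1.0], fixed_residual_variance=0.25,
                  fix_mu=float(y.mean()))
        f1 = fit_gibbs(_single_env_data(y, G), seed=4, **kw)
        f2 = fit_gibbs(_single_env_data(y[perm], Gp), seed=4, **kw)
        u1 = f1.u_means["G"].reindex([ids[i] for i in perm]).to_numpy()
        u2 = f2.u_means["G"].to_numpy()
        np.testing.assert_allclose(u1, u2, atol=0.03 * y.std())

    def test_null_data_shrinks_the_kernel_variance(self):
        from hybridgp import SimulationScenario, simulate_dataset, standardize_markers
        sc = SimulationScenario(J=300, p=150, n_env=1, h2_g=0.0,
                                residual_sd=1.0, sparsity=1.0, seed=1)
        d = simulate_dataset(sc)
        G = linear_kernel(standardize_markers(d["markers"]).X, "G")
        data = make_model_data(d["phenotypes"], [G])
        fit = fit_gibbs(data, n_iter=4000, burn_in=800, thin=2, seed=1)
        ratio = fit.kernel_variance_samples["G"] / (
            fit.kernel_variance_samples["G"] + fit.sigma2_samples
        )
        assert np.median(ratio) < 0.2

    def test_indefinite_kernel_rejected(self, rng):
        bad = Kernel(np.array([[1.0, 2.0], [2.0, 1.0]]), ["L0", "L1"], "bad")
        data = ModelData(np.ones(2), np.arange(2), [bad], bad.line_ids,
                         np.zeros(2, bool))
        with pytest.raises(ValueError, match="psd_repair"):
            fit_gibbs(data, n_iter=100, burn_in=10, seed=0)


class TestPredict:
    def test_empty_mask_gives_empty_predictions(self, rng):
        K = random_psd_kernel(rng, 10, "G")
        fit = fit_gibbs(_single_env_data(rng.normal(size=10), K),
                        n_iter=300, burn_in=50, seed=1)
        assert len(predict(fit, None)) == 0

    def test_requesting_unmasked_observation_is_an_error(self, rng):
        K = random_psd_kernel(rng, 10, "G")
        mask = np.zeros(10, bool)
        mask[2] = True
        data = _single_env_data(rng.normal(size=10), K, mask)
        fit = fit_gibbs(data, n_iter=300, burn_in=50, seed=1)
        assert list(predict(fit, data).index) == [("L2", "E0")]
        with pytest.raises(KeyError):
            predict(fit, data, keys=[("L0", "E0")])
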