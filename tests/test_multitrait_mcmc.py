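import numpy as np
import pytest
from scipy.stats import norm

from selgen.blup import blup_posterior
from selgen.core import (
    MultiTraitCovariance,
    RelationshipMatrix,
    VarianceComponents,
    genomic_relationship,
)
from selgen.multitrait_mcmc import (
    CullingSpec,
    MultiTraitModel,
    conditional_nsel,
    culling_survival_prob,
    multitrait_blup_sel,
    multitrait_log_posterior,
    run_multitrait_sampler,
)
from selgen.synthetic_data import (
    apply_sequential_culling,
    simulate_genomic_population,
    simulate_multitrait,
)

from conftest import R0_WHEAT_RAW


def _random_K(n, seed, jitter=0.5):
    rng = np.random.default_rng(seed)
    M = rng.standard_normal((n, n))
    return RelationshipMatrix(list(range(n)), M @ M.T / n + jitter * np.eye(n),
                              "genomic")


def _model(n=6, T=2, seed=0, threshold=0.0, jitter=0.5):
    K = _random_K(n, seed, jitter)
    rng = np.random.default_rng(seed + 1)
    A = rng.standard_normal((T, T))
    G0 = A @ A.T / T + 0.3 * np.eye(T)
    B = rng.standard_normal((T, T))
    R0 = B @ B.T / T + 0.3 * np.eye(T)
    cov0 = MultiTraitCovariance(G0, R0)
    Y, _ = simulate_multitrait(G0, R0, K, seed=seed + 2)
    sel, nsel, _ = apply_sequential_culling(Y, [threshold] * (T - 1))
    if len(sel) == 0 or len(nsel) == 0:  # ensure both partitions non-empty
        sel, nsel = np.arange(n - 1), np.array([n - 1])
    return MultiTraitModel(
        cov0, K, [K.ids[i] for i in sel], [K.ids[i] for i in nsel], Y[sel])


class TestMultitraitBlupSel:
    def test_single_trait_reduces_to_blup_posterior(self):
        K = _random_K(5, 3)
        g0, r0 = 0.8, 1.1
        cov0 = MultiTraitCovariance([[g0]], [[r0]])
        rng = np.random.default_rng(1)
        y = rng.standard_normal(5)
        model = MultiTraitModel(cov0, K, K.ids, [], y[:, None])
        post = multitrait_blup_sel(model)
        ref = blup_posterior(y, K, VarianceComponents(g0, r0))
        np.testing.assert_allclose(post.mean, ref.mean, atol=1e-10)
        np.testing.assert_allclose(post.cov, ref.cov, atol=1e-10)

    def test_diagonal_covariances_decouple_traits(self):
        K = _random_K(6, 4)
        cov0 = MultiTraitCovariance(np.diag([0.7, 1.2]), np.diag([0.9, 0.6]))
        rng = np.random.default_rng(2)
        Y = rng.standard_normal((6, 2))
        model = MultiTraitModel(cov0, K, K.ids, [], Y)
        post = multitrait_blup_sel(model)
        for t, (g0, r0) in enumerate([(0.7, 0.9), (1.2, 0.6)]):
            ref = blup_posterior(Y[:, t], K, VarianceComponents(g0, r0))
            np.testing.assert_allclose(post.mean[t * 6:(t + 1) * 6], ref.mean,
                                       atol=1e-10)

    def test_matches_dense_computation(self):
        model = _model(n=5, T=2, seed=7)
        post = multitrait_blup_sel(model)
        Gs, _, _ = model.G_blocks()
        ns = model.n_sel
        GG = np.kron(model.cov0.G0, Gs)
        Sig = GG + np.kron(model.cov0.R0, np.eye(ns))
        y = model.Y_sel.T.reshape(-1)
        np.testing.assert_allclose(post.mean, GG @ np.linalg.solve(Sig, y),
                                   atol=1e-10)
        np.testing.assert_allclose(post.cov, GG - GG @ np.linalg.solve(Sig, GG),
                                   atol=1e-10)


class TestCullingSurvivalProb:
    def test_independent_traits_at_mean(self):
        assert culling_survival_prob(np.zeros(3), np.eye(3), [0, 0, 0]) == \
            pytest.approx(0.125, abs=1e-6)

    def test_infinite_thresholds(self):
        p = culling_survival_prob(np.zeros(3), np.eye(3), [50, 50, 50])
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_printed_residual_block_against_monte_carlo(self):
        R0 = ((R0_WHEAT_RAW + R0_WHEAT_RAW.T) / 2)[:3, :3]
        t = np.array([0.0, 0.6, 1.3])
        p = culling_survival_prob(np.zeros(3), R0, t)
        rng = np.random.default_rng(101)
        draws = rng.multivariate_normal(np.zeros(3), R0, size=1_000_000,
                                        method="cholesky")
        hits = np.all(draws < t, axis=1)
        mc = hits.mean()
        se = np.sqrt(mc * (1 - mc) / hits.size)
        assert abs(p - mc) < 3 * se

    def test_dimension_check(self):
        with pytest.raises(ValueError):
            culling_survival_prob(np.zeros(2), np.eye(3), [0, 0, 0])


class TestConditionalNsel:
    def test_unrelated_partitions(self):
        K = RelationshipMatrix(list(range(4)),
                               np.diag([1.0, 1.0, 2.0, 2.0]), "genomic")
        cov0 = MultiTraitCovariance(np.eye(2) * 0.5, np.eye(2))
        model = MultiTraitModel(cov0, K, [0, 1], [2, 3], np.zeros((2, 2)))
        m, V = conditional_nsel(np.ones(4), model)
        np.testing.assert_allclose(m, 0.0, atol=1e-14)
        np.testing.assert_allclose(V, np.kron(cov0.G0, np.diag([2.0, 2.0])),
                                   atol=1e-12)

    def test_clone_reproduces_selected_value(self):
        base = _random_K(3, 5).K
        K = np.zeros((4, 4))
        K[:3, :3] = base
        K[3, :3] = base[0, :3]  # individual 3 is a clone of individual 0
        K[:3, 3] = base[:3, 0]
        K[3, 3] = base[0, 0]
        Krm = RelationshipMatrix(list(range(4)), K, "genomic")
        cov0 = MultiTraitCovariance([[1.0]], [[1.0]])
        model = MultiTraitModel(cov0, Krm, [0, 1, 2], [3], np.zeros((3, 1)))
        g_sel = np.array([0.7, -0.2, 1.1])
        m, V = conditional_nsel(g_sel, model)
        assert m[0] == pytest.approx(g_sel[0], abs=1e-10)
        assert V[0, 0] == pytest.approx(0.0, abs=1e-10)

    def test_joint_gaussian_oracle(self):
        model = _model(n=6, T=2, seed=9)
        T, ns, nn = model.n_traits, model.n_sel, model.n_nsel
        Gs, Gns, Gnn = model.G_blocks()
        # condition the full Kronecker normal directly
        order_cov = np.kron(
            model.cov0.G0,
            np.block([[Gs, Gns.T], [Gns, Gnn]]),
        )
        # indices of sel/nsel entries in the trait-major (sel+nsel) stack
        n = ns + nn
        sel_idx = np.concatenate([t * n + np.arange(ns) for t in range(T)])
        nsel_idx = np.concatenate([t * n + ns + np.arange(nn) for t in range(T)])
        S_ss = order_cov[np.ix_(sel_idx, sel_idx)]
        S_ns = order_cov[np.ix_(nsel_idx, sel_idx)]
        S_nn = order_cov[np.ix_(nsel_idx, nsel_idx)]
        rng = np.random.default_rng(0)
        g_sel = rng.standard_normal(T * ns)
        m_ref = S_ns @ np.linalg.solve(S_ss, g_sel)
        V_ref = S_nn - S_ns @ np.linalg.solve(S_ss, S_ns.T)
        m, V = conditional_nsel(g_sel, model)
        np.testing.assert_allclose(m, m_ref, atol=1e-10)
        np.testing.assert_allclose(V, V_ref, atol=1e-10)


def _first_principles_logpdf(g_all, model, culling):
    """Independent construction: prior x likelihood x culling probability."""
    T, ns, nn = model.n_traits, model.n_sel, model.n_nsel
    n = ns + nn
    Gs, Gns, Gnn = model.G_blocks()
    Kperm = np.block([[Gs, Gns.T], [Gns, Gnn]])
    # partitioned stack -> trait-major over (sel + nsel) individuals
    g_mat = np.empty((n, T))
    for t in range(T):
        g_mat[:ns, t] = g_all[t * ns:(t + 1) * ns]
        g_mat[ns:, t] = g_all[T * ns + t * nn:T * ns + (t + 1) * nn]
    g_stack = g_mat.T.reshape(-1)
    prior_cov = np.kron(model.cov0.G0, Kperm)
    lp = -0.5 * g_stack @ np.linalg.solve(prior_cov, g_stack)
    R0inv = np.linalg.inv(model.cov0.R0)
    for i in range(ns):
        r = model.Y_sel[i] - g_mat[i]
        lp += -0.5 * r @ R0inv @ r
    if culling is not None:
        R_sub = model.cov0.R0[: T - 1, : T - 1]
        for j in range(nn):
            p = culling_survival_prob(g_mat[ns + j, : T - 1], R_sub,
                                      culling.thresholds)
            lp += np.log(max(p, 1e-300))
    return lp


class TestMultitraitLogPosterior:
    def test_matches_first_principles_up_to_constant(self):
        model = _model(n=6, T=2, seed=13)
        culling = CullingSpec([0.0])
        rng = np.random.default_rng(3)
        dim = model.n_traits * (model.n_sel + model.n_nsel)
        g0 = 0.1 * rng.standard_normal(dim)
        ref0 = _first_principles_logpdf(g0, model, culling)
        lp0 = multitrait_log_posterior(g0, model, culling)
        for _ in range(5):
            g = 0.5 * rng.standard_normal(dim)
            diff_ours = multitrait_log_posterior(g, model, culling) - lp0
            diff_ref = _first_principles_logpdf(g, model, culling) - ref0
            assert diff_ours == pytest.approx(diff_ref, abs=1e-7)

    def test_gaussian_kernel_when_nsel_at_conditional_mean(self):
        model = _model(n=6, T=2, seed=13)
        post = multitrait_blup_sel(model)
        prec = np.linalg.inv(post.cov)
        rng = np.random.default_rng(5)
        vals = []
        for _ in range(3):
            g_sel = post.mean + 0.3 * rng.standard_normal(len(post.mean))
            m_cond, _ = conditional_nsel(g_sel, model)
            g_all = np.concatenate([g_sel, m_cond])
            lp = multitrait_log_posterior(g_all, model, None)
            d = g_sel - post.mean
            vals.append(lp - (-0.5 * d @ prec @ d))
        assert np.ptp(vals) < 1e-8  # equal up to one shared constant

    def test_culling_term_nonincreasing_in_staged_traits(self):
        model = _model(n=6, T=2, seed=13)
        culling = CullingSpec([0.0])
        rng = np.random.default_rng(6)
        dim = model.n_traits * (model.n_sel + model.n_nsel)
        T, ns, nn = model.n_traits, model.n_sel, model.n_nsel
        for _ in range(10):
            g = rng.standard_normal(dim)
            base = (multitrait_log_posterior(g, model, culling)
                    - multitrait_log_posterior(g, model, None))
            for j in range(nn):
                g2 = g.copy()
                g2[T * ns + j] += 0.2  # raise culled j's trait-1 value
                delta2 = (multitrait_log_posterior(g2, model, culling)
                          - multitrait_log_posterior(g2, model, None))
                assert delta2 <= base + 1e-10

    def test_dimension_check(self):
        with pytest.raises(ValueError):
            multitrait_log_posterior(np.zeros(3), _model(), None)


class TestSampler:
    def test_gaussian_target_without_culling(self):
        model = _model(n=5, T=2, seed=17)
        post = multitrait_blup_sel(model)
        chain = run_multitrait_sampler(model, None, n_iter=8000, seed=1,
                                       block="full", include_correction=False)
        kept = chain.draws[1600:, : len(post.mean)]
        ess = np.maximum(chain.ess[: len(post.mean)], 50)
        se = kept.std(axis=0, ddof=1) / np.sqrt(ess * 0.8)
        assert np.all(np.abs(kept.mean(axis=0) - post.mean) < 3.5 * se)

    def test_lattice_oracle_two_individuals(self):
        """4-D lattice normalization vs sampler marginals with culling."""
        K = _random_K(2, 21, jitter=0.8)
        cov0 = MultiTraitCovariance(np.array([[0.8, 0.2], [0.2, 0.7]]),
                                    np.array([[1.0, 0.1], [0.1, 0.9]]))
        model = MultiTraitModel(cov0, K, [K.ids[0]], [K.ids[1]],
                                np.array([[0.9, 0.4]]))
        culling = CullingSpec([0.0])
        # lattice over (g_sel_t1, g_sel_t2, g_n_t1, g_n_t2)
        axes = [np.linspace(-3.5, 3.5, 31) for _ in range(4)]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=1)
        from selgen.multitrait_mcmc import _MultitraitTarget
        target = _MultitraitTarget(model, None)
        quad = (-0.5 * np.einsum("ij,jk,ik->i", pts, target.H, pts)
                + pts @ target.b)
        # culled individual's trait-1 value is coordinate 2 of the lattice
        cull = norm.logcdf((0.0 - pts[:, 2]) / np.sqrt(cov0.R0[0, 0]))
        p = np.exp(quad + cull - (quad + cull).max()).reshape(31, 31, 31, 31)
        p /= p.sum()
        for block, iters in [("full", 60_000), ("augmented", 30_000)]:
            chain = run_multitrait_sampler(model, culling, n_iter=iters,
                                           seed=9, block=block)
            kept = chain.draws[iters // 5:]
            for c in range(4):
                marg = p.sum(axis=tuple(a for a in range(4) if a != c))
                step = axes[c][1] - axes[c][0]
                edges = np.concatenate([axes[c] - step / 2,
                                        [axes[c][-1] + step / 2]])
                hist, _ = np.histogram(kept[:, c], bins=edges)
                tv = 0.5 * np.abs(hist / hist.sum() - marg).sum()
                assert tv < 0.05, f"{block} coordinate {c}: TV {tv:.3f}"

    def test_block_schemes_agree(self):
        from selgen.cli_io import effective_sample_size
        model = _model(n=5, T=2, seed=23)
        culling = CullingSpec([0.0])
        means, ses = {}, {}
        for block, iters in [("full", 30_000), ("per_trait", 10_000),
                             ("per_individual", 5000), ("augmented", 5000)]:
            ch = run_multitrait_sampler(model, culling, n_iter=iters, seed=3,
                                        block=block)
            kept = ch.draws[iters // 5:]
            means[block] = kept.mean(axis=0)
            ess = np.maximum(effective_sample_size(kept), 10)
            ses[block] = kept.std(axis=0, ddof=1) / np.sqrt(ess)
        for block in ("per_trait", "per_individual", "augmented"):
            se = np.sqrt(ses[block] ** 2 + ses["full"] ** 2)
            assert np.all(np.abs(means[block] - means["full"]) < 3.5 * se)

    def test_two_seeds_converge(self):
        import warnings

        import arviz as az
        model = _model(n=4, T=2, seed=29)
        chains = [run_multitrait_sampler(model, CullingSpec([0.0]),
                                         n_iter=4000, seed=s,
                                         block="per_individual")
                  for s in (5, 6)]
        stacked = np.stack([c.draws[800:] for c in chains])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = az.rhat(az.convert_to_dataset(stacked))["x"].values
        assert np.all(rhat < 1.05)

    def test_proposal_kernel_swap_leaves_target_unchanged(self):
        model = _model(n=5, T=2, seed=31)
        post = multitrait_blup_sel(model)
        alt = RelationshipMatrix(model.K.ids, np.eye(5), "identity")
        chain = run_multitrait_sampler(model, None, n_iter=10_000, seed=2,
                                       block="full", include_correction=False,
                                       proposal_K=alt)
        kept = chain.draws[2000:, : len(post.mean)]
        ess = np.maximum(chain.ess[: len(post.mean)], 30)
        se = kept.std(axis=0, ddof=1) / np.sqrt(ess * 0.8)
        assert np.all(np.abs(kept.mean(axis=0) - post.mean) < 4 * se)


class TestEndToEndRecovery:
    def test_reduced_scale_parameter_recovery(self):
        """Culling-corrected posterior means are no worse (beyond 5%) than
        culling-ignored BLUP at the reduced two-trait protocol."""
        G0 = np.array([[0.8, 0.2], [0.2, 0.7]])
        R0 = np.array([[0.9, 0.1], [0.1, 1.0]])
        cov0 = MultiTraitCovariance(G0, R0)
        sq_corr, sq_ign, n_tot = 0.0, 0.0, 0
        for seed in range(20):
            X, _, _ = simulate_genomic_population(200, 400, seed=3000 + seed)
            K = genomic_relationship(X).repaired()
            Y, Gtrue = simulate_multitrait(G0, R0, K, seed=4000 + seed)
            sel, nsel, _ = apply_sequential_culling(Y, [0.0])
            model = MultiTraitModel(
                cov0, K, [K.ids[i] for i in sel], [K.ids[i] for i in nsel],
                Y[sel])
            truth = Gtrue[sel].T.reshape(-1)  # trait-major stack over S+
            post = multitrait_blup_sel(model)
            chain = run_multitrait_sampler(
                model, CullingSpec([0.0]), n_iter=1500, seed=5000 + seed,
                block="augmented")
            ns2 = 2 * model.n_sel
            corr_mean = chain.draws[300:, :ns2].mean(axis=0)
            sq_corr += float(np.sum((corr_mean - truth) ** 2))
            sq_ign += float(np.sum((post.mean - truth) ** 2))
            n_tot += ns2
        rmse_corr = np.sqrt(sq_corr / n_tot)
        rmse_ign = np.sqrt(sq_ign / n_tot)
        # report both in the assertion message
        assert rmse_corr <= 1.05 * rmse_ign, (
            f"corrected RMSE {rmse_corr:.4f} vs culling-ignored {rmse_ign:.4f}"
        )
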