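"""Conditional-distribution checks, including the joint-density proportionality oracle.

The oracle evaluates the full log joint posterior (likelihood × priors) on a
grid over one parameter with all others held fixed; the conditional spec's
log-density must differ from it by a constant.
"""

import numpy as np
import pytest

from bayesgge import ModelConfig, build_design
from bayesgge.conditionals import (
    ComponentFrame,
    ParamState,
    cond_beta,
    cond_lambda,
    cond_sigma_e,
    cond_sigma_lambda,
    cond_vector,
)
from bayesgge.samplers import initial_state, loglik, orthonormal_complement

from conftest import make_met


def random_state(met, design, k=1, variant="entropy", seed=0):
    rng = np.random.default_rng(seed)
    state = initial_state(met, design, ModelConfig(variant=variant, k=k))
    state.lam = np.sort(np.abs(rng.normal(2.0, 1.0, k)))[::-1]
    state.sigma2_e = 1.5
    if variant == "entropy":
        state.sigma2_lam = np.abs(rng.normal(3.0, 1.0, k))
    return state


def log_joint(state, met, design, cfg):
    """Independent evaluation of the unnormalized log joint posterior."""
    lp = loglik(state, met, design)
    lp += -0.5 * state.beta @ state.beta / cfg.sigma2_beta
    for k in range(len(state.lam)):
        s2 = (cfg.sigma2_lambda_flat if state.sigma2_lam is None
              else state.sigma2_lam[k])
        lp += -0.5 * state.lam[k] ** 2 / s2 - 0.5 * np.log(s2)
        if state.sigma2_lam is not None:
            # max-entropy hyperprior IG(a=1, b=0): density proportional to x^-2
            lp += -(cfg.a + 1.0) * np.log(state.sigma2_lam[k])
    lp += -np.log(state.sigma2_e)  # Jeffreys
    lam_sorted = np.all(np.diff(state.lam) <= 1e-12) and np.all(state.lam >= 0)
    return lp if lam_sorted else -np.inf


@pytest.fixture()
def toy():
    met = make_met(v=4, l=3, b=2, seed=2)
    design = build_design(met)
    cfg = ModelConfig(variant="entropy", k=1, sigma2_beta=2.0)
    state = random_state(met, design, k=1, seed=4)
    return met, design, cfg, state


class TestProportionalityOracle:
    def assert_constant_ratio(self, logjoint_vals, spec_vals, tol=1e-6):
        diff = np.asarray(logjoint_vals) - np.asarray(spec_vals)
        assert np.ptp(diff) < tol

    def test_beta_conditional(self, toy):
        met, design, cfg, state = toy
        spec = cond_beta(state, met, design, cfg)
        lj, lc = [], []
        for delta in np.linspace(-2, 2, 9):
            s = state.copy()
            s.beta = state.beta.copy()
            s.beta[1] += delta
            lj.append(log_joint(s, met, design, cfg))
            lc.append(spec.logpdf(s.beta))
        self.assert_constant_ratio(lj, lc)

    def test_lambda_conditional(self, toy):
        met, design, cfg, state = toy
        spec = cond_lambda(state, met, design, cfg, 0)
        lj, lc = [], []
        for lam in np.linspace(0.1, 6.0, 12):
            s = state.copy()
            s.lam = np.array([lam])
            lj.append(log_joint(s, met, design, cfg))
            lc.append(spec.logpdf(lam))
        self.assert_constant_ratio(lj, lc)

    def test_sigma_e_conditional(self, toy):
        met, design, cfg, state = toy
        spec = cond_sigma_e(state, met, design)
        lj, lc = [], []
        for s2 in np.linspace(0.5, 8.0, 10):
            s = state.copy()
            s.sigma2_e = s2
            lj.append(log_joint(s, met, design, cfg))
            lc.append(spec.logpdf(s2))
        self.assert_constant_ratio(lj, lc)

    def test_sigma_lambda_conditional(self, toy):
        met, design, cfg, state = toy
        spec = cond_sigma_lambda(state, cfg, 0)
        lj, lc = [], []
        for s2 in np.linspace(0.5, 10.0, 10):
            s = state.copy()
            s.sigma2_lam = np.array([s2])
            lj.append(log_joint(s, met, design, cfg))
            lc.append(spec.logpdf(s2))
        self.assert_constant_ratio(lj, lc)

    @pytest.mark.parametrize("side", ["genotypic", "environmental"])
    def test_vector_conditional_on_sphere(self, toy, side):
        met, design, cfg, state = toy
        spec = cond_vector(state, met, design, cfg, 0, side)
        rng = np.random.default_rng(8)
        dim = met.v if side == "genotypic" else met.l
        lj, lc = [], []
        for _ in range(8):
            u = rng.normal(size=dim)
            u /= np.linalg.norm(u)
            s = state.copy()
            if side == "genotypic":
                s.A = u[:, None]
            else:
                s.Gamma = u[:, None]
            lj.append(log_joint(s, met, design, cfg))
            lc.append(spec.logpdf(u))
        self.assert_constant_ratio(lj, lc)


class TestLambdaBounds:
    def test_order_constraint_bounds(self, paper_met):
        met, _ = paper_met
        design = build_design(met)
        cfg = ModelConfig(variant="flat", k=3)
        state = initial_state(met, design, cfg)
        top = cond_lambda(state, met, design, cfg, 0)
        mid = cond_lambda(state, met, design, cfg, 1)
        bot = cond_lambda(state, met, design, cfg, 2)
        assert top.upper == np.inf and top.lower == state.lam[1]
        assert mid.lower == state.lam[2] and mid.upper == state.lam[0]
        assert bot.lower == 0.0 and bot.upper == state.lam[1]

    def test_flat_and_frozen_entropy_agree(self, toy_design):
        met, design = toy_design
        flat_cfg = ModelConfig(variant="flat", k=2)
        ent_cfg = ModelConfig(variant="entropy", k=2)
        state = initial_state(met, design, ent_cfg)
        state.sigma2_lam = np.full(2, ent_cfg.sigma2_lambda_flat)
        for k in range(2):
            a = cond_lambda(state, met, design, flat_cfg, k)
            b = cond_lambda(state, met, design, ent_cfg, k)
            assert a == b


class TestSigmaLambda:
    def test_entropy_update_from_lambda(self, toy):
        met, design, cfg, state = toy
        state.lam = np.array([3.0])
        spec = cond_sigma_lambda(state, cfg, 0)
        assert spec.shape == 1.5 and spec.scale == 4.5
        # conditional mean stays lambda^2
        assert spec.scale / (spec.shape - 1.0) == pytest.approx(9.0)

    def test_zero_lambda_floored(self, toy):
        met, design, cfg, state = toy
        state.lam = np.array([0.0])
        spec = cond_sigma_lambda(state, cfg, 0)
        assert spec.scale == cfg.sigma2_lambda_floor > 0

    def test_flat_variant_rejects_call(self, toy_design):
        met, design = toy_design
        cfg = ModelConfig(variant="flat", k=1)
        state = initial_state(met, design, cfg)
        with pytest.raises(ValueError, match="entropy"):
            cond_sigma_lambda(state, cfg, 0)

    def test_mean_matches_quadrature_oracle(self):
        from bayesgge.conditionals import InvGammaSpec
        from scipy.integrate import quad

        spec = InvGammaSpec(shape=1.5, scale=4.5)
        mean, _ = quad(lambda x: x * np.exp(spec.logpdf(x)), 0, np.inf)
        assert mean == pytest.approx(9.0, rel=1e-6)


class TestSigmaE:
    def test_exact_fit_gives_zero_scale(self, toy):
        met, design, cfg, state = toy
        frame = ComponentFrame.from_state(state, design)
        met2 = make_met(v=4, l=3, b=2, responses=frame.mu_y)
        spec = cond_sigma_e(state, met2, design)
        assert spec.scale == pytest.approx(0.0, abs=1e-20)
        assert spec.df == met2.n

    def test_sse_over_n(self):
        met = make_met(v=2, l=2, b=1, responses=[1.0, 2.0, 3.0, 4.0])
        design = build_design(met)
        state = ParamState(
            beta=np.zeros(2), lam=np.array([0.0]),
            A=np.array([[1.0], [0.0]]), Gamma=np.array([[1.0], [0.0]]),
            sigma2_e=1.0)
        spec = cond_sigma_e(state, met, design)
        # SSE = 1+4+9+16 = 30 over n = 4
        assert spec.df == 4 and spec.scale == pytest.approx(7.5)


class TestCondBeta:
    def test_flat_prior_limit_is_cell_means(self, toy_design):
        met, design = toy_design
        cfg = ModelConfig(variant="flat", k=1)
        state = initial_state(met, design, cfg)
        state.lam = np.array([0.0])   # bilinear off: mean = per-cell average
        spec = cond_beta(state, met, design, cfg)
        counts = np.bincount(design.be_idx)
        cell_means = np.bincount(design.be_idx, weights=met.y) / counts
        np.testing.assert_allclose(spec.mean, cell_means, atol=1e-5)

    def test_ridge_solution_vs_grid_oracle(self):
        met = make_met(v=2, l=2, b=1, responses=[4.0, 6.0, 5.0, 7.0])
        design = build_design(met)
        cfg = ModelConfig(variant="flat", k=1, sigma2_beta=1.0)
        state = initial_state(met, design, cfg)
        state.lam = np.array([0.0])
        state.sigma2_e = 1.0
        spec = cond_beta(state, met, design, cfg)
        # brute-force maximizer of the conditional density over a beta grid
        grid = np.linspace(-2, 10, 241)
        for j in range(2):
            def neg_density(bj, j=j):
                beta = spec.mean.copy()
                beta[j] = bj
                resid = met.y - beta[design.be_idx]
                return resid @ resid / 2 + beta @ beta / (2 * cfg.sigma2_beta)
            vals = [neg_density(b) for b in grid]
            assert grid[int(np.argmin(vals))] == pytest.approx(spec.mean[j], abs=0.05)


class TestCondVector:
    def test_first_component_spans_full_space(self, toy):
        met, design, cfg, state = toy
        spec = cond_vector(state, met, design, cfg, 0, "genotypic")
        assert spec.m == met.v and spec.basis.shape == (met.v, met.v)

    def test_zero_lambda_gives_uniform(self, toy):
        met, design, cfg, state = toy
        state.lam = np.array([0.0])
        spec = cond_vector(state, met, design, cfg, 0, "environmental")
        assert spec.kappa == 0.0

    def test_second_component_orthogonal_subspace(self):
        met = make_met(v=4, l=3, b=2, seed=6)
        design = build_design(met)
        cfg = ModelConfig(variant="flat", k=2)
        state = initial_state(met, design, cfg)
        spec = cond_vector(state, met, design, cfg, 1, "genotypic")
        assert spec.m == met.v - 1
        # basis orthogonal to alpha_1, checked against a Gram-Schmidt oracle
        np.testing.assert_allclose(spec.basis.T @ state.A[:, 0], 0.0, atol=1e-10)
        gs = state.A[:, [0]]
        proj = spec.basis - gs @ (gs.T @ spec.basis)
        np.testing.assert_allclose(proj, spec.basis, atol=1e-10)


def test_orthonormal_complement_properties():
    H = orthonormal_complement(np.eye(3)[:, [0]])
    assert H.shape == (3, 2)
    np.testing.assert_allclose(H.T @ H, np.eye(2), atol=1e-12)
    np.testing.assert_allclose(H.T @ np.eye(3)[:, 0], 0.0, atol=1e-12)

    empty = orthonormal_complement(np.zeros((4, 0)))
    np.testing.assert_allclose(empty, np.eye(4))

    rng = np.random.default_rng(0)
    V, _ = np.linalg.qr(rng.normal(size=(8, 3)))
    H = orthonormal_complement(V)
    assert np.abs(H.T @ V).max() < 1e-12
    assert np.linalg.matrix_rank(np.hstack([V, H])) == 8

    with pytest.raises(np.linalg.LinAlgError):
        orthonormal_complement(np.ones((4, 2)))
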