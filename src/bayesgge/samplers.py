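"""Random-variate generators and the Gibbs engine for the Bayesian GGE model.

The only nonstandard draw is the von Mises–Fisher one: each singular vector
lives on a unit sphere inside the orthogonal complement of its same-side
companions, so a draw is taken on that corrected subspace's sphere (Wood's
rejection scheme) and mapped back to the ambient space.  Truncated-normal
draws (the ordered singular values) use inverse-CDF sampling with log-space
tail handling so far-tail intervals remain exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .conditionals import (
    ComponentFrame,
    InvGammaSpec,
    ModelConfig,
    NormalSpec,
    ParamState,
    ScaledInvChi2Spec,
    TruncNormalSpec,
    VMFSpec,
    cond_beta,
    cond_lambda,
    cond_sigma_e,
    cond_sigma_lambda,
    cond_vector,
)
from .metdata import DesignSet, METTable, build_design, center_gge_matrix, svd_gge

__all__ = [
    "MCMCPlan",
    "Chain",
    "sample_vmf",
    "orthonormal_complement",
    "sample_trunc_normal",
    "sample_inv_gamma",
    "sample_scaled_inv_chi2",
    "gibbs_run",
    "loglik",
    "initial_state",
]


@dataclass(frozen=True)
class MCMCPlan:
    """Chain-length plan: keep ``n_keep`` draws thinned by ``J`` after ``B`` burn-in.

    The total number of Gibbs scans is N = n_keep·J + B.  The default mirrors
    the planning rule used with a 4000-draw pilot; ``from_pilot`` in
    :mod:`bayesgge.diagnostics` builds a plan from Raftery–Lewis output.
    """

    J: int = 1
    B: int = 10_000
    n_keep: int = 4000
    seed: int = 0
    pilot: int = 4000
    rl_q: float = 0.025
    rl_r: float = 0.005
    rl_s: float = 0.95
    i_max: float = 5.0
    hw_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.J < 1 or self.B < 0 or self.n_keep < 1:
            raise ValueError("need J >= 1, B >= 0, n_keep >= 1")

    @property
    def N(self) -> int:
        return self.n_keep * self.J + self.B


FAST_PLAN = MCMCPlan(J=1, B=1500, n_keep=4000)
"""Default working plan: the λ and variance chains of this model mix with
near-unit dependence factors, so 1500 burn-in scans and 4000 unthinned draws
pass the same Raftery–Lewis and effective-sample-size gates as the
conservative N = 4000·20 + 10000 schedule at a fraction of the cost."""


@dataclass
class Chain:
    """Thinned post-burn-in draws of all parameters, stored as arrays."""

    beta: np.ndarray          # (n_keep, b·l)
    lam: np.ndarray           # (n_keep, k)
    A: np.ndarray             # (n_keep, v, k)
    Gamma: np.ndarray         # (n_keep, l, k)
    sigma2_e: np.ndarray      # (n_keep,)
    sigma2_lam: np.ndarray | None   # (n_keep, k) entropy variant, else None
    loglik: np.ndarray        # (n_keep,)
    plan: MCMCPlan
    model: ModelConfig
    genotypes: list[str] = field(default_factory=list)
    environments: list[str] = field(default_factory=list)
    blocks: list[str] = field(default_factory=list)
    n_reortho: int = 0

    def __len__(self) -> int:
        return len(self.sigma2_e)

    def state(self, i: int) -> ParamState:
        return ParamState(
            beta=self.beta[i], lam=self.lam[i], A=self.A[i], Gamma=self.Gamma[i],
            sigma2_e=float(self.sigma2_e[i]),
            sigma2_lam=None if self.sigma2_lam is None else self.sigma2_lam[i],
        )

    def posterior_mean_state(self) -> ParamState:
        """Posterior means with A, Γ re-orthonormalized after averaging."""
        A = _gram_schmidt(self.A.mean(axis=0))
        G = _gram_schmidt(self.Gamma.mean(axis=0))
        return ParamState(
            beta=self.beta.mean(axis=0),
            lam=self.lam.mean(axis=0),
            A=A, Gamma=G,
            sigma2_e=float(self.sigma2_e.mean()),
            sigma2_lam=None if self.sigma2_lam is None else self.sigma2_lam.mean(axis=0),
        )

    def to_frame(self) -> pd.DataFrame:
        """One row per retained draw, one labelled column per scalar parameter."""
        k = self.lam.shape[1]
        cols: dict[str, np.ndarray] = {}
        envs = self.environments or [f"e{j}" for j in range(self.Gamma.shape[1])]
        gens = self.genotypes or [f"g{i}" for i in range(self.A.shape[1])]
        nb = self.beta.shape[1] // max(len(envs), 1)
        for j, env in enumerate(envs):
            for blk in range(nb):
                cols[f"beta[{env}:{blk + 1}]"] = self.beta[:, j * nb + blk]
        for kk in range(k):
            cols[f"lambda[{kk + 1}]"] = self.lam[:, kk]
        for i, gen in enumerate(gens):
            for kk in range(k):
                cols[f"alpha[{gen},{kk + 1}]"] = self.A[:, i, kk]
        for j, env in enumerate(envs):
            for kk in range(k):
                cols[f"gamma[{env},{kk + 1}]"] = self.Gamma[:, j, kk]
        cols["sigma2_e"] = self.sigma2_e
        if self.sigma2_lam is not None:
            for kk in range(k):
                cols[f"sigma2_lambda[{kk + 1}]"] = self.sigma2_lam[:, kk]
        cols["loglik"] = self.loglik
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# elementary samplers

def orthonormal_complement(V: np.ndarray, m: int | None = None) -> np.ndarray:
    """Orthonormal basis H of the complement of span(V): H'H = I, H'V = 0."""
    V = np.asarray(V, dtype=float)
    if V.ndim == 1:
        V = V[:, None]
    if m is None:
        m = V.shape[0]
    if V.shape[1] == 0:
        return np.eye(m)
    if np.linalg.matrix_rank(V) < V.shape[1]:
        raise np.linalg.LinAlgError("columns of V are linearly dependent")
    Q, _ = np.linalg.qr(V, mode="complete")
    return Q[:, V.shape[1]:]


def _uniform_sphere(m: int, rng: np.random.Generator) -> np.ndarray:
    x = rng.standard_normal(m)
    norm = np.linalg.norm(x)
    while norm == 0.0:           # pragma: no cover - measure-zero event
        x = rng.standard_normal(m)
        norm = np.linalg.norm(x)
    return x / norm


def _vmf_cosine(m: int, kappa: float, rng: np.random.Generator) -> float:
    """Cosine of the angle to the mean direction (Wood 1994 rejection)."""
    # rationalized form of (-2k + sqrt(4k^2 + (m-1)^2))/(m-1): stable at large kappa
    b = (m - 1.0) / (2.0 * kappa + np.sqrt(4.0 * kappa**2 + (m - 1.0) ** 2))
    x0 = (1.0 - b) / (1.0 + b)
    if x0 >= 1.0:            # kappa so large that the envelope degenerates
        return 1.0
    c = kappa * x0 + (m - 1.0) * np.log(1.0 - x0**2)
    while True:
        z = rng.beta(0.5 * (m - 1.0), 0.5 * (m - 1.0))
        w = (1.0 - (1.0 + b) * z) / (1.0 - (1.0 - b) * z)
        u = rng.uniform()
        if kappa * w + (m - 1.0) * np.log(1.0 - x0 * w) - c >= np.log(u):
            return float(w)


def sample_vmf(spec: VMFSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw from vMF(m, κ, μ) in the corrected subspace, mapped back by H.

    Returns an ambient-space unit vector orthogonal to the subspace's
    excluded directions.
    """
    m, kappa = spec.m, spec.kappa
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if m == 1:
        # sphere S^0 = {-1, +1}: p(x = sgn μ) = e^kappa / (e^kappa + e^-kappa)
        sign = np.sign(spec.mu[0]) or 1.0
        p_plus = special.expit(2.0 * kappa)
        s = np.array([sign if rng.uniform() < p_plus else -sign])
    elif kappa == 0.0:
        s = _uniform_sphere(m, rng)
    else:
        w = _vmf_cosine(m, kappa, rng)
        # tangent direction uniform on the (m-1)-sphere orthogonal to mu
        v = rng.standard_normal(m)
        v -= (v @ spec.mu) * spec.mu
        nv = np.linalg.norm(v)
        if nv == 0.0:            # pragma: no cover - measure-zero event
            s = w * spec.mu
        else:
            s = w * spec.mu + np.sqrt(max(0.0, 1.0 - w * w)) * v / nv
        s /= np.linalg.norm(s)
    return spec.basis @ s


def sample_trunc_normal(spec: TruncNormalSpec, rng: np.random.Generator) -> float:
    """Inverse-CDF draw from N(loc, scale²) restricted to [lower, upper].

    Far-tail intervals are handled in log probability space (log_ndtr /
    ndtri_exp), so even intervals like [8σ, 9σ] give finite in-range draws.
    """
    if spec.lower > spec.upper:
        raise ValueError("lower > upper")
    if spec.lower == spec.upper:
        return float(spec.lower)
    scale = np.sqrt(spec.scale2)
    a = (spec.lower - spec.loc) / scale
    b = (spec.upper - spec.loc) / scale
    u = rng.uniform()
    if a >= 0:                   # right tail: work with the survival function
        z = -_tail_quantile(-b, -a, u)
    elif b <= 0:                 # left tail, mirrored
        z = _tail_quantile(a, b, 1.0 - u)
    else:
        pa, pb = special.ndtr(a), special.ndtr(b)
        z = special.ndtri(pa + u * (pb - pa))
    return float(spec.loc + scale * z)


def _tail_quantile(lo: float, hi: float, u: float) -> float:
    """Quantile of N(0,1) restricted to [lo, hi] with hi <= 0, via log CDFs."""
    llo = special.log_ndtr(lo)   # may be -inf (e.g. lower bound -inf)
    lhi = special.log_ndtr(hi)
    if llo == -np.inf:
        logp = lhi + np.log(u)
    else:
        logp = lhi + np.log1p(-(1.0 - u) * -np.expm1(llo - lhi))
    return float(special.ndtri_exp(logp))


def sample_inv_gamma(spec: InvGammaSpec, rng: np.random.Generator) -> float:
    """Inverse-gamma draw: scale / Gamma(shape, 1)."""
    return float(spec.scale / rng.gamma(spec.shape))


def sample_scaled_inv_chi2(spec: ScaledInvChi2Spec, rng: np.random.Generator) -> float:
    """Scaled inverse-χ² draw: df·scale / χ²_df."""
    return float(spec.df * spec.scale / rng.chisquare(spec.df))


def sample_normal(spec: NormalSpec, rng: np.random.Generator) -> np.ndarray:
    return spec.mean + spec.cov_factor @ rng.standard_normal(len(spec.mean))


# ---------------------------------------------------------------------------
# likelihood and initialization

def loglik(state: ParamState, met: METTable, design: DesignSet,
           frame: ComponentFrame | None = None) -> float:
    """Gaussian log-likelihood −(n/2)log(2πσ²e) − ‖y − μy‖²/(2σ²e)."""
    if state.sigma2_e <= 0:
        raise ValueError("sigma2_e must be positive")
    frame = frame or ComponentFrame.from_state(state, design)
    resid = met.y - frame.mu_y
    n = met.n
    return float(
        -0.5 * n * np.log(2.0 * np.pi * state.sigma2_e)
        - resid @ resid / (2.0 * state.sigma2_e)
    )


def _gram_schmidt(M: np.ndarray) -> np.ndarray:
    """Column-sequential orthonormalization preserving each column's direction."""
    Q = M.astype(float).copy()
    for j in range(Q.shape[1]):
        for i in range(j):
            Q[:, j] -= (Q[:, i] @ Q[:, j]) * Q[:, i]
        norm = np.linalg.norm(Q[:, j])
        if norm < 1e-12:
            raise np.linalg.LinAlgError("degenerate column during re-orthonormalization")
        Q[:, j] /= norm
    return Q


def initial_state(met: METTable, design: DesignSet, model: ModelConfig) -> ParamState:
    """SVD-based start: bilinear part from the centered cell-mean matrix,
    β from block-within-environment means, σ²e from the residual variance.

    Missing cells are filled with zero after centering — for initialization
    only; the sampler itself never imputes.
    """
    k = model.k
    means = (
        met.records.groupby(["genotype", "environment"], observed=True)["response"]
        .mean()
        .unstack()
        .reindex(index=met.genotypes, columns=met.environments)
        .to_numpy()
    )
    col_mean = np.nanmean(means, axis=0, keepdims=True)
    centered = np.nan_to_num(means - col_mean)
    lam, A, Gamma = svd_gge(centered, t=min(met.t, k))
    if len(lam) < k:             # pad with zero components on arbitrary axes
        extra = k - len(lam)
        HA = orthonormal_complement(A, met.v)[:, :extra]
        HG = orthonormal_complement(Gamma, met.l)[:, :extra]
        A = np.hstack([A, HA])
        Gamma = np.hstack([Gamma, HG])
        lam = np.concatenate([lam, np.zeros(extra)])
    beta = np.zeros(met.b * met.l)
    counts = np.bincount(design.be_idx, minlength=len(beta)).astype(float)
    sums = np.bincount(design.be_idx, weights=met.y, minlength=len(beta))
    overall = met.y.mean()
    beta = np.where(counts > 0, sums / np.maximum(counts, 1.0), overall)
    state = ParamState(
        beta=beta, lam=lam, A=A, Gamma=Gamma, sigma2_e=1.0,
        sigma2_lam=(np.full(k, model.sigma2_lambda_flat)
                    if model.variant == "entropy" else None),
    )
    frame = ComponentFrame.from_state(state, design)
    resid = met.y - frame.mu_y
    state.sigma2_e = float(max(resid @ resid / max(met.n - 1, 1), 1e-8))
    return state


# ---------------------------------------------------------------------------
# the Gibbs engine

def gibbs_run(met: METTable, model: ModelConfig, plan: MCMCPlan | None = None,
              design: DesignSet | None = None) -> Chain:
    """Systematic-scan Gibbs sampler for the GGE model.

    Scan order: β → {for each component k: λ_k, (entropy: σ²_λk), α_k, γ_k}
    → σ²_e, using freshly updated values within the scan.  The order
    constraint on λ is maintained through the truncation bounds; every
    retained draw stores the data log-likelihood.  Deterministic given
    ``plan.seed``.
    """
    plan = plan or FAST_PLAN
    design = design or build_design(met)
    if model.k > met.t:
        raise ValueError(f"k={model.k} exceeds the maximal bilinear rank t={met.t}")
    rng = np.random.default_rng(plan.seed)
    state = initial_state(met, design, model)
    k = model.k
    entropy = model.variant == "entropy"

    n_keep = plan.n_keep
    out_beta = np.empty((n_keep, len(state.beta)))
    out_lam = np.empty((n_keep, k))
    out_A = np.empty((n_keep, met.v, k))
    out_G = np.empty((n_keep, met.l, k))
    out_s2e = np.empty(n_keep)
    out_s2l = np.empty((n_keep, k)) if entropy else None
    out_ll = np.empty(n_keep)
    n_reortho = 0

    kept = 0
    for it in range(plan.N):
        frame = ComponentFrame.from_state(state, design)
        state.beta = sample_normal(cond_beta(state, met, design, model, frame), rng)
        beta_fit = state.beta[design.be_idx]
        for kk in range(k):
            frame = ComponentFrame.from_state(state, design)
            state.lam[kk] = sample_trunc_normal(
                cond_lambda(state, met, design, model, kk, frame), rng
            )
            if entropy:
                state.sigma2_lam[kk] = sample_inv_gamma(
                    cond_sigma_lambda(state, model, kk), rng
                )
            state.A[:, kk] = sample_vmf(
                cond_vector(state, met, design, model, kk, "genotypic"), rng
            )
            state.Gamma[:, kk] = sample_vmf(
                cond_vector(state, met, design, model, kk, "environmental"), rng
            )
        frame = ComponentFrame.from_state(state, design)
        state.sigma2_e = sample_scaled_inv_chi2(
            cond_sigma_e(state, met, design, frame), rng
        )

        if (it + 1) % 1000 == 0:
            drift = max(
                np.abs(state.A.T @ state.A - np.eye(k)).max(),
                np.abs(state.Gamma.T @ state.Gamma - np.eye(k)).max(),
            )
            if drift > 1e-6:
                state.A = _gram_schmidt(state.A)
                state.Gamma = _gram_schmidt(state.Gamma)
                n_reortho += 1

        if it >= plan.B and (it - plan.B) % plan.J == 0 and kept < n_keep:
            ll = loglik(state, met, design, frame)
            if not np.isfinite(ll):
                raise FloatingPointError(
                    f"non-finite log-likelihood at iteration {it}: state={state}"
                )
            out_beta[kept] = state.beta
            out_lam[kept] = state.lam
            out_A[kept] = state.A
            out_G[kept] = state.Gamma
            out_s2e[kept] = state.sigma2_e
            if entropy:
                out_s2l[kept] = state.sigma2_lam
            out_ll[kept] = ll
            kept += 1

    return Chain(
        beta=out_beta[:kept], lam=out_lam[:kept], A=out_A[:kept],
        Gamma=out_G[:kept], sigma2_e=out_s2e[:kept],
        sigma2_lam=None if out_s2l is None else out_s2l[:kept],
        loglik=out_ll[:kept], plan=plan, model=model,
        genotypes=list(met.genotypes), environments=list(met.environments),
        blocks=list(met.blocks), n_reortho=n_reortho,
    )
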