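"""Full-conditional posterior distributions of the Bayesian GGE model.

The model is

    y = X1 β + Σ_k λ_k diag(Z α_k) X2 γ_k + ε,     ε ~ N(0, σ²_e I),

with priors β ~ N(0, σ²_β I), λ_k ~ N+(0, σ²_λk) subject to the order
λ1 ≥ … ≥ λt ≥ 0, singular vectors uniform on spheres in corrected
(mutually orthogonal) subspaces, and Jeffreys p(σ²_e) ∝ 1/σ²_e.

Two prior regimes differ only in σ²_λk: the flat variant fixes it at 1e8
(posteriors essentially maximum-likelihood); the entropy variant places a
maximum-entropy-derived inverse-gamma hyperprior on it, whose conditional
update IG(2, λ_k²) shrinks weakly supported singular values toward zero.

Every function here returns an inert, fully parameterized distribution
spec; random draws happen in :mod:`bayesgge.samplers`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metdata import DesignSet, METTable

__all__ = [
    "ModelConfig",
    "ParamState",
    "ComponentFrame",
    "NormalSpec",
    "TruncNormalSpec",
    "InvGammaSpec",
    "ScaledInvChi2Spec",
    "VMFSpec",
    "cond_beta",
    "cond_lambda",
    "cond_sigma_lambda",
    "cond_vector",
    "cond_sigma_e",
]

FLAT, ENTROPY = "flat", "entropy"


@dataclass(frozen=True)
class ModelConfig:
    """Prior regime and bilinear dimension of one fit.

    ``variant`` is ``"flat"`` (BGGE) or ``"entropy"`` (BGGEE); ``k`` is the
    number of bilinear components retained (1..t).  ``sigma2_lambda_floor``
    keeps the λ conditional proper when a shrunk λ_k hits zero.
    """

    variant: str = ENTROPY
    k: int = 2
    sigma2_beta: float = 1e8
    sigma2_lambda_flat: float = 1e8
    a: float = 1.0
    b_scale: float = 0.0
    sigma2_lambda_floor: float = 1e-12

    def __post_init__(self) -> None:
        if self.variant not in (FLAT, ENTROPY):
            raise ValueError(f"variant must be 'flat' or 'entropy', got {self.variant!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class ParamState:
    """One draw of all model parameters."""

    beta: np.ndarray          # length b·l
    lam: np.ndarray           # length k, nonincreasing, nonnegative
    A: np.ndarray             # v×k, orthonormal columns (genotypic vectors)
    Gamma: np.ndarray         # l×k, orthonormal columns (environmental vectors)
    sigma2_e: float
    sigma2_lam: np.ndarray = field(default=None)  # length k (entropy variant)

    def copy(self) -> "ParamState":
        return ParamState(
            beta=self.beta.copy(),
            lam=self.lam.copy(),
            A=self.A.copy(),
            Gamma=self.Gamma.copy(),
            sigma2_e=float(self.sigma2_e),
            sigma2_lam=None if self.sigma2_lam is None else self.sigma2_lam.copy(),
        )

    def check(self, atol: float = 1e-8) -> None:
        k = len(self.lam)
        if np.any(np.diff(self.lam) > atol) or np.any(self.lam < -atol):
            raise ValueError("lambda must be nonincreasing and nonnegative")
        for M, name in ((self.A, "A"), (self.Gamma, "Gamma")):
            if not np.allclose(M.T @ M, np.eye(k), atol=atol):
                raise ValueError(f"{name} columns are not orthonormal")


# ---------------------------------------------------------------------------
# distribution specs

@dataclass(frozen=True)
class NormalSpec:
    mean: np.ndarray
    cov_factor: np.ndarray    # lower Cholesky factor of the covariance

    def logpdf(self, x: np.ndarray) -> float:
        L = self.cov_factor
        z = np.linalg.solve(L, np.asarray(x) - self.mean)
        return float(
            -0.5 * z @ z
            - np.log(np.diag(L)).sum()
            - 0.5 * len(self.mean) * np.log(2 * np.pi)
        )


@dataclass(frozen=True)
class TruncNormalSpec:
    loc: float
    scale2: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower > upper")
        if self.scale2 <= 0:
            raise ValueError("nonpositive scale2")

    def logpdf(self, x: float) -> float:
        from scipy import stats

        s = np.sqrt(self.scale2)
        a = (self.lower - self.loc) / s
        b = (self.upper - self.loc) / s
        return float(stats.truncnorm.logpdf(x, a, b, loc=self.loc, scale=s))


@dataclass(frozen=True)
class InvGammaSpec:
    shape: float
    scale: float

    def logpdf(self, x: float) -> float:
        from scipy import stats

        return float(stats.invgamma.logpdf(x, self.shape, scale=self.scale))


@dataclass(frozen=True)
class ScaledInvChi2Spec:
    df: float
    scale: float

    def logpdf(self, x: float) -> float:
        from scipy import stats

        # scaled-inv-chi2(df, s) is IG(df/2, df*s/2)
        return float(stats.invgamma.logpdf(x, self.df / 2.0, scale=self.df * self.scale / 2.0))


@dataclass(frozen=True)
class VMFSpec:
    """von Mises–Fisher law on the unit sphere of a corrected subspace.

    ``basis`` H (ambient × m) maps subspace coordinates back to the ambient
    space; ``mu`` is the unit mean direction in subspace coordinates and
    ``kappa`` the concentration.  ``p`` counts the other same-side vectors
    excluded from the subspace.
    """

    m: int
    kappa: float
    mu: np.ndarray
    basis: np.ndarray
    k: int
    p: int

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.kappa > 0 and abs(np.linalg.norm(self.mu) - 1.0) > 1e-8:
            raise ValueError("mean direction must have unit norm")

    def logpdf(self, x: np.ndarray) -> float:
        """Normalized vMF log-density at an ambient-space unit vector."""
        from scipy import special

        s = self.basis.T @ np.asarray(x, dtype=float)
        m, kappa = self.m, self.kappa
        log_sphere = np.log(2.0) + 0.5 * m * np.log(np.pi) - special.gammaln(0.5 * m)
        if kappa == 0.0:
            return float(-log_sphere)
        nu = 0.5 * m - 1.0
        # log C = nu*log(kappa) - (m/2)log(2*pi) - log I_nu(kappa), via ive
        log_c = (
            nu * np.log(kappa)
            - 0.5 * m * np.log(2.0 * np.pi)
            - (np.log(special.ive(nu, kappa)) + kappa)
        )
        return float(log_c + kappa * (self.mu @ s))


# ---------------------------------------------------------------------------
# component bookkeeping

@dataclass
class ComponentFrame:
    """Per-record bilinear terms Λ_k = diag(Zα_k)X2γ_k and their sums."""

    Lambda: np.ndarray        # n×k, column k = Λ_k
    M: np.ndarray             # full bilinear fit Σ_k λ_k Λ_k
    mu_y: np.ndarray          # X1β + M

    @classmethod
    def from_state(cls, state: ParamState, design: DesignSet) -> "ComponentFrame":
        # Λ_k[row] = α_k[g(row)] * γ_k[e(row)] — avoids forming diag(Zα)X2
        Lam = state.A[design.g_idx, :] * state.Gamma[design.e_idx, :]
        M = Lam @ state.lam
        mu_y = state.beta[design.be_idx] + M
        return cls(Lambda=Lam, M=M, mu_y=mu_y)

    def partial_residual(self, y: np.ndarray, beta_fit: np.ndarray,
                         lam: np.ndarray, k: int) -> np.ndarray:
        """M'_k = y − X1β − Σ_{k'≠k} λ_k' Λ_k'."""
        return y - beta_fit - (self.M - lam[k] * self.Lambda[:, k])


# ---------------------------------------------------------------------------
# conditionals

def cond_beta(state: ParamState, met: METTable, design: DesignSet,
              cfg: ModelConfig, frame: ComponentFrame | None = None) -> NormalSpec:
    """β | rest ~ N((X1'X1 + (σ²e/σ²β)I)⁻¹ X1'(y − M), (X1'X1 + (σ²e/σ²β)I)⁻¹σ²e).

    X1 is an incidence matrix, so X1'X1 is diagonal (per-cell record counts)
    and the solve is elementwise.
    """
    frame = frame or ComponentFrame.from_state(state, design)
    y = met.y
    counts = np.bincount(design.be_idx, minlength=len(state.beta)).astype(float)
    prec = counts + state.sigma2_e / cfg.sigma2_beta
    if np.any(prec <= 0):
        empty = np.flatnonzero(counts == 0)
        raise np.linalg.LinAlgError(
            f"X1 is rank deficient (no records for β index {empty.tolist()}) "
            "and the prior variance is effectively infinite"
        )
    resid = y - frame.M
    xty = np.bincount(design.be_idx, weights=resid, minlength=len(state.beta))
    mean = xty / prec
    cov_factor = np.diag(np.sqrt(state.sigma2_e / prec))
    return NormalSpec(mean=mean, cov_factor=cov_factor)


def cond_lambda(state: ParamState, met: METTable, design: DesignSet,
                cfg: ModelConfig, k: int,
                frame: ComponentFrame | None = None) -> TruncNormalSpec:
    """λ_k | rest: normal in the partial residual, truncated to keep the order."""
    frame = frame or ComponentFrame.from_state(state, design)
    sigma2_lam = (
        cfg.sigma2_lambda_flat if state.sigma2_lam is None else state.sigma2_lam[k]
    )
    Lk = frame.Lambda[:, k]
    mk = frame.partial_residual(met.y, state.beta[design.be_idx], state.lam, k)
    prec = Lk @ Lk + state.sigma2_e / sigma2_lam
    loc = (Lk @ mk) / prec
    scale2 = state.sigma2_e / prec
    lower = state.lam[k + 1] if k + 1 < len(state.lam) else 0.0
    upper = state.lam[k - 1] if k > 0 else np.inf
    return TruncNormalSpec(loc=float(loc), scale2=float(scale2),
                           lower=float(lower), upper=float(upper))


def cond_sigma_lambda(state: ParamState, cfg: ModelConfig, k: int) -> InvGammaSpec:
    """σ²_λk | rest ~ IG(a + 1/2, b + λ_k²/2); IG(3/2, λ_k²/2) at a=1, b=0.

    This is the exact conditional of the maximum-entropy hierarchy
    p(σ²) ∝ σ^(−2(a+1)) e^(−b/σ²) with λ | σ² half-normal: the IG(a+1, λ²+2b)
    form sometimes quoted for this update has the same conditional mean (λ²
    at b = 0) but is not proportional to the joint posterior.  The scale is
    floored so a fully shrunk λ_k = 0 cannot make the next λ conditional
    improper (the chain would otherwise absorb at zero).
    """
    if cfg.variant != ENTROPY:
        raise ValueError("sigma2_lambda is only sampled under the entropy variant")
    scale = 0.5 * state.lam[k] ** 2 + cfg.b_scale
    return InvGammaSpec(shape=cfg.a + 0.5, scale=max(scale, cfg.sigma2_lambda_floor))


def _orthonormal_complement_of_others(V: np.ndarray, k: int) -> np.ndarray:
    """Basis of the orthogonal complement of all columns of V except column k."""
    others = np.delete(V, k, axis=1)
    m = V.shape[0]
    if others.shape[1] == 0:
        return np.eye(m)
    # complement via full QR of the other columns
    Q, _ = np.linalg.qr(others, mode="complete")
    return Q[:, others.shape[1]:]


def cond_vector(state: ParamState, met: METTable, design: DesignSet,
                cfg: ModelConfig, k: int, side: str) -> VMFSpec:
    """Singular vector α_k or γ_k | rest, as a vMF law in the corrected subspace.

    The raw direction is Λ*'(y − X1β) with Λ* = diag(X2γ_k)Z (genotypic) or
    diag(Zα_k)X2 (environmental); projecting it on the orthogonal complement
    H of the other same-side vectors gives the subspace mean direction, with
    concentration ‖H'μ‖·λ_k/σ²_e.
    """
    y_corr = met.y - state.beta[design.be_idx]
    if side == "genotypic":
        weights = state.Gamma[design.e_idx, k] * y_corr
        mu_raw = np.bincount(design.g_idx, weights=weights, minlength=met.v)
        H = _orthonormal_complement_of_others(state.A, k)
    elif side == "environmental":
        weights = state.A[design.g_idx, k] * y_corr
        mu_raw = np.bincount(design.e_idx, weights=weights, minlength=met.l)
        H = _orthonormal_complement_of_others(state.Gamma, k)
    else:
        raise ValueError("side must be 'genotypic' or 'environmental'")
    h = H.T @ mu_raw
    norm = np.linalg.norm(h)
    m = H.shape[1]
    if norm == 0.0 or state.lam[k] == 0.0:
        mu = np.zeros(m)
        mu[0] = 1.0
        kappa = 0.0
    else:
        mu = h / norm
        kappa = norm * state.lam[k] / state.sigma2_e
    return VMFSpec(m=m, kappa=float(kappa), mu=mu, basis=H, k=k, p=state.A.shape[1] - 1)


def cond_sigma_e(state: ParamState, met: METTable, design: DesignSet,
                 frame: ComponentFrame | None = None) -> ScaledInvChi2Spec:
    """σ²_e | rest ~ scaled-inv-χ²(n, SSE/n) under the Jeffreys prior."""
    frame = frame or ComponentFrame.from_state(state, design)
    resid = met.y - frame.mu_y
    n = met.n
    return ScaledInvChi2Spec(df=float(n), scale=float(resid @ resid / n))
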