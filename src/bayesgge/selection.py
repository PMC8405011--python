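"""Model selection for the bilinear dimension k.

AIC/BIC are evaluated at the posterior-mean parameters with a free-parameter
count of b·l (linear terms) + k(v + l − k) (free parameters of a rank-k SVD)
+ 1 (residual variance).  AICM works from the posterior log-likelihood draws
alone.  The information rate IR_k = λ_k²/(Σλ²/t) flags axes carrying more
than an average share of the G+GE sum of squares (keep while IR_k > 1), and
variance shares λ_k²/Σλ² report the explained fractions directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .conditionals import ModelConfig
from .metdata import DesignSet, METTable
from .samplers import Chain, loglik

__all__ = [
    "SelectionRow",
    "information_rate",
    "variance_share",
    "aic_bic",
    "aicm",
    "posterior_mode",
    "sigma_profile",
    "selection_table",
    "bilinear_df",
]


@dataclass(frozen=True)
class SelectionRow:
    k: int
    aic: float
    bic: float
    aicm: float
    sigma2_e_mode: float
    shares: np.ndarray


def information_rate(lam: np.ndarray, t: int) -> np.ndarray:
    """IR_k = λ_k² / (Σ_k λ_k² / t); IR_k > 1 means axis k is informative."""
    lam = np.asarray(lam, dtype=float)
    ss = lam @ lam
    if ss == 0:
        raise ValueError("all singular values are zero")
    return lam**2 / (ss / t)


def variance_share(lam: np.ndarray) -> np.ndarray:
    """Proportion of the G+GE sum of squares carried by each axis."""
    lam = np.asarray(lam, dtype=float)
    ss = lam @ lam
    if ss == 0:
        raise ValueError("all singular values are zero")
    return lam**2 / ss


def bilinear_df(v: int, l: int, b: int, k: int) -> int:
    """Free-parameter count: b·l linear + k(v+l−k) bilinear + 1 variance."""
    return b * l + k * (v + l - k) + 1


def aic_bic(chain: Chain, met: METTable, design: DesignSet,
            model: ModelConfig) -> tuple[float, float]:
    """Plug-in AIC/BIC at the posterior means (lower is better)."""
    state = chain.posterior_mean_state()
    ll = loglik(state, met, design)
    df = bilinear_df(met.v, met.l, met.b, model.k)
    aic = -2.0 * ll + 2.0 * df
    bic = -2.0 * ll + df * np.log(met.n)
    return float(aic), float(bic)


def aicm(loglik_draws: np.ndarray) -> float:
    """Akaike–Monte-Carlo criterion 2·s²_ℓ − 2·ℓ̄ from log-likelihood draws."""
    ll = np.asarray(loglik_draws, dtype=float)
    if len(ll) < 2:
        raise ValueError("need at least 2 log-likelihood draws")
    return float(2.0 * ll.var(ddof=1) - 2.0 * ll.mean())


def posterior_mode(draws: np.ndarray) -> float:
    """Kernel-density posterior mode of a scalar sample."""
    draws = np.asarray(draws, dtype=float)
    if np.ptp(draws) == 0:
        return float(draws[0])
    kde = stats.gaussian_kde(draws)
    grid = np.linspace(draws.min(), draws.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def sigma_profile(chains: dict[int, Chain]) -> pd.Series:
    """Posterior mode of σ²_e per bilinear dimension k (stabilizes once the
    retained axes capture all signal)."""
    return pd.Series(
        {k: posterior_mode(c.sigma2_e) for k, c in sorted(chains.items())},
        name="sigma2_e_mode",
    )


def selection_table(chains: dict[int, Chain], met: METTable,
                    design: DesignSet) -> pd.DataFrame:
    """One SelectionRow per fitted k, as a tidy frame."""
    rows = []
    for k, chain in sorted(chains.items()):
        aic, bic = aic_bic(chain, met, design, chain.model)
        lam_mean = chain.lam.mean(axis=0)
        rows.append({
            "k": k,
            "AIC": aic,
            "BIC": bic,
            "AICM": aicm(chain.loglik),
            "sigma2_e_mode": posterior_mode(chain.sigma2_e),
            "share_first_two": float(variance_share(lam_mean)[: 2].sum())
            if k >= 2 else float(variance_share(lam_mean)[0]),
        })
    return pd.DataFrame(rows)
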