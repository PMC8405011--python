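"""Single-chain MCMC diagnostics: Raftery–Lewis, Heidelberger–Welch, ESS.

These are implemented from the original procedures rather than delegated, so
chain-length planning is self-contained and reproducible: the Raftery–Lewis
dependence factor I drives the thinning interval, with the acceptance rule
I < 5 and effective sample size > 4000.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RafteryLewisResult",
    "HeidelbergerWelchResult",
    "raftery_lewis",
    "heidelberger_welch",
    "ess",
    "plan_run",
    "spectrum0_ar",
]


@dataclass(frozen=True)
class RafteryLewisResult:
    burn_in: int
    n_required: int
    n_min: int
    dependence_factor: float
    thin: int

    def passes(self, i_max: float = 5.0) -> bool:
        return self.dependence_factor < i_max


@dataclass(frozen=True)
class HeidelbergerWelchResult:
    stationarity: bool
    kept_fraction: float
    start: int
    mean: float
    halfwidth: float
    halfwidth_pass: bool


def _markov_bic(z: np.ndarray) -> float:
    """BIC of a 2nd- vs 1st-order Markov fit to a binary chain (G² − 2 log n)."""
    n = len(z) - 2
    code = 4 * z[:-2] + 2 * z[1:-1] + z[2:]
    counts = np.bincount(code, minlength=8).reshape(2, 2, 2).astype(float)
    g2 = 0.0
    for i in range(2):
        for j in range(2):
            for k in range(2):
                obs = counts[i, j, k]
                if obs == 0:
                    continue
                expected = counts[i, j, :].sum() * counts[:, j, k].sum() / max(
                    counts[:, j, :].sum(), 1.0
                )
                g2 += 2.0 * obs * np.log(obs / expected)
    return g2 - 2.0 * np.log(n)


def raftery_lewis(series: np.ndarray, q: float = 0.025, r: float = 0.005,
                  s: float = 0.95, eps: float = 0.001) -> RafteryLewisResult:
    """Raftery–Lewis run-length control for estimating the q-quantile to ±r.

    Dichotomizes the chain at its empirical q-quantile, finds the smallest
    thinning at which the indicator chain is first-order Markov (BIC), and
    sizes burn-in and run length from the fitted transition probabilities.
    """
    series = np.asarray(series, dtype=float)
    phi = stats.norm.ppf(0.5 * (1.0 + s))
    n_min = int(np.ceil(q * (1.0 - q) * phi**2 / r**2))
    if len(series) < n_min:
        raise ValueError(
            f"pilot too short for (q={q}, r={r}, s={s}): "
            f"need at least {n_min} draws, got {len(series)}"
        )
    u = np.quantile(series, q)
    z_full = (series <= u).astype(int)

    thin = 1
    while True:
        z = z_full[::thin]
        if len(z) < 8 or _markov_bic(z) <= 0:
            break
        thin += 1
    z = z_full[::thin]
    trans = np.bincount(2 * z[:-1] + z[1:], minlength=4).reshape(2, 2).astype(float)
    row = trans.sum(axis=1)
    alpha = trans[0, 1] / row[0] if row[0] > 0 else 0.5   # P(0 -> 1)
    beta = trans[1, 0] / row[1] if row[1] > 0 else 0.5    # P(1 -> 0)
    ab = alpha + beta
    if ab <= 0 or alpha <= 0 or beta <= 0:
        burn, n_req = 0, n_min
    else:
        lam2 = abs(1.0 - ab)
        m_star = (
            0 if lam2 == 0
            else int(np.ceil(np.log(eps * ab / max(alpha, beta)) / np.log(lam2)))
        )
        burn = thin * max(m_star, 0)
        n_keep = int(np.ceil(alpha * beta * (2.0 - ab) / ab**3 * (phi / r) ** 2))
        n_req = thin * n_keep
    total = burn + n_req
    return RafteryLewisResult(
        burn_in=burn, n_required=total, n_min=n_min,
        dependence_factor=total / n_min, thin=thin,
    )


def spectrum0_ar(series: np.ndarray, max_order: int | None = None) -> float:
    """Spectral density at frequency zero via an AIC-selected AR fit."""
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    n = len(x)
    var = x @ x / n
    if var == 0:
        return 0.0
    if max_order is None:
        max_order = min(int(10 * np.log10(n)), n // 4, 30)
    acov = np.array([x[: n - k] @ x[k:] / n for k in range(max_order + 1)])
    best_s0, best_aic = var, n * np.log(var)
    # Levinson-Durbin recursion, tracking AIC per order
    a = np.zeros(max_order + 1)
    err = acov[0]
    for m in range(1, max_order + 1):
        k = (acov[m] - a[1:m] @ acov[m - 1:0:-1]) / err
        a_new = a.copy()
        a_new[m] = k
        a_new[1:m] = a[1:m] - k * a[m - 1:0:-1]
        a = a_new
        err *= 1.0 - k * k
        if err <= 0:
            break
        aic = n * np.log(err) + 2.0 * m
        if aic < best_aic:
            best_aic = aic
            best_s0 = err / (1.0 - a[1:m + 1].sum()) ** 2
    return float(best_s0)


def heidelberger_welch(series: np.ndarray, alpha: float = 0.05,
                       halfwidth_eps: float = 0.1) -> HeidelbergerWelchResult:
    """Heidelberger–Welch stationarity (Cramér–von Mises) and halfwidth tests.

    The CvM statistic of the standardized Brownian bridge of partial sums is
    compared to its asymptotic critical value; on failure the first 10% of
    the chain is discarded and the test repeated, up to half the chain.
    """
    series = np.asarray(series, dtype=float)
    n0 = len(series)
    if n0 < 100:
        raise ValueError("need at least 100 draws")
    # asymptotic CvM critical values (interpolated on standard alphas)
    crit_table = {0.10: 0.34730, 0.05: 0.46136, 0.025: 0.58061, 0.01: 0.74346}
    crit = crit_table.get(round(alpha, 4)) or float(
        np.interp(alpha, sorted(crit_table), [crit_table[a] for a in sorted(crit_table)])
    )
    if np.ptp(series) == 0.0:
        return HeidelbergerWelchResult(True, 1.0, 0, float(series[0]), 0.0, True)

    start = 0
    stationary = False
    for frac in range(5):            # keep >= 50% of the chain
        x = series[start:]
        n = len(x)
        s0 = spectrum0_ar(x)
        if s0 <= 0:
            stationary = True
            break
        csum = np.cumsum(x)
        t = np.arange(1, n + 1)
        bridge = (csum - t * x.mean()) / np.sqrt(n * s0)
        cvm = float(np.sum(bridge[:-1] ** 2) / n)
        if cvm < crit:
            stationary = True
            break
        start += n0 // 10
    x = series[start:]
    s0 = spectrum0_ar(x)
    mean = float(x.mean())
    half = float(stats.norm.ppf(1.0 - alpha / 2.0) * np.sqrt(s0 / len(x)))
    hw_pass = bool(mean == 0.0 and half == 0.0 or
                   (mean != 0.0 and abs(half / mean) < halfwidth_eps))
    return HeidelbergerWelchResult(
        stationarity=stationary,
        kept_fraction=len(x) / n0,
        start=start,
        mean=mean,
        halfwidth=half,
        halfwidth_pass=hw_pass,
    )


def ess(series: np.ndarray) -> float:
    """Effective sample size via the initial-monotone-sequence estimator.

    Sums autocovariances in adjacent pairs until a pair goes nonpositive,
    enforcing monotone decay; the result is capped at the chain length.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 draws")
    x = x - x.mean()
    var = x @ x / n
    if var == 0:
        return float(n)
    max_lag = n - 2
    acf = np.array([x[: n - k] @ x[k:] / n for k in range(max_lag + 1)]) / var
    # Geyer initial monotone positive sequence over pair sums
    pair_sums = []
    for k in range(0, max_lag, 2):
        ps = acf[k] + acf[k + 1]
        if ps <= 0:
            break
        pair_sums.append(ps)
    for i in range(1, len(pair_sums)):
        pair_sums[i] = min(pair_sums[i], pair_sums[i - 1])
    tau = max(2.0 * sum(pair_sums) - 1.0, 1.0 / n)
    return float(min(n / tau, n))


def plan_run(pilot_results: dict[str, RafteryLewisResult],
             b_floor: int = 10_000, n_keep: int = 4000, seed: int = 0):
    """Build an MCMC plan from per-parameter pilot Raftery–Lewis results.

    J is the maximal dependence-driven thinning over the monitored
    parameters (rounded up), B the larger of the maximal RL burn-in and the
    floor, and the total run N = n_keep·J + B.
    """
    from .samplers import MCMCPlan

    if not pilot_results:
        raise ValueError("no pilot results supplied")
    J = max(max(int(np.ceil(r.dependence_factor)), r.thin, 1)
            for r in pilot_results.values())
    B = max(max(r.burn_in for r in pilot_results.values()), b_floor)
    return MCMCPlan(J=J, B=B, n_keep=n_keep, seed=seed)
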