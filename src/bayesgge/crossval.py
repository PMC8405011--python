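"""Random k-fold cross-validation with PRESS and predictive correlation.

Records (individual genotype–environment–block plots) are removed at
random: 10-fold, 3-fold and 2-fold correspond to 10%, 33% and 50% removal.
Each fold is predicted from a model refit on the complement, with the
held-out cell's mean surface Rao–Blackwellized over the retained draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conditionals import ModelConfig
from .metdata import METTable, build_design, met_from_frame
from .samplers import Chain, MCMCPlan, gibbs_run

__all__ = ["CVResult", "make_folds", "predict_cells", "press", "cor_pred", "run_cv"]

CV_PLAN = MCMCPlan(J=1, B=500, n_keep=1000)
"""Per-fold refit plan; shorter than a headline fit since only the posterior
mean surface is needed per fold."""


@dataclass
class CVResult:
    """Per-fold PRESS/COR plus their means and standard deviations."""

    n_folds: int
    fold_press: np.ndarray
    fold_cor: np.ndarray
    n_skipped: int = 0
    variant: str = ""

    @property
    def press_mean(self) -> float:
        return float(np.mean(self.fold_press))

    @property
    def press_sd(self) -> float:
        return float(np.std(self.fold_press, ddof=1)) if self.n_folds > 1 else 0.0

    @property
    def cor_mean(self) -> float:
        return float(np.nanmean(self.fold_cor))

    @property
    def cor_sd(self) -> float:
        return float(np.nanstd(self.fold_cor, ddof=1)) if self.n_folds > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fold": np.arange(1, self.n_folds + 1),
            "PRESS": self.fold_press,
            "COR": self.fold_cor,
        })


def make_folds(met: METTable, n_folds: int, seed: int) -> np.ndarray:
    """Assign each record a fold label in 0..n_folds−1, sizes within 1."""
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n_folds > met.n:
        raise ValueError(f"n_folds={n_folds} exceeds the {met.n} records")
    rng = np.random.default_rng(seed)
    labels = np.resize(np.arange(n_folds), met.n)
    rng.shuffle(labels)
    return labels


def predict_cells(chain: Chain, held_out: pd.DataFrame) -> np.ndarray:
    """Posterior-mean prediction of held-out records.

    ŷ(g, e, blk) averages X1β + Σ_k λ_k α_k[g] γ_k[e] over retained draws.
    Records whose genotype or environment never appears in training are
    returned as NaN (non-predictable) — callers should drop and count them.
    """
    g_pos = {g: i for i, g in enumerate(chain.genotypes)}
    e_pos = {e: j for j, e in enumerate(chain.environments)}
    nb = chain.beta.shape[1] // len(chain.environments)
    preds = np.full(len(held_out), np.nan)
    b_pos = {b: k for k, b in enumerate(chain.blocks)}
    for row, (g, e, blk) in enumerate(
        zip(held_out["genotype"], held_out["environment"], held_out["block"])
    ):
        if g not in g_pos or e not in e_pos:
            continue
        i, j = g_pos[g], e_pos[e]
        be = j * nb + b_pos.get(blk, 0)
        bilinear = (chain.lam * chain.A[:, i, :] * chain.Gamma[:, j, :]).sum(axis=1)
        preds[row] = float((chain.beta[:, be] + bilinear).mean())
    return preds


def press(obs: np.ndarray, pred: np.ndarray) -> float:
    """Mean squared prediction error (1/n)Σ(y − ŷ)²."""
    obs, pred = np.asarray(obs, float), np.asarray(pred, float)
    if obs.shape != pred.shape:
        raise ValueError("obs and pred must have equal length")
    return float(np.mean((obs - pred) ** 2))


def cor_pred(obs: np.ndarray, pred: np.ndarray) -> float:
    """Pearson correlation between observed and predicted; NaN if degenerate."""
    obs, pred = np.asarray(obs, float), np.asarray(pred, float)
    if obs.shape != pred.shape:
        raise ValueError("obs and pred must have equal length")
    if len(obs) < 2 or np.ptp(obs) == 0 or np.ptp(pred) == 0:
        return float("nan")
    return float(np.corrcoef(obs, pred)[0, 1])


def run_cv(met: METTable, model: ModelConfig, n_folds: int, seed: int,
           plan: MCMCPlan | None = None) -> CVResult:
    """Refit on each fold's complement, predict the fold, score PRESS/COR."""
    plan = plan or CV_PLAN
    labels = make_folds(met, n_folds, seed)
    fold_press = np.empty(n_folds)
    fold_cor = np.empty(n_folds)
    skipped = 0
    for f in range(n_folds):
        train = met.records[labels != f]
        test = met.records[labels == f].reset_index(drop=True)
        train_met = met_from_frame(train)
        chain = gibbs_run(
            train_met, model,
            MCMCPlan(J=plan.J, B=plan.B, n_keep=plan.n_keep,
                     seed=int((seed + 1) * 1000 + f)),
            build_design(train_met),
        )
        pred = predict_cells(chain, test)
        ok = np.isfinite(pred)
        skipped += int((~ok).sum())
        fold_press[f] = press(test["response"].to_numpy()[ok], pred[ok])
        fold_cor[f] = cor_pred(test["response"].to_numpy()[ok], pred[ok])
    return CVResult(n_folds=n_folds, fold_press=fold_press, fold_cor=fold_cor,
                    n_skipped=skipped, variant=model.variant)
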