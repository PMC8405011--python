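"""Synthetic multi-environment trials with a sign-structured interaction.

The generator emulates a randomized complete block trial of 20 genotypes in
7 environments with 3 blocks.  Genotype, environment and block main effects
are Gaussian; the genotype×environment interaction has three response
patterns: two mirror-image "crossover" groups of five genotypes whose
interaction is forced positive in one environment subgroup and negative in
the other, and ten "stable" genotypes with unstructured low-variance
interaction.  The interaction matrix is double-centered (rows and columns
mean zero) before entering the response, so main effects stay identifiable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .metdata import METTable, met_from_frame

__all__ = ["SimConfig", "TruthParams", "simulate_met", "draw_interaction", "double_center"]


@dataclass
class SimConfig:
    """Study design and stochastic structure of the simulated trial.

    All distribution second parameters are variances.  Group indices are
    1-based genotype/environment numbers.  The genotype main-effect variance
    defaults to 16 (effect scale SD 4): with environment-centered cell means
    this puts the first singular value of the G+GE matrix near 47 and the
    first-axis information rate near 5.5, the regime the crossover design is
    meant to produce; the crossover interaction variance is 4 and the
    residual variance 6.
    """

    v: int = 20
    l: int = 7
    b: int = 3
    sigma2_g: float = 16.0
    sigma2_e: float = 4.0
    sigma2_b: float = 1.0
    sigma2_ge_unstable: float = 4.0
    sigma2_ge_stable: float = 1.0
    sigma2_eps: float = 6.0
    mu: float = 15.0
    group1: tuple[int, ...] = (1, 2, 3, 4, 5)
    group2: tuple[int, ...] = (6, 7, 8, 9, 10)
    positive_envs: tuple[int, ...] = (1, 2, 3, 4)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "sigma2_g", "sigma2_e", "sigma2_b",
            "sigma2_ge_unstable", "sigma2_ge_stable", "sigma2_eps",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        g1, g2 = set(self.group1), set(self.group2)
        if g1 & g2 or not (g1 | g2) <= set(range(1, self.v + 1)):
            raise ValueError("group1/group2 must be disjoint subsets of 1..v")
        if not set(self.positive_envs) <= set(range(1, self.l + 1)):
            raise ValueError("positive_envs must be a subset of 1..l")

    @property
    def stable(self) -> tuple[int, ...]:
        return tuple(
            i for i in range(1, self.v + 1)
            if i not in self.group1 and i not in self.group2
        )

    @property
    def negative_envs(self) -> tuple[int, ...]:
        return tuple(j for j in range(1, self.l + 1) if j not in self.positive_envs)


@dataclass
class TruthParams:
    """Ground-truth effects behind one simulated dataset."""

    mu: float
    g: np.ndarray            # genotype effects, length v
    e: np.ndarray            # environment effects, length l
    blk: np.ndarray          # block effects nested in environment, (l, b)
    GE: np.ndarray           # double-centered interaction, (v, l)
    eps: np.ndarray          # per-record residuals, length n
    GE_raw: np.ndarray = field(default=None)  # pre-centering interaction

    def to_json(self) -> str:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in asdict(self).items()}
        return json.dumps(d, indent=1)


def double_center(m: np.ndarray) -> np.ndarray:
    """Remove row and column means: m − row̄ − col̄ + grand mean."""
    m = np.asarray(m, dtype=float)
    return (
        m
        - m.mean(axis=1, keepdims=True)
        - m.mean(axis=0, keepdims=True)
        + m.mean()
    )


def draw_interaction(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw the raw (pre-centering) v×l interaction matrix.

    Crossover-group entries are |N(0, σ²_unstable)| with the sign forced by
    group × environment-subgroup membership; stable-group entries are plain
    N(0, σ²_stable) draws.
    """
    ge = np.zeros((cfg.v, cfg.l))
    sd_u = np.sqrt(cfg.sigma2_ge_unstable)
    sd_s = np.sqrt(cfg.sigma2_ge_stable)
    sign = np.ones(cfg.l)
    sign[[j - 1 for j in cfg.negative_envs]] = -1.0
    for i in range(1, cfg.v + 1):
        if i in cfg.group1:
            ge[i - 1] = np.abs(rng.normal(0.0, sd_u, cfg.l)) * sign
        elif i in cfg.group2:
            ge[i - 1] = np.abs(rng.normal(0.0, sd_u, cfg.l)) * -sign
        else:
            ge[i - 1] = rng.normal(0.0, sd_s, cfg.l)
    return ge


def simulate_met(cfg: SimConfig | None = None) -> tuple[METTable, TruthParams]:
    """Generate one trial: y = μ + g + e + blk(e) + GE + ε, seeded by ``cfg.seed``."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    g = rng.normal(0.0, np.sqrt(cfg.sigma2_g), cfg.v)
    e = rng.normal(0.0, np.sqrt(cfg.sigma2_e), cfg.l)
    blk = rng.normal(0.0, np.sqrt(cfg.sigma2_b), (cfg.l, cfg.b))
    ge_raw = draw_interaction(cfg, rng)
    ge = double_center(ge_raw)

    rows = []
    for i in range(cfg.v):
        for j in range(cfg.l):
            for k in range(cfg.b):
                rows.append((f"G{i + 1:02d}", f"E{j + 1}", f"B{k + 1}", i, j, k))
    frame = pd.DataFrame(rows, columns=["genotype", "environment", "block", "i", "j", "k"])
    eps = rng.normal(0.0, np.sqrt(cfg.sigma2_eps), len(frame))
    frame["response"] = (
        cfg.mu
        + g[frame["i"]]
        + e[frame["j"]]
        + blk[frame["j"], frame["k"]]
        + ge[frame["i"], frame["j"]]
        + eps
    )
    met = met_from_frame(frame[["genotype", "environment", "block", "response"]])
    truth = TruthParams(mu=cfg.mu, g=g, e=e, blk=blk, GE=ge, eps=eps, GE_raw=ge_raw)
    return met, truth
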