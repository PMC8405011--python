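"""Posterior biplot geometry with uncertainty.

Each retained draw yields genotype scores (λ1^{1/2}α_i1, λ2^{1/2}α_i2) and
environment scores (λ1^{1/2}γ_j1, λ2^{1/2}γ_j2).  Because the sign of each
SVD axis is arbitrary per draw, draws are first aligned to a fixed
frequentist reference.  From the aligned clouds come 95% bivariate credible
regions (convex hull of the innermost Mahalanobis-ordered points), the
average-environment axis (AEA), the ideal genotype, per-genotype distances
to the ideal, per-environment cosines to the AEA, and the who-won-where
sector partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .metdata import METTable, center_gge_matrix, subset_environments, svd_gge
from .samplers import Chain

__all__ = [
    "ScoreCloud",
    "CredibleRegion",
    "align_draws",
    "score_clouds",
    "credible_region",
    "hpd_interval",
    "average_environment",
    "env_aea_cosine",
    "ideal_genotype",
    "distance_to_ideal",
    "who_won_where",
    "subset_mega",
    "biplot_summary",
]

subset_mega = subset_environments


@dataclass
class ScoreCloud:
    """Per-draw 2-D biplot scores of one genotype or environment."""

    entity: str
    side: str                 # "genotype" | "environment"
    draws: np.ndarray         # (n_draws, 2)

    @property
    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)


@dataclass
class CredibleRegion:
    level: float
    boundary: np.ndarray      # ordered polygon vertices, (m, 2)
    contains_origin: bool
    degenerate: bool = False


def align_draws(chain: Chain) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resolve the per-draw sign indeterminacy of the first two axes.

    Reference axes come from the frequentist SVD of the posterior-mean
    bilinear matrix A·diag(λ)·Γ'.  Per draw and axis, genotype and
    environment loadings are flipped together so their stacked inner product
    with the reference is nonnegative.  Returns (lam, A, Gamma) arrays of
    the first two components, aligned.
    """
    if chain.lam.shape[1] < 2:
        raise ValueError("biplot alignment needs at least 2 bilinear components")
    mean_state = chain.posterior_mean_state()
    fit = mean_state.A @ np.diag(mean_state.lam) @ mean_state.Gamma.T
    _, A_ref, G_ref = svd_gge(fit, t=2)
    A = chain.A[:, :, :2].copy()
    G = chain.Gamma[:, :, :2].copy()
    lam = chain.lam[:, :2].copy()
    for axis in range(2):
        dots = A[:, :, axis] @ A_ref[:, axis] + G[:, :, axis] @ G_ref[:, axis]
        flip = dots < 0
        A[flip, :, axis] *= -1.0
        G[flip, :, axis] *= -1.0
    return lam, A, G


def score_clouds(chain: Chain) -> tuple[list[ScoreCloud], list[ScoreCloud]]:
    """Aligned per-entity score clouds (genotypes, environments)."""
    lam, A, G = align_draws(chain)
    w = np.sqrt(np.maximum(lam, 0.0))          # (n_draws, 2), per-axis λ^1/2
    gen = [
        ScoreCloud(g, "genotype", w * A[:, i, :])
        for i, g in enumerate(chain.genotypes)
    ]
    env = [
        ScoreCloud(e, "environment", w * G[:, j, :])
        for j, e in enumerate(chain.environments)
    ]
    return gen, env


def _polygon_contains(boundary: np.ndarray, point: np.ndarray) -> bool:
    """Point-in-convex-polygon via consistent cross-product signs."""
    m = len(boundary)
    sign = 0.0
    for i in range(m):
        a, b = boundary[i], boundary[(i + 1) % m]
        cross = (b[0] - a[0]) * (point[1] - a[1]) - (b[1] - a[1]) * (point[0] - a[0])
        if cross != 0.0:
            if sign == 0.0:
                sign = np.sign(cross)
            elif np.sign(cross) != sign:
                return False
    return True


def credible_region(cloud: ScoreCloud | np.ndarray, level: float = 0.95) -> CredibleRegion:
    """95% bivariate credible region: hull of the innermost Mahalanobis points."""
    pts = cloud.draws if isinstance(cloud, ScoreCloud) else np.asarray(cloud, float)
    if len(pts) < 100:
        raise ValueError("need at least 100 aligned draws")
    center = pts.mean(axis=0)
    dev = pts - center
    cov = dev.T @ dev / (len(pts) - 1)
    if np.linalg.matrix_rank(cov) < 2 or np.linalg.cond(cov) > 1e12:
        lo = np.quantile(pts, (1 - level) / 2, axis=0)
        hi = np.quantile(pts, 1 - (1 - level) / 2, axis=0)
        boundary = np.array([[lo[0], lo[1]], [hi[0], lo[1]],
                             [hi[0], hi[1]], [lo[0], hi[1]]])
        inside = bool(np.all(lo <= 0.0) and np.all(hi >= 0.0))
        return CredibleRegion(level, boundary, inside, degenerate=True)
    prec = np.linalg.inv(cov)
    d2 = np.einsum("ij,jk,ik->i", dev, prec, dev)
    keep = pts[np.argsort(d2)[: int(np.ceil(level * len(pts)))]]
    hull = ConvexHull(keep)
    boundary = keep[hull.vertices]
    return CredibleRegion(level, boundary, _polygon_contains(boundary, np.zeros(2)))


def hpd_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Shortest order-statistic window containing ``level`` of the sample."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    if n < 100:
        raise ValueError("need at least 100 draws")
    m = max(int(np.ceil(level * n)), 2)
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def average_environment(env_clouds: list[ScoreCloud]):
    """Per-draw average of environment scores and the unit AEA direction.

    Returns (avg_points, aea_draws, aea_mean): the average-environment point
    cloud (for its own credible region), per-draw unit AEA directions, and
    the unit direction of the mean point.  Draws whose average is the zero
    vector are skipped.
    """
    if not env_clouds:
        raise ValueError("need at least one environment")
    avg = np.mean([c.draws for c in env_clouds], axis=0)
    norms = np.linalg.norm(avg, axis=1)
    ok = norms > 0
    aea = avg[ok] / norms[ok, None]
    mean_pt = avg.mean(axis=0)
    aea_mean = mean_pt / np.linalg.norm(mean_pt)
    return avg, aea, aea_mean


def env_aea_cosine(env_clouds: list[ScoreCloud], aea_draws: np.ndarray) -> pd.DataFrame:
    """Per-environment cosine of the angle to the AEA, draw by draw.

    Returns a summary frame (mean, median, sd, HPD bounds) in the
    environment order given.
    """
    rows = []
    for cloud in env_clouds:
        pts = cloud.draws[: len(aea_draws)]
        norms = np.linalg.norm(pts, axis=1)
        ok = norms > 0
        cosines = np.einsum("ij,ij->i", pts[ok], aea_draws[ok]) / norms[ok]
        cosines = np.clip(cosines, -1.0, 1.0)
        lo, hi = hpd_interval(cosines)
        rows.append({
            "environment": cloud.entity,
            "mean": float(cosines.mean()),
            "median": float(np.median(cosines)),
            "sd": float(cosines.std(ddof=1)),
            "hpd_lower": lo,
            "hpd_upper": hi,
            "n_skipped": int((~ok).sum()),
        })
    return pd.DataFrame(rows)


def ideal_genotype(gen_clouds: list[ScoreCloud], aea_draws: np.ndarray) -> np.ndarray:
    """Per-draw ideal point: on the AEA at the maximal genotype projection."""
    scores = np.stack([c.draws[: len(aea_draws)] for c in gen_clouds], axis=1)
    proj = np.einsum("dgj,dj->dg", scores, aea_draws)
    max_proj = proj.max(axis=1)
    return max_proj[:, None] * aea_draws


def distance_to_ideal(gen_clouds: list[ScoreCloud], ideal_draws: np.ndarray) -> pd.DataFrame:
    """Per-genotype Euclidean distance to the ideal point, with HPD bounds."""
    rows = []
    for cloud in gen_clouds:
        d = np.linalg.norm(cloud.draws[: len(ideal_draws)] - ideal_draws, axis=1)
        lo, hi = hpd_interval(d)
        rows.append({
            "genotype": cloud.entity,
            "mean": float(d.mean()),
            "sd": float(d.std(ddof=1)),
            "hpd_lower": lo,
            "hpd_upper": hi,
        })
    return pd.DataFrame(rows)


@dataclass
class WhoWonWhere:
    vertices: list[str]                      # hull genotypes, counterclockwise
    polygon: np.ndarray                      # their mean scores
    sector_of_env: dict[str, str]            # environment -> winning genotype
    ties: list[str] = field(default_factory=list)
    degenerate: bool = False


def who_won_where(gen_means: dict[str, np.ndarray],
                  env_means: dict[str, np.ndarray]) -> WhoWonWhere:
    """Sector partition of the biplot by perpendiculars to the hull edges.

    The convex hull of genotype mean scores forms the polygon; rays from the
    origin perpendicular to each edge split the plane into sectors, each
    owned by the hull vertex between its rays.  An environment's winner is
    the owner of its sector — equivalently the hull genotype with the
    maximal inner product with the environment's score.  Boundary ties break
    to the lexicographically lower genotype id.
    """
    names = sorted(gen_means)
    pts = np.array([gen_means[g] for g in names])
    if len(names) < 3:
        raise ValueError("need at least 3 genotypes")
    try:
        hull = ConvexHull(pts)
        order = hull.vertices
        degenerate = False
    except Exception:                         # collinear scores
        order = np.array([int(np.argmin(pts[:, 0])), int(np.argmax(pts[:, 0]))])
        degenerate = True
    verts = [names[i] for i in order]
    vert_pts = pts[order]

    sector, ties = {}, []
    for env, e_pt in env_means.items():
        dots = vert_pts @ np.asarray(e_pt)
        best = float(dots.max())
        winners = sorted(v for v, d in zip(verts, dots) if np.isclose(d, best))
        sector[env] = winners[0]
        if len(winners) > 1:
            ties.append(env)
    return WhoWonWhere(vertices=verts, polygon=vert_pts, sector_of_env=sector,
                       ties=ties, degenerate=degenerate)


def biplot_summary(chain: Chain, level: float = 0.95) -> dict:
    """Full biplot geometry bundle for one fitted chain."""
    gen, env = score_clouds(chain)
    avg_pts, aea_draws, aea_mean = average_environment(env)
    cosines = env_aea_cosine(env, aea_draws)
    ideal = ideal_genotype(gen, aea_draws)
    distances = distance_to_ideal(gen, ideal)
    regions = {c.entity: credible_region(c, level) for c in gen + env}
    www = who_won_where(
        {c.entity: c.mean for c in gen},
        {c.entity: c.mean for c in env},
    )
    return {
        "genotype_clouds": gen,
        "environment_clouds": env,
        "regions": regions,
        "average_environment_points": avg_pts,
        "aea_direction": aea_mean,
        "cosines": cosines,
        "ideal_draws": ideal,
        "distances": distances,
        "who_won_where": www,
    }
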