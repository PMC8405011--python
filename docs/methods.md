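# Methods

## Model and likelihood

The observation vector **y** (length n = v·b·l on complete data) follows the
linear-bilinear GGE / site-regression model

y = X₁β + Σₖ₌₁ᵗ λₖ · diag(Zαₖ) · X₂γₖ + ε,  ε ~ N(0, σ²ₑ Iₙ),

with incidence matrices X₁ (block within environment, b·l columns,
environment-major block-minor order), X₂ (environment) and Z (genotype), and
t = min(v−1, l).  The linear term absorbs the general mean, environment and
block effects; the bilinear term is the SVD of the genotype-main-effect +
interaction surface Θ (v×l), the object the GGE biplot displays.  All entity
orderings are lexicographic by label so that outputs are reproducible.

Priors: β ~ N(0, σ²β I) with σ²β = 10⁸; λₖ | σ²λₖ ~ N⁺(0, σ²λₖ) subject to
λ₁ ≥ … ≥ λₜ ≥ 0; αₖ and γₖ uniform on unit spheres inside the orthogonal
complement of their same-side companions; p(σ²ₑ) ∝ 1/σ²ₑ (Jeffreys).  The two
prior regimes differ only in σ²λₖ:

* flat (BGGE): σ²λₖ = 10⁸ fixed — the posterior essentially reproduces the
  frequentist SVD on complete data;
* entropy (BGGEE): σ²λₖ carries the maximum-entropy inverse-gamma hyperprior
  IG(a, b) with a = 1, b = 0 (density ∝ (σ²λ)⁻²), producing shrinkage of
  weakly supported singular values.

## Full conditionals

With M = Σₖ λₖ diag(Zαₖ)X₂γₖ and Λₖ = diag(Zαₖ)X₂γₖ:

* β | · ~ N((X₁'X₁ + (σ²ₑ/σ²β)I)⁻¹X₁'(y − M), (X₁'X₁ + (σ²ₑ/σ²β)I)⁻¹σ²ₑ).
  The ridge addend appears in both the mean and the covariance — the
  internally consistent conjugate form, numerically identical to the
  ridge-free covariance at σ²β = 10⁸.  X₁'X₁ is diagonal, so this update is
  elementwise.
* λₖ | · is normal in the partial residual M′ₖ = y − X₁β − Σₖ′≠ₖ λₖ′Λₖ′ with
  precision Λₖ'Λₖ + σ²ₑ/σ²λₖ, truncated to [λₖ₊₁, λₖ₋₁] (0 and +∞ at the
  ends), which maintains the order constraint exactly.
* σ²λₖ | · ~ IG(a + ½, b + λₖ²/2) = IG(3/2, λₖ²/2) at (a, b) = (1, 0).  This
  is the exact conditional of the stated hierarchy (hyperprior ∝ (σ²λ)⁻⁽ᵃ⁺¹⁾
  times the half-normal λ likelihood); a frequently quoted alternative,
  IG(a+1, λ² + 2b), has the same conditional mean λ² but is not proportional
  to the joint posterior, and a Gibbs sweep mixing the two targets no
  well-defined distribution.  The scale is floored at 10⁻¹² so a fully shrunk
  λₖ = 0 keeps the next λ conditional proper.
* αₖ, γₖ | · are von Mises–Fisher on the unit sphere of the corrected
  subspace: with raw direction μ_raw = Λ*'(y − X₁β) (Λ* = diag(X₂γₖ)Z on the
  genotype side, diag(Zαₖ)X₂ on the environment side) and H an orthonormal
  basis of the complement of the *current* other same-side loadings, the
  subspace law is vMF(m, ‖H'μ_raw‖·λₖ/σ²ₑ, H'μ_raw/‖H'μ_raw‖) with m the
  number of columns of H.  Using all other current vectors (not only the
  previous ones) keeps every accepted state exactly orthonormal.
* σ²ₑ | · ~ scaled-inv-χ²(n, (y − μ_y)'(y − μ_y)/n).

The vMF conditionals drop the cross terms with the other bilinear components
and the quadratic term in the loading; both are exactly constant on complete
balanced data (orthogonality makes them vanish) and only approximately so
under record-level unbalance — see Limitations.

## Samplers

* vMF draws use Wood's (1994) envelope-rejection scheme for the cosine to the
  mean direction plus a uniform tangent, with the envelope parameter computed
  in rationalized form, b = (m−1)/(2κ + √(4κ² + (m−1)²)), so concentrations up
  to ~10⁹ (which arise in near-noiseless data) remain stable; m = 1 reduces to
  a two-point sign draw and κ = 0 to the uniform sphere.
* Truncated normals are drawn by inverse CDF with log-space tail handling
  (`log_ndtr` / `ndtri_exp`), exact even on far-tail intervals such as
  [8σ, 9σ].
* Inverse-gamma and scaled inverse-χ² draws are gamma-variate transforms.

The Gibbs scan is systematic: β → {λₖ, (σ²λₖ), αₖ, γₖ for k = 1..K} → σ²ₑ,
using freshly updated values inside the scan.  Initialization: SVD of the
environment-centered cell-mean matrix (missing cells zero-filled for
initialization only), β from block-within-environment means, σ²ₑ from that
fit's residual variance.  Orthonormality drift is checked every 1000 scans
against a 10⁻⁶ tolerance and repaired by direction-preserving Gram–Schmidt
(the repair count is recorded on the chain; in practice it stays zero).  A
single seeded generator drives the whole run; no substreams, so results are
independent of thread count.

## Chain plans

The conservative published-style schedule is N = n_keep·J + B with a 4000-draw
pilot, J the maximal Raftery–Lewis dependence factor over the monitored
scalars (all λₖ, σ²ₑ, all σ²λₖ) and B = max(RL burn-in, 10000);
`diagnostics.plan_run` builds it from pilot results.  The package's working
default (`FAST_PLAN`: B = 1500, 4000 unthinned draws) exploits that the λ and
variance chains of this model mix with dependence factors near 1, so the
reduced schedule passes the same gates (I < 5, ESS > 4000, Heidelberger–Welch
at α = 0.05).  Cross-validation refits use a shorter per-fold plan (B = 500,
1000 draws) because only the posterior-mean surface enters the fold score.

Diagnostics are implemented from the original procedures rather than
delegated: Raftery–Lewis (binary chain at the q = 0.025 quantile, BIC choice
of first-order thinning, run length for r = 0.005 at s = 0.95), Heidelberger–
Welch (Cramér–von Mises statistic of the standardized partial-sum bridge with
AR-fit spectral density at zero and iterative 10% head discarding, halfwidth
test at 10% of the mean), and the initial-monotone-sequence ESS estimator
capped at the chain length.  The Heidelberger–Welch behavior matches the
reference R implementation, including passing the CvM test on slowly drifting
chains that then fail the halfwidth test.

## Synthetic trials

`simulate.SimConfig` encodes the reference study design: v = 20 genotypes,
l = 7 environments, b = 3 blocks; environment effects N(0, 4), block effects
N(0, 1), residual N(0, 6) (all variances).  The interaction has three
patterns: genotypes 1–5 draw |N(0, 4)| values signed positive on environments
1–4 and negative on 5–7; genotypes 6–10 mirror those signs; genotypes 11–20
draw N(0, 1) freely.  Sign-forcing uses |draw|·sign, preserving the marginal
scale; the interaction matrix is double-centered before entering the
response, and the general mean (default 15, absorbed by β) is configurable.

The genotype main-effect variance defaults to 16 (effect SD 4).  This is the
one deliberate departure from reading every stated second parameter as a
variance: with var(g) = 4 the environment-centered spectrum has λ₁ ≈ 25 and
IR₁ ≈ 3.9, while var(g) = 16 puts λ₁ ≈ 47, IR₁ ≈ 5.5, 10-fold predictive
correlation ≈ 0.75 and posterior σ²ₑ ≈ 6.3–6.7 — the regime the reference
spectra and cross-validation scores describe.  Interaction and residual
scales stay at variance 4 and 6 (their SD readings are excluded by the same
spectra: λ₂ would near-double and σ²ₑ would sit near 36).

What the generator does not emulate: heterogeneous residual variances across
environments, non-Gaussian responses, genotype–block interaction, and
spatial field trends.  Passing tests therefore demonstrate correctness of the
machinery under the stated Gaussian homoscedastic design, not robustness to
those real-data features.

## Model selection and cross-validation

AIC/BIC are plug-in criteria at the posterior means (loadings re-orthonormal-
ized after averaging) with free-parameter count b·l + k(v + l − k) + 1 — the
parameter count of a rank-k SVD plus linear terms and the residual variance.
AICM = 2s²ℓ − 2ℓ̄ from the posterior log-likelihood draws (deviance scale,
lower is better).  The information rate IRₖ = λₖ²/(Σλ²/t) and variance shares
λₖ²/Σλ² are scale-invariant.  The σ²ₑ-versus-k profile reports kernel-density
posterior modes.

Cross-validation removes individual plot records (not whole genotypes):
10-fold, 3-fold and 2-fold correspond to 10%, 33% and 50% removal, the only
reading consistent with those fractions.  Held-out cells are predicted by the
Rao–Blackwellized posterior mean of the fitted surface (averaging X₁β + Θ over
retained draws), which has lower Monte-Carlo variance than plugging in
posterior-mean parameters.  Records whose genotype or environment is absent
from training are flagged non-predictable and excluded with a count.  PRESS is
the mean squared prediction error; COR the Pearson correlation of held-out
observations with predictions.

## Biplot geometry

Scores are (√λ₁·u₁, √λ₂·u₂) per draw (per-axis symmetric scaling).  Because
each SVD axis is sign-indeterminate per draw, both sides of each axis are
flipped together to agree with a fixed reference — the SVD of the
posterior-mean bilinear surface.  The 95% bivariate credible region is the
convex hull of the innermost 95% of aligned draws ranked by Mahalanobis
distance from the cloud mean (an axis-aligned percentile box, flagged, when
the cloud covariance is degenerate); on Gaussian clouds its coverage
calibrates to 0.945–0.955 and its area to the χ²₂ ellipse within 5%.  HPD
intervals are the shortest order-statistic windows.  The average-environment
axis (AEA) is the unit ray through the per-draw mean of environment scores;
an environment's representativeness is its cosine to the AEA, summarized with
mean/median/SD/HPD.  The ideal genotype is the point on the AEA at the
maximal genotype projection in that draw; genotype merit is the Euclidean
distance to it (rotation-invariant by construction).  Who-won-where takes the
convex hull of mean genotype scores, partitions the plane by perpendiculars
from the origin to the hull edges, and assigns each environment the hull
vertex maximizing the inner product with its score; boundary ties break to
the lexicographically lower genotype and are flagged.  Mega-environment
analysis subsets the trial by environment and refits (counts and t
recomputed).

## Numerical choices

* σ²λ floor 10⁻¹²: keeps conditionals proper once a singular value has shrunk
  to zero; the shrunk state is effectively absorbing, which is the intended
  behavior of the entropy prior (a retired axis stays retired).
* Degenerate vMF direction (‖H'μ_raw‖ = 0 or λₖ = 0): uniform draw on the
  corrected sphere, not an error.
* Truncated-normal intervals with lower = upper return the common bound.
* Kernel-density modes use a 512-point grid over the sample range.
* Credible regions / HPD intervals require ≥ 100 draws.

## Known limitations

* The vMF loading conditionals follow the standard GGE Gibbs algebra, whose
  cross-component and quadratic terms cancel only on complete balanced data.
  Under record-level unbalance the sweep is an approximation to the exact
  (Fisher–Bingham-type) conditionals; predictions and variance estimates are
  essentially unaffected at realistic noise, but in the joint zero-noise +
  unbalanced limit a small prediction-error floor remains.
* The bilinear surface and β share an identifiability ridge: a column-
  constant offset of Θ can be absorbed by the per-environment β entries with
  no likelihood change, and no prior pins it down.  On complete data the
  single-site sweep moves along this ridge negligibly; on sparse or near-
  noiseless data λ₁ can inflate along it.  All reported quantities except raw
  λ magnitudes (fitted surfaces, predictions, σ²ₑ, CV scores) are
  ridge-invariant.
* With a correctly mixing sampler the flat variant does not collapse under
  50% removal: its 2-fold predictive correlation sits within a few points of
  the entropy variant's (sometimes above, sometimes below, by data seed),
  because the Rao–Blackwellized mean of a diffuse full-rank posterior remains
  centered.  The entropy variant's advantage is parsimony and noise
  discrimination, not a dramatic predictive gap at heavy unbalance.
* Homoscedastic Gaussian responses only; no heterogeneous residual variances
  per environment and no non-Gaussian likelihoods.
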