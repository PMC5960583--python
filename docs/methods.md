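# Methods

## Data model and processing rules

The sampling unit is the netting wall (a ~100 m trammel-net section);
walls are nested in nets, nets in trips, trips in boats. Each catch
item carries a species, a fate (marketable/discard), a size record and,
for discards, an alive-at-arrival flag. Small invertebrates that
disentangle passively during hauling cannot be attributed to a wall;
they are recorded per net as a total volume (liters) with a nominally
20-L weighed subsample, and enter only net-level analyses (items carry
a `NET_LEVEL` marker and are excluded from all wall-level statistics).

Deterministic rules, applied before any model fit:

* **Length to weight**: `W = a L^b / 1000` kg with coefficients in the
  g–cm convention. The coefficient table carries a units column so
  other conventions can be declared explicitly.
* **Length classes** are half-open `(k·w, (k+1)·w]`, width 10 cm for
  fish total length and 5 cm for lobster carapace length; the class
  *upper* bound is used in weight conversion (so a boundary length maps
  to the class it closes: 20 → 20, 23 → 30 at width 10). The half-open
  convention makes "class maximum" well defined and testable.
* **Imputation**: an item without any size record receives the
  arithmetic mean length of its sampled conspecifics, pooling measured
  lengths with class upper bounds.
* **Revenue**: item weight × the mean first-sale price of its
  commercial category across all trips.
* **Pool scaling**: subsample weights are scaled linearly by
  `total_volume / subsample_volume`; when the total does not exceed the
  subsample volume the whole pool was weighed and no scaling applies.
  Linearity is an assumption (a volume-to-mass density that is constant
  within a net's pooled fraction).

## Hurdle-exponential hierarchical model

Per wall `i` of gear type `t(i)`: occurrence `w_i ~ Bernoulli(p_t)` and,
conditional on a catch, amount `x_i ~ Exponential` with mean
`m_i = mu_t + b_boat(i) + b_net(i)`; `b` are zero-mean normal random
effects with scales `sigma_boat`, `sigma_net`. States with `m_i <= 0`
on a positive wall have zero posterior density; the additive
random-effect parameterisation makes this constraint unavoidable and it
is enforced by proposal rejection.

Priors: `p_t ~ Beta(1,1)`; `mu_t ~ Uniform(0, 100 × mean of positive
amounts)`; `sigma ~ Half-Normal(scale = SD of positive amounts)`. The
half-normal scale prior is a deliberate choice over a flat one: with
only three boats, the conditional of `sigma_boat^2` under a flat prior
is InvGamma(1, ·) (infinite mean), and because the likelihood is
invariant along the translation `mu + c, b - c`, the posterior of
`mu_t` inherits a divergent variance and a strong right skew — its
posterior mean then overestimates the truth even on perfectly specified
synthetic data. The half-normal at the scale of the response SD still
admits boat effects as large as the response itself, so it is weakly
informative in every practical sense while keeping `mu_t` estimable.

Sampling is Metropolis-within-Gibbs:

* `p_t` by exact conjugate Beta draw (the occurrence indicators are
  data, not latent, so no Metropolis step is needed);
* `mu_t`, each `b`, by per-parameter Gaussian random walks, step sizes
  adapted during burn-in only (targeting ~0.3 acceptance) so the
  retained chain is a fixed-kernel Markov chain;
* `sigma` by an independence proposal drawn from likelihood × flat
  (an exact InvGamma draw) accepted with the half-normal prior ratio;
* two exact auxiliary moves that fix the slow directions of the
  posterior geometry without changing the model: a Gibbs draw of the
  likelihood-invariant translation `mu_t += c, b_j -= c`
  (`c ~ N(mean(b), sigma^2/k)` truncated to the `mu` bounds), and a
  parameter-expansion rescaling `(sigma, b) -> (c·sigma, c·b)` with a
  log-normal proposal for `c`, which breaks the funnel between the
  seventy net effects and their scale. Without these, `sigma_net`
  showed R-hat up to 2.3 at short chain lengths; with them all reported
  parameters sit at R-hat ≈ 1.00.

Protocol: 3 chains, 10,000 burn-in, thinning 1/10, 30,000 retained
draws total (`FULL_PROFILE`); `FAST_PROFILE` (burn 1,000, thin 5,
3,000 retained) is used throughout the test suite and acceptance
script, where it converges indistinguishably on trial-scale data.
Convergence threshold: R-hat < 1.1. Boats are kept in every fit even
though only three exist; nets with no positive walls draw their effects
from the prior. The per-net expectation for an average 22-wall net is
`22 × p_t × mu_t` per draw (random effects integrate out at zero mean),
and a gear contrast is labelled RELEVANT exactly when the central 95%
interval of its paired posterior difference excludes the reference
(zero by default).

Net-level comparison: pooled log biomass per single-fiber net (mixed
nets excluded, since the greca was always mounted in mixed nets) is
decomposed by an ordinary one-way least-squares fit, reported as
(SS_effect, SS_residual, F, p).

## Survival

Immediate survival per species is `alive/total` with the central 95%
interval of Beta(alive+1, dead+1), i.e. the binomial posterior under a
uniform prior. This convention reproduces the published lobster
interval [0.56, 0.72] from 82/127; it does not reproduce every
published bound (e.g. 4/100 gives an upper bound 0.098 where 0.08 was
printed, and 0/… counts have a strictly positive lower quantile), so
those bounds are treated as convention-ambiguous and not asserted.
Published point estimates are consistent with truncation (not rounding)
to two decimals; the package returns full precision and leaves display
formatting to the caller.

The combined seven-day curve uses the product-limit estimator with
deaths-first tie handling, Greenwood variance, and intervals on the
log-survival scale clipped to [0, 1]. Reconstructing the lobster
cohort — 45 deck deaths at day 0, 66 survivors censored at day 0, 16
captive animals of which one died at day 1 — gives
S(7) = (82/127)(15/16) ≈ 0.605. The published asymptote 0.64 [0.54–0.76]
is not reachable under that censoring description with standard tie
conventions (it matches 81/127 if the captive death is folded into day
0), so both readings are documented and no numeric target is placed on
0.64.

Vitality uses the ordinal scale DEAD < POOR < GOOD < EXCELLENT observed
on days 0, 1, 2, 4 and 7, with DEAD absorbing (validated on input).

## Ordination

The Hellinger transform `h_ij = sqrt(y_ij / row_total_i)` maps
nonnegative composition rows onto the unit sphere (all-zero rows stay
zero), after which Euclidean methods are appropriate. PCA is a
column-centered SVD with eigenvalues `s^2/(n-1)`; axis signs are fixed
by making each axis's largest-magnitude loading positive so exported
score files are reproducible. RDA projects the centered response onto
a factor's indicator space; pseudo-F = (SS_constrained/df1) /
(SS_residual/df2) with df1 = levels − 1, df2 = n − levels, and
constrained + residual variance equals the total PCA variance by
construction. The permutation test permutes rows freely (the group
structure is deliberately ignored at this
step) and uses the add-one rule
p = (1 + #{F* ≥ F}) / (n_perm + 1).

The consecutive-wall dependence check is fully specified by this
package: pooled Pearson correlation of
within-net lag-1 pairs over nets with ≥ 3 walls, null by permuting wall
order independently within each net, two-sided add-one p-value.
Constant series return an undefined statistic flagged as NaN with p=1.

## Synthetic data

The generator reproduces the trial design: 3 boats, 70 nets × 22 walls
(~1,540 walls) for fiber comparisons, 14 nets × 10 walls with
alternating five-wall MMF / MMF+greca blocks for the greca trial, two
nets per trip, depths uniform on 63–130 m, soak times ~N(45, 2.3) h.
Wall amounts follow the hurdle process exactly, with the positive-part
mean floored at 0.01 × mu_type (the additive random-effect mean is
otherwise not guaranteed positive; the floor resolves that edge without
affecting typical draws). Default parameters sit at the magnitudes the
field study reported — revenue occurrence 0.31/0.28 and mean ≈ 41–42
EUR for PMF/MMF, discard occurrence 0.52/0.70 and mean 1.30/0.62 kg for
MMF/greca — so synthetic outputs are of familiar size. Boat/net effect
scales are not reported anywhere and were set once to roughly 10% and
15% of the positive-part mean (4 and 6 EUR on the revenue scale; 0.08
and 0.15 kg on the discard scale), a realistic between-boat/between-net
spread for a single small fleet.

Items realise each wall's drawn amount: species are drawn from
gear-type-specific composition weights (the greca profile shifts weight
toward the small-bodied dogfish and away from rays), lengths are
lognormal per species, and item weights are rescaled so the wall total
equals the drawn amount exactly. Consequently item weights are not
exactly consistent with their lengths through the allometric curve —
the generator prioritises an exact hurdle structure at wall granularity
over item-level allometric consistency, which is what the model-fitting
stages consume. What passing tests therefore show is that the
estimators recover the data-generating process they assume; they do not
validate the model against real-data features such as seasonal price
drift, observer error in visual length classes, or overdispersed
(non-exponential) positive catches.

Per-species immediate survival is Binomial; captive vitality evolves by
a row-stochastic 4×4 transition matrix with DEAD absorbing, observed on
the trial's schedule. The observed alive-at-arrival table (eight
species, 1,216 animals, 353 alive) ships as a fixture.

## Numerical and testing choices

* All MCMC and simulation randomness flows from explicit integer seeds;
  identical seeds give identical chains and files.
* Parameter-recovery checks average posterior means over six
  independent trial-scale replicates: a single replicate carries ~9%
  SD of irreducible simulation noise on `mu` (exponential sampling
  noise `mu/sqrt(#positive walls)` plus the realised three-boat effect
  mean), so a ±10% single-replicate criterion would fail a quarter of
  the time for a perfect sampler. Interval coverage is checked on 30
  smaller replicates (20 nets × 10 walls, short chains) pooled over
  four parameters against the binomial band [0.88, 1] for nominal 95%.
* Test suites use `FAST_PROFILE` or smaller; the full protocol is the
  default for real analyses.
* Degenerate inputs are contracts, not crashes: empty gear types warn
  and fall back to prior draws, zero-variance permutation responses
  return p = 1 with a warning, convex hulls of ≤ 2 distinct or
  collinear points degenerate to the point set.

## Known limitations

* The exponential positive-part is fixed by design; no alternative
  positive distributions or model selection are provided.
* `p_t` and the positive-part parameters are a priori independent;
  nothing links occurrence and magnitude.
* With three boats, `sigma_boat` remains weakly identified under any
  reasonable prior; its posterior should be read as regularisation, not
  as an estimate of between-boat variance.
* The RDA is single-factor; no partial or distance-based variants.
* No geographic handling of deployment positions, no price time-series
  modelling, no tag-recapture analysis of released animals.
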