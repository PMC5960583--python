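# trammelnet

Catch-comparison and discard-survival analysis for trammel-net gear
trials, built around the design of a Mediterranean small-scale lobster
(*Palinurus elephas*) fishery study: three netting-wall gear types
(standard polyfilament **PMF**, polyethylene multi-monofilament **MMF**,
and MMF with a *greca* guarding strip) fished from a few boats, with the
~100 m netting wall as the statistical sampling unit, nested in nets and
fishing trips.

It is written for fisheries scientists who need to answer, from
observer-style catch records: does a gear modification change revenue,
discard biomass, or discard species composition — and do the discarded
animals survive?

## What it computes

**Hurdle model for per-wall amounts.** Revenue (EUR) or discard biomass
(kg) per netting wall `i` is modelled in two parts:

```
w_i ~ Bernoulli(p_type)                    occurrence of any catch
x_i | w_i=1 ~ Exponential(mean m_i),       m_i = mu_type + b_boat + b_net
b_boat ~ N(0, sigma_boat^2),  b_net ~ N(0, sigma_net^2)
```

Fitting is Bayesian via a Metropolis-within-Gibbs sampler (3 chains,
10,000 burn-in, thinning 1/10, 30,000 retained draws by default; a
`FAST_PROFILE` is provided), with Gelman–Rubin convergence diagnostics.
Gear effects are labelled *statistically relevant* when the 95%
credibility interval of the contrast excludes zero. A simpler one-way
linear model compares log biomass pooled at the net level.

**Discard survival.** Immediate survival is `alive/total` at deck
arrival with a Beta(alive+1, dead+1) credibility interval; short-term
survival combines deck outcomes with a captive seven-day cohort through
the Kaplan–Meier product-limit estimator with Greenwood variance.
A four-point vitality scale (DEAD < POOR < GOOD < EXCELLENT) tracks
captive condition.

**Composition analysis.** Hellinger-transformed species × sample
matrices feed a PCA (boat centroids and convex hulls for fleet
representativeness) and a redundancy analysis (RDA) of gear type with a
free-permutation F-test, plus a lag-1 within-net autocorrelation check
that justifies treating consecutive walls as exchangeable.

**Synthetic data.** `trammelnet.synthetic_data` generates full datasets
with the trial's hierarchy (3 boats, 70 nets × 22 walls ≈ 1,550 walls;
greca trials as alternating five-wall blocks), so every stage is
testable without any field data. The observed alive-at-arrival counts
ship as a packaged fixture.

## Worked example

```python
import numpy as np
import trammelnet as tn
from trammelnet.synthetic_data import price_table

# immediate survival of discarded undersized lobsters (observed counts)
point, lo, hi = tn.immediate_survival(tn.SurvivalCount("Palinurus elephas", 82, 127))
print(f"immediate survival: {point:.3f} (95% CrI {lo:.2f}-{hi:.2f})")

# gear comparison on synthetic trial-scale data
cfg = tn.revenue_config(seed=1)
walls, items, pools = tn.simulate_catch(cfg)
totals = tn.wall_totals(walls, items, tn.Fate.MARKETABLE, price_table(cfg))
data = tn.HurdleDataset(
    x=np.array([totals[w.wall_id] for w in walls]),
    wall_type=[w.wall_type.value for w in walls],
    boat=[w.boat_id for w in walls],
    net=[w.net_id for w in walls])
post = tn.fit_hurdle(data, tn.FAST_PROFILE, seed=2)
for t in ("PMF", "MMF"):
    p, mu = post.draws(f"p[{t}]"), post.draws(f"mu[{t}]")
    print(f"{t}: occurrence {p.mean():.2f}, mean revenue {mu.mean():.1f} EUR "
          f"({np.quantile(mu, 0.025):.1f}-{np.quantile(mu, 0.975):.1f})")
rel = tn.relevance(post.draws("mu[PMF]"), post.draws("mu[MMF]"))
print(f"PMF-MMF revenue difference: [{rel.cri_low:.1f}, {rel.cri_high:.1f}] -> {rel.label}")
```

prints

```
immediate survival: 0.646 (95% CrI 0.56-0.72)
PMF: occurrence 0.32, mean revenue 40.5 EUR (20.1-62.6)
MMF: occurrence 0.28, mean revenue 43.6 EUR (23.5-66.4)
PMF-MMF revenue difference: [-11.7, 5.4] -> NOT_RELEVANT
```

Two thirds of discarded undersized lobsters arrive on deck alive, and on
data simulated with nearly equal gear parameters the fitted occurrence
probabilities and positive-catch means recover the generating values,
with a credibility interval on the revenue contrast that correctly
covers zero (no relevant gear effect).

The same analyses run end to end from a shell:

```sh
trammelnet --seed 1 --outdir out all        # simulate -> process -> fit -> report
trammelnet --outdir out survival            # one stage only
```

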