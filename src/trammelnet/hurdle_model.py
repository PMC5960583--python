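"""Bayesian hierarchical hurdle-exponential model for per-wall amounts.

Per-netting-wall revenue (Euros) or discard biomass (kg) is modelled in
two parts.  Occurrence is Bernoulli: ``w_i ~ Binomial(p_type)`` with
``w_i = 1`` iff the wall caught anything.  Conditional on a catch, the
amount is exponential with mean

    m_i = mu_type + b_boat(i) + b_net(i),

where ``mu_type`` is the gear-type fixed effect and ``b_boat``,
``b_net`` are zero-mean normal random effects that tie together the
walls of one boat or one net.  Any parameter state with ``m_i <= 0`` on
a positive wall has zero posterior density.

Inference is Metropolis-within-Gibbs.  Because ``w`` is fully observed,
``p_type`` has a conjugate Beta posterior and is drawn exactly each
sweep; the positive-part parameters move by Gaussian random-walk
proposals whose step sizes adapt during burn-in only.  Priors are
weakly informative: ``p ~ Beta(1,1)``, ``mu ~ Uniform(0, U)`` with
``U = 100 x mean(positive amounts)``, ``b ~ Normal(0, sigma^2)`` and
``sigma ~ Half-Normal(scale = SD(positive amounts))`` — the standard
weakly-informative scale prior when a factor has very few levels (a
flat scale prior with three boats leaves the fixed-effect mean with a
divergent posterior variance along the ``mu + mean(b)`` translation).

Also here: the Gelman-Rubin potential-scale-reduction diagnostic, the
per-net expected amount, the 95%-credibility relevance rule used to
label gear effects, and the simpler net-level one-way decomposition of
log biomass.
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "HurdleDataset",
    "HurdleParams",
    "HurdlePosterior",
    "SamplerConfig",
    "FULL_PROFILE",
    "FAST_PROFILE",
    "RelevanceResult",
    "NetExpectation",
    "hurdle_loglik",
    "fit_hurdle",
    "gelman_rubin",
    "net_expectation",
    "relevance",
    "compare_net_level",
]


@dataclass(frozen=True)
class HurdleDataset:
    """Per-wall amounts with their gear type and boat/net grouping."""

    x: np.ndarray            # nonnegative amounts, one per wall
    wall_type: list[str]     # gear type label per wall
    boat: list[str]          # boat label per wall
    net: list[str]           # net label per wall

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "x", x)
        n = len(x)
        if not (len(self.wall_type) == len(self.boat) == len(self.net) == n):
            raise ValueError("x, wall_type, boat and net must have equal length")
        if n == 0:
            raise ValueError("dataset is empty")
        if np.any(x < 0):
            raise ValueError("amounts must be nonnegative")
        net_boat: dict[str, str] = {}
        for nid, bid in zip(self.net, self.boat):
            if net_boat.setdefault(nid, bid) != bid:
                raise ValueError(f"net {nid!r} maps to more than one boat")

    @property
    def w(self) -> np.ndarray:
        """Occurrence indicator: 1 iff the wall caught anything."""
        return (self.x > 0).astype(int)

    @property
    def types(self) -> list[str]:
        return sorted(set(self.wall_type))

    def subset_types(self, keep: Sequence[str]) -> "HurdleDataset":
        keep_set = set(keep)
        idx = [i for i, t in enumerate(self.wall_type) if t in keep_set]
        if not idx:
            raise ValueError(f"no walls with type in {sorted(keep_set)}")
        return HurdleDataset(
            x=self.x[idx],
            wall_type=[self.wall_type[i] for i in idx],
            boat=[self.boat[i] for i in idx],
            net=[self.net[i] for i in idx],
        )


@dataclass(frozen=True)
class HurdleParams:
    """One parameter state of the hurdle model."""

    p_type: Mapping[str, float]
    mu_type: Mapping[str, float]
    b_boat: Mapping[str, float]
    b_net: Mapping[str, float]
    sigma_boat: float = 0.0
    sigma_net: float = 0.0


def hurdle_loglik(params: HurdleParams, data: HurdleDataset) -> float:
    """Log likelihood of the hurdle model; ``-inf`` signals an invalid state.

    A state is invalid when some positive wall has nonpositive mean
    ``m_i = mu_type + b_boat + b_net``; the sampler uses the ``-inf``
    return to reject such proposals.
    """
    total = 0.0
    for xi, t, b, n in zip(data.x, data.wall_type, data.boat, data.net):
        p = params.p_type[t]
        if xi > 0:
            if p <= 0:
                return -math.inf
            m = params.mu_type[t] + params.b_boat.get(b, 0.0) + params.b_net.get(n, 0.0)
            if m <= 0:
                return -math.inf
            total += math.log(p) - math.log(m) - xi / m
        else:
            if p >= 1:
                return -math.inf
            total += math.log1p(-p)
    return total


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplerConfig:
    """MCMC protocol and prior bounds.

    ``n_retained`` counts draws across all chains; each chain runs
    ``burn_in + thin * (n_retained // chains)`` sweeps.  ``mu_upper``
    defaults to 100 x mean of the positive amounts; ``sigma_scale``
    (half-normal prior scale of the random-effect SDs) defaults to the
    SD of the positive amounts.  Fixing a sigma at 0 pins the
    corresponding random effects at zero (useful for
    degenerate/conjugate checks).
    """

    chains: int = 3
    burn_in: int = 10_000
    thin: int = 10
    n_retained: int = 30_000
    mu_upper: float | None = None
    sigma_scale: float | None = None
    sigma_boat_fixed: float | None = None
    sigma_net_fixed: float | None = None
    adapt_interval: int = 50


FULL_PROFILE = SamplerConfig()
FAST_PROFILE = SamplerConfig(burn_in=1_000, thin=5, n_retained=3_000)


class _Scalar:
    """One random-walk-updated scalar with burn-in step adaptation."""

    __slots__ = ("value", "step", "accepted", "tried")

    def __init__(self, value: float, step: float):
        self.value = value
        self.step = max(step, 1e-6)
        self.accepted = 0
        self.tried = 0

    def adapt(self) -> None:
        if self.tried:
            rate = self.accepted / self.tried
            if rate > 0.45:
                self.step *= 1.4
            elif rate < 0.15:
                self.step /= 1.4
        self.accepted = self.tried = 0


def _run_chain(data: HurdleDataset, config: SamplerConfig, seed: int,
               n_draws: int) -> dict[str, np.ndarray]:
    rng = random.Random(seed)
    types = data.types
    boats = sorted(set(data.boat))
    nets = sorted(set(data.net))
    t_idx = {t: i for i, t in enumerate(types)}
    b_idx = {b: i for i, b in enumerate(boats)}
    n_idx = {n: i for i, n in enumerate(nets)}
    nb: dict[str, str] = {}
    for nid, bid in zip(data.net, data.boat):
        nb.setdefault(nid, bid)
    net_boat = [b_idx[nb[n]] for n in nets]

    x = data.x
    w = data.w
    # occurrence sufficient statistics per type
    n1 = [0] * len(types)
    n0 = [0] * len(types)
    for wi, t in zip(w, data.wall_type):
        if wi:
            n1[t_idx[t]] += 1
        else:
            n0[t_idx[t]] += 1

    # positive walls grouped by (type, net): count and sum suffice for the
    # exponential likelihood, so every update is O(groups) not O(walls)
    gkey: dict[tuple[int, int], int] = {}
    g_n: list[float] = []
    g_S: list[float] = []
    g_type: list[int] = []
    g_net: list[int] = []
    g_boat: list[int] = []
    for xi, t, nid in zip(x, data.wall_type, data.net):
        if xi <= 0:
            continue
        key = (t_idx[t], n_idx[nid])
        if key not in gkey:
            gkey[key] = len(g_n)
            g_n.append(0.0)
            g_S.append(0.0)
            g_type.append(key[0])
            g_net.append(key[1])
            g_boat.append(net_boat[key[1]])
        gi = gkey[key]
        g_n[gi] += 1.0
        g_S[gi] += float(xi)
    n_groups = len(g_n)
    groups_of_type = [[g for g in range(n_groups) if g_type[g] == ti]
                      for ti in range(len(types))]
    groups_of_boat = [[g for g in range(n_groups) if g_boat[g] == bi]
                      for bi in range(len(boats))]
    groups_of_net = [[g for g in range(n_groups) if g_net[g] == ni]
                     for ni in range(len(nets))]

    pos = x[x > 0]
    pos_mean = float(pos.mean()) if pos.size else 1.0
    pos_sd = float(pos.std(ddof=1)) if pos.size > 1 else max(pos_mean, 1.0)
    mu_upper = config.mu_upper if config.mu_upper is not None else 100.0 * pos_mean
    sigma_scale = (config.sigma_scale if config.sigma_scale is not None
                   else pos_sd)

    empty_types = [ti for ti in range(len(types)) if not groups_of_type[ti]]
    for ti in empty_types:
        warnings.warn(
            f"gear type {types[ti]!r} has no positive walls; its mu is a prior draw",
            stacklevel=3)

    # state
    mu = [_Scalar(pos_mean if groups_of_type[ti] else mu_upper / 2.0,
                  0.25 * pos_mean) for ti in range(len(types))]
    est_sb = config.sigma_boat_fixed is None
    est_sn = config.sigma_net_fixed is None
    sb = _Scalar(0.25 * pos_sd if est_sb else float(config.sigma_boat_fixed),
                 0.1 * pos_sd)
    sn = _Scalar(0.25 * pos_sd if est_sn else float(config.sigma_net_fixed),
                 0.1 * pos_sd)
    bb = [_Scalar(rng.gauss(0.0, 0.05 * pos_sd) if est_sb else 0.0,
                  0.1 * pos_sd) for _ in boats]
    bn = [_Scalar(rng.gauss(0.0, 0.05 * pos_sd) if est_sn else 0.0,
                  0.1 * pos_sd) for _ in nets]
    p_cur = [0.5] * len(types)

    def group_ll(gi: int, m: float) -> float:
        if m <= 0:
            return -math.inf
        return -g_n[gi] * math.log(m) - g_S[gi] / m

    def mean_of(gi: int) -> float:
        return mu[g_type[gi]].value + bb[g_boat[gi]].value + bn[g_net[gi]].value

    def mh_groups(par: _Scalar, gids: list[int], prior_delta, lo: float,
                  hi: float) -> None:
        """Random-walk update of one scalar affecting the given groups."""
        old = par.value
        new = old + par.step * rng.gauss(0.0, 1.0)
        par.tried += 1
        if new <= lo or new >= hi:
            return
        delta = prior_delta(old, new)
        for gi in gids:
            m_old = mean_of(gi)
            m_new = m_old + (new - old)
            if m_new <= 0:
                return
            delta += group_ll(gi, m_new) - group_ll(gi, m_old)
        if delta >= 0 or rng.random() < math.exp(delta):
            par.value = new
            par.accepted += 1

    def flat_prior(_old: float, _new: float) -> float:
        return 0.0

    def rescale_move(sig: _Scalar, effs: list[_Scalar], eff_of_group: list[int]) -> None:
        """Joint scaling (sigma, b) -> (c sigma, c b): breaks the funnel
        between a random-effect scale and its effects.  The normal prior
        of the effects cancels against the Jacobian up to a factor c."""
        c = math.exp(0.3 * rng.gauss(0.0, 1.0))
        new_sigma = sig.value * c
        delta = (sig.value * sig.value - new_sigma * new_sigma) / \
            (2.0 * sigma_scale * sigma_scale) + math.log(c)
        for gi in range(n_groups):
            m_old = mean_of(gi)
            m_new = m_old + (c - 1.0) * effs[eff_of_group[gi]].value
            if m_new <= 0:
                return
            delta += group_ll(gi, m_new) - group_ll(gi, m_old)
        if delta >= 0 or rng.random() < math.exp(delta):
            sig.value = new_sigma
            for e in effs:
                e.value *= c

    n_iter = config.burn_in + config.thin * n_draws
    out: dict[str, list[float]] = {}
    for t in types:
        out[f"p[{t}]"] = []
        out[f"mu[{t}]"] = []
    for b in boats:
        out[f"b_boat[{b}]"] = []
    for n in nets:
        out[f"b_net[{n}]"] = []
    out["sigma_boat"] = []
    out["sigma_net"] = []

    for it in range(n_iter):
        adapting = it < config.burn_in
        # occurrence probabilities: exact conjugate Beta draw
        for ti in range(len(types)):
            p_cur[ti] = rng.betavariate(1 + n1[ti], 1 + n0[ti])
        # gear-type means
        for ti in range(len(types)):
            if groups_of_type[ti]:
                mh_groups(mu[ti], groups_of_type[ti], flat_prior, 0.0, mu_upper)
            else:
                mu[ti].value = rng.uniform(0.0, mu_upper)
        # boat random effects
        if est_sb or sb.value > 0:
            s2 = 2.0 * sb.value * sb.value
            for bi in range(len(boats)):
                gids = groups_of_boat[bi]
                if gids:
                    mh_groups(bb[bi], gids,
                              lambda o, n, s2=s2: (o * o - n * n) / s2,
                              -math.inf, math.inf)
                else:
                    bb[bi].value = rng.gauss(0.0, sb.value)
        # net random effects
        if est_sn or sn.value > 0:
            s2 = 2.0 * sn.value * sn.value
            for ni in range(len(nets)):
                gids = groups_of_net[ni]
                if gids:
                    mh_groups(bn[ni], gids,
                              lambda o, n, s2=s2: (o * o - n * n) / s2,
                              -math.inf, math.inf)
                else:
                    bn[ni].value = rng.gauss(0.0, sn.value)
        # random-effect scales (uniform prior, normal likelihood of the b's);
        # exact inverse-gamma conditional draw where available
        if est_sb:
            _draw_sigma(sb, [s.value for s in bb], sigma_scale, rng)
            rescale_move(sb, bb, g_boat)
        if est_sn:
            _draw_sigma(sn, [s.value for s in bn], sigma_scale, rng)
            rescale_move(sn, bn, g_net)
        # recentering sweep: the likelihood only sees mu_type + b, so the
        # translation (mu += c, all b -= c) has a tractable normal
        # conditional; sampling it removes the slow drift between the
        # fixed effects and the random-effect mean
        if est_sb or sb.value > 0:
            _recenter(mu, bb, sb.value, mu_upper, rng)
        if est_sn or sn.value > 0:
            _recenter(mu, bn, sn.value, mu_upper, rng)

        if adapting and (it + 1) % config.adapt_interval == 0:
            for par in mu + bb + bn + [sb, sn]:
                par.adapt()
        if not adapting and (it - config.burn_in + 1) % config.thin == 0:
            for ti, t in enumerate(types):
                out[f"p[{t}]"].append(p_cur[ti])
                out[f"mu[{t}]"].append(mu[ti].value)
            for bi, b in enumerate(boats):
                out[f"b_boat[{b}]"].append(bb[bi].value)
            for ni, n in enumerate(nets):
                out[f"b_net[{n}]"].append(bn[ni].value)
            out["sigma_boat"].append(sb.value)
            out["sigma_net"].append(sn.value)

    return {k: np.asarray(v) for k, v in out.items()}


def _draw_sigma(par: _Scalar, effects: list[float], scale: float,
                rng: random.Random) -> None:
    """Update a random-effect scale given its effects.

    Target: half-normal prior (given ``scale``) times the normal
    likelihood of the effects.  Proposal: exact draw from
    likelihood x flat, i.e. sigma^2 ~ InvGamma((k-1)/2, sum(b^2)/2);
    the Metropolis-Hastings ratio then reduces to the half-normal
    prior ratio, giving an independence sampler with high acceptance
    that automatically rejects implausibly large excursions.
    Degenerate cases fall back to a random-walk step.
    """
    k = len(effects)
    sq = sum(e * e for e in effects)
    a2 = 2.0 * scale * scale
    if k >= 2 and sq > 0:
        g = rng.gammavariate((k - 1) / 2.0, 2.0 / sq)
        if g > 0:
            new = 1.0 / math.sqrt(g)
            old = par.value
            delta = (old * old - new * new) / a2
            if delta >= 0 or rng.random() < math.exp(delta):
                par.value = new
        return
    old = par.value
    new = old + par.step * rng.gauss(0.0, 1.0)
    par.tried += 1
    if new <= 0:
        return
    delta = (-k * math.log(new) - sq / (2 * new * new) - new * new / a2
             + k * math.log(old) + sq / (2 * old * old) + old * old / a2)
    if delta >= 0 or rng.random() < math.exp(delta):
        par.value = new
        par.accepted += 1


def _recenter(mu: list[_Scalar], effects: list[_Scalar], sigma: float,
              mu_upper: float, rng: random.Random) -> None:
    """Gibbs draw of the translation c: mu_t += c, every effect b_j -= c.

    The likelihood is invariant along this direction, so c has the
    conditional N(mean(b), sigma^2/k) truncated to keep every mu_t in
    (0, mu_upper).
    """
    if sigma <= 0:
        return
    k = len(effects)
    bbar = sum(e.value for e in effects) / k
    sd = sigma / math.sqrt(k)
    lo = -min(m.value for m in mu)
    hi = mu_upper - max(m.value for m in mu)
    for _ in range(50):
        c = rng.gauss(bbar, sd)
        if lo < c < hi:
            for m in mu:
                m.value += c
            for e in effects:
                e.value -= c
            return


@dataclass
class HurdlePosterior:
    """Retained MCMC samples, organised per parameter and chain."""

    samples: dict[str, np.ndarray]  # name -> (n_chains, n_draws)
    n_burn: int
    n_thin: int
    seed: int
    types: list[str]
    boats: list[str]
    nets: list[str]

    @property
    def n_chains(self) -> int:
        return next(iter(self.samples.values())).shape[0]

    @property
    def n_retained(self) -> int:
        arr = next(iter(self.samples.values()))
        return arr.shape[0] * arr.shape[1]

    def draws(self, name: str) -> np.ndarray:
        """All retained draws of one parameter, chains concatenated."""
        return self.samples[name].reshape(-1)

    def rhat(self) -> dict[str, float]:
        return {name: gelman_rubin(arr) for name, arr in self.samples.items()}

    def summary(self):
        """Posterior mean, 95% credibility bounds and R-hat per parameter."""
        import pandas as pd

        rows = []
        for name, arr in self.samples.items():
            flat = arr.reshape(-1)
            rows.append({
                "parameter": name,
                "mean": float(flat.mean()),
                "cri_2.5": float(np.quantile(flat, 0.025)),
                "cri_97.5": float(np.quantile(flat, 0.975)),
                "rhat": gelman_rubin(arr),
            })
        return pd.DataFrame(rows)


def fit_hurdle(data: HurdleDataset, config: SamplerConfig = FULL_PROFILE,
               seed: int = 0) -> HurdlePosterior:
    """Fit the hurdle model by Metropolis-within-Gibbs MCMC.

    Runs ``config.chains`` independent chains (seeds derived from
    ``seed``), discards ``burn_in`` sweeps, retains every ``thin``-th
    state until ``n_retained`` total draws are collected.  Identical
    seeds give identical chains.
    """
    if config.chains < 1:
        raise ValueError("need at least one chain")
    n_draws = config.n_retained // config.chains
    if n_draws < 1:
        raise ValueError("n_retained smaller than chain count")
    master = random.Random(seed)
    chain_seeds = [master.randrange(2 ** 31) for _ in range(config.chains)]
    per_chain = [_run_chain(data, config, cs, n_draws) for cs in chain_seeds]
    names = per_chain[0].keys()
    samples = {name: np.stack([c[name] for c in per_chain]) for name in names}
    return HurdlePosterior(
        samples=samples, n_burn=config.burn_in, n_thin=config.thin, seed=seed,
        types=data.types, boats=sorted(set(data.boat)), nets=sorted(set(data.net)),
    )


# ---------------------------------------------------------------------------
# Diagnostics and derived quantities
# ---------------------------------------------------------------------------

def gelman_rubin(chains) -> float:
    """Potential scale reduction R-hat for one parameter.

    ``chains`` is (m, n): m >= 2 chains of equal length n >= 2.  Uses
    R-hat = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B = n * variance of the chain means (both with the
    n-1 denominator).  Returns ``inf`` with a warning when W = 0.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need >= 2 chains of equal length >= 2")
    n = arr.shape[1]
    within = float(arr.var(axis=1, ddof=1).mean())
    between = n * float(arr.mean(axis=1).var(ddof=1))
    if within == 0:
        warnings.warn("zero within-chain variance; R-hat undefined", stacklevel=2)
        return math.inf
    return math.sqrt(((n - 1) / n * within + between / n) / within)


@dataclass(frozen=True)
class NetExpectation:
    """Posterior draws of the expected amount for an average net."""

    draws: np.ndarray
    mean: float
    cri_low: float
    cri_high: float


def net_expectation(posterior: HurdlePosterior, wall_type: str,
                    n_walls: int = 22) -> NetExpectation:
    """Expected amount per net of ``n_walls`` walls: n * p_type * mu_type.

    The boat/net random effects integrate out at their zero mean, so the
    per-draw expectation combines only the occurrence probability and
    the positive-part mean.
    """
    if wall_type not in posterior.types:
        raise KeyError(f"unknown gear type {wall_type!r}")
    draws = n_walls * posterior.draws(f"p[{wall_type}]") * posterior.draws(f"mu[{wall_type}]")
    return NetExpectation(
        draws=draws, mean=float(draws.mean()),
        cri_low=float(np.quantile(draws, 0.025)),
        cri_high=float(np.quantile(draws, 0.975)),
    )


@dataclass(frozen=True)
class RelevanceResult:
    """95% credibility interval of a difference and its relevance label."""

    quantity: str
    cri_low: float
    cri_high: float
    reference: float
    label: str  # RELEVANT | NOT_RELEVANT

    @property
    def relevant(self) -> bool:
        return self.label == "RELEVANT"


def relevance(samples_a, samples_b=0.0, reference: float = 0.0,
              quantity: str = "difference") -> RelevanceResult:
    """Label a posterior difference by the 95% credibility interval rule.

    The difference ``a - b`` (``b`` may be a paired draw sequence or a
    constant) is RELEVANT when its central 95% interval excludes the
    reference value, NOT_RELEVANT when the interval covers it.
    """
    a = np.asarray(samples_a, dtype=float)
    if a.ndim != 1 or a.size < 100:
        raise ValueError("need at least 100 draws")
    if np.ndim(samples_b) == 0:
        diff = a - float(samples_b)
    else:
        b = np.asarray(samples_b, dtype=float)
        if b.shape != a.shape:
            raise ValueError("paired draw sequences must have equal length")
        diff = a - b
    lo, hi = (float(np.quantile(diff, q)) for q in (0.025, 0.975))
    label = "NOT_RELEVANT" if lo <= reference <= hi else "RELEVANT"
    return RelevanceResult(quantity=quantity, cri_low=lo, cri_high=hi,
                           reference=reference, label=label)


def compare_net_level(net_log_totals, types) -> tuple[float, float, float, float]:
    """One-way least-squares comparison of net-level log biomass.

    Returns (SS_effect, SS_residual, F, p) for the gear-type factor; the
    simple linear-model route used once the pooled net totals look
    log-normal.
    """
    y = np.asarray(net_log_totals, dtype=float)
    labels = list(types)
    if y.ndim != 1 or len(labels) != y.size:
        raise ValueError("values and labels must be equal-length 1-D")
    levels = sorted(set(labels))
    if len(levels) < 2:
        raise ValueError("need at least two gear types")
    df1 = len(levels) - 1
    df2 = y.size - len(levels)
    if df2 < 1:
        raise ValueError("no residual degrees of freedom")
    grand = y.mean()
    ss_effect = 0.0
    ss_resid = 0.0
    for lev in levels:
        sel = y[[lab == lev for lab in labels]]
        ss_effect += sel.size * (sel.mean() - grand) ** 2
        ss_resid += float(((sel - sel.mean()) ** 2).sum())
    f_stat = (ss_effect / df1) / (ss_resid / df2) if ss_resid > 0 else math.inf
    p = float(stats.f.sf(f_stat, df1, df2)) if math.isfinite(f_stat) else 0.0
    return ss_effect, ss_resid, f_stat, p
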