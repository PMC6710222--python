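"""Differential-evolution MCMC (DE-MCMC) and power-posterior sampling.

The sampler works on any *target* object exposing

* ``k`` / ``param_names`` — dimension and names of the free parameters,
* ``log_prior(thetas)`` and ``log_lik(thetas)`` — vectorized over a
  (chains, k) batch, returning (chains,) arrays (-inf outside support),
* ``sample_prior(rng, size)`` — initialization draws,
* optionally ``per_trial_log_lik(thetas)`` — an (S, n) matrix for WAIC.

Proposals are scaled chain differences, theta* = theta_i +
gamma (theta_m - theta_n) + eps, with gamma = 2.38 / sqrt(2k) and eps
uniform on (-0.001, 0.001) per coordinate. During burn-in a migration step
(probability 0.05) cycles states through a random subset of chains to
reabsorb outlier chains. Power posteriors for thermodynamic integration
run as a single population in which chain j targets
prior x likelihood^t_j on a fifth-power temperature ladder.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PosteriorSamples",
    "TemperatureLadder",
    "demcmc_sample",
    "power_posterior_run",
    "default_ladder",
    "split_rhat",
]


@dataclass
class PosteriorSamples:
    """Retained DE-MCMC draws plus the per-draw quantities the metrics need."""

    draws: np.ndarray  # (chains, keep, k)
    log_lik: np.ndarray  # (chains, keep)
    log_prior: np.ndarray  # (chains, keep)
    param_names: tuple
    temperature: float = 1.0
    per_trial_log_lik: Optional[np.ndarray] = None  # (S, n_trials)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def S(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    @property
    def flat_draws(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[2])

    @property
    def flat_log_lik(self) -> np.ndarray:
        return self.log_lik.reshape(-1)

    @property
    def flat_log_posterior(self) -> np.ndarray:
        return (self.log_lik + self.log_prior).reshape(-1)

    def rhat(self) -> dict:
        return dict(zip(self.param_names, split_rhat(self.draws)))

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            draws=self.draws,
            log_lik=self.log_lik,
            log_prior=self.log_prior,
            param_names=np.array(self.param_names),
            temperature=self.temperature,
            **(
                {"per_trial_log_lik": self.per_trial_log_lik}
                if self.per_trial_log_lik is not None
                else {}
            ),
        )

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                draws=z["draws"],
                log_lik=z["log_lik"],
                log_prior=z["log_prior"],
                param_names=tuple(str(s) for s in z["param_names"]),
                temperature=float(z["temperature"]),
                per_trial_log_lik=(
                    z["per_trial_log_lik"] if "per_trial_log_lik" in z else None
                ),
            )


@dataclass
class TemperatureLadder:
    """Ordered temperatures t_1 = 0 < ... < t_J = 1 with mean log-likelihoods."""

    temperatures: np.ndarray
    mean_log_lik: Optional[np.ndarray] = None
    samples: Optional[PosteriorSamples] = None  # chain j targets temperature j

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if abs(t[0]) > 1e-12 or abs(t[-1] - 1.0) > 1e-12:
            raise ValueError("temperature ladder must span [0, 1]")
        self.temperatures = t

    @property
    def J(self) -> int:
        return self.temperatures.size


def default_ladder(n_temperatures: int = 40, power: float = 5.0) -> np.ndarray:
    """Fifth-power schedule t_j = ((j-1)/(J-1))^5, concentrating near zero."""
    j = np.arange(n_temperatures, dtype=float)
    return (j / (n_temperatures - 1)) ** power


def split_rhat(draws: np.ndarray) -> np.ndarray:
    """Split-chain potential-scale-reduction diagnostic per parameter."""
    chains, n, k = draws.shape
    half = n // 2
    if half < 2:
        return np.full(k, np.nan)
    x = np.concatenate([draws[:, :half, :], draws[:, half : 2 * half, :]], axis=0)
    m, n2 = x.shape[0], x.shape[1]
    chain_means = x.mean(axis=1)  # (m, k)
    chain_vars = x.var(axis=1, ddof=1)  # (m, k)
    W = chain_vars.mean(axis=0)
    B = n2 * chain_means.var(axis=0, ddof=1)
    var_hat = (n2 - 1) / n2 * W + B / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(var_hat / W)


def _initialize(target, n_chains, rng, max_tries=1000):
    theta = np.empty((n_chains, target.k))
    lp = np.full(n_chains, -np.inf)
    ll = np.full(n_chains, -np.inf)
    todo = np.arange(n_chains)
    for _ in range(max_tries):
        cand = target.sample_prior(rng, todo.size)
        clp = target.log_prior(cand)
        ok = np.isfinite(clp)
        if ok.any():
            cll = np.full(todo.size, -np.inf)
            cll[ok] = target.log_lik(cand[ok])
            good = ok & np.isfinite(cll)
            theta[todo[good]] = cand[good]
            lp[todo[good]] = clp[good]
            ll[todo[good]] = cll[good]
            todo = todo[~good]
        if todo.size == 0:
            return theta, lp, ll
    raise RuntimeError("failed to initialize chains at a finite log-posterior")


def _crossover(target, theta, lp, ll, temps, gamma, eps, rng, window=None):
    C, k = theta.shape
    i = np.arange(C)
    if window is None:
        m = rng.integers(0, C - 1, C)
        m[m >= i] += 1
        n = rng.integers(0, C - 2, C)
        lo = np.minimum(m, i)
        hi = np.maximum(m, i)
        n[n >= lo] += 1
        n[n >= hi] += 1
    else:
        # difference vectors mostly from chains at nearby temperatures, whose
        # targets (and hence scales) resemble chain i's own power posterior;
        # an occasional global difference keeps long-range moves available
        lo_i = np.clip(i - window, 0, C - 1)
        hi_i = np.clip(i + window, 0, C - 1)
        glob = rng.uniform(size=C) < 0.1
        lo_i[glob] = 0
        hi_i[glob] = C - 1
        m = rng.integers(lo_i, hi_i + 1)
        n = rng.integers(lo_i, hi_i + 1)
        redraw = (m == n) | (m == i) | (n == i)
        while redraw.any():
            m[redraw] = rng.integers(lo_i[redraw], hi_i[redraw] + 1)
            n[redraw] = rng.integers(lo_i[redraw], hi_i[redraw] + 1)
            redraw = (m == n) | (m == i) | (n == i)
    prop = theta + gamma * (theta[m] - theta[n]) + rng.uniform(-eps, eps, (C, k))
    plp = target.log_prior(prop)
    pll = np.full(C, -np.inf)
    ok = np.isfinite(plp)
    if ok.any():
        pll[ok] = target.log_lik(prop[ok])
    # at t = 0 the likelihood drops out entirely (0 * -inf guarded to 0)
    hot = temps > 0
    t_pll = np.zeros(C)
    t_ll = np.zeros(C)
    t_pll[hot] = temps[hot] * pll[hot]
    t_ll[hot] = temps[hot] * ll[hot]
    log_alpha = (plp + t_pll) - (lp + t_ll)
    accept = np.log(rng.uniform(size=C)) < log_alpha
    accept &= np.isfinite(plp)
    theta[accept] = prop[accept]
    lp[accept] = plp[accept]
    ll[accept] = pll[accept]
    return theta, lp, ll


def _neighbor_swaps(theta, lp, ll, temps, rng):
    """Parallel-tempering swaps between adjacent temperatures (random parity)."""
    C = theta.shape[0]
    start = int(rng.integers(0, 2))
    j = np.arange(start, C - 1, 2)
    log_alpha = (temps[j] - temps[j + 1]) * (ll[j + 1] - ll[j])
    accept = np.log(rng.uniform(size=j.size)) < log_alpha
    a = j[accept]
    for arr in (theta, lp, ll):
        arr[a], arr[a + 1] = arr[a + 1].copy(), arr[a].copy()
    return theta, lp, ll


def _migrate(theta, lp, ll, temps, rng):
    C = theta.shape[0]
    size = int(rng.integers(1, C + 1))
    idx = rng.choice(C, size=size, replace=False)
    src = np.roll(idx, 1)  # chain idx[j] is offered the state of idx[j-1]
    log_alpha = (lp[src] + temps[idx] * ll[src]) - (lp[idx] + temps[idx] * ll[idx])
    accept = np.log(rng.uniform(size=size)) < log_alpha
    theta[idx[accept]] = theta[src[accept]]
    lp[idx[accept]] = lp[src[accept]]
    ll[idx[accept]] = ll[src[accept]]
    return theta, lp, ll


def demcmc_sample(
    target,
    n_chains: Optional[int] = None,
    burn: int = 1000,
    keep: int = 1000,
    seed=None,
    rng: Optional[np.random.Generator] = None,
    migration_prob: float = 0.05,
    gamma: Optional[float] = None,
    eps: float = 0.001,
    store_per_trial: bool = True,
) -> PosteriorSamples:
    """Sample the posterior of ``target`` with DE-MCMC.

    Defaults follow the study settings: 3k chains for k free parameters,
    1000 burn-in and 1000 retained iterations per chain. Migration runs
    during burn-in only. Reproducible given ``seed``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    k = target.k
    if n_chains is None:
        n_chains = 3 * k
    if n_chains < k + 2:
        raise ValueError("DE-MCMC needs at least k + 2 chains")
    if gamma is None:
        gamma = 2.38 / np.sqrt(2.0 * k)
    theta, lp, ll = _initialize(target, n_chains, rng)
    temps = np.ones(n_chains)

    draws = np.empty((n_chains, keep, k))
    out_ll = np.empty((n_chains, keep))
    out_lp = np.empty((n_chains, keep))
    for it in range(burn + keep):
        if it < burn and migration_prob > 0 and rng.uniform() < migration_prob:
            theta, lp, ll = _migrate(theta, lp, ll, temps, rng)
        else:
            theta, lp, ll = _crossover(target, theta, lp, ll, temps, gamma, eps, rng)
        if it >= burn:
            j = it - burn
            draws[:, j] = theta
            out_ll[:, j] = ll
            out_lp[:, j] = lp

    per_trial = None
    if store_per_trial and hasattr(target, "per_trial_log_lik"):
        per_trial = target.per_trial_log_lik(draws.reshape(-1, k))
    return PosteriorSamples(
        draws=draws,
        log_lik=out_ll,
        log_prior=out_lp,
        param_names=tuple(target.param_names),
        per_trial_log_lik=per_trial,
    )


def power_posterior_run(
    target,
    temperatures: Optional[Sequence[float]] = None,
    n_temperatures: int = 40,
    burn: int = 1000,
    keep: int = 1000,
    seed=None,
    rng: Optional[np.random.Generator] = None,
    gamma: Optional[float] = None,
    eps: float = 0.001,
    window: int = 3,
) -> TemperatureLadder:
    """Estimate the power-posterior path for thermodynamic integration.

    One DE-MCMC population in which chain j targets
    prior(theta) x likelihood(theta)^t_j; proposal differences are taken
    from chains within ``window`` ladder positions, whose targets have a
    similar scale. At t = 0 the chain samples the prior (proposals are
    rejected only on prior support). Returns the ladder with the
    per-temperature posterior mean of log p(y | theta).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if temperatures is None:
        temperatures = default_ladder(n_temperatures)
    ladder = TemperatureLadder(np.asarray(temperatures, dtype=float))
    J = ladder.J
    k = target.k
    if gamma is None:
        gamma = 2.38 / np.sqrt(2.0 * k)
    theta, lp, ll = _initialize(target, J, rng)
    temps = ladder.temperatures

    draws = np.empty((J, keep, k))
    out_ll = np.empty((J, keep))
    out_lp = np.empty((J, keep))
    for it in range(burn + keep):
        theta, lp, ll = _crossover(
            target, theta, lp, ll, temps, gamma, eps, rng, window=window
        )
        theta, lp, ll = _neighbor_swaps(theta, lp, ll, temps, rng)
        if it >= burn:
            j = it - burn
            draws[:, j] = theta
            out_ll[:, j] = ll
            out_lp[:, j] = lp

    ladder.mean_log_lik = out_ll.mean(axis=1)
    ladder.samples = PosteriorSamples(
        draws=draws,
        log_lik=out_ll,
        log_prior=out_lp,
        param_names=tuple(target.param_names),
        temperature=np.nan,
    )
    return ladder
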