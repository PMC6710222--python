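"""Model and results classes for fitting LBA variants to choice-RT data.

:class:`LBAModel` binds a dataset to one of the four nested variants and
exposes the target interface consumed by the DE-MCMC sampler;
:meth:`LBAModel.fit` returns an :class:`LBAResults` carrying the posterior
draws, point estimates with uncertainties, convergence diagnostics, and the
model-selection quantities (information criteria, bridge-sampling and
thermodynamic-integration marginal likelihoods, ROPE decisions).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels, metrics as _metrics
from .lba import DENSITY_FLOOR, ChoiceRTDataset
from .model_space import ModelSpec, build_model
from .sampler import (
    PosteriorSamples,
    TemperatureLadder,
    demcmc_sample,
    power_posterior_run,
)

__all__ = ["LBAModel", "LBAResults"]


class LBAModel:
    """An LBA variant bound to a choice-RT dataset.

    Parameters
    ----------
    data : ChoiceRTDataset or DataFrame with condition/response/rt columns.
    variant : one of "null", "drift", "threshold", "complex".
    parameterization : "per-condition" or "mean-diff".
    prior_level : "default", or one of "UP", "WIP", "MIP", "HIP" for the
        informed priors on the condition difference (mean-diff only).
    density_floor : per-trial likelihood floor applied before the log.
    """

    def __init__(
        self,
        data,
        variant: str = "null",
        parameterization: str = "per-condition",
        prior_level: str = "default",
        density_floor: float = DENSITY_FLOOR,
    ):
        if isinstance(data, pd.DataFrame):
            data = ChoiceRTDataset.from_frame(data)
        if not isinstance(data, ChoiceRTDataset):
            raise TypeError("data must be a ChoiceRTDataset or a DataFrame")
        self.data = data
        self.spec: ModelSpec = build_model(variant, parameterization, prior_level)
        self.density_floor = float(density_floor)
        self._cond0 = (data.condition - 1).astype(np.int64)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "LBAModel":
        return cls(ChoiceRTDataset.from_frame(df), **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "LBAModel":
        return cls(ChoiceRTDataset.from_csv(path), **kwargs)

    # -- target interface used by the sampler ------------------------------
    @property
    def k(self) -> int:
        return self.spec.k

    @property
    def param_names(self):
        return self.spec.param_names

    def log_prior(self, thetas):
        return self.spec.log_prior(thetas)

    def log_lik(self, thetas):
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        cond, valid = self.spec.condition_params_batch(thetas)
        out = np.full(thetas.shape[0], -np.inf)
        if self.data.n_trials == 0:
            out[valid] = 0.0
            return out
        if valid.any():
            out[valid] = _kernels.loglik_chains(
                np.ascontiguousarray(cond[valid]),
                self.data.rt,
                self._cond0,
                self.data.correct,
                self.density_floor,
            )
        return out

    def per_trial_log_lik(self, thetas):
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        cond, valid = self.spec.condition_params_batch(thetas)
        if not valid.all():
            raise ValueError("per-trial log-likelihood requested outside support")
        return _kernels.per_trial_loglik(
            np.ascontiguousarray(cond),
            self.data.rt,
            self._cond0,
            self.data.correct,
            self.density_floor,
        )

    def sample_prior(self, rng, size):
        return self.spec.sample_prior(rng, size)

    def loglike(self, theta) -> float:
        """Total log-likelihood at a single parameter vector (-inf off-support)."""
        return float(self.log_lik(np.atleast_2d(theta))[0])

    def log_unnormalized_posterior(self, thetas):
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        lp = self.log_prior(thetas)
        out = np.full(thetas.shape[0], -np.inf)
        ok = np.isfinite(lp)
        if ok.any():
            out[ok] = lp[ok] + self.log_lik(thetas[ok])
        return out

    # -- fitting ------------------------------------------------------------
    def fit(
        self,
        n_chains: Optional[int] = None,
        burn: int = 1000,
        keep: int = 1000,
        seed=None,
        migration_prob: float = 0.05,
        store_per_trial: bool = True,
    ) -> "LBAResults":
        """Posterior sampling by DE-MCMC (defaults: 3k chains, 1000/1000)."""
        samples = demcmc_sample(
            self,
            n_chains=n_chains,
            burn=burn,
            keep=keep,
            seed=seed,
            migration_prob=migration_prob,
            store_per_trial=store_per_trial,
        )
        return LBAResults(self, samples)

    def fit_power_posterior(
        self,
        n_temperatures: int = 40,
        burn: int = 1000,
        keep: int = 1000,
        seed=None,
    ) -> TemperatureLadder:
        """Power-posterior ladder for thermodynamic integration (default 40 temperatures)."""
        return power_posterior_run(
            self, n_temperatures=n_temperatures, burn=burn, keep=keep, seed=seed
        )


class LBAResults:
    """Posterior fit of one LBA variant: estimates, diagnostics, metrics."""

    def __init__(self, model: LBAModel, samples: PosteriorSamples):
        self.model = model
        self.samples = samples
        flat = samples.flat_draws
        self.params = pd.Series(flat.mean(axis=0), index=model.param_names)
        self.bse = pd.Series(flat.std(axis=0, ddof=1), index=model.param_names)

    @property
    def k(self) -> int:
        return self.model.k

    @property
    def nobs(self) -> int:
        return self.model.data.n_trials

    @property
    def max_loglik(self) -> float:
        """Best log-likelihood contained in the posterior draws."""
        return float(self.samples.flat_log_lik.max())

    @property
    def deviance(self) -> float:
        return -2.0 * self.max_loglik

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        lo, hi = np.quantile(
            self.samples.flat_draws, [alpha / 2, 1 - alpha / 2], axis=0
        )
        return pd.DataFrame(
            {"lower": lo, "upper": hi}, index=list(self.model.param_names)
        )

    def rhat(self) -> pd.Series:
        return pd.Series(self.samples.rhat())

    # -- selection metrics ---------------------------------------------------
    def aic(self) -> float:
        return _metrics.aic(self.max_loglik, self.k).value

    def bic(self) -> float:
        return _metrics.bic(self.max_loglik, self.k, self.nobs).value

    def dic(self) -> float:
        return _metrics.dic(self.samples.flat_log_lik).value

    def waic(self) -> float:
        if self.samples.per_trial_log_lik is None:
            raise ValueError("fit with store_per_trial=True to compute WAIC")
        return _metrics.waic(self.samples.per_trial_log_lik).value

    def dic_p(self) -> float:
        return _metrics.dic_p(self.samples.flat_log_posterior).value

    def bridge_logml(self, seed=None, **kwargs) -> float:
        return _metrics.bridge_logml(
            self.samples, self.model.log_unnormalized_posterior, seed=seed, **kwargs
        ).value

    def condition_differences(self) -> dict:
        """Posterior draws of condition-2 minus condition-1 effects on v_c and b."""
        cond, _ = self.model.spec.condition_params_batch(self.samples.flat_draws)
        return {
            "v_c": cond[:, 1, 0] - cond[:, 0, 0],
            "b": cond[:, 1, 5] - cond[:, 0, 5],
        }

    def rope_decision(self, bounds=None):
        d = self.condition_differences()
        return _metrics.rope_select(d["v_c"], d["b"], bounds=bounds)

    def summary(self) -> str:
        spec = self.model.spec
        ci = self.conf_int()
        lines = [
            "LBA model fit (DE-MCMC)",
            "=" * 58,
            f"variant: {spec.variant:<12} parameterization: {spec.parameterization}",
            f"prior level: {spec.prior_level:<8} trials: {self.nobs}   "
            f"draws: {self.samples.S} ({self.samples.n_chains} chains)",
            "-" * 58,
            f"{'parameter':<12}{'mean':>9}{'sd':>9}{'2.5%':>9}{'97.5%':>9}{'rhat':>8}",
        ]
        rh = self.rhat()
        for name in self.model.param_names:
            lines.append(
                f"{name:<12}{self.params[name]:>9.3f}{self.bse[name]:>9.3f}"
                f"{ci.loc[name, 'lower']:>9.3f}{ci.loc[name, 'upper']:>9.3f}"
                f"{rh[name]:>8.3f}"
            )
        lines += [
            "-" * 58,
            f"max log-lik: {self.max_loglik:.2f}   AIC: {self.aic():.2f}   "
            f"BIC: {self.bic():.2f}   DIC: {self.dic():.2f}",
        ]
        return "\n".join(lines)
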