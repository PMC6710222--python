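"""Fit the four nested LBA variants to one dataset and apply all selection methods."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .metrics import ALL_METHODS, DEVIANCE_METHODS, LOGML_METHODS, RopeBounds
from .model import LBAModel, LBAResults
from .model_space import VARIANTS
from .sampler import demcmc_sample, power_posterior_run
from .scoring import model_weights, rope_weights

__all__ = ["SelectionResult", "compare_models"]


@dataclass
class SelectionResult:
    """Per-method metric values, probability weights, and selected variants."""

    values: pd.DataFrame  # method x variant metric values (NaN for decision rules)
    weights: pd.DataFrame  # method x variant probability weights
    selected: dict  # method -> selected variant
    details: dict = field(default_factory=dict)
    fits: Optional[dict] = None

    def to_tidy(self, **ids) -> pd.DataFrame:
        """Long-format rows: one per (method, variant), with ids prepended."""
        rows = []
        for method in self.values.index:
            scale = (
                "deviance"
                if method in DEVIANCE_METHODS
                else "log-marginal-likelihood"
                if method in LOGML_METHODS
                else "decision"
            )
            for variant in self.values.columns:
                rows.append(
                    {
                        **ids,
                        "method": method,
                        "variant": variant,
                        "value": self.values.loc[method, variant],
                        "scale": scale,
                        "weight": self.weights.loc[method, variant],
                        "selected": self.selected[method] == variant,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Model selection across LBA variants", "=" * 60]
        with pd.option_context("display.width", 120):
            lines.append(self.values.round(2).to_string())
        lines.append("-" * 60)
        lines.append("selected: " + ", ".join(f"{m}={v}" for m, v in self.selected.items()))
        return "\n".join(lines)


def compare_models(
    data,
    methods: Sequence[str] = ALL_METHODS,
    parameterization: str = "per-condition",
    prior_level: str = "default",
    n_chains: Optional[int] = None,
    burn: int = 1000,
    keep: int = 1000,
    n_temperatures: int = 40,
    ti_burn: Optional[int] = None,
    ti_keep: Optional[int] = None,
    alpha: float = 0.05,
    rope_bounds: Optional[RopeBounds] = None,
    seed=None,
    keep_fits: bool = False,
) -> SelectionResult:
    """Fit all four variants and evaluate the requested selection methods.

    Child seeds for each (variant, task) are spawned deterministically from
    ``seed``, so the full evaluation is reproducible and individual jobs are
    order-independent.
    """
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = {
        (variant, task): np.random.default_rng(
            np.random.SeedSequence(
                entropy=ss.entropy, spawn_key=ss.spawn_key + (vi, ti)
            )
        )
        for vi, variant in enumerate(VARIANTS)
        for ti, task in enumerate(("fit", "bridge", "ti"))
    }
    need_waic = "WAIC" in methods
    need_ti = "BF-TI" in methods

    values = pd.DataFrame(np.nan, index=list(methods), columns=list(VARIANTS))
    weights = pd.DataFrame(np.nan, index=list(methods), columns=list(VARIANTS))
    fits = {}
    details = {}

    for variant in VARIANTS:
        model = LBAModel(data, variant, parameterization, prior_level)
        samples = demcmc_sample(
            model,
            n_chains=n_chains,
            burn=burn,
            keep=keep,
            rng=children[(variant, "fit")],
            store_per_trial=need_waic,
        )
        res = LBAResults(model, samples)
        fits[variant] = res
        if "AIC" in methods:
            values.loc["AIC", variant] = res.aic()
        if "BIC" in methods:
            values.loc["BIC", variant] = res.bic()
        if "DIC" in methods:
            values.loc["DIC", variant] = res.dic()
        if "WAIC" in methods:
            values.loc["WAIC", variant] = res.waic()
        if "DICp" in methods:
            values.loc["DICp", variant] = res.dic_p()
        if "BF-BS" in methods:
            values.loc["BF-BS", variant] = _metrics.bridge_logml(
                samples,
                model.log_unnormalized_posterior,
                rng=children[(variant, "bridge")],
            ).value
        if need_ti:
            ladder = power_posterior_run(
                model,
                n_temperatures=n_temperatures,
                burn=burn if ti_burn is None else ti_burn,
                keep=keep if ti_keep is None else ti_keep,
                rng=children[(variant, "ti")],
            )
            values.loc["BF-TI", variant] = _metrics.ti_logml(ladder).value

    selected = {}
    for method in methods:
        if method in DEVIANCE_METHODS:
            row = values.loc[method]
            selected[method] = row.idxmin()
            weights.loc[method] = model_weights(row.to_dict(), "deviance").as_series()
        elif method in LOGML_METHODS:
            row = values.loc[method]
            selected[method] = row.idxmax()
            weights.loc[method] = model_weights(row.to_dict(), "log-ml").as_series()
        elif method == "chi2":
            deviances = {v: fits[v].deviance for v in VARIANTS}
            res = _metrics.chi2_select(deviances, alpha=alpha)
            selected["chi2"] = res.variant
            details["chi2_tests"] = res.extra["tests"]
        elif method == "ROPEa":
            res = fits["complex"].rope_decision(bounds=rope_bounds)
            selected["ROPEa"] = res.variant
            details["rope_prop_outside"] = res.extra["prop_outside"]
            weights.loc["ROPEa"] = rope_weights(res.extra["prop_outside"]).as_series()

    return SelectionResult(
        values=values,
        weights=weights,
        selected=selected,
        details=details,
        fits=fits if keep_fits else None,
    )
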