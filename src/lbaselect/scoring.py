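"""Probability weights, Brier scores, and selection-accuracy summaries.

Deviance-scale criteria are converted to model probabilities with
exp(-0.5 x value) weights; marginal-likelihood methods with exp(value)
weights (both normalized after subtracting the best value for stability).
The augmented-ROPE weights are built from the per-effect posterior mass
inside/outside the ROPE, treating the two effects as independent binary
decisions. Raw Brier scores are mapped to an adjusted scale anchored at
1 (perfect forecast), 0 (uniform chance), and -1 (all mass on one wrong
model); the map is piecewise linear between those anchors — a
reconstruction, since only the anchors are fixed by the convention used
here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "WeightVector",
    "BrierOutcome",
    "model_weights",
    "rope_weights",
    "brier",
    "score_cell",
    "agreement_matrix",
    "VARIANT_EFFECTS",
]

#: Which effects (drift, threshold) each variant contains.
VARIANT_EFFECTS = {
    "null": (False, False),
    "drift": (True, False),
    "threshold": (False, True),
    "complex": (True, True),
}


@dataclass
class WeightVector:
    """Normalized model probability weights (sum to 1)."""

    weights: dict
    scale: str

    def __post_init__(self):
        total = sum(self.weights.values())
        if not np.isclose(total, 1.0, atol=1e-12):
            raise ValueError("weights must sum to 1")
        if min(self.weights.values()) < 0:
            raise ValueError("weights must be non-negative")

    def __getitem__(self, key):
        return self.weights[key]

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights)


@dataclass
class BrierOutcome:
    raw: float
    adjusted: float
    true_variant: str
    R: int


def model_weights(values: Mapping[str, float], scale: str) -> WeightVector:
    """Probability weights from per-model metric values.

    ``scale='deviance'``: W_i proportional to exp(-0.5 MSM_i);
    ``scale='log-ml'``: W_i proportional to exp(MSM_i). Computed after
    subtracting the best value; -inf is allowed on the log-ML scale.
    """
    names = list(values)
    if len(names) < 2:
        raise ValueError("need at least two models to weight")
    v = np.array([values[n] for n in names], dtype=float)
    if scale in ("deviance",):
        if not np.isfinite(v).all():
            raise ValueError("deviance-scale values must be finite")
        logw = -0.5 * (v - v.min())
    elif scale in ("log-ml", "log-marginal-likelihood"):
        if np.all(np.isneginf(v)):
            raise ValueError("all log marginal likelihoods are -inf")
        logw = v - v[np.isfinite(v)].max()
    else:
        raise ValueError(f"unknown scale {scale!r}")
    w = np.exp(logw)
    w = w / w.sum()
    return WeightVector(dict(zip(names, w)), scale)


def rope_weights(prop_outside: Mapping[str, float]) -> WeightVector:
    """Model weights from per-effect posterior mass outside the ROPE.

    A variant's weight is the product over effects of the posterior
    proportion outside the ROPE (if the variant includes the effect) or
    inside it (if not), renormalized.
    """
    pd_out = float(prop_outside["v_c"])
    pb_out = float(prop_outside["b"])
    for p in (pd_out, pb_out):
        if not 0.0 <= p <= 1.0:
            raise ValueError("proportions must lie in [0, 1]")
    raw = {
        var: (pd_out if has_d else 1 - pd_out) * (pb_out if has_b else 1 - pb_out)
        for var, (has_d, has_b) in VARIANT_EFFECTS.items()
    }
    total = sum(raw.values())
    if total == 0:  # degenerate: both proportions exactly 0 and 1 impossible
        raw = {k: 0.25 for k in raw}
        total = 1.0
    return WeightVector({k: v / total for k, v in raw.items()}, "posterior-density")


def brier(weights, true_outcome) -> BrierOutcome:
    """Adjusted Brier score of a probabilistic model forecast.

    raw = (1/R) sum_i (f_i - o_i)^2 over the R candidate outcomes. The
    adjusted score maps raw = 0 to 1, the uniform forecast to 0, and the
    worst forecast (all mass on a wrong outcome) to -1, linearly on each
    side of the chance point.
    """
    if isinstance(weights, WeightVector):
        weights = weights.weights
    names = list(weights)
    f = np.array([weights[n] for n in names], dtype=float)
    if true_outcome not in names:
        raise ValueError(f"true outcome {true_outcome!r} not among candidates")
    o = np.array([n == true_outcome for n in names], dtype=float)
    R = len(names)
    raw = float(np.mean((f - o) ** 2))
    b_chance = (R - 1) / R**2
    b_max = 2.0 / R
    if raw <= b_chance:
        adjusted = 1.0 - raw / b_chance
    else:
        adjusted = -(raw - b_chance) / (b_max - b_chance)
    return BrierOutcome(raw, adjusted, str(true_outcome), R)


def _effect_brier(weights: Mapping[str, float], effect_idx: int, present: bool) -> float:
    p_present = sum(
        w for var, w in weights.items() if VARIANT_EFFECTS[var][effect_idx]
    )
    wv = {"present": p_present, "absent": 1.0 - p_present}
    return brier(wv, "present" if present else "absent").adjusted


def score_cell(table: pd.DataFrame, true_variant: str) -> pd.DataFrame:
    """Per-method selection summaries over the replicates of one design cell.

    ``table`` is tidy with columns [replicate, method, variant, weight,
    selected]; methods without weights (the chi-square test) may carry NaN
    weights and are excluded from Brier scoring. Returns one row per method
    with the proportion of correct selections, per-effect selection
    proportions, and mean adjusted Brier scores (overall and per effect).
    """
    required = {"replicate", "method", "variant", "weight", "selected"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    true_d, true_b = VARIANT_EFFECTS[true_variant]
    rows = []
    for method, g in table.groupby("method", sort=False):
        correct, drift_ok, thresh_ok = [], [], []
        briers, briers_d, briers_b = [], [], []
        for _, rep in g.groupby("replicate", sort=False):
            sel = rep.loc[rep["selected"], "variant"]
            if len(sel) != 1:
                raise ValueError("each replicate needs exactly one selected variant")
            sel = sel.iloc[0]
            sd, sb = VARIANT_EFFECTS[sel]
            correct.append(sel == true_variant)
            drift_ok.append(sd == true_d)
            thresh_ok.append(sb == true_b)
            if rep["weight"].notna().all():
                w = dict(zip(rep["variant"], rep["weight"]))
                briers.append(brier(w, true_variant).adjusted)
                briers_d.append(_effect_brier(w, 0, true_d))
                briers_b.append(_effect_brier(w, 1, true_b))
        rows.append(
            {
                "method": method,
                "n_replicates": len(correct),
                "prop_correct": np.mean(correct),
                "prop_drift_correct": np.mean(drift_ok),
                "prop_threshold_correct": np.mean(thresh_ok),
                "mean_brier": np.mean(briers) if briers else np.nan,
                "mean_brier_drift": np.mean(briers_d) if briers_d else np.nan,
                "mean_brier_threshold": np.mean(briers_b) if briers_b else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("method")


def agreement_matrix(selections: pd.DataFrame) -> pd.DataFrame:
    """Proportion of replicates on which each pair of methods agrees.

    ``selections`` is wide: one row per replicate, one column per method,
    entries are selected variants. The result is symmetric with unit
    diagonal.
    """
    methods = list(selections.columns)
    n = len(selections)
    if n == 0:
        raise ValueError("need at least one replicate")
    out = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
    for i, a in enumerate(methods):
        for b in methods[i + 1 :]:
            p = float((selections[a] == selections[b]).mean())
            out.loc[a, b] = out.loc[b, a] = p
    return out
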