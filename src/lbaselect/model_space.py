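"""The four nested LBA variants, their priors, and reparameterizations.

Four sub-models encode which parameters may differ between two
within-subject conditions: ``null`` (nothing varies), ``drift`` (correct
drift rate v_c varies), ``threshold`` (threshold b varies), and ``complex``
(both vary). The threshold is sampled as B = b - A, which keeps the prior
support rectangular; b is recovered as A + B.

Two parameterizations are supported for the varying parameters:

* ``per-condition`` — an independent copy of the default prior per
  condition (v_c,i ~ TN(3, 3, 0, inf), B_i ~ TN(2, 2, 0, inf));
* ``mean-diff`` — the across-condition mean X_mean (default prior) and the
  half-difference X_diff, with X_1 = X_mean - X_diff and
  X_2 = X_mean + X_diff. The difference prior is a zero-mean normal whose
  SD sets the informativeness level: UP (SD 10), WIP (1), MIP (0.1),
  HIP (0.01). X_diff is not truncated; parameter-support violations of the
  mapped condition values are handled by a -inf log-prior.

All truncated-normal priors are TN(mean, SD, 0, inf) — the second argument
is a standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.special import ndtr
from scipy.stats import norm, truncnorm

from .lba import LBAParams

__all__ = [
    "Prior",
    "ModelSpec",
    "build_model",
    "log_prior",
    "theta_to_condition_params",
    "to_mean_diff",
    "from_mean_diff",
    "VARIANTS",
    "PRIOR_LEVELS",
    "DIFF_PRIOR_SD",
]

VARIANTS = ("null", "drift", "threshold", "complex")
PRIOR_LEVELS = ("default", "UP", "WIP", "MIP", "HIP")
DIFF_PRIOR_SD = {"UP": 10.0, "WIP": 1.0, "MIP": 0.1, "HIP": 0.01}

_LOG_SQRT2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class Prior:
    """Univariate prior: a normal or a zero-lower-truncated normal."""

    family: str  # "truncnorm" | "normal"
    mean: float
    sd: float

    def __post_init__(self):
        if self.family not in ("truncnorm", "normal"):
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.sd <= 0:
            raise ValueError("prior SD must be positive")

    @property
    def lower(self) -> float:
        return 0.0 if self.family == "truncnorm" else -np.inf

    def _frozen(self):
        if self.family == "truncnorm":
            a = (0.0 - self.mean) / self.sd
            return truncnorm(a, np.inf, loc=self.mean, scale=self.sd)
        return norm(loc=self.mean, scale=self.sd)

    def logpdf(self, x):
        return self._frozen().logpdf(x)

    def pdf(self, x):
        return self._frozen().pdf(x)

    def rvs(self, rng, size):
        return self._frozen().rvs(size=size, random_state=rng)


_DEFAULTS = {
    "v_c": Prior("truncnorm", 3.0, 3.0),
    "v_e": Prior("truncnorm", 2.0, 3.0),
    "sv_e": Prior("truncnorm", 2.0, 3.0),
    "A": Prior("truncnorm", 2.0, 2.0),
    "B": Prior("truncnorm", 2.0, 2.0),  # prior is on b - A
    "t0": Prior("truncnorm", 0.5, 0.5),
}


def _default_prior(name: str) -> Prior:
    base = name.split("_1")[0].split("_2")[0].replace("_mean", "")
    return _DEFAULTS[base]


@dataclass(frozen=True)
class ModelSpec:
    """A model variant bound to a parameterization and prior set.

    ``param_names`` orders the free parameters; ``priors`` aligns with it.
    The mapping to per-condition accumulator parameters and the joint
    log-prior are vectorized over batches of draws.
    """

    variant: str
    parameterization: str
    prior_level: str
    param_names: Tuple[str, ...]
    priors: Tuple[Prior, ...]

    @property
    def k(self) -> int:
        return len(self.param_names)

    def index(self, name: str) -> int:
        return self.param_names.index(name)

    def _col(self, thetas: np.ndarray, name: str) -> np.ndarray:
        return thetas[:, self.index(name)]

    def _varying(self, thetas: np.ndarray, base: str) -> Tuple[np.ndarray, np.ndarray]:
        """Condition-1 and condition-2 values of a possibly varying parameter."""
        names = self.param_names
        if f"{base}_mean" in names:
            m = self._col(thetas, f"{base}_mean")
            d = self._col(thetas, f"{base}_diff")
            return m - d, m + d
        if f"{base}_1" in names:
            return self._col(thetas, f"{base}_1"), self._col(thetas, f"{base}_2")
        x = self._col(thetas, base)
        return x, x

    def condition_params_batch(self, thetas: np.ndarray):
        """Map draws (C, k) to accumulator parameters (C, 2, 7) + validity mask.

        Columns are [v_c, v_e, sv_c, sv_e, A, b, t0]; b = A + B. A draw is
        invalid (mask False) when any mapped parameter leaves its support —
        in particular when a mean-diff mapping drives v_c or B negative.
        """
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        C = thetas.shape[0]
        vc1, vc2 = self._varying(thetas, "v_c")
        B1, B2 = self._varying(thetas, "B")
        v_e = self._col(thetas, "v_e")
        sv_e = self._col(thetas, "sv_e")
        A = self._col(thetas, "A")
        t0 = self._col(thetas, "t0")

        out = np.empty((C, 2, 7))
        for cond, (vc, B) in enumerate(((vc1, B1), (vc2, B2))):
            out[:, cond, 0] = vc
            out[:, cond, 1] = v_e
            out[:, cond, 2] = 1.0
            out[:, cond, 3] = sv_e
            out[:, cond, 4] = A
            out[:, cond, 5] = A + B
            out[:, cond, 6] = t0
        valid = (
            np.isfinite(thetas).all(axis=1)
            & (vc1 >= 0) & (vc2 >= 0)
            & (B1 >= 0) & (B2 >= 0)
            & (v_e >= 0) & (sv_e > 0) & (A >= 0) & (t0 >= 0)
        )
        return out, valid

    def condition_params(self, theta) -> Tuple[LBAParams, LBAParams]:
        arr, valid = self.condition_params_batch(np.atleast_2d(theta))
        if not valid[0]:
            raise ValueError("theta outside model support")
        out = []
        for cond in range(2):
            r = arr[0, cond]
            out.append(
                LBAParams(v_c=r[0], v_e=r[1], sv_e=r[3], A=r[4], b=r[5], t0=r[6])
            )
        return tuple(out)

    def log_prior(self, thetas):
        """Joint log-prior; -inf outside support. Vectorized over (C, k)."""
        thetas = np.asarray(thetas, dtype=float)
        scalar = thetas.ndim == 1
        thetas = np.atleast_2d(thetas)
        means = np.array([p.mean for p in self.priors])
        sds = np.array([p.sd for p in self.priors])
        trunc = np.array([p.family == "truncnorm" for p in self.priors])
        z = (thetas - means) / sds
        terms = -0.5 * z * z - np.log(sds) - _LOG_SQRT2PI
        # renormalization of the zero-truncated components
        terms[:, trunc] -= np.log(ndtr(means[trunc] / sds[trunc]))
        lp = terms.sum(axis=1)
        below = (thetas[:, trunc] < 0).any(axis=1)
        lp[below] = -np.inf
        _, valid = self.condition_params_batch(thetas)
        lp[~valid] = -np.inf
        return float(lp[0]) if scalar else lp

    def sample_prior(self, rng, size: int) -> np.ndarray:
        out = np.empty((size, self.k))
        for j, p in enumerate(self.priors):
            out[:, j] = p.rvs(rng, size)
        return out


def _param_names(variant: str, parameterization: str) -> Tuple[str, ...]:
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    drift_varies = variant in ("drift", "complex")
    thresh_varies = variant in ("threshold", "complex")

    def expand(base, varies):
        if not varies:
            return [base]
        if parameterization == "mean-diff":
            return [f"{base}_mean", f"{base}_diff"]
        return [f"{base}_1", f"{base}_2"]

    names = expand("v_c", drift_varies) + ["v_e", "sv_e", "A"] + expand(
        "B", thresh_varies
    ) + ["t0"]
    return tuple(names)


def build_model(
    variant: str,
    parameterization: str = "per-condition",
    prior_level: str = "default",
) -> ModelSpec:
    """Construct a :class:`ModelSpec` for one of the four nested variants.

    ``prior_level`` other than ``default`` selects the informed prior on the
    condition difference and therefore requires the mean-diff
    parameterization; conversely mean-diff requires an explicit level.
    """
    if parameterization not in ("per-condition", "mean-diff"):
        raise ValueError(f"unknown parameterization {parameterization!r}")
    if prior_level not in PRIOR_LEVELS:
        raise ValueError(f"unknown prior level {prior_level!r}")
    if prior_level != "default" and parameterization != "mean-diff":
        raise ValueError("informed prior levels require the mean-diff parameterization")
    if (
        parameterization == "mean-diff"
        and prior_level == "default"
        and variant != "null"
    ):
        raise ValueError("mean-diff parameterization requires an informed prior level")
    names = _param_names(variant, parameterization)
    priors = tuple(
        Prior("normal", 0.0, DIFF_PRIOR_SD[prior_level])
        if name.endswith("_diff")
        else _default_prior(name)
        for name in names
    )
    return ModelSpec(variant, parameterization, prior_level, names, priors)


def log_prior(theta, spec: ModelSpec):
    """Module-level convenience wrapper around :meth:`ModelSpec.log_prior`."""
    return spec.log_prior(theta)


def theta_to_condition_params(theta, spec: ModelSpec) -> Tuple[LBAParams, LBAParams]:
    """Map a free-parameter vector to the two conditions' accumulator parameters."""
    return spec.condition_params(theta)


def to_mean_diff(x1: float, x2: float) -> Tuple[float, float]:
    """Condition values -> (across-condition mean, half-difference)."""
    return 0.5 * (x1 + x2), 0.5 * (x2 - x1)


def from_mean_diff(x_mean: float, x_diff: float) -> Tuple[float, float]:
    """(mean, half-difference) -> condition values (X_mean - X_diff, X_mean + X_diff)."""
    return x_mean - x_diff, x_mean + x_diff
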