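"""Linear ballistic accumulator (LBA) densities, likelihood, and simulator.

The LBA models two-choice decisions as a race between one accumulator per
response. Evidence accrues linearly and noiselessly within a trial;
between-trial variability comes from the drift rate, drawn from a normal
distribution truncated below at zero (mean ``v``, SD ``sv``), and the start
point, drawn uniformly from ``[0, A]``. The first accumulator to reach the
threshold ``b`` produces the response, at time ``t0 + (b - start) / drift``.

Because each drift is truncated to positive values, every accumulator
finishes almost surely: the two defective densities (winner density times
loser survivor function) integrate to the two response probabilities,
which sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import truncnorm

from . import _kernels

__all__ = [
    "LBAParams",
    "ChoiceRTDataset",
    "node_density",
    "node_cdf",
    "defective_log_density",
    "log_likelihood",
    "simulate_trials",
    "DENSITY_FLOOR",
]

#: Per-trial likelihood floor applied before taking logs. Prevents a single
#: outlier trial from driving the total log-likelihood to -inf during MCMC.
DENSITY_FLOOR = 1e-10

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class LBAParams:
    """One condition's accumulator parameters.

    v_c / v_e: mean drift rate of the correct / error accumulator
    (evidence per second); sv_c / sv_e: between-trial drift SDs (sv_c is
    fixed at 1 to satisfy the model's scaling property); A: upper bound of
    the uniform start-point distribution; b: response threshold (b >= A);
    t0: non-decision time in seconds.
    """

    v_c: float
    v_e: float
    A: float
    b: float
    t0: float
    sv_c: float = 1.0
    sv_e: float = 1.0

    def __post_init__(self):
        vals = (self.v_c, self.v_e, self.A, self.b, self.t0, self.sv_c, self.sv_e)
        if not all(np.isfinite(vals)):
            raise ValueError("LBA parameters must be finite")
        if min(vals) < 0:
            raise ValueError("LBA parameters must be non-negative")
        if self.b < self.A:
            raise ValueError("threshold b must be >= start-point range A")
        if self.sv_c != 1.0:
            raise ValueError("sv_c is fixed to 1 (scaling constraint)")
        if self.sv_e <= 0:
            raise ValueError("sv_e must be positive")

    def as_array(self) -> np.ndarray:
        """Row [v_c, v_e, sv_c, sv_e, A, b, t0] as used by the likelihood kernels."""
        return np.array(
            [self.v_c, self.v_e, self.sv_c, self.sv_e, self.A, self.b, self.t0]
        )


@dataclass
class ChoiceRTDataset:
    """Trial-level choice-RT data: condition label (1-based), accuracy, RT (s)."""

    condition: np.ndarray
    correct: np.ndarray
    rt: np.ndarray

    def __post_init__(self):
        self.condition = np.asarray(self.condition, dtype=np.int64)
        self.correct = np.asarray(self.correct, dtype=bool)
        self.rt = np.asarray(self.rt, dtype=np.float64)
        if not (self.condition.shape == self.correct.shape == self.rt.shape):
            raise ValueError("condition, correct, rt must have equal length")
        if self.n_trials:
            if self.rt.min() <= 0:
                raise ValueError("all RTs must be positive")
            labels = np.unique(self.condition)
            if labels[0] != 1 or not np.array_equal(labels, np.arange(1, labels.size + 1)):
                raise ValueError("condition labels must be contiguous starting at 1")

    @property
    def n_trials(self) -> int:
        return self.rt.size

    @property
    def n_conditions(self) -> int:
        return int(self.condition.max()) if self.n_trials else 0

    @property
    def response(self) -> np.ndarray:
        return np.where(self.correct, "correct", "error")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"condition": self.condition, "response": self.response, "rt": self.rt}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ChoiceRTDataset":
        resp = df["response"].astype(str).to_numpy()
        bad = ~np.isin(resp, ["correct", "error"])
        if bad.any():
            raise ValueError("response column must be 'correct' or 'error'")
        return cls(df["condition"].to_numpy(), resp == "correct", df["rt"].to_numpy())

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ChoiceRTDataset":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def empty(cls) -> "ChoiceRTDataset":
        return cls(np.empty(0, int), np.empty(0, bool), np.empty(0))


def _check_node_args(b, A, v, sv):
    vals = np.array([b, A, v, sv], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("node parameters must be finite")
    if A < 0 or b < A:
        raise ValueError("require b >= A >= 0")
    if sv <= 0:
        raise ValueError("require sv > 0")


def node_density(t, b, A, v, sv):
    """Density of one accumulator first reaching ``b`` at decision time ``t``.

    The drift rate is TN(v, sv, 0, inf); the closed-form density for an
    untruncated drift is divided by Phi(v / sv) so that it integrates to one
    over t in (0, inf). Vectorized over ``t``; t <= 0 maps to density 0.
    """
    _check_node_args(b, A, v, sv)
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    denom = max(ndtr(v / sv), 1e-300)
    if A < 1e-12:
        z = (b / tp - v) / sv
        out[pos] = np.exp(-0.5 * z * z) / _SQRT2PI * b / (sv * tp * tp) / denom
    else:
        ts = tp * sv
        z1 = (b - A - tp * v) / ts
        z2 = (b - tp * v) / ts
        phi1 = np.exp(-0.5 * z1 * z1) / _SQRT2PI
        phi2 = np.exp(-0.5 * z2 * z2) / _SQRT2PI
        f = (-v * ndtr(z1) + sv * phi1 + v * ndtr(z2) - sv * phi2) / A / denom
        out[pos] = np.clip(f, 0.0, None)
    return float(out[0]) if scalar else out


def node_cdf(t, b, A, v, sv):
    """First-passage CDF companion of :func:`node_density` (truncated drift)."""
    _check_node_args(b, A, v, sv)
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    denom = max(ndtr(v / sv), 1e-300)
    if A < 1e-12:
        out[pos] = ndtr((v - b / tp) / sv) / denom
    else:
        ts = tp * sv
        z1 = (b - A - tp * v) / ts
        z2 = (b - tp * v) / ts
        phi1 = np.exp(-0.5 * z1 * z1) / _SQRT2PI
        phi2 = np.exp(-0.5 * z2 * z2) / _SQRT2PI
        F = (1.0
             + (b - A - tp * v) / A * ndtr(z1)
             - (b - tp * v) / A * ndtr(z2)
             + ts / A * (phi1 - phi2)) / denom
        out[pos] = np.clip(F, 0.0, 1.0)
    return float(out[0]) if scalar else out


def defective_log_density(rt, response, params: LBAParams, floor: float = DENSITY_FLOOR):
    """Log joint density of (response, rt): winner density times loser survivor.

    Evaluated at decision time ``t = rt - t0``. RTs at or below ``t0`` (and
    underflowing densities) return ``log(floor)`` rather than -inf.
    ``response`` may be 'correct'/'error' strings or booleans (True =
    correct); vectorized over trials.
    """
    if not isinstance(params, LBAParams):
        raise TypeError("params must be an LBAParams instance")
    rt = np.asarray(rt, dtype=float)
    scalar = rt.ndim == 0
    rt = np.atleast_1d(rt)
    resp = np.atleast_1d(np.asarray(response))
    if resp.dtype.kind in "US":
        correct = resp == "correct"
    else:
        correct = resp.astype(bool)
    correct = np.broadcast_to(correct, rt.shape)

    t = rt - params.t0
    dens = np.full(rt.shape, floor)
    v_w = np.where(correct, params.v_c, params.v_e)
    s_w = np.where(correct, params.sv_c, params.sv_e)
    v_l = np.where(correct, params.v_e, params.v_c)
    s_l = np.where(correct, params.sv_e, params.sv_c)
    ok = t > 0
    if ok.any():
        d = np.empty(ok.sum())
        ti = t[ok]
        for j, (tt, vw, sw, vl, sl) in enumerate(
            zip(ti, v_w[ok], s_w[ok], v_l[ok], s_l[ok])
        ):
            d[j] = node_density(tt, params.b, params.A, vw, sw) * (
                1.0 - node_cdf(tt, params.b, params.A, vl, sl)
            )
        dens[ok] = np.maximum(d, floor)
    out = np.log(dens)
    return float(out[0]) if scalar else out


def log_likelihood(data: ChoiceRTDataset, spec, theta) -> float:
    """Total log-likelihood of a dataset under a model spec at ``theta``.

    ``spec`` maps the free-parameter vector to per-condition accumulator
    parameters (see :mod:`lbaselect.model_space`). Returns -inf when theta
    falls outside the model's support; an empty dataset gives 0.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    cond_params, valid = spec.condition_params_batch(theta)
    if not valid[0]:
        return -np.inf
    if data.n_trials == 0:
        return 0.0
    ll = _kernels.loglik_chains(
        cond_params[:1],
        data.rt,
        (data.condition - 1).astype(np.int64),
        data.correct,
        DENSITY_FLOOR,
    )
    return float(ll[0])


def _truncnorm_pos(rng, mean, sd, size):
    a = (0.0 - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_trials(
    params: Sequence[LBAParams],
    n_per_condition: int | Iterable[int],
    seed=None,
    rng: np.random.Generator | None = None,
) -> ChoiceRTDataset:
    """Simulate an LBA race for each trial in each condition.

    Per trial and accumulator, drift ~ TN(v, sv, 0, inf) and start point
    ~ U(0, A); the finishing time is (b - start) / drift, the response is
    the accumulator with the smaller finishing time, and
    rt = t0 + winning time (so every rt exceeds t0).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    params = list(params)
    if isinstance(n_per_condition, (int, np.integer)):
        n_per_condition = [int(n_per_condition)] * len(params)
    else:
        n_per_condition = [int(n) for n in n_per_condition]
    if len(n_per_condition) != len(params):
        raise ValueError("one trial count per condition required")
    conds, corrects, rts = [], [], []
    for ci, (p, n) in enumerate(zip(params, n_per_condition), start=1):
        if n < 0:
            raise ValueError("n_per_condition must be >= 0")
        if n == 0:
            continue
        drift_c = _truncnorm_pos(rng, p.v_c, p.sv_c, n)
        drift_e = _truncnorm_pos(rng, p.v_e, p.sv_e, n)
        start_c = rng.uniform(0.0, p.A, n) if p.A > 0 else np.zeros(n)
        start_e = rng.uniform(0.0, p.A, n) if p.A > 0 else np.zeros(n)
        t_c = (p.b - start_c) / drift_c
        t_e = (p.b - start_e) / drift_e
        win_c = t_c <= t_e
        conds.append(np.full(n, ci, dtype=np.int64))
        corrects.append(win_c)
        rts.append(p.t0 + np.where(win_c, t_c, t_e))
    if not conds:
        return ChoiceRTDataset.empty()
    return ChoiceRTDataset(
        np.concatenate(conds), np.concatenate(corrects), np.concatenate(rts)
    )
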