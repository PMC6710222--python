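"""The nine model-selection methods.

Deviance-scale criteria (AIC, BIC, DIC, WAIC, DIC_p), marginal-likelihood
estimators (bridge sampling, thermodynamic integration), the augmented-ROPE
parameter-estimation rule, and the chi-square relative-deviance decision
tree. The maximum likelihood entering AIC, BIC, and the chi-square test is
the best per-draw log-likelihood contained in the posterior sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import numpy as np
from scipy.special import logsumexp
from scipy.stats import chi2, multivariate_normal

__all__ = [
    "MetricResult",
    "RopeBounds",
    "aic",
    "bic",
    "dic",
    "waic",
    "dic_p",
    "chi2_select",
    "rope_select",
    "bridge_logml",
    "ti_logml",
    "K_BY_VARIANT",
    "DEVIANCE_METHODS",
    "LOGML_METHODS",
    "ALL_METHODS",
]

#: Free-parameter counts of the four variants (per-condition parameterization;
#: identical under mean-diff, which trades two condition copies for mean+diff).
K_BY_VARIANT = {"null": 6, "drift": 7, "threshold": 7, "complex": 8}

DEVIANCE_METHODS = ("AIC", "BIC", "DIC", "WAIC", "DICp")
LOGML_METHODS = ("BF-BS", "BF-TI")
ALL_METHODS = DEVIANCE_METHODS + LOGML_METHODS + ("ROPEa", "chi2")


@dataclass
class MetricResult:
    """One (method, model) evaluation with its scale."""

    method: str
    value: float
    scale: str  # "deviance" | "log-marginal-likelihood" | "decision"
    variant: Optional[str] = None
    extra: dict = field(default_factory=dict)


@dataclass(frozen=True)
class RopeBounds:
    """Regions of practical equivalence around zero for the two effects.

    Defaults are the values that define a small effect in the simulation
    design: v_c in [-0.3, 0.3], b in [-0.11, 0.11].
    """

    v_c: tuple = (-0.3, 0.3)
    b: tuple = (-0.11, 0.11)

    def __post_init__(self):
        for lo, hi in (self.v_c, self.b):
            if not (lo < 0 < hi):
                raise ValueError("ROPE must straddle zero")


def aic(max_loglik: float, k: int, variant: Optional[str] = None) -> MetricResult:
    """AIC = -2(L_hat - k)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return MetricResult("AIC", -2.0 * (max_loglik - k), "deviance", variant)


def bic(max_loglik: float, k: int, n: int, variant: Optional[str] = None) -> MetricResult:
    """BIC = -2(L_hat - k log(n) / 2), with n the total trial count."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return MetricResult(
        "BIC", -2.0 * (max_loglik - 0.5 * k * np.log(n)), "deviance", variant
    )


def dic(per_draw_loglik, variant: Optional[str] = None) -> MetricResult:
    """DIC with the minimum-deviance point estimate.

    D_bar is the posterior mean log-likelihood; the effective number of
    parameters is P_D = max(log-lik) - D_bar; DIC = -2(D_bar - P_D).
    """
    ll = np.ravel(np.asarray(per_draw_loglik, dtype=float))
    if ll.size == 0:
        raise ValueError("need at least one posterior draw")
    d_bar = ll.mean()
    p_d = ll.max() - d_bar
    return MetricResult(
        "DIC", -2.0 * (d_bar - p_d), "deviance", variant, {"p_d": p_d, "d_bar": d_bar}
    )


def waic(per_trial_loglik, variant: Optional[str] = None) -> MetricResult:
    """WAIC from the (draws x trials) log-likelihood matrix.

    lpd_i = log mean_s p(y_i | theta_s); the penalty is the per-trial
    posterior variance of the log-likelihood (sample variance, S - 1).
    """
    mat = np.asarray(per_trial_loglik, dtype=float)
    if mat.ndim != 2 or mat.size == 0:
        raise ValueError("need a non-empty draws-by-trials matrix")
    S = mat.shape[0]
    lpd = (logsumexp(mat, axis=0) - np.log(S)).sum()
    penalty = mat.var(axis=0, ddof=1).sum() if S > 1 else 0.0
    return MetricResult(
        "WAIC", -2.0 * (lpd - penalty), "deviance", variant,
        {"lpd": lpd, "p_waic": penalty},
    )


def dic_p(per_draw_logposterior, variant: Optional[str] = None) -> MetricResult:
    """DIC computed on the unnormalized log posterior (likelihood x prior)."""
    res = dic(per_draw_logposterior, variant)
    res.method = "DICp"
    return res


def chi2_select(
    deviances: Mapping[str, float], alpha: float = 0.05
) -> MetricResult:
    """Nested chi-square tests on relative deviance (-2 max log-lik).

    The better single-effect model (drift or threshold) is tested against
    the null (df 1). If significant, that model is tested against the
    complex model (df 1); otherwise the null is tested against the complex
    model (df = 2, the parameter-count difference).
    """
    missing = set(K_BY_VARIANT) - set(deviances)
    if missing:
        raise ValueError(f"missing deviances for {sorted(missing)}")
    single = "drift" if deviances["drift"] <= deviances["threshold"] else "threshold"
    tests = []

    def test(simple, complex_):
        stat = deviances[simple] - deviances[complex_]
        df = K_BY_VARIANT[complex_] - K_BY_VARIANT[simple]
        p = float(chi2.sf(stat, df))
        tests.append({"simple": simple, "complex": complex_, "stat": stat,
                      "df": df, "p": p})
        return p < alpha

    if test("null", single):
        selected = "complex" if test(single, "complex") else single
    else:
        selected = "complex" if test("null", "complex") else "null"
    return MetricResult("chi2", np.nan, "decision", selected, {"tests": tests})


def rope_select(
    drift_diff, threshold_diff, bounds: Optional[RopeBounds] = None
) -> MetricResult:
    """Augmented ROPE: each effect judged by majority posterior mass.

    An effect is present iff more than half of the posterior draws of the
    condition difference fall outside its region of practical equivalence
    (exact ties count as absent). The two binary decisions combine into one
    of the four variants.
    """
    if bounds is None:
        bounds = RopeBounds()
    out = {}
    for name, draws, (lo, hi) in (
        ("v_c", np.ravel(drift_diff), bounds.v_c),
        ("b", np.ravel(threshold_diff), bounds.b),
    ):
        out[name] = float(np.mean((draws < lo) | (draws > hi)))
    drift_in = out["v_c"] > 0.5
    thresh_in = out["b"] > 0.5
    selected = {
        (False, False): "null",
        (True, False): "drift",
        (False, True): "threshold",
        (True, True): "complex",
    }[(drift_in, thresh_in)]
    return MetricResult(
        "ROPEa", np.nan, "decision", selected, {"prop_outside": out}
    )


def bridge_logml(
    samples,
    log_unnormalized_posterior: Callable,
    seed=None,
    rng: Optional[np.random.Generator] = None,
    n_proposal: Optional[int] = None,
    tol: float = 1e-10,
    max_iter: int = 1000,
    variant: Optional[str] = None,
) -> MetricResult:
    """Log marginal likelihood by bridge sampling with the optimal bridge.

    The posterior draws are split in half: the first half moment-matches a
    multivariate-normal proposal, the second half enters the iteration. By
    default as many proposal draws are taken as there are posterior draws.
    Non-convergence within ``max_iter`` is flagged in ``extra``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    draws = samples.flat_draws if hasattr(samples, "flat_draws") else np.asarray(samples)
    S = draws.shape[0]
    half = S // 2
    fit_half, iter_half = draws[:half], draws[half:]
    mean = fit_half.mean(axis=0)
    cov = np.atleast_2d(np.cov(fit_half, rowvar=False))
    cov += 1e-10 * np.eye(cov.shape[0])
    if n_proposal is None:
        n_proposal = S
    proposal = rng.multivariate_normal(mean, cov, size=n_proposal)
    q = multivariate_normal(mean=mean, cov=cov, allow_singular=True)

    l1 = log_unnormalized_posterior(iter_half) - q.logpdf(iter_half)
    l2 = log_unnormalized_posterior(proposal) - q.logpdf(proposal)
    lstar = np.median(l1)
    n1, n2 = l1.size, l2.size
    s1 = n1 / (n1 + n2)
    s2 = n2 / (n1 + n2)
    # cap the exponent: huge ratios saturate their bridge terms at 1/s1 anyway
    e1 = np.exp(np.minimum(l1 - lstar, 700.0))
    e2 = np.exp(np.minimum(l2 - lstar, 700.0))

    r = 1.0
    converged = False
    niter = 0
    for niter in range(1, max_iter + 1):
        num = np.mean(e2 / (s1 * e2 + s2 * r))
        den = np.mean(1.0 / (s1 * e1 + s2 * r))
        r_new = num / den
        if np.isfinite(r_new) and abs(r_new - r) <= tol * abs(r_new):
            r = r_new
            converged = True
            break
        r = r_new
    logml = float(np.log(r) + lstar)
    return MetricResult(
        "BF-BS", logml, "log-marginal-likelihood", variant,
        {"converged": converged, "iterations": niter},
    )


def ti_logml(ladder, variant: Optional[str] = None) -> MetricResult:
    """Log marginal likelihood by trapezoidal thermodynamic integration.

    Integrates the per-temperature posterior expectation of
    log p(y | theta) over the temperature path from 0 (prior) to 1
    (posterior).
    """
    t = np.asarray(ladder.temperatures, dtype=float)
    means = np.asarray(ladder.mean_log_lik, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("temperature ladder must be strictly increasing")
    if abs(t[0]) > 1e-12 or abs(t[-1] - 1.0) > 1e-12:
        raise ValueError("ladder must span [0, 1]")
    value = float(np.trapezoid(means, t))
    return MetricResult("BF-TI", value, "log-marginal-likelihood", variant)
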