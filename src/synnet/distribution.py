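"""Degree-distribution modeling: power law vs Poisson.

The cumulative distribution P(K >= k) (inclusive) is computed on the
observed, unbinned support. Two estimation routes are deliberately kept
side by side:

* the exponent gamma' of the cumulative tail comes from ordinary least
  squares of log10 P(K >= k) on log10 k, together with that regression's
  R^2 (gamma = gamma' + 1);
* log-likelihood and AIC come from the discrete maximum-likelihood fit of
  P(k) ∝ k^-gamma on k >= k_min (normalized by the Hurwitz zeta), or from
  the Poisson pmf.

Model selection prefers the smaller AIC; exact ties go to Poisson as the
fewer-assumption default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
from scipy import optimize, special, stats

from synnet.errors import ValidationError
from synnet.metrics import DegreeStats

_LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class DegreeDistribution:
    """Histogram, pmf and inclusive cumulative distribution of degrees >= 1."""

    histogram: dict[int, int]
    pmf: dict[int, float]
    cumulative: dict[int, float]
    sample: np.ndarray  # sorted degrees, zeros excluded

    @property
    def n(self) -> int:
        return int(self.sample.size)

    @property
    def support(self) -> np.ndarray:
        return np.array(sorted(self.histogram), dtype=np.int64)


@dataclass(frozen=True)
class PowerLawFit:
    """Power-law fit; ``gamma`` = ``gamma_prime`` + 1 by definition.

    ``gamma_prime`` (and R2) come from the log-log OLS on the cumulative
    distribution; ``gamma_mle`` is the discrete maximum-likelihood exponent
    that produced ``loglik`` and ``aic``. The two exponent estimates agree
    only asymptotically and are deliberately both reported.
    """

    gamma: float
    gamma_prime: float
    R2: float
    aic: float
    loglik: float
    gamma_mle: float
    fit_range: tuple[int, int]
    n: int


@dataclass(frozen=True)
class PoissonFit:
    lam: float
    R2: float
    aic: float
    loglik: float
    n: int


@dataclass(frozen=True)
class ModelComparison:
    power_law: PowerLawFit
    poisson: PoissonFit
    preferred: Literal["power_law", "poisson"]
    delta_aic: float


def cumulative_degree_distribution(
    degrees: DegreeStats | Iterable[int],
) -> DegreeDistribution:
    """Build the inclusive cumulative distribution P(K >= k).

    Degree-0 vertices are excluded from the support; the cumulative value
    at the minimum observed degree is therefore exactly 1.
    """
    if isinstance(degrees, DegreeStats):
        values = degrees.sample
    else:
        values = np.array(sorted(degrees), dtype=np.int64)
    values = values[values >= 1]
    if values.size == 0:
        raise ValidationError("no vertices with degree >= 1")
    support, counts = np.unique(values, return_counts=True)
    n = values.size
    pmf = counts / n
    # P(K >= k): reverse cumulative sum over the support
    cum = np.cumsum(counts[::-1])[::-1] / n
    return DegreeDistribution(
        histogram={int(k): int(c) for k, c in zip(support, counts)},
        pmf={int(k): float(p) for k, p in zip(support, pmf)},
        cumulative={int(k): float(c) for k, c in zip(support, cum)},
        sample=values,
    )


def _loglog_points(
    dist: DegreeDistribution, k_min: int
) -> tuple[np.ndarray, np.ndarray]:
    ks = np.array([k for k in sorted(dist.cumulative) if k >= k_min], dtype=float)
    ys = np.array([dist.cumulative[int(k)] for k in ks])
    return np.log10(ks), np.log10(np.clip(ys, _LOG_FLOOR, None))


def _powerlaw_loglik(sample: np.ndarray, gamma: float, k_min: int) -> float:
    # discrete power law on k >= k_min: P(k) = k^-gamma / zeta(gamma, k_min)
    return float(
        -gamma * np.log(sample).sum() - sample.size * np.log(special.zeta(gamma, k_min))
    )


def fit_power_law(dist: DegreeDistribution, k_min: int = 1) -> PowerLawFit:
    """Fit P(k) ~ k^-gamma to the degree data.

    gamma' (and its R^2) come from the log-log OLS on the cumulative
    distribution over k >= k_min; the log-likelihood and AIC come from the
    discrete MLE of gamma on the same truncated sample.

    Raises
    ------
    ValidationError
        If fewer than 3 distinct support points lie at or above ``k_min``.
    """
    log_k, log_c = _loglog_points(dist, k_min)
    if log_k.size < 3:
        raise ValidationError(
            f"insufficient support: need >= 3 distinct degrees >= {k_min}, "
            f"got {log_k.size}"
        )
    res = stats.linregress(log_k, log_c)
    gamma_prime = -res.slope
    r2 = res.rvalue**2

    sample = dist.sample[dist.sample >= k_min]
    opt = optimize.minimize_scalar(
        lambda g: -_powerlaw_loglik(sample, g, k_min),
        bounds=(1.0 + 1e-9, 20.0),
        method="bounded",
    )
    gamma_mle = float(opt.x)
    loglik = _powerlaw_loglik(sample, gamma_mle, k_min)
    return PowerLawFit(
        gamma=float(gamma_prime) + 1.0,
        gamma_prime=float(gamma_prime),
        R2=float(r2),
        aic=2.0 - 2.0 * loglik,
        loglik=loglik,
        gamma_mle=gamma_mle,
        fit_range=(int(round(10 ** log_k[0])), int(round(10 ** log_k[-1]))),
        n=int(sample.size),
    )


def fit_poisson(dist: DegreeDistribution, k_min: int = 1) -> PoissonFit:
    """Fit a Poisson model; lambda is the sample mean degree (MLE).

    R^2 is computed on the same log-log cumulative domain used by the
    power-law fit so the two values are directly comparable; it may be
    negative when the model is grossly wrong in the tail.
    """
    sample = dist.sample
    if sample.size == 0:
        raise ValidationError("empty distribution")
    lam = float(sample.mean())
    loglik = float(stats.poisson.logpmf(sample, lam).sum())

    log_k, log_c = _loglog_points(dist, k_min)
    ks = np.round(10**log_k).astype(int)
    model_cum = stats.poisson.sf(ks - 1, lam)  # P(K >= k)
    log_model = np.log10(np.clip(model_cum, _LOG_FLOOR, None))
    ss_res = float(((log_c - log_model) ** 2).sum())
    ss_tot = float(((log_c - log_c.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return PoissonFit(
        lam=lam,
        R2=float(r2),
        aic=2.0 - 2.0 * loglik,
        loglik=loglik,
        n=int(sample.size),
    )


def compare_models(power: PowerLawFit, pois: PoissonFit) -> ModelComparison:
    """Pick the model with the smaller AIC (ties go to Poisson)."""
    if power.n != pois.n:
        raise ValidationError(
            f"fits are on different samples (n={power.n} vs n={pois.n})"
        )
    delta = pois.aic - power.aic
    preferred = "power_law" if power.aic < pois.aic else "poisson"
    return ModelComparison(
        power_law=power, poisson=pois, preferred=preferred, delta_aic=float(delta)
    )


def fit_report(comparison: ModelComparison) -> dict:
    """JSON-ready summary of both fits and the preference."""
    p, q = comparison.power_law, comparison.poisson
    return {
        "power_law": {
            "gamma": p.gamma,
            "gamma_mle": p.gamma_mle,
            "gamma_prime": p.gamma_prime,
            "R2": p.R2,
            "aic": p.aic,
            "loglik": p.loglik,
            "fit_range": list(p.fit_range),
            "n": p.n,
        },
        "poisson": {
            "lambda": q.lam,
            "R2": q.R2,
            "aic": q.aic,
            "loglik": q.loglik,
            "n": q.n,
        },
        "preferred": comparison.preferred,
        "delta_aic": comparison.delta_aic,
    }
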