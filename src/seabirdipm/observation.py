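"""Observation-error and missing-data models.

Counts of breeding females and fledged female chicks are linked to the
latent states through a normal error with a single variance ``s^2``
shared by all years, derived from the spread of repeated within-season
censuses (``s^2 = mean within-year variance / mean replicate number``).

Mark-recapture survival estimates are observed through a normal error
whose variance is itself uncertain: ``V ~ Uniform(0, Vmax)`` with
``Vmax`` drawn from a gamma distribution representing the spread of the
variances implied by the published 95% confidence intervals.

Missing covariate segments get explicit models: female arrival mass is
an i.i.d. normal variate matched to the observed record, and the
pre-monitoring predation block is a backward random walk anchored at the
first observed year, so serial autocorrelation carries into the imputed
values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CountObservation",
    "SurvivalObservation",
    "ObservationHyperparams",
    "GammaSpec",
    "repeated_count_variance",
    "count_loglik",
    "ci_to_variance",
    "fit_vmax_gamma",
    "survival_obs_loglik",
    "arrival_mass_prior",
    "predation_rw_prior",
    "check_replicate_protocol",
]

_LOG2PI = math.log(2.0 * math.pi)


def norm_logpdf(x, mu, var):
    """Normal log density; vectorised, no scipy overhead."""
    x = np.asarray(x, dtype=float)
    return -0.5 * (_LOG2PI + np.log(var) + (x - mu) ** 2 / var)


@dataclass
class CountObservation:
    """One season's census: breeding females and fledged female chicks."""

    year: int
    females: float
    chicks_f: float
    replicates: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.females < 0 or self.chicks_f < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class SurvivalObservation:
    """A year's mark-recapture survival estimate with its 95% CI."""

    year: int
    age_class: str  # "fledgling" or "older"
    estimate: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.age_class not in ("fledgling", "older"):
            raise ValueError(f"unknown age class {self.age_class!r}")
        if not (0.0 < self.estimate < 1.0):
            raise ValueError("estimate outside (0, 1)")
        if not (self.ci_low < self.estimate < self.ci_high):
            raise ValueError("require ci_low < estimate < ci_high")


@dataclass
class GammaSpec:
    """Gamma(shape, rate) for the survival max-variance; ``fixed`` holds a
    degenerate fallback value when the CI spread is zero."""

    shape: float | None
    rate: float | None
    fixed: float | None = None

    def mean(self) -> float:
        if self.fixed is not None:
            return self.fixed
        return self.shape / self.rate


@dataclass
class ObservationHyperparams:
    """Fixed observation hyperparameters entering the joint density."""

    s2_counts: float
    vmax_gamma_f: GammaSpec | None = None
    vmax_gamma_a: GammaSpec | None = None

    def __post_init__(self) -> None:
        if self.s2_counts <= 0:
            raise ValueError("s2_counts must be positive")


def check_replicate_protocol(replicates: Sequence[float]) -> bool:
    """Field protocol: counts repeated to within 10% of one another, or at
    least three times.  Returns True when the protocol is satisfied."""
    reps = np.asarray(replicates, dtype=float)
    if reps.size >= 3:
        return True
    if reps.size == 2:
        lo, hi = reps.min(), reps.max()
        return hi <= 1.1 * lo if lo > 0 else lo == hi
    return False


def repeated_count_variance(replicates: Mapping[int, Sequence[float]]) -> float:
    """Count observation variance from repeated censuses.

    ``s^2 = (mean over years of the within-year sample variance) /
    (mean number of replicates)``, on the scale the counts are supplied
    in.  Years with fewer than two replicates are ignored.
    """
    variances, numbers = [], []
    for reps in replicates.values():
        reps = np.asarray(reps, dtype=float)
        if reps.size >= 2:
            variances.append(reps.var(ddof=1))
            numbers.append(reps.size)
    if not variances:
        raise ValueError(
            "no year has >=2 replicate counts; supply s2_counts in the config"
        )
    return float(np.mean(variances) / np.mean(numbers))


def count_loglik(latent_females, latent_chicks, obs_females, obs_chicks, s2):
    """Normal log likelihood of the two census series.

    Each observed count is centred on the corresponding latent value
    with the common variance ``s2``; NaN observations contribute
    nothing (years without a census).
    """
    if s2 <= 0:
        raise ValueError("s2 must be positive")
    total = 0.0
    for latent, obs in (
        (np.asarray(latent_females, float), np.asarray(obs_females, float)),
        (np.asarray(latent_chicks, float), np.asarray(obs_chicks, float)),
    ):
        ok = ~np.isnan(obs)
        if ok.any():
            total += float(norm_logpdf(obs[ok], latent[ok], s2).sum())
    return total


def ci_to_variance(ci_low: float, ci_high: float, estimate: float | None = None) -> float:
    """Variance implied by a symmetric-normal 95% CI.

    Uses the larger half-width when the interval is asymmetric around
    the estimate (conservative), i.e. ``(half-width / 1.96)**2``.
    """
    if ci_high <= ci_low:
        raise ValueError("degenerate CI: ci_high <= ci_low")
    if estimate is None:
        hw = (ci_high - ci_low) / 2.0
    else:
        hw = max(ci_high - estimate, estimate - ci_low)
    return (hw / 1.96) ** 2


def fit_vmax_gamma(variances) -> GammaSpec:
    """Moment-match a gamma to the CI-implied variances across years.

    ``shape = m^2 / v`` and ``rate = m / v`` from the sample mean and
    variance of the implied variances.  When the spread is (near) zero
    the gamma degenerates; a fixed ``Vmax`` equal to the common implied
    variance is returned instead.
    """
    v = np.asarray(variances, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no CI-implied variances to fit")
    m = float(v.mean())
    s2 = float(v.var(ddof=1)) if v.size > 1 else 0.0
    if s2 <= 1e-12 * max(m, 1.0) ** 2:
        return GammaSpec(shape=None, rate=None, fixed=m)
    return GammaSpec(shape=m * m / s2, rate=m / s2)


def survival_obs_loglik(estimate, phi, V):
    """Normal log density of a mark-recapture estimate around the model's
    survival rate, given the (sampled) error variance ``V``."""
    return float(np.sum(norm_logpdf(estimate, phi, V)))


def arrival_mass_prior(observed) -> tuple[float, float]:
    """Imputation distribution for missing arrival-mass years: normal with
    the observed record's mean and (n-1) standard deviation."""
    obs = np.asarray(observed, dtype=float)
    obs = obs[~np.isnan(obs)]
    if obs.size < 2:
        raise ValueError("need >=2 observed arrival-mass values to impute")
    return float(obs.mean()), float(obs.std(ddof=1))


def predation_rw_prior(observed) -> tuple[float, float]:
    """Backward random-walk prior settings for the missing predation block.

    Returns ``(anchor, sig2_scale)``: the earliest observed value (the
    walk's anchor) and the sample variance of first differences of the
    observed segment, used as the scale of the weakly-informative prior
    on the walk variance.
    """
    obs = np.asarray(observed, dtype=float)
    obs = obs[~np.isnan(obs)]
    if obs.size == 0:
        raise ValueError("empty observed predation segment")
    anchor = float(obs[0])
    if obs.size >= 3:
        scale = float(np.diff(obs).var(ddof=1))
    elif obs.size == 2:
        scale = float(np.diff(obs)[0] ** 2)
    else:
        scale = 1.0
    return anchor, max(scale, 1e-6)
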