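"""Age-structured demographic process for a crested-penguin colony.

The population is modelled through females only (a 1:1 sex ratio is
assumed, so breeding females equal breeding pairs and female chicks are
half of total productivity).  Six stage classes are tracked: stages 1-5
are pre-recruitment age classes and stage 6 holds breeding adults.  Three
vital rates drive the projection,

* ``phi_f`` -- first-year (fledgling) survival,
* ``phi_a`` -- survival of all older birds,
* ``b``    -- productivity, chicks fledged per breeding pair,

each linked to annual covariates on the logit scale.  Every covariate
slope is gated by a Bernoulli 0/1 inclusion indicator (stochastic search
variable selection), so a model with all indicators off collapses to the
covariate-free baseline exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "N_STAGES",
    "BREEDING_STAGE",
    "PRODUCTIVITY_TERMS",
    "SURVIVAL_TERMS",
    "VitalRates",
    "SurvivalCoefficients",
    "ProductivityCoefficients",
    "DegenerateSeriesError",
    "MissingCovariateError",
    "standardize",
    "survival_rates",
    "productivity_rate",
    "build_transition_matrix",
    "project_deterministic",
    "project_stochastic",
    "dominant_eigenvalue",
    "stable_stage_distribution",
]

N_STAGES = 6
#: 0-based index of the breeding-adult stage (stage 6 in 1-based notation).
BREEDING_STAGE = 5

#: Productivity covariate terms, in the order their coefficients are indexed:
#: arrival mass, predation, SSTa (lag 0, 1), SAM (lag 0, 1), ENSO (lag 2, 3),
#: interspecific competition, and the intraspecific auto-covariate.
PRODUCTIVITY_TERMS = ("A", "P", "S", "S1", "M", "M1", "E2", "E3", "D", "C")

#: Survival covariate terms: shared predation, extra fledgling predation
#: (both act through the same predation index), and SSTa with a 1-yr lag.
SURVIVAL_TERMS = ("P", "Pf", "S1")


class DegenerateSeriesError(ValueError):
    """Raised when a covariate series cannot be standardized."""


class MissingCovariateError(ValueError):
    """Raised when a vital rate is requested with an unavailable covariate."""


@dataclass(frozen=True)
class VitalRates:
    """One year's demographic rates; all must lie strictly in (0, 1)."""

    phi_f: float
    phi_a: float
    b: float

    def __post_init__(self) -> None:
        for name in ("phi_f", "phi_a", "b"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name}={v!r} outside the open unit interval")


@dataclass
class SurvivalCoefficients:
    """Logit-scale coefficients of the two survival functions.

    ``alpha_1`` is the predation effect shared by both age classes,
    ``alpha_2`` the additional predation effect on fledglings, ``alpha_3``
    the lag-1 SSTa effect shared by both age classes.  ``I1..I3`` are the
    corresponding inclusion indicators.
    """

    alpha_f0: float = 0.0
    alpha_a0: float = 0.0
    alpha_1: float = 0.0
    alpha_2: float = 0.0
    alpha_3: float = 0.0
    I1: int = 1
    I2: int = 1
    I3: int = 1

    def __post_init__(self) -> None:
        for name in ("I1", "I2", "I3"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"indicator {name} must be 0 or 1")


@dataclass
class ProductivityCoefficients:
    """Logit-scale productivity coefficients for the ten terms of
    :data:`PRODUCTIVITY_TERMS`, each gated by an indicator ``J``."""

    beta_0: float = 0.0
    beta: np.ndarray = field(default_factory=lambda: np.zeros(10))
    J: np.ndarray = field(default_factory=lambda: np.ones(10, dtype=int))

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.J = np.asarray(self.J, dtype=int)
        if self.beta.shape != (10,) or self.J.shape != (10,):
            raise ValueError("beta and J must have length 10")
        if not np.isin(self.J, (0, 1)).all():
            raise ValueError("indicators J must be 0 or 1")


def standardize(series, mask=None):
    """Centre and scale a series to zero mean and unit sample variance.

    Only entries flagged observed contribute to the moments; missing
    entries (``mask`` False, or NaN when no mask is given) are preserved
    as NaN so downstream imputation can recognise them.

    Returns ``(z, mean, sd)`` where ``sd`` uses the n-1 denominator; the
    scaler is returned so imputed or fed-back values can be placed on the
    same scale.
    """
    x = np.asarray(series, dtype=float)
    if mask is None:
        mask = ~np.isnan(x)
    mask = np.asarray(mask, dtype=bool)
    obs = x[mask]
    if obs.size < 2:
        raise DegenerateSeriesError(
            f"need >=2 observed values to standardize, got {obs.size}"
        )
    mean = float(obs.mean())
    sd = float(obs.std(ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateSeriesError("zero or non-finite variance in observed values")
    z = np.full_like(x, np.nan)
    z[mask] = (obs - mean) / sd
    return z, mean, sd


def _check_available(value, name, year):
    if np.any(np.isnan(np.asarray(value, dtype=float))):
        raise MissingCovariateError(
            f"covariate {name!r} unavailable (NaN) for year {year}"
        )


def survival_rates(coeffs: SurvivalCoefficients, P, S1, year="?"):
    """Fledgling and older-bird survival from the logit link.

    ``logit(phi_f) = alpha_f0 + (I1 a1 + I2 a2) P + I3 a3 S1`` and
    ``logit(phi_a) = alpha_a0 + I1 a1 P + I3 a3 S1``; the extra predation
    coefficient acts on fledglings only.  ``P`` and ``S1`` may be scalars
    or aligned arrays (vectorised over years).
    """
    _check_available(P, "P", year)
    _check_available(S1, "S1", year)
    c = coeffs
    eta_f = c.alpha_f0 + (c.I1 * c.alpha_1 + c.I2 * c.alpha_2) * P + c.I3 * c.alpha_3 * S1
    eta_a = c.alpha_a0 + c.I1 * c.alpha_1 * P + c.I3 * c.alpha_3 * S1
    return expit(eta_f), expit(eta_a)


def productivity_rate(coeffs: ProductivityCoefficients, x, year="?"):
    """Productivity ``b`` (chicks per pair) from the ten-term logit link.

    ``x`` holds the covariate values in :data:`PRODUCTIVITY_TERMS` order,
    shape ``(10,)`` or ``(T, 10)``; the last column is the standardized
    intraspecific auto-covariate fed back from the latent breeder count.
    """
    x = np.asarray(x, dtype=float)
    _check_available(x, "productivity covariates", year)
    if x.shape[-1] != 10:
        raise ValueError("expected 10 covariate terms")
    eta = coeffs.beta_0 + x @ (coeffs.J * coeffs.beta)
    return expit(eta)


def build_transition_matrix(v: VitalRates) -> np.ndarray:
    """Deterministic 6x6 projection matrix.

    Fecundity (top-right) is ``phi_a * (b/2) * phi_f``: surviving adults
    produce female chicks at b/2 per pair, which must survive their first
    year to enter stage 1.  Survival ``phi_a`` fills the subdiagonal and
    the adult self-loop.
    """
    R = np.zeros((N_STAGES, N_STAGES))
    R[0, BREEDING_STAGE] = v.phi_a * (v.b / 2.0) * v.phi_f
    for i in range(N_STAGES - 1):
        R[i + 1, i] = v.phi_a
    R[BREEDING_STAGE, BREEDING_STAGE] = v.phi_a
    return R


def project_deterministic(state, matrix) -> np.ndarray:
    """Expected next-year stage vector ``matrix @ state``."""
    state = np.asarray(state, dtype=float)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (N_STAGES, N_STAGES) or state.shape != (N_STAGES,):
        raise ValueError(
            f"dimension mismatch: matrix {matrix.shape}, state {state.shape}"
        )
    return matrix @ state


def project_stochastic(state, v: VitalRates, rng, return_chicks: bool = False):
    """One year of the demographic process with binomial stochasticity.

    Female chicks are realised first from the current breeder pool,
    ``chicks_f ~ Binomial(n6, b/2)``; recruits entering stage 1 then
    survive their first year with probability ``phi_a * phi_f`` (the
    maternal-survival factor of the deterministic matrix folded into the
    first-year draw, so every component's expectation equals the
    deterministic projection).  Each pre-breeder stage advances with
    probability ``phi_a``; stage-5 survivors join surviving adults in
    stage 6.
    """
    state = np.asarray(state)
    if not np.issubdtype(state.dtype, np.integer):
        if not np.allclose(state, np.round(state)):
            raise ValueError("stochastic projection requires an integer state")
        state = np.round(state).astype(np.int64)
    if state.shape != (N_STAGES,) or (state < 0).any():
        raise ValueError("state must be 6 non-negative integers")
    nxt = np.zeros(N_STAGES, dtype=np.int64)
    chicks_f = rng.binomial(state[BREEDING_STAGE], v.b / 2.0)
    nxt[0] = rng.binomial(chicks_f, v.phi_a * v.phi_f)
    for i in range(0, BREEDING_STAGE - 1):
        nxt[i + 1] = rng.binomial(state[i], v.phi_a)
    nxt[BREEDING_STAGE] = rng.binomial(
        state[BREEDING_STAGE - 1] + state[BREEDING_STAGE], v.phi_a
    )
    if return_chicks:
        return nxt, int(chicks_f)
    return nxt


def dominant_eigenvalue(matrix) -> float:
    """Dominant (largest-magnitude) eigenvalue; real for this matrix family."""
    ev = np.linalg.eigvals(np.asarray(matrix, dtype=float))
    return float(ev[np.argmax(np.abs(ev))].real)


def stable_stage_distribution(matrix) -> np.ndarray:
    """Right eigenvector of the dominant eigenvalue, normalised to sum 1."""
    vals, vecs = np.linalg.eig(np.asarray(matrix, dtype=float))
    w = np.abs(vecs[:, np.argmax(np.abs(vals))].real)
    return w / w.sum()
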