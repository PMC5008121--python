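"""Joint posterior and MCMC for the state-space population model.

The joint density couples

* the age-structured demographic process (binomial transitions,
  approximated by moment-matched normals by default for sampler
  efficiency, with an exact integer-state option),
* normal observation models for the census counts and the
  mark-recapture survival estimates (the latter with a stochastic
  error-variance hierarchy ``V ~ U(0, Vmax)``, ``Vmax ~ Gamma``),
* imputation models for the missing covariate segments (i.i.d. normal
  for arrival mass, a backward random walk for the predation index),
* weakly-informative normal priors on logit-scale coefficients, and a
  Bernoulli/uniform hierarchy on the inclusion indicators (stochastic
  search variable selection in the Kuo-Mallick style: an excluded
  coefficient is refreshed from its prior, which doubles as the
  pseudo-prior).

Sampling is Metropolis-within-Gibbs: adaptive random-walk updates for
continuous parameters (plus an adaptive joint proposal per coefficient
block), exact Gibbs draws for conjugate pieces (inclusion
probabilities, the random-walk variance), marginal Bernoulli flips for
the indicators, and vectorised even/odd single-year updates for the
latent stage abundances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .core import (
    BREEDING_STAGE,
    N_STAGES,
    PRODUCTIVITY_TERMS,
    SURVIVAL_TERMS,
    VitalRates,
    build_transition_matrix,
    stable_stage_distribution,
)
from .covariates import CovariateMatrix
from .observation import (
    GammaSpec,
    arrival_mass_prior,
    ci_to_variance,
    fit_vmax_gamma,
    norm_logpdf,
    predation_rw_prior,
    repeated_count_variance,
)

__all__ = [
    "PriorConfig",
    "MCMCConfig",
    "ModelOptions",
    "ModelData",
    "StateSpaceModel",
    "SamplerState",
    "PosteriorDraws",
    "run_mcmc",
    "log_joint",
    "gelman_rubin",
    "max_rhat",
    "inclusion_probabilities",
    "DEFAULT_MONITORED",
]

_LOG2PI = math.log(2.0 * math.pi)

#: reference rates used only to centre the weakly-informative prior on the
#: initial pre-recruitment stage abundances (stable stage structure).
_PRIOR_RATES = VitalRates(phi_f=0.4, phi_a=0.85, b=0.5)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PriorConfig:
    """Prior hyperparameters.

    Coefficient priors are normal on the logit scale: sd 1.5 for slopes
    (roughly uniform on the probability scale after the link) and sd 10
    for baseline logits.  ``baseline_prior="uniform_prob"`` switches the
    baselines to a uniform prior on the probability scale (used by the
    conjugate-oracle tests).
    """

    slope_sd: float = 1.5
    baseline_sd: float = 10.0
    baseline_prior: str = "normal"
    init_var_factor: float = 10.0  # initial breeder-count prior variance = factor * s2
    # inverse-gamma shape for the random-walk variance; the prior mean is
    # pinned to the variance of first differences of the observed
    # predation segment, and this shape keeps the unobserved period's
    # year-to-year variability on the scale the observed period exhibits
    # (a diffuse tail here lets the imputed block act as free year
    # effects, a degenerate regime)
    rw_shape: float = 5.0

    def __post_init__(self) -> None:
        if self.baseline_prior not in ("normal", "uniform_prob"):
            raise ValueError(f"unknown baseline_prior {self.baseline_prior!r}")


@dataclass
class MCMCConfig:
    """MCMC budget.  ``burn_in`` counts post-thinning draws discarded per
    chain; the default desk-scale budget retains 2,000 of 4,000 draws
    per chain — the smallest budget at which the convergence criterion
    (all monitored R-hat below 1.02) holds with margin across seeds."""

    chains: int = 3
    iterations: int = 40_000
    thin: int = 10
    burn_in: int = 2_000
    seed: int | None = None
    seeds: list[int] | None = None
    init_jitter: float = 0.3

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if self.seed is None and not self.seeds:
            raise ValueError("a seed is required; reproducibility is mandatory")
        if self.iterations // self.thin <= self.burn_in:
            raise ValueError("burn_in leaves no retained draws")

    def chain_seeds(self) -> list[int]:
        if self.seeds:
            if len(self.seeds) < self.chains:
                raise ValueError("fewer seeds than chains")
            return list(self.seeds[: self.chains])
        ss = np.random.SeedSequence(self.seed)
        return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(self.chains)]


@dataclass
class ModelOptions:
    """Structural switches.

    ``forced_off`` names covariate terms whose indicator is pinned to 0
    (used to build the "without" fits of the sensitivity analysis);
    survival terms are ``P``, ``Pf``, ``S1``, productivity terms those
    of :data:`~seabirdipm.core.PRODUCTIVITY_TERMS`, prefixed
    ``surv:``/``prod:``.
    """

    process_likelihood: str = "normal"  # or "binomial"
    update_latents: bool = True
    include_process: bool = True
    include_observations: bool = True
    forced_off: frozenset[str] = frozenset()
    s2_counts: float | None = None
    c_scaler: tuple[float, float] | None = None
    var_floor: float = 0.5

    def __post_init__(self) -> None:
        if self.process_likelihood not in ("normal", "binomial"):
            raise ValueError("process_likelihood must be 'normal' or 'binomial'")
        self.forced_off = frozenset(self.forced_off)


@dataclass
class ModelData:
    """Aligned annual series.  Counts are on the female scale (breeding
    females and female chicks); survival estimates/CIs are NaN outside
    the mark-recapture window."""

    years: np.ndarray
    obs_females: np.ndarray
    obs_chicks_f: np.ndarray
    cov: CovariateMatrix
    replicates: dict[int, list[float]] = field(default_factory=dict)
    surv_est_f: np.ndarray | None = None
    surv_lo_f: np.ndarray | None = None
    surv_hi_f: np.ndarray | None = None
    surv_est_a: np.ndarray | None = None
    surv_lo_a: np.ndarray | None = None
    surv_hi_a: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        T = len(self.years)
        for name in ("obs_females", "obs_chicks_f"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (T,):
                raise ValueError(f"{name} not aligned with years")
            setattr(self, name, arr)
        for name in (
            "surv_est_f", "surv_lo_f", "surv_hi_f",
            "surv_est_a", "surv_lo_a", "surv_hi_a",
        ):
            arr = getattr(self, name)
            arr = np.full(T, np.nan) if arr is None else np.asarray(arr, dtype=float)
            if arr.shape != (T,):
                raise ValueError(f"{name} not aligned with years")
            setattr(self, name, arr)
        if not np.array_equal(self.cov.years, self.years):
            raise ValueError("covariate years do not match count years")


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


def _binom_logpmf(k, n, p):
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1 - 1e-12)
    out = np.where(
        (k < -0.5) | (k > n + 0.5),
        -np.inf,
        gammaln(n + 1) - gammaln(np.maximum(k, 0) + 1)
        - gammaln(np.maximum(n - k, 0) + 1)
        + k * np.log(p) + (n - k) * np.log1p(-p),
    )
    return out


class StateSpaceModel:
    """Assembled model: data, priors, derived constants, and the joint
    density.  Instances are immutable during sampling."""

    def __init__(
        self,
        data: ModelData,
        priors: PriorConfig | None = None,
        options: ModelOptions | None = None,
    ) -> None:
        self.data = data
        self.priors = priors or PriorConfig()
        self.options = options or ModelOptions()
        self.T = len(data.years)

        # count observation variance
        if self.options.s2_counts is not None:
            self.s2 = float(self.options.s2_counts)
        else:
            self.s2 = repeated_count_variance(data.replicates)
        if self.s2 <= 0:
            raise ValueError("count observation variance must be positive")

        # survival windows and CI-implied variances
        self.idx_sf = np.flatnonzero(~np.isnan(data.surv_est_f))
        self.idx_sa = np.flatnonzero(~np.isnan(data.surv_est_a))
        self.var_sf = self._implied_vars(
            data.surv_est_f, data.surv_lo_f, data.surv_hi_f, self.idx_sf
        )
        self.var_sa = self._implied_vars(
            data.surv_est_a, data.surv_lo_a, data.surv_hi_a, self.idx_sa
        )
        self.gamma_f = fit_vmax_gamma(self.var_sf) if self.idx_sf.size else None
        self.gamma_a = fit_vmax_gamma(self.var_sa) if self.idx_sa.size else None

        # covariate structure
        cov = data.cov
        self.S1 = cov["S1"]
        if np.isnan(self.S1).any():
            raise ValueError("SSTa lag-1 column has missing cells")
        self.P_obs = cov["P"]
        self.idx_Pmiss = np.flatnonzero(np.isnan(self.P_obs))
        if self.idx_Pmiss.size:
            obs_idx = np.flatnonzero(~np.isnan(self.P_obs))
            if obs_idx.size == 0:
                raise ValueError("predation series entirely missing")
            if self.idx_Pmiss.max() > obs_idx.min():
                raise ValueError(
                    "predation missing block must precede the observed segment"
                )
            self.P_anchor_idx = int(obs_idx.min())
            anchor, rw_scale = predation_rw_prior(self.P_obs)
            self.P_anchor = anchor
            self.rw_b0 = rw_scale * (self.priors.rw_shape - 1.0)
        else:
            self.P_anchor_idx = None
            self.rw_b0 = None
        self.A_obs = cov["A"]
        self.idx_Amiss = np.flatnonzero(np.isnan(self.A_obs))
        if (~np.isnan(self.A_obs)).sum() >= 2:
            self.A_mu, self.A_sd = arrival_mass_prior(self.A_obs)
        elif self.idx_Amiss.size:
            raise ValueError("need >=2 observed arrival-mass values to impute")
        else:
            self.A_mu, self.A_sd = 0.0, 1.0
        for col in ("S", "M", "M1", "E2", "E3", "D"):
            if np.isnan(cov[col]).any():
                raise ValueError(f"covariate column {col!r} has missing cells")

        # auto-covariate scaler (fixed across MCMC iterations)
        if self.options.c_scaler is not None:
            self.c_mu, self.c_sd = map(float, self.options.c_scaler)
        else:
            obs = data.obs_females[~np.isnan(data.obs_females)]
            self.c_mu = float(obs.mean())
            self.c_sd = float(obs.std(ddof=1))
        if self.c_sd <= 0:
            raise ValueError("degenerate auto-covariate scaler")

        # fixed productivity design columns (everything except A, P, C)
        self.X_fixed = {c: cov[c] for c in ("S", "S1", "M", "M1", "E2", "E3", "D")}

        # initial-state prior
        first = data.obs_females[~np.isnan(data.obs_females)][0]
        self.init6_mean = float(first)
        self.init6_var = self.priors.init_var_factor * self.s2
        w = stable_stage_distribution(build_transition_matrix(_PRIOR_RATES))
        ratios = w / w[BREEDING_STAGE]
        self.init_pre_mean = ratios[:BREEDING_STAGE] * self.init6_mean
        self.init_pre_sd = np.maximum(0.5 * self.init_pre_mean, 20.0)

        # indicator bookkeeping
        self.forced_off_surv = np.array(
            [f"surv:{t}" in self.options.forced_off for t in SURVIVAL_TERMS]
        )
        self.forced_off_prod = np.array(
            [f"prod:{t}" in self.options.forced_off for t in PRODUCTIVITY_TERMS]
        )

    @staticmethod
    def _implied_vars(est, lo, hi, idx):
        out = np.array(
            [ci_to_variance(lo[i], hi[i], est[i]) for i in idx], dtype=float
        )
        return out

    # -- derived quantities -------------------------------------------
    def phi_vectors(self, alpha, I, Pfull):
        """(phi_f, phi_a) over all years from the survival link."""
        eta_f = alpha[0] + (I[0] * alpha[2] + I[1] * alpha[3]) * Pfull \
            + I[2] * alpha[4] * self.S1
        eta_a = alpha[1] + I[0] * alpha[2] * Pfull + I[2] * alpha[4] * self.S1
        return expit(eta_f), expit(eta_a)

    def eta_b_base(self, beta0, beta, J, Afull, Pfull):
        """Productivity linear predictor excluding the auto-covariate term."""
        eta = beta0 + J[0] * beta[0] * Afull + J[1] * beta[1] * Pfull
        for k, col in enumerate(("S", "S1", "M", "M1", "E2", "E3", "D"), start=2):
            if J[k]:
                eta = eta + beta[k] * self.X_fixed[col]
        return eta


# ---------------------------------------------------------------------------
# sampler state and joint density
# ---------------------------------------------------------------------------


@dataclass
class SamplerState:
    """A full point in the joint space (parameters, latents, imputations)."""

    alpha: np.ndarray  # (5,) f0, a0, a1, a2, a3
    I: np.ndarray  # (3,)
    pI: np.ndarray  # (3,)
    beta0: float
    beta: np.ndarray  # (10,)
    J: np.ndarray  # (10,)
    pJ: np.ndarray  # (10,)
    V_f: np.ndarray
    Vmax_f: np.ndarray
    V_a: np.ndarray
    Vmax_a: np.ndarray
    sig2_rw: float
    P_imputed: np.ndarray
    A_imputed: np.ndarray
    N: np.ndarray  # (T, 6)
    CF: np.ndarray  # (T,)

    def copy(self) -> "SamplerState":
        return SamplerState(
            **{
                k: (v.copy() if isinstance(v, np.ndarray) else v)
                for k, v in self.__dict__.items()
            }
        )


def _coeff_logprior(model: StateSpaceModel, alpha, beta0, beta):
    pr = model.priors
    if pr.baseline_prior == "uniform_prob":
        # uniform on the probability scale => density p(1-p) on the logit scale
        base = sum(
            -np.logaddexp(0.0, -e) - np.logaddexp(0.0, e)
            for e in (alpha[0], alpha[1], beta0)
        )
    else:
        base = float(
            norm_logpdf(np.array([alpha[0], alpha[1], beta0]), 0.0, pr.baseline_sd**2).sum()
        )
    slopes = np.concatenate([alpha[2:], beta])
    return base + float(norm_logpdf(slopes, 0.0, pr.slope_sd**2).sum())


def log_joint(model: StateSpaceModel, state: SamplerState):
    """Full joint log density; returns ``(total, components)``.

    A non-finite total raises with the offending component named.
    """
    comp: dict[str, float] = {}
    Pfull = model.P_obs.copy()
    if model.idx_Pmiss.size:
        Pfull[model.idx_Pmiss] = state.P_imputed
    Afull = model.A_obs.copy()
    if model.idx_Amiss.size:
        Afull[model.idx_Amiss] = state.A_imputed
    phi_f, phi_a = model.phi_vectors(state.alpha, state.I, Pfull)
    C = (state.N[:, BREEDING_STAGE] - model.c_mu) / model.c_sd
    eta = model.eta_b_base(state.beta0, state.beta, state.J, Afull, Pfull)
    if state.J[9]:
        eta = eta + state.beta[9] * C
    b = expit(eta)

    comp["prior_coefficients"] = _coeff_logprior(model, state.alpha, state.beta0, state.beta)
    p_all = np.concatenate([state.pI, state.pJ])
    i_all = np.concatenate([state.I, state.J]).astype(float)
    comp["prior_indicators"] = float(
        (i_all * np.log(p_all) + (1 - i_all) * np.log1p(-p_all)).sum()
    )
    comp["prior_initial_state"] = float(
        norm_logpdf(state.N[0, BREEDING_STAGE], model.init6_mean, model.init6_var)
        + norm_logpdf(
            state.N[0, :BREEDING_STAGE], model.init_pre_mean, model.init_pre_sd**2
        ).sum()
    )

    if model.options.include_process:
        comp["process"] = _process_ll(model, state.N, state.CF, phi_f, phi_a, b)
    if model.options.include_observations:
        comp["obs_counts"] = _count_ll(model, state.N, state.CF)
        comp["obs_survival"] = _surv_ll(model, phi_f, phi_a, state.V_f, state.V_a)
        comp["prior_V"] = _v_prior_ll(model, state)
    comp["imputation"] = _imputation_ll(model, state)

    total = sum(comp.values())
    if not np.isfinite(total):
        bad = [k for k, v in comp.items() if not np.isfinite(v)]
        raise FloatingPointError(f"non-finite log joint; offending components: {bad}")
    return total, comp


def _process_ll(model, N, CF, phi_f, phi_a, b):
    fl = model.options.var_floor
    pa = phi_a[:-1]
    q1 = (phi_a * phi_f)[:-1]
    half_b = b / 2.0
    if model.options.process_likelihood == "normal":
        ll = norm_logpdf(N[1:, 0], CF[:-1] * q1, CF[:-1] * q1 * (1 - q1) + fl).sum()
        for i in range(1, BREEDING_STAGE):
            base = N[:-1, i - 1]
            ll += norm_logpdf(N[1:, i], base * pa, base * pa * (1 - pa) + fl).sum()
        base6 = N[:-1, BREEDING_STAGE - 1] + N[:-1, BREEDING_STAGE]
        ll += norm_logpdf(N[1:, BREEDING_STAGE], base6 * pa, base6 * pa * (1 - pa) + fl).sum()
        n6 = N[:, BREEDING_STAGE]
        ll += norm_logpdf(CF, n6 * half_b, n6 * half_b * (1 - half_b) + fl).sum()
    else:
        ll = _binom_logpmf(N[1:, 0], CF[:-1], q1).sum()
        for i in range(1, BREEDING_STAGE):
            ll += _binom_logpmf(N[1:, i], N[:-1, i - 1], pa).sum()
        base6 = N[:-1, BREEDING_STAGE - 1] + N[:-1, BREEDING_STAGE]
        ll += _binom_logpmf(N[1:, BREEDING_STAGE], base6, pa).sum()
        ll += _binom_logpmf(CF, N[:, BREEDING_STAGE], half_b).sum()
    return float(ll)


def _count_ll(model, N, CF):
    d = model.data
    ll = 0.0
    ok = ~np.isnan(d.obs_females)
    if ok.any():
        ll += norm_logpdf(d.obs_females[ok], N[ok, BREEDING_STAGE], model.s2).sum()
    ok = ~np.isnan(d.obs_chicks_f)
    if ok.any():
        ll += norm_logpdf(d.obs_chicks_f[ok], CF[ok], model.s2).sum()
    return float(ll)


def _surv_ll(model, phi_f, phi_a, V_f, V_a):
    d = model.data
    ll = 0.0
    if model.idx_sf.size:
        ll += norm_logpdf(d.surv_est_f[model.idx_sf], phi_f[model.idx_sf], V_f).sum()
    if model.idx_sa.size:
        ll += norm_logpdf(d.surv_est_a[model.idx_sa], phi_a[model.idx_sa], V_a).sum()
    return float(ll)


def _gamma_logpdf(x, spec: GammaSpec):
    if spec.fixed is not None:
        return 0.0
    return (
        spec.shape * math.log(spec.rate)
        - gammaln(spec.shape)
        + (spec.shape - 1) * np.log(x)
        - spec.rate * x
    )


def _v_prior_ll(model, state):
    ll = 0.0
    for V, Vmax, spec in (
        (state.V_f, state.Vmax_f, model.gamma_f),
        (state.V_a, state.Vmax_a, model.gamma_a),
    ):
        if spec is None or V.size == 0:
            continue
        if (V <= 0).any() or (V > Vmax).any():
            return -np.inf
        ll += float(np.sum(_gamma_logpdf(Vmax, spec))) - float(np.sum(np.log(Vmax)))
    return ll


def _imputation_ll(model, state):
    ll = 0.0
    if model.idx_Amiss.size:
        ll += float(
            norm_logpdf(state.A_imputed, model.A_mu, model.A_sd**2).sum()
        )
    if model.idx_Pmiss.size:
        seq = np.append(state.P_imputed, model.P_anchor)
        eps = np.diff(seq)
        s2 = state.sig2_rw
        ll += float(norm_logpdf(eps, 0.0, s2).sum())
        # inverse-gamma prior on the walk variance
        a0, b0 = model.priors.rw_shape, model.rw_b0
        ll += a0 * math.log(b0) - gammaln(a0) - (a0 + 1) * math.log(s2) - b0 / s2
    return ll


# ---------------------------------------------------------------------------
# posterior container and diagnostics
# ---------------------------------------------------------------------------


@dataclass
class PosteriorDraws:
    """Thinned, burn-in-stripped draws, shaped ``(chains, n_draws, ...)``."""

    draws: dict[str, np.ndarray]
    meta: dict

    def __getitem__(self, name: str) -> np.ndarray:
        return self.draws[name]

    def __contains__(self, name: str) -> bool:
        return name in self.draws

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws with the chain axis flattened away."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, arr in sorted(self.draws.items()):
            flat = arr.reshape(-1, *arr.shape[2:])
            flat2 = flat.reshape(flat.shape[0], -1)
            for j in range(flat2.shape[1]):
                col = flat2[:, j]
                label = name if flat2.shape[1] == 1 else f"{name}[{j}]"
                rows.append(
                    {
                        "parameter": label,
                        "mean": col.mean(),
                        "sd": col.std(ddof=1),
                        "q2.5": np.quantile(col, 0.025),
                        "median": np.quantile(col, 0.5),
                        "q97.5": np.quantile(col, 0.975),
                    }
                )
        return pd.DataFrame(rows)

    def save(self, path) -> None:
        import json
        from pathlib import Path

        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), **self.draws)
        path.with_suffix(".json").write_text(json.dumps(self.meta, default=str, indent=1))

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        import json
        from pathlib import Path

        path = Path(path)
        with np.load(path.with_suffix(".npz")) as z:
            draws = {k: z[k] for k in z.files}
        meta_path = path.with_suffix(".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(draws=draws, meta=meta)


def gelman_rubin(draws, params=None):
    """Brooks-Gelman-Rubin potential scale reduction per quantity.

    Classic (non-split) form: with m chains of length n, within-chain
    variance ``W`` and between-chain variance ``B`` of the chain means,
    ``R-hat = sqrt(((n-1)/n W + B/n) / W)``.  Values near 1 signal
    convergence.  Accepts a :class:`PosteriorDraws` or a mapping of
    name -> array shaped ``(chains, n, ...)``.
    """
    source = draws.draws if isinstance(draws, PosteriorDraws) else draws
    names = params if params is not None else list(source)
    out = {}
    for name in names:
        arr = np.asarray(source[name], dtype=float)
        if arr.ndim < 2 or arr.shape[0] < 2:
            raise ValueError(f"{name}: need >=2 chains")
        m, n = arr.shape[:2]
        if n < 10:
            raise ValueError(f"{name}: need >=10 draws per chain")
        flat = arr.reshape(m, n, -1)
        means = flat.mean(axis=1)
        W = flat.var(axis=1, ddof=1).mean(axis=0)
        B_over_n = means.var(axis=0, ddof=1)
        var_hat = (n - 1) / n * W + B_over_n
        with np.errstate(divide="ignore", invalid="ignore"):
            rhat = np.sqrt(var_hat / W)
        rhat = np.where((W == 0) & (B_over_n == 0), 1.0, rhat)
        rhat = np.where((W == 0) & (B_over_n > 0), np.inf, rhat)
        out[name] = rhat.reshape(arr.shape[2:]) if arr.ndim > 2 else float(rhat[0])
    return out


#: quantities whose convergence is checked by default: every coefficient,
#: the inclusion probabilities, the error-variance hyperparameters, and
#: the latent breeding-female abundances.
DEFAULT_MONITORED = (
    "alpha_f0", "alpha_a0", "alpha_1", "alpha_2", "alpha_3",
    "beta_0", "beta",
    "p_incl_surv", "p_incl_prod",
    "sig2_rw", "Vmax_f", "Vmax_a",
    "n6",
)


def max_rhat(draws: PosteriorDraws, monitored=DEFAULT_MONITORED) -> float:
    """Maximum R-hat over the monitored quantities present in ``draws``."""
    present = [m for m in monitored if m in draws]
    rh = gelman_rubin(draws, present)
    vals = []
    for v in rh.values():
        vals.append(np.atleast_1d(v))
    return float(np.max(np.concatenate([np.ravel(v) for v in vals])))


def inclusion_probabilities(draws: PosteriorDraws) -> pd.Series:
    """Posterior inclusion probability per covariate term (posterior mean
    of the Bernoulli indicator).  A probability above 0.5 means the term
    operates in more than half of the model parameterisations."""
    labels, values = [], []
    I = draws.stacked("I")
    for k, t in enumerate(SURVIVAL_TERMS):
        labels.append(f"surv:{t}")
        values.append(I[:, k].mean())
    J = draws.stacked("J")
    for k, t in enumerate(PRODUCTIVITY_TERMS):
        labels.append(f"prod:{t}")
        values.append(J[:, k].mean())
    return pd.Series(values, index=labels, name="inclusion_probability")


# ---------------------------------------------------------------------------
# the chain runner
# ---------------------------------------------------------------------------


def _nlp(x, mu, var):
    return -0.5 * (_LOG2PI + math.log(var) + (x - mu) ** 2 / var)


class _ChainRunner:
    """One MCMC chain with adaptive proposal scales."""

    def __init__(self, model: StateSpaceModel, rng: np.random.Generator, jitter: float):
        self.m = model
        self.rng = rng
        self.T = model.T
        self.fl = model.options.var_floor
        self._init_state(jitter)
        self._refresh_caches()
        # proposal scales
        self.sc_alpha = np.full(5, 0.1)
        self.sc_beta = np.full(11, 0.1)
        self.sc_vmax = 0.6
        self.sc_pblock = 0.3
        self.sc_pscale = 0.1
        self.sc_cohort = 0.2
        self.sc_pmiss = np.full(model.idx_Pmiss.size, 0.3)
        self.sc_state = np.full((self.T, 7), 1.0) * np.maximum(
            np.sqrt(np.concatenate([self.N, self.CF[:, None]], axis=1)), 2.0
        ) * 0.6
        self._acc = {}
        self._try = {}
        # adaptive joint proposals (Haario-style) per coefficient block
        self._am_alpha = _RunningCov(5)
        self._am_beta = _RunningCov(11)
        self.adapting = True

    # -- initialisation -----------------------------------------------
    def _init_state(self, jitter):
        m, rng = self.m, self.rng
        d = m.data
        T = self.T

        def jit(scale=1.0):
            return rng.normal(0.0, jitter * scale)

        est_f = d.surv_est_f[m.idx_sf]
        est_a = d.surv_est_a[m.idx_sa]
        phi_f0 = float(np.clip(est_f.mean() if est_f.size else 0.4, 0.05, 0.95))
        phi_a0 = float(np.clip(est_a.mean() if est_a.size else 0.85, 0.05, 0.95))
        alpha = np.array(
            [
                math.log(phi_f0 / (1 - phi_f0)) + jit(),
                math.log(phi_a0 / (1 - phi_a0)) + jit(),
                jit(0.5), jit(0.5), jit(0.5),
            ]
        )
        females = pd.Series(d.obs_females).interpolate(limit_direction="both").to_numpy()
        chicks = pd.Series(d.obs_chicks_f).interpolate(limit_direction="both").to_numpy()
        females = np.maximum(females, 1.0)
        chicks = np.maximum(chicks, 1.0)
        b_obs = float(np.clip(np.nanmean(2.0 * chicks / females), 0.05, 0.95))
        beta0 = math.log(b_obs / (1 - b_obs)) + jit()
        beta = rng.normal(0.0, 0.3, size=10) * (jitter / 0.3 if jitter else 0.0)

        # start in the full model (all terms operating); overdispersion
        # comes from the jittered coefficients, latents and imputations
        I = np.ones(3, dtype=np.int64)
        J = np.ones(10, dtype=np.int64)
        I[m.forced_off_surv] = 0
        J[m.forced_off_prod] = 0
        pI = rng.uniform(0.2, 0.8, size=3)
        pJ = rng.uniform(0.2, 0.8, size=10)

        V_f = m.var_sf.copy() if m.idx_sf.size else np.empty(0)
        Vmax_f = V_f * 1.5 if V_f.size else np.empty(0)
        V_a = m.var_sa.copy() if m.idx_sa.size else np.empty(0)
        Vmax_a = V_a * 1.5 if V_a.size else np.empty(0)

        sig2_rw = (
            (m.rw_b0 / (m.priors.rw_shape - 1.0)) * math.exp(jit(0.5))
            if m.idx_Pmiss.size
            else 1.0
        )
        P_imp = (
            m.P_anchor + rng.normal(0, 0.3, size=m.idx_Pmiss.size)
            if m.idx_Pmiss.size
            else np.empty(0)
        )
        A_imp = (
            m.A_mu + rng.normal(0, 0.3, size=m.idx_Amiss.size)
            if m.idx_Amiss.size
            else np.empty(0)
        )

        N = np.zeros((T, N_STAGES))
        N[:, BREEDING_STAGE] = females * np.exp(rng.normal(0, 0.02, size=T))
        ratios = m.init_pre_mean / m.init6_mean
        for i in range(BREEDING_STAGE):
            N[:, i] = ratios[i] * N[:, BREEDING_STAGE]
        CF = chicks * np.exp(rng.normal(0, 0.02, size=T))
        if m.options.process_likelihood == "binomial":
            N = np.round(N)
            CF = np.round(CF)

        self.state = SamplerState(
            alpha=alpha, I=I, pI=pI, beta0=beta0, beta=beta, J=J, pJ=pJ,
            V_f=V_f, Vmax_f=Vmax_f, V_a=V_a, Vmax_a=Vmax_a,
            sig2_rw=sig2_rw, P_imputed=P_imp, A_imputed=A_imp, N=N, CF=CF,
        )
        self.N = self.state.N
        self.CF = self.state.CF

    def set_state(self, state: SamplerState) -> None:
        """Replace the current point (used to pin latents in sub-models)."""
        self.state = state
        self.N = state.N
        self.CF = state.CF
        self._refresh_caches()

    # -- caches --------------------------------------------------------
    def _refresh_caches(self):
        s, m = self.state, self.m
        self.Pfull = m.P_obs.copy()
        if m.idx_Pmiss.size:
            self.Pfull[m.idx_Pmiss] = s.P_imputed
        self.Afull = m.A_obs.copy()
        if m.idx_Amiss.size:
            self.Afull[m.idx_Amiss] = s.A_imputed
        self.phi_f, self.phi_a = m.phi_vectors(s.alpha, s.I, self.Pfull)
        self.C = (self.N[:, BREEDING_STAGE] - m.c_mu) / m.c_sd
        self.eta_base = m.eta_b_base(s.beta0, s.beta, s.J, self.Afull, self.Pfull)
        self.b = expit(self.eta_base + s.J[9] * s.beta[9] * self.C)
        self._refresh_transitions()

    def _refresh_transitions(self):
        """Stacked (year, stage) transition outcomes and denominators,
        reused across the many survival-likelihood evaluations between
        latent-state updates."""
        N, CF = self.N, self.CF
        X = np.empty((self.T - 1, N_STAGES))
        B = np.empty_like(X)
        X[:] = N[1:, :]
        B[:, 0] = CF[:-1]
        B[:, 1:BREEDING_STAGE] = N[:-1, 0:BREEDING_STAGE - 1]
        B[:, BREEDING_STAGE] = N[:-1, BREEDING_STAGE - 1] + N[:-1, BREEDING_STAGE]
        self._tX, self._tB = X, B

    # -- block likelihoods ---------------------------------------------
    def _ll_phi(self, phi_f, phi_a):
        """Terms involving the survival rates: process transitions and
        survival observations (chick production excluded)."""
        m, s = self.m, self.state
        N, CF, fl = self.N, self.CF, self.fl
        ll = 0.0
        if m.options.include_process:
            pa = phi_a[:-1]
            q1 = (phi_a * phi_f)[:-1]
            if m.options.process_likelihood == "normal":
                # fused over the stacked (year, stage) transition terms
                P = np.empty_like(self._tB)
                P[:, 0] = q1
                P[:, 1:] = pa[:, None]
                mu = self._tB * P
                var = mu * (1.0 - P) + fl
                ll += float(
                    (-0.5 * (_LOG2PI + np.log(var) + (self._tX - mu) ** 2 / var)).sum()
                )
            else:
                ll += _binom_logpmf(N[1:, 0], CF[:-1], q1).sum()
                for i in range(1, BREEDING_STAGE):
                    ll += _binom_logpmf(N[1:, i], N[:-1, i - 1], pa).sum()
                base6 = N[:-1, BREEDING_STAGE - 1] + N[:-1, BREEDING_STAGE]
                ll += _binom_logpmf(N[1:, BREEDING_STAGE], base6, pa).sum()
        if m.options.include_observations:
            if m.idx_sf.size:
                ll += norm_logpdf(
                    m.data.surv_est_f[m.idx_sf], phi_f[m.idx_sf], s.V_f
                ).sum()
            if m.idx_sa.size:
                ll += norm_logpdf(
                    m.data.surv_est_a[m.idx_sa], phi_a[m.idx_sa], s.V_a
                ).sum()
        return float(ll)

    def _ll_b(self, b):
        """Chick-production terms (the only ones involving productivity)."""
        m = self.m
        if not m.options.include_process:
            return 0.0
        n6, CF, fl = self.N[:, BREEDING_STAGE], self.CF, self.fl
        hb = b / 2.0
        if m.options.process_likelihood == "normal":
            return float(norm_logpdf(CF, n6 * hb, n6 * hb * (1 - hb) + fl).sum())
        return float(_binom_logpmf(CF, n6, hb).sum())

    # -- adaptation helpers ---------------------------------------------
    def _bump(self, key, accepted):
        self._acc[key] = self._acc.get(key, 0) + (1 if accepted else 0)
        self._try[key] = self._try.get(key, 0) + 1

    def adapt(self):
        """Rescale proposals from batch acceptance rates (burn-in only)."""
        for key, tries in self._try.items():
            if tries == 0:
                continue
            rate = self._acc.get(key, 0) / tries
            kind = key[0]
            # ridge-traversing moves aim low (big steps cover the ridge)
            target = 0.15 if kind in ("ps", "pb") else 0.35
            f = math.exp(0.6 * (rate - target))
            if kind == "a":
                self.sc_alpha[key[1]] *= f
            elif kind == "b":
                self.sc_beta[key[1]] *= f
            elif kind == "v":
                self.sc_vmax *= f
            elif kind == "pb":
                self.sc_pblock *= f
            elif kind == "ps":
                self.sc_pscale *= f
            elif kind == "co":
                self.sc_cohort *= f
            elif kind == "p":
                self.sc_pmiss[key[1]] *= f
        self._acc.clear()
        self._try.clear()

    # -- parameter updates ----------------------------------------------
    def update_survival_coefficients(self):
        """Single-site and joint adaptive Metropolis on the survival
        coefficients, conditional on the latent states (fast local
        exploration; the transported ridge moves handle the slow joint
        directions)."""
        m, s, rng = self.m, self.state, self.rng
        pr = m.priors
        active = [0, 1]
        for k, slot in ((0, 2), (1, 3), (2, 4)):
            if s.I[k]:
                active.append(slot)
            else:
                s.alpha[slot] = rng.normal(0.0, pr.slope_sd)
        cur_ll = self._ll_phi(self.phi_f, self.phi_a)
        for slot in active:
            prop = s.alpha.copy()
            prop[slot] += rng.normal(0.0, self.sc_alpha[slot])
            pf, pa = m.phi_vectors(prop, s.I, self.Pfull)
            logr = self._ll_phi(pf, pa) - cur_ll
            logr += _coeff_logprior(m, prop, s.beta0, s.beta) - _coeff_logprior(
                m, s.alpha, s.beta0, s.beta
            )
            ok = math.log(rng.random()) < logr
            if ok:
                s.alpha = prop
                self.phi_f, self.phi_a = pf, pa
                cur_ll = self._ll_phi(pf, pa)
            if self.adapting:
                self._bump(("a", slot), ok)
        # joint adaptive move over the whole block
        cov = self._am_alpha.cov()
        if cov is not None:
            prop = s.alpha + rng.multivariate_normal(np.zeros(5), cov)
            pf, pa = m.phi_vectors(prop, s.I, self.Pfull)
            logr = self._ll_phi(pf, pa) - cur_ll
            logr += _coeff_logprior(m, prop, s.beta0, s.beta) - _coeff_logprior(
                m, s.alpha, s.beta0, s.beta
            )
            if math.log(rng.random()) < logr:
                s.alpha = prop
                self.phi_f, self.phi_a = pf, pa
        if self.adapting:
            self._am_alpha.push(s.alpha)

    def update_productivity_coefficients(self):
        m, s, rng = self.m, self.state, self.rng
        pr = m.priors
        vec = np.concatenate([[s.beta0], s.beta])
        active = [0] + [k + 1 for k in range(10) if s.J[k]]
        for k in range(10):
            if not s.J[k]:
                vec[k + 1] = rng.normal(0.0, pr.slope_sd)
        cur_ll = self._ll_b(self.b)

        def set_vec(v):
            s.beta0 = float(v[0])
            s.beta = v[1:].copy()
            self.eta_base = m.eta_b_base(s.beta0, s.beta, s.J, self.Afull, self.Pfull)
            self.b = expit(self.eta_base + s.J[9] * s.beta[9] * self.C)

        set_vec(vec)
        cur_ll = self._ll_b(self.b)
        for slot in active:
            prop = vec.copy()
            prop[slot] += rng.normal(0.0, self.sc_beta[slot])
            eta = m.eta_b_base(prop[0], prop[1:], s.J, self.Afull, self.Pfull)
            b_prop = expit(eta + s.J[9] * prop[10] * self.C)
            logr = self._ll_b(b_prop) - cur_ll
            logr += _coeff_logprior(m, s.alpha, prop[0], prop[1:]) - _coeff_logprior(
                m, s.alpha, vec[0], vec[1:]
            )
            ok = math.log(rng.random()) < logr
            if ok:
                vec = prop
                set_vec(vec)
                cur_ll = self._ll_b(self.b)
            if self.adapting:
                self._bump(("b", slot), ok)
        cov = self._am_beta.cov()
        if cov is not None:
            prop = vec + rng.multivariate_normal(np.zeros(11), cov)
            eta = m.eta_b_base(prop[0], prop[1:], s.J, self.Afull, self.Pfull)
            b_prop = expit(eta + s.J[9] * prop[10] * self.C)
            logr = self._ll_b(b_prop) - cur_ll
            logr += _coeff_logprior(m, s.alpha, prop[0], prop[1:]) - _coeff_logprior(
                m, s.alpha, vec[0], vec[1:]
            )
            if math.log(rng.random()) < logr:
                vec = prop
                set_vec(vec)
        if self.adapting:
            self._am_beta.push(vec)

    def swap_predation_terms(self):
        """Mode-jumping move exchanging the shared and fledgling-specific
        predation terms, ``(I1, a1) <-> (I2, a2)``.

        The two terms act identically on fledgling survival, so the
        sampler can otherwise get trapped in a mode that explains
        predation through the fledgling-only coefficient; the swap is a
        measure-preserving involution (identical priors on a1 and a2)
        accepted on the likelihood and indicator-prior ratio.
        """
        m, s, rng = self.m, self.state, self.rng
        if m.forced_off_surv[0] or m.forced_off_surv[1]:
            return
        prop_alpha = s.alpha.copy()
        prop_alpha[2], prop_alpha[3] = s.alpha[3], s.alpha[2]
        prop_I = s.I.copy()
        prop_I[0], prop_I[1] = s.I[1], s.I[0]
        pf, pa = m.phi_vectors(prop_alpha, prop_I, self.Pfull)
        logr = self._ll_phi(pf, pa) - self._ll_phi(self.phi_f, self.phi_a)
        for k in (0, 1):
            logr += (prop_I[k] - s.I[k]) * (
                math.log(s.pI[k]) - math.log1p(-s.pI[k])
            )
        if math.log(rng.random()) < logr:
            s.alpha = prop_alpha
            s.I = prop_I
            self.phi_f, self.phi_a = pf, pa

    def update_indicators(self):
        m, s, rng = self.m, self.state, self.rng
        cur_ll_phi = self._ll_phi(self.phi_f, self.phi_a)
        for k in range(3):
            if m.forced_off_surv[k]:
                s.I[k] = 0
                continue
            cur = int(s.I[k])
            trial = s.I.copy()
            trial[k] = 1 - cur
            pf, pa = m.phi_vectors(s.alpha, trial, self.Pfull)
            lls = {cur: cur_ll_phi, 1 - cur: self._ll_phi(pf, pa)}
            logodds = math.log(s.pI[k]) - math.log1p(-s.pI[k]) + lls[1] - lls[0]
            new = 1 if rng.random() < expit(logodds) else 0
            if new != cur:
                s.I[k] = new
                self.phi_f, self.phi_a = pf, pa
                cur_ll_phi = lls[new]
        cur_ll_b = self._ll_b(self.b)
        for k in range(10):
            if m.forced_off_prod[k]:
                s.J[k] = 0
                continue
            cur = int(s.J[k])
            trial = s.J.copy()
            trial[k] = 1 - cur
            eta = m.eta_b_base(s.beta0, s.beta, trial, self.Afull, self.Pfull)
            b = expit(eta + trial[9] * s.beta[9] * self.C)
            lls = {cur: cur_ll_b, 1 - cur: self._ll_b(b)}
            logodds = math.log(s.pJ[k]) - math.log1p(-s.pJ[k]) + lls[1] - lls[0]
            new = 1 if rng.random() < expit(logodds) else 0
            if new != cur:
                s.J[k] = new
                self.eta_base = eta
                self.b = b
                cur_ll_b = lls[new]

    def update_inclusion_probabilities(self):
        s, rng = self.state, self.rng
        s.pI = rng.beta(1.0 + s.I, 2.0 - s.I)
        s.pJ = rng.beta(1.0 + s.J, 2.0 - s.J)

    def update_error_variances(self):
        m, s, rng = self.m, self.state, self.rng
        if not m.options.include_observations:
            return
        for est_name, idx, V, Vmax, spec in (
            ("surv_est_f", m.idx_sf, s.V_f, s.Vmax_f, m.gamma_f),
            ("surv_est_a", m.idx_sa, s.V_a, s.Vmax_a, m.gamma_a),
        ):
            if spec is None or idx.size == 0:
                continue
            est = getattr(m.data, est_name)[idx]
            phi = (self.phi_f if est_name.endswith("f") else self.phi_a)[idx]
            for j in range(idx.size):
                vp = rng.uniform(0.0, Vmax[j])
                logr = _nlp(est[j], phi[j], vp) - _nlp(est[j], phi[j], V[j])
                if math.log(rng.random()) < logr:
                    V[j] = vp
                if spec.fixed is None:
                    lvp = math.log(Vmax[j]) + rng.normal(0.0, self.sc_vmax)
                    vmp = math.exp(lvp)
                    if vmp > V[j]:
                        logr = (
                            float(_gamma_logpdf(vmp, spec))
                            - float(_gamma_logpdf(Vmax[j], spec))
                            - math.log(vmp) + math.log(Vmax[j])  # U(0,Vmax) density
                            + lvp - math.log(Vmax[j])  # log-scale proposal Jacobian
                        )
                        ok = math.log(rng.random()) < logr
                        if ok:
                            Vmax[j] = vmp
                        if self.adapting:
                            self._bump(("v",), ok)

    def update_rw_variance(self):
        m, s, rng = self.m, self.state, self.rng
        if not m.idx_Pmiss.size:
            return
        eps = np.diff(np.append(s.P_imputed, m.P_anchor))
        a_post = m.priors.rw_shape + eps.size / 2.0
        b_post = m.rw_b0 + 0.5 * float(eps @ eps)
        s.sig2_rw = b_post / rng.gamma(a_post)

    # -- local year terms ----------------------------------------------
    def _year_phi_terms(self, j, phi_f_j, phi_a_j):
        """Process/observation terms at year j that move with phi_j."""
        m = self.m
        N, CF, fl = self.N, self.CF, self.fl
        ll = 0.0
        if m.options.include_process and j < self.T - 1:
            q1 = phi_a_j * phi_f_j
            pa = phi_a_j
            mu = float(CF[j]) * q1
            ll += _nlp(float(N[j + 1, 0]), mu, float(CF[j]) * q1 * (1 - q1) + fl)
            for i in range(1, BREEDING_STAGE):
                base = float(N[j, i - 1])
                ll += _nlp(float(N[j + 1, i]), base * pa, base * pa * (1 - pa) + fl)
            base6 = float(N[j, BREEDING_STAGE - 1] + N[j, BREEDING_STAGE])
            ll += _nlp(float(N[j + 1, BREEDING_STAGE]), base6 * pa, base6 * pa * (1 - pa) + fl)
        if m.options.include_observations:
            if not math.isnan(m.data.surv_est_f[j]):
                pos = int(np.searchsorted(m.idx_sf, j))
                ll += _nlp(m.data.surv_est_f[j], phi_f_j, float(self.state.V_f[pos]))
            if not math.isnan(m.data.surv_est_a[j]):
                pos = int(np.searchsorted(m.idx_sa, j))
                ll += _nlp(m.data.surv_est_a[j], phi_a_j, float(self.state.V_a[pos]))
        return ll

    def _year_chick_term(self, j, b_j):
        m = self.m
        if not m.options.include_process:
            return 0.0
        n6 = float(self.N[j, BREEDING_STAGE])
        hb = b_j / 2.0
        return _nlp(float(self.CF[j]), n6 * hb, n6 * hb * (1 - hb) + self.fl)

    def _phi_at(self, j, P_j):
        s = self.state
        S1j = float(self.m.S1[j])
        eta_f = s.alpha[0] + (s.I[0] * s.alpha[2] + s.I[1] * s.alpha[3]) * P_j \
            + s.I[2] * s.alpha[4] * S1j
        eta_a = s.alpha[1] + s.I[0] * s.alpha[2] * P_j + s.I[2] * s.alpha[4] * S1j
        return 1.0 / (1.0 + math.exp(-eta_f)), 1.0 / (1.0 + math.exp(-eta_a))

    def _pred_year_ll(self, j, P_j, cur_P_j, uses_phi, uses_b):
        """Likelihood terms at year j that move with the predation value
        (random-walk prior terms excluded)."""
        s = self.state
        ll = 0.0
        if uses_phi:
            pf, pa = self._phi_at(j, P_j)
            ll += self._year_phi_terms(j, pf, pa)
        if uses_b:
            eta = float(self.eta_base[j]) + s.beta[1] * (P_j - cur_P_j)
            eta += s.J[9] * s.beta[9] * float(self.C[j])
            b_j = 1.0 / (1.0 + math.exp(-eta))
            ll += self._year_chick_term(j, b_j)
        return ll

    def _accept_pred(self, pos, j, new, uses_phi, uses_b):
        s = self.state
        cur = float(s.P_imputed[pos])
        s.P_imputed[pos] = new
        self.Pfull[j] = new
        self.eta_base[j] += s.J[1] * s.beta[1] * (new - cur)
        if uses_phi:
            self.phi_f[j], self.phi_a[j] = self._phi_at(j, new)
        self.b[j] = 1.0 / (
            1.0 + math.exp(-(self.eta_base[j] + s.J[9] * s.beta[9] * self.C[j]))
        )

    def update_imputed_predation(self, n_passes: int = 3):
        """Single-site bridge proposals plus a whole-block translation.

        Each missing year gets an independence proposal from the
        random-walk full conditional given its neighbours (exact Gibbs
        when predation is switched off everywhere, a likelihood-only
        Metropolis ratio otherwise).  The block translation trades the
        whole imputed segment against the predation coefficients, the
        slow direction of this posterior.
        """
        m, s, rng = self.m, self.state, self.rng
        if not m.idx_Pmiss.size:
            return
        sig2 = s.sig2_rw
        uses_phi = bool(s.I[0] or s.I[1])
        uses_b = bool(s.J[1])
        informed = uses_phi or uses_b
        # current per-year likelihood terms: valid until that year's value
        # is accepted (they depend only on the year's own covariate value)
        cur_ll = [
            self._pred_year_ll(j, float(s.P_imputed[pos]), float(s.P_imputed[pos]),
                               uses_phi, uses_b)
            for pos, j in enumerate(m.idx_Pmiss)
        ] if informed else None
        for ipass in range(n_passes):
            rw_pass = informed and ipass % 2 == 1
            for pos, j in enumerate(m.idx_Pmiss):
                cur = float(s.P_imputed[pos])
                nxt = float(self.Pfull[j + 1])
                if j > 0:
                    prev = float(self.Pfull[j - 1])
                    mu, var = 0.5 * (prev + nxt), sig2 / 2.0
                else:
                    mu, var = nxt, sig2
                if rw_pass:
                    # small adaptive step for years where the likelihood
                    # is tight and bridge proposals are mostly rejected
                    prop = cur + rng.normal(0.0, self.sc_pmiss[pos])
                    prop_ll = self._pred_year_ll(j, prop, cur, uses_phi, uses_b)
                    logr = (
                        _nlp(prop, mu, var) - _nlp(cur, mu, var)
                        + prop_ll - cur_ll[pos]
                    )
                    ok = math.log(rng.random()) < logr
                    if ok:
                        self._accept_pred(pos, j, prop, uses_phi, uses_b)
                        cur_ll[pos] = prop_ll
                    if self.adapting:
                        self._bump(("p", pos), ok)
                    continue
                prop = rng.normal(mu, math.sqrt(var))
                if informed:
                    prop_ll = self._pred_year_ll(j, prop, cur, uses_phi, uses_b)
                    if math.log(rng.random()) >= prop_ll - cur_ll[pos]:
                        continue
                    cur_ll[pos] = prop_ll
                self._accept_pred(pos, j, prop, uses_phi, uses_b)
        self.translate_predation_block()

    def translate_predation_block(self, n_moves: int = 2):
        """Whole-block translations with baseline compensation.

        Proposes ``P_imputed -> P_imputed + delta`` together with
        ``aa0 -> aa0 - a1 delta`` and ``af0 -> af0 - (I1 a1 + I2 a2)
        delta``, which leaves every imputed-year survival logit
        unchanged (unit Jacobian); the observed-year terms, the anchor
        increment of the random walk and the priors arbitrate the block
        level.  This is the second soft ridge of the imputation
        posterior (the first, its scale, is handled by
        :meth:`rescale_predation_block`)."""
        m, s, rng = self.m, self.state, self.rng
        if not m.idx_Pmiss.size:
            return
        cur_ll = self._ridge_cur_ll()
        for _ in range(n_moves):
            delta = rng.normal(0.0, self.sc_pblock)
            P_prop = s.P_imputed + delta
            alpha_prop = s.alpha.copy()
            alpha_prop[1] -= s.I[0] * alpha_prop[2] * delta
            alpha_prop[0] -= (
                s.I[0] * alpha_prop[2] + s.I[1] * alpha_prop[3]
            ) * delta
            Pfull_prop = self.Pfull.copy()
            Pfull_prop[m.idx_Pmiss] = P_prop
            out = self._ridge_logr(alpha_prop, Pfull_prop, cur_ll)
            ok = False
            if out is not None:
                logr, payload = out
                logr += _coeff_logprior(m, alpha_prop, s.beta0, s.beta) \
                    - _coeff_logprior(m, s.alpha, s.beta0, s.beta)
                # only the increment onto the anchor changes under translation
                last = float(s.P_imputed[-1])
                logr += (
                    -((last + delta - m.P_anchor) ** 2)
                    + ((last - m.P_anchor) ** 2)
                ) / (2 * s.sig2_rw)
                ok = math.log(rng.random()) < logr
            if ok:
                self._ridge_apply(alpha_prop, Pfull_prop, payload)
                cur_ll = self._ridge_cur_ll()
            if self.adapting:
                self._bump(("pb",), ok)

    def _transport_latents(self, phi_f_new, phi_a_new, eta_base_new):
        """Move the latent states with a proposed set of rates so the
        standardized process residuals are preserved.

        For each transition the latent outcome is mapped through
        ``x' = mu' + (x - mu) sqrt(v'/v)``; the accumulated Jacobian is
        returned so the acceptance ratio can pair it with the exact
        process-density change.  The productivity auto-covariate is
        re-derived from the transported breeder counts year by year.
        Returns ``(N', CF', b', log_jacobian)`` or None when a
        transported value would go negative.
        """
        m = self.m
        fl = self.fl
        N, CF = self.N, self.CF
        T = self.T
        s = self.state
        pf_o, pa_o, b_o = self.phi_f, self.phi_a, self.b
        Np = np.empty_like(N)
        CFp = np.empty_like(CF)
        bp = np.empty(T)
        Np[0] = N[0]
        logjac = 0.0
        j9b9 = s.J[9] * s.beta[9]
        for t in range(T):
            n6o = float(N[t, BREEDING_STAGE])
            n6n = float(Np[t, BREEDING_STAGE])
            eta = float(eta_base_new[t]) + j9b9 * (n6n - m.c_mu) / m.c_sd
            b_t = 1.0 / (1.0 + math.exp(-eta))
            bp[t] = b_t
            ho, hn = b_o[t] / 2.0, b_t / 2.0
            mo, vo = n6o * ho, n6o * ho * (1 - ho) + fl
            mn, vn = n6n * hn, n6n * hn * (1 - hn) + fl
            cfp = mn + (float(CF[t]) - mo) * math.sqrt(vn / vo)
            if cfp < 0:
                return None
            CFp[t] = cfp
            logjac += 0.5 * (math.log(vn) - math.log(vo))
            if t == T - 1:
                break
            pao, pan = pa_o[t], phi_a_new[t]
            q1o, q1n = pao * pf_o[t], phi_a_new[t] * phi_f_new[t]
            mo, vo = CF[t] * q1o, CF[t] * q1o * (1 - q1o) + fl
            mn, vn = cfp * q1n, cfp * q1n * (1 - q1n) + fl
            x = mn + (float(N[t + 1, 0]) - mo) * math.sqrt(vn / vo)
            if x < 0:
                return None
            Np[t + 1, 0] = x
            logjac += 0.5 * (math.log(vn) - math.log(vo))
            for i in range(1, BREEDING_STAGE):
                bo, bn = float(N[t, i - 1]), float(Np[t, i - 1])
                mo, vo = bo * pao, bo * pao * (1 - pao) + fl
                mn, vn = bn * pan, bn * pan * (1 - pan) + fl
                x = mn + (float(N[t + 1, i]) - mo) * math.sqrt(vn / vo)
                if x < 0:
                    return None
                Np[t + 1, i] = x
                logjac += 0.5 * (math.log(vn) - math.log(vo))
            bo = float(N[t, BREEDING_STAGE - 1] + N[t, BREEDING_STAGE])
            bn = float(Np[t, BREEDING_STAGE - 1] + Np[t, BREEDING_STAGE])
            mo, vo = bo * pao, bo * pao * (1 - pao) + fl
            mn, vn = bn * pan, bn * pan * (1 - pan) + fl
            x = mn + (float(N[t + 1, BREEDING_STAGE]) - mo) * math.sqrt(vn / vo)
            if x < 0:
                return None
            Np[t + 1, BREEDING_STAGE] = x
            logjac += 0.5 * (math.log(vn) - math.log(vo))
        return Np, CFp, bp, logjac

    def _ridge_cur_ll(self):
        """Current-state likelihood pieces shared by the ridge moves."""
        m, s = self.m, self.state
        total = 0.0
        if m.options.include_process:
            total += _process_ll(m, self.N, self.CF, self.phi_f, self.phi_a, self.b)
        if m.options.include_observations:
            total += _count_ll(m, self.N, self.CF)
            total += _surv_ll(m, self.phi_f, self.phi_a, s.V_f, s.V_a)
        return total

    def _ridge_logr(self, alpha_prop, Pfull_prop, cur_ll):
        """Acceptance ingredients for a joint (coefficients, imputed
        block, latent transport) proposal; returns (logr, payload) or
        None when the transport fails.  ``logr`` covers everything
        except the move-specific prior/Jacobian extras."""
        m, s = self.m, self.state
        pf, pa = m.phi_vectors(alpha_prop, s.I, Pfull_prop)
        eta_prop = m.eta_b_base(s.beta0, s.beta, s.J, self.Afull, Pfull_prop)
        if (
            m.options.update_latents
            and m.options.include_process
            and m.options.process_likelihood == "normal"
        ):
            transported = self._transport_latents(pf, pa, eta_prop)
            if transported is None:
                return None
            Np, CFp, bp, logjac = transported
        else:
            Np, CFp, logjac = self.N, self.CF, 0.0
            bp = expit(eta_prop + s.J[9] * s.beta[9] * self.C)
        logr = logjac - cur_ll
        if m.options.include_process:
            logr += _process_ll(m, Np, CFp, pf, pa, bp)
        if m.options.include_observations:
            logr += _count_ll(m, Np, CFp)
            logr += _surv_ll(m, pf, pa, s.V_f, s.V_a)
        payload = (pf, pa, Np, CFp)
        return logr, payload

    def _ridge_apply(self, alpha_prop, Pfull_prop, payload, sig2_prop=None):
        m, s = self.m, self.state
        pf, pa, Np, CFp = payload
        s.alpha = alpha_prop
        s.P_imputed = Pfull_prop[m.idx_Pmiss].copy()
        if sig2_prop is not None:
            s.sig2_rw = sig2_prop
        self.N[...] = Np
        self.CF[...] = CFp
        self.Pfull = Pfull_prop
        self._refresh_caches()

    def rescale_predation_block(self, n_moves: int = 2):
        """Joint moves along the soft ridge between the predation
        coefficients and the scale of the imputed block.

        Each proposal is ``P_imputed -> c P_imputed``,
        ``sig2_rw -> c^2 sig2_rw``, ``a1 -> a1/c``, ``a2 -> a2/c``
        (log-Jacobian ``k log c``).  This leaves both the survival
        logits of the imputed years and the random-walk density
        invariant, so only the observed-year terms and the priors
        arbitrate the scale; large steps then traverse the whole ridge.
        Several proposals are batched per sweep with the current terms
        cached."""
        m, s, rng = self.m, self.state, self.rng
        if not m.idx_Pmiss.size:
            return
        if not (s.I[0] or s.I[1]):
            return
        k = m.idx_Pmiss.size
        sd2 = m.priors.slope_sd**2
        a0, b0 = m.priors.rw_shape, m.rw_b0

        def rw_terms(P_imp, sig2):
            eps = np.diff(np.append(P_imp, m.P_anchor))
            ll = float(norm_logpdf(eps, 0.0, sig2).sum())
            ll += -(a0 + 1) * math.log(sig2) - b0 / sig2
            return ll

        cur_ll = self._ridge_cur_ll()
        for _ in range(n_moves):
            c = math.exp(rng.normal(0.0, self.sc_pscale))
            P_prop = s.P_imputed * c
            sig2_prop = c * c * s.sig2_rw
            alpha_prop = s.alpha.copy()
            alpha_prop[2] /= c
            alpha_prop[3] /= c
            Pfull_prop = self.Pfull.copy()
            Pfull_prop[m.idx_Pmiss] = P_prop
            out = self._ridge_logr(alpha_prop, Pfull_prop, cur_ll)
            ok = False
            if out is not None:
                logr, payload = out
                logr += float(
                    norm_logpdf(alpha_prop[2:4], 0.0, sd2).sum()
                    - norm_logpdf(s.alpha[2:4], 0.0, sd2).sum()
                )
                logr += rw_terms(P_prop, sig2_prop) - rw_terms(s.P_imputed, s.sig2_rw)
                logr += k * math.log(c)  # P scaled c, sig2 by c^2, two slopes by 1/c
                ok = math.log(rng.random()) < logr
            if ok:
                self._ridge_apply(alpha_prop, Pfull_prop, payload, sig2_prop=sig2_prop)
                cur_ll = self._ridge_cur_ll()
            if self.adapting:
                self._bump(("ps",), ok)

    def flip_predation_sign(self):
        """Reflection move ``P_imputed -> -P_imputed``, ``a1 -> -a1``,
        ``a2 -> -a2`` (unit Jacobian, symmetric coefficient priors).

        The imputed block only enters the survival logits through
        products with the predation coefficients, so a chain can settle
        in a mirrored regime (positive coefficient, negated block);
        the reflection connects it to the data-supported labelling.
        Interior random-walk increments keep their magnitudes, so only
        the anchor increment and the observed-year terms arbitrate.
        """
        m, s, rng = self.m, self.state, self.rng
        if not m.idx_Pmiss.size or not (s.I[0] or s.I[1]):
            return
        P_prop = -s.P_imputed
        alpha_prop = s.alpha.copy()
        alpha_prop[2] = -alpha_prop[2]
        alpha_prop[3] = -alpha_prop[3]
        Pfull_prop = self.Pfull.copy()
        Pfull_prop[m.idx_Pmiss] = P_prop
        pf, pa = m.phi_vectors(alpha_prop, s.I, Pfull_prop)
        logr = self._ll_phi(pf, pa) - self._ll_phi(self.phi_f, self.phi_a)
        if s.J[1]:
            eta_prop = m.eta_b_base(s.beta0, s.beta, s.J, self.Afull, Pfull_prop)
            b_prop = expit(eta_prop + s.J[9] * s.beta[9] * self.C)
            logr += self._ll_b(b_prop) - self._ll_b(self.b)
        sig2 = s.sig2_rw
        last = float(s.P_imputed[-1])
        logr += (
            -((-last - m.P_anchor) ** 2) + ((last - m.P_anchor) ** 2)
        ) / (2.0 * sig2)
        if math.log(rng.random()) < logr:
            s.P_imputed = P_prop
            s.alpha = alpha_prop
            self._refresh_caches()

    def update_imputed_mass(self):
        m, s, rng = self.m, self.state, self.rng
        if not m.idx_Amiss.size:
            return
        uses_b = bool(s.J[0])
        for pos, j in enumerate(m.idx_Amiss):
            cur = float(s.A_imputed[pos])
            # independence proposal from the imputation prior; exact Gibbs
            # when the mass term is switched off
            prop = rng.normal(m.A_mu, m.A_sd)
            if uses_b:

                def lik(Aj):
                    eta = float(self.eta_base[j]) + s.beta[0] * (Aj - cur)
                    eta += s.J[9] * s.beta[9] * float(self.C[j])
                    b_j = 1.0 / (1.0 + math.exp(-eta))
                    return self._year_chick_term(j, b_j)

                if math.log(rng.random()) >= lik(prop) - lik(cur):
                    continue
            s.A_imputed[pos] = prop
            self.Afull[j] = prop
            self.eta_base[j] += s.J[0] * s.beta[0] * (prop - cur)
            self.b[j] = 1.0 / (
                1.0 + math.exp(-(self.eta_base[j] + s.J[9] * s.beta[9] * self.C[j]))
            )

    # -- latent-state updates -------------------------------------------
    def _state_local_ll(self, series, idx, vals):
        """Vectorised local log density for candidate values of one latent
        series at a set of (parity-separated) years."""
        m = self.m
        N, CF, fl = self.N, self.CF, self.fl
        T = self.T
        pf, pa, b = self.phi_f, self.phi_a, self.b
        normal = m.options.process_likelihood == "normal"

        def dens(x, base, p):
            mu = base * p
            if normal:
                return norm_logpdf(x, mu, base * p * (1 - p) + fl)
            return _binom_logpmf(x, base, p)

        ll = np.zeros(len(idx))
        inner = idx < T - 1
        first = idx == 0
        if series == 6:  # female chicks CF[t]
            if m.options.include_process:
                ll += dens(vals, N[idx, BREEDING_STAGE], b[idx] / 2.0)
                i2 = idx[inner]
                q1 = (pa * pf)[i2]
                ll[inner] += dens(N[i2 + 1, 0], vals[inner], q1)
            obs = m.data.obs_chicks_f[idx]
            ok = ~np.isnan(obs)
            if m.options.include_observations and ok.any():
                ll[ok] += norm_logpdf(obs[ok], vals[ok], m.s2)
            return ll

        sidx = series
        if m.options.include_process:
            # arrival term (this value as the realised transition outcome)
            prevyr = idx[~first] - 1
            tgt = vals[~first]
            if sidx == 0:
                ll[~first] += dens(tgt, CF[prevyr], (pa * pf)[prevyr])
            elif sidx < BREEDING_STAGE:
                ll[~first] += dens(tgt, N[prevyr, sidx - 1], pa[prevyr])
            else:
                base6 = N[prevyr, BREEDING_STAGE - 1] + N[prevyr, BREEDING_STAGE]
                ll[~first] += dens(tgt, base6, pa[prevyr])
            # departure terms (this value as the binomial denominator)
            i2 = idx[inner]
            v2 = vals[inner]
            if sidx < BREEDING_STAGE - 1:
                ll[inner] += dens(N[i2 + 1, sidx + 1], v2, pa[i2])
            elif sidx == BREEDING_STAGE - 1:
                ll[inner] += dens(
                    N[i2 + 1, BREEDING_STAGE], v2 + N[i2, BREEDING_STAGE], pa[i2]
                )
            else:  # breeding stage: feeds next-year adults and this-year chicks
                ll[inner] += dens(
                    N[i2 + 1, BREEDING_STAGE], N[i2, BREEDING_STAGE - 1] + v2, pa[i2]
                )
                if self.state.J[9]:
                    cvals = (vals - m.c_mu) / m.c_sd
                    eta = self.eta_base[idx] + self.state.beta[9] * cvals
                    b_loc = expit(eta)
                else:
                    b_loc = b[idx]
                ll += dens(CF[idx], vals, b_loc / 2.0)
        # initial-state prior
        if first.any():
            if sidx == BREEDING_STAGE:
                ll[first] += norm_logpdf(vals[first], m.init6_mean, m.init6_var)
            else:
                ll[first] += norm_logpdf(
                    vals[first], m.init_pre_mean[sidx], m.init_pre_sd[sidx] ** 2
                )
        if sidx == BREEDING_STAGE and m.options.include_observations:
            obs = m.data.obs_females[idx]
            ok = ~np.isnan(obs)
            if ok.any():
                ll[ok] += norm_logpdf(obs[ok], vals[ok], m.s2)
        return ll

    def update_latent_states(self):
        m, rng = self.m, self.rng
        if not m.options.update_latents:
            return
        T = self.T
        integer = m.options.process_likelihood == "binomial"
        all_idx = np.arange(T)
        for series in (6, 5, 4, 3, 2, 1, 0):
            col = self.CF if series == 6 else self.N[:, series]
            for parity in (0, 1):
                idx = all_idx[all_idx % 2 == parity]
                cur = col[idx]
                if integer:
                    step = np.maximum(np.round(self.sc_state[idx, series]), 1)
                    prop = cur + rng.integers(-1, 2, size=idx.size) * rng.integers(
                        1, step.astype(int) + 1
                    )
                else:
                    prop = cur + rng.normal(0.0, self.sc_state[idx, series])
                valid = prop >= 0
                ll_cur = self._state_local_ll(series, idx, cur)
                ll_prop = np.full(idx.size, -np.inf)
                if valid.any():
                    ll_prop[valid] = self._state_local_ll(
                        series, idx[valid], prop[valid]
                    )
                accept = np.log(rng.random(idx.size)) < (ll_prop - ll_cur)
                if accept.any():
                    col[idx[accept]] = prop[accept]
                    if series == 5:
                        n6 = self.N[:, BREEDING_STAGE]
                        self.C = (n6 - m.c_mu) / m.c_sd
                        self.b = expit(
                            self.eta_base + self.state.J[9] * self.state.beta[9] * self.C
                        )
                if self.adapting:
                    rate = accept.mean() if idx.size else 0.0
                    self.sc_state[idx, series] *= math.exp(0.3 * (rate - 0.4))
        self._refresh_transitions()

    def update_cohorts(self):
        """Multiplicative moves along cohort diagonals of the
        pre-breeder stages.

        A cohort's members (stage s in year t, stage s+1 in year t+1,
        ...) are observed only at their endpoints — chick production
        and, five seasons later, recruitment into the breeding stage —
        so whole-cohort size is a slow mode under single-year updates.
        Scaling a full diagonal by a common factor (log-Jacobian
        ``n_cells log c``) moves it in one step.
        """
        m, rng = self.m, self.rng
        if not m.options.update_latents or m.options.process_likelihood != "normal":
            return
        if not m.options.include_process:
            return
        N, CF, fl = self.N, self.CF, self.fl
        T = self.T
        pa, pf, b = self.phi_a, self.phi_f, self.b

        def dens(x, base, p):
            mu = base * p
            return _nlp(x, mu, base * p * (1 - p) + fl)

        for start in range(-4, T - 1):
            # diagonal cells (t, s) with t - s = start, s in 0..4
            cells = [(start + s, s) for s in range(5) if 0 <= start + s < T]
            if not cells:
                continue
            c = math.exp(rng.normal(0.0, self.sc_cohort))
            logr = len(cells) * math.log(c)
            t0, s0 = cells[0]
            x0 = float(N[t0, s0])
            if t0 == 0:
                logr += _nlp(c * x0, m.init_pre_mean[s0], m.init_pre_sd[s0] ** 2) \
                    - _nlp(x0, m.init_pre_mean[s0], m.init_pre_sd[s0] ** 2)
            elif s0 == 0:
                base = float(CF[t0 - 1])
                q1 = pa[t0 - 1] * pf[t0 - 1]
                logr += dens(c * x0, base, q1) - dens(x0, base, q1)
            for (t, s), (tn, sn) in zip(cells[:-1], cells[1:]):
                xb, xt = float(N[t, s]), float(N[tn, sn])
                logr += dens(c * xt, c * xb, pa[t]) - dens(xt, xb, pa[t])
            tL, sL = cells[-1]
            if sL == 4 and tL + 1 < T:
                xb = float(N[tL, 4])
                other = float(N[tL, 5])
                tgt = float(N[tL + 1, 5])
                logr += dens(tgt, c * xb + other, pa[tL]) - dens(tgt, xb + other, pa[tL])
            ok = math.log(rng.random()) < logr
            if ok:
                for t, s in cells:
                    N[t, s] *= c
            if self.adapting:
                self._bump(("co",), ok)
        self._refresh_transitions()

    # -- one sweep -------------------------------------------------------
    def sweep(self, select: bool = True):
        self.update_survival_coefficients()
        self.update_productivity_coefficients()
        if select:
            self.update_indicators()
            self.swap_predation_terms()
        self.update_inclusion_probabilities()
        self.update_error_variances()
        self.update_rw_variance()
        self.update_imputed_predation()
        self.rescale_predation_block()
        self.flip_predation_sign()
        self.update_imputed_mass()
        self.update_latent_states()
        self.update_cohorts()

    # -- recording --------------------------------------------------------
    def record(self, store):
        s = self.state
        store["alpha_f0"].append(s.alpha[0])
        store["alpha_a0"].append(s.alpha[1])
        store["alpha_1"].append(s.alpha[2])
        store["alpha_2"].append(s.alpha[3])
        store["alpha_3"].append(s.alpha[4])
        store["I"].append(s.I.copy())
        store["p_incl_surv"].append(s.pI.copy())
        store["beta_0"].append(s.beta0)
        store["beta"].append(s.beta.copy())
        store["J"].append(s.J.copy())
        store["p_incl_prod"].append(s.pJ.copy())
        store["n6"].append(self.N[:, BREEDING_STAGE].copy())
        store["cf"].append(self.CF.copy())
        store["n_init"].append(self.N[0].copy())
        store["phi_f"].append(self.phi_f.copy())
        store["phi_a"].append(self.phi_a.copy())
        store["b"].append(self.b.copy())
        if self.m.idx_Pmiss.size:
            store["P_imputed"].append(s.P_imputed.copy())
            store["sig2_rw"].append(s.sig2_rw)
        if self.m.idx_Amiss.size:
            store["A_imputed"].append(s.A_imputed.copy())
        if self.m.idx_sf.size:
            store["Vmax_f"].append(s.Vmax_f.copy())
            store["V_f"].append(s.V_f.copy())
        if self.m.idx_sa.size:
            store["Vmax_a"].append(s.Vmax_a.copy())
            store["V_a"].append(s.V_a.copy())


class _RunningCov:
    """Running empirical covariance for Haario-style joint proposals."""

    def __init__(self, dim, warmup=300):
        self.dim = dim
        self.warmup = warmup
        self.n = 0
        self.mean = np.zeros(dim)
        self.M2 = np.zeros((dim, dim))

    def push(self, x):
        self.n += 1
        d = x - self.mean
        self.mean += d / self.n
        self.M2 += np.outer(d, x - self.mean)

    def cov(self):
        if self.n < self.warmup:
            return None
        c = self.M2 / (self.n - 1)
        return (2.38**2 / self.dim) * (c + 1e-8 * np.eye(self.dim))


def run_mcmc(
    model: StateSpaceModel,
    config: MCMCConfig,
    initial_states: list[SamplerState] | None = None,
) -> PosteriorDraws:
    """Run the Metropolis-within-Gibbs sampler.

    Chains are initialised at different points in parameter space
    (data-informed centres with per-chain jitter, random indicator
    patterns).  Proposal scales adapt during the burn-in sweeps only,
    then freeze, so the retained draws come from a fixed kernel.  Draws
    are thinned by ``config.thin`` and the first ``config.burn_in``
    retained draws are discarded.
    """
    seeds = config.chain_seeds()
    n_keep_total = config.iterations // config.thin
    adapt_until = config.burn_in * config.thin  # sweeps
    chains_store: list[dict[str, list]] = []
    from collections import defaultdict

    for c in range(config.chains):
        rng = np.random.default_rng(seeds[c])
        runner = _ChainRunner(model, rng, jitter=config.init_jitter)
        if initial_states is not None:
            runner.set_state(initial_states[c].copy())
        store = defaultdict(list)
        # let coefficients, latents and imputations settle before the
        # selection indicators start switching (burn-in only)
        select_after = min(500, adapt_until // 2)
        for it in range(1, config.iterations + 1):
            runner.sweep(select=it > select_after)
            if runner.adapting and it % 50 == 0:
                runner.adapt()
            if it >= adapt_until:
                runner.adapting = False
            if it % config.thin == 0:
                runner.record(store)
        if not np.isfinite(log_joint(model, runner.state)[0]):
            raise FloatingPointError(f"chain {c}: non-finite joint at end of run")
        chains_store.append(store)

    draws: dict[str, np.ndarray] = {}
    for name in chains_store[0]:
        stacked = np.stack(
            [np.asarray(st[name], dtype=float) for st in chains_store]
        )
        draws[name] = stacked[:, config.burn_in :]
    meta = {
        "chains": config.chains,
        "iterations": config.iterations,
        "thin": config.thin,
        "burn_in": config.burn_in,
        "seeds": seeds,
        "years": model.data.years.tolist(),
        "n_draws": n_keep_total - config.burn_in,
        "s2_counts": model.s2,
        "c_scaler": [model.c_mu, model.c_sd],
        "forced_off": sorted(model.options.forced_off),
    }
    return PosteriorDraws(draws=draws, meta=meta)
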