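"""Two-stage parameter search: evolutionary algorithm + DRAM-MCMC.

The six free parameters of the gradient mechanism (gamma_max, gamma_km,
c_max, c_km, d, e) are fitted to a reference rosette via the nine-component
score.  A generational GA performs the global search; Delayed Rejection
Adaptive Metropolis then samples locally around the optimum, treating the
score components as residuals of a sum-of-squares objective whose error
variance carries an inverse-gamma prior (hyperparameters S20, N0).

Candidate evaluations use the documented fast settings: coarse grid,
RK2 reaction substeps, seeded initialization, short horizon; the rng seed
of the initialization noise is shared by all candidates of a generation
(common random numbers) so that scores are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .domain import SimDomain, build_disk
from .params import WPGAPParams
from .profiles import LogisticParams, REPRESENTATIVE, spatial_rate_profiles
from .scoring import ScoreTarget, score
from .solver import BlowUpError, integrate
from .synth import InitSpec, RosetteTemplate, noisy_initial_condition

__all__ = ["PARAM_NAMES", "SearchSpace", "EAConfig", "MCMCConfig",
           "EvalSettings", "evaluate_candidate", "ea_search", "dram_mcmc",
           "convergence_diagnostics", "geweke_pvalue", "gelman_rubin",
           "FAILED_SCORE"]

PARAM_NAMES = ("gamma_max", "gamma_km", "c_max", "c_km", "d", "e")

#: sentinel score for candidates whose simulation blows up
FAILED_SCORE = 1e6


@dataclass(frozen=True)
class SearchSpace:
    """Bounds for the sampled parameters plus the fixed rates."""

    lower: np.ndarray
    upper: np.ndarray
    fixed: dict = dfield(default_factory=lambda: {
        "b": REPRESENTATIVE["b"], "sigma": REPRESENTATIVE["sigma"],
        "gamma_alpha": REPRESENTATIVE["gamma_alpha"],
        "c_alpha": REPRESENTATIVE["c_alpha"]})

    def __post_init__(self):
        if len(self.lower) != len(PARAM_NAMES) \
                or len(self.upper) != len(PARAM_NAMES):
            raise ValueError("bounds must cover all sampled parameters")
        if np.any(np.asarray(self.lower) <= 0) \
                or np.any(np.asarray(self.upper) <= np.asarray(self.lower)):
            raise ValueError("bounds must be positive with upper > lower")

    @classmethod
    def default(cls, span: float = 10.0) -> "SearchSpace":
        center = np.array([REPRESENTATIVE[n] for n in PARAM_NAMES])
        return cls(lower=center / span, upper=center * span)

    def clip(self, theta: np.ndarray) -> np.ndarray:
        return np.clip(theta, self.lower, self.upper)

    def contains(self, theta: np.ndarray) -> bool:
        return bool(np.all(theta >= self.lower)
                    and np.all(theta <= self.upper))


@dataclass(frozen=True)
class EvalSettings:
    """Simulation settings for one candidate evaluation."""

    r0: float = 2.0
    R: float = 4.0
    n_phi: int = 64
    n_r: int = 64
    dt: float = 0.025
    t_final: float = 20.0
    fast: bool = True              # RK2 reaction substeps
    template: RosetteTemplate = RosetteTemplate()

    def build_domain(self) -> SimDomain:
        return build_disk(R=self.R, n_phi=self.n_phi, n_r=self.n_r)


def _theta_to_setup(theta: np.ndarray, space: SearchSpace,
                    settings: EvalSettings):
    tp = dict(zip(PARAM_NAMES, theta))
    fixed = space.fixed
    params = WPGAPParams(b=fixed["b"], gamma=fixed["gamma_alpha"],
                         sigma=fixed["sigma"], c=fixed["c_alpha"],
                         d=tp["d"], e=tp["e"])
    gp = LogisticParams.from_min_max(fixed["gamma_alpha"], tp["gamma_max"],
                                     tp["gamma_km"], settings.r0)
    cp = LogisticParams.from_min_max(fixed["c_alpha"], tp["c_max"],
                                     tp["c_km"], settings.r0)
    return params, gp, cp


def _simulate_and_score(theta, target, settings, space, rng_seed, domain):
    theta = np.asarray(theta, dtype=float)
    if not space.contains(theta):
        return None
    dom = domain or settings.build_domain()
    params, gp, cp = _theta_to_setup(theta, space, settings)
    gam, cc, _ = spatial_rate_profiles(gp, cp, dom)
    spec = InitSpec(rng_seed=rng_seed, seed_pattern="rosette",
                    template=settings.template)
    state0 = noisy_initial_condition(params, dom, spec)
    try:
        traj = integrate(state0, params, dom, dt=settings.dt,
                         t_final=settings.t_final,
                         snapshot_every=settings.t_final,
                         profiles={"gamma": gam, "c": cc},
                         fast=settings.fast, seed=rng_seed)
    except BlowUpError:
        return None
    return score(traj.final.u, dom, target)


def evaluate_candidate(theta: np.ndarray, target: ScoreTarget,
                       settings: EvalSettings, space: SearchSpace,
                       rng_seed: int, domain: SimDomain | None = None
                       ) -> float:
    """Score one parameter vector against the target rosette.

    Deterministic in (theta, rng_seed).  A blow-up returns the worst-score
    sentinel rather than raising, so population search can continue.
    """
    br = _simulate_and_score(theta, target, settings, space, rng_seed,
                             domain)
    return FAILED_SCORE if br is None else br.aggregate


def sum_of_squares(theta: np.ndarray, target: ScoreTarget,
                   settings: EvalSettings, space: SearchSpace,
                   rng_seed: int, domain: SimDomain | None = None) -> float:
    """SS objective for DRAM: the 9 score components as squared residuals."""
    br = _simulate_and_score(theta, target, settings, space, rng_seed,
                             domain)
    if br is None:
        return FAILED_SCORE
    return float(br.mean_component ** 2 + np.sum(br.octant_components ** 2))


# --------------------------------------------------------------------------
# evolutionary algorithm
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EAConfig:
    population: int = 100
    generations: int = 100
    mutation_rate: float = 0.3
    crossover_rate: float = 0.5
    tournament_size: int = 3
    mutation_sigma: float = 0.15   # log-space std of multiplicative steps
    # optional geometric annealing of the mutation width across
    # generations (coarse search early, refinement late)
    mutation_sigma_final: float | None = None
    rng_seed: int = 0
    # optional localized initialization (scaled-down searches start near a
    # known working set); each gene ~ center * U(1/span, span)
    init_center: tuple | None = None
    init_span: float = 2.0
    # fixed initialization-noise seed for every evaluation (common random
    # numbers); None draws a fresh shared seed per generation
    eval_seed: int | None = None

    def __post_init__(self):
        if not (0 <= self.mutation_rate <= 1
                and 0 <= self.crossover_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")


@dataclass
class EAResult:
    population: np.ndarray      # (pop, dim), final generation, sorted
    scores: np.ndarray          # sorted ascending (best first)
    best_theta: np.ndarray
    best_score: float
    history: pd.DataFrame       # generation, best, median


def ea_search(config: EAConfig, space: SearchSpace, target: ScoreTarget,
              settings: EvalSettings,
              evaluator: Callable | None = None) -> EAResult:
    """Generational GA with tournament selection, uniform crossover,
    Gaussian mutation and single-slot elitism.

    ``evaluator(theta, rng_seed)`` may override the default simulation
    evaluation (used for cheap objectives in calibration tests).
    """
    rng = np.random.default_rng(config.rng_seed)
    dim = len(PARAM_NAMES)
    dom = settings.build_domain()
    if evaluator is None:
        def evaluator(th, seed):  # noqa: F811 - default simulation route
            return evaluate_candidate(th, target, settings, space, seed,
                                      domain=dom)

    if config.init_center is not None:
        center = np.asarray(config.init_center, dtype=float)
        factors = rng.uniform(1.0 / config.init_span, config.init_span,
                              size=(config.population, dim))
        pop = space.clip(center * factors)
    else:
        pop = rng.uniform(space.lower, space.upper,
                          size=(config.population, dim))
    hist = []
    best_theta, best_score = None, np.inf

    for gen in range(config.generations):
        # one seed per generation, shared by all candidates
        sim_seed = config.eval_seed if config.eval_seed is not None \
            else int(rng.integers(2 ** 31 - 1))
        scores = np.array([evaluator(ind, sim_seed) for ind in pop])
        order = np.argsort(scores)
        if not np.isfinite(scores[order[0]]):
            raise RuntimeError(f"all candidates failed in generation {gen}")
        if scores[order[0]] < best_score:
            best_score = float(scores[order[0]])
            best_theta = pop[order[0]].copy()
        hist.append({"generation": gen, "best": best_score,
                     "gen_best": float(scores[order[0]]),
                     "median": float(np.median(scores))})

        # tournament selection
        idx = rng.integers(0, config.population,
                           size=(config.population, config.tournament_size))
        winners = idx[np.arange(config.population),
                      np.argmin(scores[idx], axis=1)]
        children = pop[winners].copy()
        # arithmetic blend crossover on consecutive pairs
        for i in range(0, config.population - 1, 2):
            if rng.random() < config.crossover_rate:
                alpha = rng.random(dim)
                p1, p2 = children[i].copy(), children[i + 1].copy()
                children[i] = alpha * p1 + (1 - alpha) * p2
                children[i + 1] = alpha * p2 + (1 - alpha) * p1
        # Gaussian mutation in log space (rates are positive and span
        # decades, so steps are multiplicative), width optionally annealed
        if config.mutation_sigma_final is not None \
                and config.generations > 1:
            frac = gen / (config.generations - 1)
            sigma = config.mutation_sigma \
                * (config.mutation_sigma_final
                   / config.mutation_sigma) ** frac
        else:
            sigma = config.mutation_sigma
        mutate = rng.random(config.population) < config.mutation_rate
        factors = np.exp(rng.normal(0.0, sigma,
                                    size=(config.population, dim)))
        children[mutate] = space.clip(children[mutate] * factors[mutate])
        children[0] = best_theta  # elitism
        pop = children

    final_seed = config.eval_seed if config.eval_seed is not None \
        else int(rng.integers(2 ** 31 - 1))
    scores = np.array([evaluator(ind, final_seed) for ind in pop])
    order = np.argsort(scores)
    if scores[order[0]] < best_score:
        best_score = float(scores[order[0]])
        best_theta = pop[order[0]].copy()
    return EAResult(pop[order], scores[order], best_theta, best_score,
                    pd.DataFrame(hist))


# --------------------------------------------------------------------------
# DRAM-MCMC
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MCMCConfig:
    n_steps: int = 10000
    burn_in: int | None = None     # default: all but the last 5000 steps
    S20: float = 0.015             # prior mean of the error variance
    N0: float = 0.015              # prior weight (pseudo-observations)
    n_obs: int = 9                 # residual count of the score objective
    adapt_interval: int = 100
    dr_scale: float = 5.0          # stage-2 proposal shrink factor
    init_scale: float = 0.05       # initial proposal std as fraction of theta0
    rng_seed: int = 0

    def __post_init__(self):
        if self.burn_in is not None and self.burn_in >= self.n_steps:
            raise ValueError("chain length must exceed burn-in")

    def effective_burn_in(self) -> int:
        if self.burn_in is not None:
            return self.burn_in
        return max(self.n_steps - 5000, 0)


@dataclass
class MCMCResult:
    chain: np.ndarray          # (n_steps, dim) including burn-in
    ss_chain: np.ndarray       # objective value per step
    s2_chain: np.ndarray       # sampled error variance per step
    acceptance_rate: float
    burn_in: int

    @property
    def samples(self) -> np.ndarray:
        return self.chain[self.burn_in:]

    def summary(self, names: Sequence[str] = PARAM_NAMES) -> pd.DataFrame:
        s = self.samples
        return pd.DataFrame({"parameter": list(names),
                             "mean": s.mean(axis=0),
                             "std": s.std(axis=0)})

    def spearman(self) -> np.ndarray:
        from scipy.stats import spearmanr
        rho = spearmanr(self.samples).statistic
        return np.atleast_2d(rho)


def _mvn_logpdf(x, mean, cov_chol):
    """Log-density of N(mean, LL^T) at x, up to the dimension constant."""
    from scipy.linalg import solve_triangular
    sol = solve_triangular(cov_chol, x - mean, lower=True)
    return -0.5 * sol @ sol - np.log(np.diag(cov_chol)).sum()


def dram_mcmc(config: MCMCConfig, theta0: np.ndarray, space: SearchSpace,
              objective: Callable[[np.ndarray], float]) -> MCMCResult:
    """Delayed Rejection Adaptive Metropolis on a sum-of-squares objective.

    ``objective(theta)`` returns SS(theta) >= 0.  The likelihood is
    exp(-SS/(2 s2)) with the error variance s2 Gibbs-sampled from its
    conjugate inverse-gamma posterior (prior IG(N0/2, N0*S20/2), data
    weight ``n_obs``).  Proposals are Gaussian; the covariance adapts to
    the chain history every ``adapt_interval`` steps, and each rejection
    triggers one delayed-rejection retry with a shrunk proposal.
    """
    rng = np.random.default_rng(config.rng_seed)
    theta0 = np.asarray(theta0, dtype=float)
    dim = theta0.size
    ss_x = float(objective(theta0))
    if not np.isfinite(ss_x):
        raise ValueError("theta0 has non-finite objective")

    s2 = config.S20
    C = np.diag((config.init_scale * np.abs(theta0)) ** 2)
    chol = np.linalg.cholesky(C)
    sd = 2.4 ** 2 / dim
    eps = 1e-12

    chain = np.empty((config.n_steps, dim))
    ss_chain = np.empty(config.n_steps)
    s2_chain = np.empty(config.n_steps)
    x = theta0.copy()
    n_accept = 0

    def log_post(ss):
        return -ss / (2.0 * s2)

    for k in range(config.n_steps):
        y1 = x + chol @ rng.normal(size=dim)
        in1 = space.contains(y1)
        ss_y1 = float(objective(y1)) if in1 else np.inf
        log_a1 = log_post(ss_y1) - log_post(ss_x)
        if np.log(rng.random()) < log_a1:
            x, ss_x = y1, ss_y1
            n_accept += 1
        else:
            # delayed-rejection stage with shrunk proposal
            chol2 = chol / config.dr_scale
            y2 = x + chol2 @ rng.normal(size=dim)
            in2 = space.contains(y2)
            ss_y2 = float(objective(y2)) if in2 else np.inf
            if np.isfinite(ss_y2):
                # alpha1 evaluated at (y2 -> y1)
                log_a1_y2 = log_post(ss_y1) - log_post(ss_y2)
                num_reject = np.log1p(-min(1.0, np.exp(min(log_a1_y2, 0.0)))) \
                    if log_a1_y2 < 0 else -np.inf
                den_reject = np.log1p(-min(1.0, np.exp(min(log_a1, 0.0)))) \
                    if log_a1 < 0 else -np.inf
                # q1(y2, y1) / q1(x, y1) under the stage-1 Gaussian
                lq_num = _mvn_logpdf(y1, y2, chol)
                lq_den = _mvn_logpdf(y1, x, chol)
                log_a2 = (log_post(ss_y2) - log_post(ss_x)
                          + lq_num - lq_den + num_reject - den_reject)
                if np.log(rng.random()) < log_a2:
                    x, ss_x = y2, ss_y2
                    n_accept += 1
        # Gibbs update of the error variance
        shape = 0.5 * (config.N0 + config.n_obs)
        scale = 0.5 * (config.N0 * config.S20 + ss_x)
        s2 = scale / rng.gamma(shape)
        chain[k] = x
        ss_chain[k] = ss_x
        s2_chain[k] = s2
        # covariance adaptation
        if (k + 1) % config.adapt_interval == 0 and k > dim:
            hist_cov = np.cov(chain[:k + 1].T)
            C = sd * (hist_cov + eps * np.eye(dim))
            try:
                chol = np.linalg.cholesky(C)
            except np.linalg.LinAlgError:
                chol = np.linalg.cholesky(C + 1e-10 * np.eye(dim))

    rate = n_accept / config.n_steps
    if not 0.05 <= rate <= 0.8:
        import warnings
        warnings.warn(f"MCMC acceptance rate {rate:.1%} outside [5%, 80%]; "
                      "consider adjusting the initial proposal scale",
                      stacklevel=2)
    return MCMCResult(chain, ss_chain, s2_chain, rate,
                      config.effective_burn_in())


# --------------------------------------------------------------------------
# convergence diagnostics
# --------------------------------------------------------------------------

def _spectral_var(x: np.ndarray) -> float:
    """Spectral density at frequency zero (Bartlett-windowed autocov)."""
    n = x.size
    x = x - x.mean()
    max_lag = min(n - 1, int(np.sqrt(n)) * 2)
    acov = np.correlate(x, x, mode="full")[n - 1:n + max_lag] / n
    w = 1.0 - np.arange(max_lag + 1) / (max_lag + 1)
    return float(acov[0] + 2.0 * np.sum(w[1:] * acov[1:]))


def geweke_pvalue(chain_1d: np.ndarray, first: float = 0.1,
                  last: float = 0.5) -> float:
    """Geweke stationarity z-test: first 10% vs last 50% of the chain."""
    from scipy.stats import norm
    n = chain_1d.size
    if n < 100:
        raise ValueError("chain too short for the Geweke diagnostic")
    a = chain_1d[:int(first * n)]
    b = chain_1d[int((1 - last) * n):]
    var = _spectral_var(a) / a.size + _spectral_var(b) / b.size
    if var <= 0:
        return 1.0
    z = (a.mean() - b.mean()) / np.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


def gelman_rubin(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor R-hat (one parameter).

    ``chains``: (m, n) array of m chains.  Each chain is split in half,
    doubling m, before the standard between/within variance ratio.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need at least two chains")
    n = chains.shape[1] // 2
    if n < 50:
        raise ValueError("chain too short for R-hat")
    halves = np.concatenate([chains[:, :n], chains[:, n:2 * n]], axis=0)
    m = halves.shape[0]
    means = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    var_hat = (n - 1) / n * W + B / n
    if W <= 0:
        return 1.0
    return float(np.sqrt(var_hat / W))


def convergence_diagnostics(chains: np.ndarray,
                            names: Sequence[str] = PARAM_NAMES
                            ) -> pd.DataFrame:
    """Geweke p (per chain, averaged) and split R-hat per parameter.

    ``chains``: (m, n, dim) post-burn-in samples from m >= 2 chains.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 3:
        raise ValueError("expected (m_chains, n_steps, dim)")
    rows = []
    for j, name in enumerate(names[:chains.shape[2]]):
        pvals = [geweke_pvalue(c[:, j]) for c in chains]
        rows.append({"parameter": name,
                     "geweke_p": float(np.mean(pvals)),
                     "rhat": gelman_rubin(chains[:, :, j])})
    return pd.DataFrame(rows)


__all__.append("sum_of_squares")
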