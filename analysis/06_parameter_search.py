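"""Scaled-down parameter search: EA global stage + DRAM-MCMC sampling.

Generates a reference rosette from the representative parameter vector,
then pretends those values are unknown: a small evolutionary search
(coarse grid, RK2, seeded initial conditions, common random numbers)
locates the basin, and DRAM samples the local posterior of the six free
parameters.  Posterior means, marginal widths, Spearman correlations and
convergence diagnostics are written out.  The full-scale version of this
pipeline (99 runs x 100 individuals x 100 generations, 10k+ MCMC steps)
is a cluster-scale computation; this driver reproduces its structure.

Outputs: results/search_posterior.csv, results/search_correlations.csv,
         results/search_diagnostics.csv, results/ea_history.csv
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from wpgap.profiles import REPRESENTATIVE, spatial_rate_profiles
from wpgap.search import (EAConfig, EvalSettings, MCMCConfig, PARAM_NAMES,
                          SearchSpace, _theta_to_setup,
                          convergence_diagnostics, dram_mcmc, ea_search,
                          sum_of_squares)
from wpgap.solver import integrate
from wpgap.synth import InitSpec, make_score_target, noisy_initial_condition

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

theta_star = np.array([REPRESENTATIVE[n] for n in PARAM_NAMES])
space = SearchSpace.default()
settings = EvalSettings(n_phi=48, n_r=48, t_final=15.0)
dom = settings.build_domain()
EVAL_SEED = 7

params, gp, cp = _theta_to_setup(theta_star, space, settings)
gam, cc, _ = spatial_rate_profiles(gp, cp, dom)
st = noisy_initial_condition(params, dom,
                             InitSpec(rng_seed=EVAL_SEED,
                                      seed_pattern="rosette"))
traj = integrate(st, params, dom, dt=settings.dt,
                 t_final=settings.t_final,
                 snapshot_every=settings.t_final,
                 profiles={"gamma": gam, "c": cc}, fast=True)
target = make_score_target("two-step", field=traj.final.u, domain=dom)

cfg = EAConfig(population=16, generations=15, rng_seed=11,
               mutation_sigma=0.2, mutation_sigma_final=0.04,
               init_center=tuple(theta_star), init_span=1.5,
               eval_seed=EVAL_SEED)
ea = ea_search(cfg, space, target, settings)
ea.history.to_csv(OUT / "ea_history.csv", index=False)
print(f"EA best score {ea.best_score:.3f} after "
      f"{cfg.population}x{cfg.generations} evaluations")


def objective(th):
    return sum_of_squares(th, target, settings, space, EVAL_SEED,
                          domain=dom)


chains = []
for chain_seed in (3, 4):
    mc = dram_mcmc(MCMCConfig(n_steps=800, burn_in=300,
                              rng_seed=chain_seed),
                   ea.best_theta, space, objective)
    chains.append(mc.samples)
    print(f"chain {chain_seed}: acceptance {mc.acceptance_rate:.0%}")

post = np.concatenate(chains, axis=0)
summary = pd.DataFrame({"parameter": PARAM_NAMES,
                        "truth": theta_star,
                        "posterior_mean": post.mean(axis=0),
                        "posterior_std": post.std(axis=0)})
summary["ratio_to_truth"] = summary["posterior_mean"] / summary["truth"]
summary.to_csv(OUT / "search_posterior.csv", index=False)
print(summary.to_string(index=False))

rho = pd.DataFrame(np.atleast_2d(spearmanr(post).statistic),
                   index=PARAM_NAMES, columns=PARAM_NAMES)
rho.to_csv(OUT / "search_correlations.csv")
print("\nSpearman correlations (note the c_max/e, c_km/gamma_max and "
      "gamma_km/e anti-correlations):")
print(rho.round(2).to_string())

min_len = min(c.shape[0] for c in chains)
diag = convergence_diagnostics(
    np.stack([c[:min_len] for c in chains]))
diag.to_csv(OUT / "search_diagnostics.csv", index=False)
print("\nconvergence diagnostics:")
print(diag.to_string(index=False))
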