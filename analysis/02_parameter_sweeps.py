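"""Pattern regimes of the uniform WPGAP circuit.

Sweeps each kinetic rate from the baseline set and labels the final
pattern (low/high homogeneous, spots, maze, holes); then sweeps constant
(gamma, c) pairs on a grid and overlays the representative gradient
mechanism's parametric (gamma(r), c(r)) curve, showing why patterning is
confined to a spatial zone near the disk edge.

Outputs: results/sweep_1d.csv, results/sweep_2d.csv,
         results/gamma_c_curve.csv
"""

from pathlib import Path

import numpy as np
import pandas as pd

from wpgap.domain import build_rectangle
from wpgap.experiments import (representative_rate_curve,
                               run_param_sweep_1d, run_param_sweep_2d)
from wpgap.params import baseline_params

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

base = baseline_params()
dom = build_rectangle(Lx=5.0, Ly=5.0, n_x=64, n_y=64)

sweeps = {
    "b": [0.25, 1.0, 4.0, 8.0],
    "gamma": [2.0, 12.0, 20.0, 30.0, 40.0, 60.0],
    "sigma": [25.0, 15.0, 10.0, 3.0, 0.2],
    "c": [0.01, 0.05, 0.08, 0.12],
    "d": [3.0, 10.0, 30.0],
    "e": [3.0, 10.0, 30.0],
}
frames = [run_param_sweep_1d(name, vals, base, dom, rng_seed=0, dt=0.01)
          for name, vals in sweeps.items()]
df1 = pd.concat(frames, ignore_index=True)
df1.to_csv(OUT / "sweep_1d.csv", index=False)
print(df1.to_string(index=False))

gammas = np.array([2.0, 6.0, 10.0, 20.0, 40.0])
cs = np.array([0.005, 0.02, 0.05, 0.1])
df2 = run_param_sweep_2d(cs, gammas, base, dom, rng_seed=0, dt=0.01)
df2.to_csv(OUT / "sweep_2d.csv", index=False)
print("\ntwo-parameter sweep:")
print(df2.pivot(index="c", columns="gamma", values="regime").to_string())

curve = representative_rate_curve()
curve.to_csv(OUT / "gamma_c_curve.csv", index=False)
r_star = curve.loc[(curve["gamma"] / curve["c"]).idxmax(), "r"]
print(f"\nrepresentative gamma(r)/c(r) ratio peaks at r = {r_star:.2f} um "
      "(just outside the 2.0 um disk edge)")
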