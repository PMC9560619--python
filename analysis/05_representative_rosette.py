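"""Rosette formation through gradients: the representative parameter set.

Simulates the gradient mechanism (logistic gamma(r) and c(r) centered on
a 2 um disk, representative posterior-mean kinetics) from noise-only
initial conditions, quantifies the emergent rosette, and scores it
against a reference rosette produced by the two-step model.

Outputs: results/representative_rosette.csv,
         results/representative_radial_profiles.csv,
         results/score_target.csv
"""

from pathlib import Path

import numpy as np
import pandas as pd

from wpgap.experiments import run_representative, run_two_step
from wpgap.scoring import octant_radial_std, radial_profile, score
from wpgap.spots import classify_rosette, label_spots
from wpgap.synth import make_score_target

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

# reference rosette from the two-step (gamma-ring) model
two_step = run_two_step("gamma", rng_seed=0)
target = make_score_target("two-step", field=two_step.final.u,
                           domain=two_step.domain)
target.to_csv(OUT / "score_target.csv")

rows = []
for seed in (0, 1, 2, 3):
    traj = run_representative(rng_seed=seed)
    ss = label_spots(traj.final.u, traj.domain)
    br = score(traj.final.u, traj.domain, target)
    rows.append({"seed": seed, "n_spots": ss.count,
                 "outcome": classify_rosette(ss, ring_radius=2.3),
                 "mean_centroid_r":
                     float(ss.table["centroid_r"].mean()),
                 "score": br.aggregate})
    if seed == 0:
        edges = target.bin_edges
        centers = (edges[:-1] + edges[1:]) / 2
        prof = pd.DataFrame({
            "r": centers,
            "radial_mean": radial_profile(traj.final.u, traj.domain,
                                          edges),
            "radial_std_octant_mean":
                octant_radial_std(traj.final.u, traj.domain,
                                  edges).mean(axis=0),
            "target_mean": target.mean, "target_std": target.std})
        prof.to_csv(OUT / "representative_radial_profiles.csv",
                    index=False)

df = pd.DataFrame(rows)
df.to_csv(OUT / "representative_rosette.csv", index=False)
print(df.to_string(index=False))
print("\nspots sit on a ring just outside the 2 um disk edge; lower "
      "score = closer match to the two-step reference rosette")
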