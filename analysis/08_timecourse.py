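"""Rosette formation dynamics of the representative parameter set.

Four replicate simulations with 1 s snapshots: rosettes mostly organize
within ~20 s and the spot count is stable well before 60 s.

Outputs: results/timecourse.csv
"""

from pathlib import Path

import pandas as pd

from wpgap.experiments import run_timecourse

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

df = run_timecourse(seeds=(1, 2, 3, 4), t_final=60.0)
df.drop(columns="counts").to_csv(OUT / "timecourse.csv", index=False)
print(df.drop(columns="counts").to_string(index=False))
print("\nall replicates stabilize their spot count by "
      f"t = {df['stabilization_time'].max():.0f} s")
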