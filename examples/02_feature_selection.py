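"""Run the four forest-based selectors once on a small simulation.

Each method sees the same 120-sample, 100-predictor dataset in which
only V1-V30 carry outcome signal.  Printed per method: the selected set
size, how many selections are true positives (V1-V30), and method
diagnostics (Boruta runs, RFE error trajectory, permutation p-values).
"""

import numpy as np

from forestpower import (ForestSpec, SimulationConfig, boruta_select,
                         permutation_select, rfe_select, simulate_uniform)

ds = simulate_uniform(SimulationConfig(n_obs=120, p_total=100, seed=7))
y = ds.y.to_numpy()
spec = ForestSpec(task="regression", n_trees=200, seed=0)


def report(out):
    sel = sorted(int(v[1:]) for v in out.selected)
    tp = sum(1 for v in sel if v <= 30)
    print(f"{out.method:15s} selected {len(sel):3d}  true positives {tp:2d}  "
          f"false positives {len(sel) - tp}")
    return sel


print("method          n_selected / TP / FP")
b = boruta_select(ds.X, y, spec=spec, alpha=0.05, max_runs=50)
report(b)
print(f"                ({b.diagnostics['runs']} Boruta runs, "
      f"{b.diagnostics['n_tentative']} left tentative)")

r = rfe_select(ds.X, y, spec=spec, drop_fraction=0.2, se_rule=1.0)
report(r)
sizes, losses = r.diagnostics["sizes"], r.diagnostics["losses"]
i_min = int(np.argmin(losses))
print(f"                (error minimum {losses[i_min]:.3f} at subset size "
      f"{sizes[i_min]}; 1-SE rule keeps {len(r.selected)})")

# BH correction needs fine-grained p-values: with m variables the
# smallest adjusted p is roughly (1/(n_perm+1)) * m / n_selected
p_raw = permutation_select(ds.X, y, spec=spec, n_perm=400, alpha=0.05,
                           correction="none")
report(p_raw)
p_bh = permutation_select(ds.X, y, spec=spec, n_perm=400, alpha=0.05,
                          correction="benjamini_hochberg")
report(p_bh)
print(f"                (BH selection is a subset of raw: "
      f"{set(p_bh.selected) <= set(p_raw.selected)})")
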