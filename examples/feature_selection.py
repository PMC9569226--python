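"""Multiview feature selection with primary/auxiliary view weighting.

Generates the default synthetic benchmark (3 views, 10 planted
class-discriminative edges per view, per-feature signal-to-noise 1.0) and
runs the view-weighted L1 selection: each view in turn is the lightly
penalised primary view (weight a1 = 0.2) while the others are auxiliary
(a2 = 0.8).  The recovered supports are scored against the planted truth.
"""

import numpy as np

from mvconn.selection import run_per_view_selection
from mvconn.synth import SynthConfig, generate_multiview

data, truth = generate_multiview(SynthConfig(seed=0))
print(f"dataset: {data.n_views} views, widths {data.view_widths}, "
      f"N = {data.n_subjects}")

reduced, result = run_per_view_selection(data, a1=0.2, lam=1.0)
for v, (sup, planted) in enumerate(zip(result.support_per_view,
                                       truth.planted_per_view)):
    hits = len(set(sup.tolist()) & set(planted.tolist()))
    print(f"view {v}: kept {len(sup)} of {data.view_widths[v]} features, "
          f"{hits}/{len(planted)} planted edges recovered")
print(f"mean Jaccard overlap with the planted supports: "
      f"{result.jaccard(truth.planted_per_view):.3f}")

model = result.models[0]
drops = np.diff(model.objective_trace)
print(f"solver: {model.iters_run} proximal iterations, objective "
      f"{model.objective_trace[0]:.4f} -> {model.objective_trace[-1]:.4f} "
      f"(monotone: {bool(np.all(drops <= 1e-10))})")
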