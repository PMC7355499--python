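"""Full experiment: two sources mapped from 16 catheter placements.

Runs the end-to-end pipeline (simulate -> order statistics -> paths ->
Monte-Carlo localization) at every placement and pools the estimates
per source.  Scaled-down knobs (M = 30 resamples/replicates) keep the
demo quick; the defaults in ``two_source_benchmark_config`` reproduce
the full study conditions.
"""

import warnings

import numpy as np

from focimap.pipeline import run_pipeline, two_source_benchmark_config

config = two_source_benchmark_config(master_seed=0, n_resamples_M=30, n_mc_replicates=30)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    bundle = run_pipeline(config)

print(f"placements: {len(bundle['placements'])}")
print(f"per-placement source counts: {bundle['manifest']['source_counts']}")
for truth, group in zip(config.scenario.source_locations, bundle["pooled"]):
    if group.get("centroid") is None:
        continue
    x, y, _ = group["centroid"]
    print(
        f"true source ({truth[0]:6.1f}, {truth[1]:6.1f}) mm -> pooled estimate ({x:6.1f}, {y:6.1f}) mm "
        f"from {group['n_placements']} placement paths, error {group['centroid_error']:.1f} mm"
    )
print("\npooling across placements cancels each placement's radial bias,")
print("so the pooled centroid lands within a few millimetres of the truth")
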