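"""Simulate voxel patterns with a planted cross-repetition correlation
and show that the similarity pipeline recovers it.

Each subject's repetition-2 pattern is built as rho * standardized
repetition-1 plus scaled independent noise, so the expected Pearson
correlation between repetitions equals the planted rho.
"""

import numpy as np

from pattlearn import SimulationConfig, simulate_patterns, similarity_table

cfg = SimulationConfig(
    n_subjects=200, n_rois=1, n_voxels=100,
    rho_trained=(0.5, 0.5), rho_control=(0.1, 0.1),
    coupled_rois=(), include_item_groups=False, seed=11,
)
patterns, truth = simulate_patterns(cfg)
table = similarity_table(patterns)

for cond, planted in (("trained", 0.5), ("control", 0.1)):
    rs = table.frame.loc[table.frame["condition"] == cond, "r"]
    se = rs.std(ddof=1) / np.sqrt(len(rs))
    print(f"{cond:>8}: planted rho = {planted:.2f}, "
          f"mean observed r = {rs.mean():.3f} +/- {se:.3f} (SE over subjects)")

# The mean observed correlation sits within sampling error of the planted
# value; individual subjects scatter with sd ~ (1 - rho^2)/sqrt(n_voxels).
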