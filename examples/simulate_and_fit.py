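"""Simulate a 4SU labeling course and recover half-lives by intron normalization.

Generates a 500-gene approach-to-equilibrium experiment (multinomial
sampling at 2e6 reads per time point), runs the intron-normalized pipeline,
and compares estimated half-lives with the generating truth.
"""

import numpy as np
from scipy.stats import spearmanr

from druid import ExperimentDesign, make_truth, run_from_matrices, simulate_labeling_experiment

truth = make_truth(n_genes=500, n_introns=300, seed=1, misbehaving_fraction=0.4)
sim = simulate_labeling_experiment(truth, time_points=(1, 2, 4, 8, 12, 24))

result = run_from_matrices(ExperimentDesign(seed=1), sim.exon_counts, sim.intron_coverage)
print("stage counts:", result.stage_counts)

table = result.half_lives[result.half_lives.converged]
joined = table.join(truth.truth_table(), rsuffix="_true")
rho = spearmanr(joined.half_life_hours, joined.true_half_life_hours).statistic
err = (np.abs(joined.half_life_hours - joined.true_half_life_hours)
       / joined.true_half_life_hours)

print(joined[["half_life_hours", "true_half_life_hours"]].head(5).round(3))
print(f"Spearman(estimated, true) = {rho:.4f}; median |rel. error| = {err.median():.1%}")
# rho near 1 and errors of a few percent: compositional sampling noise is the
# only error source, and the summed intron factor absorbs it well.
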