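"""Repeated-measures statistics on a synthetic oval-density cohort.

Simulates a cohort with the planted monotone arousal gradient, runs the
pipeline, and prints the omnibus test (normality-screened choice between
GG-corrected RM-ANOVA and Friedman) plus the Bonferroni post-hoc pairs
that reach significance — the gradient concentrates them in
extreme-vs-extreme density contrasts.
"""

import logging
from itertools import combinations

from crowdeda import PipelineConfig, run_pipeline, simulate_study

logging.disable(logging.INFO)

cohort = simulate_study("study2", n_subjects=12, seed=21, fs=8.0,
                        duration_s=90.0)
config = PipelineConfig(fs=8.0, decompose_fs=2.0, baseline_label=None,
                        edasymp_nperseg=64)
result = run_pipeline(cohort.recordings, cohort.markers, config)

rep = result.reports["mean_scl"]
df2 = f", {rep.df2:.2f}" if rep.df2 else ""
print(f"mean_scl omnibus: {rep.test} statistic={rep.statistic:.2f} "
      f"df=({rep.df1:.2f}{df2}) p={rep.p:.2e}")
if rep.epsilon is not None:
    print(f"Greenhouse-Geisser epsilon = {rep.epsilon:.3f}")
print("significant Bonferroni pairs (p < .05):")
for a, b in combinations(rep.posthoc.index, 2):
    p = rep.posthoc.loc[a, b]
    if p < 0.05:
        print(f"  {a:>5} vs {b:<5} p = {p:.4f}")
print("-> the planted SCL gradient is detected; pairwise significance "
      "sits mostly between the sparsest and densest conditions.")
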