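"""Measure the published system's diagnostic performance on a synthetic
cohort: the per-cutoff performance table and the rank-based AUC.
"""

from eplscore import CohortConfig, auc_rank, generate_group_conditional, performance_table, published_system, score_cohort
from eplscore.evaluation import render_performance_table

system, risk_table = published_system()
cohort = generate_group_conditional(CohortConfig(n=20_000, seed=3))
scores = score_cohort(cohort, system)
outcomes = cohort["outcome"].to_numpy()

rows = performance_table(scores, outcomes, risk_table)
print(render_performance_table(rows))
print(f"\nAUC (Mann-Whitney): {auc_rank(scores, outcomes):.3f}")

# Each row treats "score >= cutoff" as a positive prediction of early
# loss. Sensitivity falls and specificity rises with the cutoff; the
# dashes mark metrics whose denominator is empty at extreme cutoffs.
# The AUC here reflects the synthetic cohort's independence assumptions,
# not the real study population.
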