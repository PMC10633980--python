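"""Individual-level replication with a weighted genetic risk score.

Simulates a 50,000-participant cohort whose incident-event hazard increases
by a true factor 1.14 per unit of the taxon's wt-GRS, excludes prevalent
cases, and fits a covariate-adjusted Cox proportional hazards model with a
Schoenfeld proportional-hazards check.
"""
from gutmr import (SimulationConfig, compute_wtgrs, exclude_prevalent, fit_ph,
                   simulate_cohort)

weights = {"rs101": 0.15, "rs102": 0.20}  # instrument effect sizes from the exposure GWAS
cfg = SimulationConfig(cohort_n=50_000, true_hr=1.14, prevalent_frac=0.03, seed=9)

cohort = simulate_cohort(cfg, weights)
n_before = len(cohort)
cohort = exclude_prevalent(cohort)
print(f"{n_before - len(cohort)} prevalent cases excluded; {len(cohort)} analyzed")

scores = compute_wtgrs(cohort, weights)
assoc = fit_ph(cohort, scores,
               adjust=("age", "sex", "batch", "center", "pc1", "pc2", "pc3", "pc4"))

print(f"incident events: {assoc.n_events}")
print(f"HR per wt-GRS unit = {assoc.hr:.3f} "
      f"(95% CI {assoc.ci_low:.3f}-{assoc.ci_high:.3f}, p = {assoc.pvalue:.4f})")
print(f"Schoenfeld proportional-hazards p = {assoc.ph_test_p:.3f}")
print("\nAn HR above 1 replicates the summary-level MR finding at the")
print("individual level; a non-significant Schoenfeld p supports the")
print("proportional-hazards assumption.")
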