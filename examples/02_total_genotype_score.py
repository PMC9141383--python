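"""Score a simulated cohort with the additive total genotype score (TGS).

Simulates athletes and non-athletes at the packaged genotype frequencies,
scores both groups under the data-led scheme and compares them: mean/SD,
extreme-quartile membership and ROC discrimination.
"""

from tgsmdr import (
    builtin_scheme,
    chi2_contingency,
    published_study_spec,
    quartile_membership,
    roc_auc,
    score_cohort,
    simulate_cohort,
    summarize_tgs,
    t_test_ind,
)

records = simulate_cohort(published_study_spec(seed=1))
scheme = builtin_scheme("data_led")
results = score_cohort(records, scheme)

athletes = [r for r in results if r.group == "athlete"]
non_athletes = [r for r in results if r.group == "non_athlete"]

for name, group in (("athletes", athletes), ("non-athletes", non_athletes)):
    s = summarize_tgs(group)
    print(f"{name}: n={s.n}, mean TGS {s.mean:.1f} (SD {s.sd:.1f}), "
          f"kurtosis {s.kurtosis:.3f} (SE {s.kurtosis_se:.3f})")

a = [r.tgs for r in athletes]
n = [r.tgs for r in non_athletes]
t = t_test_ind(a, n)
qt = quartile_membership(athletes, non_athletes)
chi = chi2_contingency(qt.counts)
roc = roc_auc(a, n)

print(f"t-test athletes vs non-athletes: t={t['t']:.2f}, p={t['p']:.3f}")
print(f"extreme-quartile table {qt.counts.tolist()}: chi2 p={chi.p:.3f}")
print(f"ROC AUC {roc.auc:.3f} (95% CI {roc.ci_lower:.3f}-{roc.ci_upper:.3f})")
print()
print("Reading: an AUC near 0.5 means the seven-component score cannot")
print("distinguish simulated athletes from non-athletes at these frequencies.")
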