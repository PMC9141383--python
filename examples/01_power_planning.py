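"""A priori sample-size planning for case-control genotype comparisons.

A Pearson chi-square test's power depends on Cohen's effect size
w = sqrt(chi2/N): we solve for the smallest N whose noncentral chi-square
exceedance probability reaches the target power.
"""

from tgsmdr import chi2_power, chi2_power_n

for w, label in ((0.10, "small effect (whole-cohort comparison)"),
                 (0.13, "positional subgroup comparison")):
    res = chi2_power_n(w, df=1, alpha=0.05, power=0.8)
    print(f"w = {w:.2f} ({label}):")
    print(f"  exact solution  n = {res['n_exact']:.1f}")
    print(f"  minimum integer n = {res['n_min']} "
          f"(power there = {chi2_power(res['n_min'], w):.4f})")

print()
print("Reading: recruiting at least n_min participants gives the df=1")
print("chi-square test at alpha=0.05 at least 80% power at that effect size.")
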