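"""Recover a planted gene-gene interaction with the MDR search.

Plants a pure two-locus XOR penetrance effect (risk iff exactly one locus is
heterozygous) with essentially no marginal single-locus signal, then runs
the exhaustive cross-validated MDR search to find it.
"""

from tgsmdr import carrier_combination_frequency, mdr_search, simulate_cohort
from tgsmdr.simulate import (
    SimulationSpec,
    balanced_validation_table,
    xor_penetrance,
)

spec = SimulationSpec(
    group_sizes={"pop": 800},
    frequencies=balanced_validation_table(),  # all loci at allele freq 1/2
    seed=5,
    plant=xor_penetrance("COMT", "MAPT", high=0.9, low=0.1),
)
records = simulate_cohort(spec)
print(f"simulated {len(records)} individuals; "
      f"{sum(r.group == 'case' for r in records)} labelled case by the plant")

result = mdr_search(
    records,
    case_groups=("case",),
    attributes=("ANKK1", "APOE_rs405509", "BDNF_AS", "COMT", "MAPT", "NOS3"),
    k_range=(1, 2),
    folds=10,
    seed=5,
)
for k, model in sorted(result.by_size.items()):
    print(f"best {k}-locus model: {'+'.join(model.combination)} "
          f"(training BA {model.mean_training_ba:.3f}, "
          f"testing BA {model.mean_testing_ba:.3f}, CVC {model.cvc}/{model.folds})")
print(f"selected model: {'+'.join(result.best.combination)}")

freqs = carrier_combination_frequency(records, [("COMT", "G"), ("MAPT", "C")])
for group, cf in sorted(freqs.items()):
    print(f"COMT:G + MAPT:C carriers among {group}s: {100 * cf.proportion:.1f}% "
          f"({cf.carriers:.0f}/{cf.n})")
print()
print("Reading: the planted COMT x MAPT interaction should win with a high")
print("cross-validation consistency despite its flat single-locus marginals.")
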