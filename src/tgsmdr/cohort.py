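"""Cohort-level genotype tabulation and Hardy-Weinberg quality control."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .panel import (
    APOE_EPSILON,
    DEFAULT_PANEL,
    E4_MINUS,
    E4_PLUS,
    GenotypeRecord,
    Locus,
    apoe_epsilon_category,
)

_FREQ_TOL = 1e-9


@dataclass
class CohortFrequencyTable:
    """Per-group, per-locus genotype category frequencies.

    ``frequencies[group][locus][category]`` is a proportion over the
    individuals with a non-missing call at that locus; ``counts`` (when
    present) holds the corresponding absolute counts and ``group_sizes`` the
    number of individuals per group.
    """

    frequencies: dict[str, dict[str, dict[str, float]]]
    group_sizes: dict[str, int] = field(default_factory=dict)
    counts: dict[str, dict[str, dict[str, int]]] | None = None

    def __post_init__(self) -> None:
        for group, per_locus in self.frequencies.items():
            for locus, cats in per_locus.items():
                total = sum(cats.values())
                if abs(total - 1.0) > _FREQ_TOL:
                    raise ValueError(
                        f"{group}/{locus}: frequencies sum to {total}, expected 1"
                    )
                for cat, p in cats.items():
                    if not (-_FREQ_TOL <= p <= 1 + _FREQ_TOL):
                        raise ValueError(f"{group}/{locus}/{cat}: proportion {p} outside [0,1]")

    @property
    def groups(self) -> list[str]:
        return list(self.frequencies)

    def loci(self, group: str) -> list[str]:
        return list(self.frequencies[group])

    def locus_frequencies(self, group: str, locus: str) -> dict[str, float]:
        return dict(self.frequencies[group][locus])


def genotype_frequencies(
    records: Sequence[GenotypeRecord],
    group: Optional[str] = None,
    *,
    panel: Sequence[Locus] = DEFAULT_PANEL,
    include_epsilon: bool = True,
) -> CohortFrequencyTable:
    """Tabulate per-locus genotype frequencies over non-missing calls.

    Parameters
    ----------
    records
        Genotype records; only those matching ``group`` are used when a group
        label is given, otherwise every group present is tabulated.
    include_epsilon
        Also tabulate the derived APOE e4 carrier status (``"e4+"``/``"e4-"``)
        as pseudo-locus ``APOE_e`` when both APOE SNPs are in the panel.
    """
    if group is not None:
        groups = {group: [r for r in records if r.group == group]}
        if not groups[group]:
            raise ValueError(f"no records in group {group!r}")
    else:
        groups = {}
        for r in records:
            groups.setdefault(r.group, []).append(r)

    panel_names = [locus.name for locus in panel]
    epsilon = (
        include_epsilon
        and "APOE_rs429358" in panel_names
        and "APOE_rs7412" in panel_names
    )
    freqs: dict[str, dict[str, dict[str, float]]] = {}
    counts: dict[str, dict[str, dict[str, int]]] = {}
    sizes: dict[str, int] = {}
    for gname, recs in groups.items():
        sizes[gname] = len(recs)
        freqs[gname] = {}
        counts[gname] = {}
        for locus in panel:
            cats = {g: 0 for g in locus.genotypes}
            for r in recs:
                call = r.call(locus.name)
                if call is not None:
                    cats[call] += 1
            total = sum(cats.values())
            if total == 0:
                continue
            counts[gname][locus.name] = cats
            freqs[gname][locus.name] = {g: c / total for g, c in cats.items()}
        if epsilon:
            cats = {E4_PLUS: 0, E4_MINUS: 0}
            for r in recs:
                cat = apoe_epsilon_category(r)
                if cat is not None:
                    cats[cat] += 1
            total = sum(cats.values())
            if total:
                counts[gname][APOE_EPSILON] = cats
                freqs[gname][APOE_EPSILON] = {g: c / total for g, c in cats.items()}
    return CohortFrequencyTable(frequencies=freqs, group_sizes=sizes, counts=counts)


@dataclass(frozen=True)
class HweResult:
    """Pearson chi-square test of Hardy-Weinberg proportions (df = 1).

    ``applicable`` is False for monomorphic loci, where the test is
    undefined; the statistic and p-value are then ``None`` rather than a
    misleading p = 1.
    """

    chi2: Optional[float]
    df: int
    p: Optional[float]
    applicable: bool
    n: int
    allele_freq: Optional[float]  # frequency of the first allele


def hwe_test(counts: Sequence[int] | Mapping[str, int]) -> HweResult:
    """Test genotype counts (hom1, het, hom2) against Hardy-Weinberg proportions.

    Allele frequencies are estimated from the counts; expected counts are
    n*p^2, 2npq and n*q^2 and the Pearson chi-square statistic is referred to
    the upper tail of chi-square with one degree of freedom (no continuity
    correction).
    """
    if isinstance(counts, Mapping):
        obs = np.asarray(list(counts.values()), dtype=float)
    else:
        obs = np.asarray(counts, dtype=float)
    if obs.shape != (3,):
        raise ValueError("expected three genotype counts (hom1, het, hom2)")
    if np.any(obs < 0):
        raise ValueError("genotype counts must be non-negative")
    n = float(obs.sum())
    if n < 1:
        raise ValueError("total genotype count must be at least 1")
    p = (2 * obs[0] + obs[1]) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return HweResult(None, 1, None, applicable=False, n=int(n), allele_freq=p)
    expected = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(np.sum((obs - expected) ** 2 / expected))
    pval = float(stats.chi2.sf(chi2, df=1))
    return HweResult(chi2, 1, pval, applicable=True, n=int(n), allele_freq=float(p))


def hwe_report(
    records: Sequence[GenotypeRecord],
    *,
    panel: Sequence[Locus] = DEFAULT_PANEL,
) -> dict[str, dict[str, HweResult]]:
    """Per-group, per-locus HWE tests over the bi-allelic panel SNPs.

    The derived APOE epsilon attribute is not a bi-allelic genotype and is
    never HWE-tested; the two raw APOE SNPs are.
    """
    table = genotype_frequencies(records, panel=panel, include_epsilon=False)
    out: dict[str, dict[str, HweResult]] = {}
    for group in table.groups:
        out[group] = {}
        for locus in panel:
            cats = table.counts[group].get(locus.name)
            if cats is None:
                continue
            hom1, het, hom2 = (cats[g] for g in locus.genotypes)
            out[group][locus.name] = hwe_test((hom1, het, hom2))
    return out
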