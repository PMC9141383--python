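"""Synthetic case-control genotype cohorts.

The generator emulates the study design the analysis assumes: two (or more)
groups of fixed size, each locus drawn independently of the others (linkage
equilibrium — the panel loci lie on different chromosomes), with per-group
genotype-category probabilities taken from a frequency table.  The packaged
table reproduces the published athlete (n = 635) / non-athlete (n = 722)
genotype frequencies.

APOE is special-cased: the table carries only the e4 carrier rate, so the
two underlying SNPs are generated by drawing epsilon haplotypes (e2/e3/e4)
whose e4 frequency matches the target carrier rate under Hardy-Weinberg
haplotype pairing, then back-converting to rs429358/rs7412 genotypes.  The
e2:e3 split uses a fixed 0.08:0.77 base ratio, a typical European value; no
downstream statistic in this package depends on it beyond the e4 rate.

An optional two-locus penetrance plant relabels individuals case/control
from their joint genotype cell, enabling validation of the epistasis search
against interactions with known structure (including pure, zero-marginal
XOR-style effects).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cohort import CohortFrequencyTable
from .io import load_published_frequencies
from .panel import (
    APOE_EPSILON,
    DEFAULT_PANEL,
    E4_MINUS,
    E4_PLUS,
    GenotypeRecord,
    Locus,
    epsilon_to_snp_genotypes,
    panel_by_name,
)

#: e2 : e3 base weights used to split the non-e4 haplotype mass.
E2_E3_BASE = (0.08, 0.77)

_APOE_RAW = ("APOE_rs429358", "APOE_rs7412")


class SimulationConfigError(ValueError):
    """The simulation spec is inconsistent with the panel or frequency table."""


@dataclass(frozen=True)
class PenetrancePlant:
    """A planted two-locus disease model.

    ``penetrance`` maps a pair of canonical genotypes at ``loci`` to the
    probability of the case label; cells not listed fall back to
    ``baseline``.
    """

    loci: tuple[str, str]
    penetrance: dict[tuple[str, str], float] = field(default_factory=dict)
    baseline: float = 0.5

    def __post_init__(self) -> None:
        for cell, p in self.penetrance.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"penetrance {p} for cell {cell} outside [0, 1]")
        if not (0.0 <= self.baseline <= 1.0):
            raise ValueError("baseline penetrance outside [0, 1]")

    def cell_penetrance(self, g1: str, g2: str) -> float:
        return self.penetrance.get((g1, g2), self.baseline)


def xor_penetrance(
    locus_a: str,
    locus_b: str,
    *,
    high: float = 0.9,
    low: float = 0.1,
) -> PenetrancePlant:
    """A pure-interaction (XOR) penetrance table over two three-level loci.

    Risk is ``high`` iff exactly one of the two genotypes is heterozygous,
    ``low`` otherwise.  When both loci sit at allele frequency 1/2 in HWE the
    single-locus marginal penetrances are constant, so the interaction is
    invisible to any marginal test and only a genuine two-locus search can
    recover it.
    """
    by_name = panel_by_name()
    table: dict[tuple[str, str], float] = {}
    for ga in by_name[locus_a].genotypes:
        for gb in by_name[locus_b].genotypes:
            het_a = ga[0] != ga[1]
            het_b = gb[0] != gb[1]
            table[(ga, gb)] = high if het_a != het_b else low
    return PenetrancePlant(loci=(locus_a, locus_b), penetrance=table, baseline=low)


@dataclass
class SimulationSpec:
    """Everything needed to draw a reproducible synthetic cohort.

    Parameters
    ----------
    group_sizes
        Individuals per group label, e.g. ``{"athlete": 635, "non_athlete": 722}``.
    frequencies
        Per-group genotype frequency table; defaults to the packaged
        published table.
    mode
        ``"genotype"`` draws categories at the tabulated proportions exactly;
        ``"hwe"`` re-derives allele frequencies and draws Hardy-Weinberg
        genotype proportions instead.
    missingness
        Per-locus completely-at-random no-call probability in [0, 1).
    frequency_group
        Optional map from a cohort group label to the frequency-table group
        it should be drawn from (e.g. positional subgroups drawn from the
        pooled athlete frequencies).
    plant
        Optional penetrance plant; when present, simulated individuals are
        relabelled ``"case"``/``"control"`` from their two-locus genotype.
    seed
        Seed for all randomness in the draw.
    """

    group_sizes: dict[str, int]
    frequencies: Optional[CohortFrequencyTable] = None
    mode: str = "genotype"
    missingness: float = 0.0
    frequency_group: Optional[dict[str, str]] = None
    plant: Optional[PenetrancePlant] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("genotype", "hwe"):
            raise SimulationConfigError(f"unknown simulation mode {self.mode!r}")
        if not self.group_sizes:
            raise SimulationConfigError("at least one group is required")
        for g, n in self.group_sizes.items():
            if n < 1:
                raise SimulationConfigError(f"group {g!r} size must be >= 1")
        if not (0.0 <= self.missingness < 1.0):
            raise SimulationConfigError("missingness must lie in [0, 1)")

    def resolved_frequencies(self) -> CohortFrequencyTable:
        return self.frequencies if self.frequencies is not None else load_published_frequencies()


def _epsilon_haplotype_freqs(e4_carrier_rate: float) -> tuple[float, float, float]:
    """(f_e2, f_e3, f_e4) with HWE carrier rate matching the target e4+ rate."""
    f4 = 1.0 - math.sqrt(1.0 - e4_carrier_rate)
    w2, w3 = E2_E3_BASE
    rest = 1.0 - f4
    return (rest * w2 / (w2 + w3), rest * w3 / (w2 + w3), f4)


def _genotype_probs(locus: Locus, freqs: dict[str, float], mode: str) -> np.ndarray:
    cats = locus.genotypes
    unknown = [c for c in freqs if c not in cats]
    if unknown:
        raise SimulationConfigError(
            f"{locus.name}: frequency table categories {unknown} are not genotypes "
            f"of this locus {list(cats)}"
        )
    p = np.asarray([freqs.get(c, 0.0) for c in cats], dtype=float)
    if mode == "hwe":
        a = p[0] + 0.5 * p[1]  # frequency of the first declared allele
        p = np.asarray([a * a, 2 * a * (1 - a), (1 - a) * (1 - a)])
    return p / p.sum()


def simulate_cohort(spec: SimulationSpec) -> list[GenotypeRecord]:
    """Draw a cohort of genotype records per the spec; seeded and reproducible.

    Loci are independent.  The two raw APOE SNPs are generated jointly from
    epsilon haplotypes when the frequency table provides the derived
    ``APOE_e`` carrier rate, and directly from their own genotype rows
    otherwise.
    """
    table = spec.resolved_frequencies()
    rng = np.random.default_rng(spec.seed)
    records: list[GenotypeRecord] = []
    plain_loci = [loc for loc in DEFAULT_PANEL if loc.name not in _APOE_RAW]
    by_name = panel_by_name()

    for group, size in spec.group_sizes.items():
        fgroup = (spec.frequency_group or {}).get(group, group)
        if fgroup not in table.frequencies:
            raise SimulationConfigError(f"frequency table has no group {fgroup!r}")
        per_locus = table.frequencies[fgroup]

        calls: dict[str, list[Optional[str]]] = {}
        for locus in plain_loci:
            if locus.name not in per_locus:
                raise SimulationConfigError(
                    f"frequency table for group {fgroup!r} is missing locus {locus.name!r}"
                )
            probs = _genotype_probs(locus, per_locus[locus.name], spec.mode)
            draws = rng.choice(len(probs), size=size, p=probs)
            calls[locus.name] = [locus.genotypes[i] for i in draws]

        if APOE_EPSILON in per_locus:
            f2, f3, f4 = _epsilon_haplotype_freqs(per_locus[APOE_EPSILON][E4_PLUS])
            haps = rng.choice(3, size=(size, 2), p=[f2, f3, f4])
            eps = [["e2", "e3", "e4"][h] for h in haps.ravel()]
            g429358, g7412 = [], []
            for i in range(size):
                dip = "/".join(sorted((eps[2 * i], eps[2 * i + 1])))
                g1, g2 = epsilon_to_snp_genotypes(dip)
                g429358.append(g1)
                g7412.append(g2)
            calls["APOE_rs429358"] = g429358
            calls["APOE_rs7412"] = g7412
        else:
            for name in _APOE_RAW:
                if name not in per_locus:
                    raise SimulationConfigError(
                        f"frequency table for group {fgroup!r} has neither {APOE_EPSILON!r} "
                        f"nor raw {name!r} frequencies"
                    )
                locus = by_name[name]
                probs = _genotype_probs(locus, per_locus[name], spec.mode)
                draws = rng.choice(len(probs), size=size, p=probs)
                calls[name] = [locus.genotypes[i] for i in draws]

        if spec.missingness > 0:
            for name in calls:
                drop = rng.random(size) < spec.missingness
                calls[name] = [None if d else g for g, d in zip(calls[name], drop)]

        for i in range(size):
            records.append(
                GenotypeRecord(
                    sample_id=f"{group}_{i:05d}",
                    group=group,
                    calls={name: calls[name][i] for name in calls},
                )
            )

    if spec.plant is not None:
        plant_seed = int(rng.integers(0, 2**31 - 1))
        records = plant_labels(records, spec.plant, seed=plant_seed)
    return records


def plant_labels(
    records: Sequence[GenotypeRecord],
    plant: PenetrancePlant,
    seed: int = 0,
    *,
    case_label: str = "case",
    control_label: str = "control",
) -> list[GenotypeRecord]:
    """Relabel individuals case/control from a two-locus penetrance table.

    Each individual becomes a case with the penetrance of their joint
    genotype cell at the plant's two loci; individuals missing either call
    fall back to the baseline penetrance.
    """
    rng = np.random.default_rng(seed)
    la, lb = plant.loci
    out = []
    for r in records:
        g1, g2 = r.call(la), r.call(lb)
        p = plant.baseline if (g1 is None or g2 is None) else plant.cell_penetrance(g1, g2)
        group = case_label if rng.random() < p else control_label
        out.append(GenotypeRecord(r.sample_id, group, dict(r.calls)))
    return out


def balanced_validation_table(group: str = "pop") -> CohortFrequencyTable:
    """A synthetic frequency table with every bi-allelic SNP at allele
    frequency 1/2 in HWE (genotype proportions 1/4, 1/2, 1/4).

    At these frequencies an XOR penetrance plant has exactly flat
    single-locus marginal penetrances, making it invisible to any marginal
    test — the cleanest possible validation target for an interaction
    search.  The e4 carrier rate is set to 0.3.
    """
    freqs: dict[str, dict[str, float]] = {}
    for locus in DEFAULT_PANEL:
        if locus.name in _APOE_RAW:
            continue
        hom1, het, hom2 = locus.genotypes
        freqs[locus.name] = {hom1: 0.25, het: 0.5, hom2: 0.25}
    freqs[APOE_EPSILON] = {E4_PLUS: 0.3, E4_MINUS: 0.7}
    return CohortFrequencyTable({group: freqs})


def published_study_spec(
    seed: int = 0,
    *,
    athletes: int = 635,
    non_athletes: int = 722,
    mode: str = "genotype",
    missingness: float = 0.0,
) -> SimulationSpec:
    """Spec for the published study design: athlete and non-athlete cohorts
    at the printed group sizes and genotype frequencies."""
    return SimulationSpec(
        group_sizes={"athlete": athletes, "non_athlete": non_athletes},
        frequencies=load_published_frequencies(),
        mode=mode,
        missingness=missingness,
        seed=seed,
    )
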