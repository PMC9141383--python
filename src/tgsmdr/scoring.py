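"""Additive total genotype score (TGS) engine.

A scoring scheme assigns each of seven score components an integer genotype
score in {0, 1, 2} — six bi-allelic SNPs scored codominantly and the derived
APOE epsilon attribute scored 2 for e4 non-carriers and 0 for carriers (no
intermediate score).  The TGS is the component sum rescaled to 0-100 by
100 / (2 x 7) = 100/14, so 100 is the 'perfect' profile (every preferable
homozygote) and 0 the 'worst'.  Attainable scores are the fifteen multiples
of 100/14; printed values are conventionally shown to one decimal (e.g. 92.9
for a component sum of 13, 21.4 for a sum of 3).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .cohort import CohortFrequencyTable
from .panel import (
    APOE_EPSILON,
    DEFAULT_PANEL,
    E4_MINUS,
    E4_PLUS,
    GenotypeRecord,
    apoe_epsilon_category,
    panel_by_name,
)

VALID_SCORES = (0, 1, 2)


@dataclass(frozen=True)
class ScoreComponent:
    """One additive component: a source attribute and its genotype->score map.

    ``source`` is either a panel locus name or ``"APOE_e"`` for the derived
    epsilon-4 carrier attribute.
    """

    source: str
    mapping: tuple[tuple[str, int], ...]

    def score(self, category: str) -> int:
        for cat, s in self.mapping:
            if cat == category:
                return s
        raise KeyError(f"{self.source}: no score for category {category!r}")

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(cat for cat, _ in self.mapping)

    def as_dict(self) -> dict[str, int]:
        return dict(self.mapping)


@dataclass(frozen=True)
class ScoringScheme:
    name: str
    components: tuple[ScoreComponent, ...]

    def __post_init__(self) -> None:
        by_name = panel_by_name()
        for comp in self.components:
            scores = [s for _, s in comp.mapping]
            if any(s not in VALID_SCORES for s in scores):
                raise ValueError(f"{comp.source}: scores must lie in {VALID_SCORES}")
            if comp.source == APOE_EPSILON:
                m = comp.as_dict()
                if set(m) != {E4_PLUS, E4_MINUS} or m[E4_PLUS] != 0 or m[E4_MINUS] != 2:
                    raise ValueError(
                        "APOE epsilon component must score e4+ -> 0 and e4- -> 2"
                    )
            elif comp.source in by_name:
                expected = set(by_name[comp.source].genotypes)
                if set(comp.categories) != expected:
                    raise ValueError(
                        f"{comp.source}: mapping must cover genotypes {sorted(expected)}"
                    )

    @property
    def normaliser(self) -> float:
        """100 / (2 x number of components); 100/14 for the seven-component panel."""
        return 100.0 / (2 * len(self.components))

    @property
    def max_sum(self) -> int:
        return 2 * len(self.components)

    def component(self, source: str) -> ScoreComponent:
        for comp in self.components:
            if comp.source == source:
                return comp
        raise KeyError(source)


@dataclass
class TgsResult:
    """Per-individual component scores and total genotype score.

    ``tgs`` is kept at full precision; use :func:`tgs_display` for the
    conventional one-decimal form.  ``complete`` is False when any component
    could not be scored, in which case ``tgs`` is None under the default
    complete-case policy (or imputed, with ``complete`` still False, under
    the imputation policy).
    """

    sample_id: str
    group: str
    component_scores: dict[str, Optional[float]]
    tgs: Optional[float]
    complete: bool


def tgs_display(tgs: float) -> float:
    """Round a TGS to the one-decimal display convention."""
    return round(tgs, 1)


# --- builtin schemes -------------------------------------------------------

def _comp(source: str, mapping: dict[str, int]) -> ScoreComponent:
    return ScoreComponent(source, tuple(mapping.items()))


def _literature_components() -> dict[str, dict[str, int]]:
    return {
        "ANKK1": {"GG": 2, "AG": 1, "AA": 0},
        APOE_EPSILON: {E4_MINUS: 2, E4_PLUS: 0},
        "APOE_rs405509": {"GG": 2, "GT": 1, "TT": 0},
        "BDNF_AS": {"CC": 2, "CT": 1, "TT": 0},
        "COMT": {"AA": 2, "AG": 1, "GG": 0},
        "MAPT": {"CC": 2, "CT": 1, "TT": 0},
        "NOS3": {"TT": 2, "CT": 1, "CC": 0},
    }


BUILTIN_SCHEMES = ("literature", "literature_nos3_flipped", "data_led")


def builtin_scheme(name: str) -> ScoringScheme:
    """A packaged seven-component scoring scheme.

    ``"literature"`` scores each SNP by the prior-literature 'preferable'
    homozygote (ANKK1 GG=2, APOE e4- = 2, rs405509 GG=2, BDNF-AS CC=2,
    COMT AA=2, MAPT CC=2, NOS3 TT=2).  ``"data_led"`` reverses the rs405509
    and COMT components (TT=2 and GG=2 respectively) to follow genotype
    frequencies observed in elite rugby athletes.  ``"literature_nos3_flipped"``
    is the literature scheme with the NOS3 component reversed (CC=2), provided
    because published accounts of which NOS3 homozygote the literature scheme
    preferred are inconsistent.
    """
    maps = _literature_components()
    if name == "data_led":
        maps["APOE_rs405509"] = {"TT": 2, "GT": 1, "GG": 0}
        maps["COMT"] = {"GG": 2, "AG": 1, "AA": 0}
    elif name == "literature_nos3_flipped":
        maps["NOS3"] = {"CC": 2, "CT": 1, "TT": 0}
    elif name != "literature":
        raise ValueError(f"unknown scheme {name!r}; valid names: {', '.join(BUILTIN_SCHEMES)}")
    return ScoringScheme(name, tuple(_comp(src, m) for src, m in maps.items()))


# --- scheme file round-trip ------------------------------------------------

def write_scheme(scheme: ScoringScheme, path: Union[str, Path]) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# scheme\t{scheme.name}\n")
        fh.write("component\tcategory\tscore\n")
        for comp in scheme.components:
            for cat, s in comp.mapping:
                fh.write(f"{comp.source}\t{cat}\t{s}\n")


def read_scheme(path: Union[str, Path]) -> ScoringScheme:
    name = Path(path).stem
    order: list[str] = []
    maps: dict[str, dict[str, int]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                parts = line.lstrip("# ").split("\t")
                if parts[0] == "scheme" and len(parts) == 2:
                    name = parts[1]
                continue
            fields = line.split("\t")
            if fields == ["component", "category", "score"]:
                continue
            src, cat, score = fields
            if src not in maps:
                maps[src] = {}
                order.append(src)
            maps[src][cat] = int(score)
    return ScoringScheme(name, tuple(_comp(src, maps[src]) for src in order))


# --- scoring ---------------------------------------------------------------

def component_category(
    record: GenotypeRecord, component: ScoreComponent, *, apoe_ambiguous: str = "e2e4"
) -> Optional[str]:
    """The record's category for a component, or None when underivable."""
    if component.source == APOE_EPSILON:
        return apoe_epsilon_category(record, ambiguous=apoe_ambiguous)
    return record.call(component.source)


def score_individual(
    record: GenotypeRecord,
    scheme: ScoringScheme,
    *,
    policy: str = "complete",
    frequencies: Optional[CohortFrequencyTable] = None,
    apoe_ambiguous: str = "e2e4",
) -> TgsResult:
    """Score one individual under a scheme.

    ``policy="complete"`` (default) leaves the TGS undefined when any
    component is missing; ``policy="impute"`` replaces each missing component
    score by its expectation under the individual's group frequencies (which
    must be supplied), flagged by ``complete=False``.
    """
    if policy not in ("complete", "impute"):
        raise ValueError(f"unknown missing-component policy {policy!r}")
    scores: dict[str, Optional[float]] = {}
    complete = True
    for comp in scheme.components:
        cat = component_category(record, comp, apoe_ambiguous=apoe_ambiguous)
        if cat is None:
            complete = False
            if policy == "impute":
                if frequencies is None:
                    raise ValueError("imputation policy requires a frequency table")
                scores[comp.source] = _expected_component_score(
                    comp, frequencies, record.group
                )
            else:
                scores[comp.source] = None
        else:
            scores[comp.source] = comp.score(cat)
    if complete or policy == "impute":
        tgs = scheme.normaliser * sum(scores.values())  # type: ignore[arg-type]
    else:
        tgs = None
    return TgsResult(record.sample_id, record.group, scores, tgs, complete)


def score_cohort(
    records: Sequence[GenotypeRecord],
    scheme: ScoringScheme,
    *,
    policy: str = "complete",
    frequencies: Optional[CohortFrequencyTable] = None,
    apoe_ambiguous: str = "e2e4",
) -> list[TgsResult]:
    return [
        score_individual(
            r, scheme, policy=policy, frequencies=frequencies, apoe_ambiguous=apoe_ambiguous
        )
        for r in records
    ]


def _expected_component_score(
    comp: ScoreComponent, table: CohortFrequencyTable, group: str
) -> float:
    freqs = table.frequencies[group][comp.source]
    return sum(p * comp.score(cat) for cat, p in freqs.items())


# --- distribution summaries ------------------------------------------------

@dataclass(frozen=True)
class DistributionSummary:
    """Mean/SD, small-sample excess kurtosis with its standard error, and
    linear-interpolation quartile cut-points of a TGS distribution."""

    n: int
    mean: float
    sd: float
    kurtosis: Optional[float]
    kurtosis_se: Optional[float]
    quartiles: tuple[float, float, float]


def kurtosis_se(n: int) -> float:
    """Standard error of the small-sample excess kurtosis statistic.

    SE(kurt) = 2 * SE(skew) * sqrt((n^2-1) / ((n-3)(n+5))) with
    SE(skew) = sqrt(6n(n-1) / ((n-2)(n+1)(n+3))).
    """
    if n < 4:
        raise ValueError("kurtosis standard error requires n >= 4")
    se_skew = math.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))
    return 2.0 * se_skew * math.sqrt((n * n - 1.0) / ((n - 3.0) * (n + 5.0)))


def summarize_tgs(results: Iterable[TgsResult]) -> DistributionSummary:
    """Summarise complete TGS results: mean, SD (n-1), bias-corrected excess
    kurtosis with its SE, and interpolated quartile cut-points.

    Kurtosis is reported as None for degenerate (constant) samples.
    """
    values = np.asarray([r.tgs for r in results if r.complete and r.tgs is not None])
    n = len(values)
    if n < 4:
        raise ValueError("TGS summary requires at least 4 complete results")
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        kurt, kse = None, None
    else:
        kurt = float(stats.kurtosis(values, fisher=True, bias=False))
        kse = kurtosis_se(n)
    q1, q2, q3 = np.percentile(values, [25, 50, 75])
    return DistributionSummary(
        n=n,
        mean=float(np.mean(values)),
        sd=sd,
        kurtosis=kurt,
        kurtosis_se=kse,
        quartiles=(float(q1), float(q2), float(q3)),
    )


@dataclass(frozen=True)
class QuartileTable:
    """Group-by-extreme-quartile membership counts.

    ``counts`` rows are (group A, group B); columns are (top quartile,
    bottom quartile) of the pooled distribution; the middle 50% is excluded.
    """

    counts: np.ndarray
    cutpoints: tuple[float, float]  # (lower = Q1, upper = Q3)


def quartile_membership(
    results_a: Sequence[TgsResult], results_b: Sequence[TgsResult]
) -> QuartileTable:
    """Cross-tabulate two groups' membership of the pooled top/bottom TGS quartiles.

    Cut-points are the pooled 25th/75th percentiles (linear interpolation);
    scores at or beyond a cut-point count as extreme.
    """
    a = np.asarray([r.tgs for r in results_a if r.complete and r.tgs is not None])
    b = np.asarray([r.tgs for r in results_b if r.complete and r.tgs is not None])
    pooled = np.concatenate([a, b])
    if len(pooled) < 8:
        raise ValueError("quartile membership requires at least 8 pooled complete results")
    q1, q3 = np.percentile(pooled, [25, 75])
    counts = np.array(
        [
            [int(np.sum(a >= q3)), int(np.sum(a <= q1))],
            [int(np.sum(b >= q3)), int(np.sum(b <= q1))],
        ]
    )
    return QuartileTable(counts=counts, cutpoints=(float(q1), float(q3)))


# --- expected TGS by enumeration ------------------------------------------

def expected_tgs_distribution(
    scheme: ScoringScheme, table: CohortFrequencyTable, group: str
) -> dict[float, float]:
    """Exact TGS distribution under independent loci, by full enumeration of
    the component-score product space (<= 3^6 x 2 cells for the default panel).

    Returns a map TGS value -> probability.
    """
    per_component: list[list[tuple[int, float]]] = []
    for comp in scheme.components:
        freqs = table.frequencies[group][comp.source]
        per_component.append([(comp.score(cat), p) for cat, p in freqs.items()])
    sums: dict[int, float] = {}
    for cells in itertools.product(*per_component):
        total = sum(s for s, _ in cells)
        prob = math.prod(p for _, p in cells)
        sums[total] = sums.get(total, 0.0) + prob
    return {scheme.normaliser * k: p for k, p in sorted(sums.items())}


def expected_tgs_mean(
    scheme: ScoringScheme, table: CohortFrequencyTable, group: str
) -> float:
    """Expected TGS under independent loci (mean of the enumerated distribution)."""
    dist = expected_tgs_distribution(scheme, table, group)
    return sum(v * p for v, p in dist.items())
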