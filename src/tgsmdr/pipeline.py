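"""End-to-end study workflow: cohort (simulated or read from file) -> HWE QC
-> TGS under one or more schemes -> group comparisons (t-test, extreme
quartiles, ROC) -> MDR epistasis search -> allele-combination frequencies.

Everything is computed in memory first and written only on success, so a
failing run never leaves a partial report behind.  The seed and full
configuration are embedded in the structured-text summary; reruns with the
same configuration and seed are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .cohort import HweResult, hwe_report
from .io import read_genotype_table, write_genotype_table
from .mdr import (
    COMPONENT_ATTRIBUTES,
    RAW_SNP_ATTRIBUTES,
    CombinationFrequency,
    MdrResult,
    carrier_combination_frequency,
    mdr_search,
)
from .panel import DEFAULT_PANEL, GenotypeRecord
from .scoring import (
    DistributionSummary,
    QuartileTable,
    TgsResult,
    builtin_scheme,
    quartile_membership,
    score_cohort,
    summarize_tgs,
    tgs_display,
)
from .simulate import SimulationSpec, simulate_cohort
from .stats import (
    Chi2Result,
    OddsRatioResult,
    RocResult,
    chi2_contingency,
    odds_ratio,
    roc_auc,
    t_test_ind,
)

#: Default athlete subgroup structure: 534 rugby union athletes split into
#: forwards (304) and backs (230), plus 101 rugby league athletes, against
#: 722 non-athletes (635 athletes in total).
DEFAULT_GROUP_SIZES = {
    "RU_forward": 304,
    "RU_back": 230,
    "RL": 101,
    "non_athlete": 722,
}

ATHLETE_GROUPS = ("RU_forward", "RU_back", "RL")

#: (row label, case groups, control groups); the first five compare athlete
#: groupings against non-athletes (the Table-3-style layout), the last
#: compares rugby union forwards with backs.
DEFAULT_COMPARISONS: tuple[tuple[str, tuple[str, ...], tuple[str, ...]], ...] = (
    ("all_athletes", ATHLETE_GROUPS, ("non_athlete",)),
    ("RU_athletes", ("RU_forward", "RU_back"), ("non_athlete",)),
    ("RL_athletes", ("RL",), ("non_athlete",)),
    ("RU_forwards", ("RU_forward",), ("non_athlete",)),
    ("RU_backs", ("RU_back",), ("non_athlete",)),
    ("RU_forwards_vs_backs", ("RU_forward",), ("RU_back",)),
)

DEFAULT_COMBINATION = (("COMT", "G"), ("MAPT", "C"))


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    genotype_file: Optional[str] = None  #: read this TSV instead of simulating
    simulation: Optional[SimulationSpec] = None
    schemes: tuple[str, ...] = ("literature", "data_led")
    comparisons: tuple[tuple[str, tuple[str, ...], tuple[str, ...]], ...] = (
        DEFAULT_COMPARISONS
    )
    baseline_group: str = "non_athlete"
    mdr_k_range: tuple[int, ...] = (1, 2)
    mdr_folds: int = 10
    mdr_attributes: str = "components"  #: "components" or "raw_snps"
    combination: tuple[tuple[str, str], ...] = DEFAULT_COMBINATION
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.comparisons:
            raise ValueError("at least one comparison is required")


@dataclass
class ComparisonResult:
    name: str
    case_groups: tuple[str, ...]
    control_groups: tuple[str, ...]
    case_summary: DistributionSummary
    control_summary: DistributionSummary
    t_test: dict[str, float]
    quartiles: QuartileTable
    quartile_chi2: Chi2Result
    roc: RocResult


@dataclass
class SchemeReport:
    scheme: str
    baseline_summary: DistributionSummary
    comparisons: list[ComparisonResult]
    histogram: dict[str, dict[float, int]]  #: group -> displayed TGS -> count
    individual: list[TgsResult]


@dataclass
class CombinationReport:
    pairs: tuple[tuple[str, str], ...]
    frequencies: dict[str, CombinationFrequency]
    odds_vs_baseline: dict[str, OddsRatioResult]


@dataclass
class PipelineReport:
    config: RunConfig
    records: list[GenotypeRecord]
    hwe: dict[str, dict[str, HweResult]]
    schemes: list[SchemeReport]
    mdr: MdrResult
    combination: CombinationReport


def _subset(results: Sequence[TgsResult], groups: Sequence[str]) -> list[TgsResult]:
    return [r for r in results if r.group in groups]


def _complete_scores(results: Sequence[TgsResult]) -> list[float]:
    return [r.tgs for r in results if r.complete and r.tgs is not None]


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Execute the full workflow and return the in-memory report bundle."""
    if config.genotype_file is not None:
        records = read_genotype_table(config.genotype_file)
    else:
        spec = config.simulation or SimulationSpec(
            group_sizes=dict(DEFAULT_GROUP_SIZES),
            frequency_group={g: "athlete" for g in ATHLETE_GROUPS},
            seed=config.seed,
        )
        records = simulate_cohort(spec)

    present = {r.group for r in records}
    for _, cases, controls in config.comparisons:
        for g in (*cases, *controls):
            if g not in present:
                raise PipelineError(f"comparison group {g!r} has no records")

    hwe = hwe_report(records)

    scheme_reports = []
    for scheme_name in config.schemes:
        scheme = builtin_scheme(scheme_name)
        results = score_cohort(records, scheme)
        baseline = summarize_tgs(_subset(results, (config.baseline_group,)))
        comparisons = []
        for name, cases, controls in config.comparisons:
            case_res = _subset(results, cases)
            ctrl_res = _subset(results, controls)
            qt = quartile_membership(case_res, ctrl_res)
            comparisons.append(
                ComparisonResult(
                    name=name,
                    case_groups=tuple(cases),
                    control_groups=tuple(controls),
                    case_summary=summarize_tgs(case_res),
                    control_summary=summarize_tgs(ctrl_res),
                    t_test=t_test_ind(_complete_scores(case_res), _complete_scores(ctrl_res)),
                    quartiles=qt,
                    quartile_chi2=chi2_contingency(qt.counts),
                    roc=roc_auc(_complete_scores(case_res), _complete_scores(ctrl_res)),
                )
            )
        histogram: dict[str, dict[float, int]] = {}
        for r in results:
            if r.complete and r.tgs is not None:
                bucket = histogram.setdefault(r.group, {})
                key = tgs_display(r.tgs)
                bucket[key] = bucket.get(key, 0) + 1
        scheme_reports.append(
            SchemeReport(
                scheme=scheme_name,
                baseline_summary=baseline,
                comparisons=comparisons,
                histogram=histogram,
                individual=results,
            )
        )

    attributes = (
        COMPONENT_ATTRIBUTES if config.mdr_attributes == "components" else RAW_SNP_ATTRIBUTES
    )
    case_groups = tuple(g for g in present if g != config.baseline_group)
    mdr = mdr_search(
        records,
        case_groups=case_groups,
        attributes=attributes,
        k_range=config.mdr_k_range,
        folds=config.mdr_folds,
        seed=config.seed,
    )

    freqs = carrier_combination_frequency(records, config.combination)
    # pool athlete subgroups into an all-case entry for the headline figure
    pooled = carrier_combination_frequency(
        [
            GenotypeRecord(r.sample_id, "all_cases" if r.group != config.baseline_group else r.group, r.calls)
            for r in records
        ],
        config.combination,
    )
    freqs = {**freqs, "all_cases": pooled["all_cases"]}
    base = freqs.get(config.baseline_group)
    odds = {}
    if base is not None and base.mode == "carrier":
        for group, cf in freqs.items():
            if group == config.baseline_group:
                continue
            odds[group] = odds_ratio(
                cf.carriers,
                cf.n - cf.carriers,
                base.carriers,
                base.n - base.carriers,
            )
    combination = CombinationReport(
        pairs=config.combination, frequencies=freqs, odds_vs_baseline=odds
    )

    return PipelineReport(
        config=config,
        records=records,
        hwe=hwe,
        schemes=scheme_reports,
        mdr=mdr,
        combination=combination,
    )


# --- report serialisation --------------------------------------------------

def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        return format(x, ".10g")
    return str(x)


def write_report(report: PipelineReport, outdir: str | Path) -> None:
    """Write the full report bundle (TSVs + structured-text summary)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    write_genotype_table(report.records, out / "cohort.tsv")

    with open(out / "hwe.tsv", "wt", encoding="utf-8") as fh:
        fh.write("group\tlocus\tn\tallele_freq\tchi2\tp\tapplicable\n")
        for group, per_locus in report.hwe.items():
            for locus, res in per_locus.items():
                fh.write(
                    "\t".join(
                        [
                            group,
                            locus,
                            str(res.n),
                            _fmt(res.allele_freq),
                            _fmt(res.chi2),
                            _fmt(res.p),
                            str(res.applicable),
                        ]
                    )
                    + "\n"
                )

    for sr in report.schemes:
        with open(out / f"tgs_individual_{sr.scheme}.tsv", "wt", encoding="utf-8") as fh:
            sources = [c.source for c in builtin_scheme(sr.scheme).components]
            fh.write("sample_id\tgroup\t" + "\t".join(sources) + "\ttgs\tcomplete\n")
            for r in sr.individual:
                row = [r.sample_id, r.group]
                row += [_fmt(r.component_scores.get(s)) for s in sources]
                row += [_fmt(r.tgs), str(r.complete)]
                fh.write("\t".join(row) + "\n")

        header = (
            "comparison\tn\tmean_tgs\tsd_tgs\tkurtosis\tkurtosis_se\t"
            "t_p\tquartile_chi2_p\tauc\tauc_ci_lower\tauc_ci_upper\tauc_p\n"
        )
        baseline_name = report.config.baseline_group
        vs_baseline = [
            c for c in sr.comparisons if c.control_groups == (baseline_name,)
        ]
        other = [c for c in sr.comparisons if c.control_groups != (baseline_name,)]
        with open(out / f"tgs_summary_{sr.scheme}.tsv", "wt", encoding="utf-8") as fh:
            fh.write(header)
            b = sr.baseline_summary
            fh.write(
                "\t".join(
                    [
                        f"{baseline_name}_baseline",
                        str(b.n),
                        _fmt(b.mean),
                        _fmt(b.sd),
                        _fmt(b.kurtosis),
                        _fmt(b.kurtosis_se),
                        "NA",
                        "NA",
                        "NA",
                        "NA",
                        "NA",
                        "NA",
                    ]
                )
                + "\n"
            )
            for c in vs_baseline:
                s = c.case_summary
                fh.write(
                    "\t".join(
                        [
                            c.name,
                            str(s.n),
                            _fmt(s.mean),
                            _fmt(s.sd),
                            _fmt(s.kurtosis),
                            _fmt(s.kurtosis_se),
                            _fmt(c.t_test["p"]),
                            _fmt(c.quartile_chi2.p),
                            _fmt(c.roc.auc),
                            _fmt(c.roc.ci_lower),
                            _fmt(c.roc.ci_upper),
                            _fmt(c.roc.p),
                        ]
                    )
                    + "\n"
                )

        if other:
            with open(
                out / f"tgs_other_comparisons_{sr.scheme}.tsv", "wt", encoding="utf-8"
            ) as fh:
                fh.write(header)
                for c in other:
                    s = c.case_summary
                    fh.write(
                        "\t".join(
                            [
                                c.name,
                                str(s.n),
                                _fmt(s.mean),
                                _fmt(s.sd),
                                _fmt(s.kurtosis),
                                _fmt(s.kurtosis_se),
                                _fmt(c.t_test["p"]),
                                _fmt(c.quartile_chi2.p),
                                _fmt(c.roc.auc),
                                _fmt(c.roc.ci_lower),
                                _fmt(c.roc.ci_upper),
                                _fmt(c.roc.p),
                            ]
                        )
                        + "\n"
                    )

        with open(out / f"tgs_histogram_{sr.scheme}.tsv", "wt", encoding="utf-8") as fh:
            fh.write("group\ttgs\tcount\n")
            for group in sorted(sr.histogram):
                for tgs in sorted(sr.histogram[group]):
                    fh.write(f"{group}\t{tgs}\t{sr.histogram[group][tgs]}\n")

    with open(out / "mdr_report.tsv", "wt", encoding="utf-8") as fh:
        fh.write("k\tcombination\tmean_training_ba\tmean_testing_ba\tcvc\tfolds\tbest\n")
        for k in sorted(report.mdr.by_size):
            m = report.mdr.by_size[k]
            fh.write(
                "\t".join(
                    [
                        str(k),
                        "+".join(m.combination),
                        _fmt(m.mean_training_ba),
                        _fmt(m.mean_testing_ba),
                        f"{m.cvc}/{m.folds}",
                        str(m.folds),
                        str(m.combination == report.mdr.best.combination),
                    ]
                )
                + "\n"
            )

    with open(out / "carrier_combination.tsv", "wt", encoding="utf-8") as fh:
        fh.write("group\tn\tcarriers\tproportion\tor_vs_baseline\tci_lower\tci_upper\n")
        for group, cf in report.combination.frequencies.items():
            orr = report.combination.odds_vs_baseline.get(group)
            fh.write(
                "\t".join(
                    [
                        group,
                        str(cf.n),
                        _fmt(cf.carriers),
                        _fmt(cf.proportion),
                        _fmt(orr.odds_ratio if orr else None),
                        _fmt(orr.ci_lower if orr else None),
                        _fmt(orr.ci_upper if orr else None),
                    ]
                )
                + "\n"
            )

    cfg = report.config
    lines = [
        f"tgsmdr {__version__} analysis report",
        f"seed: {cfg.seed}",
        f"input: {cfg.genotype_file or 'simulated cohort'}",
        f"schemes: {', '.join(cfg.schemes)}",
        f"comparisons: {', '.join(name for name, _, _ in cfg.comparisons)}",
        f"mdr: sizes {list(cfg.mdr_k_range)}, {cfg.mdr_folds}-fold CV, "
        f"attributes={cfg.mdr_attributes}",
        "",
        f"best MDR model: {'+'.join(report.mdr.best.combination)} "
        f"(testing BA {report.mdr.best.mean_testing_ba:.3f}, "
        f"CVC {report.mdr.best.cvc}/{report.mdr.best.folds})",
        "",
    ]
    for sr in report.schemes:
        lines.append(f"[{sr.scheme}] non-athlete mean (SD) TGS: "
                     f"{sr.baseline_summary.mean:.1f} ({sr.baseline_summary.sd:.1f})")
        for c in sr.comparisons:
            lines.append(
                f"[{sr.scheme}] {c.name}: mean {c.case_summary.mean:.1f} "
                f"(SD {c.case_summary.sd:.1f}), t-test p={c.t_test['p']:.3f}, "
                f"quartile chi2 p={c.quartile_chi2.p:.3f}, "
                f"AUC {c.roc.auc:.3f} ({c.roc.ci_lower:.3f}-{c.roc.ci_upper:.3f})"
            )
        lines.append("")
    combo = "+".join(f"{loc}:{al}" for loc, al in report.combination.pairs)
    for group, cf in report.combination.frequencies.items():
        orr = report.combination.odds_vs_baseline.get(group)
        suffix = f", OR {orr.odds_ratio:.2f} ({orr.ci_lower:.2f}-{orr.ci_upper:.2f})" if orr else ""
        lines.append(f"{combo} carriers in {group}: {100 * cf.proportion:.1f}%{suffix}")
    with open(out / "summary.txt", "wt", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
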