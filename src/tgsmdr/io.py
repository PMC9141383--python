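"""Tab-separated file dialects for genotype tables and frequency tables.

Genotype tables are TSV with a header row ``sample_id  group  <locus>...``,
genotypes as two adjacent allele characters (unordered; ``GA`` == ``AG``) and
missing calls as ``NA``.  Frequency tables are long-format TSV with columns
``group  locus  genotype  frequency [count]``; ``# group_size`` comment lines
carry the cohort sizes.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

from .cohort import CohortFrequencyTable
from .panel import DEFAULT_PANEL, GenotypeRecord, GenotypeError, Locus, panel_by_name

MISSING = "NA"

PathLike = Union[str, Path]


class FileFormatError(ValueError):
    """A structural problem with an input file (missing column, bad row)."""


def read_genotype_table(
    path: PathLike,
    panel: Sequence[Locus] = DEFAULT_PANEL,
) -> list[GenotypeRecord]:
    """Read a genotype TSV into records, canonicalising genotype spellings.

    Every panel locus must appear as a column; allele symbols outside a
    locus's declared pair raise :class:`~tgsmdr.panel.GenotypeError` naming
    the offending row and locus.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        return _read_genotype_stream(fh, panel, str(path))


def _read_genotype_stream(
    fh: TextIO, panel: Sequence[Locus], source: str
) -> list[GenotypeRecord]:
    header_line = fh.readline()
    if not header_line.strip():
        raise FileFormatError(f"{source}: empty file")
    header = header_line.rstrip("\n").split("\t")
    for required in ("sample_id", "group"):
        if required not in header:
            raise FileFormatError(f"{source}: missing required column {required!r}")
    col = {name: i for i, name in enumerate(header)}
    for locus in panel:
        if locus.name not in col:
            raise FileFormatError(f"{source}: missing required column {locus.name!r}")

    records = []
    for lineno, line in enumerate(fh, start=2):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != len(header):
            raise FileFormatError(
                f"{source}:{lineno}: expected {len(header)} fields, found {len(fields)}"
            )
        calls: dict[str, str | None] = {}
        for locus in panel:
            raw = fields[col[locus.name]].strip()
            if raw == MISSING or raw == "":
                calls[locus.name] = None
                continue
            try:
                calls[locus.name] = locus.canonical_genotype(raw)
            except GenotypeError as exc:
                raise GenotypeError(f"{source}:{lineno}: {exc}") from exc
        records.append(
            GenotypeRecord(
                sample_id=fields[col["sample_id"]],
                group=fields[col["group"]],
                calls=calls,
            )
        )
    return records


def write_genotype_table(
    records: Iterable[GenotypeRecord],
    path: PathLike,
    panel: Sequence[Locus] = DEFAULT_PANEL,
) -> None:
    names = [locus.name for locus in panel]
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(["sample_id", "group", *names]) + "\n")
        for r in records:
            row = [r.sample_id, r.group]
            row.extend(r.calls.get(n) or MISSING for n in names)
            fh.write("\t".join(row) + "\n")


def write_frequency_table(table: CohortFrequencyTable, path: PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for group, size in table.group_sizes.items():
            fh.write(f"# group_size\t{group}\t{size}\n")
        cols = ["group", "locus", "genotype", "frequency"]
        has_counts = table.counts is not None
        if has_counts:
            cols.append("count")
        fh.write("\t".join(cols) + "\n")
        for group, per_locus in table.frequencies.items():
            for locus, cats in per_locus.items():
                for cat, freq in cats.items():
                    row = [group, locus, cat, format(freq, ".10g")]
                    if has_counts:
                        row.append(str(table.counts[group][locus][cat]))
                    fh.write("\t".join(row) + "\n")


def read_frequency_table(path: PathLike) -> CohortFrequencyTable:
    with open(path, "rt", encoding="utf-8") as fh:
        return _read_frequency_stream(fh, str(path))


def _read_frequency_stream(fh: TextIO, source: str) -> CohortFrequencyTable:
    sizes: dict[str, int] = {}
    header: list[str] | None = None
    freqs: dict[str, dict[str, dict[str, float]]] = {}
    counts: dict[str, dict[str, dict[str, int]]] = {}
    have_counts = False
    by_name = panel_by_name()
    for lineno, line in enumerate(fh, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            parts = line.lstrip("# ").split("\t")
            if parts and parts[0] == "group_size" and len(parts) == 3:
                sizes[parts[1]] = int(parts[2])
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            for required in ("group", "locus", "genotype", "frequency"):
                if required not in header:
                    raise FileFormatError(f"{source}: missing required column {required!r}")
            have_counts = "count" in header
            continue
        row = dict(zip(header, fields))
        group, locus, cat = row["group"], row["locus"], row["genotype"]
        if locus in by_name:  # canonicalise genotype spellings for panel loci
            cat = by_name[locus].canonical_genotype(cat)
        freqs.setdefault(group, {}).setdefault(locus, {})[cat] = float(row["frequency"])
        if have_counts:
            counts.setdefault(group, {}).setdefault(locus, {})[cat] = int(row["count"])
    if header is None:
        raise FileFormatError(f"{source}: no header row")
    return CohortFrequencyTable(
        frequencies=freqs,
        group_sizes=sizes,
        counts=counts if have_counts else None,
    )


def load_published_frequencies() -> CohortFrequencyTable:
    """The packaged per-locus genotype frequency fixture for the elite rugby
    athlete (n = 635) and non-athlete (n = 722) cohorts, as published."""
    ref = resources.files("tgsmdr").joinpath("data/published_cohort_frequencies.tsv")
    with ref.open("rt", encoding="utf-8") as fh:
        return _read_frequency_stream(fh, str(ref))
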