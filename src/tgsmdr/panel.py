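"""Candidate-SNP panel, genotype records and APOE epsilon diplotype derivation.

The default panel is an eight-polymorphism concussion-candidate set spanning
six genes on six different chromosomes: ANKK1 rs1800497, the three APOE-region
variants rs429358 / rs7412 / rs405509, BDNF-AS rs6265, COMT rs4680, MAPT
rs10445337 and NOS3 rs2070744.  rs429358 and rs7412 jointly define the
tri-allelic APOE epsilon (e2/e3/e4) polymorphism; everything else is plain
bi-allelic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional


class GenotypeError(ValueError):
    """An allele or genotype inconsistent with the locus definition."""


class ApoeUnresolvableError(ValueError):
    """APOE SNP pair admits no diplotype free of the rare e1 haplotype."""


@dataclass(frozen=True)
class Locus:
    """A bi-allelic polymorphism in the panel.

    Parameters
    ----------
    name
        Working identifier, used as the column header in genotype tables
        (e.g. ``"COMT"``).
    rsid
        dbSNP identifier.
    alleles
        Ordered pair of single-character allele symbols; the order fixes the
        canonical genotype spelling (``"AG"``, never ``"GA"``).
    risk_allele
        Allele previously associated with the adverse phenotype, or
        ``"undetermined"``.
    """

    name: str
    rsid: str
    alleles: tuple[str, str]
    risk_allele: str = "undetermined"

    def __post_init__(self) -> None:
        if len(self.alleles) != 2 or self.alleles[0] == self.alleles[1]:
            raise ValueError(f"{self.name}: alleles must be two distinct symbols")
        if self.risk_allele != "undetermined" and self.risk_allele not in self.alleles:
            raise ValueError(f"{self.name}: risk allele {self.risk_allele!r} not in {self.alleles}")

    @property
    def genotypes(self) -> tuple[str, str, str]:
        """The three canonical genotype strings (hom1, het, hom2)."""
        a, b = self.alleles
        return (a + a, a + b, b + b)

    def canonical_genotype(self, genotype: str) -> str:
        """Normalise an unordered two-character genotype to canonical order.

        ``"GA"`` and ``"AG"`` map to the same string; allele symbols outside
        the locus definition raise :class:`GenotypeError`.
        """
        g = genotype.strip().upper()
        if len(g) != 2:
            raise GenotypeError(f"{self.name}: genotype {genotype!r} is not two allele symbols")
        for sym in g:
            if sym not in self.alleles:
                raise GenotypeError(
                    f"{self.name}: allele {sym!r} not in declared alleles {self.alleles}"
                )
        a, b = sorted(g, key=self.alleles.index)
        return a + b


#: The eight-polymorphism concussion-candidate panel.
DEFAULT_PANEL: tuple[Locus, ...] = (
    Locus("ANKK1", "rs1800497", ("A", "G"), risk_allele="A"),
    Locus("APOE_rs429358", "rs429358", ("C", "T"), risk_allele="C"),
    Locus("APOE_rs7412", "rs7412", ("C", "T"), risk_allele="undetermined"),
    Locus("APOE_rs405509", "rs405509", ("G", "T"), risk_allele="T"),
    Locus("BDNF_AS", "rs6265", ("C", "T"), risk_allele="T"),
    Locus("COMT", "rs4680", ("A", "G"), risk_allele="undetermined"),
    Locus("MAPT", "rs10445337", ("C", "T"), risk_allele="T"),
    Locus("NOS3", "rs2070744", ("C", "T"), risk_allele="C"),
)

#: Pseudo-locus name for the derived APOE epsilon-4 carrier attribute.
APOE_EPSILON = "APOE_e"
E4_PLUS = "e4+"
E4_MINUS = "e4-"


def panel_by_name(panel: Iterable[Locus] = DEFAULT_PANEL) -> dict[str, Locus]:
    return {locus.name: locus for locus in panel}


@dataclass
class GenotypeRecord:
    """One individual's called genotypes across the panel plus a group label.

    ``calls`` maps locus name to a canonical two-character genotype, or
    ``None`` for a missing call.
    """

    sample_id: str
    group: str
    calls: dict[str, Optional[str]] = field(default_factory=dict)

    def call(self, locus: str) -> Optional[str]:
        return self.calls.get(locus)

    def dosage(self, locus_name: str, allele: str) -> Optional[int]:
        """Copies of ``allele`` carried at a locus (0-2), or None if missing."""
        g = self.calls.get(locus_name)
        if g is None:
            return None
        return g.count(allele)


# APOE haplotypes over (rs429358, rs7412).  e1 = (C, T) is the rare fourth
# haplotype excluded by convention when an alternative phasing exists.
_HAPLOTYPE_TO_EPSILON = {("T", "T"): "e2", ("T", "C"): "e3", ("C", "C"): "e4", ("C", "T"): "e1"}

APOE_DIPLOTYPES = ("e2/e2", "e2/e3", "e2/e4", "e3/e3", "e3/e4", "e4/e4")


@dataclass(frozen=True)
class ApoeDiplotype:
    """One of the six APOE epsilon genotypes, with e4-carrier status."""

    value: str

    def __post_init__(self) -> None:
        if self.value not in APOE_DIPLOTYPES:
            raise ValueError(f"not an APOE epsilon diplotype: {self.value!r}")

    @property
    def e4_carrier(self) -> bool:
        return "e4" in self.value

    @property
    def carrier_category(self) -> str:
        return E4_PLUS if self.e4_carrier else E4_MINUS


def derive_apoe(
    rs429358: str,
    rs7412: str,
    *,
    ambiguous: str = "e2e4",
) -> ApoeDiplotype:
    """Derive the APOE epsilon diplotype from the rs429358 and rs7412 genotypes.

    The two C/T SNPs at codons 112 (rs429358) and 158 (rs7412) define the
    epsilon haplotypes e2 = (T, T), e3 = (T, C) and e4 = (C, C); the six
    diplotypes over {e2, e3, e4} are the classical APOE genotypes.

    Parameters
    ----------
    rs429358, rs7412
        Two-character unordered genotypes over {C, T}.
    ambiguous
        Policy for the doubly heterozygous call (C/T at both SNPs), whose
        phasings are e2/e4 or e1/e3.  ``"e2e4"`` (default) resolves to e2/e4,
        the standard convention that excludes the rare e1 haplotype;
        ``"exclude"`` raises :class:`ApoeUnresolvableError` instead.

    Raises
    ------
    ApoeUnresolvableError
        If every phasing involves the e1 haplotype (or the double
        heterozygote under ``ambiguous="exclude"``).
    """
    if ambiguous not in ("e2e4", "exclude"):
        raise ValueError(f"unknown ambiguity policy {ambiguous!r}")
    g1 = _apoe_snp_genotype(rs429358, "rs429358")
    g2 = _apoe_snp_genotype(rs7412, "rs7412")

    resolutions = set()
    for pairing in (((g1[0], g2[0]), (g1[1], g2[1])), ((g1[0], g2[1]), (g1[1], g2[0]))):
        eps = sorted(_HAPLOTYPE_TO_EPSILON[h] for h in pairing)
        resolutions.add("/".join(eps))
    clean = sorted(r for r in resolutions if "e1" not in r)
    if not clean:
        raise ApoeUnresolvableError(
            f"rs429358 {rs429358}/rs7412 {rs7412}: every phasing requires the e1 haplotype"
        )
    if len(clean) > 1:  # only the double heterozygote reaches here
        raise AssertionError("unreachable: at most one e1-free resolution exists")
    if clean[0] == "e2/e4" and g1[0] != g1[1] and g2[0] != g2[1] and ambiguous == "exclude":
        raise ApoeUnresolvableError(
            "rs429358 C/T with rs7412 C/T is phase-ambiguous (e2/e4 or e1/e3)"
        )
    return ApoeDiplotype(clean[0])


def _apoe_snp_genotype(genotype: str, which: str) -> tuple[str, str]:
    g = genotype.strip().upper()
    if len(g) != 2 or any(sym not in "CT" for sym in g):
        raise GenotypeError(f"{which}: genotype {genotype!r} must be two alleles from {{C,T}}")
    return (g[0], g[1])


def epsilon_to_snp_genotypes(diplotype: ApoeDiplotype | str) -> tuple[str, str]:
    """Back-convert an epsilon diplotype to (rs429358, rs7412) genotypes.

    Inverse of :func:`derive_apoe` on the six e1-free diplotypes, used by the
    cohort simulator.
    """
    value = diplotype.value if isinstance(diplotype, ApoeDiplotype) else diplotype
    eps_to_hap = {v: k for k, v in _HAPLOTYPE_TO_EPSILON.items()}
    h1, h2 = (eps_to_hap[e] for e in value.split("/"))
    by_name = panel_by_name()
    g429358 = by_name["APOE_rs429358"].canonical_genotype(h1[0] + h2[0])
    g7412 = by_name["APOE_rs7412"].canonical_genotype(h1[1] + h2[1])
    return g429358, g7412


def apoe_epsilon_category(
    record: GenotypeRecord, *, ambiguous: str = "e2e4"
) -> Optional[str]:
    """e4 carrier category ("e4+"/"e4-") for a record, or None if underivable.

    Returns None when either APOE SNP call is missing or the pair is
    unresolvable under the chosen ambiguity policy; callers treat such
    records as missing for epsilon-based scoring.
    """
    g1 = record.call("APOE_rs429358")
    g2 = record.call("APOE_rs7412")
    if g1 is None or g2 is None:
        return None
    try:
        return derive_apoe(g1, g2, ambiguous=ambiguous).carrier_category
    except ApoeUnresolvableError:
        return None
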