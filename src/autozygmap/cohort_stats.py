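"""Allele/carrier frequencies from genotype counts and recessive
segregation checks.

Frequencies are computed from raw genotype counts (no Hardy–Weinberg
modelling): for counts (n_hom_ref, n_het, n_hom_alt) the alternate-allele
frequency is (2·n_hom_alt + n_het) / (2·total).  Percentages render with one
decimal, rounding half away from zero.

The segregation check tests the recessive expectation at a candidate
variant: every affected animal homozygous-alternate, every genotyped parent
of an affected animal (an obligate carrier) heterozygous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

from .io import GT_HET, GT_HOM_ALT

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenotypeCounts:
    cohort: str
    n_hom_ref: int
    n_het: int
    n_hom_alt: int

    def __post_init__(self):
        if min(self.n_hom_ref, self.n_het, self.n_hom_alt) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt


@dataclass(frozen=True)
class SegregationReport:
    n_cases_concordant: int
    n_cases_discordant: int
    n_obligate_concordant: int
    n_obligate_discordant: int

    @property
    def overall_consistent(self) -> bool:
        return self.n_cases_discordant == 0 and self.n_obligate_discordant == 0


def allele_frequency(counts: GenotypeCounts) -> float:
    """Alternate-allele frequency (2·hom_alt + het) / (2·total)."""
    if counts.total == 0:
        raise ValueError(f"cohort {counts.cohort}: zero total count")
    return (2 * counts.n_hom_alt + counts.n_het) / (2 * counts.total)


def carrier_frequency(counts: GenotypeCounts) -> float:
    """Fraction of heterozygous carriers, n_het / total."""
    if counts.total == 0:
        raise ValueError(f"cohort {counts.cohort}: zero total count")
    return counts.n_het / counts.total


def format_percent(fraction: float) -> str:
    """Render a fraction as a percent string with one decimal, rounding half
    away from zero (0.08249 → '8.2%')."""
    pct = Decimal(str(fraction * 100)).quantize(Decimal("0.1"), ROUND_HALF_UP)
    return f"{pct}%"


def segregation_check(genotypes: Mapping[str, str], pedigree,
                      phenotypes: Mapping[str, str] | None = None
                      ) -> SegregationReport:
    """Test recessive genotype–phenotype co-segregation at one variant.

    ``genotypes`` maps sample id → genotype state; phenotypes come from the
    pedigree unless overridden.  Affected individuals must be hom-alt,
    genotyped parents of affected individuals het.  A genotyped individual
    with unknown phenotype that is not an obligate parent is left untested
    with a warning.
    """
    if phenotypes is None:
        phenotypes = {iid: pedigree[iid].phenotype
                      for iid in pedigree.individuals()}
    affected = [iid for iid, ph in phenotypes.items() if ph == "affected"]
    if not any(iid in genotypes for iid in affected):
        raise ValueError("no genotyped case available for segregation check")
    obligate = set()
    for iid in affected:
        if iid in pedigree:
            ind = pedigree[iid]
            for parent in (ind.sire, ind.dam):
                if parent is not None:
                    obligate.add(parent)

    cases_ok = cases_bad = obl_ok = obl_bad = 0
    for iid, g in genotypes.items():
        if iid in obligate:
            if g == GT_HET:
                obl_ok += 1
            else:
                obl_bad += 1
        elif phenotypes.get(iid) == "affected":
            if g == GT_HOM_ALT:
                cases_ok += 1
            else:
                cases_bad += 1
        elif phenotypes.get(iid, "unknown") == "unknown":
            log.warning("sample %s genotyped but phenotype unknown; untested", iid)
    return SegregationReport(n_cases_concordant=cases_ok,
                             n_cases_discordant=cases_bad,
                             n_obligate_concordant=obl_ok,
                             n_obligate_discordant=obl_bad)
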