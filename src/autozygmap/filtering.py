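"""Recessive private-variant filtering and minimal consequence annotation.

The filter encodes the classic mapping-by-sequencing criterion for a fully
penetrant recessive disorder: keep variants that are homozygous for the
alternate allele in *every* case and homozygous-alternate in *no* control
(heterozygous and reference-homozygous controls are allowed — carriers are
expected in the population).

Annotation is a deliberately small transcript-based consequence model: a
genomic position is mapped to a CDS coordinate across exons (strand-aware),
the affected codon is translated before and after the substitution with the
standard nuclear code, and HGVS-style ``c.``/``p.`` names are produced with
three-letter amino-acid codes (e.g. ``c.751G>A`` / ``p.Asp251Asn``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .io import (GT_HOM_ALT, GT_HOM_REF, GT_HET, GT_MISSING, TranscriptModel,
                 VariantRecord, normalize_chrom)
from .roh import SharedRegion

log = logging.getLogger(__name__)

SPLICE_REGION_BP = 2  # intronic positions this close to an exon edge

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


@dataclass(frozen=True)
class FilterPolicy:
    """Recessive private-variant filter: ids of cases and controls.

    ``max_control_genotype`` names the most severe control genotype tolerated
    (heterozygous); ``require_all_cases_hom_alt`` is the recessive clause.
    Both are fixed by the recessive model and exposed for report clarity.
    """

    case_ids: tuple[str, ...]
    control_ids: tuple[str, ...]
    max_control_genotype: str = GT_HET
    require_all_cases_hom_alt: bool = True

    def __post_init__(self):
        if not self.case_ids:
            raise ValueError("case id list must be non-empty")
        if not self.control_ids:
            raise ValueError("control id list must be non-empty")
        if set(self.case_ids) & set(self.control_ids):
            raise ValueError("case and control id sets must be disjoint")


@dataclass(frozen=True)
class Consequence:
    """Predicted effect of a coding or non-coding substitution."""

    klass: str                      # missense | synonymous | nonsense |
                                    # noncoding | splice_region_unsupported
    cds_pos: int | None = None
    codon_index: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    hgvs_c: str | None = None
    hgvs_p: str | None = None


def filter_recessive_private(variants: Sequence[VariantRecord],
                             policy: FilterPolicy) -> list[VariantRecord]:
    """Keep variants hom-alt in all cases and hom-alt in no control.

    A missing genotype in a case fails the variant (conservative); a missing
    control is ignored at that site.  Input order is preserved.
    """
    out = []
    for v in variants:
        if any(v.genotypes.get(c, GT_MISSING) != GT_HOM_ALT
               for c in policy.case_ids):
            continue
        if any(v.genotypes.get(c, GT_MISSING) == GT_HOM_ALT
               for c in policy.control_ids):
            continue
        out.append(v)
    return out


def annotate_region(variants: Sequence[VariantRecord],
                    regions: Sequence[SharedRegion]) -> None:
    """Flag each variant inside/outside each shared region (in place).

    Regions are closed intervals: a variant at the start or end position is
    inside.  Flags are keyed ``chrom:start-end``.
    """
    for v in variants:
        for r in regions:
            key = f"{r.chrom}:{r.start_bp}-{r.end_bp}"
            v.region_flags[key] = (normalize_chrom(r.chrom) == v.chrom
                                   and r.start_bp <= v.pos_bp <= r.end_bp)


def cds_position(genomic_pos: int, transcript: TranscriptModel) -> int | None:
    """1-based CDS coordinate of a genomic position, or None outside the CDS.

    On the minus strand the CDS is read from ``cds_end_bp`` backwards, so the
    caller must complement alleles before translating.
    """
    intervals = transcript.coding_intervals()
    if transcript.strand == "+":
        offset = 0
        for s, e in intervals:
            if s <= genomic_pos <= e:
                return offset + (genomic_pos - s) + 1
            offset += e - s + 1
    else:
        offset = 0
        for s, e in reversed(intervals):
            if s <= genomic_pos <= e:
                return offset + (e - genomic_pos) + 1
            offset += e - s + 1
    return None


def genomic_position(cds_pos: int, transcript: TranscriptModel) -> int:
    """Inverse of :func:`cds_position`; raises for out-of-range coordinates."""
    if cds_pos < 1 or cds_pos > transcript.cds_length():
        raise ValueError(f"cds_pos {cds_pos} outside CDS of length "
                         f"{transcript.cds_length()}")
    intervals = transcript.coding_intervals()
    remaining = cds_pos
    if transcript.strand == "+":
        for s, e in intervals:
            n = e - s + 1
            if remaining <= n:
                return s + remaining - 1
            remaining -= n
    else:
        for s, e in reversed(intervals):
            n = e - s + 1
            if remaining <= n:
                return e - remaining + 1
            remaining -= n
    raise AssertionError("unreachable")


def complement(base: str) -> str:
    return "".join(_COMPLEMENT[b] for b in base.upper())


def consequence_of(cds_pos: int, ref_base: str, alt_base: str,
                   coding_sequence: str) -> Consequence:
    """Classify a coding single-base substitution and name it in HGVS style.

    ``coding_sequence`` is the spliced, strand-oriented CDS (length divisible
    by 3, starting at c.1); ``ref_base`` must match it at ``cds_pos`` — a
    mismatch signals transcript/genome inconsistency and is an error.
    """
    cds = coding_sequence.upper()
    if len(cds) % 3 != 0:
        raise ValueError("coding sequence length must be divisible by 3")
    if not (1 <= cds_pos <= len(cds)):
        raise ValueError(f"cds_pos {cds_pos} outside coding sequence")
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if cds[cds_pos - 1] != ref_base:
        raise ValueError(
            f"reference mismatch at c.{cds_pos}: coding sequence has "
            f"{cds[cds_pos - 1]!r}, variant claims {ref_base!r}"
        )
    codon_index = (cds_pos - 1) // 3 + 1
    within = (cds_pos - 1) % 3
    codon = cds[(codon_index - 1) * 3: codon_index * 3]
    alt_codon = codon[:within] + alt_base + codon[within + 1:]
    ref_aa = str(Seq(codon).translate())   # standard nuclear code
    alt_aa = str(Seq(alt_codon).translate())
    ref_aa3, alt_aa3 = seq3(ref_aa), seq3(alt_aa)
    if alt_aa == "*":
        klass = "nonsense"
    elif ref_aa == alt_aa:
        klass = "synonymous"
    else:
        klass = "missense"
    return Consequence(
        klass=klass, cds_pos=cds_pos, codon_index=codon_index,
        ref_aa=ref_aa3, alt_aa=alt_aa3,
        hgvs_c=f"c.{cds_pos}{ref_base}>{alt_base}",
        hgvs_p=f"p.{ref_aa3}{codon_index}{alt_aa3}",
    )


def _noncoding_class(pos: int, transcript: TranscriptModel) -> str:
    """noncoding, or splice_region_unsupported for near-exon intronic bases."""
    first, last = transcript.exons[0][0], transcript.exons[-1][1]
    if first <= pos <= last and not any(s <= pos <= e for s, e in transcript.exons):
        for s, e in transcript.exons:
            if 0 < s - pos <= SPLICE_REGION_BP or 0 < pos - e <= SPLICE_REGION_BP:
                return "splice_region_unsupported"
    return "noncoding"


def annotate_consequences(variants: Sequence[VariantRecord],
                          transcript: TranscriptModel,
                          coding_sequence: str) -> None:
    """Attach a Consequence to each SNV (in place).

    Variants off the transcript's chromosome or outside the CDS are
    ``noncoding`` (intronic bases within 2 bp of an exon edge are labelled
    ``splice_region_unsupported``).  Indels get no Consequence — the model
    names substitutions only — and are never counted protein-changing.
    """
    tchrom = normalize_chrom(transcript.chrom)
    for v in variants:
        if not v.is_snv:
            v.consequence = None
            continue
        if v.chrom != tchrom:
            v.consequence = Consequence(klass="noncoding")
            continue
        cpos = cds_position(v.pos_bp, transcript)
        if cpos is None:
            v.consequence = Consequence(klass=_noncoding_class(v.pos_bp, transcript))
            continue
        ref, alt = v.ref, v.alt
        if transcript.strand == "-":
            ref, alt = complement(ref), complement(alt)
        v.consequence = consequence_of(cpos, ref, alt, coding_sequence)


def protein_changing(variants: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Subset of annotated variants whose class is missense or nonsense."""
    return [v for v in variants
            if v.consequence is not None
            and v.consequence.klass in ("missense", "nonsense")]
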