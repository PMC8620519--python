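"""Readers and writers for the external file formats of the pipeline.

Formats handled here:

* PLINK-style text PED plus a 6-column MAP dialect (chrom, id, cM, pos,
  allele_a, allele_b — i.e. a ``.bim``-like text map, because genotype codes
  are defined against declared alleles, not against whatever allele happens
  to be observed first);
* VCF 4.x with GT fields (read through :mod:`cyvcf2`, written as plain text);
* pedigree TSV (id, sire, dam[, sex], phenotype; ``0`` or empty = unknown);
* a genePred-like one-row transcript TSV plus a coding-sequence FASTA;
* cohort genotype-count TSV (cohort, n_hom_ref, n_het, n_hom_alt);
* a two-column per-sample genotyping TSV for single-variant assays.

Coordinates are 1-based inclusive throughout.  Chromosome labels are opaque
strings normalised by stripping a leading ``chr``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

log = logging.getLogger(__name__)

# Genotype codes for array data (GenotypeMatrix.codes).
HOM_A = 0   # homozygous for allele_a
HET = 1
HOM_B = 2   # homozygous for allele_b
MISSING = -1

# Genotype states for sequence variants (VariantRecord.genotypes values).
GT_HOM_REF = "hom_ref"
GT_HET = "het"
GT_HOM_ALT = "hom_alt"
GT_MISSING = "missing"
GT_STATES = frozenset({GT_HOM_REF, GT_HET, GT_HOM_ALT, GT_MISSING})

SEX_CHROMS = frozenset({"X", "Y", "x", "y", "30", "31"})


def normalize_chrom(label: str) -> str:
    """Strip a leading ``chr`` so that ``chr14`` and ``14`` compare equal."""
    return label[3:] if label.lower().startswith("chr") else label


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass(frozen=True)
class Marker:
    """One biallelic array marker at a 1-based physical position."""

    chrom: str
    pos_bp: int
    id: str
    allele_a: str
    allele_b: str

    def __post_init__(self):
        if self.pos_bp < 1:
            raise ValueError(f"marker {self.id}: pos_bp must be >= 1")
        if self.allele_a == self.allele_b:
            raise ValueError(f"marker {self.id}: alleles must differ")


@dataclass(frozen=True)
class SampleInfo:
    id: str
    cohort: str = "population_control"   # case | obligate_parent | population_control
    phenotype: str = "unknown"           # affected | unaffected | unknown

    def __post_init__(self):
        if self.cohort == "case" and self.phenotype != "affected":
            raise ValueError(f"sample {self.id}: every case must be affected")


@dataclass
class GenotypeMatrix:
    """samples x markers biallelic genotype codes for ROH scanning.

    ``codes`` is an ``int8`` array with entries in {HOM_A, HET, HOM_B,
    MISSING}; rows follow ``samples``, columns follow ``markers`` (sorted by
    position within each chromosome).
    """

    samples: list[str]
    markers: list[Marker]
    codes: np.ndarray

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.codes, (HOM_A, HET, HOM_B, MISSING))
        if bad.any():
            raise ValueError("genotype codes outside {0,1,2,MISSING}")
        seen = set()
        for m in self.markers:
            if m.id in seen:
                raise ValueError(f"duplicate marker id {m.id}")
            seen.add(m.id)
        for chrom, idx in self.chrom_indices().items():
            pos = [self.markers[i].pos_bp for i in idx]
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise ValueError(f"markers on {chrom} not strictly sorted by position")

    def chrom_indices(self) -> dict[str, list[int]]:
        """Column indices per chromosome, in storage order."""
        out: dict[str, list[int]] = {}
        for i, m in enumerate(self.markers):
            out.setdefault(m.chrom, []).append(i)
        return out

    def sample_row(self, sample_id: str) -> np.ndarray:
        return self.codes[self.samples.index(sample_id)]

    def drop_sex_chromosomes(self) -> "GenotypeMatrix":
        keep = [i for i, m in enumerate(self.markers) if m.chrom not in SEX_CHROMS]
        return GenotypeMatrix(
            samples=list(self.samples),
            markers=[self.markers[i] for i in keep],
            codes=self.codes[:, keep],
        )


@dataclass
class TranscriptModel:
    """Minimal gene model: ordered exons plus genomic CDS bounds.

    Exons are 1-based inclusive ``[start, end]`` intervals in genomic order
    regardless of strand; ``strand`` decides the reading direction.
    """

    gene: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start_bp: int
    cds_end_bp: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"exon [{s},{e}] reversed")
            if s <= prev_end:
                raise ValueError("exons overlap or are unsorted")
            prev_end = e
        if self.cds_start_bp > self.cds_end_bp:
            raise ValueError("cds_start_bp > cds_end_bp")
        for bound in (self.cds_start_bp, self.cds_end_bp):
            if not any(s <= bound <= e for s, e in self.exons):
                raise ValueError(f"CDS bound {bound} not inside any exon")
        if self.cds_length() % 3 != 0:
            raise ValueError(f"CDS length {self.cds_length()} not divisible by 3")

    def coding_intervals(self) -> list[tuple[int, int]]:
        """Exon pieces intersected with the CDS, in genomic order."""
        out = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start_bp), min(e, self.cds_end_bp)
            if lo <= hi:
                out.append((lo, hi))
        return out

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.coding_intervals())


@dataclass
class VariantRecord:
    """One biallelic sequence variant with per-sample genotype states."""

    chrom: str
    pos_bp: int
    ref: str
    alt: str
    genotypes: dict[str, str] = field(default_factory=dict)
    consequence: object | None = None          # filled by variant_filtering
    region_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        self.chrom = normalize_chrom(self.chrom)
        if self.pos_bp < 1:
            raise ValueError("pos_bp must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        for s, g in self.genotypes.items():
            if g not in GT_STATES:
                raise ValueError(f"sample {s}: bad genotype state {g!r}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos_bp, self.ref, self.alt)


# ---------------------------------------------------------------------------
# PED / MAP
# ---------------------------------------------------------------------------

def read_map(map_path: str | Path) -> list[Marker]:
    markers = []
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        f = line.split()
        if len(f) != 6:
            raise FormatError(
                f"{map_path}:{ln}: expected 6 columns "
                "(chrom id cM pos allele_a allele_b), got " + str(len(f))
            )
        markers.append(
            Marker(chrom=normalize_chrom(f[0]), pos_bp=int(f[3]), id=f[1],
                   allele_a=f[4], allele_b=f[5])
        )
    return markers


def _sort_markers(markers: Sequence[Marker]) -> list[int]:
    """Storage order: chromosomes in order of first appearance, positions ascending."""
    chrom_order: dict[str, int] = {}
    for m in markers:
        chrom_order.setdefault(m.chrom, len(chrom_order))
    return sorted(range(len(markers)),
                  key=lambda i: (chrom_order[markers[i].chrom], markers[i].pos_bp))


_PHENO = {"2": "affected", "1": "unaffected"}


def read_pedmap(ped_path: str | Path, map_path: str | Path
                ) -> tuple[GenotypeMatrix, list[SampleInfo]]:
    """Load a PED/MAP pair into a GenotypeMatrix plus sample metadata.

    ``0 0`` allele pairs become MISSING; any allele not matching the marker's
    declared pair is an error naming both marker and sample.
    """
    raw_markers = read_map(map_path)
    order = _sort_markers(raw_markers)
    markers = [raw_markers[i] for i in order]

    samples: list[str] = []
    infos: list[SampleInfo] = []
    rows: list[np.ndarray] = []
    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        f = line.split()
        if len(f) != 6 + 2 * len(raw_markers):
            raise FormatError(
                f"{ped_path}: row {ln}: expected {6 + 2 * len(raw_markers)} "
                f"fields for {len(raw_markers)} markers, got {len(f)}"
            )
        sid = f[1]
        pheno = _PHENO.get(f[5], "unknown")
        infos.append(SampleInfo(
            id=sid,
            cohort="case" if pheno == "affected" else "population_control",
            phenotype=pheno,
        ))
        samples.append(sid)
        row = np.empty(len(raw_markers), dtype=np.int8)
        for j, m in enumerate(raw_markers):
            a1, a2 = f[6 + 2 * j], f[7 + 2 * j]
            if a1 == "0" and a2 == "0":
                row[j] = MISSING
                continue
            code = 0
            for a in (a1, a2):
                if a == m.allele_b:
                    code += 1
                elif a != m.allele_a:
                    raise FormatError(
                        f"{ped_path}: sample {sid}, marker {m.id}: allele {a!r} "
                        f"not in declared pair ({m.allele_a},{m.allele_b})"
                    )
            row[j] = code
        rows.append(row[order])
    codes = np.vstack(rows) if rows else np.empty((0, len(markers)), dtype=np.int8)
    return GenotypeMatrix(samples=samples, markers=markers, codes=codes), infos


def write_pedmap(gmatrix: GenotypeMatrix, infos: Iterable[SampleInfo],
                 ped_path: str | Path, map_path: str | Path) -> None:
    info_by_id = {i.id: i for i in infos}
    with open(map_path, "w") as fh:
        for m in gmatrix.markers:
            fh.write(f"{m.chrom}\t{m.id}\t0\t{m.pos_bp}\t{m.allele_a}\t{m.allele_b}\n")
    pheno_code = {"affected": "2", "unaffected": "1", "unknown": "0"}
    with open(ped_path, "w") as fh:
        for si, sid in enumerate(gmatrix.samples):
            info = info_by_id.get(sid, SampleInfo(id=sid))
            fields = ["FAM", sid, "0", "0", "0", pheno_code[info.phenotype]]
            for mi, m in enumerate(gmatrix.markers):
                c = gmatrix.codes[si, mi]
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == HOM_A:
                    fields += [m.allele_a, m.allele_a]
                elif c == HET:
                    fields += [m.allele_a, m.allele_b]
                else:
                    fields += [m.allele_b, m.allele_b]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Parse biallelic SNVs/indels from a VCF 4.x with GT fields.

    Multiallelic rows are skipped with a logged warning (the analysis targets
    biallelic variants); ``./.`` becomes the missing state.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    out: list[VariantRecord] = []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            log.warning("skipping multiallelic row %s:%d (%s -> %s)",
                        v.CHROM, v.POS, v.REF, ",".join(v.ALT))
            continue
        if v.format("GT") is None and not samples:
            raise FormatError(f"{path}: row {v.CHROM}:{v.POS} has no GT field")
        gt_types = v.gt_types  # 0=hom_ref 1=het 2=hom_alt 3=missing (gts012)
        gts = {}
        for s, t in zip(samples, gt_types):
            gts[s] = (GT_HOM_REF, GT_HET, GT_HOM_ALT, GT_MISSING)[t]
        out.append(VariantRecord(chrom=v.CHROM, pos_bp=v.POS,
                                 ref=v.REF, alt=v.ALT[0], genotypes=gts))
    if n_multi:
        log.warning("skipped %d multiallelic rows in %s", n_multi, path)
    return out


_GT_FIELD = {GT_HOM_REF: "0/0", GT_HET: "0/1", GT_HOM_ALT: "1/1", GT_MISSING: "./."}


def write_vcf(variants: Sequence[VariantRecord], samples: Sequence[str],
              path: str | Path, contigs: dict[str, int] | None = None) -> None:
    """Write variants as minimal VCF 4.2 text with GT-only genotypes."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=autozygmap\n")
        for chrom, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for v in sorted(variants, key=lambda r: (r.chrom, r.pos_bp)):
            gts = "\t".join(_GT_FIELD[v.genotypes.get(s, GT_MISSING)] for s in samples)
            fh.write(f"{v.chrom}\t{v.pos_bp}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Pedigree / transcript / counts / genotyping tables
# ---------------------------------------------------------------------------

def read_pedigree(path: str | Path):
    """Load a pedigree TSV (id, sire, dam[, sex], phenotype) into a Pedigree."""
    from .pedigree import Pedigree

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("0")
    required = {"id", "sire", "dam"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: pedigree needs columns id, sire, dam")
    ped = Pedigree()
    for _, row in df.iterrows():
        ped.add(
            row["id"],
            sire=None if row["sire"] in ("0", "") else row["sire"],
            dam=None if row["dam"] in ("0", "") else row["dam"],
            phenotype=row.get("phenotype", "unknown") or "unknown",
        )
    ped.validate()
    return ped


def write_pedigree(ped, path: str | Path) -> None:
    rows = []
    for iid in ped.individuals():
        ind = ped[iid]
        rows.append({"id": iid, "sire": ind.sire or "0", "dam": ind.dam or "0",
                     "phenotype": ind.phenotype})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_transcript(path: str | Path) -> TranscriptModel:
    """Load a one-row genePred-like transcript TSV; invariants enforced."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"gene", "chrom", "strand", "cds_start", "cds_end",
            "exon_starts", "exon_ends"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: transcript table needs columns {sorted(need)}")
    row = df.iloc[0]
    starts = [int(x) for x in str(row["exon_starts"]).rstrip(",").split(",")]
    ends = [int(x) for x in str(row["exon_ends"]).rstrip(",").split(",")]
    if len(starts) != len(ends):
        raise FormatError(f"{path}: exon start/end count mismatch")
    return TranscriptModel(
        gene=row["gene"], chrom=normalize_chrom(row["chrom"]), strand=row["strand"],
        exons=list(zip(starts, ends)),
        cds_start_bp=int(row["cds_start"]), cds_end_bp=int(row["cds_end"]),
    )


def write_transcript(t: TranscriptModel, path: str | Path) -> None:
    pd.DataFrame([{
        "gene": t.gene, "chrom": t.chrom, "strand": t.strand,
        "cds_start": t.cds_start_bp, "cds_end": t.cds_end_bp,
        "exon_starts": ",".join(str(s) for s, _ in t.exons),
        "exon_ends": ",".join(str(e) for _, e in t.exons),
    }]).to_csv(path, sep="\t", index=False)


def read_cohort_counts(path: str | Path):
    """Load cohort genotype-count rows (cohort, n_hom_ref, n_het, n_hom_alt)."""
    from .cohort_stats import GenotypeCounts

    df = pd.read_csv(path, sep="\t")
    need = {"cohort", "n_hom_ref", "n_het", "n_hom_alt"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: cohort counts need columns {sorted(need)}")
    return [GenotypeCounts(cohort=r["cohort"], n_hom_ref=int(r["n_hom_ref"]),
                           n_het=int(r["n_het"]), n_hom_alt=int(r["n_hom_alt"]))
            for _, r in df.iterrows()]


def write_cohort_counts(counts, path: str | Path) -> None:
    pd.DataFrame([{"cohort": c.cohort, "n_hom_ref": c.n_hom_ref,
                   "n_het": c.n_het, "n_hom_alt": c.n_hom_alt}
                  for c in counts]).to_csv(path, sep="\t", index=False)


def read_genotyping_table(path: str | Path) -> dict[str, str]:
    """Per-sample genotype calls of a single-variant assay (sample, genotype)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "genotype"}.issubset(df.columns):
        raise FormatError(f"{path}: genotyping table needs columns sample, genotype")
    out = {}
    for _, r in df.iterrows():
        g = r["genotype"]
        if g not in GT_STATES:
            raise FormatError(f"{path}: sample {r['sample']}: bad genotype {g!r}")
        out[r["sample"]] = g
    return out


def write_genotyping_table(genotypes: dict[str, str], path: str | Path) -> None:
    pd.DataFrame([{"sample": s, "genotype": g} for s, g in genotypes.items()]
                 ).to_csv(path, sep="\t", index=False)
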