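"""Gene-drop simulator producing study-shaped inputs with known truth.

The generator plants a single founder carrier of a recessive causal variant
at the top of a multi-generation pedigree and drops haplotypes through it
with per-meiosis recombination (Haldane model: Poisson crossover counts,
uniform positions).  All cases descend from the founder through a common
carrier backbone chain with per-case dedicated carrier parents, so the
mutant haplotype is eroded mostly by each case's final meioses — the
structure that lets a dozen deep cases still share a multi-megabase
autozygous segment, as observed in real single-origin recessive outbreaks.

Transmission along designated carrier paths is conditioned to pass the
mutant allele (the complementary gamete is taken when the random one does
not carry it), which preserves the recombination process while guaranteeing
the case/carrier structure.  Descent is tracked exactly through founder-
haplotype segment ids; the per-case true autozygous segment and carrier
states recorded in :class:`SimTruth` are therefore exact, not inferred.

Outputs: an array panel (PED/MAP) for the cases, a WGS-style VCF for the
sequenced cases plus controls (one coding causal variant, linked non-coding
private variants on the founder haplotype, background polymorphism), the
pedigree table, a synthetic transcript model with its coding sequence, a
single-variant genotyping table (cases + parents), and population cohort
genotype counts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as aio
from .filtering import genomic_position
from .io import (GT_HET, GT_HOM_ALT, GT_HOM_REF, GenotypeMatrix, Marker,
                 SampleInfo, TranscriptModel, VariantRecord)
from .pedigree import Pedigree

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped scenario: defaults mirror the mapped outbreak's cohort
    structure (12 cases, 3 sequenced, 567 WGS controls, a 2952-animal
    population cohort at 8.2% allele frequency, founder 8–11 generations up,
    ~2.5 Mb target shared haplotype, 34 linked non-coding private variants).
    """

    seed: int
    n_cases: int = 12
    n_sequenced_cases: int = 3
    n_controls_wgs: int = 567
    population_n: int = 2952
    target_allele_freq: float = 0.082
    depth_min: int = 8
    depth_max: int = 11
    n_founders: int | None = None           # None = exactly as many as needed
    chrom_lengths: dict = field(
        default_factory=lambda: {"14": 12_000_000, "11": 8_000_000})
    causal_chrom: str = "14"
    causal_pos: int = 6_000_000
    shared_hap_target_bp: int = 2_500_000
    marker_density_per_mb: float = 100.0
    recomb_rate_cm_per_mb: float = 1.0
    genotyping_error_rate: float = 0.001
    n_linked_noncoding_private: int = 34
    n_background_variants: int = 300
    control_carrier_rate: float = 0.02
    plant_selection_signature: bool = True  # fixed homozygous block on chr 11

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0 <= self.genotyping_error_rate <= 0.1):
            raise ValueError("genotyping error rate must be in [0, 0.1]")
        for name in ("n_cases", "n_sequenced_cases", "n_controls_wgs",
                     "population_n", "n_linked_noncoding_private"):
            if getattr(self, name) < 0 or (name in ("n_cases", "population_n")
                                           and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if self.n_sequenced_cases > self.n_cases:
            raise ValueError("n_sequenced_cases exceeds n_cases")
        if not (1 <= self.depth_min <= self.depth_max):
            raise ValueError("need 1 <= depth_min <= depth_max")
        if self.causal_chrom not in self.chrom_lengths:
            raise ValueError("causal chromosome missing from chrom_lengths")
        if not (1 <= self.causal_pos <= self.chrom_lengths[self.causal_chrom]):
            raise ValueError("causal position outside its chromosome")


@dataclass
class SimTruth:
    """Planted ground truth used as the acceptance oracle."""

    causal_chrom: str
    causal_pos: int
    causal_ref: str
    causal_alt: str
    founder_id: str
    mutant_copies: dict            # individual id -> 0/1/2 at the causal locus
    case_segments: dict            # case id -> (start_bp, end_bp) true autozygous
    founder_depths: dict           # case id -> sorted list of path lengths
    linked_positions: list         # planted linked non-coding private variants
    case_ids: list
    sequenced_case_ids: list

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


@dataclass
class SimResult:
    """Everything the generator produced, in memory."""

    config: SimConfig
    pedigree: Pedigree
    truth: SimTruth
    gmatrix: GenotypeMatrix            # array panel for the cases
    sample_infos: list
    variants: list                     # VCF records (sequenced cases + controls)
    vcf_samples: list
    transcript: TranscriptModel
    coding_sequence: str
    genotyping: dict                   # causal-variant assay: cases + parents
    cohort_counts: list


# ---------------------------------------------------------------------------
# pedigree construction
# ---------------------------------------------------------------------------

def build_pedigree(config: SimConfig, rng: np.random.Generator | None = None
                   ) -> tuple[Pedigree, str, dict]:
    """Build the carrier-backbone pedigree; returns (pedigree, founder id,
    forced-transmission map child -> [carrier parents]).

    The founder couple heads a chain of carrier individuals K1..K_{depth_max-2};
    each case gets dedicated carrier parents bred from chain members chosen so
    the case's path lengths to the founder fall inside [depth_min, depth_max],
    with the extremes guaranteed to occur.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if config.depth_min < 2:
        raise ValueError("infeasible config: chain design needs depth_min >= 2")
    chain_len = max(config.depth_max - 2, 0)
    # founders used: founder couple + chain mates + one mate per case parent
    needed = 2 + chain_len + 2 * config.n_cases
    if config.n_founders is not None and config.n_founders < needed:
        raise ValueError(
            f"infeasible config: {needed} founders needed, {config.n_founders} allowed")

    ped = Pedigree()
    founder = "F0"
    ped.add(founder)
    ped.add("M0")
    forced: dict[str, list[str]] = {}   # child -> parents that must pass mutant

    chain = []
    prev = founder
    prev_mate = "M0"
    for d in range(1, chain_len + 1):
        kid = f"K{d}"
        ped.add(kid, sire=prev, dam=prev_mate, phenotype="unaffected")
        forced[kid] = [prev]
        mate = f"KM{d}"
        ped.add(mate)
        chain.append(kid)
        prev, prev_mate = kid, mate

    # case depths: cycle through [depth_min, depth_max] so the full range is
    # realised, then shuffle assignment across cases
    span = list(range(config.depth_min, config.depth_max + 1))
    depths = [(span[i % len(span)], span[(i + 1) % len(span)])
              for i in range(config.n_cases)]
    rng.shuffle(depths)

    cases = []
    for i, (ds, dd) in enumerate(depths, 1):
        sire, dam = f"S{i}", f"D{i}"
        # parent of the case sits at depth ds-1: child of chain member K_{ds-2}
        # (or of the founder directly when ds == 2)
        ks = chain[ds - 3] if ds >= 3 else founder
        kd = chain[dd - 3] if dd >= 3 else founder
        ped.add(sire, sire=ks, dam=f"SM{i}", phenotype="unaffected")
        ped.add(f"SM{i}")
        forced[sire] = [ks]
        ped.add(dam, sire=kd, dam=f"DM{i}", phenotype="unaffected")
        ped.add(f"DM{i}")
        forced[dam] = [kd]
        case = f"case{i}"
        ped.add(case, sire=sire, dam=dam, phenotype="affected")
        forced[case] = [sire, dam]
        cases.append(case)

    ped.validate()
    return ped, founder, forced


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------
# A haplotype is a list of (start_bp, end_bp, founder_hap_id) segments
# covering [1, L]; founder haplotype ids are globally unique, so descent is
# exact.

Hap = list  # list[tuple[int, int, int]]


def _meiosis(hap1: Hap, hap2: Hap, length: int, rate_cm_per_mb: float,
             rng: np.random.Generator) -> tuple[Hap, Hap]:
    """One meiosis: returns the sampled gamete and its complement.

    Crossover count ~ Poisson(map length in Morgans), positions uniform
    (Haldane, no interference).
    """
    morgans = rate_cm_per_mb * (length / 1e6) / 100.0
    n_x = rng.poisson(morgans)
    cuts = sorted(int(p) + 1 for p in rng.uniform(0, length, size=n_x))
    first = rng.integers(2)

    def build(start_with: int) -> Hap:
        gamete: Hap = []
        bounds = [1] + cuts + [length + 1]
        src = start_with
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if lo >= hi:
                src ^= 1
                continue
            source = hap1 if src == 0 else hap2
            for s, e, fid in source:
                a, b = max(s, lo), min(e, hi - 1)
                if a <= b:
                    gamete.append((a, b, fid))
            src ^= 1
        return gamete

    return build(first), build(first ^ 1)


def _source_at(hap: Hap, pos: int) -> int:
    for s, e, fid in hap:
        if s <= pos <= e:
            return fid
    raise ValueError(f"position {pos} not covered by haplotype")


def _founder_interval_at(hap: Hap, pos: int) -> tuple[int, int] | None:
    for s, e, fid in hap:
        if s <= pos <= e:
            return (s, e)
    return None


def gene_drop(pedigree: Pedigree, founder: str, forced: dict, config: SimConfig,
              rng: np.random.Generator | None = None
              ) -> tuple[dict, dict, int]:
    """Drop haplotypes through the pedigree on every chromosome.

    Returns (diplotypes, mutant-copy counts, mutant founder haplotype id).
    ``diplotypes[iid][chrom] = (hap, hap)``.  Along forced edges the gamete
    carrying the founder's mutant haplotype at the causal locus is taken
    (the complementary gamete when the sampled one does not carry it).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    order = []
    remaining = set(pedigree.individuals())
    while remaining:   # parents before children
        batch = [i for i in sorted(remaining)
                 if all(p not in remaining for p in pedigree.parents(i))]
        order.extend(batch)
        remaining -= set(batch)

    next_fid = 0
    diplo: dict[str, dict[str, tuple[Hap, Hap]]] = {}
    mutant_fid = None
    for iid in order:
        parents = pedigree.parents(iid)
        diplo[iid] = {}
        if not parents:
            # one haplotype-id pair per founder, shared across chromosomes
            for chrom, L in config.chrom_lengths.items():
                diplo[iid][chrom] = ([(1, L, next_fid)], [(1, L, next_fid + 1)])
            if iid == founder:
                mutant_fid = next_fid       # founder's first haplotype is mutant
            next_fid += 2
        else:
            ind = pedigree[iid]
            gametes = {}
            L_causal = config.chrom_lengths[config.causal_chrom]
            half = config.shared_hap_target_bp // 2
            window = (max(1, config.causal_pos - half),
                      min(L_causal, config.causal_pos + half))
            for pid in (ind.sire, ind.dam):
                for chrom, L in config.chrom_lengths.items():
                    if (chrom == config.causal_chrom
                            and pid in forced.get(iid, [])):
                        # condition on transmitting the mutant copy with the
                        # planted haplotype window intact (the ascertainment a
                        # single-origin case cohort embodies); rejection is
                        # rare at realistic map lengths
                        h1, h2 = diplo[pid][chrom]
                        g = None
                        for _ in range(1000):
                            cand, comp = _meiosis(h1, h2, L,
                                                  config.recomb_rate_cm_per_mb, rng)
                            if not _descends(cand, config.causal_pos, mutant_fid):
                                cand = comp
                            iv = _mutant_interval(cand, config.causal_pos, mutant_fid)
                            if iv and iv[0] <= window[0] and iv[1] >= window[1]:
                                g = cand
                                break
                        if g is None:   # pathological window/rate combinations
                            g = cand
                    else:
                        h1, h2 = diplo[pid][chrom]
                        g, _ = _meiosis(h1, h2, L, config.recomb_rate_cm_per_mb, rng)
                    gametes.setdefault(chrom, []).append(g)
            for chrom in config.chrom_lengths:
                diplo[iid][chrom] = tuple(gametes[chrom])

    copies = {}
    for iid in order:
        h1, h2 = diplo[iid][config.causal_chrom]
        copies[iid] = int(_descends(h1, config.causal_pos, mutant_fid)) + \
            int(_descends(h2, config.causal_pos, mutant_fid))
    return diplo, copies, mutant_fid


def _descends(hap: Hap, pos: int, mutant_fid: int) -> bool:
    return _source_at(hap, pos) == mutant_fid


def _mutant_interval(hap: Hap, pos: int, mutant_fid: int
                     ) -> tuple[int, int] | None:
    """Contiguous mutant-descent interval containing ``pos`` (merges
    adjacent mutant segments)."""
    segs = sorted((s, e) for s, e, fid in hap if fid == mutant_fid)
    merged: list[list[int]] = []
    for s, e in segs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    for s, e in merged:
        if s <= pos <= e:
            return (s, e)
    return None


def _autozygous_segment(diplo_chrom: tuple[Hap, Hap], pos: int,
                        mutant_fid: int) -> tuple[int, int] | None:
    """Interval around ``pos`` where both haplotypes descend from the mutant
    founder haplotype."""
    ivs = []
    for hap in diplo_chrom:
        iv = _mutant_interval(hap, pos, mutant_fid)
        if iv is None:
            return None
        ivs.append(iv)
    lo = max(s for s, _ in ivs)
    hi = min(e for _, e in ivs)
    return (lo, hi) if lo <= hi else None


# ---------------------------------------------------------------------------
# transcript + coding sequence
# ---------------------------------------------------------------------------

_SENSE_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES
                 if a + b + c not in ("TAA", "TAG", "TGA")]


def build_transcript(config: SimConfig, rng: np.random.Generator
                     ) -> tuple[TranscriptModel, str]:
    """Synthetic 18-exon plus-strand gene model positioned so that CDS
    position 751 (codon 251, set to GAT/Asp) lies exactly at the causal
    genomic position.  Coding sequence: ATG start, random sense codons, TAA
    stop; 810 codons (2430 bp)."""
    coding_lengths = [120] * 5 + [180] + [138] * 11 + [132]   # sums to 2430
    introns = [int(rng.integers(2000, 6000)) for _ in range(17)]
    utr5, utr3 = 50, 100

    exons, pos = [], 1
    for i, clen in enumerate(coding_lengths):
        elen = clen + (utr5 if i == 0 else 0) + (utr3 if i == 17 else 0)
        exons.append((pos, pos + elen - 1))
        if i < 17:
            pos = exons[-1][1] + 1 + introns[i]
    cds_start = exons[0][0] + utr5
    cds_end = exons[-1][1] - utr3

    t = TranscriptModel(gene="GENE1", chrom=config.causal_chrom, strand="+",
                        exons=exons, cds_start_bp=cds_start, cds_end_bp=cds_end)
    shift = config.causal_pos - genomic_position(751, t)
    t = TranscriptModel(gene="GENE1", chrom=t.chrom, strand="+",
                        exons=[(s + shift, e + shift) for s, e in t.exons],
                        cds_start_bp=cds_start + shift, cds_end_bp=cds_end + shift)

    codons = ["ATG"] + [str(_SENSE_CODONS[i])
                        for i in rng.integers(0, len(_SENSE_CODONS), size=808)] + ["TAA"]
    codons[250] = "GAT"   # codon 251: aspartate, c.751 = G
    cds = "".join(codons)
    assert len(cds) == t.cds_length() == 2430 and cds[750] == "G"
    return t, cds


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig) -> SimResult:
    """Run the full generator: pedigree, gene drop, array panel, VCF,
    transcript, genotyping table and cohort counts, all deterministic under
    the configured seed."""
    rng = np.random.default_rng(config.seed)
    ped, founder, forced = build_pedigree(config, rng)
    diplo, copies, mutant_fid = gene_drop(ped, founder, forced, config, rng)
    cases = [i for i in ped.individuals() if ped[i].phenotype == "affected"]
    cases.sort(key=lambda c: int(c.replace("case", "")))
    sequenced = cases[:config.n_sequenced_cases]

    depths = {c: sorted(ped.ancestors_with_depths(c)[founder]) for c in cases}
    case_segments = {}
    for c in cases:
        seg = _autozygous_segment(diplo[c][config.causal_chrom],
                                  config.causal_pos, mutant_fid)
        assert seg is not None, "forced transmission must make cases autozygous"
        case_segments[c] = seg

    transcript, cds = build_transcript(config, rng)

    # ---- array panel -------------------------------------------------------
    n_haps = 2 * sum(1 for i in ped.individuals() if not ped.parents(i))
    markers, founder_alleles = [], {}
    for chrom, L in sorted(config.chrom_lengths.items()):
        n = max(2, int(round(config.marker_density_per_mb * L / 1e6)))
        pos = np.unique(rng.integers(1, L + 1, size=3 * n))
        while len(pos) < n:    # collisions are vanishingly rare at these sizes
            pos = np.unique(np.concatenate([pos, rng.integers(1, L + 1, size=n)]))
        pos = np.sort(rng.choice(pos, size=n, replace=False))
        freqs = rng.uniform(0.05, 0.5, size=n)
        alleles = rng.random((n_haps, n)) < freqs   # True = allele_b
        if config.plant_selection_signature and chrom == "11":
            lo, hi = int(0.25 * L), int(0.25 * L) + 2_300_000
            inside = (pos >= lo) & (pos <= hi)
            alleles[:, inside] = False              # fixed: everyone hom allele_a
        pair_idx = rng.integers(0, 4, size=n)
        for j, p in enumerate(pos):
            a = BASES[pair_idx[j]]
            b = BASES[(pair_idx[j] + 1 + int(rng.integers(3))) % 4]
            markers.append(Marker(chrom=chrom, pos_bp=int(p),
                                  id=f"snp_{chrom}_{j}", allele_a=a, allele_b=b))
        founder_alleles[chrom] = (pos, alleles)

    def hap_alleles(hap: Hap, chrom: str) -> np.ndarray:
        pos, alleles = founder_alleles[chrom]
        out = np.zeros(len(pos), dtype=bool)
        for s, e, fid in hap:
            i0, i1 = np.searchsorted(pos, s), np.searchsorted(pos, e, side="right")
            out[i0:i1] = alleles[fid, i0:i1]
        return out

    rows = []
    for c in cases:
        row = []
        for chrom in sorted(config.chrom_lengths):
            h1, h2 = diplo[c][chrom]
            row.append(hap_alleles(h1, chrom).astype(np.int8)
                       + hap_alleles(h2, chrom).astype(np.int8))
        rows.append(np.concatenate(row))
    codes = np.vstack(rows)
    if config.genotyping_error_rate > 0:
        flip = rng.random(codes.shape) < config.genotyping_error_rate
        hom = flip & ((codes == 0) | (codes == 2))
        het = flip & (codes == 1)
        codes[hom] = 1
        codes[het] = np.where(rng.random(codes.shape) < 0.5, 0, 2)[het]
    gmatrix = GenotypeMatrix(samples=list(cases), markers=markers, codes=codes)
    infos = [SampleInfo(id=c, cohort="case", phenotype="affected") for c in cases]

    # ---- WGS-style VCF -----------------------------------------------------
    controls = [f"ctrl{i}" for i in range(1, config.n_controls_wgs + 1)]
    vcf_samples = sequenced + controls
    variants: list[VariantRecord] = []

    def control_private_gts():
        het = rng.random(len(controls)) < config.control_carrier_rate
        return {c: (GT_HET if h else GT_HOM_REF) for c, h in zip(controls, het)}

    causal = VariantRecord(
        chrom=config.causal_chrom, pos_bp=config.causal_pos, ref="G", alt="A",
        genotypes={**{s: GT_HOM_ALT for s in sequenced}, **control_private_gts()})
    variants.append(causal)

    # linked non-coding private variants: on the founder haplotype, inside the
    # sequenced cases' shared autozygous interval, outside exons/splice windows
    shared_lo = max(case_segments[c][0] for c in sequenced)
    shared_hi = min(case_segments[c][1] for c in sequenced)
    half = config.shared_hap_target_bp // 2
    lo = max(shared_lo, config.causal_pos - half)
    hi = min(shared_hi, config.causal_pos + half)
    exon_mask = [(s - 3, e + 3) for s, e in transcript.exons]
    linked, tries = [], 0
    while len(linked) < config.n_linked_noncoding_private and tries < 100_000:
        tries += 1
        p = int(rng.integers(lo, hi + 1))
        if p == config.causal_pos or p in linked:
            continue
        if any(s <= p <= e for s, e in exon_mask):
            continue
        linked.append(p)
    linked.sort()
    for p in linked:
        ref, alt = rng.choice(BASES, size=2, replace=False)
        variants.append(VariantRecord(
            chrom=config.causal_chrom, pos_bp=p, ref=str(ref), alt=str(alt),
            genotypes={**{s: GT_HOM_ALT for s in sequenced},
                       **control_private_gts()}))

    # background polymorphism shared with controls
    chrom_list = sorted(config.chrom_lengths)
    used = set(linked) | {config.causal_pos}
    for _ in range(config.n_background_variants):
        chrom = chrom_list[int(rng.integers(len(chrom_list)))]
        p = int(rng.integers(1, config.chrom_lengths[chrom] + 1))
        if (chrom, p) in used or (chrom == config.causal_chrom and p in used):
            continue
        used.add((chrom, p))
        q = float(rng.uniform(0.05, 0.5))
        ref, alt = rng.choice(BASES, size=2, replace=False)
        gts = {}
        in_shared = (chrom == config.causal_chrom and shared_lo <= p <= shared_hi)
        if in_shared:
            b = rng.random() < q      # single founder-haplotype allele draw
            for s in sequenced:
                gts[s] = GT_HOM_ALT if b else GT_HOM_REF
        else:
            for s in sequenced:
                gts[s] = _hw_draw(q, rng)
        for c in controls:
            gts[c] = _hw_draw(q, rng)
        variants.append(VariantRecord(chrom=chrom, pos_bp=p, ref=str(ref),
                                      alt=str(alt), genotypes=gts))
    variants.sort(key=lambda v: (v.chrom, v.pos_bp))

    # ---- causal-variant genotyping assay (cases + obligate parents) --------
    genotyping = {c: GT_HOM_ALT for c in cases}
    # carrier parents have exactly one mutant copy by construction
    for c in cases:
        for p in ped.parents(c):
            genotyping[p] = {0: GT_HOM_REF, 1: GT_HET, 2: GT_HOM_ALT}[copies[p]]

    # ---- population cohort counts ------------------------------------------
    q = config.target_allele_freq
    n_aa, n_ab, n_bb = rng.multinomial(
        config.population_n, [(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
    from .cohort_stats import GenotypeCounts
    counts = [
        GenotypeCounts("affected", 0, 0, len(cases)),
        GenotypeCounts("obligate_carrier", 0, len({p for c in cases
                                                   for p in ped.parents(c)}), 0),
        GenotypeCounts("population", int(n_aa), int(n_ab), int(n_bb)),
    ]

    truth = SimTruth(
        causal_chrom=config.causal_chrom, causal_pos=config.causal_pos,
        causal_ref="G", causal_alt="A", founder_id=founder,
        mutant_copies=copies, case_segments=case_segments,
        founder_depths={c: [int(d) for d in depths[c]] for c in cases},
        linked_positions=linked, case_ids=cases, sequenced_case_ids=sequenced)
    return SimResult(config=config, pedigree=ped, truth=truth, gmatrix=gmatrix,
                     sample_infos=infos, variants=variants,
                     vcf_samples=vcf_samples, transcript=transcript,
                     coding_sequence=cds, genotyping=genotyping,
                     cohort_counts=counts)


def _hw_draw(q: float, rng: np.random.Generator) -> str:
    u = rng.random()
    if u < (1 - q) ** 2:
        return GT_HOM_REF
    if u < (1 - q) ** 2 + 2 * q * (1 - q):
        return GT_HET
    return GT_HOM_ALT


def emit_dataset(result: SimResult, out_dir: str | Path) -> dict[str, Path]:
    """Write every artefact to ``out_dir``; returns the path map.

    Deterministic: identical SimResult gives byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ped": out / "array.ped", "map": out / "array.map",
        "vcf": out / "wgs.vcf", "pedigree": out / "pedigree.tsv",
        "transcript": out / "transcript.tsv", "cds_fasta": out / "cds.fasta",
        "genotyping": out / "genotyping.tsv",
        "cohort_counts": out / "cohort_counts.tsv",
        "truth": out / "truth.json",
    }
    aio.write_pedmap(result.gmatrix, result.sample_infos, paths["ped"], paths["map"])
    aio.write_vcf(result.variants, result.vcf_samples, paths["vcf"],
                  contigs={c: l for c, l in sorted(result.config.chrom_lengths.items())})
    aio.write_pedigree(result.pedigree, paths["pedigree"])
    aio.write_transcript(result.transcript, paths["transcript"])
    with open(paths["cds_fasta"], "w") as fh:
        fh.write(f">{result.transcript.gene} synthetic coding sequence\n")
        seq = result.coding_sequence
        for i in range(0, len(seq), 60):
            fh.write(seq[i:i + 60] + "\n")
    aio.write_genotyping_table(result.genotyping, paths["genotyping"])
    aio.write_cohort_counts(result.cohort_counts, paths["cohort_counts"])
    paths["truth"].write_text(result.truth.to_json())
    return paths
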