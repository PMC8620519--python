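# Methods

## Scope and model

The package implements homozygosity mapping for a fully penetrant,
monogenic, autosomal recessive trait with a single founder origin. The
working model: all affected individuals are autozygous (identical by
descent) for a chromosomal segment inherited twice from one ancestral
carrier; the causal variant lies inside the segment shared by all cases;
unaffected parents of cases are obligate heterozygous carriers. Every stage
below is a deterministic function of its inputs.

## ROH scanning

The scanner is the classic windowed proportion-of-homozygous-windows
algorithm used by SNP-array autozygosity tools. Parameters, with defaults:

| parameter | default | meaning |
|---|---|---|
| `window_snps` | 50 | markers per sliding window |
| `window_het` | 0 | max heterozygous calls for a window to qualify |
| `window_missing` | 0 | max missing calls for a window to qualify |
| `hit_threshold` | 0.05 | min fraction of qualifying overlapping windows per marker |
| `min_snps` | 10 | min markers per emitted run |
| `min_kb` | 1000 | min run span |
| `max_gap_kb` | 1000 | max gap between consecutive run markers |
| `max_density_kb_per_snp` | 30 | max average span per marker in a run |

Runs are assembled from markers whose window-hit fraction reaches the
threshold and are split **only** by the physical-gap rule: markers whose
fraction fails (isolated heterozygous or missing calls and their window
neighbourhoods) are excluded from the marker count but do not by themselves
terminate a run. Chromosomes shorter than the window shrink the window to
the chromosome length. Two numerical consequences worth knowing:

* with `window_het = 0` a single heterozygous call zeroes the fraction of
  every marker within a window length, so the scanner presumes essentially
  error-free (imputed-grade) genotypes;
* run edges are trimmed by construction: a boundary marker keeps fraction ≥
  0.05 only while ≥ ~`0.05·window_snps` of its windows stay inside the
  homozygous stretch, so detected runs start/end a few markers inside the
  true segment.

Shared regions are maximal intervals covered by an ROH of every case
(pairwise sorted-interval intersection), annotated with the number of
internal markers at which all cases are homozygous and a consensus flag
(same homozygous allele everywhere). Consensus uses unphased allele
identity; true phase is unavailable from array homozygotes and unnecessary.
Region size is reported as `end − start` bp. Sex chromosomes are dropped
before scanning when configured (default on).

## Recessive private-variant filter

A variant survives iff all cases are `hom_alt` and no control is `hom_alt`.
Degenerate genotypes: a missing call in a *case* fails the variant
(conservative — a candidate must be positively supported in every case); a
missing call in a *control* is ignored at that site. No control
allele-frequency cap is imposed beyond the hom-alt exclusion. Multiallelic
VCF rows are skipped with a warning rather than split; the target class is
biallelic SNVs and small indels. Indels pass through the filter but receive
no codon-level consequence (the annotator names substitutions only) and are
never counted protein-changing.

## Consequence annotation

Genomic→CDS mapping walks exon∩CDS intervals in genomic order (plus strand)
or reverse (minus strand, with alleles complemented by the caller). The
affected codon is `(cds_pos − 1) // 3 + 1`; reference and alternate codons
are translated with the standard nuclear code (Biopython). Classes:
`missense`, `synonymous`, `nonsense` (alternate codon is a stop),
`noncoding` (outside the CDS, including UTR and deep intron), and
`splice_region_unsupported` for intronic bases within 2 bp of an exon edge —
the name is deliberate: the model flags but does not interpret splice
effects. The annotator validates the claimed reference base against the
coding sequence and raises on mismatch (guards transcript/genome
inconsistency).

## Pedigree analysis

Ancestry uses dynamic programming over the parent DAG; for each ancestor the
*set* of distinct path lengths is kept, because inbreeding loops yield
several ("generations ago" = parent edges, parent = 1). Common ancestors of
the case set report the generation range over all paths of all cases — a
deliberately explicit convention, since "N generations ago" is otherwise
ambiguous in looped pedigrees. Loop evidence is the number of ancestors
reachable by ≥ 2 distinct paths (verified against exhaustive path
enumeration in tests). Unknown parents truncate paths silently. Wright's F
(kinship of the parents, recursive tabular method) is exposed as a derived
statistic but not used by any decision rule.

## Frequency and segregation statistics

Frequencies come from raw genotype counts, no Hardy–Weinberg modelling;
percentages render with one decimal, rounding half away from zero. The
segregation check classifies genotyped individuals as affected (must be
`hom_alt`) or obligate carriers — parents of an affected individual, derived
from the pedigree, never from genotype — (must be `het`); genotyped
individuals with unknown phenotype are left untested with a warning.

## Synthetic-data generator

The generator emulates the study design the pipeline targets: 12 affected
descendants of one founder carrier placed 8–11 generations up, 3 of them
sequenced, 567 WGS controls, a 2952-animal population cohort at 8.2% target
allele frequency, a ~2.5 Mb shared haplotype around a coding causal variant,
34 linked non-coding private variants, and (by default) a second,
population-wide fixed homozygous block on another chromosome that mimics a
breed selection signature.

**Pedigree.** All cases descend from the founder through a single carrier
backbone chain, with dedicated carrier parents per case bred from chain
members chosen so each case's two path lengths to the founder fall inside
the configured depth window (cycled so the extremes are realised). This
single-recent-origin topology — rather than independent founder-to-case
lines — is what lets a dozen deep cases still share a multi-megabase
segment: chain meioses erode the haplotype once for everybody, only each
case's last meioses erode it independently.

**Gene drop.** Haplotypes are segment lists tagged with founder-haplotype
ids, so descent (and hence every truth field: carrier states, per-case
autozygous segments) is tracked exactly rather than inferred from allele
signatures. Recombination follows Haldane's model: Poisson crossover count
with mean = map length (default 1 cM/Mb), uniform positions, no
interference. Transmissions on founder→case carrier paths are conditioned
to pass the mutant allele (the complementary gamete is taken when the
sampled one lacks it) *and*, by rejection sampling, to keep the target
haplotype window around the locus intact — the ascertainment a single-origin
case cohort embodies (a case set is only ever mapped because it shares a
workable segment). Rejection discards ~2.4% of candidate gametes at the
defaults. All other meioses are unconditioned, so transmission at unlinked
loci is fair (checked at 10,000 meioses).

**Array panel.** Marker positions are uniform at 100 markers/Mb (the
imputed panels such scanners consume run ~250/Mb; anything much below
~33/Mb is structurally incompatible with the 30 kb/SNP density cap, so
sparse-array emulation is not meaningful here). Founder haplotype alleles
are drawn site-wise at uniform random frequencies in [0.05, 0.5]; genotyping
error (default 0.001) flips hom→het or het→hom. Error-free runs emulate the
imputed panel; note the scanner section above — at 0.001 a run-splitting het
lands inside the shared region often enough that full region recovery
succeeds in roughly 9 of 10 simulations, which is the honest behaviour of a
zero-het scanner on unimputed data. Tests of region recovery therefore use
error-free panels; tests of the sequence-variant path use the noisy default,
which it does not depend on.

**Variant table.** The causal variant (placed so its CDS coordinate is 751,
codon 251 = GAT) and the linked non-coding variants are hom-alt in sequenced
cases and het in a random 2% of controls; background sites are
Hardy–Weinberg draws at uniform frequencies (0.05–0.5), with sequenced-case
genotypes made descent-consistent inside their shared segment. Linkage
among background sites is not modelled — no consumer stage uses it. The
synthetic transcript is an 18-exon, 2430 bp-CDS plus-strand gene; the coding
sequence is random sense codons with fixed start/stop and the planted
aspartate codon.

**What passing tests do and do not show.** The generator exercises the
pipeline's logic end to end (descent, filtering, annotation, ancestry,
frequencies) with exact truth, but it does not reproduce coalescent LD,
allele-frequency spectra, array ascertainment bias, or sequencing artefacts;
success here demonstrates correctness of the method's implementation, not
its power on any particular real dataset.

## Problem sizes and numerical choices

Default simulations use two chromosomes (12 and 8 Mb) at 100 markers/Mb and
~335 sequence variants over 570 samples — small enough that a full
simulate–map–filter–annotate cycle runs in well under a second, chosen so
that multi-seed success-rate estimates (50 seeds) and brute-force oracle
comparisons (hundreds of random chromosomes) are routine. Coordinates are
1-based inclusive everywhere; chromosome labels are opaque strings with a
leading `chr` stripped; `MISSING` is a distinct genotype code, never
conflated with reference homozygosity. Determinism: one `numpy` Generator
seeded from the config drives the whole simulation; identical configs give
byte-identical emitted files.

## Known limitations

* The scanner's zero-het default makes ROH fragmentation on unimputed data
  a feature of the method, not a bug of the implementation; users with raw
  array data should either impute or raise `window_het`/`window_missing`.
* Strand normalisation of array alleles is assumed done upstream.
* The consequence model names single-base substitutions only (no
  frameshift/extension nomenclature, no splice-effect prediction).
* Shared-ROH analysis cannot by itself distinguish a disease IBD region
  from a population-wide selection signature — the simulator plants one on
  purpose; disambiguation comes from the variant-filtering stage.
* The pedigree module assumes recorded parentage is correct; pedigree
  errors masquerade as absent or spurious loops.
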