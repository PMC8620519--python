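# autozygmap

Autozygosity mapping of recessive Mendelian variants in pedigreed
populations: runs-of-homozygosity (ROH) detection, shared identity-by-descent
(IBD) region intersection, recessive private-variant filtering with HGVS
consequence annotation, pedigree ancestry analysis, and cohort allele-
frequency estimation — plus a gene-drop simulator that produces study-shaped
datasets with exact planted truth so the whole pipeline is testable without
any external data.

## Who it is for

Geneticists mapping a fully penetrant recessive trait (typically in
livestock or companion animals) who have: SNP-array genotypes for a handful
of affected individuals, whole-genome sequence for a subset of them plus a
control cohort, pedigree records, and population genotyping counts for a
candidate variant.

## The method

**ROH scanning.** For each case, a window of `window_snps` consecutive
markers slides along the chromosome; a window is *homozygous* when it
contains at most `window_het` heterozygous and `window_missing` missing
calls. Each marker is scored by the fraction of its overlapping windows that
are homozygous; markers with fraction ≥ `hit_threshold` form runs, split
where the inter-marker gap exceeds `max_gap_kb`, and a run is emitted when
it has ≥ `min_snps` markers, spans ≥ `min_kb`, and averages ≤
`max_density_kb_per_snp` of span per marker. Defaults mirror a published
scanner option set for autozygosity mapping (`min_snps=10`,
`max_density_kb_per_snp=30`, `max_gap_kb=1000`, `window_het=0`,
`window_missing=0`, with tool defaults `window_snps=50`, `min_kb=1000`,
`hit_threshold=0.05`).

**Shared regions.** The maximal intervals covered by an ROH of *every* case
are candidate IBD regions; each is verified by a consensus check (all cases
homozygous for the same allele at every internal marker) and sized as
`end − start` bp.

**Recessive private filter.** A sequence variant survives iff every case is
homozygous for the alternate allele and no control is — heterozygous
controls (carriers) are expected and allowed. Survivors are annotated
against a transcript model: genomic → CDS coordinate across exons
(strand-aware), affected codon translated before/after substitution with the
standard nuclear code, named in HGVS style (`c.751G>A`, `p.Asp251Asn`).

**Pedigree ancestry.** On the sire/dam graph: ancestors common to all cases
with the full set of path lengths (inbreeding loops give several),
loop counts, and Wright's inbreeding coefficient as a derived statistic.

**Cohort statistics.** From genotype counts `(n_hom_ref, n_het, n_hom_alt)`:
allele frequency `(2·n_hom_alt + n_het) / (2·total)`, carrier frequency
`n_het / total`, and a recessive segregation check (cases homozygous,
obligate-carrier parents heterozygous).

## Worked example

```bash
python examples/02_filter_and_annotate.py
```

```
335 variants, 3 cases, 567 controls
35 variants survive the recessive private filter
classes: {'noncoding': 34, 'missense': 1}

protein-changing candidate: 14:6000000G>A
  c.751G>A  p.Asp251Asn  (codon 251, Asp -> Asn)
  matches planted causal variant: True
```

The simulator plants a founder carrier 8–11 generations above 12 affected
descendants, gene-drops haplotypes with recombination, and emits a WGS-style
variant table. Filtering 3 sequenced cases against 567 controls leaves one
missense candidate (the planted causal variant) among 34 linked non-coding
private variants riding the same founder haplotype — the classic signature
of a recessive founder mutation. `examples/01_simulate_and_map.py` shows the
ROH mapping stage (the shared consensus region containing the locus, next to
a population-wide homozygous block that mimics a selection signature),
`03_cohort_frequencies.py` the frequency arithmetic (counts 2477/463/12 →
allele frequency 8.2%), and `04_pedigree_ancestry.py` the ancestry and
segregation analysis.

A thin CLI wraps the same functions (`autozygmap simulate | map | intersect
| filter | ancestry | stats | run-all`); `run-all` drives the whole pipeline
from one YAML config and renders TSV tables plus a markdown summary.

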