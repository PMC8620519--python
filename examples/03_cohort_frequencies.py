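"""Allele and carrier frequencies from published-style genotype counts.

Uses the genotype-count layout of a population genotyping survey: counts of
(hom ref, het, hom alt) animals per cohort.
"""

from autozygmap import (GenotypeCounts, allele_frequency, carrier_frequency,
                        format_percent)

cohorts = [
    GenotypeCounts("population cohort", 2477, 463, 12),
    GenotypeCounts("second breed", 14976, 52, 0),
    GenotypeCounts("sequenced controls", 552, 15, 0),
]
for c in cohorts:
    af, cf = allele_frequency(c), carrier_frequency(c)
    print(f"{c.cohort:20s} n={c.total:6d}  "
          f"allele freq {format_percent(af):>6s}  "
          f"carriers {format_percent(cf):>6s}")

# The mutant-allele frequency is (2*hom_alt + het) / (2*total): 8.2% in the
# affected breed's population cohort means roughly one animal in six carries
# at least one copy — ample justification for carrier screening.
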