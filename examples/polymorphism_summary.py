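"""Genotype frequencies and AUC ratios relative to wild type.

Summarises one published genotype study: group sizes per genotype become
frequencies, and per-genotype AUC means become percentages of the
wild-type group (values above 100% mean reduced glucuronidation capacity
in carriers of the variant allele).
"""

from ugtvar.polymorphism import (
    AucByGenotype,
    GenotypeCounts,
    auc_ratio_to_wildtype,
    genotype_frequencies,
)

counts = GenotypeCounts(population="Caucasian", snp_id="UGT1A1*28", counts=(30, 25, 6))
f_wt, f_het, f_hom = genotype_frequencies(counts)
print(f"{counts.snp_id} in {counts.population}s (n={sum(counts.counts)}):")
print(f"  wt/wt {f_wt:.1%}   wt/var {f_het:.1%}   var/var {f_hom:.1%}")

auc = AucByGenotype(
    substrate="oxazepam",
    auc_values={"wt/wt": 200.0, "wt/var": 294.0, "var/var": 486.0},
)
ratios = auc_ratio_to_wildtype(auc)
print(f"\n{auc.substrate} AUC ratio to wild type (%):")
for genotype, pct in ratios.items():
    print(f"  {genotype:8s} {pct:5.0f}")
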