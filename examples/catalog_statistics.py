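"""Summarize the evolved-strain mutation catalog.

Loads the packaged 23-strain catalog (a synthetic reconstruction of the
published evolved HLHT-tolerant mutants), classifies every mutation against
the reference annotation, and prints the headline statistics.
"""

from hypermut import catalog_summary
from hypermut.synthetic_fixture import evolved_strain_catalog

catalog = evolved_strain_catalog()
s = catalog_summary(catalog)

print(f"strains:               {s['n_strains']}")
print(f"mutation records:      {s['total_records']}")
print(f"mean per strain:       {s['mean_per_strain']}")
print(f"distinct types:        {s['n_types']} "
      f"({s['snp_types']} SNPs + {s['indel_types']} InDels)")
print(f"InDel split:           {s['insertion_types']} insertions, "
      f"{s['deletion_types']} deletions")
print(f"CDS SNP effects:       {s['effect_counts']['non_synonymous']} non-synonymous, "
      f"{s['effect_counts']['synonymous']} synonymous, "
      f"{s['effect_counts']['nonsense']} nonsense")
print(f"zygosity:              {s['zygosity_counts']}")

# Each record is one mutation in one strain; a "type" collapses identical
# (position, ref, alt) triples that recurred independently across strains.
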