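"""Rank candidate functional mutations by the three lines of evidence.

Recurrence across strains, presence in minimally mutated strains (<= 2
mutations), and multiple independent hits in the same gene or region.
"""

from hypermut import evidence_table, minimal_strains
from hypermut.synthetic_fixture import evolved_strain_catalog

catalog = evolved_strain_catalog()
print("strains with only two mutations:", ", ".join(minimal_strains(catalog, 2)))

df = evidence_table(catalog, k=2)
print(df.head(10).to_string(index=False))
print("ranking rule:", df.attrs["ranking_rule"])

# High-recurrence types carried by minimal strains (here 0336 and the NC2
# group, plus 1799 and the 2215 indels) are the reverse-genetics candidates.
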