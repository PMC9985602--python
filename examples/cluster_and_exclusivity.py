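"""Cluster evolved strains by shared mutations and scan for exclusive drivers.

Builds the binary strain x mutation-type matrix, clusters strains with the
reciprocal-overlap dissimilarity 1/(a.b + 1) under UPGMA linkage, and scans
for pairs of mutation groups whose carriers are disjoint yet cover every
strain — the signature of alternative driver mutations.
"""

from hypermut import MutationMatrix, cluster_strains, exclusivity_scan, region_of_code
from hypermut.synthetic_fixture import evolved_strain_catalog

matrix = MutationMatrix.from_catalog(evolved_strain_catalog())
tree, dm = cluster_strains(matrix, linkage="average")

print(f"{len(matrix.strains)} strains x {len(matrix.types)} mutation types")
print(f"dendrogram ({dm.linkage_method} linkage), Newick:")
print(str(tree).strip()[:120] + " ...")

grouping = {c: region_of_code(c) for c in matrix.types}
for g1, g2, n1, n2 in exclusivity_scan(matrix, grouping):
    print(f"exclusive pair: {g1} ({n1} strains) vs {g2} ({n2} strains)")

# The exclusive pair means every strain carries exactly one of the two
# mutation groups — strong evidence that each is an independent route to
# the selected phenotype.
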