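"""Independent brute-force oracles used by the end-to-end checks.

These deliberately avoid the package's codon arithmetic and scan logic:
effects are derived by translating both *whole* proteins and diffing, and
exclusive pairs by a plain double loop over carrier sets.
"""

from Bio.Seq import Seq


def protein_rebuild_effect(record, annotation):
    feature = annotation.cds_at(record.position)
    if feature is None:
        return "noncoding"
    cds = annotation.sequence[feature.start - 1 : feature.end]
    idx = record.position - feature.start
    mutated = cds[:idx] + record.alt + cds[idx + 1 :]
    if feature.strand == "-":
        cds = str(Seq(cds).reverse_complement())
        mutated = str(Seq(mutated).reverse_complement())
    p_ref = str(Seq(cds).translate())
    p_alt = str(Seq(mutated).translate())
    if p_alt == p_ref:
        return "synonymous"
    changed = [b for a, b in zip(p_ref, p_alt) if a != b]
    return "nonsense" if "*" in changed else "non_synonymous"


def brute_force_exclusive_pairs(matrix):
    carriers = {}
    for j, code in enumerate(matrix.types):
        for i, strain in enumerate(matrix.strains):
            if matrix.cells[i, j]:
                carriers.setdefault(code, set()).add(strain)
    everyone = set(matrix.strains)
    out = []
    for g1 in sorted(carriers):
        for g2 in sorted(carriers):
            if (
                g1 < g2
                and not (carriers[g1] & carriers[g2])
                and carriers[g1] | carriers[g2] == everyone
            ):
                out.append((g1, g2, len(carriers[g1]), len(carriers[g2])))
    return out
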