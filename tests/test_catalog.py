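"""Token parsing, effect classification, code assignment and summaries."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from hypermut.catalog import (
    AnnotationError,
    Feature,
    GenomeAnnotation,
    MutationCatalog,
    MutationRecord,
    TokenParseError,
    assign_codes,
    catalog_summary,
    classify_catalog,
    classify_effect,
    format_mutation_token,
    parse_mutation_token,
)

BASES = "ACGT"


@pytest.mark.parametrize(
    "token,expected",
    [
        ("G905452A", (905452, "G", "A", "SNP")),
        ("158234D1", (158234, "N", "", "deletion")),
        ("158234D3", (158234, "NNN", "", "deletion")),
        ("158234IACG", (158234, "", "ACG", "insertion")),
        ("T1C", (1, "T", "C", "SNP")),
    ],
)
def test_parse_token_dialects(token, expected):
    assert parse_mutation_token(token) == expected


@pytest.mark.parametrize("token", ["G905452G", "905452", "12D0", "AxT", "", "12IU"])
def test_parse_token_rejects_malformed(token):
    with pytest.raises(TokenParseError):
        parse_mutation_token(token)


def test_parse_token_rejects_position_zero():
    with pytest.raises(ValueError):
        parse_mutation_token("A0T")


@given(
    pos=st.integers(1, 10_000_000),
    ref=st.sampled_from(BASES),
    alt=st.sampled_from(BASES),
    dellen=st.integers(1, 30),
    ins=st.text(alphabet=BASES, min_size=1, max_size=12),
    kind=st.sampled_from(["SNP", "deletion", "insertion"]),
)
def test_token_round_trip(pos, ref, alt, dellen, ins, kind):
    """format(parse(token)) is the identity on every well-formed token."""
    if kind == "SNP":
        if ref == alt:
            return
        token = f"{ref}{pos}{alt}"
    elif kind == "deletion":
        token = f"{pos}D{dellen}"
    else:
        token = f"{pos}I{ins}"
    assert format_mutation_token(*parse_mutation_token(token)) == token


def test_snp_record_rejects_ref_equal_alt():
    with pytest.raises(ValueError):
        MutationRecord("s", 10, "G", "G", "SNP")


@pytest.fixture(scope="module")
def mini_annotation():
    # 60 bp genome; one + strand CDS at 11..28 (ATG GCT TAC CCA GGA TAA)
    # and one - strand CDS at 41..52 (revcomp -> ATG TTT GCC TAG)
    seq = list("A" * 60)
    seq[10:28] = "ATGGCTTACCCAGGATAA"
    seq[40:52] = "CTAGGCAAACAT"
    return GenomeAnnotation(
        "".join(seq),
        [Feature("mini_0001", 11, 28, "+"), Feature("mini_0002", 41, 52, "-")],
    )


@pytest.mark.parametrize(
    "record,expected",
    [
        # third codon base GCT -> GCC: both Ala
        (MutationRecord("s", 16, "T", "C", "SNP"), "synonymous"),
        # TAC -> TAA on the + strand: stop gained
        (MutationRecord("s", 19, "C", "A", "SNP"), "nonsense"),
        # GCT -> GAT: Ala -> Asp
        (MutationRecord("s", 15, "C", "A", "SNP"), "non_synonymous"),
        # 1-bp deletion inside a CDS shifts the frame
        (MutationRecord("s", 15, "C", "", "deletion"), "frameshift"),
        (MutationRecord("s", 14, "GCT", "", "deletion"), "in_frame_indel"),
        (MutationRecord("s", 15, "", "TTT", "insertion"), "in_frame_indel"),
        # between the two CDS
        (MutationRecord("s", 33, "A", "G", "SNP"), "noncoding"),
        # - strand CDS: genome A48->C is coding TTT->TGT (Phe->Cys)
        (MutationRecord("s", 48, "A", "C", "SNP"), "non_synonymous"),
        # - strand synonymous: genome A47->G is coding TTT->TTC (both Phe)
        (MutationRecord("s", 47, "A", "G", "SNP"), "synonymous"),
    ],
)
def test_classify_effect_examples(mini_annotation, record, expected):
    assert classify_effect(record, mini_annotation) == expected


def test_classify_effect_rejects_bad_inputs(mini_annotation):
    with pytest.raises(ValueError):
        classify_effect(MutationRecord("s", 999, "A", "G", "SNP"), mini_annotation)
    with pytest.raises(AnnotationError):  # genome base at 16 is T, not G
        classify_effect(MutationRecord("s", 16, "G", "C", "SNP"), mini_annotation)
    broken = GenomeAnnotation(mini_annotation.sequence, [Feature("x_1", 11, 27, "+")])
    with pytest.raises(AnnotationError):
        classify_effect(MutationRecord("s", 15, "C", "A", "SNP"), broken)


def _protein_oracle_effect(record, annotation):
    """Independent oracle: rebuild both full protein sequences and compare."""
    from Bio.Seq import Seq

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


def test_classify_effect_matches_protein_rebuild_oracle(small_toy_genome):
    """Codon-level classification agrees with translating both whole proteins,
    across random SNPs on a random annotated genome."""
    import numpy as np

    rng = np.random.default_rng(42)
    n_checked = 0
    while n_checked < 1000:
        pos = int(rng.integers(1, len(small_toy_genome) + 1))
        ref = small_toy_genome.sequence[pos - 1]
        alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        record = MutationRecord("s", pos, ref, alt, "SNP")
        assert classify_effect(record, small_toy_genome) == _protein_oracle_effect(
            record, small_toy_genome
        )
        n_checked += 1


class TestAssignCodes:
    def _annotation(self):
        seq = "A" * 400
        feats = [
            Feature("gene_0010", 11, 70, "+"),
            Feature("gene_0020", 101, 160, "+"),
            Feature("gene_0030", 201, 260, "+"),
        ]
        return GenomeAnnotation(seq, feats)

    def _catalog(self, positions_gene, positions_nc):
        recs = [
            MutationRecord("s1", p, "A", "G", "SNP", region="CDS",
                           locus_tag="gene_0010", effect="non_synonymous")
            for p in positions_gene
        ] + [
            MutationRecord("s1", p, "A", "G", "SNP", region="intergenic",
                           effect="noncoding")
            for p in positions_nc
        ]
        return MutationCatalog(recs)

    def test_multi_type_gene_gets_ascending_subindices(self):
        cat = self._catalog([12, 25, 40, 66], [])
        coded = assign_codes(cat, self._annotation())
        assert [r.code for r in sorted(coded.records, key=lambda r: r.position)] == [
            "0010-1", "0010-2", "0010-3", "0010-4",
        ]

    def test_single_type_gene_gets_bare_code(self):
        coded = assign_codes(self._catalog([12], []), self._annotation())
        assert coded.records[0].code == "0010"

    def test_intergenic_named_region_and_override(self):
        names = {frozenset({"gene_0010", "gene_0020"}): "NC2"}
        cat = self._catalog([], [75, 80, 95])
        coded = assign_codes(cat, self._annotation(), region_names=names)
        by_pos = {r.position: r.code for r in coded.records}
        assert by_pos == {75: "NC2-1", 80: "NC2-2", 95: "NC2-3"}
        # published sub-indices can override the coordinate order
        coded = assign_codes(
            cat, self._annotation(), region_names=names,
            code_overrides={(95, "A", "G"): "NC2-1", (75, "A", "G"): "NC2-3"},
        )
        by_pos = {r.position: r.code for r in coded.records}
        assert by_pos == {95: "NC2-1", 80: "NC2-2", 75: "NC2-3"}

    def test_auto_numbering_starts_at_nc1_in_genomic_order(self):
        cat = self._catalog([], [80, 180, 280])
        coded = assign_codes(cat, self._annotation())
        assert {r.position: r.code for r in coded.records} == {
            80: "NC1", 180: "NC2", 280: "NC3",
        }

    def test_deterministic(self, fixture_catalog):
        from hypermut.synthetic_fixture import (
            code_overrides, evolved_strain_catalog, region_names, synthetic_reference,
        )

        again = assign_codes(
            classify_catalog(
                MutationCatalog(
                    [MutationRecord(r.strain_id, r.position, r.ref, r.alt, r.kind,
                                    r.zygosity) for r in fixture_catalog.records],
                    strains=list(fixture_catalog.strains),
                ),
                synthetic_reference(),
            ),
            synthetic_reference(), region_names(), code_overrides(),
        )
        assert again.records == fixture_catalog.records


class TestCatalogSummary:
    def test_empty_catalog_is_all_zeros(self):
        s = catalog_summary(MutationCatalog([]))
        assert s["total_records"] == 0 and s["n_types"] == 0
        assert s["mean_per_strain"] == 0.0

    def test_shared_types_deduplicate(self):
        recs = [
            MutationRecord(strain, pos, "A", "G", "SNP")
            for strain in ("s1", "s2", "s3")
            for pos in (10, 20)
        ]
        s = catalog_summary(MutationCatalog(recs))
        assert s["total_records"] == 6
        assert s["n_types"] == 2

    def test_type_partition_invariants(self, fixture_catalog):
        s = catalog_summary(fixture_catalog)
        assert s["snp_types"] + s["indel_types"] == s["n_types"]
        assert s["insertion_types"] + s["deletion_types"] == s["indel_types"]
        effects = s["effect_counts"]
        cds_snp_effects = (
            effects.get("synonymous", 0)
            + effects.get("non_synonymous", 0)
            + effects.get("nonsense", 0)
        )
        assert cds_snp_effects == s["cds_snp_types"]
        assert sum(s["per_strain_counts"].values()) == s["total_records"]
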