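"""Mutation cataloguing for evolved cyanobacterial strains.

Parses the compact genomic-token notation used to report resequencing
variants (``G905452A`` = SNP, ``158234D1`` = 1-bp deletion,
``158234IACG`` = insertion of ``ACG``), classifies each mutation against a
genome annotation (synonymous / non-synonymous / nonsense for CDS SNPs,
frameshift / in-frame for CDS indels, noncoding for intergenic sites), and
assigns the short location-based codes used throughout the analysis: the
numeric suffix of the locus tag for genic mutations (``synpcc7942_0884`` ->
``0884``), with ``-k`` sub-indices when one gene or region holds several
distinct mutation types, and ``NC<j>`` names for intergenic regions.

Coordinates are 1-based and inclusive throughout, matching the token
notation.  The genome is treated as circular for intergenic-interval lookup
only; codes never wrap.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Optional, Sequence

from Bio.Seq import Seq

__all__ = [
    "Effect",
    "Kind",
    "Zygosity",
    "MutationRecord",
    "Feature",
    "GenomeAnnotation",
    "MutationCatalog",
    "TokenParseError",
    "AnnotationError",
    "CodingError",
    "parse_mutation_token",
    "format_mutation_token",
    "classify_effect",
    "classify_catalog",
    "assign_codes",
    "catalog_summary",
]

Kind = Literal["SNP", "insertion", "deletion"]
Zygosity = Literal["homozygous", "heterogeneous"]
Effect = Literal[
    "non_synonymous",
    "synonymous",
    "nonsense",
    "frameshift",
    "in_frame_indel",
    "noncoding",
    "unknown",
]

_SNP_EFFECTS = frozenset({"synonymous", "non_synonymous", "nonsense"})
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class TokenParseError(ValueError):
    """A mutation token does not match any recognised dialect."""


class AnnotationError(ValueError):
    """The genome annotation is inconsistent (e.g. CDS length not a codon multiple)."""


class CodingError(ValueError):
    """A code cannot be assigned (e.g. locus tag without a numeric suffix)."""


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MutationRecord:
    """One mutation observed in one evolved strain.

    ``ref`` is empty for a pure insertion, ``alt`` empty for a pure deletion.
    A deletion whose removed bases are unknown (token dialect carries only
    the length) uses ``N`` placeholders in ``ref``.
    """

    strain_id: str
    position: int
    ref: str
    alt: str
    kind: Kind
    zygosity: Zygosity = "homozygous"
    locus_tag: str = ""
    region: Literal["CDS", "intergenic", ""] = ""
    effect: Effect = "unknown"
    code: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.kind == "SNP":
            if len(self.ref) != 1 or len(self.alt) != 1:
                raise ValueError("SNP requires single-base ref and alt")
            if self.ref == self.alt:
                raise ValueError(f"SNP ref equals alt ({self.ref})")
        elif self.kind == "deletion":
            if self.alt != "" or not self.ref:
                raise ValueError("deletion requires empty alt and non-empty ref")
        elif self.kind == "insertion":
            if self.ref != "" or not self.alt:
                raise ValueError("insertion requires empty ref and non-empty alt")
        else:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.zygosity not in ("homozygous", "heterogeneous"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.region == "intergenic" and self.effect not in ("noncoding", "unknown"):
            raise ValueError("intergenic mutations must have effect 'noncoding'")
        if self.effect in _SNP_EFFECTS and (self.kind != "SNP" or self.region != "CDS"):
            raise ValueError(f"effect {self.effect!r} requires a CDS SNP")

    @property
    def type_key(self) -> tuple[int, str, str]:
        """Identity of the mutation type: exact (position, ref, alt) triple."""
        return (self.position, self.ref, self.alt)

    def token(self) -> str:
        return format_mutation_token(self.position, self.ref, self.alt, self.kind)


@dataclass(frozen=True)
class Feature:
    locus_tag: str
    start: int  # 1-based inclusive
    end: int
    strand: Literal["+", "-"]
    type: str = "CDS"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad feature interval {self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class GenomeAnnotation:
    """Genome sequence plus CDS features, 1-based inclusive coordinates."""

    sequence: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for f in self.features:
            if f.end > n:
                raise ValueError(f"feature {f.locus_tag} exceeds genome length {n}")
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))

    def __len__(self) -> int:
        return len(self.sequence)

    def cds_at(self, position: int) -> Optional[Feature]:
        if not (1 <= position <= len(self.sequence)):
            raise ValueError(f"position {position} outside genome of length {len(self)}")
        for f in self.features:
            if f.type == "CDS" and position in f:
                return f
        return None

    def intergenic_interval(self, position: int) -> tuple[str, str, int, int]:
        """Return ``(left_tag, right_tag, start, end)`` of the annotation gap
        containing ``position``.  The genome is circular: the gap spanning the
        origin is one interval flanked by the last and first features."""
        if self.cds_at(position) is not None:
            raise ValueError(f"position {position} lies inside a CDS")
        feats = [f for f in self.features if f.type == "CDS"]
        if not feats:
            return ("", "", 1, len(self.sequence))
        for left, right in zip(feats, feats[1:]):
            if left.end < position < right.start:
                return (left.locus_tag, right.locus_tag, left.end + 1, right.start - 1)
        # wrap-around gap between last feature end and first feature start
        last, first = feats[-1], feats[0]
        if position > last.end or position < first.start:
            return (last.locus_tag, first.locus_tag, last.end + 1, first.start - 1)
        raise AnnotationError(f"position {position} not locatable in annotation")


@dataclass
class MutationCatalog:
    """All mutation records across the evolved strains.

    ``strains`` preserves first-appearance order unless given explicitly;
    ``types`` deduplicates records to unique (position, ref, alt) triples.
    """

    records: list[MutationRecord]
    strains: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.strains:
            seen: dict[str, None] = {}
            for r in self.records:
                seen.setdefault(r.strain_id, None)
            self.strains = list(seen)
        else:
            missing = {r.strain_id for r in self.records} - set(self.strains)
            if missing:
                raise ValueError(f"records reference unknown strains: {sorted(missing)}")

    @property
    def types(self) -> list[tuple[int, str, str]]:
        seen: dict[tuple[int, str, str], None] = {}
        for r in sorted(self.records, key=lambda r: r.type_key):
            seen.setdefault(r.type_key, None)
        return list(seen)

    def type_codes(self) -> dict[tuple[int, str, str], str]:
        codes: dict[tuple[int, str, str], str] = {}
        for r in self.records:
            if r.code:
                prev = codes.setdefault(r.type_key, r.code)
                if prev != r.code:
                    raise CodingError(
                        f"type {r.type_key} carries conflicting codes {prev!r}/{r.code!r}"
                    )
        return codes

    def records_of(self, strain_id: str) -> list[MutationRecord]:
        return [r for r in self.records if r.strain_id == strain_id]


_SNP_RE = re.compile(r"^([ACGT])(\d+)([ACGT])$")
_DEL_RE = re.compile(r"^(\d+)D(\d+)$")
_INS_RE = re.compile(r"^(\d+)I([ACGT]+)$")


def parse_mutation_token(token: str) -> tuple[int, str, str, Kind]:
    """Parse a compact mutation token into ``(position, ref, alt, kind)``.

    Dialects: ``<ref><pos><alt>`` SNP; ``<pos>D<n>`` deletion of *n* bases
    (ref reported as ``N * n`` since the token carries only the length);
    ``<pos>I<seq>`` insertion of ``seq`` after ``pos``.
    """
    m = _SNP_RE.match(token)
    if m:
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        if pos < 1:
            raise ValueError(f"token {token!r}: position must be >= 1")
        if ref == alt:
            raise TokenParseError(f"token {token!r}: SNP ref equals alt")
        return (pos, ref, alt, "SNP")
    m = _DEL_RE.match(token)
    if m:
        pos, n = int(m.group(1)), int(m.group(2))
        if pos < 1:
            raise ValueError(f"token {token!r}: position must be >= 1")
        if n < 1:
            raise TokenParseError(f"token {token!r}: deletion length must be >= 1")
        return (pos, "N" * n, "", "deletion")
    m = _INS_RE.match(token)
    if m:
        pos, seq = int(m.group(1)), m.group(2)
        if pos < 1:
            raise ValueError(f"token {token!r}: position must be >= 1")
        return (pos, "", seq, "insertion")
    raise TokenParseError(f"malformed mutation token {token!r}")


def format_mutation_token(position: int, ref: str, alt: str, kind: Kind) -> str:
    if kind == "SNP":
        return f"{ref}{position}{alt}"
    if kind == "deletion":
        return f"{position}D{len(ref)}"
    if kind == "insertion":
        return f"{position}I{alt}"
    raise ValueError(f"unknown kind {kind!r}")


def resolve_deletion_ref(record: MutationRecord, annotation: GenomeAnnotation) -> MutationRecord:
    """Fill a deletion's placeholder ``N`` ref bases from the genome sequence."""
    if record.kind != "deletion" or set(record.ref) != {"N"}:
        return record
    n = len(record.ref)
    return replace(record, ref=annotation.sequence[record.position - 1 : record.position - 1 + n])


def _codon_context(feature: Feature, annotation: GenomeAnnotation, position: int) -> tuple[str, int]:
    """Return the coding-strand codon containing ``position`` and the 0-based
    within-codon index of that position in coding orientation."""
    length = feature.end - feature.start + 1
    if length % 3 != 0:
        raise AnnotationError(
            f"CDS {feature.locus_tag} length {length} not divisible by 3"
        )
    seq = annotation.sequence
    if feature.strand == "+":
        offset = position - feature.start
        codon_start = feature.start - 1 + 3 * (offset // 3)
        return seq[codon_start : codon_start + 3], offset % 3
    offset = feature.end - position
    codon_end = feature.end - 3 * (offset // 3)  # 1-based genome coord of codon's first base
    genome_triplet = seq[codon_end - 3 : codon_end]
    return _revcomp(genome_triplet), offset % 3


def classify_effect(record: MutationRecord, annotation: GenomeAnnotation) -> Effect:
    """Classify one mutation against the annotation.

    CDS SNPs are translated on the coding strand (reverse-complemented for
    ``-`` features): identical amino acid -> synonymous, stop gained ->
    nonsense, otherwise non-synonymous.  CDS indels are frameshift unless the
    inserted/deleted length is a codon multiple.  Anything outside all CDS is
    noncoding.
    """
    if not (1 <= record.position <= len(annotation)):
        raise ValueError(
            f"position {record.position} outside genome of length {len(annotation)}"
        )
    feature = annotation.cds_at(record.position)
    if feature is None:
        return "noncoding"
    if record.kind == "SNP":
        genome_ref = annotation.sequence[record.position - 1]
        if genome_ref != record.ref:
            raise AnnotationError(
                f"reference mismatch at {record.position}: genome has {genome_ref}, "
                f"record claims {record.ref}"
            )
        codon, within = _codon_context(feature, annotation, record.position)
        alt_base = record.alt if feature.strand == "+" else record.alt.translate(_COMPLEMENT)
        mutated = codon[:within] + alt_base + codon[within + 1 :]
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(mutated).translate())
        if aa_alt == aa_ref:
            return "synonymous"
        if aa_alt == "*":
            return "nonsense"
        return "non_synonymous"
    indel_len = len(record.ref) if record.kind == "deletion" else len(record.alt)
    return "frameshift" if indel_len % 3 != 0 else "in_frame_indel"


def classify_catalog(catalog: MutationCatalog, annotation: GenomeAnnotation) -> MutationCatalog:
    """Return a catalog with region, locus tag and effect filled for every record."""
    out = []
    for r in catalog.records:
        r = resolve_deletion_ref(r, annotation)
        feature = annotation.cds_at(r.position)
        effect = classify_effect(r, annotation)
        out.append(
            replace(
                r,
                region="CDS" if feature is not None else "intergenic",
                locus_tag=feature.locus_tag if feature is not None else "",
                effect=effect,
            )
        )
    return MutationCatalog(out, strains=list(catalog.strains))


_TAG_SUFFIX_RE = re.compile(r"(\d+)$")


def _gene_code(locus_tag: str) -> str:
    m = _TAG_SUFFIX_RE.search(locus_tag)
    if not m:
        raise CodingError(f"locus tag {locus_tag!r} has no numeric suffix")
    return m.group(1)


def assign_codes(
    catalog: MutationCatalog,
    annotation: GenomeAnnotation,
    region_names: Optional[Mapping[frozenset, str]] = None,
    code_overrides: Optional[Mapping[tuple[int, str, str], str]] = None,
) -> MutationCatalog:
    """Assign location-based short codes to every mutation type.

    Genic types take the numeric suffix of their locus tag; intergenic types
    are grouped by shared annotation gap into regions named ``NC<j>`` (auto-
    numbered from NC1 by genomic order) unless ``region_names`` maps the gap's
    flanking locus-tag pair (``frozenset({left, right})``) to a name.  Groups
    holding more than one type get ``-k`` sub-indices by ascending genomic
    coordinate; ``code_overrides`` replaces individual type codes afterwards
    (used when published codes deviate from the coordinate order).
    """
    region_names = dict(region_names or {})
    names_seen: dict[str, frozenset] = {}
    for key, name in region_names.items():
        if name in names_seen and names_seen[name] != key:
            raise CodingError(f"region name {name!r} assigned to two different intervals")
        names_seen[name] = key

    classified = catalog if all(r.region for r in catalog.records) else classify_catalog(
        catalog, annotation
    )

    # group types by gene / intergenic interval
    groups: dict[tuple, list[tuple[int, str, str]]] = defaultdict(list)
    group_kind: dict[tuple, str] = {}
    for tkey in classified.types:
        rec = next(r for r in classified.records if r.type_key == tkey)
        if rec.region == "CDS":
            gkey = ("gene", rec.locus_tag)
            group_kind[gkey] = "gene"
        else:
            left, right, start, end = annotation.intergenic_interval(rec.position)
            gkey = ("intergenic", start, end, left, right)
            group_kind[gkey] = "intergenic"
        if tkey not in groups[gkey]:
            groups[gkey].append(tkey)

    # name intergenic groups: explicit names first, then auto-number the rest
    intergenic_keys = sorted(
        (g for g in groups if group_kind[g] == "intergenic"), key=lambda g: g[1]
    )
    region_label: dict[tuple, str] = {}
    auto_j = 1
    used_names = set()
    for g in intergenic_keys:
        flank = frozenset({g[3], g[4]})
        if flank in region_names:
            region_label[g] = region_names[flank]
            used_names.add(region_names[flank])
    for g in intergenic_keys:
        if g in region_label:
            continue
        while f"NC{auto_j}" in used_names:
            auto_j += 1
        region_label[g] = f"NC{auto_j}"
        used_names.add(f"NC{auto_j}")
        auto_j += 1

    codes: dict[tuple[int, str, str], str] = {}
    for gkey, tkeys in groups.items():
        if group_kind[gkey] == "gene":
            base = _gene_code(gkey[1])
        else:
            base = region_label[gkey]
        tkeys = sorted(tkeys)  # ascending (position, ref, alt)
        if len(tkeys) == 1:
            codes[tkeys[0]] = base
        else:
            for k, tkey in enumerate(tkeys, start=1):
                codes[tkey] = f"{base}-{k}"
    if code_overrides:
        unknown = set(code_overrides) - set(codes)
        if unknown:
            raise CodingError(f"code_overrides reference unknown types: {sorted(unknown)}")
        codes.update(code_overrides)

    out = [replace(r, code=codes[r.type_key]) for r in classified.records]
    return MutationCatalog(out, strains=list(classified.strains))


def catalog_summary(catalog: MutationCatalog) -> dict:
    """Descriptive statistics of a (classified) catalog.

    Counts records (per-strain occurrences) and types (deduplicated
    position/ref/alt triples); an empty catalog yields zeros.
    """
    records = catalog.records
    n_records = len(records)
    n_strains = len(catalog.strains)
    type_keys = catalog.types
    kind_of: dict[tuple[int, str, str], str] = {}
    region_of: dict[tuple[int, str, str], str] = {}
    effect_of: dict[tuple[int, str, str], str] = {}
    for r in records:
        kind_of[r.type_key] = r.kind
        region_of[r.type_key] = r.region
        effect_of[r.type_key] = r.effect
    snp_types = [t for t in type_keys if kind_of[t] == "SNP"]
    indel_types = [t for t in type_keys if kind_of[t] != "SNP"]
    cds_snp_types = [t for t in snp_types if region_of[t] == "CDS"]
    effect_counts = Counter(effect_of[t] for t in type_keys)
    per_strain = {s: sum(1 for r in records if r.strain_id == s) for s in catalog.strains}
    return {
        "total_records": n_records,
        "n_strains": n_strains,
        "mean_per_strain": round(n_records / n_strains, 1) if n_strains else 0.0,
        "n_types": len(type_keys),
        "snp_types": len(snp_types),
        "indel_types": len(indel_types),
        "insertion_types": sum(1 for t in indel_types if kind_of[t] == "insertion"),
        "deletion_types": sum(1 for t in indel_types if kind_of[t] == "deletion"),
        "cds_types": sum(1 for t in type_keys if region_of[t] == "CDS"),
        "intergenic_types": sum(1 for t in type_keys if region_of[t] == "intergenic"),
        "cds_snp_types": len(cds_snp_types),
        "effect_counts": dict(effect_counts),
        "zygosity_counts": dict(Counter(r.zygosity for r in records)),
        "per_strain_counts": per_strain,
    }
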