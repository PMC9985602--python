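"""Seeded synthetic-data generators with known ground truth.

Every analysis stage in this package has a matching generator that emulates
the statistical structure of its real input, so the whole pipeline is
testable end-to-end without downloads:

* strain catalogs with two mutually exclusive planted driver groups and
  Poisson-distributed passenger mutations on a toy annotated genome;
* selective-plating replicates with Poisson-sampled resistant-colony counts
  at a set true mutant frequency;
* proteomes whose classes have controlled aromatic (Y/F/W) fractions;
* P700-style exponential recovery traces with additive Gaussian noise.

All generators are bit-reproducible given a seed and return a truth record
alongside the dataset; recovery tests consume only the dataset and compare
against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .catalog import (
    Feature,
    GenomeAnnotation,
    MutationCatalog,
    MutationRecord,
    assign_codes,
    classify_catalog,
)
from .composition import ProteinRecord
from .physiology import KineticTrace
from .rates import PlatingExperiment

__all__ = [
    "CatalogSimSpec",
    "PlatingSimSpec",
    "toy_genome",
    "simulate_catalog",
    "simulate_plating",
    "simulate_proteome",
    "simulate_trace",
]

_BASES = "ACGT"
_NON_AROMATIC = "ACDEGHIKLMNPQRSTV"  # canonical alphabet minus Y, F, W


def toy_genome(length: int = 2_000_000, gene_length: int = 900,
               gene_spacing: int = 1000, seed: int = 0) -> GenomeAnnotation:
    """Linear toy genome with evenly spaced CDS features.

    Real codon arithmetic needs a real annotation, not the real genome: one
    CDS of ``gene_length`` bp (a codon multiple) every ``gene_spacing`` bp,
    alternating strands, locus tags ``toy_<k>``.
    """
    if gene_length % 3 != 0:
        raise ValueError("gene_length must be a codon multiple")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(_BASES.encode(), dtype=np.uint8)
    seq = bases[rng.integers(0, 4, length)].tobytes().decode()
    features = []
    k = 1
    start = 51
    while start + gene_length - 1 <= length - 50:
        features.append(
            Feature(f"toy_{k:04d}", start, start + gene_length - 1,
                    "+" if k % 2 else "-")
        )
        start += gene_spacing
        k += 1
    return GenomeAnnotation(seq, features)


@dataclass(frozen=True)
class CatalogSimSpec:
    """Planted-driver catalog simulation parameters.

    Each strain draws one of two driver groups (group A with probability
    ``p``) and carries one uniformly chosen type from that group, plus
    Poisson(``passenger_rate``) passengers sampled with replacement from a
    shared pool.  Defaults mirror the evolved-strain study regime: 23
    strains, a 65/35 driver split, and enough passengers for roughly four
    mutations per strain.
    """

    n_strains: int = 23
    p: float = 0.652
    n_types_group_a: int = 1
    n_types_group_b: int = 3
    passenger_rate: float = 2.8
    passenger_pool_size: int = 40
    heterogeneous_prob: float = 0.07
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")
        if self.passenger_rate < 0:
            raise ValueError("passenger_rate must be >= 0")
        if self.passenger_pool_size < 1:
            raise ValueError("passenger_pool_size must be >= 1")
        if min(self.n_types_group_a, self.n_types_group_b) < 1:
            raise ValueError("driver groups need at least one type each")


def _random_snp(annotation: GenomeAnnotation, rng: np.random.Generator,
                used: set[int]) -> tuple[int, str, str]:
    while True:
        pos = int(rng.integers(1, len(annotation) + 1))
        if pos in used:
            continue
        used.add(pos)
        ref = annotation.sequence[pos - 1]
        alt = _BASES[(_BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        return (pos, ref, alt)


def simulate_catalog(
    spec: CatalogSimSpec, annotation: Optional[GenomeAnnotation] = None
) -> tuple[MutationCatalog, dict]:
    """Simulate a coded strain catalog with planted exclusive drivers.

    Returns ``(catalog, truth)`` where ``truth`` lists the driver type codes
    of each group, each strain's group, and the passenger pool codes.
    """
    rng = np.random.default_rng(spec.seed)
    if annotation is None:
        annotation = toy_genome(seed=spec.seed)
    used: set[int] = set()
    group_a = [_random_snp(annotation, rng, used) for _ in range(spec.n_types_group_a)]
    group_b = [_random_snp(annotation, rng, used) for _ in range(spec.n_types_group_b)]
    pool = [_random_snp(annotation, rng, used) for _ in range(spec.passenger_pool_size)]

    records: list[MutationRecord] = []
    assignment: dict[str, str] = {}
    strains = [f"SIM{n:03d}" for n in range(1, spec.n_strains + 1)]
    for strain in strains:
        in_a = bool(rng.random() < spec.p)
        assignment[strain] = "A" if in_a else "B"
        group = group_a if in_a else group_b
        picks = {tuple(group[int(rng.integers(len(group)))])}
        n_pass = int(rng.poisson(spec.passenger_rate))
        picks.update(tuple(pool[int(i)]) for i in rng.integers(0, len(pool), n_pass))
        for pos, ref, alt in sorted(picks):
            zyg = "heterogeneous" if rng.random() < spec.heterogeneous_prob else "homozygous"
            records.append(MutationRecord(strain, pos, ref, alt, "SNP", zyg))
    catalog = MutationCatalog(records, strains=strains)
    catalog = assign_codes(classify_catalog(catalog, annotation), annotation)
    codes = catalog.type_codes()
    truth = {
        "driver_codes_a": sorted(codes[t] for t in group_a if t in codes),
        "driver_codes_b": sorted(codes[t] for t in group_b if t in codes),
        "strain_groups": assignment,
        "passenger_codes": sorted(codes[t] for t in pool if t in codes),
    }
    return catalog, truth


@dataclass(frozen=True)
class PlatingSimSpec:
    """Poisson plating-assay simulation at a known true mutant frequency."""

    true_frequency: float
    plated_cells: int = 2_000_000_000
    n_replicates: int = 3
    strain_id: str = "SIM"
    binomial: bool = False  # exact sampling; Poisson is the regime-appropriate default
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.true_frequency <= 1.0):
            raise ValueError("true_frequency must lie in [0, 1]")
        if self.plated_cells < 1:
            raise ValueError("plated_cells must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def simulate_plating(spec: PlatingSimSpec) -> list[PlatingExperiment]:
    """Resistant-colony counts, one :class:`PlatingExperiment` per replicate."""
    rng = np.random.default_rng(spec.seed)
    lam = spec.true_frequency * spec.plated_cells
    if lam > 2**62:
        raise OverflowError("frequency x plated_cells too large to sample")
    if spec.binomial:
        counts = rng.binomial(spec.plated_cells, spec.true_frequency, spec.n_replicates)
    else:
        counts = np.minimum(rng.poisson(lam, spec.n_replicates), spec.plated_cells)
    return [
        PlatingExperiment(spec.strain_id, spec.plated_cells, int(c), replicate=i + 1)
        for i, c in enumerate(counts)
    ]


def simulate_proteome(
    n_per_class: int,
    class_fractions: Mapping[str, float],
    protein_length: int = 300,
    seed: int = 0,
) -> list[ProteinRecord]:
    """Proteins drawn residue-wise with per-class aromatic probability.

    Aromatic positions are Bernoulli(target fraction) and filled uniformly
    from {Y, F, W}; the composition analysis recovers each class target
    within binomial sampling error.
    """
    for cls, frac in class_fractions.items():
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"class {cls!r}: fraction {frac} outside [0, 1]")
    rng = np.random.default_rng(seed)
    proteins = []
    for cls in class_fractions:  # mapping order is part of the reproducible stream
        frac = class_fractions[cls]
        for i in range(n_per_class):
            aromatic = rng.random(protein_length) < frac
            residues = [
                "YFW"[int(rng.integers(3))] if a else
                _NON_AROMATIC[int(rng.integers(len(_NON_AROMATIC)))]
                for a in aromatic
            ]
            loc = cls if cls in ("membrane", "soluble") else "unknown"
            proteins.append(
                ProteinRecord(f"{cls}_{i:04d}", "".join(residues), localization=loc,
                              pathway_tags=frozenset({cls}))
            )
    return proteins


def simulate_trace(
    k: float,
    noise_sd: float = 0.0,
    sampling_rate: float = 100.0,
    t_off: float = 40.0,
    pre_duration: float = 5.0,
    post_duration: float = 8.0,
    amplitude: float = 1.0,
    offset: float = 0.0,
    seed: int = 0,
) -> KineticTrace:
    """Exponential recovery trace: plateau 1 before ``light_off``, then
    ``1 - exp(-k (t - t_off))`` after, scaled by ``amplitude`` and shifted by
    ``offset``, with additive Gaussian noise.  The initial slope of the
    underlying model at light-off is exactly ``k`` (times ``amplitude``).
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    rng = np.random.default_rng(seed)
    dt = 1.0 / sampling_rate
    t = np.arange(t_off - pre_duration, t_off + post_duration + dt / 2, dt)
    s = np.where(t < t_off, 1.0, 1.0 - np.exp(-k * np.maximum(t - t_off, 0.0)))
    signal = offset + amplitude * s + rng.normal(0.0, noise_sd, t.size)
    return KineticTrace(t, signal, {"light_off": t_off})
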