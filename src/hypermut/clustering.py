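"""Strain similarity clustering over binary mutation profiles.

Each evolved strain is a 0/1 vector over the deduplicated mutation types,
and the pairwise dissimilarity is

    Distance(a, b) = 1 / (a . b + 1)

i.e. the reciprocal of one plus the number of shared mutation types.  Note
this is *not* a metric: the self-distance is 1/(|a| + 1) > 0 and the
triangle inequality fails.  For agglomerative clustering the diagonal is
forced to 0 purely as an algorithmic convention; the off-diagonal values are
reported as defined.  Two strains sharing nothing sit at distance exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .catalog import MutationCatalog

__all__ = [
    "MutationMatrix",
    "StrainDistanceMatrix",
    "eq1_distance",
    "distance_matrix",
    "cluster_strains",
    "exclusivity_scan",
]

_LINKAGE_METHODS = ("single", "complete", "average")


@dataclass
class MutationMatrix:
    """Binary strains x mutation-types incidence matrix."""

    strains: list[str]
    types: list[str]
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells)
        if self.cells.shape != (len(self.strains), len(self.types)):
            raise ValueError("cells shape does not match strains x types")
        if not np.isin(self.cells, (0, 1)).all():
            raise ValueError("cells must be binary")

    @classmethod
    def from_catalog(cls, catalog: MutationCatalog) -> "MutationMatrix":
        """Presence/absence of each coded mutation type per strain.
        Heterogeneous mutations count as present (value 1)."""
        codes = catalog.type_codes()
        if len(codes) < len(catalog.types):
            raise ValueError("catalog types are not all coded; run assign_codes first")
        type_order = [codes[t] for t in catalog.types]
        index = {c: j for j, c in enumerate(type_order)}
        cells = np.zeros((len(catalog.strains), len(type_order)), dtype=int)
        row = {s: i for i, s in enumerate(catalog.strains)}
        for r in catalog.records:
            cells[row[r.strain_id], index[r.code]] = 1
        return cls(list(catalog.strains), type_order, cells)

    def vector(self, strain_id: str) -> np.ndarray:
        return self.cells[self.strains.index(strain_id)]

    def carriers(self, code: str) -> list[str]:
        j = self.types.index(code)
        return [s for s, v in zip(self.strains, self.cells[:, j]) if v]


@dataclass
class StrainDistanceMatrix:
    strains: list[str]
    values: np.ndarray
    linkage_method: str = ""


def eq1_distance(a: Sequence[int], b: Sequence[int]) -> float:
    """Dissimilarity 1 / (a.b + 1) of two equal-length binary vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return 1.0 / (float(a @ b) + 1.0)


def distance_matrix(matrix: MutationMatrix) -> StrainDistanceMatrix:
    """All pairwise strain dissimilarities (diagonal reported as defined,
    i.e. 1/(|a|+1), not zeroed)."""
    overlap = matrix.cells @ matrix.cells.T
    return StrainDistanceMatrix(list(matrix.strains), 1.0 / (overlap + 1.0))


def cluster_strains(
    matrix: MutationMatrix, linkage: str = "average"
) -> tuple[TreeNode, StrainDistanceMatrix]:
    """Agglomerative clustering of strains under the reciprocal-overlap
    dissimilarity; returns a tree with merge heights as branch lengths.

    Strains are processed in lexicographic order so the result is invariant
    to input row order (up to leaf rotation).  Linkage is UPGMA by default.
    """
    if linkage not in _LINKAGE_METHODS:
        raise ValueError(f"linkage must be one of {_LINKAGE_METHODS}")
    if len(matrix.strains) < 2:
        raise ValueError("need at least 2 strains to cluster")
    order = np.argsort(matrix.strains)
    strains = [matrix.strains[i] for i in order]
    cells = matrix.cells[order]
    dist = 1.0 / (cells @ cells.T + 1.0)
    np.fill_diagonal(dist, 0.0)  # clustering convention only
    z = scipy_linkage(squareform(dist, checks=False), method=linkage)
    tree = TreeNode.from_linkage_matrix(z, strains)
    dm = StrainDistanceMatrix(strains, dist, linkage_method=linkage)
    return tree, dm


def _collapse(matrix: MutationMatrix, grouping: Optional[Mapping[str, str]]) -> dict[str, frozenset]:
    """Carrier strain-sets per (possibly collapsed) mutation group."""
    carriers: dict[str, set] = {}
    for j, code in enumerate(matrix.types):
        group = grouping.get(code, code) if grouping else code
        carriers.setdefault(group, set()).update(
            s for s, v in zip(matrix.strains, matrix.cells[:, j]) if v
        )
    return {g: frozenset(c) for g, c in carriers.items()}


def exclusivity_scan(
    matrix: MutationMatrix, grouping: Optional[Mapping[str, str]] = None
) -> list[tuple[str, str, int, int]]:
    """Find pairs of mutation groups with disjoint carrier sets that jointly
    cover every strain — the mutual-exclusivity signature of alternative
    driver mutations.  ``grouping`` may collapse codes (e.g. NC2-1/2/3 ->
    NC2).  Returns ``(group1, group2, n_carriers1, n_carriers2)`` tuples,
    lexicographically ordered; an empty list is a valid result.
    """
    carriers = _collapse(matrix, grouping)
    all_strains = set(matrix.strains)
    pairs = []
    for g1, g2 in combinations(sorted(carriers), 2):
        c1, c2 = carriers[g1], carriers[g2]
        if c1 and c2 and not (c1 & c2) and (c1 | c2) == all_strains:
            pairs.append((g1, g2, len(c1), len(c2)))
    return pairs
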