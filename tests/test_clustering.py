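"""Reciprocal-overlap dissimilarity, hierarchical clustering, exclusivity."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hypermut.clustering import (
    MutationMatrix,
    cluster_strains,
    distance_matrix,
    eq1_distance,
    exclusivity_scan,
)
from hypermut.prioritize import region_of_code
from hypermut.synthgen import CatalogSimSpec, simulate_catalog

binary_vec = st.lists(st.integers(0, 1), min_size=1, max_size=40)


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ([1, 0, 1], [0, 1, 0], 1.0),   # disjoint
        ([1, 0, 0], [1, 0, 0], 0.5),   # one shared type
        ([1, 1, 1, 0], [1, 1, 1, 1], 0.25),  # three shared
    ],
)
def test_distance_examples(a, b, expected):
    assert eq1_distance(a, b) == pytest.approx(expected)


def test_distance_rejects_length_mismatch():
    with pytest.raises(ValueError):
        eq1_distance([1, 0], [1, 0, 1])


@given(pair=st.integers(1, 39).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(0, 1), min_size=n, max_size=n),
        st.lists(st.integers(0, 1), min_size=n, max_size=n),
    )
))
def test_distance_symmetric_bounded_and_monotone(pair):
    """d(a,b) = d(b,a), lies in (0, 1], and strictly decreases when one more
    shared type is added."""
    a, b = pair
    d = eq1_distance(a, b)
    assert d == eq1_distance(b, a)
    assert 0.0 < d <= 1.0
    free = [i for i in range(len(a)) if not (a[i] and b[i])]
    if free:
        i = free[0]
        a2, b2 = list(a), list(b)
        a2[i] = b2[i] = 1
        assert eq1_distance(a2, b2) < d


def test_not_a_metric_self_distance_positive():
    """The dissimilarity is deliberately not a metric: a strain's distance to
    itself is 1/(|a|+1) > 0.  distance_matrix reports it as defined; only the
    clustering step zeroes the diagonal."""
    m = MutationMatrix(["a", "b"], ["t1", "t2", "t3"],
                       np.array([[1, 1, 0], [0, 1, 1]]))
    dm = distance_matrix(m)
    assert dm.values[0, 0] == pytest.approx(1 / 3)
    assert dm.values[0, 1] == pytest.approx(1 / 2)


def test_matrix_from_catalog_row_sums_match_counts(fixture_catalog):
    m = MutationMatrix.from_catalog(fixture_catalog)
    counts = {s: 0 for s in fixture_catalog.strains}
    for r in fixture_catalog.records:
        counts[r.strain_id] += 1
    # a strain's row sum equals its number of distinct types
    for s in fixture_catalog.strains:
        distinct = len({r.type_key for r in fixture_catalog.records_of(s)})
        assert m.vector(s).sum() == distinct == counts[s]


def test_planted_groups_form_the_two_root_children():
    """With single-type exclusive driver groups, no passengers and hence no
    cross-group sharing, every linkage method splits the two groups at the
    root (between-group distances are exactly 1, within-group 0.5)."""
    cat, truth = simulate_catalog(
        CatalogSimSpec(passenger_rate=0.0, n_types_group_b=1, seed=11)
    )
    m = MutationMatrix.from_catalog(cat)
    ga = frozenset(s for s, g in truth["strain_groups"].items() if g == "A")
    gb = frozenset(truth["strain_groups"]) - ga
    for method in ("single", "complete", "average"):
        tree, _ = cluster_strains(m, method)
        children = {
            frozenset(t.name for t in child.tips()) if child.children
            else frozenset({child.name})
            for child in tree.children
        }
        assert children == {ga, gb}, method


def test_identical_strains_merge_first_at_minimal_distance():
    m = MutationMatrix(
        ["a", "b", "c"],
        ["t1", "t2", "t3"],
        np.array([[1, 1, 1], [1, 1, 1], [1, 0, 0]]),
    )
    tree, dm = cluster_strains(m)
    first_pair = min(
        combinations(range(3), 2), key=lambda ij: dm.values[ij[0], ij[1]]
    )
    assert {m.strains[i] for i in first_pair} == {"a", "b"}
    ab = tree.find("a").parent
    assert {t.name for t in ab.tips()} == {"a", "b"}
    assert ab.find("a").length == pytest.approx(0.25 / 2)  # merge height 1/4


def test_cluster_requires_two_strains():
    m = MutationMatrix(["a"], ["t1"], np.array([[1]]))
    with pytest.raises(ValueError):
        cluster_strains(m)


def test_cluster_invariant_to_strain_input_order(fixture_catalog):
    m = MutationMatrix.from_catalog(fixture_catalog)
    rng = np.random.default_rng(3)
    perm = rng.permutation(len(m.strains))
    shuffled = MutationMatrix([m.strains[i] for i in perm], m.types, m.cells[perm])
    t1, _ = cluster_strains(m)
    t2, _ = cluster_strains(shuffled)
    assert str(t1) == str(t2)


def _brute_force_pairs(matrix, grouping=None):
    carriers = {}
    for j, code in enumerate(matrix.types):
        g = grouping.get(code, code) if grouping else code
        for i, s in enumerate(matrix.strains):
            if matrix.cells[i, j]:
                carriers.setdefault(g, set()).add(s)
    out = []
    everyone = set(matrix.strains)
    for g1 in sorted(carriers):
        for g2 in sorted(carriers):
            if g1 < g2 and not (carriers[g1] & carriers[g2]) \
                    and carriers[g1] | carriers[g2] == everyone:
                out.append((g1, g2, len(carriers[g1]), len(carriers[g2])))
    return out


def test_exclusivity_on_fixture(fixture_catalog):
    m = MutationMatrix.from_catalog(fixture_catalog)
    grouping = {c: region_of_code(c) for c in m.types}
    pairs = exclusivity_scan(m, grouping)
    assert ("0336", "NC2", 15, 8) in pairs


def test_shared_carrier_excludes_the_pair():
    m = MutationMatrix(
        ["a", "b", "c"], ["x", "y"], np.array([[1, 0], [0, 1], [1, 1]])
    )
    assert exclusivity_scan(m) == []


def test_exclusivity_matches_brute_force_on_random_matrices():
    rng = np.random.default_rng(5)
    for _ in range(30):
        n_strains = int(rng.integers(3, 12))
        n_groups = int(rng.integers(2, 20))
        cells = (rng.random((n_strains, n_groups)) < 0.3).astype(int)
        m = MutationMatrix(
            [f"s{i}" for i in range(n_strains)],
            [f"g{j}" for j in range(n_groups)],
            cells,
        )
        assert exclusivity_scan(m) == _brute_force_pairs(m)


def test_random_passenger_matrices_rarely_exclusive():
    """At planted passenger density, spurious exclusive-and-covering pairs
    are rare: over seeded random matrices most scans are empty."""
    rng = np.random.default_rng(12)
    n_hits = 0
    for _ in range(50):
        cells = (rng.random((23, 15)) < 0.25).astype(int)
        m = MutationMatrix(
            [f"s{i}" for i in range(23)], [f"g{j}" for j in range(15)], cells
        )
        n_hits += bool(exclusivity_scan(m))
    assert n_hits <= 2
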