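"""Aromatic (Y/F/W) residue composition of a proteome.

The shikimate pathway supplies the three aromatic amino acids; their
proportion in a proteome, overall and split by protein localization class
(membrane vs soluble, e.g. from a transmembrane-topology predictor) or
pathway tag, indicates how strongly each protein class depends on pathway
flux.  Two statistics are emitted side by side: the pooled proportion
(total aromatic residues / total residues, i.e. the length-weighted mean)
and the unweighted per-protein mean.  Ambiguity codes (X, B, Z, U, O) are
excluded from both numerator and denominator: they are not amino-acid
observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

__all__ = ["ProteinRecord", "aromatic_fraction", "proteome_composition", "AROMATIC"]

AROMATIC = frozenset("YFW")
_CANONICAL = frozenset("ACDEFGHIKLMNPQRSTVWY")
_AMBIGUOUS = frozenset("XBZUO")


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    sequence: str
    localization: Literal["membrane", "soluble", "unknown"] = "unknown"
    pathway_tags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id}: empty sequence")
        bad = set(self.sequence.upper()) - _CANONICAL - _AMBIGUOUS - {"*"}
        if bad:
            raise ValueError(f"protein {self.protein_id}: invalid residues {sorted(bad)}")


def _counts(sequence: str) -> tuple[int, int]:
    """(aromatic count, canonical-residue denominator) for one sequence."""
    seq = sequence.upper()
    aromatic = sum(seq.count(a) for a in AROMATIC)
    denom = sum(1 for c in seq if c in _CANONICAL)
    return aromatic, denom


def aromatic_fraction(sequence: str) -> float:
    """Fraction of Y+F+W among the canonical residues of one protein."""
    if not sequence:
        raise ValueError("empty sequence")
    aromatic, denom = _counts(sequence)
    if denom == 0:
        raise ValueError("sequence contains no canonical residues")
    return aromatic / denom


def proteome_composition(
    proteins: Sequence[ProteinRecord], group_by: Literal["class", "tag"] = "class"
) -> pd.DataFrame:
    """Aromatic composition per group plus an ``all`` row.

    Each row reports residue counts for Y, F, W, the total canonical residue
    count, the pooled proportion, the unweighted per-protein mean proportion,
    and the protein count.  Proteins with unknown class (or no tags) appear
    in the ``all`` row only; a protein with several tags contributes to each.
    """
    if not proteins:
        raise ValueError("need at least one protein")

    def groups_of(p: ProteinRecord) -> Iterable[str]:
        if group_by == "class":
            return [p.localization] if p.localization != "unknown" else []
        return sorted(p.pathway_tags)

    rows: dict[str, dict] = {}

    def add(group: str, p: ProteinRecord) -> None:
        seq = p.sequence.upper()
        g = rows.setdefault(
            group, {"Y": 0, "F": 0, "W": 0, "total_residues": 0,
                    "n_proteins": 0, "_fracs": []}
        )
        for aa in "YFW":
            g[aa] += seq.count(aa)
        _, denom = _counts(seq)
        g["total_residues"] += denom
        g["n_proteins"] += 1
        g["_fracs"].append(aromatic_fraction(seq))

    for p in proteins:
        add("all", p)
        for group in groups_of(p):
            add(group, p)

    out = []
    for group, g in rows.items():
        out.append(
            {
                "group": group,
                "Y": g["Y"],
                "F": g["F"],
                "W": g["W"],
                "total_residues": g["total_residues"],
                "n_proteins": g["n_proteins"],
                "pooled_proportion": (g["Y"] + g["F"] + g["W"]) / g["total_residues"],
                "mean_proportion": sum(g["_fracs"]) / len(g["_fracs"]),
            }
        )
    df = pd.DataFrame(out).set_index("group")
    return df.loc[["all"] + sorted(i for i in df.index if i != "all")]
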