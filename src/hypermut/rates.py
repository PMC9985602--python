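"""Mutation-frequency estimation from selective plating assays.

The rifampicin-resistance plating assay counts spontaneous resistant
colonies among a known number of plated cells; the resistant-cell frequency
(colonies / plated cells) is the mutation-rate proxy, and strain effects are
expressed as fold changes against a wild-type reference with a two-tailed
unpaired t-test on per-replicate frequencies.  Frequencies, not
Luria-Delbruck corrected rates, are the primary statistic here;
fluctuation-assay maximum-likelihood estimation is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PlatingExperiment",
    "RelativeRateResult",
    "mutation_frequency",
    "relative_rate",
    "survival_rate",
]


@dataclass(frozen=True)
class PlatingExperiment:
    """One replicate of a selective plating assay under one condition."""

    strain_id: str
    plated_cells: int
    resistant_colonies: int
    condition: tuple = ()
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.plated_cells < 1:
            raise ValueError("plated_cells must be >= 1")
        if self.resistant_colonies < 0:
            raise ValueError("resistant_colonies must be >= 0")
        if self.resistant_colonies > self.plated_cells:
            raise ValueError("resistant_colonies cannot exceed plated_cells")


@dataclass(frozen=True)
class RelativeRateResult:
    strain_id: str
    condition: tuple
    mean_frequency: float
    sd_frequency: float
    fold_change: float
    p_value: float
    n: int


def mutation_frequency(exp: PlatingExperiment) -> float:
    """Resistant-cell frequency of one plating replicate."""
    return exp.resistant_colonies / exp.plated_cells


def relative_rate(
    test: Sequence[PlatingExperiment],
    reference: Sequence[PlatingExperiment],
    welch: bool = False,
) -> RelativeRateResult:
    """Fold change of mean resistant-cell frequency against a reference.

    ``fold = mean(test freqs) / mean(reference freqs)``, with a two-tailed
    unpaired Student's t-test on the per-replicate frequencies (equal
    variances by default, Welch with ``welch=True``).  The reference pool is
    aggregated over all its replicates; zero-colony replicates are kept at
    frequency 0.  Identical test and reference samples give fold 1 and p 1.
    """
    if not test or not reference:
        raise ValueError("need at least one replicate on each side")
    f_test = np.array([mutation_frequency(e) for e in test])
    f_ref = np.array([mutation_frequency(e) for e in reference])
    ref_mean = f_ref.mean()
    if ref_mean == 0:
        raise ZeroDivisionError("reference mean frequency is 0; fold change undefined")
    fold = f_test.mean() / ref_mean
    if np.array_equal(f_test, f_ref):
        p = 1.0
    elif len(f_test) < 2 or len(f_ref) < 2:
        p = math.nan
    else:
        p = float(stats.ttest_ind(f_test, f_ref, equal_var=not welch).pvalue)
    return RelativeRateResult(
        strain_id=test[0].strain_id,
        condition=test[0].condition,
        mean_frequency=float(f_test.mean()),
        sd_frequency=float(f_test.std(ddof=1)) if len(f_test) > 1 else 0.0,
        fold_change=float(fold),
        p_value=p,
        n=len(f_test),
    )


def survival_rate(treated_colonies: int, plated_cells: int) -> tuple[float, float]:
    """Survival fraction and lethality after a mutagen treatment.

    ``survival = colonies / plated cells``; ``lethality = 1 - survival``.
    """
    if plated_cells < 1:
        raise ValueError("plated_cells must be >= 1")
    if treated_colonies < 0 or treated_colonies > plated_cells:
        raise ValueError("colony count must lie in [0, plated_cells]")
    survival = treated_colonies / plated_cells
    return survival, 1.0 - survival
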