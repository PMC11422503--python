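"""Gene labelling: turn observation counts plus count cutoffs into core/middle/rare labels."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .matrix_io import PresenceAbsenceMatrix
from .poisbin import (
    ThresholdConfig,
    adjust_core_threshold,
    adjust_rare_threshold,
    unadjusted_cutoffs,
)

__all__ = [
    "ThresholdResult",
    "GeneClassification",
    "gene_counts",
    "classify_genes",
    "compute_thresholds",
]


@dataclass(frozen=True)
class ThresholdResult:
    """Integer count cutoffs and their estimated error probabilities.

    A gene observed strictly more than ``x_core`` times is core; strictly
    fewer than ``x_rare`` times is rare; otherwise middle. ``x_core = -1``
    is the sentinel meaning every observed gene is core. The three label
    regions always partition the count range 0..N.
    """

    x_core: int
    x_rare: int
    fnr_at_core: float
    fpr_at_rare: float
    n_genomes: int
    config: ThresholdConfig | None = None

    def __post_init__(self) -> None:
        if not -1 <= self.x_core <= self.n_genomes:
            raise ValueError(f"x_core={self.x_core} outside [-1, {self.n_genomes}]")
        if not 0 <= self.x_rare <= self.n_genomes + 1:
            raise ValueError(f"x_rare={self.x_rare} outside [0, {self.n_genomes + 1}]")
        if self.x_rare > self.x_core + 1:
            raise ValueError(
                f"x_rare ({self.x_rare}) > x_core + 1 ({self.x_core + 1}): "
                "label regions would overlap"
            )


@dataclass(frozen=True)
class GeneClassification:
    gene_id: str
    count: int
    frequency: float
    label: str  # core | middle | rare


def gene_counts(matrix: PresenceAbsenceMatrix) -> np.ndarray:
    """Number of genomes each gene was observed in (row sums)."""
    return matrix.values.sum(axis=1, dtype=np.int64)


def compute_thresholds(
    completeness: Sequence[float],
    config: ThresholdConfig,
    adjust: bool = True,
) -> ThresholdResult:
    """Compute core and rare count cutoffs for a genome collection.

    With ``adjust=True`` both cutoffs come from the Poisson-binomial model
    marginalised over the truncated Beta prior; with ``adjust=False`` the
    classical fixed-frequency rule is used (core iff observed frequency
    >= t_core, rare iff < t_rare) and the error probabilities are not
    estimated (reported as NaN).
    """
    c = np.asarray(completeness, dtype=float)
    n = c.size
    if adjust:
        x_core, fnr = adjust_core_threshold(c, config)
        x_rare, fpr = adjust_rare_threshold(c, config)
    else:
        x_core, x_rare = unadjusted_cutoffs(n, config.t_core, config.t_rare)
        fnr = fpr = float("nan")
    return ThresholdResult(
        x_core=x_core,
        x_rare=x_rare,
        fnr_at_core=fnr,
        fpr_at_rare=fpr,
        n_genomes=n,
        config=config,
    )


def classify_genes(
    matrix: PresenceAbsenceMatrix, thresholds: ThresholdResult
) -> tuple[list[GeneClassification], dict[str, int]]:
    """Label every gene and summarise.

    Returns the per-gene records plus ``{"n_core", "n_middle", "n_rare"}``.
    The partition is exhaustive and exclusive, so the summary always sums to
    the gene total. Genes never observed at all are labelled rare but
    flagged with a warning: clusterers normally do not emit all-zero rows,
    so their presence points at an upstream problem.
    """
    if matrix.n_genomes != thresholds.n_genomes:
        raise ValueError(
            f"matrix has {matrix.n_genomes} genomes but thresholds were "
            f"computed for {thresholds.n_genomes}"
        )
    counts = gene_counts(matrix)
    n = matrix.n_genomes
    n_zero = int((counts == 0).sum())
    if n_zero:
        warnings.warn(
            f"{n_zero} gene(s) observed in no genome; retained and labelled "
            "by the cutoffs, but all-zero rows usually signal an upstream "
            "clustering issue",
            stacklevel=2,
        )
    results: list[GeneClassification] = []
    summary = {"n_core": 0, "n_middle": 0, "n_rare": 0}
    for gene_id, count in zip(matrix.gene_ids, counts):
        count = int(count)
        if count > thresholds.x_core:
            label = "core"
        elif count < thresholds.x_rare:
            label = "rare"
        else:
            label = "middle"
        summary[f"n_{label}"] += 1
        results.append(
            GeneClassification(
                gene_id=gene_id, count=count, frequency=count / n, label=label
            )
        )
    return results, summary
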