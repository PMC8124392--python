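"""Quality control and reproducibility diagnostics.

Biotin pull-downs carry two built-in loading controls: the endogenously
biotinylated carboxylases (ACACA, HLCS, MCCC1, PC, PCCA), which report the
amount of biological material, and ubiquitin itself (plus the avidin bait),
which reports the total ubiquitinated material.  Neither should shift
between control and DUB-silenced samples; a significant shift flags the
experiment.  Replicate agreement is summarised by pairwise Pearson
correlation of observed (non-imputed) log2 intensities and by Venn-region
overlap counts of the identified protein sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .differential import DifferentialResult, Thresholds
from .preprocess import IntensityMatrix

__all__ = [
    "QCPanel",
    "QCMemberReport",
    "QCReport",
    "qc_report",
    "replicate_correlation",
    "overlap_counts",
    "pairwise_containment",
]


@dataclass(frozen=True)
class QCPanel:
    """Identifier panels for the built-in controls (all configurable)."""

    carboxylase_genes: frozenset[str] = frozenset({"ACACA", "HLCS", "MCCC1", "PC", "PCCA"})
    ubiquitin_ids: frozenset[str] = frozenset({"UBB", "UBC", "UBA52", "RPS27A"})
    avidin_ids: frozenset[str] = frozenset({"AVD"})

    @property
    def all_ids(self) -> frozenset[str]:
        return self.carboxylase_genes | self.ubiquitin_ids | self.avidin_ids


@dataclass(frozen=True)
class QCMemberReport:
    gene: str
    detected: bool
    log2_fc: float | None = None
    p_value: float | None = None
    significant: bool = False


@dataclass(frozen=True)
class QCReport:
    members: tuple[QCMemberReport, ...]
    passed: bool
    warnings: tuple[str, ...] = ()

    def offenders(self) -> list[str]:
        return [m.gene for m in self.members if m.significant]


def qc_report(
    results: Sequence[DifferentialResult],
    panel: QCPanel | None = None,
    thresholds: Thresholds | None = None,
) -> QCReport:
    """Check that no QC-panel member shifts significantly between conditions.

    A member fails when |log2 FC| >= ``min_abs_log2_fc`` and p <
    ``max_p``; the report passes when no detected member fails.  Members
    absent from the results are reported as not detected, not as failures.
    """
    panel = panel or QCPanel()
    thresholds = thresholds or Thresholds()
    by_gene = {r.gene_name.upper(): r for r in results}
    members: list[QCMemberReport] = []
    notes: list[str] = []
    for gene in sorted(panel.all_ids):
        r = by_gene.get(gene.upper())
        if r is None:
            members.append(QCMemberReport(gene=gene, detected=False))
            continue
        significant = abs(r.log2_fc) >= thresholds.min_abs_log2_fc and r.p_value < thresholds.max_p
        members.append(
            QCMemberReport(
                gene=gene,
                detected=True,
                log2_fc=r.log2_fc,
                p_value=r.p_value,
                significant=significant,
            )
        )
    if not panel.all_ids:
        notes.append("QC panel is empty; report passes vacuously")
    elif not any(m.detected for m in members):
        notes.append("no QC panel member detected; report passes vacuously")
    return QCReport(
        members=tuple(members),
        passed=not any(m.significant for m in members),
        warnings=tuple(notes),
    )


def replicate_correlation(matrix: IntensityMatrix) -> np.ndarray:
    """Samples x samples Pearson correlation over pairwise-complete observed
    values.

    Imputed and missing cells are excluded, so the metric reflects measured
    data only.  Pairs with fewer than 3 common observed proteins are
    reported as NaN (undefined).
    """
    X = matrix.values
    observed = ~np.isnan(X) & ~matrix.imputed_mask
    n = X.shape[1]
    corr = np.eye(n)
    for i, j in combinations(range(n), 2):
        common = observed[:, i] & observed[:, j]
        if common.sum() < 3:
            corr[i, j] = corr[j, i] = np.nan
            continue
        xi, xj = X[common, i], X[common, j]
        if xi.std() == 0 or xj.std() == 0:
            corr[i, j] = corr[j, i] = np.nan
            continue
        corr[i, j] = corr[j, i] = float(np.corrcoef(xi, xj)[0, 1])
    return corr


def overlap_counts(id_sets: Mapping[str, Iterable]) -> dict[str, int]:
    """Counts of all 2^k - 1 exclusive Venn regions of k (2..5) named sets.

    Region labels join the member set names (sorted) with ``&``; counts sum
    to the size of the union.
    """
    names = sorted(id_sets)
    k = len(names)
    if not 2 <= k <= 5:
        raise ValueError(f"need between 2 and 5 sets, got {k}")
    sets = {name: set(id_sets[name]) for name in names}
    universe = set().union(*sets.values())
    counts: dict[str, int] = {}
    for r in range(1, k + 1):
        for members in combinations(names, r):
            counts["&".join(members)] = 0
    for element in universe:
        members = tuple(name for name in names if element in sets[name])
        counts["&".join(members)] += 1
    return counts


def pairwise_containment(set_a: Iterable, set_b: Iterable) -> float:
    """Fraction of the smaller set contained in the larger: |A∩B|/min(|A|,|B|)."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("both sets must be nonempty")
    return len(a & b) / min(len(a), len(b))
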