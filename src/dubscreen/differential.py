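"""Differential ubiquitination analysis and three-criterion substrate calling.

For each protein group the silenced and control log2 LFQ means are compared
with an equal-variance (pooled) two-tailed Student's t-test.  A protein is a
putative DUB substrate when it

1. shows at least a 2-fold LFQ increase upon silencing (log2 fold change
   >= 1) at p < 0.05,
2. is identified by at least 2 unique peptides, and
3. has an acceptable level of imputation: no imputed value in at least one
   condition, or at most one imputed value in each condition.

Fold changes are differences of condition means on the post-imputation log2
matrix, so the fold change and the t-test see the same data.  The inclusive
fold-change boundary (>= 2-fold, i.e. log2 >= 1) means a protein printed at
log2 FC 1.00 passes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .design import CONTROL, SILENCED
from .preprocess import IntensityMatrix
from .tables_io import ProteinGroupTable

__all__ = [
    "Thresholds",
    "DifferentialResult",
    "student_t_test",
    "imputation_rule",
    "DifferentialAnalyzer",
    "compute_differential",
    "call_substrates",
    "volcano_dataset",
    "benjamini_hochberg",
]

TINY_P = float(np.nextafter(0.0, 1.0))

CATEGORY_UP = "up"
CATEGORY_DOWN = "down"
CATEGORY_NS = "not_significant"
CATEGORY_QC = "qc_protein"
CATEGORY_DUB = "silenced_dub"


@dataclass(frozen=True)
class Thresholds:
    """Substrate-calling thresholds.

    Defaults match the screen's criteria: 2-fold LFQ change (|log2 FC| >= 1),
    p < 0.05, >= 2 unique peptides, up-regulated direction.
    """

    min_abs_log2_fc: float = 1.0
    max_p: float = 0.05
    min_unique_peptides: int = 2
    direction: str = "up"

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down", "both"):
            raise ValueError(f"direction must be up/down/both, got {self.direction!r}")
        if not 0 < self.max_p <= 1:
            raise ValueError("max_p must be in (0, 1]")


@dataclass(frozen=True)
class DifferentialResult:
    """Per-protein differential-ubiquitination outcome (silenced vs control)."""

    row_key: str
    gene_name: str
    description: str
    log2_fc: float
    p_value: float
    t_statistic: float
    mean_control: float
    mean_silenced: float
    n_imputed_control: int
    n_imputed_silenced: int
    unique_peptides: int
    category: str


def student_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pooled-variance two-sample Student's t-test, two-tailed.

    ``t`` is positive when ``mean(x) > mean(y)``; in the pipeline ``x`` is the
    silenced condition.  Degenerate inputs with zero pooled variance yield
    (0, 1) for equal means and (+/-inf, smallest positive float) with a
    warning for unequal means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        warnings.warn(
            "zero pooled variance with unequal means; reporting the smallest "
            "representable positive p-value",
            stacklevel=2,
        )
        return float(np.sign(x.mean() - y.mean()) * np.inf), TINY_P
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def imputation_rule(n_imp_ctrl: int, n_imp_sil: int, n_reps: int) -> bool:
    """Imputation-level acceptance for substrate calls.

    True when at least one condition contains no imputed values, or each
    condition contains at most one.
    """
    if not (0 <= n_imp_ctrl <= n_reps and 0 <= n_imp_sil <= n_reps):
        raise ValueError("imputed counts must lie in [0, n_reps]")
    return n_imp_ctrl == 0 or n_imp_sil == 0 or (n_imp_ctrl <= 1 and n_imp_sil <= 1)


# Default identifier panels used to tag QC rows in the volcano categories.
DEFAULT_QC_GENES = frozenset(
    {"ACACA", "HLCS", "MCCC1", "PC", "PCCA", "UBB", "UBC", "UBA52", "RPS27A", "AVD"}
)


class DifferentialAnalyzer:
    """Estimator-style wrapper for the differential-ubiquitination analysis.

    ``fit`` consumes a fully imputed :class:`IntensityMatrix` plus the
    filtered :class:`ProteinGroupTable` and exposes the per-protein results,
    the initial selection (fold change + p-value only) and the putative
    substrates (all three criteria).

    Parameters
    ----------
    thresholds : Thresholds
    qc_genes : iterable of str
        Gene symbols tagged ``qc_protein`` (endogenously biotinylated
        carboxylases, ubiquitin and avidin identifiers by default).  QC rows
        and the silenced DUB itself are never callable as substrates.
    p_adjust : {"none", "bh"}
        Optional Benjamini-Hochberg adjustment of the raw t-test p-values.
        Off by default: the screen's criteria use raw p-values.

    Attributes
    ----------
    results_ : list of DifferentialResult
    initial_selection_ : list of DifferentialResult
    putative_substrates_ : list of DifferentialResult
    """

    def __init__(
        self,
        thresholds: Thresholds | None = None,
        qc_genes: Iterable[str] = DEFAULT_QC_GENES,
        p_adjust: str = "none",
    ) -> None:
        self.thresholds = thresholds
        self.qc_genes = qc_genes
        self.p_adjust = p_adjust

    def get_params(self, deep: bool = True) -> dict:
        return {
            "thresholds": self.thresholds,
            "qc_genes": self.qc_genes,
            "p_adjust": self.p_adjust,
        }

    def set_params(self, **params) -> "DifferentialAnalyzer":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, matrix: IntensityMatrix, table: ProteinGroupTable) -> "DifferentialAnalyzer":
        thresholds = self.thresholds or Thresholds()
        if self.p_adjust not in ("none", "bh"):
            raise ValueError(f"p_adjust must be 'none' or 'bh', got {self.p_adjust!r}")
        results = compute_differential(
            matrix,
            table,
            dub_name=matrix.design.dub_name,
            qc_genes=set(self.qc_genes),
            p_adjust=self.p_adjust,
        )
        initial, putative = call_substrates(results, thresholds)
        self.results_ = results
        self.initial_selection_ = initial
        self.putative_substrates_ = putative
        self.n_proteins_ = len(results)
        return self


def compute_differential(
    matrix: IntensityMatrix,
    table: ProteinGroupTable,
    dub_name: str,
    qc_genes: Iterable[str] = DEFAULT_QC_GENES,
    p_adjust: str = "none",
) -> list[DifferentialResult]:
    """Per-protein fold changes, t-tests and volcano categories.

    Category precedence: ``qc_protein`` > ``silenced_dub`` > up/down/
    not_significant, the last three at the fixed volcano boundaries
    |log2 FC| >= 1 and p < 0.05.
    """
    if not matrix.imputed or np.isnan(matrix.values).any():
        raise ValueError("matrix must be fully imputed before testing")
    design = matrix.design
    ctrl_idx = matrix.column_index(design.control_labels)
    sil_idx = matrix.column_index(design.silenced_labels)
    X = matrix.values
    mask = matrix.imputed_mask
    sil, ctrl = X[:, sil_idx], X[:, ctrl_idx]
    mean_sil = sil.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    log2_fc = mean_sil - mean_ctrl

    # Vectorised pooled t-test (x = silenced); degenerate rows patched after.
    with np.errstate(divide="ignore", invalid="ignore"):
        t_vec, p_vec = stats.ttest_ind(sil, ctrl, axis=1, equal_var=True)
    zero_var = (sil.var(axis=1, ddof=1) == 0) & (ctrl.var(axis=1, ddof=1) == 0)
    equal_means = mean_sil == mean_ctrl
    t_vec = np.where(zero_var & equal_means, 0.0, t_vec)
    p_vec = np.where(zero_var & equal_means, 1.0, p_vec)
    degenerate = zero_var & ~equal_means
    t_vec = np.where(degenerate, np.sign(log2_fc) * np.inf, t_vec)
    p_vec = np.where(degenerate, TINY_P, p_vec)
    p_vec = np.clip(p_vec, TINY_P, 1.0)

    if p_adjust == "bh":
        p_vec = benjamini_hochberg(p_vec)

    n_imp_ctrl = mask[:, ctrl_idx].sum(axis=1)
    n_imp_sil = mask[:, sil_idx].sum(axis=1)

    qc = {g.upper() for g in qc_genes}
    genes = table.df["gene_name"].to_numpy()
    if not any(str(g).upper() == dub_name.upper() for g in genes):
        warnings.warn(
            f"silenced DUB {dub_name!r} not detected in the table; no row will "
            "carry the silenced_dub category",
            stacklevel=2,
        )

    results = []
    df = table.df
    for i in range(len(df)):
        gene = str(genes[i])
        if gene.upper() in qc:
            category = CATEGORY_QC
        elif gene.upper() == dub_name.upper():
            category = CATEGORY_DUB
        elif log2_fc[i] >= 1.0 and p_vec[i] < 0.05:
            category = CATEGORY_UP
        elif log2_fc[i] <= -1.0 and p_vec[i] < 0.05:
            category = CATEGORY_DOWN
        else:
            category = CATEGORY_NS
        results.append(
            DifferentialResult(
                row_key=str(matrix.row_keys[i]),
                gene_name=gene,
                description=str(df["description"].iat[i]),
                log2_fc=float(log2_fc[i]),
                p_value=float(p_vec[i]),
                t_statistic=float(t_vec[i]),
                mean_control=float(mean_ctrl[i]),
                mean_silenced=float(mean_sil[i]),
                n_imputed_control=int(n_imp_ctrl[i]),
                n_imputed_silenced=int(n_imp_sil[i]),
                unique_peptides=int(df["unique_peptides"].iat[i]),
                category=category,
            )
        )
    return results


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def _passes_direction(r: DifferentialResult, thresholds: Thresholds) -> bool:
    fc, t = r.log2_fc, thresholds
    if t.direction == "up":
        return fc >= t.min_abs_log2_fc
    if t.direction == "down":
        return fc <= -t.min_abs_log2_fc
    return abs(fc) >= t.min_abs_log2_fc


def call_substrates(
    results: Sequence[DifferentialResult],
    thresholds: Thresholds | None = None,
) -> tuple[list[DifferentialResult], list[DifferentialResult]]:
    """Apply the three substrate criteria.

    Returns ``(initial_selection, putative_substrates)``:

    * initial selection — fold change (direction-aware, inclusive boundary)
      and p-value only;
    * putative substrates — additionally >= ``min_unique_peptides`` unique
      peptides and an acceptable imputation level (:func:`imputation_rule`).

    QC-protein and silenced-DUB rows are never callable.  Both lists are
    sorted by descending |log2 FC|, then ascending p, then gene name.
    """
    thresholds = thresholds or Thresholds()
    initial = [
        r
        for r in results
        if r.category not in (CATEGORY_QC, CATEGORY_DUB)
        and _passes_direction(r, thresholds)
        and r.p_value < thresholds.max_p
    ]
    putative = []
    for r in initial:
        n_reps = max(3, r.n_imputed_control, r.n_imputed_silenced)
        if r.unique_peptides >= thresholds.min_unique_peptides and imputation_rule(
            r.n_imputed_control, r.n_imputed_silenced, n_reps
        ):
            putative.append(r)
    key = lambda r: (-abs(r.log2_fc), r.p_value, r.gene_name)
    return sorted(initial, key=key), sorted(putative, key=key)


def volcano_dataset(
    results: Sequence[DifferentialResult],
    thresholds: Thresholds | None = None,
) -> list[tuple[str, str, float, float, str]]:
    """(gene, description, log2_fc, -log10 p, category) per result.

    p-values of zero are replaced by the smallest representable positive
    float before the log.  Every input appears exactly once.
    """
    out = []
    for r in results:
        p = r.p_value if r.p_value > 0 else TINY_P
        out.append((r.gene_name, r.description, r.log2_fc, float(-np.log10(p)), r.category))
    return out
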