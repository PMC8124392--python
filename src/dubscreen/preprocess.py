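"""Row filtering, log2 transform, and downshifted-normal imputation.

Label-free proteomics intensity matrices are missing-not-at-random: values
drop out preferentially below the detection limit.  The standard remedy in
the Perseus workflow is to replace each missing value with a draw from a
normal distribution centred below the observed intensities:

    x_miss ~ Normal(m - downshift * s, (width * s)^2)

where ``m`` and ``s`` are the mean and standard deviation of the observed
log2 intensities (per sample column by default) and the defaults are
``width = 0.3`` and ``downshift = 1.8``.  The draws stand in for expression
levels below the detection limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import ExperimentDesign
from .tables_io import ProteinGroupTable

__all__ = [
    "IntensityMatrix",
    "FilterLog",
    "filter_rows",
    "log2_transform",
    "DownshiftedNormalImputer",
    "impute",
]

# Removal reasons, in precedence order: a row is logged once, under the first
# reason that applies.
FILTER_REASONS = (
    "reverse",
    "contaminant",
    "only_by_site",
    "no_unique_peptides",
    "no_intensity",
)

FilterLog = dict[str, int]


@dataclass
class IntensityMatrix:
    """Proteins x samples matrix of log2 LFQ intensities.

    ``values`` holds NaN for not-quantified cells before imputation and no
    NaN afterwards; ``imputed_mask`` marks exactly the cells that were filled
    in (all-false before imputation).
    """

    values: np.ndarray
    imputed_mask: np.ndarray
    row_keys: list[str]
    sample_labels: list[str]
    design: ExperimentDesign
    imputed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.imputed_mask = np.asarray(self.imputed_mask, dtype=bool)
        if self.values.shape != self.imputed_mask.shape:
            raise ValueError("values and imputed_mask shapes differ")
        if self.values.shape != (len(self.row_keys), len(self.sample_labels)):
            raise ValueError("matrix shape does not match row_keys x sample_labels")

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    def column_index(self, labels: list[str]) -> np.ndarray:
        return np.array([self.sample_labels.index(l) for l in labels])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_keys, columns=self.sample_labels)

    def mask_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.imputed_mask, index=self.row_keys, columns=self.sample_labels)

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.copy(),
            self.imputed_mask.copy(),
            list(self.row_keys),
            list(self.sample_labels),
            self.design,
            self.imputed,
        )


def filter_rows(table: ProteinGroupTable) -> tuple[ProteinGroupTable, FilterLog]:
    """Remove decoy, contaminant, only-identified-by-site, zero-unique-peptide
    and all-zero-intensity protein groups.

    Returns the retained table and a log counting removed rows by the first
    matching reason (precedence: reverse > contaminant > only_by_site >
    no_unique_peptides > no_intensity).  Idempotent.
    """
    df = table.df
    lfq = df[table.sample_labels].to_numpy(dtype=float)
    conditions = {
        "reverse": df["reverse"].to_numpy(dtype=bool),
        "contaminant": df["contaminant"].to_numpy(dtype=bool),
        "only_by_site": df["only_by_site"].to_numpy(dtype=bool),
        "no_unique_peptides": df["unique_peptides"].to_numpy() <= 0,
        "no_intensity": (lfq <= 0).all(axis=1),
    }
    removed = np.zeros(len(df), dtype=bool)
    log: FilterLog = {}
    for reason in FILTER_REASONS:
        hit = conditions[reason] & ~removed
        count = int(hit.sum())
        if count:
            log[reason] = count
        removed |= conditions[reason]
    kept = ProteinGroupTable(df.loc[~removed].reset_index(drop=True), list(table.sample_labels))
    return kept, log


def log2_transform(table: ProteinGroupTable, design: ExperimentDesign) -> IntensityMatrix:
    """log2 of positive LFQ values; zeros become NaN (not quantified)."""
    lfq = table.df[table.sample_labels].to_numpy(dtype=float)
    values = np.where(lfq > 0, np.log2(np.where(lfq > 0, lfq, 1.0)), np.nan)
    return IntensityMatrix(
        values=values,
        imputed_mask=np.zeros_like(values, dtype=bool),
        row_keys=list(table.df["protein_ids"]),
        sample_labels=list(table.sample_labels),
        design=design,
    )


class DownshiftedNormalImputer:
    """Impute missing log2 intensities from a downshifted normal distribution.

    scikit-learn-style transformer.  ``fit`` records, per column (or for the
    whole matrix), the mean ``m`` and standard deviation ``s`` of the observed
    values; ``transform`` replaces each NaN with an independent draw from
    ``Normal(m - downshift * s, (width * s)^2)``.

    Parameters
    ----------
    width : float, default 0.3
        Standard deviation of the imputation distribution, in units of the
        observed standard deviation.
    downshift : float, default 1.8
        Downward shift of its mean, in units of the observed standard
        deviation.
    mode : {"per_column", "whole_matrix"}, default "per_column"
        Whether m and s are computed per sample column (the Perseus default)
        or once over the whole matrix.
    random_state : int or numpy.random.Generator, optional
        Seed for the draws.  Cells are filled in row-major order from a
        single generator, so results are reproducible across platforms.

    Attributes
    ----------
    loc_ : ndarray of shape (n_columns,)
        Imputation means ``m - downshift * s`` per column.
    scale_ : ndarray of shape (n_columns,)
        Imputation standard deviations ``width * s`` per column.
    n_features_in_ : int
    """

    def __init__(
        self,
        width: float = 0.3,
        downshift: float = 1.8,
        mode: str = "per_column",
        random_state: int | np.random.Generator | None = None,
    ) -> None:
        self.width = width
        self.downshift = downshift
        self.mode = mode
        self.random_state = random_state

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "width": self.width,
            "downshift": self.downshift,
            "mode": self.mode,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "DownshiftedNormalImputer":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # ----------------------------------------------------------------------
    def _validate(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D proteins x samples matrix")
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.downshift < 0:
            raise ValueError("downshift must be >= 0")
        if self.mode not in ("per_column", "whole_matrix"):
            raise ValueError(f"unknown mode {self.mode!r}")
        return X

    def fit(self, X: np.ndarray, y=None) -> "DownshiftedNormalImputer":
        X = self._validate(X)
        observed = ~np.isnan(X)
        if observed.sum() < 2:
            raise ValueError("need at least 2 observed values to fit the imputer")
        global_m = float(np.nanmean(X))
        global_s = float(np.nanstd(X, ddof=1))
        n_cols = X.shape[1]
        loc = np.empty(n_cols)
        scale = np.empty(n_cols)
        if self.mode == "whole_matrix":
            loc[:] = global_m - self.downshift * global_s
            scale[:] = self.width * global_s
        else:
            for j in range(n_cols):
                col = X[observed[:, j], j]
                if col.size < 2:
                    warnings.warn(
                        f"column {j} has fewer than 2 observed values; "
                        "falling back to whole-matrix statistics",
                        stacklevel=2,
                    )
                    m, s = global_m, global_s
                else:
                    m, s = float(col.mean()), float(col.std(ddof=1))
                loc[j] = m - self.downshift * s
                scale[j] = self.width * s
        self.loc_ = loc
        self.scale_ = scale
        self.n_features_in_ = n_cols
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "loc_"):
            raise ValueError("imputer is not fitted; call fit first")
        X = self._validate(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("column count differs from the fitted matrix")
        rng = (
            self.random_state
            if isinstance(self.random_state, np.random.Generator)
            else np.random.default_rng(self.random_state)
        )
        out = X.copy()
        missing = np.isnan(X)
        # Single generator consumed in row-major cell order: deterministic.
        rows, cols = np.nonzero(missing)
        draws = rng.standard_normal(rows.size)
        out[rows, cols] = self.loc_[cols] + self.scale_[cols] * draws
        return out

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


@dataclass(frozen=True)
class ImputationParams:
    """Bundle of imputation settings (width/downshift in observed-sd units)."""

    width: float = 0.3
    downshift: float = 1.8
    mode: str = "per_column"
    seed: int | None = None


def impute(matrix: IntensityMatrix, params: ImputationParams | None = None) -> IntensityMatrix:
    """Impute an :class:`IntensityMatrix`, recording the imputation mask.

    Thin wrapper over :class:`DownshiftedNormalImputer`.  Observed cells are
    left untouched; the returned mask marks exactly the previously missing
    cells, and no NaN remains.
    """
    params = params or ImputationParams()
    if matrix.imputed:
        raise ValueError("matrix is already imputed")
    imputer = DownshiftedNormalImputer(
        width=params.width,
        downshift=params.downshift,
        mode=params.mode,
        random_state=params.seed,
    )
    missing = np.isnan(matrix.values)
    values = imputer.fit_transform(matrix.values)
    return replace(
        matrix,
        values=values,
        imputed_mask=missing,
        row_keys=list(matrix.row_keys),
        sample_labels=list(matrix.sample_labels),
        imputed=True,
    )
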