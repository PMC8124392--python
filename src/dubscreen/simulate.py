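"""Synthetic MaxQuant-dialect datasets with known ground truth.

Emulates one DUB-silencing screen (3 control vs 3 silenced biotin-pulldown
replicates by default) so every pipeline stage is testable without raw MS
data:

* per-protein true log2 abundance ``a_i ~ Normal(base_mean, base_sd^2)``;
* sample value = ``a_i + effect_i * [silenced] + Normal(0, replicate_sd^2)``;
* missing-not-at-random dropout: a value is observed with probability
  ``sigmoid((value - dropout_midpoint) / dropout_slope)``, so low-abundance
  proteins drop out preferentially (missing values are written as LFQ 0);
* a spiked substrate subset gains ``effect_log2`` (default +2, i.e. 4-fold)
  in the silenced arm, and a smaller subset loses the same amount;
* the endogenously biotinylated QC panel (ACACA, HLCS, MCCC1, PC, PCCA),
  ubiquitin (UBB) and avidin (AVD) get effect 0 and high abundance, so they
  are always observed and never shift;
* decoy (reverse) and contaminant rows exercise the row filters;
* 1-3 GlyGly sites per spiked substrate with localization probabilities
  ~ Uniform(0.5, 1).

The whole dataset is reproducible from a single seed, and
:func:`score_recovery` scores a substrate call list against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import ExperimentDesign, default_design
from .tables_io import GlyGlySiteRow, ProteinGroupTable, write_glygly_sites, write_protein_groups

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate", "generate_tables", "score_recovery", "QC_GENES"]

# (gene, always-observed) panel spiked into every synthetic dataset.
QC_GENES = ("ACACA", "HLCS", "MCCC1", "PC", "PCCA", "UBB", "AVD")

LABEL_SUBSTRATE_UP = "substrate_up"
LABEL_SUBSTRATE_DOWN = "substrate_down"
LABEL_NULL = "null"
LABEL_QC = "qc"
LABEL_DECOY = "decoy"
LABEL_CONTAMINANT = "contaminant"


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults emulate one mid-depth triplicate screen."""

    n_proteins: int = 2000
    n_substrates: int = 40
    effect_log2: float = 2.0
    n_down: int = 10
    base_mean: float = 26.0
    base_sd: float = 2.5
    replicate_sd: float = 0.3
    n_reps: int = 3
    dropout_midpoint: float = 22.5
    dropout_slope: float = 1.5
    n_decoys: int = 20
    n_contaminants: int = 15
    qc_panel_included: bool = True
    unique_peptide_lambda: float = 6.0
    dub_name: str = "USP9X"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_substrates + self.n_down > self.n_proteins:
            raise ValueError("n_substrates + n_down must not exceed n_proteins")
        for name in ("base_sd", "replicate_sd", "dropout_slope"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_reps < 2:
            raise ValueError("need at least 2 replicates per condition")


@dataclass
class SyntheticTruth:
    """Ground truth per generated row: label and true log2 effect."""

    df: pd.DataFrame  # columns: protein_id, gene_name, label, true_effect_log2

    def genes_with_label(self, label: str) -> set[str]:
        return set(self.df.loc[self.df["label"] == label, "gene_name"])

    @property
    def n_substrates_up(self) -> int:
        return int((self.df["label"] == LABEL_SUBSTRATE_UP).sum())

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_tables(
    config: SyntheticConfig | None = None,
) -> tuple[ProteinGroupTable, list[GlyGlySiteRow], SyntheticTruth, ExperimentDesign]:
    """Generate in-memory tables (see module docstring for the model)."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    design = default_design(cfg.dub_name, n_reps=cfg.n_reps)

    n = cfg.n_proteins
    labels = np.array([LABEL_NULL] * n, dtype=object)
    order = rng.permutation(n)
    up_idx = order[: cfg.n_substrates]
    down_idx = order[cfg.n_substrates : cfg.n_substrates + cfg.n_down]
    labels[up_idx] = LABEL_SUBSTRATE_UP
    labels[down_idx] = LABEL_SUBSTRATE_DOWN
    effects = np.zeros(n)
    effects[up_idx] = cfg.effect_log2
    effects[down_idx] = -cfg.effect_log2

    genes = np.array([f"GENE{i:04d}" for i in range(n)], dtype=object)
    protein_ids = np.array([f"SYN{i:05d}" for i in range(n)], dtype=object)
    abundance = rng.normal(cfg.base_mean, cfg.base_sd, size=n)

    # QC panel: effect 0, high abundance (base_mean + 3) => always observed.
    if cfg.qc_panel_included:
        qc_abund = np.full(len(QC_GENES), cfg.base_mean + 3.0)
        genes = np.concatenate([genes, np.array(QC_GENES, dtype=object)])
        protein_ids = np.concatenate(
            [protein_ids, np.array([f"QC_{g}" for g in QC_GENES], dtype=object)]
        )
        abundance = np.concatenate([abundance, qc_abund])
        effects = np.concatenate([effects, np.zeros(len(QC_GENES))])
        labels = np.concatenate([labels, np.array([LABEL_QC] * len(QC_GENES), dtype=object)])

    total = len(genes)
    n_samples = 2 * cfg.n_reps
    is_silenced = np.array([0] * cfg.n_reps + [1] * cfg.n_reps)  # ctr first

    values = (
        abundance[:, None]
        + effects[:, None] * is_silenced[None, :]
        + rng.normal(0.0, cfg.replicate_sd, size=(total, n_samples))
    )
    observed = rng.random((total, n_samples)) < _sigmoid(
        (values - cfg.dropout_midpoint) / cfg.dropout_slope
    )
    if cfg.qc_panel_included:
        observed[total - len(QC_GENES) :, :] = True  # QC panel never missing
    lfq = np.where(observed, np.exp2(values), 0.0)

    unique_peptides = 1 + rng.poisson(cfg.unique_peptide_lambda, size=total)

    rows = pd.DataFrame(
        {
            "protein_ids": protein_ids,
            "gene_name": genes,
            "description": [f"Synthetic protein {g}" for g in genes],
            "unique_peptides": unique_peptides.astype(int),
            "reverse": False,
            "contaminant": False,
            "only_by_site": False,
        }
    )
    for j, lab in enumerate(design.sample_labels):
        rows[lab] = lfq[:, j]

    # Decoy and contaminant rows (flagged; filtered out by the pipeline).
    extra_frames = []
    for kind, count, flag in (
        (LABEL_DECOY, cfg.n_decoys, "reverse"),
        (LABEL_CONTAMINANT, cfg.n_contaminants, "contaminant"),
    ):
        if count == 0:
            continue
        ab = rng.normal(cfg.base_mean, cfg.base_sd, size=count)
        vals = ab[:, None] + rng.normal(0.0, cfg.replicate_sd, size=(count, n_samples))
        obs = rng.random((count, n_samples)) < _sigmoid(
            (vals - cfg.dropout_midpoint) / cfg.dropout_slope
        )
        extra = pd.DataFrame(
            {
                "protein_ids": [f"{kind.upper()}{i:04d}" for i in range(count)],
                "gene_name": [f"{kind.upper()}_{i:04d}" for i in range(count)],
                "description": f"Synthetic {kind}",
                "unique_peptides": (1 + rng.poisson(cfg.unique_peptide_lambda, size=count)).astype(int),
                "reverse": flag == "reverse",
                "contaminant": flag == "contaminant",
                "only_by_site": False,
            }
        )
        for j, lab in enumerate(design.sample_labels):
            extra[lab] = np.where(obs[:, j], np.exp2(vals[:, j]), 0.0)
        extra_frames.append((extra, kind))

    truth_df = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "gene_name": genes,
            "label": labels,
            "true_effect_log2": effects,
        }
    )
    for extra, kind in extra_frames:
        rows = pd.concat([rows, extra], ignore_index=True)
        truth_df = pd.concat(
            [
                truth_df,
                pd.DataFrame(
                    {
                        "protein_id": extra["protein_ids"],
                        "gene_name": extra["gene_name"],
                        "label": kind,
                        "true_effect_log2": 0.0,
                    }
                ),
            ],
            ignore_index=True,
        )

    table = ProteinGroupTable(rows, list(design.sample_labels))

    # GlyGly sites: 1-3 per spiked (up) substrate, probabilities ~ U(0.5, 1).
    site_rows: list[GlyGlySiteRow] = []
    for i in np.sort(up_idx):
        n_sites = int(rng.integers(1, 4))
        positions = sorted(int(p) for p in rng.choice(np.arange(5, 800), size=n_sites, replace=False))
        for pos in positions:
            site_rows.append(
                GlyGlySiteRow(
                    protein_id=str(protein_ids[i]),
                    gene_name=str(genes[i]),
                    position=pos,
                    localization_probability=float(rng.uniform(0.5, 1.0)),
                    intensity={
                        lab: float(np.exp2(abundance[i] + rng.normal(0, cfg.replicate_sd)))
                        for lab in design.sample_labels
                    },
                )
            )

    return table, site_rows, SyntheticTruth(truth_df), design


def generate(
    config: SyntheticConfig | None = None,
    out_dir: str | Path = ".",
) -> tuple[Path, Path, SyntheticTruth, ExperimentDesign]:
    """Generate and write proteinGroups.tsv, glygly.tsv and truth.csv.

    Files are byte-identical for identical configs (seed included).
    """
    cfg = config or SyntheticConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, sites, truth, design = generate_tables(cfg)
    pg_path = out / "proteinGroups.tsv"
    gg_path = out / "glygly.tsv"
    write_protein_groups(table, pg_path)
    write_glygly_sites(sites, gg_path, design.sample_labels)
    truth.to_csv(out / "truth.csv")
    return pg_path, gg_path, truth, design


def score_recovery(
    called: Sequence[str],
    truth: SyntheticTruth,
    n_substrates: int | None = None,
) -> tuple[float, float]:
    """Sensitivity and false-discovery proportion of an up-substrate call list.

    sensitivity = |called ∩ substrate_up| / n_substrates;
    FDP = |called \\ substrate_up| / max(1, |called|).
    """
    called_set = set(called)
    known = set(truth.df["gene_name"])
    unknown = called_set - known
    if unknown:
        raise ValueError(f"called genes missing from truth: {sorted(unknown)[:5]}")
    up = truth.genes_with_label(LABEL_SUBSTRATE_UP)
    denom = n_substrates if n_substrates is not None else max(1, len(up))
    sensitivity = len(called_set & up) / denom
    fdp = len(called_set - up) / max(1, len(called_set))
    return sensitivity, fdp
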