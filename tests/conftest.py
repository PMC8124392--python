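import numpy as np
import pandas as pd
import pytest

from dubscreen import (
    DifferentialAnalyzer,
    ImputationParams,
    ProteinGroupTable,
    default_design,
    filter_rows,
    impute,
    log2_transform,
)
from dubscreen.simulate import SyntheticConfig, generate_tables


@pytest.fixture(scope="session")
def design():
    return default_design("USP9X")


@pytest.fixture(scope="session")
def small_config():
    # Desk-scale screen for fast unit tests; study-scale defaults are used in
    # the acceptance suite.
    return SyntheticConfig(n_proteins=300, n_substrates=12, n_down=4, n_decoys=5,
                           n_contaminants=4, seed=7)


@pytest.fixture(scope="session")
def small_screen(small_config):
    return generate_tables(small_config)


@pytest.fixture(scope="session")
def fitted_small_screen(small_screen, small_config):
    table, sites, truth, design = small_screen
    kept, log = filter_rows(table)
    matrix = impute(log2_transform(kept, design), ImputationParams(seed=small_config.seed))
    analyzer = DifferentialAnalyzer().fit(matrix, kept)
    return kept, matrix, analyzer, truth, design


def make_table(design, rows):
    """Build a canonical ProteinGroupTable from compact row dicts."""
    records = []
    for i, row in enumerate(rows):
        rec = {
            "protein_ids": row.get("protein_ids", f"P{i:03d}"),
            "gene_name": row.get("gene_name", f"G{i:03d}"),
            "description": row.get("description", ""),
            "unique_peptides": row.get("unique_peptides", 5),
            "reverse": row.get("reverse", False),
            "contaminant": row.get("contaminant", False),
            "only_by_site": row.get("only_by_site", False),
        }
        lfq = row.get("lfq", [100.0] * len(design.sample_labels))
        for lab, v in zip(design.sample_labels, lfq):
            rec[lab] = float(v)
        records.append(rec)
    return ProteinGroupTable(pd.DataFrame(records), list(design.sample_labels))


@pytest.fixture
def table_factory(design):
    return lambda rows: make_table(design, rows)
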