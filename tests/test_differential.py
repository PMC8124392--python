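import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dubscreen import (
    DifferentialAnalyzer,
    ImputationParams,
    IntensityMatrix,
    Thresholds,
    call_substrates,
    compute_differential,
    default_design,
    filter_rows,
    impute,
    imputation_rule,
    log2_transform,
    student_t_test,
    volcano_dataset,
)
from dubscreen.differential import DifferentialResult


def pooled_t_oracle(x, y):
    """Independent closed-form pooled two-sample t (textbook formula)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n, m = len(x), len(y)
    sp2 = ((n - 1) * x.var(ddof=1) + (m - 1) * y.var(ddof=1)) / (n + m - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n + 1 / m))
    p = 2 * stats.t.sf(abs(t), n + m - 2)
    return t, p


class TestStudentTTest:
    def test_identical_groups(self):
        assert student_t_test((5, 5, 5), (5, 5, 5)) == (0.0, 1.0)

    def test_closed_form_example(self):
        t, p = student_t_test((2, 3, 4), (1, 2, 3))
        et, ep = pooled_t_oracle((2, 3, 4), (1, 2, 3))
        assert t == pytest.approx(et, abs=1e-12) and p == pytest.approx(ep, abs=1e-12)
        assert t == pytest.approx(1.224745, abs=1e-6)
        assert p == pytest.approx(0.287900, abs=1e-4)

    def test_swap_negates_t_keeps_p(self):
        t1, p1 = student_t_test((2, 3, 9), (1, 2, 3))
        t2, p2 = student_t_test((1, 2, 3), (2, 3, 9))
        assert t1 == -t2 and p1 == p2

    def test_zero_variance_unequal_means(self):
        with pytest.warns(UserWarning, match="zero pooled variance"):
            t, p = student_t_test((5, 5, 5), (3, 3, 3))
        assert t == np.inf and 0 < p < 1e-300

    def test_group_too_small(self):
        with pytest.raises(ValueError):
            student_t_test((1.0,), (2.0, 3.0))


class TestImputationRule:
    def test_exhaustive_enumeration_matches_rule_text(self):
        # "no imputed values in at least one condition, or at most one in each"
        passing = {
            (i, j)
            for i in range(4)
            for j in range(4)
            if i == 0 or j == 0 or (i <= 1 and j <= 1)
        }
        assert len(passing) == 8
        for i in range(4):
            for j in range(4):
                assert imputation_rule(i, j, 3) is ((i, j) in passing)

    @pytest.mark.parametrize(
        "ctrl,sil,expected",
        [(0, 3, True), (1, 1, True), (2, 1, False), (0, 0, True), (3, 0, True)],
    )
    def test_examples(self, ctrl, sil, expected):
        assert imputation_rule(ctrl, sil, 3) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            imputation_rule(4, 0, 3)


def make_result(**kw):
    defaults = dict(
        row_key="P1", gene_name="G1", description="", log2_fc=2.0, p_value=0.01,
        t_statistic=5.0, mean_control=24.0, mean_silenced=26.0,
        n_imputed_control=0, n_imputed_silenced=0, unique_peptides=5, category="up",
    )
    defaults.update(kw)
    return DifferentialResult(**defaults)


def matrix_from(values, design, mask=None, keys=None):
    values = np.asarray(values, float)
    return IntensityMatrix(
        values=values,
        imputed_mask=np.zeros_like(values, bool) if mask is None else np.asarray(mask, bool),
        row_keys=keys or [f"P{i}" for i in range(values.shape[0])],
        sample_labels=list(design.sample_labels),
        design=design,
        imputed=True,
    )


class TestComputeDifferential:
    def test_categories_and_precedence(self, table_factory, design):
        # rows: strong up, QC gene with huge fc, the silenced DUB going down,
        # sub-threshold fc with tiny p
        table = table_factory(
            [
                {"gene_name": "TTK"},
                {"gene_name": "PCCA"},
                {"gene_name": "USP9X"},
                {"gene_name": "WEAK"},
            ]
        )
        values = np.array(
            [
                [24, 24.1, 23.9, 26.3, 26.4, 26.2],   # fc ~ +2.3
                [24, 24.1, 23.9, 27.0, 27.1, 26.9],   # QC despite big fc
                [26, 26.1, 25.9, 24.0, 24.1, 23.9],   # silenced DUB, fc ~ -2
                [24, 24.01, 23.99, 24.5, 24.51, 24.49],  # fc 0.5, tiny p
            ]
        )
        results = compute_differential(matrix_from(values, design), table, "USP9X")
        cats = {r.gene_name: r.category for r in results}
        assert cats == {
            "TTK": "up",
            "PCCA": "qc_protein",
            "USP9X": "silenced_dub",
            "WEAK": "not_significant",
        }
        ttk = next(r for r in results if r.gene_name == "TTK")
        assert ttk.log2_fc == pytest.approx(ttk.mean_silenced - ttk.mean_control)
        assert ttk.p_value < 0.05

    def test_down_category(self, table_factory, design):
        table = table_factory([{"gene_name": "DOWN1"}])
        values = np.array([[26, 26.1, 25.9, 24.0, 24.1, 23.9]])
        (r,) = compute_differential(matrix_from(values, design), table, "USP9X")
        assert r.category == "down" and r.log2_fc < -1

    def test_missing_dub_warns(self, table_factory, design):
        table = table_factory([{"gene_name": "OTHER"}])
        values = np.array([[24.0, 24, 24, 24, 24, 24]])
        with pytest.warns(UserWarning, match="USP9X"):
            compute_differential(matrix_from(values, design), table, "USP9X")

    def test_unimputed_matrix_rejected(self, table_factory, design):
        m = log2_transform(table_factory([{}]), design)
        with pytest.raises(ValueError, match="imputed"):
            compute_differential(m, table_factory([{}]), "USP9X")

    def test_imputed_counts_per_condition(self, table_factory, design):
        table = table_factory([{"gene_name": "G"}])
        values = np.array([[22.0, 24, 24, 26, 26, 26]])
        mask = np.array([[True, False, False, False, False, False]])
        (r,) = compute_differential(matrix_from(values, design, mask), table, "USP9X")
        assert (r.n_imputed_control, r.n_imputed_silenced) == (1, 0)


class TestCallSubstrates:
    def test_three_criteria(self):
        passing = make_result()
        low_peptides = make_result(gene_name="G2", unique_peptides=1)
        bad_imputation = make_result(gene_name="G3", n_imputed_control=2,
                                     n_imputed_silenced=1)
        initial, putative = call_substrates([passing, low_peptides, bad_imputation])
        assert {r.gene_name for r in initial} == {"G1", "G2", "G3"}
        assert [r.gene_name for r in putative] == ["G1"]

    def test_boundary_fc_is_inclusive(self):
        # a record printed at log2 FC exactly 1.00 passes the default cut
        r = make_result(log2_fc=1.0)
        initial, putative = call_substrates([r])
        assert len(initial) == len(putative) == 1

    def test_qc_and_dub_never_callable(self):
        rows = [
            make_result(gene_name="PCCA", category="qc_protein", log2_fc=3.0),
            make_result(gene_name="USP9X", category="silenced_dub", log2_fc=2.0),
        ]
        initial, putative = call_substrates(rows)
        assert initial == [] and putative == []

    def test_empty_input(self):
        assert call_substrates([]) == ([], [])

    def test_direction_down(self):
        up = make_result(log2_fc=2.0)
        down = make_result(gene_name="G2", log2_fc=-2.0, category="down")
        initial, _ = call_substrates([up, down], Thresholds(direction="down"))
        assert [r.gene_name for r in initial] == ["G2"]

    def test_sorted_by_abs_fc_then_p_then_gene(self):
        rows = [
            make_result(gene_name="B", log2_fc=1.5),
            make_result(gene_name="A", log2_fc=2.5),
            make_result(gene_name="C", log2_fc=2.5, p_value=0.001),
        ]
        initial, _ = call_substrates(rows)
        assert [r.gene_name for r in initial] == ["C", "A", "B"]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        fc=st.floats(min_value=1.0, max_value=3.0),
        p=st.floats(min_value=0.001, max_value=0.049),
        uniq=st.integers(min_value=2, max_value=10),
        tighter_fc=st.floats(min_value=0.0, max_value=2.0),
        tighter_p=st.floats(min_value=0.0001, max_value=0.04),
        tighter_uniq=st.integers(min_value=0, max_value=8),
    )
    def test_monotonicity_in_all_thresholds(self, fc, p, uniq, tighter_fc, tighter_p, tighter_uniq):
        rows = [make_result(gene_name=f"G{i}", log2_fc=fc + 0.3 * i, p_value=p,
                            unique_peptides=uniq) for i in range(4)]
        base = Thresholds()
        tight = Thresholds(
            min_abs_log2_fc=base.min_abs_log2_fc + tighter_fc,
            max_p=min(base.max_p, tighter_p),
            min_unique_peptides=base.min_unique_peptides + tighter_uniq,
        )
        i0, p0 = call_substrates(rows, base)
        i1, p1 = call_substrates(rows, tight)
        assert {r.gene_name for r in i1} <= {r.gene_name for r in i0}
        assert {r.gene_name for r in p1} <= {r.gene_name for r in p0}
        assert {r.gene_name for r in p0} <= {r.gene_name for r in i0}


class TestVolcano:
    def test_neg_log10_and_conservation(self):
        rows = [make_result(gene_name=f"G{i}", p_value=0.05) for i in range(100)]
        points = volcano_dataset(rows)
        assert len(points) == 100
        assert points[0][3] == pytest.approx(1.3010, abs=1e-4)

    def test_categories_partition(self, fitted_small_screen):
        _, _, analyzer, _, _ = fitted_small_screen
        points = volcano_dataset(analyzer.results_)
        cats = [p[4] for p in points]
        valid = {"up", "down", "not_significant", "qc_protein", "silenced_dub"}
        assert set(cats) <= valid and len(points) == len(analyzer.results_)


class TestAntisymmetry:
    def test_condition_swap_negates_fc_keeps_p(self, small_screen, small_config):
        from dubscreen.design import ExperimentDesign, SampleInfo

        table, _, _, design = small_screen
        kept, _ = filter_rows(table)
        matrix = impute(log2_transform(kept, design), ImputationParams(seed=2))
        fwd = compute_differential(matrix, kept, design.dub_name)

        swapped_design = ExperimentDesign(
            experiment_id=design.experiment_id,
            dub_name=design.dub_name,
            samples=tuple(
                SampleInfo(s.label, "control" if s.condition == "silenced" else "silenced",
                           s.replicate)
                for s in design.samples
            ),
        )
        swapped_matrix = IntensityMatrix(
            matrix.values, matrix.imputed_mask, matrix.row_keys,
            matrix.sample_labels, swapped_design, imputed=True,
        )
        rev = compute_differential(swapped_matrix, kept, design.dub_name)
        fc_f = np.array([r.log2_fc for r in fwd])
        fc_r = np.array([r.log2_fc for r in rev])
        assert np.allclose(fc_f, -fc_r)
        assert np.allclose([r.p_value for r in fwd], [r.p_value for r in rev])
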