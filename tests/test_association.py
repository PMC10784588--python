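"""Dichotomization, contingency building, and the Fisher scan."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from flyspan import association, io, simulate
from flyspan.association import ContingencyTable
from flyspan.errors import AnalysisError
from flyspan.io import ALT, MISSING, REF, GenotypeMatrix


def _phenotypes(medians, diet="DR"):
    return pd.DataFrame(
        {
            "line_id": [f"L{i + 1:03d}" for i in range(len(medians))],
            "diet": diet,
            "median_lifespan": medians,
        }
    )


class TestAssignCases:
    def test_top_k_takes_exactly_k_longest_lived(self):
        phen = _phenotypes(list(range(20, 50)))  # 30 lines
        cases = association.assign_cases(phen, "DR", top_k=25)
        assert len(cases.in_case) == 25
        assert len(cases.non_case) == 5
        worst_in = phen.set_index("line_id").loc[list(cases.in_case), "median_lifespan"].min()
        best_out = phen.set_index("line_id").loc[list(cases.non_case), "median_lifespan"].max()
        assert worst_in > best_out

    def test_threshold_is_strictly_greater(self):
        phen = _phenotypes([40.0, 41.0, 42.0])
        cases = association.assign_cases(
            phen, "DR", mode="threshold", lifespan_threshold=41.0
        )
        assert cases.in_case == {"L003"}

    def test_top_k_equals_n_lines_takes_all(self):
        phen = _phenotypes([30.0, 31.0, 32.0])
        cases = association.assign_cases(phen, "DR", top_k=3)
        assert cases.in_case == {"L001", "L002", "L003"}
        assert not cases.non_case

    def test_ties_at_kth_value_broken_by_line_id(self):
        phen = _phenotypes([50.0, 42.0, 42.0, 42.0, 30.0])
        cases = association.assign_cases(phen, "DR", top_k=2)
        # L002/L003/L004 tie at 42; ascending line id wins the last slot
        assert cases.in_case == {"L001", "L002"}

    def test_shift_invariance_of_top_k(self):
        rng = np.random.default_rng(4)
        medians = rng.uniform(30, 60, size=40).round(1)
        base = association.assign_cases(_phenotypes(medians), "DR", top_k=10)
        shifted = association.assign_cases(_phenotypes(medians + 17.3), "DR", top_k=10)
        assert base.in_case == shifted.in_case

    def test_too_few_lines_rejected(self):
        with pytest.raises(AnalysisError, match="top_k"):
            association.assign_cases(_phenotypes([40.0] * 10), "DR", top_k=25)

    def test_empty_threshold_group_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            cases = association.assign_cases(
                _phenotypes([30.0, 31.0]), "DR", mode="threshold", lifespan_threshold=99.0
            )
        assert not cases.in_case


class TestBuildTable:
    def _cases(self, in_case, non_case):
        return association.CaseAssignment(
            in_case=frozenset(in_case), non_case=frozenset(non_case), diet="DR", mode="top_k"
        )

    def test_balanced_four_line_table(self):
        calls = np.array([[REF], [ALT], [REF], [ALT]], dtype=np.int8)
        m = GenotypeMatrix(["a", "b", "c", "d"], ["m"], calls)
        table = association.build_table(m, "m", self._cases({"a", "b"}, {"c", "d"}))
        assert table.as_array().tolist() == [[1, 1], [1, 1]]

    def test_missing_call_excluded_from_all_cells(self):
        calls = np.array([[MISSING], [ALT], [REF], [ALT]], dtype=np.int8)
        m = GenotypeMatrix(["a", "b", "c", "d"], ["m"], calls)
        table = association.build_table(m, "m", self._cases({"a", "b"}, {"c", "d"}))
        assert table.total == 3
        assert table.case_ref == 0 and table.case_alt == 1

    def test_counts_conserve_labeled_nonmissing_lines(self, small_study):
        genotypes, _, phenotypes, _ = small_study
        cases = association.assign_cases(phenotypes, "DR", top_k=25)
        for marker in genotypes.marker_ids[:10]:
            table = association.build_table(genotypes, marker, cases)
            col = genotypes.calls[:, genotypes.marker_index(marker)]
            labeled = np.isin(np.array(genotypes.line_ids, dtype=object), list(cases.labeled_lines))
            assert table.total == int((labeled & (col != MISSING)).sum())

    def test_absent_marker_rejected(self, toy_matrix):
        with pytest.raises(KeyError):
            association.build_table(toy_matrix, "nope", self._cases({"L1"}, {"L2"}))


class TestFisherExact:
    def test_perfectly_balanced_table(self):
        assert association.fisher_exact_two_sided(ContingencyTable(5, 5, 5, 5)) == 1.0

    def test_perfect_separation_closed_form(self):
        from math import comb

        p = association.fisher_exact_two_sided(ContingencyTable(10, 0, 0, 10))
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_all_tables_qualify_gives_one(self):
        # probabilities (1,9,9,1)/20; observed 9/20; every table qualifies
        assert association.fisher_exact_two_sided(ContingencyTable(2, 1, 1, 2)) == 1.0

    def test_all_zero_table_is_one(self):
        assert association.fisher_exact_two_sided(ContingencyTable(0, 0, 0, 0)) == 1.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 25)] * 4))
    def test_matches_enumeration_oracle(self, counts):
        p = association.fisher_exact_two_sided(ContingencyTable(*counts))
        assert p == pytest.approx(oracles.fisher_two_sided(*counts), rel=1e-9, abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 15)] * 4))
    def test_invariant_under_row_and_column_swap(self, counts):
        a, b, c, d = counts
        p1 = association.fisher_exact_two_sided(ContingencyTable(a, b, c, d))
        p2 = association.fisher_exact_two_sided(ContingencyTable(d, c, b, a))
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(AnalysisError):
            ContingencyTable(-1, 0, 0, 0)


class TestRunAssociation:
    def test_zero_markers_gives_empty_results(self, toy_phenotypes):
        cfg = simulate.SimulationConfig(n_lines=6, n_markers=0, seed=0)
        m = simulate.simulate_genotypes(cfg)
        m.line_ids = list(toy_phenotypes["line_id"].unique())
        cases = association.assign_cases(toy_phenotypes, "DR", top_k=3)
        assert len(association.run_association(m, cases)) == 0

    def test_planted_separator_has_minimum_p(self, small_study):
        genotypes, _, phenotypes, truth = small_study
        cases = association.assign_cases(phenotypes, "DR", top_k=25)
        results = association.run_association(genotypes, cases)
        best = results.loc[results["p_nominal"].idxmin(), "marker_id"]
        assert best == truth.causal_marker_id
        assert results["marker_id"].tolist() == genotypes.marker_ids  # order kept

    def test_deterministic_across_runs(self, small_study):
        genotypes, _, phenotypes, _ = small_study
        cases = association.assign_cases(phenotypes, "DR", top_k=25)
        r1 = association.run_association(genotypes, cases)
        r2 = association.run_association(genotypes, cases)
        pd.testing.assert_frame_equal(r1, r2)

    def test_null_rejection_fraction_conservative(self):
        """No causal marker: fraction of p <= 0.05 stays at/below nominal."""
        cfg = simulate.SimulationConfig(n_lines=100, n_markers=500, seed=42)
        genotypes = simulate.simulate_genotypes(cfg)
        _, phenotypes, _ = simulate.simulate_lifespans(genotypes, cfg)
        cases = association.assign_cases(phenotypes, "DR", top_k=25)
        results = association.run_association(genotypes, cases)
        frac = (results["p_nominal"] <= 0.05).mean()
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 500)


class TestAnnotateMarkers:
    @pytest.fixture
    def intervals(self):
        return pd.DataFrame(
            {"gene_id": ["geneA"], "contig": ["2L"], "start": [50], "end": [150]}
        )

    @pytest.mark.parametrize(
        "position,expected", [(100, "geneA"), (50, "geneA"), (150, "geneA"), (151, ""), (49, "")]
    )
    def test_inclusive_interval_membership(self, intervals, position, expected):
        results = pd.DataFrame(
            {"marker_id": ["m"], "contig": ["2L"], "position": [position], "p_nominal": [0.5]}
        )
        out = association.annotate_markers(results, intervals)
        assert out.loc[0, "gene_ids"] == expected

    def test_overlapping_genes_comma_joined(self):
        intervals = pd.DataFrame(
            {
                "gene_id": ["geneA", "geneB"],
                "contig": ["2L", "2L"],
                "start": [50, 90],
                "end": [150, 110],
            }
        )
        results = pd.DataFrame(
            {"marker_id": ["m"], "contig": ["2L"], "position": [100], "p_nominal": [0.5]}
        )
        assert association.annotate_markers(results, intervals).loc[0, "gene_ids"] == "geneA,geneB"

    def test_results_without_coordinates_warn(self, intervals):
        results = pd.DataFrame({"marker_id": ["m"], "p_nominal": [0.5]})
        with pytest.warns(UserWarning, match="no coordinates"):
            out = association.annotate_markers(results, intervals)
        assert "gene_ids" not in out.columns
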