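"""MEC/MECI, TSS/ESS, classification, FICI bound and reference models."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nds_synergy as ns
from nds_synergy.errors import IncompleteDesignError, InvalidParameterError

from conftest import diagonal_table


class TestMEC:
    def test_breakpoint_normalized_pair(self, ecoli_panel):
        x = ns.ConcentrationVector(
            {n: 0.0 for n in ecoli_panel.names} | {"Ampicillin": 8.0, "Aztreonam": 0.25}
        )
        assert ns.mec(x, ecoli_panel) == pytest.approx(1.0)

    def test_single_drug_at_normalization(self, mic_panel_2):
        x = ns.ConcentrationVector({"A": 1.0, "B": 0.0})
        assert ns.mec(x, mic_panel_2) == pytest.approx(1.0)

    def test_quarter_normalization_pair(self, mic_panel_2):
        x = ns.ConcentrationVector({"A": 0.25, "B": 0.25})
        assert ns.mec(x, mic_panel_2) == pytest.approx(0.25)

    def test_rescaling_normalizations_scales_mec_inversely(self, mic_panel_2):
        x = ns.ConcentrationVector({"A": 0.5, "B": 0.25})
        assert ns.mec(x, mic_panel_2.rescaled(4.0)) == pytest.approx(
            ns.mec(x, mic_panel_2) / 4.0
        )

    def test_all_zero_rejected(self, mic_panel_2):
        with pytest.raises(InvalidParameterError):
            ns.mec(ns.ConcentrationVector({"A": 0.0, "B": 0.0}), mic_panel_2)


class TestMECIFromNDS:
    def test_singleton_effective_at_mic(self, mic_panel_2, quarter_mic_pair_table):
        s = ns.meci_from_nds(quarter_mic_pair_table, {"A"}, mic_panel_2)
        assert s.meci == pytest.approx(1.0)
        assert s.witness.support == {"A"}

    def test_pair_diagonal_quarter(self, mic_panel_2, quarter_mic_pair_table):
        s = ns.meci_from_nds(quarter_mic_pair_table, {"A", "B"}, mic_panel_2)
        assert s.meci == pytest.approx(0.25)
        assert s.witness.support == {"A", "B"}
        assert s.witness["A"] == pytest.approx(0.25)

    def test_nothing_effective_gives_not_found(self, mic_panel_2):
        table = diagonal_table(mic_panel_2, ns.build_ladder(1, 2, 3), lambda s, c: False)
        s = ns.meci_from_nds(table, {"A", "B"}, mic_panel_2)
        assert s.meci is ns.NOT_FOUND
        assert s.classification == "indeterminate"
        assert s.witness is None

    def test_missing_diagonals_reported(self, mic_panel_2, quarter_mic_pair_table):
        truncated = ns.EffectivenessTable(
            quarter_mic_pair_table.data[quarter_mic_pair_table.data["subset"] != "B"],
            quarter_mic_pair_table.threshold,
        )
        with pytest.raises(IncompleteDesignError) as exc:
            ns.meci_from_nds(truncated, {"A", "B"}, mic_panel_2)
        assert frozenset({"B"}) in exc.value.missing

    def test_closure_vs_raw_min_on_nonmonotone_diagonal(self, mic_panel_2):
        # effective at 0.25 (dip) and at 1.0, but not at 0.5: paradoxical pattern
        def rule(subset, c):
            if len(subset) == 2:
                return c in (0.25, 1.0)
            return c >= 1.0

        table = diagonal_table(mic_panel_2, ns.build_ladder(1, 2, 3), rule)
        closed = ns.meci_from_nds(table, {"A", "B"}, mic_panel_2, closure="closure")
        raw = ns.meci_from_nds(table, {"A", "B"}, mic_panel_2, closure="raw-min")
        assert closed.meci == pytest.approx(1.0)
        assert raw.meci == pytest.approx(0.25)


class TestTSSESS:
    def test_mic_normalized_tss_equals_meci(self):
        m = {frozenset("A"): 1.0, frozenset("B"): 1.0, frozenset("AB"): 0.25}
        assert ns.tss(m, "AB") == pytest.approx(0.25)

    def test_tss_against_best_single(self):
        m = {frozenset("A"): 0.25, frozenset("B"): 1.0, frozenset("AB"): 0.5}
        assert ns.tss(m, "AB") == pytest.approx(2.0)

    def test_ess_cutoff_scenario(self):
        m = {frozenset("A"): 1.0, frozenset("B"): 1.0, frozenset("AB"): 0.25}
        assert ns.ess(m, "AB") == pytest.approx(0.25)

    def test_ess_one_when_subset_as_good(self):
        m = {
            frozenset("A"): 1.0,
            frozenset("B"): 1.0,
            frozenset("C"): 1.0,
            frozenset("AB"): 0.25,
            frozenset("AC"): 1.0,
            frozenset("BC"): 1.0,
            frozenset("ABC"): 0.25,
        }
        assert ns.ess(m, "ABC") == pytest.approx(1.0)
        assert ns.tss(m, "ABC") == pytest.approx(0.25)

    def test_not_found_subsets_skipped(self):
        m = {frozenset("A"): ns.NOT_FOUND, frozenset("B"): 0.5, frozenset("AB"): 0.25}
        assert ns.tss(m, "AB") == pytest.approx(0.5)
        assert ns.ess(m, "AB") == pytest.approx(0.5)

    def test_undefined_when_no_subset_defined(self):
        m = {frozenset("A"): ns.NOT_FOUND, frozenset("B"): ns.NOT_FOUND, frozenset("AB"): 0.25}
        assert ns.tss(m, "AB") is None
        assert ns.ess(m, "AB") is None


class TestClassify:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.25, "synergy"),  # inclusive boundary
            (0.1, "synergy"),
            (0.5, "weak synergy"),
            (0.9999, "weak synergy"),
            (1.0, "none"),
            (2.0, "none"),
            (None, "indeterminate"),
        ],
    )
    def test_labels(self, value, label):
        assert ns.classify(value) == label


class TestFICI:
    def test_diagonal_pair_bound(self, mic_panel_2, quarter_mic_pair_table):
        assert ns.fici_diagonal_bound(
            quarter_mic_pair_table, {"A", "B"}, mic_panel_2
        ) == pytest.approx(0.5)

    def test_off_diagonal_fic(self, mic_panel_2):
        x = ns.ConcentrationVector({"A": 0.25, "B": 0.5})
        assert ns.fic(x, mic_panel_2) == pytest.approx(0.75)

    def test_single_drug_at_mic(self, mic_panel_2, quarter_mic_pair_table):
        assert ns.fici_diagonal_bound(
            quarter_mic_pair_table, {"A"}, mic_panel_2
        ) == pytest.approx(1.0)

    def test_undefined_without_effective_points(self, mic_panel_2):
        table = diagonal_table(mic_panel_2, ns.build_ladder(1, 2, 3), lambda s, c: False)
        assert ns.fici_diagonal_bound(table, {"A", "B"}, mic_panel_2) is None


class TestReferenceModels:
    def test_worked_examples(self):
        assert ns.bliss_expected([0.5, 0.8]) == pytest.approx(0.9)
        assert ns.hsa_expected([0.5, 0.8]) == pytest.approx(0.8)

    def test_identity_and_absorbing(self):
        assert ns.bliss_expected([0.37]) == pytest.approx(0.37)
        assert ns.bliss_expected([0.2, 1.0, 0.5]) == pytest.approx(1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            ns.bliss_expected([0.5, 1.2])
        with pytest.raises(InvalidParameterError):
            ns.hsa_expected([-0.1])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_bliss_dominates_hsa(self, effects):
        assert ns.bliss_expected(effects) >= ns.hsa_expected(effects) - 1e-12


class TestScoreAllSubsets:
    def test_row_count_d4(self, mic_panel_4):
        table = diagonal_table(
            mic_panel_4, ns.build_ladder(1, 2, 4), lambda s, c: c >= 1.0
        )
        scores = ns.score_all_subsets(table, mic_panel_4)
        assert len(scores) == 15
        assert sum(1 for s in scores if s.size >= 2) == 11

    def test_all_inert_all_indeterminate(self, mic_panel_4):
        table = diagonal_table(mic_panel_4, ns.build_ladder(1, 2, 4), lambda s, c: False)
        scores = ns.score_all_subsets(table, mic_panel_4)
        assert all(s.meci is ns.NOT_FOUND for s in scores)
        assert all(s.classification == "indeterminate" for s in scores)

    def test_injected_pair_is_only_synergy(self, mic_panel_4):
        def rule(subset, c):
            if subset == frozenset("AB") or subset >= frozenset("AB"):
                return c >= 0.25
            return c >= 1.0

        table = diagonal_table(mic_panel_4, ns.build_ladder(1, 2, 6), rule)
        scores = ns.score_all_subsets(table, mic_panel_4)
        synergistic = [s for s in scores if s.classification == "synergy"]
        assert [sorted(s.subset) for s in synergistic] == [["A", "B"]]
        assert synergistic[0].ess == pytest.approx(0.25)

    def test_invariants_tss_le_ess_le_one_and_monotone_meci(self, mic_panel_4):
        rng = np.random.default_rng(4)
        # random upward-closed diagonal rules
        cut = {
            }
        ladder = ns.build_ladder(1, 2, 6)

        def rule(subset, c):
            key = frozenset(subset)
            if key not in cut:
                cut[key] = rng.choice(list(ladder.ratios) + [np.inf])
            return c >= cut[key]

        table = diagonal_table(mic_panel_4, ladder, rule)
        scores = ns.score_all_subsets(table, mic_panel_4)
        by_subset = {s.subset: s for s in scores}
        for s in scores:
            if s.tss is not None and s.ess is not None:
                assert s.tss <= s.ess + 1e-12
                assert s.ess <= 1.0 + 1e-12
            # MECI nonincreasing under superset inclusion
            for other in scores:
                if s.subset < other.subset:
                    if s.meci is not ns.NOT_FOUND and other.meci is not ns.NOT_FOUND:
                        assert other.meci <= s.meci + 1e-12

    def test_rescaling_normalizations_preserves_tss_ess(self, mic_panel_4):
        ladder = ns.build_ladder(1, 2, 5)

        def rule(subset, c):
            return c >= (0.25 if len(subset) >= 2 else 1.0)

        table = diagonal_table(mic_panel_4, ladder, rule)
        base = ns.score_all_subsets(table, mic_panel_4)
        scaled_panel = mic_panel_4.rescaled(4.0)
        scaled = ns.score_all_subsets(table, scaled_panel)
        for a, b in zip(base, scaled):
            assert a.subset == b.subset
            # identical ratios: MECI values (in normalized units) are unchanged
            # by rescaling N_i because the table stores ratios; TSS/ESS and
            # classification must be identical
            assert (a.tss is None) == (b.tss is None)
            if a.tss is not None:
                assert a.tss == pytest.approx(b.tss)
                assert a.ess == pytest.approx(b.ess)
            assert a.classification == b.classification

    def test_drug_order_permutation_invariance(self):
        names = ["A", "B", "C"]
        ladder = ns.build_ladder(1, 2, 4)

        def rule(subset, c):
            return c >= (0.25 if subset == frozenset("AC") else 1.0)

        results = {}
        for order in itertools.permutations(names):
            panel = ns.DrugPanel(
                tuple(ns.DrugSpec(n, mic=1.0, normalization_label="MIC") for n in order)
            )
            table = diagonal_table(panel, ladder, rule)
            scores = ns.score_all_subsets(table, panel)
            results[order] = {
                s.subset: (s.meci if s.meci is not ns.NOT_FOUND else None, s.tss, s.ess)
                for s in scores
            }
        first = next(iter(results.values()))
        for other in results.values():
            assert other == first
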