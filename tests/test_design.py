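"""Panel representation, dilution ladders and NDS design construction."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nds_synergy as ns
from nds_synergy.errors import InvalidParameterError


class TestDrugPanel:
    def test_normalization_resolution(self):
        amp = ns.DrugSpec("Ampicillin", asm_code="AMP", mic=16, breakpoint=8)
        assert amp.normalization == 8 and amp.normalization_label == "breakpoint"
        solo = ns.DrugSpec("X", mic=2.0)
        assert solo.normalization == 2.0 and solo.normalization_label == "MIC"
        custom = ns.DrugSpec("Y", mic=2.0, normalization=5.0)
        assert custom.normalization_label == "custom"

    def test_mic_label_overrides_breakpoint(self):
        d = ns.DrugSpec("X", mic=4, breakpoint=1, normalization_label="MIC")
        assert d.normalization == 4

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mic=0.0),
            dict(mic=-1.0),
            dict(mic=1.0, breakpoint=0.0),
            dict(mic=1.0, normalization_label="custom"),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            ns.DrugSpec("X", **kwargs)

    def test_duplicate_names_rejected(self):
        with pytest.raises(InvalidParameterError):
            ns.DrugPanel((ns.DrugSpec("X", mic=1), ns.DrugSpec("X", mic=2)))

    def test_example_panel_normalizations(self, ecoli_panel):
        assert len(ecoli_panel) == 8
        cip = ecoli_panel.drug("CIP")
        assert cip.normalization == cip.breakpoint == 0.25
        mic_version = ns.ecoli_mg1655_panel("MIC")
        assert mic_version.drug("CIP").normalization == 0.015625


class TestLadder:
    @pytest.mark.parametrize(
        "top,factor,steps,expected",
        [
            (1, 2, 3, (1.0, 0.5, 0.25)),
            (1, 2, 1, (1.0,)),
            (2, 4, 2, (2.0, 0.5)),
        ],
    )
    def test_geometric_ratios(self, top, factor, steps, expected):
        assert ns.build_ladder(top, factor, steps).ratios == pytest.approx(expected)

    def test_ten_step_twofold_gradient(self):
        lad = ns.build_ladder(1, 2, 10)
        assert len(lad) == 10
        assert lad.ratios[-1] == pytest.approx(2.0**-9)
        assert all(a > b for a, b in zip(lad.ratios, lad.ratios[1:]))

    @pytest.mark.parametrize("args", [(0, 2, 3), (1, 1, 3), (1, 0.5, 3), (1, 2, 0)])
    def test_invalid_ladder_parameters(self, args):
        with pytest.raises(InvalidParameterError):
            ns.build_ladder(*args)


class TestDesignCounts:
    @pytest.mark.parametrize(
        "d,steps,replicates,drug_points",
        [(2, 3, 1, 9), (1, 5, 1, 5), (3, 4, 2, 56)],
    )
    def test_enumeration_count(self, d, steps, replicates, drug_points):
        panel = ns.DrugPanel(
            tuple(ns.DrugSpec(f"d{i}", mic=1.0, normalization_label="MIC") for i in range(d))
        )
        design = ns.enumerate_nds(panel, ns.build_ladder(1, 2, steps), replicates)
        assert len(design.drug_points()) == drug_points
        assert len(design.control_points()) == replicates

    def test_eight_drug_ten_step_well_accounting(self):
        formula, unique = ns.design_size(8, 10)
        assert formula == 2560
        assert unique == 9 * 255 + 1 == 2296

    def test_one_drug_one_dose(self):
        assert ns.design_size(1, 2) == (4, 2)

    @pytest.mark.parametrize("d,m,expected", [(8, 10, 10**8), (1, 7, 7), (3, 4, 64)])
    def test_full_factorial_size(self, d, m, expected):
        assert ns.full_factorial_size(d, m) == expected

    @given(d=st.integers(1, 6), steps=st.integers(1, 10))
    @settings(max_examples=30, deadline=None)
    def test_enumeration_matches_closed_forms(self, d, steps):
        panel = ns.DrugPanel(
            tuple(ns.DrugSpec(f"d{i}", mic=1.0, normalization_label="MIC") for i in range(d))
        )
        design = ns.enumerate_nds(panel, ns.build_ladder(1, 2, steps), 1)
        formula, unique = ns.design_size(d, steps + 1)
        assert len(design.points) == unique
        assert len(design.drug_points()) == steps * (2**d - 1)

    @given(d=st.integers(1, 5), steps=st.integers(1, 6))
    @settings(max_examples=20, deadline=None)
    def test_diagonal_property(self, d, steps):
        """Every drug-containing point has equal normalized ratio across its subset."""
        panel = ns.DrugPanel(
            tuple(
                ns.DrugSpec(f"d{i}", mic=float(2**i), normalization_label="MIC")
                for i in range(d)
            )
        )
        design = ns.enumerate_nds(panel, ns.build_ladder(1, 2, steps), 1)
        norms = panel.normalizations()
        for p in design.drug_points():
            ratios = {p.concentrations[n] / norms[n] for n in p.subset}
            assert len(ratios) == 1
            assert next(iter(ratios)) == pytest.approx(design.ladder.ratio(p.step_index))


class TestLayout:
    def test_plate_count_for_eight_drug_screen(self, ecoli_panel):
        # de-duplicated 10-level screen: 9*255 + 1 = 2296 conditions
        design = ns.enumerate_nds(ecoli_panel, ns.build_ladder(1, 2, 9), 1)
        placed = ns.randomize_layout(design, wells_per_plate=96, seed=0)
        plates = {p.plate for p in placed.points}
        assert len(plates) == math.ceil(len(placed.points) / 96) == 24
        assert len({(p.plate, p.well) for p in placed.points}) == 2296
        # the headline accounting (duplicate controls at every step) would
        # instead need ceil(2560/96) = 27 plates
        assert math.ceil(ns.design_size(8, 10)[0] / 96) == 27

    def test_randomization_deterministic_and_collision_free(self, ecoli_panel):
        design = ns.enumerate_nds(ecoli_panel, ns.build_ladder(1, 2, 3), 1)
        a = ns.randomize_layout(design, seed=7)
        b = ns.randomize_layout(design, seed=7)
        assert [(p.plate, p.well) for p in a.points] == [(p.plate, p.well) for p in b.points]
        assert len({(p.plate, p.well) for p in a.points}) == len(a.points)
        c = ns.randomize_layout(design, seed=8)
        assert [(p.plate, p.well) for p in a.points] != [(p.plate, p.well) for p in c.points]

    def test_small_design_fits_one_plate(self, mic_panel_2):
        design = ns.enumerate_nds(mic_panel_2, ns.build_ladder(1, 2, 3), 1)
        placed = ns.randomize_layout(design, wells_per_plate=96, seed=0)
        assert {p.plate for p in placed.points} == {"P1"}
        assert len({p.well for p in placed.points}) == len(placed.points)


class TestStepsBetween:
    @pytest.mark.parametrize(
        "a,b,factor,expected",
        [
            (0.25, 0.015625, 2, 4.0),  # ciprofloxacin breakpoint vs MIC
            (16, 8, 2, 1.0),  # ampicillin MIC vs breakpoint
            (3.7, 3.7, 2, 0.0),
        ],
    )
    def test_values(self, a, b, factor, expected):
        assert ns.steps_between(a, b, factor) == pytest.approx(expected)

    def test_rejects_nonpositive(self):
        with pytest.raises(InvalidParameterError):
            ns.steps_between(0, 1, 2)
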