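"""Neutral-loss fragment assignment and MSn tree construction."""

import pytest
from conftest import WORKED_EXAMPLES

from mycomet.chem import ElementalFormula, IonSpecies, parse_formula
from mycomet.fragments import (
    FragmentObservation,
    LossFilter,
    assign_fragment,
    build_tree,
    loss_mass,
)
from oracles import subformula_assignments_oracle


class TestLossMass:
    def test_printed_adenosine_loss(self):
        assert loss_mass(268.1051, 136.0601) == pytest.approx(132.0450, abs=1e-10)

    def test_water_loss(self):
        assert loss_mass(500.0, 500.0 - 18.0106) == pytest.approx(18.0106, abs=1e-9)

    def test_acetaldehyde_loss(self):
        assert loss_mass(360.2166, 316.1897) == pytest.approx(44.0269, abs=1e-10)

    def test_nonpositive_difference_rejected(self):
        with pytest.raises(ValueError):
            loss_mass(100.0, 100.0)


def _printed_cases():
    for name, info in WORKED_EXAMPLES.items():
        for frag_mz, path in info["fragments"].items():
            yield pytest.param(info["formula"], frag_mz, path, id=f"{name}-{frag_mz}")


class TestAssignFragment:
    @pytest.mark.parametrize(
        "neutral, frag_mz, expected_loss",
        [
            ("C21H29NO4", 316.1897, "C2H4O"),
            ("C18H39NO3", 300.2869, "H2O"),
            ("C10H13N5O4", 136.0601, "C5H8O4"),
        ],
    )
    def test_top_assignment_examples(self, neutral, frag_mz, expected_loss):
        ion = IonSpecies(parse_formula(neutral)).composition
        top = assign_fragment(ion, frag_mz, tolerance_mda=5.0)[0]
        assert top.loss_formula.hill() == expected_loss

    def test_adenine_ion_retained(self):
        ion = IonSpecies(parse_formula("C10H13N5O4")).composition
        top = assign_fragment(ion, 136.0601, tolerance_mda=5.0)[0]
        assert top.fragment_formula.hill() == "C5H6N5"

    @pytest.mark.parametrize(
        "neutral, frag_mz",
        [("C10H13N5O4", 136.0601), ("C21H29NO4", 272.1633), ("C18H39NO3", 102.0891)],
    )
    def test_matches_subformula_oracle(self, neutral, frag_mz):
        ion = IonSpecies(parse_formula(neutral)).composition
        filt = LossFilter()
        got = {a.fragment_formula.hill() for a in assign_fragment(ion, frag_mz, 5.0)}
        expected = subformula_assignments_oracle(
            ion, frag_mz, 5.0, accept_loss=lambda loss: not loss or filt.accepts(loss)
        )
        assert got == expected

    def test_elemental_conservation(self):
        ion = IonSpecies(parse_formula("C21H29NO4")).composition
        for a in assign_fragment(ion, 272.1633, tolerance_mda=20.0):
            assert a.fragment_formula + a.loss_formula == ion

    def test_tolerance_monotonicity(self):
        ion = IonSpecies(parse_formula("C21H29NO4")).composition
        tight = {a.fragment_formula.hill() for a in assign_fragment(ion, 198.0912, 2.0)}
        loose = {a.fragment_formula.hill() for a in assign_fragment(ion, 198.0912, 10.0)}
        assert tight <= loose

    def test_no_match_returns_empty(self):
        ion = IonSpecies(parse_formula("CH4")).composition
        assert assign_fragment(ion, 5000.0, tolerance_mda=1.0) == []

    def test_empty_precursor_rejected(self):
        with pytest.raises(ValueError):
            assign_fragment(ElementalFormula(), 100.0)


class TestLossFilter:
    def test_printed_losses_all_pass(self):
        filt = LossFilter()
        for loss in ("C2H4O", "C4H8O2", "C4H10O", "C6H12O", "H2O", "C2H6O2",
                     "C11H22", "C5H8O4"):
            assert filt.accepts(parse_formula(loss)), loss

    def test_radical_losses_rejected_by_default(self):
        assert not LossFilter().accepts(parse_formula("CH3"))
        assert LossFilter(allow_radical=True).accepts(parse_formula("CH3"))

    def test_hydrogen_infeasible_rejected(self):
        assert not LossFilter().accepts(parse_formula("CH10"))

    def test_unsaturation_density_cap(self):
        # near-fully-unsaturated compositions rejected; aromatics at the cap kept
        assert not LossFilter().accepts(parse_formula("C6H4N4"))  # RDBE 7 > cap 6
        assert LossFilter().accepts(parse_formula("C6H6"))  # benzene, RDBE 4 = cap
        assert LossFilter().accepts(parse_formula("C5H5N5"))  # adenine, RDBE 6 = cap


class TestBuildTree:
    def _tree(self, name):
        info = WORKED_EXAMPLES[name]
        precursor_mz = info["measured_mz"]
        ms2 = [
            FragmentObservation(2, precursor_mz, mz)
            for mz, path in info["fragments"].items()
            if len(path) == 1
        ]
        ms3: dict[float, list[FragmentObservation]] = {}
        for mz, path in info["fragments"].items():
            if len(path) == 2:
                # the MS3 blocks re-isolate the most intense MS2 ion
                sel = {"oxasetin": 272.1633, "phytosphingosine": 256.2626}[name]
                ms3.setdefault(sel, []).append(FragmentObservation(3, sel, mz))
        return build_tree(
            precursor_mz, parse_formula(WORKED_EXAMPLES[name]["formula"]), ms2, ms3
        )

    @pytest.mark.parametrize("name", ["adenosine", "oxasetin", "phytosphingosine"])
    def test_all_printed_paths_recovered_top_ranked(self, name):
        info = WORKED_EXAMPLES[name]
        tree = self._tree(name)
        got = {
            round(n.observation.fragment_mz, 4): [
                f.hill() for f in n.best.cumulative_losses
            ]
            for n in tree.all_nodes()
            if n.assigned
        }
        for frag_mz, path in info["fragments"].items():
            if len(path) == 1 or frag_mz in got:
                assert got[frag_mz] == path

    def test_oxasetin_cumulative_losses(self):
        tree = self._tree("oxasetin")
        ms3_paths = {
            round(n.observation.fragment_mz, 4): [f.hill() for f in n.best.cumulative_losses]
            for parent in tree.ms2_nodes
            for n in parent.children
        }
        assert ms3_paths == {
            228.1366: ["C4H8O2", "C2H4O"],
            198.0912: ["C4H8O2", "C4H10O"],
            172.0733: ["C4H8O2", "C6H12O"],
        }

    def test_self_fragment_has_empty_loss(self):
        f = parse_formula("C10H13N5O4")
        mz = IonSpecies(f).mz()
        tree = build_tree(mz, f, [FragmentObservation(2, mz, mz)], {})
        best = tree.ms2_nodes[0].best
        assert best.loss_formula == ElementalFormula()
        assert best.cumulative_losses == ()

    def test_unmatched_ms3_precursor_raises(self):
        f = parse_formula("C10H13N5O4")
        mz = IonSpecies(f).mz()
        ms2 = [FragmentObservation(2, mz, 136.0601)]
        ms3 = {200.0: [FragmentObservation(3, 200.0, 100.0)]}
        with pytest.raises(ValueError, match="200"):
            build_tree(mz, f, ms2, ms3)

    def test_unassignable_fragment_retained(self):
        f = parse_formula("C10H13N5O4")
        mz = IonSpecies(f).mz()
        tree = build_tree(mz, f, [FragmentObservation(2, mz, 137.5)], {})
        node = tree.ms2_nodes[0]
        assert not node.assigned and node.best is None

    def test_children_compositions_subsets_of_parent(self):
        tree = self._tree("phytosphingosine")
        for parent in tree.ms2_nodes:
            if not parent.assigned:
                continue
            for child in parent.children:
                if child.assigned:
                    assert parent.best.fragment_formula.contains(
                        child.best.fragment_formula
                    )
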