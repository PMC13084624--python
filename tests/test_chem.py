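"""Mass calculus checked against pyteomics as an independent per-atom oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pt_mass

from adductomics.chem import (
    ELECTRON_MASS,
    ElementalComposition,
    FormulaError,
    Modification,
    PlacementError,
    RESIDUE_FORMULAS,
    UnsupportedModificationError,
    diagnostic_ion_mz,
    fragment_mz,
    modification_delta_mass,
    monoisotopic_mass,
    parse_formula,
    peptide_mass,
)

RESIDUES = sorted(RESIDUE_FORMULAS)


def oracle_mass(formula: str) -> float:
    """Independent per-atom summation via pyteomics."""
    return pt_mass.calculate_mass(formula=formula)


@pytest.mark.parametrize(
    "text, counts",
    [
        ("C4H9SO", {"C": 4, "H": 9, "S": 1, "O": 1}),
        ("H2O", {"H": 2, "O": 1}),
        ("C6H13S2O", {"C": 6, "H": 13, "S": 2, "O": 1}),
        ("C8H16S2O2", {"C": 8, "H": 16, "S": 2, "O": 2}),
    ],
)
def test_parse_formula(text, counts):
    assert parse_formula(text).counts == counts


def test_parse_formula_roundtrips_to_hill_order():
    assert parse_formula("SO C4 H9".replace(" ", "")).hill_formula() == "C4H9OS"
    assert parse_formula(parse_formula("H9C4SO").hill_formula()).counts == parse_formula("C4H9SO").counts


@pytest.mark.parametrize("bad", ["", "  ", "Xx4", "C4h9", "4C"])
def test_parse_formula_rejects_garbage(bad):
    with pytest.raises(FormulaError):
        parse_formula(bad)


def test_composition_subtraction_never_goes_negative():
    a, b = parse_formula("CH4"), parse_formula("C2H2")
    with pytest.raises(FormulaError):
        a - b
    assert (parse_formula("C2H6") - parse_formula("CH2")).hill_formula() == "CH4"


@pytest.mark.parametrize(
    "formula, expected",
    [("H2O", 18.010565), ("C4H9SO", 105.03741)],
)
def test_monoisotopic_mass_matches_per_atom_oracle(formula, expected):
    got = monoisotopic_mass(parse_formula(formula))
    assert got == pytest.approx(expected, abs=1e-5)
    assert got == pytest.approx(oracle_mass(formula), abs=1e-6)


def test_empty_composition_has_zero_mass():
    assert monoisotopic_mass(ElementalComposition()) == 0.0


@settings(max_examples=100, derandomize=True)
@given(
    st.dictionaries(
        st.sampled_from(["C", "H", "N", "O", "S", "P"]),
        st.integers(min_value=1, max_value=40),
        min_size=1,
        max_size=6,
    ),
    st.dictionaries(
        st.sampled_from(["C", "H", "N", "O", "S", "P"]),
        st.integers(min_value=1, max_value=40),
        min_size=1,
        max_size=6,
    ),
)
def test_mass_additivity(a_counts, b_counts):
    a, b = ElementalComposition(a_counts), ElementalComposition(b_counts)
    assert monoisotopic_mass(a) + monoisotopic_mass(b) == pytest.approx(
        monoisotopic_mass(a + b), abs=1e-9
    )


@pytest.mark.parametrize(
    "name, printed_mz",
    [("HETE", 105.04), ("HETET", 137.01)],
)
def test_reporter_ions_round_to_printed_values(mods, name, printed_mz):
    assert round(diagnostic_ion_mz(mods[name]), 2) == printed_mz


def test_hetete_reporter_follows_its_composition(mods):
    # the composition C6H13S2O computes to 165.040, the value the screen uses
    assert diagnostic_ion_mz(mods["HETETE"]) == pytest.approx(165.0402, abs=1e-3)


def test_every_registry_reporter_matches_oracle(mods):
    for mod in mods.values():
        if mod.diagnostic_ion is None:
            continue
        expected = oracle_mass(mod.diagnostic_ion.hill_formula()) - ELECTRON_MASS
        assert diagnostic_ion_mz(mod) == pytest.approx(expected, abs=1e-4)


def test_diagnostic_mz_requires_reporter(mods):
    with pytest.raises(UnsupportedModificationError):
        diagnostic_ion_mz(mods["CAM"])


@pytest.mark.parametrize(
    "name, formula, expected",
    [
        ("HETE", "C4H8SO", 104.02959),
        ("HETETE", "C6H12S2O", 164.03296),
        ("HETEOETE", "C8H16S2O2", 208.05917),
    ],
)
def test_adduct_delta_masses(mods, name, formula, expected):
    assert modification_delta_mass(mods[name]) == pytest.approx(expected, abs=1e-5)
    assert modification_delta_mass(mods[name]) == pytest.approx(
        oracle_mass(formula), abs=1e-6
    )


def test_peptide_mass_examples(mods):
    assert peptide_mass("CPF") == pytest.approx(365.14092, abs=1e-4)
    assert peptide_mass("G") == pytest.approx(75.03203, abs=1e-5)
    assert peptide_mass("CPF", [(1, mods["HETETE"])]) == pytest.approx(
        529.17388, abs=1e-4
    )
    # modified minus unmodified equals the delta exactly
    delta = peptide_mass("CPF", [(1, mods["HETETE"])]) - peptide_mass("CPF")
    assert delta == pytest.approx(modification_delta_mass(mods["HETETE"]), abs=1e-9)


def test_peptide_mass_matches_pyteomics_for_random_sequences():
    rng = np.random.default_rng(1)
    for _ in range(100):
        seq = "".join(rng.choice(RESIDUES, size=rng.integers(1, 25)))
        assert peptide_mass(seq) == pytest.approx(
            pt_mass.calculate_mass(sequence=seq), abs=1e-6
        )


def test_placement_errors(mods):
    with pytest.raises(PlacementError):
        peptide_mass("GPG", [(1, mods["HETE"])])  # G is not a target
    with pytest.raises(PlacementError):
        peptide_mass("CC", [(0, mods["HETE"])])  # position out of range
    # N-terminal placement allowed only on protein N-terminal peptides
    assert peptide_mass("VAK", [(1, mods["HETE"])], is_protein_nterm=True) > 0
    with pytest.raises(PlacementError):
        peptide_mass("VAK", [(1, mods["HETE"])], is_protein_nterm=False)


def test_fragment_examples(mods):
    assert fragment_mz("GG", (), "b", 1) == pytest.approx(58.02874, abs=1e-5)
    # full-length y ion is the singly protonated peptide
    assert fragment_mz("CPF", (), "y", 3) == pytest.approx(
        peptide_mass("CPF") + 1.00728, abs=1e-4
    )


def test_by_complementarity_random_modified_peptides(mods):
    """neutral(b_i) + neutral(y_{n-i}) equals the neutral peptide mass."""
    rng = np.random.default_rng(2)
    mod_list = [mods["HETE"], mods["HETETE"], mods["HETEOETE"]]
    proton = 1.00727646688
    for _ in range(100):
        seq = "".join(rng.choice(RESIDUES, size=rng.integers(2, 20)))
        targets = [
            i + 1 for i, aa in enumerate(seq) if aa in "CEDHM"
        ]
        assignments = []
        if targets:
            pos = int(rng.choice(targets))
            assignments = [(pos, mod_list[rng.integers(0, 3)])]
        total = peptide_mass(seq, assignments)
        n = len(seq)
        for i in range(1, n):
            b = fragment_mz(seq, assignments, "b", i) - proton
            y = fragment_mz(seq, assignments, "y", n - i) - proton
            assert b + y == pytest.approx(total, abs=1e-6)


def test_modification_invariants():
    with pytest.raises(ValueError):
        Modification(name="bad", delta=parse_formula("H2O"), targets=frozenset())
    with pytest.raises(ValueError):
        Modification(name="bad", delta=ElementalComposition(), targets=frozenset("C"))
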