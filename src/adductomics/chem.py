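"""Elemental-composition arithmetic, monoisotopic mass calculus, and the
sulfur-mustard modification registry.

Sulfur mustards (HD, sesquimustard Q, O-mustard T) alkylate nucleophilic
residues of serum proteins -- Cys, Glu, Asp, His, Met and the protein
N-terminus -- leaving hydroxyethylthioethyl-type chains (HETE, HETETE,
HETEOETE).  Each adduct family has a fixed elemental-composition delta and,
in MS2, sheds a small even-electron reporter cation from the alkyl side
chain (e.g. the HETE reporter C4H9SO+ at 105.04 m/z).  Everything downstream
(digestion, screening, simulation) rests on the mass calculus defined here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "ElementalComposition",
    "Modification",
    "parse_formula",
    "monoisotopic_mass",
    "diagnostic_ion_mz",
    "modification_delta_mass",
    "peptide_mass",
    "fragment_mz",
    "precursor_mz",
    "load_registry",
    "default_modifications",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "WATER_MASS",
    "RESIDUE_FORMULAS",
]

# CODATA/IUPAC monoisotopic atomic masses (Da), fixed at package build.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Se": 79.9165213,
}

PROTON_MASS = 1.00727646688
ELECTRON_MASS = 0.00054857990946


class FormulaError(ValueError):
    """Raised for malformed molecular formulas or unknown elements."""


class PlacementError(ValueError):
    """Raised when a modification is assigned to a residue it cannot target."""


class ElementalComposition:
    """Immutable element -> count mapping with element-wise arithmetic.

    Counts are strictly positive for stored keys; subtraction that would go
    negative raises.  Only elements with a defined monoisotopic mass are
    accepted.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None):
        clean: dict[str, int] = {}
        for el, n in (counts or {}).items():
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if not isinstance(n, int):
                raise FormulaError(f"count for {el} must be an integer, got {n!r}")
            if n < 0:
                raise FormulaError(f"negative count for {el}: {n}")
            if n > 0:
                clean[el] = n
        self._counts = clean

    @property
    def counts(self) -> dict[str, int]:
        return dict(self._counts)

    def __getitem__(self, el: str) -> int:
        return self._counts.get(el, 0)

    def __iter__(self):
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __bool__(self) -> bool:
        return bool(self._counts)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ElementalComposition):
            return NotImplemented
        return self._counts == other._counts

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self._counts)
        for el, n in other._counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalComposition(merged)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self._counts)
        for el, n in other._counts.items():
            left = merged.get(el, 0) - n
            if left < 0:
                raise FormulaError(
                    f"subtraction yields negative {el} count ({left})"
                )
            merged[el] = left
        return ElementalComposition(merged)

    def __mul__(self, k: int) -> "ElementalComposition":
        if not isinstance(k, int) or k < 0:
            raise FormulaError("composition can only be scaled by a non-negative int")
        return ElementalComposition({el: n * k for el, n in self._counts.items()})

    __rmul__ = __mul__

    def hill_formula(self) -> str:
        """Canonical Hill-order formula: C, H, then other elements alphabetically."""
        parts = []
        order = [el for el in ("C", "H") if el in self._counts]
        order += sorted(el for el in self._counts if el not in ("C", "H"))
        for el in order:
            n = self._counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __repr__(self) -> str:
        return f"ElementalComposition({self.hill_formula()!r})"


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementalComposition:
    """Parse a molecular formula such as ``"C4H9SO"`` into a composition.

    Grammar: element symbol followed by an optional positive integer count.
    Repeated symbols accumulate.  Unknown symbols or an empty string raise
    :class:`FormulaError`.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip()
    pos = 0
    counts: dict[str, int] = {}
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        el, digits = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return ElementalComposition(counts)


def monoisotopic_mass(comp: ElementalComposition | Mapping[str, int]) -> float:
    """Neutral monoisotopic mass in Da: sum of count x atomic mass."""
    if not isinstance(comp, ElementalComposition):
        comp = ElementalComposition(comp)
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in comp.counts.items())


WATER = parse_formula("H2O")
WATER_MASS = monoisotopic_mass(WATER)

# Residue (i.e. amino-acid minus water) elemental compositions, 20 standard
# letters; I and L are distinct keys with identical composition.
RESIDUE_FORMULAS: dict[str, ElementalComposition] = {
    "G": parse_formula("C2H3NO"),
    "A": parse_formula("C3H5NO"),
    "S": parse_formula("C3H5NO2"),
    "P": parse_formula("C5H7NO"),
    "V": parse_formula("C5H9NO"),
    "T": parse_formula("C4H7NO2"),
    "C": parse_formula("C3H5NOS"),
    "L": parse_formula("C6H11NO"),
    "I": parse_formula("C6H11NO"),
    "N": parse_formula("C4H6N2O2"),
    "D": parse_formula("C4H5NO3"),
    "Q": parse_formula("C5H8N2O2"),
    "K": parse_formula("C6H12N2O"),
    "E": parse_formula("C5H7NO3"),
    "M": parse_formula("C5H9NOS"),
    "H": parse_formula("C6H7N3O"),
    "F": parse_formula("C9H9NO"),
    "R": parse_formula("C6H12N4O"),
    "Y": parse_formula("C9H9NO2"),
    "W": parse_formula("C11H10N2O"),
}

VALID_RESIDUES = frozenset(RESIDUE_FORMULAS)

RESIDUE_MASSES: dict[str, float] = {
    aa: monoisotopic_mass(f) for aa, f in RESIDUE_FORMULAS.items()
}


@dataclass(frozen=True)
class Modification:
    """A covalent adduct (or fixed modification) definition.

    Parameters
    ----------
    name : str
        Label, e.g. ``"HETETE"``.
    delta : ElementalComposition
        Elemental composition added to the residue (neutral, mass > 0).
    targets : frozenset of str
        Residue letters the adduct can sit on.
    protein_nterm : bool
        Whether the protein N-terminal residue is additionally eligible
        regardless of its letter (N-terminal valine alkylation).
    diagnostic_ion : ElementalComposition or None
        Composition of the singly charged reporter cation shed from the
        alkyl side chain in MS2 (hydrogens of the cation included), if any.
    """

    name: str
    delta: ElementalComposition
    targets: frozenset = field(default_factory=frozenset)
    protein_nterm: bool = False
    diagnostic_ion: ElementalComposition | None = None

    def __post_init__(self):
        object.__setattr__(self, "targets", frozenset(self.targets))
        if monoisotopic_mass(self.delta) <= 0:
            raise ValueError(f"{self.name}: modification delta mass must be > 0")
        if not self.targets and not self.protein_nterm:
            raise ValueError(f"{self.name}: target residue set is empty")
        bad = self.targets - VALID_RESIDUES
        if bad:
            raise ValueError(f"{self.name}: unknown target residues {sorted(bad)}")
        if self.diagnostic_ion is not None and monoisotopic_mass(self.diagnostic_ion) <= 0:
            raise ValueError(f"{self.name}: diagnostic ion must have positive mass")


class UnsupportedModificationError(ValueError):
    """Raised when an operation needs a diagnostic ion the modification lacks."""


def modification_delta_mass(mod: Modification) -> float:
    """Monoisotopic mass added to a residue by the adduct, in Da."""
    return monoisotopic_mass(mod.delta)


def diagnostic_ion_mz(mod: Modification) -> float:
    """m/z of the singly charged reporter cation.

    The stored composition already includes the cation's hydrogens, so the
    m/z is its mass minus one electron (charge +1).
    """
    if mod.diagnostic_ion is None:
        raise UnsupportedModificationError(
            f"{mod.name} has no diagnostic ion defined"
        )
    return monoisotopic_mass(mod.diagnostic_ion) - ELECTRON_MASS


def _default_registry_spec() -> list[dict]:
    # HETE/HETETE/HETEOETE deltas follow the adduct structures (alkyl chain
    # replacing one residue hydrogen); reporter cations carry one extra H.
    return [
        {
            "name": "HETE",
            "delta": "C4H8SO",
            "targets": "CEDHM",
            "protein_nterm": True,
            "diagnostic_ion": "C4H9SO",
        },
        {
            "name": "HETETE",
            "delta": "C6H12S2O",
            "targets": "CEDHM",
            "protein_nterm": True,
            "diagnostic_ion": "C6H13S2O",
        },
        {
            "name": "HETEOETE",
            "delta": "C8H16S2O2",
            "targets": "CEDHM",
            "protein_nterm": True,
            "diagnostic_ion": "C8H17S2O2",
        },
        {
            # In-source side-chain fragment of the HETETE chain observed as
            # an additional reporter at 137.01 m/z; registered as a screening
            # target only.
            "name": "HETET",
            "delta": "C4H8S2O",
            "targets": "CEDHM",
            "protein_nterm": False,
            "diagnostic_ion": "C4H9S2O",
        },
        {
            # Carbamidomethylation of Cys (fixed alkylation from sample prep);
            # no reporter ion.
            "name": "CAM",
            "delta": "C2H3NO",
            "targets": "C",
            "protein_nterm": False,
            "diagnostic_ion": None,
        },
    ]


def _build_modification(entry: Mapping) -> Modification:
    targets = entry.get("targets", "")
    if isinstance(targets, str):
        targets = frozenset(targets)
    else:
        targets = frozenset(targets)
    diag = entry.get("diagnostic_ion")
    return Modification(
        name=str(entry["name"]),
        delta=parse_formula(entry["delta"]),
        targets=targets,
        protein_nterm=bool(entry.get("protein_nterm", False)),
        diagnostic_ion=parse_formula(diag) if diag else None,
    )


def default_modifications() -> dict[str, Modification]:
    """The built-in sulfur-mustard adduct registry, keyed by name."""
    return {e["name"]: _build_modification(e) for e in _default_registry_spec()}


def load_registry(path) -> dict[str, Modification]:
    """Load a user modification registry from YAML.

    Expected layout: a list of mappings with keys ``name``, ``delta``
    (formula string), ``targets`` (string of residue letters),
    ``protein_nterm`` (optional bool) and ``diagnostic_ion`` (optional
    formula).  This is how new electrophiles are added without code changes.
    """
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    if not isinstance(entries, list):
        raise ValueError("registry YAML must be a list of modification entries")
    mods = {}
    for e in entries:
        m = _build_modification(e)
        mods[m.name] = m
    return mods


def _check_sequence(sequence: str) -> None:
    bad = set(sequence) - VALID_RESIDUES
    if not sequence:
        raise ValueError("empty peptide sequence")
    if bad:
        raise ValueError(f"non-standard residues in sequence: {sorted(bad)}")


def _check_assignments(
    sequence: str,
    assignments: Iterable[tuple[int, Modification]],
    is_protein_nterm: bool = False,
) -> list[tuple[int, Modification]]:
    seen: set[int] = set()
    out = []
    for pos, mod in assignments:
        if not 1 <= pos <= len(sequence):
            raise PlacementError(
                f"modification position {pos} outside 1..{len(sequence)}"
            )
        if pos in seen:
            raise PlacementError(f"duplicate modification position {pos}")
        seen.add(pos)
        residue = sequence[pos - 1]
        nterm_ok = mod.protein_nterm and pos == 1 and is_protein_nterm
        if residue not in mod.targets and not nterm_ok:
            raise PlacementError(
                f"{mod.name} cannot target residue {residue} at position {pos}"
            )
        out.append((pos, mod))
    return out


def peptide_mass(
    sequence: str,
    assignments: Sequence[tuple[int, Modification]] = (),
    is_protein_nterm: bool = False,
) -> float:
    """Neutral monoisotopic mass of a (modified) peptide in Da.

    Sum of residue masses + one water + modification deltas.  Modification
    positions are 1-based within the peptide.
    """
    _check_sequence(sequence)
    assignments = _check_assignments(sequence, assignments, is_protein_nterm)
    mass = WATER_MASS + sum(RESIDUE_MASSES[aa] for aa in sequence)
    mass += sum(modification_delta_mass(mod) for _, mod in assignments)
    return mass


def precursor_mz(neutral_mass: float, charge: int) -> float:
    """m/z of a protonated species: (M + z*proton)/z."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass + charge * PROTON_MASS) / charge


def fragment_mz(
    sequence: str,
    assignments: Sequence[tuple[int, Modification]],
    series: str,
    index: int,
    charge: int = 1,
    is_protein_nterm: bool = False,
) -> float:
    """m/z of a b- or y-series fragment ion.

    ``b_i`` covers residues 1..i (neutral = residue sum + mods), ``y_i``
    covers the last i residues (neutral = residue sum + mods + water); the
    observed ion carries ``charge`` protons.  Complementarity:
    neutral(b_i) + neutral(y_{n-i}) equals the neutral peptide mass.
    """
    _check_sequence(sequence)
    assignments = _check_assignments(sequence, assignments, is_protein_nterm)
    n = len(sequence)
    if series not in ("b", "y"):
        raise ValueError(f"unknown ion series {series!r}")
    if not 1 <= index <= n:
        raise ValueError(f"fragment index {index} outside 1..{n}")
    if series == "b" and index == n:
        raise ValueError("b ion index must be < peptide length")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    mod_mass = dict.fromkeys(range(1, n + 1), 0.0)
    for pos, mod in assignments:
        mod_mass[pos] += modification_delta_mass(mod)
    if series == "b":
        neutral = sum(
            RESIDUE_MASSES[sequence[i - 1]] + mod_mass[i] for i in range(1, index + 1)
        )
    else:
        neutral = WATER_MASS + sum(
            RESIDUE_MASSES[sequence[i - 1]] + mod_mass[i]
            for i in range(n - index + 1, n + 1)
        )
    return (neutral + charge * PROTON_MASS) / charge
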