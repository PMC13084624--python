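"""In silico enzymatic digestion.

Two proteases matter for adduct hunting in serum: trypsin (specific
cleavage C-terminal of K/R, classically blocked by a following proline,
with missed cleavages) for bottom-up discovery, and a Proteinase-K-like
non-specific protease modelled as exhaustive short-substring generation --
sufficient to enumerate the Cys34 CPF tripeptide of human serum albumin
that anchors targeted verification.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

from .chem import (
    Modification,
    VALID_RESIDUES,
    fragment_mz as _fragment_mz,
    peptide_mass as _peptide_mass,
    precursor_mz as _precursor_mz,
)

__all__ = [
    "Protein",
    "Peptide",
    "ModifiedPeptide",
    "tryptic_digest",
    "nonspecific_digest",
    "enumerate_modified_forms",
    "cleavage_sites",
    "read_fasta",
    "write_digest_tsv",
]


@dataclass(frozen=True)
class Protein:
    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"protein {self.id}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"protein {self.id}: non-standard residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class Peptide:
    """A digested peptide with 1-based inclusive protein coordinates."""

    protein_id: str
    sequence: str
    start: int
    end: int
    missed_cleavages: int = 0

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("peptide coordinates inconsistent with sequence length")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")

    @property
    def is_protein_nterm(self) -> bool:
        return self.start == 1


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide plus per-residue modification assignments.

    ``assignments`` holds (1-based peptide position, Modification) pairs;
    positions are unique and each residue must be in the modification's
    target set (or be the protein N-terminus for N-terminal adducts).
    """

    peptide: Peptide
    assignments: tuple = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "assignments", tuple(self.assignments))
        # validates positions/eligibility; raises PlacementError on misuse
        _peptide_mass(
            self.peptide.sequence, self.assignments, self.peptide.is_protein_nterm
        )

    @property
    def sequence(self) -> str:
        return self.peptide.sequence

    def mass(self) -> float:
        """Neutral monoisotopic mass in Da."""
        return _peptide_mass(
            self.sequence, self.assignments, self.peptide.is_protein_nterm
        )

    def precursor_mz(self, charge: int = 1) -> float:
        return _precursor_mz(self.mass(), charge)

    def fragment_mz(self, series: str, index: int, charge: int = 1) -> float:
        return _fragment_mz(
            self.sequence,
            self.assignments,
            series,
            index,
            charge,
            self.peptide.is_protein_nterm,
        )

    def modification_string(self) -> str:
        """Compact annotation like ``"C1:HETETE;E5:HETE"`` (empty if bare)."""
        return ";".join(
            f"{self.sequence[pos - 1]}{pos}:{mod.name}"
            for pos, mod in sorted(self.assignments)
        )


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """Positions (1-based) after which trypsin cuts.

    Cleave after K or R; when ``proline_rule`` is on, a following P blocks
    the cut (the classical "specific" trypsin rule).  The C-terminus is not
    a cleavage site.
    """
    sites = []
    for i, aa in enumerate(sequence[:-1], start=1):
        if aa in "KR" and not (proline_rule and sequence[i] == "P"):
            sites.append(i)
    return sites


def tryptic_digest(
    prot: Protein, max_missed: int = 2, proline_rule: bool = True
) -> list[Peptide]:
    """All tryptic peptides with up to ``max_missed`` missed cleavages.

    Returned ordered by (start, end); coordinates 1-based inclusive.
    Concatenating the 0-missed-cleavage peptides reconstructs the protein.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = prot.sequence
    sites = cleavage_sites(seq, proline_rule)
    bounds = [0] + sites + [len(seq)]  # segment boundaries (0-based end offsets)
    peptides = []
    n_seg = len(bounds) - 1
    for i in range(n_seg):
        for j in range(i + 1, min(i + 1 + max_missed + 1, n_seg + 1)):
            start, end = bounds[i] + 1, bounds[j]
            peptides.append(
                Peptide(
                    protein_id=prot.id,
                    sequence=seq[start - 1 : end],
                    start=start,
                    end=end,
                    missed_cleavages=j - i - 1,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def nonspecific_digest(prot: Protein, min_len: int = 2, max_len: int = 4) -> list[Peptide]:
    """Proteinase-K-like digestion: every substring with length in range.

    Modelled as exhaustive substring enumeration within a short length
    window rather than cleavage-site kinetics; deduplicated by (start, end)
    and ordered by (start, end).
    """
    n = len(prot.sequence)
    if not (1 <= min_len <= max_len <= n):
        raise ValueError(
            f"need 1 <= min_len <= max_len <= {n}, got [{min_len}, {max_len}]"
        )
    peptides = []
    for start in range(1, n + 1):
        for length in range(min_len, max_len + 1):
            end = start + length - 1
            if end > n:
                break
            peptides.append(
                Peptide(
                    protein_id=prot.id,
                    sequence=prot.sequence[start - 1 : end],
                    start=start,
                    end=end,
                    missed_cleavages=0,
                )
            )
    return peptides


def eligible_positions(pep: Peptide, mod: Modification) -> list[int]:
    """1-based peptide positions where ``mod`` may sit."""
    pos = [i for i, aa in enumerate(pep.sequence, start=1) if aa in mod.targets]
    if mod.protein_nterm and pep.is_protein_nterm and 1 not in pos:
        pos.insert(0, 1)
    return pos


def enumerate_modified_forms(
    peps: Iterable[Peptide],
    mods: Sequence[Modification],
    max_mods_per_peptide: int = 2,
) -> list[ModifiedPeptide]:
    """All assignments of at most ``max_mods_per_peptide`` modifications.

    Includes the unmodified form of every peptide.  At one position, each
    applicable modification is an alternative; positions within one form
    are unique.
    """
    if max_mods_per_peptide < 0:
        raise ValueError("max_mods_per_peptide must be >= 0")
    forms: list[ModifiedPeptide] = []
    for pep in peps:
        options = []  # list of (position, modification) single assignments
        for mod in mods:
            for pos in eligible_positions(pep, mod):
                options.append((pos, mod))
        forms.append(ModifiedPeptide(pep, ()))
        for k in range(1, max_mods_per_peptide + 1):
            for combo in itertools.combinations(options, k):
                positions = [pos for pos, _ in combo]
                if len(set(positions)) != k:
                    continue
                forms.append(ModifiedPeptide(pep, combo))
    return forms


def read_fasta(path) -> list[Protein]:
    """Read proteins from FASTA (record id used as accession)."""
    return [
        Protein(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_digest_tsv(forms: Iterable[ModifiedPeptide | Peptide], path) -> None:
    """Write a digest (plain or modified peptides) as TSV."""
    with open(path, "w") as fh:
        fh.write(
            "protein_id\tstart\tend\tsequence\tmissed_cleavages\tmodifications\n"
        )
        for f in forms:
            if isinstance(f, ModifiedPeptide):
                pep, mods = f.peptide, f.modification_string()
            else:
                pep, mods = f, ""
            fh.write(
                f"{pep.protein_id}\t{pep.start}\t{pep.end}\t{pep.sequence}\t"
                f"{pep.missed_cleavages}\t{mods or 'NA'}\n"
            )
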