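"""Protein sequences and enumeration of assignable atoms."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

from . import topology


@dataclass(frozen=True)
class ProteinSequence:
    """A protein chain as an ordered list of three-letter residue codes.

    Residue numbering is strictly consecutive starting at
    ``first_residue_number``.
    """

    residues: tuple[str, ...]
    first_residue_number: int = 1

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty sequence")
        for i, code in enumerate(self.residues):
            if code not in topology.THREE_LETTER:
                raise ValueError(
                    f"unknown residue code {code!r} at position {i + 1}"
                )

    @classmethod
    def from_one_letter(cls, seq: str, first_residue_number: int = 1) -> "ProteinSequence":
        try:
            residues = tuple(topology.ONE_TO_THREE[c] for c in seq.upper())
        except KeyError as exc:
            raise ValueError(f"unknown one-letter code {exc.args[0]!r}") from exc
        return cls(residues, first_residue_number)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def numbers(self) -> range:
        return range(self.first_residue_number, self.first_residue_number + len(self))

    def residue_type(self, number: int) -> str:
        idx = number - self.first_residue_number
        if not 0 <= idx < len(self):
            raise KeyError(f"residue number {number} outside chain")
        return self.residues[idx]

    def one_letter(self) -> str:
        return "".join(topology.THREE_TO_ONE[r] for r in self.residues)


class Atom(NamedTuple):
    """One assignable atom: residue context, NMR name and nucleus."""

    residue_number: int
    residue_type: str
    atom_name: str
    nucleus: str

    @classmethod
    def make(cls, residue_number: int, residue_type: str, atom_name: str) -> "Atom":
        atom_name = topology.normalize_atom_name(atom_name)
        nuc = topology.nucleus_of(atom_name)
        if nuc is None:
            raise ValueError(f"{atom_name} is not an NMR-active 1H/13C/15N atom")
        return cls(residue_number, residue_type, atom_name, nuc)

    @property
    def key(self) -> tuple[int, str]:
        return (self.residue_number, self.atom_name)


@dataclass
class AtomSet:
    """All assignable atoms of a chain plus the per-residue covalent graph."""

    sequence: ProteinSequence
    atoms: tuple[Atom, ...]
    bonds: frozenset[frozenset] = field(default_factory=frozenset)
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {a.key: a for a in self.atoms}

    def __contains__(self, key: tuple[int, str]) -> bool:
        return key in self._index

    def __len__(self) -> int:
        return len(self.atoms)

    def get(self, residue_number: int, atom_name: str) -> Atom | None:
        return self._index.get((residue_number, topology.normalize_atom_name(atom_name)))

    def __getitem__(self, key: tuple[int, str]) -> Atom:
        atom = self.get(*key)
        if atom is None:
            raise KeyError(key)
        return atom

    def residue_atoms(self, residue_number: int) -> list[Atom]:
        return [a for a in self.atoms if a.residue_number == residue_number]

    def protons(self) -> list[Atom]:
        return [a for a in self.atoms if a.nucleus == "1H"]

    def bonded(self, a: Atom, b: Atom) -> bool:
        return frozenset((a.key, b.key)) in self.bonds

    def heavy_of(self, proton: Atom) -> Atom | None:
        """Heavy atom bonded to a proton (if assignable; O/S-bound protons -> None)."""
        rt = proton.residue_type
        heavy = topology.attached_heavy(rt, proton.atom_name)
        return self.get(proton.residue_number, heavy)


def enumerate_atoms(sequence: ProteinSequence) -> AtomSet:
    """Enumerate every assignable 1H/13C/15N atom of a protein.

    The N-terminal amide proton and proline HN are excluded; all other
    residues contribute their full standard atom complement.
    """
    atoms: list[Atom] = []
    bonds: set[frozenset] = set()
    prev_number: int | None = None
    for i, (number, rtype) in enumerate(zip(sequence.numbers, sequence.residues)):
        names = topology.residue_atoms(rtype, n_terminal=(i == 0))
        for name in names:
            atoms.append(Atom.make(number, rtype, name))
        for a, b in topology.residue_bonds(rtype):
            bonds.add(frozenset(((number, a), (number, b))))
        if prev_number is not None:
            bonds.add(frozenset(((prev_number, "C"), (number, "N"))))
        prev_number = number
    return AtomSet(sequence=sequence, atoms=tuple(atoms), bonds=frozenset(bonds))


# ---------------------------------------------------------------------------
# sequence file I/O

def read_fasta(path: str | Path) -> ProteinSequence:
    """Read a single-record FASTA file (one-letter codes)."""
    lines = Path(path).read_text().splitlines()
    seqs: list[str] = []
    current: list[str] = []
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if current:
                seqs.append("".join(current))
                current = []
        else:
            current.append(line)
    if current:
        seqs.append("".join(current))
    if len(seqs) != 1:
        raise ValueError(f"expected exactly one FASTA record, found {len(seqs)}")
    return ProteinSequence.from_one_letter(seqs[0])


def read_seq(path: str | Path) -> ProteinSequence:
    """Read a numbered three-letter sequence file (one 'RES  number' per line)."""
    residues: list[str] = []
    numbers: list[int] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        residues.append(parts[0].upper())
        numbers.append(int(parts[1]) if len(parts) > 1 else (numbers[-1] + 1 if numbers else 1))
    if not residues:
        raise ValueError("empty sequence file")
    for prev, nxt in zip(numbers, numbers[1:]):
        if nxt != prev + 1:
            raise ValueError("residue numbering must be strictly consecutive")
    return ProteinSequence(tuple(residues), numbers[0])


def write_seq(sequence: ProteinSequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        for number, rtype in zip(sequence.numbers, sequence.residues):
            fh.write(f"{rtype}  {number}\n")
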