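"""Covalent topology of the 20 standard amino-acid residues.

Atom names follow BMRB/IUPAC NMR conventions with stereospecific proton
names enumerated individually (HB2/HB3, methyl HG21/HG22/HG23, ...).
The amide proton is canonically "HN" and the backbone carbonyl carbon "C";
common aliases (H, C') are handled by :func:`normalize_atom_name`.

Neutral-pH protonation is assumed: His carries HD1 (Nδ1-H tautomer),
Asp/Glu are deprotonated, Lys NZ carries three protons.
"""

from __future__ import annotations

THREE_LETTER = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

# Input-name normalization (alias -> canonical).
_ATOM_ALIASES = {
    "H": "HN",
    "C'": "C",
    "CO": "C",
    "HN1": "HN",
}


def normalize_atom_name(name: str) -> str:
    """Map common atom-name dialect variants onto the canonical names used here."""
    name = name.strip().upper()
    return _ATOM_ALIASES.get(name, name)


def element_of(atom_name: str) -> str:
    """Chemical element inferred from an NMR atom name."""
    c = atom_name[0]
    if c in "HCNOS":
        return c
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


_NUCLEUS = {"H": "1H", "C": "13C", "N": "15N"}


def nucleus_of(atom_name: str) -> str | None:
    """NMR-active nucleus for an atom name, or None for O/S."""
    return _NUCLEUS.get(element_of(atom_name))


# Side-chain heavy atoms as (atom, parent) in build order, side-chain
# hydrogens as (hydrogen, bonded heavy atom).  CB bonds to CA implicitly.
# 'rings': ordered ring paths (closure bond = last->first), used by the
# geometry builder; 'planar': sp2 heavy atoms.
_SIDE_CHAINS: dict[str, dict] = {
    "ALA": {
        "heavy": [("CB", "CA")],
        "hyd": [("HB1", "CB"), ("HB2", "CB"), ("HB3", "CB")],
    },
    "ARG": {
        "heavy": [("CB", "CA"), ("CG", "CB"), ("CD", "CG"), ("NE", "CD"),
                  ("CZ", "NE"), ("NH1", "CZ"), ("NH2", "CZ")],
        "hyd": [("HB2", "CB"), ("HB3", "CB"), ("HG2", "CG"), ("HG3", "CG"),
                ("HD2", "CD"), ("HD3", "CD"), ("HE", "NE"),
                ("HH11", "NH1"), ("HH12", "NH1"), ("HH21", "NH2"), ("HH22", "NH2")],
        "planar": {"NE", "CZ", "NH1", "NH2"},
    },
    "ASN": {
        "heavy": [("CB", "CA"), ("CG", "CB"), ("OD1", "CG"), ("ND2", "CG")],
        "hyd": [("HB2", "CB"), ("HB3", "CB"), ("HD21", "ND2"), ("HD22", "ND2")],
        "planar": {"CG", "OD1", "ND2"},
    },
    "ASP": {
        "heavy": [("CB", "CA"), ("CG", "CB"), ("OD1", "CG"), ("OD2", "CG")],
        "hyd": [("HB2", "CB"), ("HB3", "CB")],
        "planar": {"CG", "OD1", "OD2"},
    },
    "CYS": {
        "heavy": [("CB", "CA"), ("SG", "CB")],
        "hyd": [("HB2", "CB"), ("HB3", "CB"), ("HG", "SG")],
    },
    "GLN": {
        "heavy": [("CB", "CA"), ("CG", "CB"), ("CD", "CG"), ("OE1", "CD"), ("NE2", "CD")],
        "hyd": [("HB2", "CB"), ("HB3", "CB"), ("HG2", "CG"), ("HG3", "CG"),
                ("HE21", "NE2"), ("HE22", "NE2")],
        "planar": {"CD", "OE1", "NE2"},
    },
    "GLU": {
        "heavy": [("CB", "CA"), ("CG", "CB"), ("CD", "CG"), ("OE1", "CD"), ("OE2", "CD")],
        "hyd": [("HB2", "CB"), ("HB3", "CB"), ("HG2", "CG"), ("HG3", "CG")],
        "planar": {"CD", "OE1", "OE2"},
    },
    "GLY": {"heavy": [], "hyd": []},
    "HIS": {
        "heavy": [("CB", "CA"), ("CG", "CB"), ("ND1", "CG"), ("CE1", "ND1"),
                  ("NE2", "CE1"), ("CD2", "NE2")],
        "hyd": [("HB2", "CB"), ("HB3", "CB"), ("HD1", "ND1"), ("HD2", "CD2"), ("HE1", "CE1")],
        "rings": [["CG", "ND1", "CE1", "NE2", "CD2"]],
        "planar": {"CG", "ND1", "CE1", "NE2", "CD2"},
    },
    "ILE": {
        "heavy": [("CB", "CA"), ("CG1", "CB"), ("CG2", "CB"), ("CD1", "CG1")],
        "hyd": [("HB", "CB"), ("HG12", "CG1"), ("HG13", "CG1"),
                ("HG21", "CG2"), ("HG22", "CG2"), ("HG23", "CG2"),
                ("HD11", "CD1"), ("HD12", "CD1"), ("HD13", "CD1")],
    },
    "LEU": {
        "heavy": [("CB", "CA"), ("CG", "CB"), ("CD1", "CG"), ("CD2", "CG")],
        "hyd": [("HB2", "CB"), ("HB3", "CB"), ("HG", "CG"),
                ("HD11", "CD1"), ("HD12", "CD1"), ("HD13", "CD1"),
                ("HD21", "CD2"), ("HD22", "CD2"), ("HD23", "CD2")],
    },
    "LYS": {
        "heavy": [("CB", "CA"), ("CG", "CB"), ("CD", "CG"), ("CE", "CD"), ("NZ", "CE")],
        "hyd": [("HB2", "CB"), ("HB3", "CB"), ("HG2", "CG"), ("HG3", "CG"),
                ("HD2", "CD"), ("HD3", "CD"), ("HE2", "CE"), ("HE3", "CE"),
                ("HZ1", "NZ"), ("HZ2", "NZ"), ("HZ3", "NZ")],
    },
    "MET": {
        "heavy": [("CB", "CA"), ("CG", "CB"), ("SD", "CG"), ("CE", "SD")],
        "hyd": [("HB2", "CB"), ("HB3", "CB"), ("HG2", "CG"), ("HG3", "CG"),
                ("HE1", "CE"), ("HE2", "CE"), ("HE3", "CE")],
    },
    "PHE": {
        "heavy": [("CB", "CA"), ("CG", "CB"), ("CD1", "CG"), ("CE1", "CD1"),
                  ("CZ", "CE1"), ("CE2", "CZ"), ("CD2", "CE2")],
        "hyd": [("HB2", "CB"), ("HB3", "CB"), ("HD1", "CD1"), ("HD2", "CD2"),
                ("HE1", "CE1"), ("HE2", "CE2"), ("HZ", "CZ")],
        "rings": [["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]],
        "planar": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    },
    "PRO": {
        "heavy": [("CB", "CA"), ("CG", "CB"), ("CD", "CG")],
        "hyd": [("HB2", "CB"), ("HB3", "CB"), ("HG2", "CG"), ("HG3", "CG"),
                ("HD2", "CD"), ("HD3", "CD")],
        # CD additionally bonds to backbone N, closing the pyrrolidine ring.
        "extra_bonds": [("CD", "N")],
        "rings": [["CB", "CG", "CD"]],
    },
    "SER": {
        "heavy": [("CB", "CA"), ("OG", "CB")],
        "hyd": [("HB2", "CB"), ("HB3", "CB"), ("HG", "OG")],
    },
    "THR": {
        "heavy": [("CB", "CA"), ("OG1", "CB"), ("CG2", "CB")],
        "hyd": [("HB", "CB"), ("HG1", "OG1"),
                ("HG21", "CG2"), ("HG22", "CG2"), ("HG23", "CG2")],
    },
    "TRP": {
        "heavy": [("CB", "CA"), ("CG", "CB"), ("CD1", "CG"), ("NE1", "CD1"),
                  ("CE2", "NE1"), ("CD2", "CE2"), ("CZ2", "CE2"), ("CH2", "CZ2"),
                  ("CZ3", "CH2"), ("CE3", "CZ3")],
        "hyd": [("HB2", "CB"), ("HB3", "CB"), ("HD1", "CD1"), ("HE1", "NE1"),
                ("HE3", "CE3"), ("HZ2", "CZ2"), ("HZ3", "CZ3"), ("HH2", "CH2")],
        "extra_bonds": [("CD2", "CG"), ("CE3", "CD2")],
        "rings": [["CG", "CD1", "NE1", "CE2", "CD2"],
                  ["CE2", "CZ2", "CH2", "CZ3", "CE3"]],
        "planar": {"CG", "CD1", "NE1", "CE2", "CD2", "CZ2", "CH2", "CZ3", "CE3"},
    },
    "TYR": {
        "heavy": [("CB", "CA"), ("CG", "CB"), ("CD1", "CG"), ("CE1", "CD1"),
                  ("CZ", "CE1"), ("CE2", "CZ"), ("CD2", "CE2"), ("OH", "CZ")],
        "hyd": [("HB2", "CB"), ("HB3", "CB"), ("HD1", "CD1"), ("HD2", "CD2"),
                ("HE1", "CE1"), ("HE2", "CE2"), ("HH", "OH")],
        "extra_bonds": [("CD2", "CG")],
        "rings": [["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]],
        "planar": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"},
    },
    "VAL": {
        "heavy": [("CB", "CA"), ("CG1", "CB"), ("CG2", "CB")],
        "hyd": [("HB", "CB"),
                ("HG11", "CG1"), ("HG12", "CG1"), ("HG13", "CG1"),
                ("HG21", "CG2"), ("HG22", "CG2"), ("HG23", "CG2")],
    },
}

_AROMATIC_CARBONS = {
    "HIS": {"CG", "CE1", "CD2"},
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
}
# Side-chain carbons with carbonyl/carboxyl/guanidinium character.
_CARBONYL_SIDE = {
    "ASP": {"CG"}, "GLU": {"CD"}, "ASN": {"CG"}, "GLN": {"CD"}, "ARG": {"CZ"},
}


def residue_atoms(residue_type: str, *, n_terminal: bool = False) -> list[str]:
    """All NMR-assignable atoms (1H/13C/15N) of one residue.

    Prolines carry no HN; the N-terminal residue's amide proton is excluded
    (it exchanges too fast to be observable).
    """
    if residue_type not in THREE_LETTER:
        raise ValueError(f"unknown residue type {residue_type!r}")
    sc = _SIDE_CHAINS[residue_type]
    atoms = ["N", "CA", "C"]
    if residue_type != "PRO" and not n_terminal:
        atoms.append("HN")
    if residue_type == "GLY":
        atoms += ["HA2", "HA3"]
    else:
        atoms.append("HA")
    for name, _parent in sc["heavy"]:
        if element_of(name) in "HCN":
            atoms.append(name)
    # hydroxyl/thiol protons exchange fast but belong to the standard complement
    atoms.extend(name for name, _parent in sc["hyd"])
    return atoms


def residue_bonds(residue_type: str) -> list[tuple[str, str]]:
    """Covalent bonds within one residue (backbone O included; inter-residue
    peptide bond N(i)-C(i-1) is handled at chain level)."""
    sc = _SIDE_CHAINS[residue_type]
    bonds = [("N", "CA"), ("CA", "C"), ("C", "O")]
    if residue_type != "PRO":
        bonds.append(("N", "HN"))
    if residue_type == "GLY":
        bonds += [("CA", "HA2"), ("CA", "HA3")]
    else:
        bonds.append(("CA", "HA"))
    bonds += [(p, a) for a, p in sc["heavy"]]
    bonds += [(p, a) for a, p in sc["hyd"]]
    bonds += [tuple(b) for b in sc.get("extra_bonds", [])]
    return bonds


def carbon_class(residue_type: str, atom_name: str) -> str:
    """Classify a carbon: 'aliphatic', 'aromatic' or 'carbonyl'."""
    if element_of(atom_name) != "C":
        raise ValueError(f"{atom_name} is not a carbon")
    if atom_name == "C":
        return "carbonyl"
    if atom_name in _AROMATIC_CARBONS.get(residue_type, ()):
        return "aromatic"
    if atom_name in _CARBONYL_SIDE.get(residue_type, ()):
        return "carbonyl"
    return "aliphatic"


def attached_heavy(residue_type: str, h_name: str) -> str:
    """Heavy atom to which a given proton is bonded."""
    for a, b in residue_bonds(residue_type):
        if a == h_name:
            return b
        if b == h_name:
            return a
    raise KeyError(h_name)


# Stereo/prochiral swap partners used by the lenient evaluation mode.
def stereo_partner(residue_type: str, atom_name: str) -> str | None:
    """Partner atom under a stereo swap (HB2<->HB3, Val/Leu methyl groups,
    aromatic ring symmetry D1<->D2, E1<->E2), or None."""
    pairs: dict[str, str] = {}

    def add(a: str, b: str) -> None:
        pairs[a] = b
        pairs[b] = a

    sc_names = {n for n, _ in _SIDE_CHAINS[residue_type]["hyd"]}
    for stem in ("HA", "HB", "HG", "HD", "HE", "HG1", "HD1", "HQ"):
        a, b = stem + "2", stem + "3"
        if residue_type == "GLY" and stem == "HA":
            add("HA2", "HA3")
        elif a in sc_names and b in sc_names:
            add(a, b)
    if residue_type == "ILE":
        add("HG12", "HG13")
    if residue_type in ("LEU",):
        add("CD1", "CD2")
        for i in "123":
            add("HD1" + i, "HD2" + i)
    if residue_type in ("VAL",):
        add("CG1", "CG2")
        for i in "123":
            add("HG1" + i, "HG2" + i)
    if residue_type in ("PHE", "TYR"):
        add("CD1", "CD2")
        add("CE1", "CE2")
        add("HD1", "HD2")
        add("HE1", "HE2")
    return pairs.get(atom_name)


def side_chain(residue_type: str) -> dict:
    return _SIDE_CHAINS[residue_type]


# Methyl carbons per residue (their three protons are magnetically equivalent).
_METHYLS = {
    "ALA": ["CB"], "ILE": ["CG2", "CD1"], "LEU": ["CD1", "CD2"],
    "MET": ["CE"], "THR": ["CG2"], "VAL": ["CG1", "CG2"],
}


def equivalence_groups(residue_type: str) -> list[list[str]]:
    """Groups of protons (or carbons) with one observable shift value.

    Methyl protons rotate fast; Phe/Tyr ring positions average by ring
    flipping; Lys NZ protons exchange among equivalent sites.  Reference
    shift lists report a single value for each such group.
    """
    groups: list[list[str]] = []
    for c in _METHYLS.get(residue_type, []):
        stem = "H" + c[1:]
        groups.append([stem + "1", stem + "2", stem + "3"])
    if residue_type in ("PHE", "TYR"):
        groups += [["HD1", "HD2"], ["HE1", "HE2"], ["CD1", "CD2"], ["CE1", "CE2"]]
    if residue_type == "LYS":
        groups.append(["HZ1", "HZ2", "HZ3"])
    return groups


def is_fast_exchanging(residue_type: str, atom_name: str) -> bool:
    """Protons lost to fast solvent exchange (no observable NOESY peaks):
    hydroxyl and thiol protons, and the Lys ammonium protons."""
    if element_of(atom_name) != "H":
        return False
    heavy = attached_heavy(residue_type, atom_name)
    if element_of(heavy) in ("O", "S"):
        return True
    return residue_type == "LYS" and heavy == "NZ"
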