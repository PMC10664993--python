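"""Bundled per-(residue, atom) chemical-shift statistics.

Gaussian means/SDs in ppm resembling the distributions of assigned shifts
in the BMRB archive: residue-specific random-coil values for backbone and
common side-chain atoms, class-based defaults elsewhere.  Users may supply
their own table; this one only needs to be realistic.
"""

from __future__ import annotations

from functools import lru_cache

from . import topology

# Random-coil backbone carbon means (ppm).
_CA = {
    "ALA": 52.5, "ARG": 56.0, "ASN": 53.1, "ASP": 54.2, "CYS": 58.2,
    "GLN": 55.7, "GLU": 56.6, "GLY": 45.1, "HIS": 55.0, "ILE": 61.1,
    "LEU": 55.1, "LYS": 56.2, "MET": 55.4, "PHE": 57.7, "PRO": 63.3,
    "SER": 58.3, "THR": 61.8, "TRP": 57.5, "TYR": 57.9, "VAL": 62.2,
}
_CB = {
    "ALA": 19.1, "ARG": 30.9, "ASN": 38.9, "ASP": 41.1, "CYS": 28.0,
    "GLN": 29.4, "GLU": 30.0, "HIS": 29.0, "ILE": 38.8, "LEU": 42.4,
    "LYS": 33.1, "MET": 32.9, "PHE": 39.6, "PRO": 32.1, "SER": 63.8,
    "THR": 69.8, "TRP": 29.6, "TYR": 38.8, "VAL": 32.9,
}
# Side-chain heavy-atom means, (residue, atom) -> ppm.
_SIDE_HEAVY = {
    ("ARG", "CG"): 27.2, ("ARG", "CD"): 43.2, ("ARG", "CZ"): 159.5, ("ARG", "NE"): 84.8,
    ("ASN", "CG"): 176.8, ("ASN", "ND2"): 112.8,
    ("ASP", "CG"): 179.2,
    ("GLN", "CG"): 33.7, ("GLN", "CD"): 179.7, ("GLN", "NE2"): 111.9,
    ("GLU", "CG"): 36.1, ("GLU", "CD"): 183.8,
    ("HIS", "ND1"): 194.0, ("HIS", "NE2"): 177.0, ("HIS", "CD2"): 119.8, ("HIS", "CE1"): 136.5,
    ("ILE", "CG1"): 27.2, ("ILE", "CG2"): 17.4, ("ILE", "CD1"): 12.6,
    ("LEU", "CG"): 26.8, ("LEU", "CD1"): 24.6, ("LEU", "CD2"): 23.8,
    ("LYS", "CG"): 24.9, ("LYS", "CD"): 29.0, ("LYS", "CE"): 41.9, ("LYS", "NZ"): 33.2,
    ("MET", "CG"): 32.0, ("MET", "CE"): 17.0,
    ("PHE", "CG"): 138.9, ("PHE", "CD1"): 131.5, ("PHE", "CD2"): 131.5,
    ("PHE", "CE1"): 130.7, ("PHE", "CE2"): 130.7, ("PHE", "CZ"): 129.2,
    ("PRO", "CG"): 27.2, ("PRO", "CD"): 50.3,
    ("THR", "CG2"): 21.4,
    ("TRP", "CG"): 110.5, ("TRP", "CD1"): 126.4, ("TRP", "CD2"): 127.5,
    ("TRP", "NE1"): 129.3, ("TRP", "CE2"): 138.5, ("TRP", "CE3"): 120.5,
    ("TRP", "CZ2"): 114.3, ("TRP", "CZ3"): 121.4, ("TRP", "CH2"): 123.9,
    ("TYR", "CG"): 129.8, ("TYR", "CD1"): 132.9, ("TYR", "CD2"): 132.9,
    ("TYR", "CE1"): 117.9, ("TYR", "CE2"): 117.9, ("TYR", "CZ"): 156.6,
    ("VAL", "CG1"): 21.2, ("VAL", "CG2"): 20.5,
}
# Proton means by (residue, name-prefix); longest prefix wins.
_H_PREFIX = {
    "ALA": [("HB", 1.39)],
    "ARG": [("HB", 1.80), ("HG", 1.60), ("HD", 3.20), ("HE", 7.30), ("HH", 6.80)],
    "ASN": [("HB", 2.80), ("HD2", 7.30)],
    "ASP": [("HB", 2.70)],
    "CYS": [("HB", 2.90), ("HG", 1.80)],
    "GLN": [("HB", 2.10), ("HG", 2.40), ("HE2", 7.20)],
    "GLU": [("HB", 2.00), ("HG", 2.30)],
    "GLY": [("HA", 3.96)],
    "HIS": [("HB", 3.10), ("HD1", 9.50), ("HD2", 7.00), ("HE1", 8.00)],
    "ILE": [("HB", 1.80), ("HG1", 1.30), ("HG2", 0.90), ("HD1", 0.80)],
    "LEU": [("HB", 1.65), ("HG", 1.60), ("HD", 0.90)],
    "LYS": [("HB", 1.80), ("HG", 1.40), ("HD", 1.70), ("HE", 3.00), ("HZ", 7.50)],
    "MET": [("HB", 2.10), ("HG", 2.60), ("HE", 2.10)],
    "PHE": [("HB", 3.00), ("HD", 7.30), ("HE", 7.35), ("HZ", 7.30)],
    "PRO": [("HB", 2.10), ("HG", 2.00), ("HD", 3.60)],
    "SER": [("HB", 3.90), ("HG", 5.30)],
    "THR": [("HB", 4.20), ("HG2", 1.20), ("HG1", 5.20)],
    "TRP": [("HB", 3.20), ("HD1", 7.20), ("HE1", 10.10), ("HE3", 7.60),
            ("HZ2", 7.50), ("HZ3", 7.10), ("HH2", 7.20)],
    "TYR": [("HB", 3.00), ("HD", 7.10), ("HE", 6.80), ("HH", 9.20)],
    "VAL": [("HB", 2.10), ("HG", 0.90)],
}

# Class-based SDs (ppm).
_SD = {
    "CA": 2.0, "CB": 2.0, "C": 1.5, "N": 4.0, "HN": 0.60, "HA": 0.45,
    "H_side": 0.40, "H_aromatic": 0.50, "H_exchange": 1.20,
    "C_aliphatic": 2.2, "C_aromatic": 2.5, "C_carbonyl": 1.8, "N_side": 5.0,
}


def _mean_sd(residue_type: str, atom_name: str) -> tuple[float, float]:
    if atom_name == "CA":
        return _CA[residue_type], _SD["CA"]
    if atom_name == "CB":
        return _CB[residue_type], _SD["CB"]
    if atom_name == "C":
        return 176.2, _SD["C"]
    if atom_name == "N":
        mean = {"GLY": 109.5, "PRO": 135.0}.get(residue_type, 119.5)
        return mean, _SD["N"]
    if atom_name == "HN":
        return 8.30, _SD["HN"]
    if atom_name.startswith("HA"):
        base = _CA  # residue-dependence of HA is mild; use a flat mean
        mean = 3.96 if residue_type == "GLY" else 4.35
        return mean, _SD["HA"]
    el = topology.element_of(atom_name)
    if el == "C":
        if (residue_type, atom_name) in _SIDE_HEAVY:
            mean = _SIDE_HEAVY[(residue_type, atom_name)]
        else:
            cls = topology.carbon_class(residue_type, atom_name)
            mean = {"aliphatic": 30.0, "aromatic": 128.0, "carbonyl": 177.0}[cls]
        cls = topology.carbon_class(residue_type, atom_name)
        return mean, _SD[f"C_{cls}"]
    if el == "N":
        mean = _SIDE_HEAVY.get((residue_type, atom_name), 110.0)
        return mean, _SD["N_side"]
    # protons
    for prefix, mean in sorted(_H_PREFIX.get(residue_type, []), key=lambda t: -len(t[0])):
        if atom_name.startswith(prefix):
            heavy = topology.attached_heavy(residue_type, atom_name)
            hel = topology.element_of(heavy)
            if hel in ("O", "S"):
                sd = _SD["H_exchange"]
            elif hel == "N":
                sd = _SD["H_side"] + 0.1
            elif topology.carbon_class(residue_type, heavy) == "aromatic":
                sd = _SD["H_aromatic"]
            else:
                sd = _SD["H_side"]
            return mean, sd
    return 2.0, _SD["H_side"]


@lru_cache(maxsize=1)
def default_statistics() -> dict[tuple[str, str], tuple[float, float]]:
    """The bundled statistics table: (residue_type, atom_name) -> (mean, sd)."""
    table: dict[tuple[str, str], tuple[float, float]] = {}
    for rtype in topology.THREE_LETTER:
        for name in topology.residue_atoms(rtype):
            table[(rtype, name)] = _mean_sd(rtype, name)
    return table
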