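"""Ideal-covalent-geometry model building in torsion space.

Chains are grown atom by atom with the standard internal-coordinate (NeRF)
construction: each atom is placed at a fixed bond length and angle from its
parent, at a dihedral relative to the parent chain.  Backbone conformation
is set by (phi, psi) per residue; side chains use rotatable torsions from a
policy (staggered/extended by default, uniformly random for random-coil
bundles).  Rings are built as planar polygons (a deliberate simplification
— proline pucker and indole closure are approximate), which is sufficient
for realistic inter-proton distance patterns.

Coordinates are returned as ``{(residue_number, atom_name): ndarray(3)}``
including non-assignable O/S atoms.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np

from . import topology
from .sequence import ProteinSequence

# Bond lengths (Å)
_BL = {
    ("C", "C"): 1.52, ("C", "N"): 1.47, ("C", "O"): 1.42, ("C", "S"): 1.81,
    ("C", "H"): 1.09, ("N", "H"): 1.01, ("O", "H"): 0.96, ("S", "H"): 1.34,
}
_BL_AROMATIC_CC = 1.39
_BL_CO_DOUBLE = 1.23

# Backbone ideal values
_N_CA, _CA_C, _C_N, _C_O, _N_H = 1.458, 1.525, 1.329, 1.231, 1.01
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA = 111.2, 117.2, 121.7
_ANG_CA_C_O, _ANG_C_N_H = 120.5, 119.5

HELIX = (-57.0, -47.0)
EXTENDED = (-120.0, 120.0)

# Side-chain geometry overrides: (residue, atom) -> (angle_deg, torsion_spec)
# torsion_spec: float = fixed dihedral; "chi" = rotatable from the policy.
_SC_GEOM: dict[tuple[str, str], tuple[float, float | str]] = {
    # His imidazole
    ("HIS", "ND1"): (126.0, "chi"), ("HIS", "CE1"): (108.0, 180.0),
    ("HIS", "NE2"): (108.0, 0.0), ("HIS", "CD2"): (108.0, 0.0),
    # Phe / Tyr ring
    ("PHE", "CD1"): (120.0, "chi"), ("PHE", "CE1"): (120.0, 180.0),
    ("PHE", "CZ"): (120.0, 0.0), ("PHE", "CE2"): (120.0, 0.0), ("PHE", "CD2"): (120.0, 0.0),
    ("TYR", "CD1"): (120.0, "chi"), ("TYR", "CE1"): (120.0, 180.0),
    ("TYR", "CZ"): (120.0, 0.0), ("TYR", "CE2"): (120.0, 0.0), ("TYR", "CD2"): (120.0, 0.0),
    ("TYR", "OH"): (120.0, 180.0),
    # Trp indole (two fused rings, approximate closure)
    ("TRP", "CD1"): (127.0, "chi"), ("TRP", "NE1"): (110.0, 180.0),
    ("TRP", "CE2"): (107.0, 0.0), ("TRP", "CD2"): (107.0, 0.0),
    ("TRP", "CZ2"): (130.0, 180.0), ("TRP", "CH2"): (118.0, 180.0),
    ("TRP", "CZ3"): (121.0, 0.0), ("TRP", "CE3"): (121.0, 0.0),
    # Pro ring, planar approximation
    ("PRO", "CG"): (104.0, 0.0), ("PRO", "CD"): (104.0, 0.0),
    # planar amide / carboxyl / guanidinium groups
    ("ASN", "OD1"): (121.0, 0.0), ("ASN", "ND2"): (122.0, 180.0),
    ("ASP", "OD1"): (118.5, 0.0), ("ASP", "OD2"): (118.5, 180.0),
    ("GLN", "OE1"): (121.0, 0.0), ("GLN", "NE2"): (122.0, 180.0),
    ("GLU", "OE1"): (118.5, 0.0), ("GLU", "OE2"): (118.5, 180.0),
    ("ARG", "CZ"): (124.0, 180.0), ("ARG", "NH1"): (120.0, 0.0), ("ARG", "NH2"): (120.0, 180.0),
}

# parents whose substituents are planar (sp2)
_SP2_PARENTS = {
    ("ASN", "ND2"), ("GLN", "NE2"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("HIS", "ND1"), ("HIS", "CD2"), ("HIS", "CE1"), ("TRP", "NE1"),
    ("TRP", "CD1"), ("TRP", "CE3"), ("TRP", "CZ2"), ("TRP", "CZ3"), ("TRP", "CH2"),
}


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: new atom bonded to ``c`` with angle at (b, c) and
    dihedral (a, b, c, new)."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-9:  # colinear references: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0]) if abs(bc[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, bc)
    d = np.array([
        -length * math.cos(ang),
        length * math.sin(ang) * math.cos(tor),
        length * math.sin(ang) * math.sin(tor),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Dihedral angle p0-p1-p2-p3 in degrees."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def _bond_length(res: str, parent: str, child: str) -> float:
    pe, ce = topology.element_of(parent), topology.element_of(child)
    if pe == "C" and ce == "O" and child in ("OD1", "OD2", "OE1", "OE2"):
        return _BL_CO_DOUBLE
    if pe == "C" and ce == "C":
        try:
            if (topology.carbon_class(res, parent) == "aromatic"
                    and topology.carbon_class(res, child) == "aromatic"):
                return _BL_AROMATIC_CC
        except ValueError:
            pass
    key = tuple(sorted((pe, ce)))
    return _BL.get(key, _BL.get((key[1], key[0]), 1.5))


def build_conformer(
    sequence: ProteinSequence,
    phi: np.ndarray,
    psi: np.ndarray,
    chi_policy: Callable[[], float],
) -> dict[tuple[int, str], np.ndarray]:
    """Build one full-atom conformer from backbone torsions and a side-chain
    torsion policy (called once per rotatable bond)."""
    nres = len(sequence)
    coords: dict[tuple[int, str], np.ndarray] = {}
    numbers = list(sequence.numbers)

    # bootstrap frame
    v_prev_c = np.array([-_C_N, 0.0, 0.0])
    v_helper = np.array([-2.0, 1.0, 0.0])
    prev_c: np.ndarray | None = None
    prev_ca: np.ndarray | None = None
    prev_ca2: np.ndarray | None = None

    for i in range(nres):
        num = numbers[i]
        rtype = sequence.residues[i]
        if i == 0:
            n = np.zeros(3)
            ca = place_atom(v_helper, v_prev_c, n, _N_CA, _ANG_C_N_CA, 77.0)
            c = place_atom(v_prev_c, n, ca, _CA_C, _ANG_N_CA_C, phi[i])
            frame_prev_c = v_prev_c
        else:
            n = place_atom(prev_ca2, prev_ca, prev_c, _C_N, _ANG_CA_C_N, psi[i - 1])
            ca = place_atom(prev_ca, prev_c, n, _N_CA, _ANG_C_N_CA, 180.0)  # omega trans
            c = place_atom(prev_c, n, ca, _CA_C, _ANG_N_CA_C, phi[i])
            frame_prev_c = prev_c
        coords[(num, "N")] = n
        coords[(num, "CA")] = ca
        coords[(num, "C")] = c
        coords[(num, "O")] = place_atom(n, ca, c, _C_O, _ANG_CA_C_O, psi[i] + 180.0)
        if rtype != "PRO" and i > 0:
            # amide proton in the peptide plane, trans to the carbonyl O
            coords[(num, "HN")] = place_atom(prev_ca, prev_c, n, _N_H, _ANG_C_N_H, 180.0)

        # CA substituents: HA and CB relative to phi about the N-CA bond
        if rtype == "GLY":
            coords[(num, "HA2")] = place_atom(frame_prev_c, n, ca, 1.09, 109.5, phi[i] + 122.5)
            coords[(num, "HA3")] = place_atom(frame_prev_c, n, ca, 1.09, 109.5, phi[i] - 118.5)
        else:
            coords[(num, "HA")] = place_atom(frame_prev_c, n, ca, 1.09, 109.5, phi[i] - 118.5)

        # side chain
        sc = topology.side_chain(rtype)
        parent_chain: dict[str, str] = {"CA": "N", "N": "__prevC__", "CB": "CA"}
        for a, p in sc["heavy"]:
            parent_chain[a] = p
        for h, p in sc["hyd"]:
            parent_chain[h] = p

        def ref_pos(name: str) -> np.ndarray:
            if name == "__prevC__":
                return frame_prev_c
            return coords[(num, name)]

        used_torsions: dict[str, list[float]] = {}
        chi_of_parent: dict[str, float] = {}

        def frame_of(pname: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
            g = parent_chain[pname]
            gg = parent_chain.get(g, "__prevC__")
            return ref_pos(gg), ref_pos(g), ref_pos(pname)

        if rtype != "GLY":
            cb = place_atom(frame_prev_c, n, ca, _bond_length(rtype, "CA", "CB"),
                            110.5, phi[i] + 122.5)
            coords[(num, "CB")] = cb
            used_torsions["CA"] = [phi[i] + 122.5]

        for a, p in sc["heavy"]:
            if a == "CB":
                continue
            gg, g, pp = frame_of(p)
            length = _bond_length(rtype, p, a)
            if (rtype, a) in _SC_GEOM:
                angle, tspec = _SC_GEOM[(rtype, a)]
                if tspec == "chi":
                    tor = chi_policy()
                    chi_of_parent[p] = tor
                else:
                    tor = float(tspec)
            else:
                angle = 111.0
                if p not in chi_of_parent:
                    chi_of_parent[p] = chi_policy()
                    tor = chi_of_parent[p]
                else:  # additional branch off the same parent
                    tor = chi_of_parent[p] + 120.0 * len([t for t in used_torsions.get(p, [])])
            coords[(num, a)] = place_atom(gg, g, pp, length, angle, tor)
            used_torsions.setdefault(p, []).append(tor)

        for h, p in sc["hyd"]:
            gg, g, pp = frame_of(p)
            length = _bond_length(rtype, p, h)
            planar = ((rtype, p) in _SP2_PARENTS
                      or (topology.element_of(p) == "C"
                          and topology.carbon_class(rtype, p) != "aliphatic"))
            if planar:
                slots = [0.0, 180.0]
                angle = 120.0
            else:
                base = chi_of_parent.get(p)
                if base is None:
                    base = used_torsions[p][0] if used_torsions.get(p) else chi_policy()
                slots = [base, base + 120.0, base + 240.0]
                angle = 109.5
            used = used_torsions.get(p, [])
            free = [s for s in slots
                    if all(min(abs((s - u) % 360), 360 - (s - u) % 360) > 25 for u in used)]
            tor = free[0] if free else slots[0] + 60.0
            coords[(num, h)] = place_atom(gg, g, pp, length, angle, tor)
            used_torsions.setdefault(p, []).append(tor)

        prev_ca2, prev_ca, prev_c = n, ca, c

    return coords


def backbone_torsions(
    coords: dict[tuple[int, str], np.ndarray], sequence: ProteinSequence
) -> tuple[np.ndarray, np.ndarray]:
    """Extract (phi, psi) per residue from coordinates (chain-end values are
    assigned neutral extended defaults where undefined)."""
    numbers = list(sequence.numbers)
    nres = len(numbers)
    phi = np.full(nres, EXTENDED[0])
    psi = np.full(nres, EXTENDED[1])
    for i, num in enumerate(numbers):
        n, ca, c = coords[(num, "N")], coords[(num, "CA")], coords[(num, "C")]
        if i > 0:
            phi[i] = dihedral(coords[(num - 1, "C")], n, ca, c)
        if i < nres - 1:
            psi[i] = dihedral(n, ca, c, coords[(num + 1, "N")])
    return phi, psi


def mode_torsions(
    mode: str, nres: int, rng: np.random.Generator, noise_deg: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    if mode == "helix":
        phi0, psi0 = HELIX
        phi = np.full(nres, phi0)
        psi = np.full(nres, psi0)
    elif mode == "extended":
        phi0, psi0 = EXTENDED
        phi = np.full(nres, phi0)
        psi = np.full(nres, psi0)
    elif mode == "random":
        phi = rng.uniform(-180.0, 180.0, nres)
        psi = rng.uniform(-180.0, 180.0, nres)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if noise_deg > 0:
        phi = phi + rng.normal(0.0, noise_deg, nres)
        psi = psi + rng.normal(0.0, noise_deg, nres)
    return phi, psi


def make_chi_policy(mode: str, rng: np.random.Generator, noise_deg: float = 0.0) -> Callable[[], float]:
    """Rotatable side-chain torsion source: anti (180°) with optional noise,
    or uniformly random for random-coil structures."""
    if mode == "random":
        return lambda: float(rng.uniform(-180.0, 180.0))
    return lambda: 180.0 + float(rng.normal(0.0, noise_deg)) if noise_deg > 0 else 180.0


def place_hydrogens(
    coords: dict[tuple[int, str], np.ndarray], sequence: ProteinSequence
) -> dict[tuple[int, str], np.ndarray]:
    """Add missing protons to a heavy-atom coordinate set by ideal geometry.

    Existing proton positions are kept.  Used for predicted-model input,
    which typically ships without hydrogens.
    """
    out = dict(coords)
    numbers = list(sequence.numbers)
    for i, num in enumerate(numbers):
        rtype = sequence.residues[i]
        sc = topology.side_chain(rtype)
        parent_chain: dict[str, str] = {"CA": "N", "CB": "CA"}
        for a, p in sc["heavy"]:
            parent_chain[a] = p

        def pos(name: str, residue: int = num) -> np.ndarray | None:
            return out.get((residue, name))

        # backbone amide proton
        if rtype != "PRO" and i > 0 and (num, "HN") not in out:
            pc, pca = pos("C", num - 1), pos("CA", num - 1)
            n = pos("N")
            if pc is not None and pca is not None and n is not None:
                out[(num, "HN")] = place_atom(pca, pc, n, _N_H, _ANG_C_N_H, 180.0)
        # HA
        n, ca, c = pos("N"), pos("CA"), pos("C")
        if n is None or ca is None or c is None:
            continue
        phi_ref = pos("C", num - 1) if i > 0 else c + (n - ca)
        phi_val = dihedral(phi_ref, n, ca, c) if i > 0 else EXTENDED[0]
        if rtype == "GLY":
            for name, off in (("HA2", 122.5), ("HA3", -118.5)):
                if (num, name) not in out:
                    out[(num, name)] = place_atom(phi_ref, n, ca, 1.09, 109.5, phi_val + off)
        elif (num, "HA") not in out:
            out[(num, "HA")] = place_atom(phi_ref, n, ca, 1.09, 109.5, phi_val - 118.5)

        for h, p in sc["hyd"]:
            if (num, h) in out:
                continue
            g = parent_chain.get(p)
            gg = parent_chain.get(g, "CA") if g else None
            if g is None or pos(p) is None or pos(g) is None:
                continue
            ggpos = pos(gg) if gg else None
            if ggpos is None:
                ggpos = pos("N")
                if ggpos is None:
                    continue
            length = _bond_length(rtype, p, h)
            planar = ((rtype, p) in _SP2_PARENTS
                      or (topology.element_of(p) == "C"
                          and topology.carbon_class(rtype, p) != "aliphatic"))
            # torsions already occupied by placed neighbors of p
            used = []
            for other, op in list(sc["heavy"]) + list(sc["hyd"]):
                if op == p and pos(other) is not None and other != h:
                    used.append(dihedral(ggpos, pos(g), pos(p), pos(other)))
            if planar:
                slots = [0.0, 180.0]
                angle = 120.0
            else:
                base = used[0] if used else 60.0
                slots = [base, base + 120.0, base + 240.0]
                angle = 109.5
            free = [s for s in slots
                    if all(min(abs((s - u) % 360), 360 - (s - u) % 360) > 25 for u in used)]
            tor = free[0] if free else slots[0] + 60.0
            out[(num, h)] = place_atom(ggpos, pos(g), pos(p), length, angle, tor)
    return out


def clash_score(coords: dict[tuple[int, str], np.ndarray], cutoff: float = 1.6) -> int:
    """Number of non-bonded heavy-atom pairs (residue separation >= 2)
    closer than ``cutoff`` Å."""
    keys = [k for k in coords if topology.element_of(k[1]) != "H"]
    xyz = np.array([coords[k] for k in keys])
    resnum = np.array([k[0] for k in keys])
    from scipy.spatial import cKDTree

    tree = cKDTree(xyz)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return 0
    sep = np.abs(resnum[pairs[:, 0]] - resnum[pairs[:, 1]])
    return int(np.sum(sep >= 2))
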