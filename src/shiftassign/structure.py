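"""Structure bundles, distances, expected NOESY peaks and backbone RMSD.

A structure bundle is a set of conformers (NMR-style models, a predicted
five-model bundle, a decoy triplet, or internally generated random-coil
chains) indexed by the same (residue_number, atom_name) keys as the atom
set.  Expected NOESY cross peaks follow the all-conformer rule: a peak is
generated only when the proton-proton distance is below 6.0 Å in every
conformer, with an observation probability tiered by the maximal distance
d_max over the bundle:

    0.9  d_max < 4 Å      0.8  4 <= d_max < 4.5
    0.7  4.5 <= d_max < 5  0.6  5 <= d_max < 5.5   0.5  5.5 <= d_max < 6
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import geometry, topology
from .experiments import ExpectedPeak, SpectrumDefinition
from .sequence import Atom, AtomSet, ProteinSequence

logger = logging.getLogger(__name__)

NOESY_CUTOFF = 6.0  # Å, in all conformers

Coords = dict[tuple[int, str], np.ndarray]


@dataclass
class StructureBundle:
    """One or more conformers of the same molecule."""

    conformers: list[Coords]
    label: str = "experimental"  # experimental | predicted | random | decoy

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError("a structure bundle needs at least one conformer")
        keys = set(self.conformers[0])
        for i, conf in enumerate(self.conformers[1:], start=2):
            if set(conf) != keys:
                raise ValueError(f"conformer {i} has a different atom key set")

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def atom_keys(self) -> set[tuple[int, str]]:
        return set(self.conformers[0])

    def subset(self, conformer_indices: list[int], label: str | None = None) -> "StructureBundle":
        return StructureBundle(
            [self.conformers[i] for i in conformer_indices], label or self.label
        )


def max_distance(bundle: StructureBundle, a: Atom | tuple[int, str], b: Atom | tuple[int, str]) -> float:
    """Maximum over conformers of the Euclidean distance between two atoms."""
    ka = a.key if isinstance(a, Atom) else tuple(a)
    kb = b.key if isinstance(b, Atom) else tuple(b)
    dmax = 0.0
    for i, conf in enumerate(bundle.conformers):
        if ka not in conf:
            raise KeyError(f"atom {ka} missing from conformer {i + 1}")
        if kb not in conf:
            raise KeyError(f"atom {kb} missing from conformer {i + 1}")
        d = float(np.linalg.norm(conf[ka] - conf[kb]))
        if d > dmax:
            dmax = d
    return dmax


def noesy_probability(d_max: float) -> float | None:
    """Tiered observation probability for an expected NOESY peak, or None
    when d_max >= 6 Å (no peak)."""
    if d_max < 4.0:
        return 0.9
    if d_max < 4.5:
        return 0.8
    if d_max < 5.0:
        return 0.7
    if d_max < 5.5:
        return 0.6
    if d_max < NOESY_CUTOFF:
        return 0.5
    return None


def _origin(res_a: int, res_b: int) -> str:
    sep = abs(res_a - res_b)
    if sep <= 1:
        return "noesy-short"
    if sep <= 4:
        return "noesy-medium"
    return "noesy-long"


def expected_noesy(
    bundle: StructureBundle,
    atom_set: AtomSet,
    spectrum: SpectrumDefinition,
    include_symmetric: bool = True,
) -> list[ExpectedPeak]:
    """Generate expected NOESY peaks from a structure bundle.

    15N-edited: (H_x, N_i, HN_i) for every proton H_x within the cutoff of
    an amide proton HN_i.  13C-edited: (H_x, C_j, H_j) for every proton pair
    where H_j is carbon-bound.  Diagonal peaks (H_x == detected proton) are
    excluded; symmetric partners are distinct peaks and both emitted unless
    ``include_symmetric`` is false (then only one per unordered pair).
    """
    if spectrum.kind != "NOESY":
        raise ValueError(f"{spectrum.name} is not a NOESY experiment")
    if not bundle.conformers:
        raise ValueError("empty structure bundle")

    # hydroxyl/thiol/ammonium protons exchange too fast to give NOESY peaks
    protons = [
        p for p in atom_set.protons()
        if not topology.is_fast_exchanging(p.residue_type, p.atom_name)
    ]
    keys = bundle.atom_keys
    missing = [p for p in protons if p.key not in keys]
    if missing:
        logger.warning(
            "%d protons missing from the structure bundle; peaks involving "
            "them are skipped (first: %s)", len(missing), missing[0].key,
        )
    present = [p for p in protons if p.key not in {m.key for m in missing}]

    # stacked coordinates: (n_protons, n_conformers, 3)
    xyz = np.array([[conf[p.key] for conf in bundle.conformers] for p in present])
    peaks: list[ExpectedPeak] = []

    if spectrum.name == "N15NOESY":
        roots = [
            (idx, p, atom_set.get(p.residue_number, "N"))
            for idx, p in enumerate(present)
            if p.atom_name == "HN"
        ]
        for j, hn, n_atom in roots:
            if n_atom is None:
                continue
            d = np.linalg.norm(xyz - xyz[j][None, :, :], axis=2).max(axis=1)
            for x, px in enumerate(present):
                if x == j:
                    continue
                prob = noesy_probability(float(d[x]))
                if prob is None:
                    continue
                if not include_symmetric and px.atom_name == "HN" and x < j:
                    continue
                peaks.append(ExpectedPeak(
                    spectrum.name, (px, n_atom, hn), prob,
                    _origin(px.residue_number, hn.residue_number),
                ))
    elif spectrum.name == "C13NOESY":
        roots = []
        for idx, p in enumerate(present):
            heavy = atom_set.heavy_of(p)
            if heavy is not None and heavy.nucleus == "13C":
                roots.append((idx, p, heavy))
        root_idx = {j for j, _p, _c in roots}
        for j, hj, cj in roots:
            d = np.linalg.norm(xyz - xyz[j][None, :, :], axis=2).max(axis=1)
            for x, px in enumerate(present):
                if x == j:
                    continue
                prob = noesy_probability(float(d[x]))
                if prob is None:
                    continue
                if not include_symmetric and x in root_idx and x < j:
                    continue
                peaks.append(ExpectedPeak(
                    spectrum.name, (px, cj, hj), prob,
                    _origin(px.residue_number, hj.residue_number),
                ))
    else:
        raise ValueError(f"unknown NOESY spectrum {spectrum.name}")
    return peaks


def fallback_bundle(sequence: ProteinSequence, n_conformers: int = 20, seed: int = 0) -> StructureBundle:
    """Random-coil bundle used when no structure is supplied.

    Conformers have correct covalent geometry with independently random
    backbone and side-chain torsions, lightly relaxed to relieve steric
    clashes.  Applying the all-conformer NOESY rule to such a bundle leaves
    only short-range expected peaks, because long-range proton pairs are
    essentially never consistently close in every random conformer.
    """
    if n_conformers < 2:
        raise ValueError("a random fallback bundle needs at least 2 conformers")
    from .synthetic import build_structure  # local import; synthetic builds on this module

    bundle = build_structure(sequence, mode="random", n_conformers=n_conformers, seed=seed)
    return StructureBundle(bundle.conformers, label="random")


def backbone_rmsd(
    bundle_a: StructureBundle,
    bundle_b: StructureBundle,
    residue_range: tuple[int, int] | None = None,
    mean_over_pairs: bool = False,
) -> float:
    """Backbone (N, CA, C) RMSD after least-squares Kabsch superposition.

    By default the first conformers are compared; with ``mean_over_pairs``
    the mean over all conformer pairs is returned.
    """
    keys = sorted(
        k for k in bundle_a.atom_keys & bundle_b.atom_keys
        if k[1] in ("N", "CA", "C")
        and (residue_range is None or residue_range[0] <= k[0] <= residue_range[1])
    )
    if not keys:
        raise ValueError("no common backbone atoms to superimpose")
    if mean_over_pairs:
        vals = [
            _kabsch_rmsd(ca, cb, keys)
            for ca in bundle_a.conformers
            for cb in bundle_b.conformers
        ]
        return float(np.mean(vals))
    return _kabsch_rmsd(bundle_a.conformers[0], bundle_b.conformers[0], keys)


def _kabsch_rmsd(ca: Coords, cb: Coords, keys: list[tuple[int, str]]) -> float:
    p = np.array([ca[k] for k in keys])
    q = np.array([cb[k] for k in keys])
    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)
    h = p.T @ q
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = (rot @ p.T).T - q
    return float(np.sqrt((diff ** 2).sum() / len(keys)))


# ---------------------------------------------------------------------------
# PDB / mmCIF I/O (multi-model bundles) via gemmi

def read_bundle(
    path: str | Path,
    sequence: ProteinSequence | None = None,
    label: str = "experimental",
    build_protons: bool = True,
) -> StructureBundle:
    """Read a (multi-MODEL) PDB or mmCIF file into a StructureBundle.

    Atom names are normalized (H -> HN, C' -> C).  When the input lacks
    hydrogens (typical for predicted models) and a sequence is given,
    protons are built from heavy-atom geometry.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    conformers: list[Coords] = []
    for model in st:
        coords: Coords = {}
        chain = model[0]
        for res in chain:
            for at in res:
                name = topology.normalize_atom_name(at.name)
                coords[(res.seqid.num, name)] = np.array(
                    [at.pos.x, at.pos.y, at.pos.z]
                )
        conformers.append(coords)
    if sequence is not None and build_protons:
        conformers = [geometry.place_hydrogens(c, sequence) for c in conformers]
    # keep the intersection of atom keys so all conformers agree
    common = set(conformers[0])
    for c in conformers[1:]:
        common &= set(c)
    conformers = [{k: c[k] for k in common} for c in conformers]
    return StructureBundle(conformers, label=label)


def write_bundle(
    bundle: StructureBundle, sequence: ProteinSequence, path: str | Path
) -> None:
    """Write a bundle as a multi-MODEL PDB file."""
    import gemmi

    st = gemmi.Structure()
    st.name = "bundle"
    for m, conf in enumerate(bundle.conformers, start=1):
        model = gemmi.Model(m)
        chain = gemmi.Chain("A")
        for num, rtype in zip(sequence.numbers, sequence.residues):
            res = gemmi.Residue()
            res.name = rtype
            res.seqid = gemmi.SeqId(num, " ")
            for (rnum, aname), xyz in sorted(conf.items()):
                if rnum != num:
                    continue
                at = gemmi.Atom()
                at.name = "H" if aname == "HN" else aname
                at.element = gemmi.Element(topology.element_of(aname))
                at.pos = gemmi.Position(*map(float, xyz))
                res.add_atom(at)
            chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    doc_path = str(path)
    st.write_pdb(doc_path)
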