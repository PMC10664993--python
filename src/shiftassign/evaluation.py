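"""Scoring a consensus assignment against a reference shift list.

An assigned atom with a reference value is *correct* when |ω − ref| is
within the per-nucleus tolerance (0.03 ppm for 1H, 0.4 ppm for 13C/15N).
Backbone amide groups are scored jointly: an HN/N pair counts as correct
only when both shifts are within tolerance.  Metrics use these
denominators, reported as NA (None) when empty:

    correct_strong       correct strong / strong with reference
    correct_weak         correct weak / weak with reference
    correct_all          correct assigned / assigned with reference
    strong               strong with reference / assigned with reference
    completeness_strong  correct strong / atoms with reference
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from . import topology
from .consensus import ConsensusAssignment

DEFAULT_TOLERANCES = {"1H": 0.03, "13C": 0.4, "15N": 0.4}

Reference = Mapping[tuple[int, str], float]


@dataclass
class EvalReport:
    correct_strong: float | None
    completeness_strong: float | None
    strong: float | None
    correct_weak: float | None
    correct_all: float | None
    hn_accuracy: float | None
    n_reference: int
    n_assigned_with_reference: int
    per_atom_type: dict[str, tuple[int, int]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "correct_strong": self.correct_strong,
            "completeness_strong": self.completeness_strong,
            "strong": self.strong,
            "correct_weak": self.correct_weak,
            "correct_all": self.correct_all,
            "hn_accuracy": self.hn_accuracy,
            "n_reference": self.n_reference,
            "n_assigned_with_reference": self.n_assigned_with_reference,
        }


def _nucleus(atom_name: str) -> str:
    nuc = topology.nucleus_of(atom_name)
    if nuc is None:
        raise ValueError(f"{atom_name} has no NMR-active nucleus")
    return nuc


def _pct(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def _is_correct(
    key: tuple[int, str],
    value: float,
    reference: Reference,
    tolerances: Mapping[str, float],
    residue_type: str | None,
    stereo_lenient: bool,
) -> bool:
    nuc = _nucleus(key[1])
    if nuc not in tolerances:
        raise KeyError(f"no tolerance for nucleus {nuc}")
    tol = tolerances[nuc]
    ref = reference.get(key)
    if ref is not None and abs(value - ref) <= tol + 1e-12:
        return True
    if stereo_lenient and residue_type is not None:
        partner = topology.stereo_partner(residue_type, key[1])
        if partner is not None:
            ref2 = reference.get((key[0], partner))
            if ref2 is not None and abs(value - ref2) <= tol + 1e-12:
                return True
    return False


def compare(
    assignment: ConsensusAssignment,
    reference: Reference,
    tolerances: Mapping[str, float] | None = None,
    residue_types: Mapping[int, str] | None = None,
    stereo_lenient: bool = True,
) -> EvalReport:
    """Score consensus assignments against a reference shift list.

    ``residue_types`` (residue number -> three-letter code) enables the
    stereo-swap leniency: a stereospecific assignment swapped relative to
    the reference (HB2/HB3, Val or Leu methyl pairs, aromatic ring symmetry)
    counts as correct.
    """
    if not reference:
        raise ValueError("reference shift list is empty")
    tols = dict(DEFAULT_TOLERANCES, **(tolerances or {}))

    def rtype(resnum: int) -> str | None:
        return residue_types.get(resnum) if residue_types else None

    def has_ref(key: tuple[int, str]) -> bool:
        if key in reference:
            return True
        if stereo_lenient and rtype(key[0]) is not None:
            partner = topology.stereo_partner(rtype(key[0]), key[1])
            return partner is not None and (key[0], partner) in reference
        return False

    n_strong_ref = n_strong_ok = 0
    n_weak_ref = n_weak_ok = 0
    per_type: dict[str, list[int]] = {}
    for key, entry in assignment.atoms.items():
        if entry.klass == "unassigned" or entry.shift is None:
            continue
        if not has_ref(key):
            continue
        ok = _is_correct(key, entry.shift, reference, tols, rtype(key[0]), stereo_lenient)
        if entry.klass == "strong":
            n_strong_ref += 1
            n_strong_ok += ok
        else:
            n_weak_ref += 1
            n_weak_ok += ok
        stats = per_type.setdefault(key[1], [0, 0])
        stats[0] += ok
        stats[1] += 1

    n_assigned_ref = n_strong_ref + n_weak_ref
    n_ok = n_strong_ok + n_weak_ok
    return EvalReport(
        correct_strong=_pct(n_strong_ok, n_strong_ref),
        completeness_strong=_pct(n_strong_ok, len(reference)),
        strong=_pct(n_strong_ref, n_assigned_ref),
        correct_weak=_pct(n_weak_ok, n_weak_ref),
        correct_all=_pct(n_ok, n_assigned_ref),
        hn_accuracy=hn_accuracy(assignment, reference, tols),
        n_reference=len(reference),
        n_assigned_with_reference=n_assigned_ref,
        per_atom_type={k: (v[0], v[1]) for k, v in sorted(per_type.items())},
    )


def hn_accuracy(
    assignment: ConsensusAssignment,
    reference: Reference,
    tolerances: Mapping[str, float] | None = None,
) -> float | None:
    """Joint backbone amide accuracy: percent of (HN, N) pairs — both
    assigned and both with reference — where both deviations are within
    tolerance.  None (NA) when no such pair exists."""
    tols = dict(DEFAULT_TOLERANCES, **(tolerances or {}))
    n_pairs = n_ok = 0
    residues = {k[0] for k in assignment.atoms}
    for resnum in sorted(residues):
        h = assignment.atoms.get((resnum, "HN"))
        n = assignment.atoms.get((resnum, "N"))
        if h is None or n is None or h.shift is None or n.shift is None:
            continue
        if h.klass == "unassigned" or n.klass == "unassigned":
            continue
        ref_h = reference.get((resnum, "HN"))
        ref_n = reference.get((resnum, "N"))
        if ref_h is None or ref_n is None:
            continue
        n_pairs += 1
        if (abs(h.shift - ref_h) <= tols["1H"] + 1e-12
                and abs(n.shift - ref_n) <= tols["15N"] + 1e-12):
            n_ok += 1
    return _pct(n_ok, n_pairs)
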