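"""Gaussian chemical-shift priors.

Every assignable atom carries one normal prior N(mean, sd^2).  Priors come
either from bundled per-(residue, atom) statistics, or — for the six
backbone atom names CA, CB, C, HN, HA, N — from structure-based shift
predictions with predictor-specific default uncertainties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .sequence import Atom, AtomSet
from .shift_stats import default_statistics
from . import topology

#: Default SD (ppm) attached to predicted backbone shifts, per atom name
#: (the predictor's reported RMSD against archive assignments).
PREDICTED_SD = {"C": 0.85, "CA": 0.77, "CB": 0.86, "HN": 0.39, "HA": 0.20, "N": 1.98}

BACKBONE_PREDICTABLE = frozenset(PREDICTED_SD)


@dataclass(frozen=True)
class ShiftPrior:
    atom: Atom
    mean: float
    sd: float
    source: str  # "statistics" | "predicted"

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"prior sd must be positive, got {self.sd}")


@dataclass
class PriorSet:
    """One ShiftPrior per atom of an AtomSet (total coverage)."""

    priors: dict[tuple[int, str], ShiftPrior]

    def __getitem__(self, atom: Atom) -> ShiftPrior:
        return self.priors[atom.key]

    def get(self, atom: Atom) -> ShiftPrior | None:
        return self.priors.get(atom.key)

    def __len__(self) -> int:
        return len(self.priors)

    def __iter__(self):
        return iter(self.priors.values())


def statistical_priors(
    atom_set: AtomSet,
    stats_table: Mapping[tuple[str, str], tuple[float, float]] | None = None,
) -> PriorSet:
    """Build priors from a per-(residue_type, atom_name) mean/sd table.

    The bundled BMRB-like table is used when none is given.  A missing table
    entry for an atom present in the atom set is an error.
    """
    table = default_statistics() if stats_table is None else stats_table
    priors: dict[tuple[int, str], ShiftPrior] = {}
    for atom in atom_set.atoms:
        key = (atom.residue_type, atom.atom_name)
        if key not in table:
            raise KeyError(
                f"statistics table has no entry for atom {atom.atom_name} "
                f"of residue {atom.residue_type} {atom.residue_number}"
            )
        mean, sd = table[key]
        priors[atom.key] = ShiftPrior(atom, float(mean), float(sd), "statistics")
    return PriorSet(priors)


def predicted_priors(
    atom_set: AtomSet,
    predictions: Iterable[tuple[Atom, float]],
    sd_overrides: Mapping[str, float] | None = None,
    statistical: PriorSet | None = None,
) -> PriorSet:
    """Overlay structure-based backbone shift predictions on statistical priors.

    Predictions are accepted only for the backbone atom names CA, CB, C
    (carbonyl), HN, HA and N; each predicted atom receives
    N(predicted value, default sd for its atom name), every other atom keeps
    its statistical prior.
    """
    if statistical is None:
        statistical = statistical_priors(atom_set)
    sds = dict(PREDICTED_SD)
    if sd_overrides:
        sds.update({topology.normalize_atom_name(k): float(v) for k, v in sd_overrides.items()})
    priors = dict(statistical.priors)
    for atom, value in predictions:
        name = topology.normalize_atom_name(atom.atom_name)
        if name not in BACKBONE_PREDICTABLE:
            raise ValueError(
                f"shift prediction for non-backbone atom {name} "
                f"(residue {atom.residue_number}) rejected"
            )
        if atom.key not in priors:
            raise KeyError(f"predicted atom {atom.key} not in atom set")
        priors[atom.key] = ShiftPrior(priors[atom.key].atom, float(value), sds[name], "predicted")
    return PriorSet(priors)
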