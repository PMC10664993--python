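"""Multi-run consensus, strong/weak classification and accuracy estimation.

The assignment algorithm is run R times (20 by default) with identical
input but different random seeds.  For each atom, the per-run shift values
are pooled; the consensus shift is the center of the window of width 2·Δω
covering the most values (Δω = 0.03 ppm for 1H, 0.4 ppm for 13C/15N).  An
atom is *strong* when at least 80% of the values found for it fall inside
the window — support of exactly 0.8 qualifies.  Atoms found in fewer than
half the runs are demoted to weak regardless of support, guarding against
spuriously unanimous one-run assignments.

The percentage S of strong assignments predicts the overall assignment
accuracy A and the accuracy of the strong subset:

    A = 0.89·S + 7.88 %          A_strong = 0.45·S + 51.49 %
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .engine import MappingSolution

DEFAULT_DELTA = {"1H": 0.03, "13C": 0.4, "15N": 0.4}
STRONG_SUPPORT = 0.8


@dataclass
class AtomConsensus:
    shift: float | None
    support: float
    n_runs_found: int
    klass: str  # strong | weak | unassigned


@dataclass
class ConsensusAssignment:
    atoms: dict[tuple[int, str], AtomConsensus]
    n_runs: int

    def assigned_keys(self) -> list[tuple[int, str]]:
        return [k for k, v in self.atoms.items() if v.klass != "unassigned"]

    def strong_keys(self) -> list[tuple[int, str]]:
        return [k for k, v in self.atoms.items() if v.klass == "strong"]

    @property
    def percent_strong(self) -> float:
        """S: percent strong among assigned atoms."""
        assigned = self.assigned_keys()
        if not assigned:
            return 0.0
        return 100.0 * len(self.strong_keys()) / len(assigned)

    def shift_of(self, key: tuple[int, str]) -> float | None:
        entry = self.atoms.get(key)
        return None if entry is None else entry.shift


def _best_window(values: np.ndarray, delta: float) -> tuple[float, np.ndarray]:
    """Max-coverage window of width 2·delta; the optimal window can always be
    anchored at a member value, so candidate centers are the members
    themselves (exact O(n^2) search).  Ties pick the window with the
    smallest member median."""
    best_mask: np.ndarray | None = None
    best_count = -1
    best_median = np.inf
    for v in values:
        mask = np.abs(values - v) <= delta + 1e-12
        count = int(mask.sum())
        med = float(np.median(values[mask]))
        if count > best_count or (count == best_count and med < best_median - 1e-12):
            best_count = count
            best_mask = mask
            best_median = med
    center = float(np.mean(values[best_mask]))
    # re-center the window on the in-window mean and re-collect members
    mask = np.abs(values - center) <= delta + 1e-12
    if mask.sum() < best_count:
        mask = best_mask
    return center, mask


def consensus(
    solutions: Sequence[MappingSolution],
    tolerances: Mapping[str, float] | None = None,
    nucleus_of: Mapping[tuple[int, str], str] | None = None,
    strict_denominator: bool = False,
) -> ConsensusAssignment:
    """Combine R independent runs into per-atom consensus assignments.

    ``nucleus_of`` maps atom keys to nuclei for tolerance lookup; when
    omitted, names starting with H/C/N resolve to 1H/13C/15N.  With
    ``strict_denominator`` the support fraction is computed over all R runs
    instead of over the runs in which the atom was found.
    """
    runs = list(solutions)
    if len(runs) < 2:
        raise ValueError("consensus needs at least 2 runs")
    deltas = dict(DEFAULT_DELTA, **(tolerances or {}))

    pooled: dict[tuple[int, str], list[float]] = {}
    for sol in runs:
        for key, value in sol.shifts.items():
            pooled.setdefault(key, []).append(value)

    atoms: dict[tuple[int, str], AtomConsensus] = {}
    for key, values_list in pooled.items():
        values = np.array(values_list, dtype=float)
        if nucleus_of is not None and key in nucleus_of:
            nuc = nucleus_of[key]
        else:
            nuc = {"H": "1H", "C": "13C", "N": "15N"}[key[1][0]]
        delta = deltas[nuc]
        center, mask = _best_window(values, delta)
        denom = len(runs) if strict_denominator else len(values)
        support = float(mask.sum()) / denom
        klass = "strong" if support >= STRONG_SUPPORT else "weak"
        if len(values) < 0.5 * len(runs):
            klass = "weak"  # found too rarely to call reliable
        atoms[key] = AtomConsensus(
            shift=float(np.mean(values[mask])),
            support=support,
            n_runs_found=len(values),
            klass=klass,
        )
    return ConsensusAssignment(atoms, n_runs=len(runs))


@dataclass(frozen=True)
class AccuracyEstimate:
    S: float
    A: float
    A_strong: float


def estimate_accuracy(percent_strong: float) -> AccuracyEstimate:
    """Predict assignment accuracy from the percentage of strong assignments."""
    if not 0.0 <= percent_strong <= 100.0:
        raise ValueError("S must be a percentage in [0, 100]")
    return AccuracyEstimate(
        S=percent_strong,
        A=0.89 * percent_strong + 7.88,
        A_strong=0.45 * percent_strong + 51.49,
    )
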