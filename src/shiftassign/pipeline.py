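"""End-to-end orchestration: expected peaks -> filtering -> R runs ->
consensus -> accuracy estimate -> optional evaluation."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import io as sio
from .consensus import AccuracyEstimate, ConsensusAssignment, consensus, estimate_accuracy
from .engine import EngineParams, MappingSolution, run_single
from .evaluation import EvalReport, compare
from .experiments import (
    ExpectedPeak,
    ObservedPeakList,
    SpectrumDefinition,
    expected_peaks_throughbond,
    select_observed_peaks,
    spectrum_definition,
)
from .priors import PriorSet, predicted_priors, statistical_priors
from .sequence import Atom, AtomSet, ProteinSequence, enumerate_atoms, read_fasta, read_seq
from .structure import StructureBundle, expected_noesy, fallback_bundle, read_bundle

logger = logging.getLogger(__name__)

DEFAULT_RUNS = 20
FALLBACK_CONFORMERS = 20


@dataclass
class RunConfig:
    sequence: str  # path to FASTA or three-letter .seq file
    spectra: list[tuple[str, str]]  # (spectrum name, peak list path)
    structure: str | None = None
    predictions: str | None = None
    reference: str | None = None
    engine: EngineParams = field(default_factory=EngineParams)
    runs: int = DEFAULT_RUNS
    out_dir: str | None = None
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.runs < 2:
            raise ValueError("need at least 2 runs for consensus classification")
        for name, _path in self.spectra:
            spectrum_definition(name)  # raises on unknown names


@dataclass
class AssignmentResult:
    consensus: ConsensusAssignment
    estimate: AccuracyEstimate
    solutions: list[MappingSolution]
    expected: list[ExpectedPeak]
    report: EvalReport | None = None

    @property
    def percent_strong(self) -> float:
        return self.consensus.percent_strong


def build_expected_peaks(
    atom_set: AtomSet,
    spectra_names: Sequence[str],
    bundle: StructureBundle | None,
    base_seed: int = 0,
) -> tuple[list[ExpectedPeak], dict[str, SpectrumDefinition]]:
    """Expected peaks for all spectra; NOESY peaks come from the structure
    bundle, or from a random-coil fallback bundle when none is given."""
    expected: list[ExpectedPeak] = []
    sdefs: dict[str, SpectrumDefinition] = {}
    noesy_bundle = bundle
    for name in spectra_names:
        sdef = spectrum_definition(name)
        sdefs[sdef.name] = sdef
        if sdef.kind == "NOESY":
            if noesy_bundle is None:
                logger.info("no structure given: building a %d-conformer random bundle",
                            FALLBACK_CONFORMERS)
                noesy_bundle = fallback_bundle(
                    atom_set.sequence, FALLBACK_CONFORMERS, seed=base_seed
                )
            peaks = expected_noesy(noesy_bundle, atom_set, sdef)
        else:
            peaks = expected_peaks_throughbond(sdef, atom_set)
        if not peaks:
            logger.warning("spectrum %s yields no expected peaks; skipped", sdef.name)
            continue
        expected.extend(peaks)
    return expected, sdefs


def assign_problem(
    sequence: ProteinSequence,
    peak_lists: Mapping[str, ObservedPeakList],
    bundle: StructureBundle | None = None,
    predictions: Mapping[tuple[int, str], float] | None = None,
    reference: Mapping[tuple[int, str], float] | None = None,
    params: EngineParams | None = None,
    runs: int = DEFAULT_RUNS,
    base_seed: int = 0,
) -> AssignmentResult:
    """Run the full assignment workflow on in-memory inputs.

    Through-bond peak lists are reduced to the expected-count highest
    confidence peaks; NOESY lists are thresholded at confidence 0.1.  The
    reference (if any) is consulted only by the final evaluation.
    """
    params = params or EngineParams()
    atom_set = enumerate_atoms(sequence)
    priors = statistical_priors(atom_set)
    if predictions:
        pred_atoms = []
        for (resnum, name), value in predictions.items():
            atom = atom_set.get(resnum, name)
            if atom is not None:
                pred_atoms.append((atom, value))
        priors = predicted_priors(atom_set, pred_atoms, statistical=priors)

    expected, sdefs = build_expected_peaks(
        atom_set, list(peak_lists), bundle, base_seed
    )
    if not expected:
        raise ValueError("no spectrum produced any expected peaks")

    expected_count: dict[str, int] = {}
    for e in expected:
        expected_count[e.spectrum] = expected_count.get(e.spectrum, 0) + 1
    observed: dict[str, ObservedPeakList] = {}
    for name, plist in peak_lists.items():
        cname = spectrum_definition(name).name
        kind = sdefs[cname].kind if cname in sdefs else spectrum_definition(name).kind
        observed[cname] = select_observed_peaks(
            ObservedPeakList(cname, plist.peaks), expected_count.get(cname), kind
        )

    from .engine import _Problem, _ShiftICM, _run_on_problem

    prob = _Problem(expected, observed, priors, params, sdefs)
    icm = _ShiftICM(prob)
    solutions: list[MappingSolution] = []
    for r in range(runs):
        sol = _run_on_problem(prob, icm, base_seed + r)
        logger.info("run %d/%d: score %.2f, %d peaks mapped, %d atoms assigned",
                    r + 1, runs, sol.score, len(sol.mapping), len(sol.shifts))
        solutions.append(sol)

    nucleus_of = {a.key: a.nucleus for a in atom_set.atoms}
    cons = consensus(solutions, nucleus_of=nucleus_of)
    est = estimate_accuracy(cons.percent_strong)
    report = None
    if reference:
        residue_types = {n: sequence.residue_type(n) for n in sequence.numbers}
        report = compare(cons, reference, residue_types=residue_types)
    return AssignmentResult(cons, est, solutions, expected, report)


def assign(config: RunConfig) -> AssignmentResult:
    """File-based entry point mirroring :func:`assign_problem`."""
    seq_path = Path(config.sequence)
    sequence = (
        read_fasta(seq_path)
        if seq_path.suffix.lower() in (".fasta", ".fa")
        else read_seq(seq_path)
    )
    peak_lists = {
        name: sio.read_xeasy(path, spectrum_definition(name).name)
        for name, path in config.spectra
    }
    bundle = None
    if config.structure:
        bundle = read_bundle(config.structure, sequence, label="predicted")
    predictions = sio.read_predictions(config.predictions) if config.predictions else None
    reference = sio.read_prot(config.reference) if config.reference else None

    result = assign_problem(
        sequence,
        peak_lists,
        bundle=bundle,
        predictions=predictions,
        reference=reference,
        params=config.engine,
        runs=config.runs,
        base_seed=config.base_seed,
    )
    if config.out_dir:
        write_outputs(result, Path(config.out_dir))
    return result


def write_outputs(result: AssignmentResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    sio.write_consensus_table(result.consensus, out_dir / "shifts.prot")
    shifts = {k: v.shift for k, v in result.consensus.atoms.items() if v.shift is not None}
    sio.write_star(shifts, out_dir / "shifts.star")
    summary = {
        "percent_strong": result.percent_strong,
        "estimated_accuracy": result.estimate.A,
        "estimated_accuracy_strong": result.estimate.A_strong,
        "n_assigned": len(result.consensus.assigned_keys()),
        "n_strong": len(result.consensus.strong_keys()),
        "runs": result.consensus.n_runs,
        "run_scores": [s.score for s in result.solutions],
    }
    if result.report is not None:
        summary["evaluation"] = result.report.as_dict()
    (out_dir / "report.json").write_text(json.dumps(summary, indent=2))
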