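"""Synthetic benchmark experiments used for validation.

Each function builds ground-truthed synthetic problems with
:mod:`shiftassign.synthetic`, runs the full assignment workflow, and
returns the evaluation metrics.  Problem sizes default to a desk-scale
benchmark (12-30 residue proteins, a handful of consensus runs) chosen so
a complete validation pass stays within minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import EngineParams
from .evaluation import EvalReport
from .experiments import spectrum_definition
from .pipeline import assign_problem, build_expected_peaks
from .priors import statistical_priors
from .sequence import ProteinSequence, enumerate_atoms
from .structure import StructureBundle
from .synthetic import (
    Domain,
    NoiseModel,
    NOISELESS,
    build_structure,
    concatenate_domains,
    perturb_to_rmsd,
    sample_true_shifts,
    simulate_peak_lists,
)

#: spectrum sets mirroring the benchmark dataset definitions
DATASET_3 = ("N15HSQC", "C13HSQC", "N15NOESY", "C13NOESY", "CBCACONH",
             "HCCHTOCSY", "CCHTOCSY")
DATASET_17 = ("N15HSQC", "C13HSQC", "N15NOESY", "C13NOESY")
DATASET_25 = ("N15HSQC", "N15NOESY")
DATASET_LITE = ("N15HSQC", "N15NOESY", "CBCACONH")  # reduced benchmark set

_ALPHABET = "ACDEFGHIKLMNQRSTVWY"  # proline excluded from random benchmarks


def random_sequence(length: int, rng: np.random.Generator) -> ProteinSequence:
    letters = "".join(_ALPHABET[i] for i in rng.integers(0, len(_ALPHABET), length))
    return ProteinSequence.from_one_letter(letters)


@dataclass
class BenchmarkProblem:
    sequence: ProteinSequence
    bundle: StructureBundle | None
    truth: dict
    observed: dict
    expected: list


def make_benchmark_problem(
    seed: int,
    length: int = 12,
    spectra: tuple[str, ...] = DATASET_LITE,
    noise: NoiseModel | None = None,
    mode: str = "helix",
    bundle: StructureBundle | None = None,
) -> BenchmarkProblem:
    """One ground-truthed synthetic problem (sequence, structure, peak lists)."""
    rng = np.random.default_rng(seed)
    sequence = random_sequence(length, rng)
    atom_set = enumerate_atoms(sequence)
    priors = statistical_priors(atom_set)
    if bundle is None and any(
        spectrum_definition(s).kind == "NOESY" for s in spectra
    ):
        bundle = build_structure(sequence, mode=mode, n_conformers=3, seed=seed + 1)
    expected, sdefs = build_expected_peaks(atom_set, list(spectra), bundle, seed)
    truth = sample_true_shifts(priors, seed=seed + 2)
    observed, _map = simulate_peak_lists(expected, truth, noise or NOISELESS, sdefs)
    return BenchmarkProblem(sequence, bundle, truth, observed, expected)


def run_assignment(
    problem: BenchmarkProblem,
    runs: int = 5,
    base_seed: int = 0,
    use_structure: bool = True,
    params: EngineParams | None = None,
) -> EvalReport:
    result = assign_problem(
        problem.sequence,
        problem.observed,
        bundle=problem.bundle if use_structure else None,
        reference=problem.truth,
        params=params,
        runs=runs,
        base_seed=base_seed,
    )
    return result.report


def noisy_class_separation(
    seeds: range,
    length: int = 12,
    spectra: tuple[str, ...] = DATASET_LITE,
    runs: int = 5,
) -> tuple[float, float]:
    """Median correct_strong and correct_weak over noisy problems
    (jitter = tolerance/3, detection by peak probability, 10% artifacts)."""
    strong, weak = [], []
    for seed in seeds:
        noise = NoiseModel(seed=seed + 11)
        problem = make_benchmark_problem(seed, length, spectra, noise)
        report = run_assignment(problem, runs=runs, base_seed=seed)
        if report.correct_strong is not None:
            strong.append(report.correct_strong)
        if report.correct_weak is not None:
            weak.append(report.correct_weak)
    return float(np.median(strong)), float(np.median(weak))


def structure_benefit(
    seeds: range,
    length: int = 12,
    spectra: tuple[str, ...] = DATASET_17,
    runs: int = 4,
) -> tuple[float, float]:
    """Median correct_all with and without the structure bundle."""
    with_s, without_s = [], []
    for seed in seeds:
        noise = NoiseModel(seed=seed + 13)
        problem = make_benchmark_problem(seed, length, spectra, noise)
        r_with = run_assignment(problem, runs=runs, base_seed=seed)
        r_without = run_assignment(problem, runs=runs, base_seed=seed,
                                   use_structure=False)
        with_s.append(r_with.correct_all or 0.0)
        without_s.append(r_without.correct_all or 0.0)
    return float(np.median(with_s)), float(np.median(without_s))


def decoy_gradient(
    seeds: range,
    tiers: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0),
    length: int = 12,
    spectra: tuple[str, ...] = DATASET_25,
    runs: int = 3,
) -> tuple[dict[float, float], float]:
    """Median correct_all per decoy RMSD tier, plus the no-structure median.

    The reference structure generates the spectra; assignment uses decoy
    bundles perturbed to each tier (0 = the reference itself).
    """
    per_tier: dict[float, list[float]] = {t: [] for t in tiers}
    no_structure: list[float] = []
    for seed in seeds:
        noise = NoiseModel(seed=seed + 17)
        problem = make_benchmark_problem(seed, length, spectra, noise)
        for tier in tiers:
            if tier == 0.0:
                decoys = problem.bundle
            else:
                decoys = perturb_to_rmsd(problem.bundle, tier, seed=seed + int(tier),
                                         sequence=problem.sequence)
            decoy_problem = BenchmarkProblem(
                problem.sequence, decoys, problem.truth, problem.observed,
                problem.expected,
            )
            report = run_assignment(decoy_problem, runs=runs, base_seed=seed)
            per_tier[tier].append(report.correct_all or 0.0)
        r0 = run_assignment(problem, runs=runs, base_seed=seed, use_structure=False)
        no_structure.append(r0.correct_all or 0.0)
    medians = {t: float(np.median(v)) for t, v in per_tier.items()}
    return medians, float(np.median(no_structure))


def concatenation_benchmark(
    seed: int = 0,
    domain_length: int = 12,
    n_domains: int = 3,
    spectra: tuple[str, ...] = DATASET_25,
    runs: int = 3,
) -> dict[str, float]:
    """Accuracy of single-domain vs concatenated multi-domain systems, with
    and without structure; returns correct_all for each condition."""
    rng = np.random.default_rng(seed)
    domains = []
    for d in range(n_domains):
        p = make_benchmark_problem(seed + 31 * d, domain_length, spectra,
                                   NoiseModel(seed=seed + d))
        domains.append(Domain(p.sequence, p.bundle, p.truth, p.observed))
    single = BenchmarkProblem(domains[0].sequence, domains[0].bundle,
                              domains[0].truth, domains[0].peak_lists, [])
    combined = concatenate_domains(domains)
    multi = BenchmarkProblem(combined.sequence, combined.bundle, combined.truth,
                             combined.peak_lists, [])
    out: dict[str, float] = {}
    for label, problem in (("single", single), ("multi", multi)):
        for use_structure in (True, False):
            rep = run_assignment(problem, runs=runs, base_seed=seed,
                                 use_structure=use_structure)
            key = f"{label}_{'with' if use_structure else 'without'}_structure"
            out[key] = rep.correct_all or 0.0
    return out


def noiseless_round_trip(
    seed: int = 0,
    length: int = 30,
    spectra: tuple[str, ...] = DATASET_3,
    runs: int = 4,
) -> EvalReport:
    """The zero-noise, full-detection benchmark on one synthetic protein."""
    problem = make_benchmark_problem(seed, length, spectra, NOISELESS)
    return run_assignment(problem, runs=runs, base_seed=seed)
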