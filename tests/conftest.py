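"""Shared fixtures: small ground-truthed synthetic assignment problems."""

import numpy as np
import pytest

import shiftassign as sa
from shiftassign.synthetic import NOISELESS


def make_problem(seq_str, spectra, truth_seed=0, noise=None, mode="helix",
                 structure_seed=1, n_conformers=3):
    """Build a complete synthetic instance; returns a dict of its parts."""
    from shiftassign.pipeline import build_expected_peaks

    seq = sa.ProteinSequence.from_one_letter(seq_str)
    atom_set = sa.enumerate_atoms(seq)
    priors = sa.statistical_priors(atom_set)
    bundle = None
    if any(sa.spectrum_definition(s).kind == "NOESY" for s in spectra):
        bundle = sa.build_structure(seq, mode=mode, n_conformers=n_conformers,
                                    seed=structure_seed)
    expected, sdefs = build_expected_peaks(atom_set, list(spectra), bundle, 0)
    truth = sa.sample_true_shifts(priors, seed=truth_seed)
    observed, truth_map = sa.simulate_peak_lists(
        expected, truth, noise or NOISELESS, sdefs
    )
    return {
        "sequence": seq,
        "atom_set": atom_set,
        "priors": priors,
        "bundle": bundle,
        "expected": expected,
        "spectra": sdefs,
        "truth": truth,
        "observed": observed,
        "truth_map": truth_map,
    }


def correct_fraction(shifts, truth, residue_types=None, lenient=True):
    """Fraction of assigned atoms within tolerance of the truth (with stereo
    swap leniency by default)."""
    from shiftassign import topology

    n_ok = n = 0
    for key, value in shifts.items():
        ref = truth.get(key)
        if ref is None:
            continue
        tol = 0.03 if key[1].startswith("H") else 0.4
        n += 1
        if abs(value - ref) <= tol:
            n_ok += 1
            continue
        if lenient and residue_types:
            partner = topology.stereo_partner(residue_types[key[0]], key[1])
            ref2 = truth.get((key[0], partner)) if partner else None
            if ref2 is not None and abs(value - ref2) <= tol:
                n_ok += 1
    return n_ok / max(n, 1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
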