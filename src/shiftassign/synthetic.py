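"""Ground-truthed synthetic assignment problems.

Everything the assignment pipeline consumes can be generated here with a
known answer: full-atom structure bundles at chosen secondary structure,
true shifts drawn from the Gaussian priors, peak lists with positional
jitter, probabilistic peak loss and artifact peaks, decoy bundles at a
target backbone RMSD, and multi-domain concatenations joined by 10-glycine
linkers.

The noise defaults emulate well-behaved solution-NMR data: positional
jitter of one third of the matching tolerance per dimension, peak detection
following each expected peak's observation probability, and one artifact
per ten true peaks.  Confidence scores are Beta(8,2)-distributed for true
peaks and Beta(2,8) for artifacts, so most true peaks clear the NOESY 0.1
confidence threshold while artifacts exercise the filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import geometry
from .experiments import (
    ExpectedPeak,
    ObservedPeak,
    ObservedPeakList,
    SpectrumDefinition,
    spectrum_definition,
)
from .priors import PriorSet
from .sequence import ProteinSequence, enumerate_atoms
from .structure import StructureBundle, backbone_rmsd

TrueShifts = dict[tuple[int, str], float]


@dataclass
class NoiseModel:
    position_jitter_sd: float = 1.0 / 3.0  # fraction of the dimension tolerance
    detection: bool = True  # Bernoulli(p_e) peak loss
    artifact_rate: float = 0.1  # artifacts per true peak
    true_score_beta: tuple[float, float] = (8.0, 2.0)
    artifact_score_beta: tuple[float, float] = (2.0, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.position_jitter_sd < 0 or self.artifact_rate < 0:
            raise ValueError("jitter and artifact_rate must be non-negative")


NOISELESS = NoiseModel(position_jitter_sd=0.0, detection=False, artifact_rate=0.0)


def build_structure(
    sequence: ProteinSequence,
    mode: str = "helix",
    n_conformers: int = 5,
    seed: int = 0,
    backbone_noise_deg: float = 4.0,
    chi_noise_deg: float = 12.0,
    max_clash_retries: int = 8,
) -> StructureBundle:
    """Build an ideal-geometry full-atom bundle.

    ``mode`` sets the backbone: 'helix' (-57, -47), 'extended' (-120, 120)
    or 'random' (uniform torsions, re-sampled a few times to relieve steric
    clashes).  Conformers differ by small torsion noise.
    """
    rng = np.random.default_rng(seed)
    conformers = []
    for _ in range(n_conformers):
        best = None
        best_clash = None
        for _attempt in range(max_clash_retries if mode == "random" else 1):
            phi, psi = geometry.mode_torsions(mode, len(sequence), rng, backbone_noise_deg)
            chi = geometry.make_chi_policy(mode, rng, chi_noise_deg)
            coords = geometry.build_conformer(sequence, phi, psi, chi)
            clashes = geometry.clash_score(coords)
            if best_clash is None or clashes < best_clash:
                best, best_clash = coords, clashes
            if clashes == 0:
                break
        conformers.append(best)
    label = "random" if mode == "random" else "predicted"
    return StructureBundle(conformers, label=label)


def perturb_to_rmsd(
    bundle: StructureBundle,
    target_rmsd: float,
    seed: int = 0,
    sequence: ProteinSequence | None = None,
    tolerance: float = 0.1,
    n_decoys: int = 3,
) -> StructureBundle:
    """Decoy bundle at a controlled backbone RMSD from the input.

    Backbone torsions of the first conformer are perturbed by Gaussian noise
    whose magnitude is found by bisection until the measured backbone RMSD
    lies within target ± 10%.  The result is a triplet (by default) of
    decoys with pairwise backbone RMSD below 1 Å.
    """
    if target_rmsd < 0:
        raise ValueError("target RMSD must be non-negative")
    if sequence is None:
        raise ValueError("sequence is required to rebuild decoy coordinates")
    if target_rmsd == 0:
        return StructureBundle([dict(c) for c in bundle.conformers[:n_decoys]]
                               or [dict(bundle.conformers[0])], label="decoy")
    rng = np.random.default_rng(seed)
    ref = bundle.conformers[0]
    phi0, psi0 = geometry.backbone_torsions(ref, sequence)
    nres = len(sequence)
    noise_phi = rng.normal(0.0, 1.0, nres)
    noise_psi = rng.normal(0.0, 1.0, nres)
    chi_seed = int(rng.integers(0, 2 ** 31))

    def build(scale: float, extra_seed: int = 0) -> dict:
        r = np.random.default_rng(chi_seed + extra_seed)
        jitter = 0.6  # deg, keeps decoy triplet spread well under 1 Å pairwise
        phi = phi0 + scale * noise_phi + r.normal(0, jitter, nres)
        psi = psi0 + scale * noise_psi + r.normal(0, jitter, nres)
        chi = geometry.make_chi_policy("fixed", r, 6.0)
        return geometry.build_conformer(sequence, phi, psi, chi)

    def measured(scale: float) -> float:
        cand = StructureBundle([build(scale)], label="decoy")
        return backbone_rmsd(bundle, cand)

    lo, hi = 0.0, 2.0
    while measured(hi) < target_rmsd and hi < 360.0:
        hi *= 2.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        r = measured(mid)
        if abs(r - target_rmsd) <= tolerance * target_rmsd:
            lo = hi = mid
            break
        if r < target_rmsd:
            lo = mid
        else:
            hi = mid
    scale = 0.5 * (lo + hi)
    conformers = [build(scale, extra_seed=k) for k in range(n_decoys)]
    return StructureBundle(conformers, label="decoy")


def sample_true_shifts(priors: PriorSet, seed: int = 0) -> TrueShifts:
    """Draw one true shift per atom from its Gaussian prior, truncated at
    ±3 SD (matching the engine's hard search range).

    Magnetically equivalent atoms (methyl protons, Phe/Tyr ring-flip pairs,
    Lys NZ protons) share a single value, as they do in real shift lists.
    """
    from . import topology

    rng = np.random.default_rng(seed)
    shifts: TrueShifts = {}
    group_of: dict[tuple[int, str], tuple[int, str]] = {}
    for prior in priors:
        resnum, rtype = prior.atom.residue_number, prior.atom.residue_type
        for grp in topology.equivalence_groups(rtype):
            if prior.atom.atom_name in grp:
                group_of[prior.atom.key] = (resnum, grp[0])
    for prior in sorted(priors, key=lambda p: p.atom.key):
        key = prior.atom.key
        leader = group_of.get(key, key)
        if leader != key and leader in shifts:
            shifts[key] = shifts[leader]
            continue
        while True:
            z = rng.normal()
            if abs(z) <= 3.0:
                break
        shifts[key] = prior.mean + z * prior.sd
    return shifts


def simulate_peak_lists(
    expected: Sequence[ExpectedPeak],
    truth: TrueShifts,
    noise: NoiseModel | None = None,
    spectra: Mapping[str, SpectrumDefinition] | None = None,
) -> tuple[dict[str, ObservedPeakList], dict[str, list[int | None]]]:
    """Generate observed peak lists from expected peaks and true shifts.

    Returns (peak lists per spectrum, ground-truth map per spectrum).  The
    ground-truth map lists, per observed peak (in list order), the index of
    the expected peak it came from, or None for artifacts.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    spectra = dict(spectra or {})

    by_spectrum: dict[str, list[tuple[int, ExpectedPeak]]] = {}
    for i, e in enumerate(expected):
        by_spectrum.setdefault(e.spectrum, []).append((i, e))

    lists: dict[str, ObservedPeakList] = {}
    truth_map: dict[str, list[int | None]] = {}
    for sname, items in by_spectrum.items():
        sdef = spectra.get(sname) or spectrum_definition(sname)
        tols = np.array(sdef.tolerances)
        peaks: list[ObservedPeak] = []
        origin: list[int | None] = []
        next_id = 1
        true_positions = []
        for i, e in items:
            pos = np.array([truth[a.key] for a in e.atoms])
            if noise.detection and rng.random() >= e.probability:
                continue
            jitter = rng.normal(0.0, 1.0, len(pos)) * tols * noise.position_jitter_sd
            conf = float(rng.beta(*noise.true_score_beta))
            inten = float(rng.lognormal(0.0, 0.5))
            peaks.append(ObservedPeak(next_id, tuple(pos + jitter), conf, inten))
            origin.append(i)
            true_positions.append(pos)
            next_id += 1
        n_artifacts = rng.poisson(len(items) * noise.artifact_rate) if noise.artifact_rate else 0
        if n_artifacts and true_positions:
            box = np.array(true_positions)
            lo, hi = box.min(axis=0), box.max(axis=0)
            span = np.maximum(hi - lo, 10 * tols)
            for _ in range(n_artifacts):
                pos = lo + rng.random(len(tols)) * span
                conf = float(rng.beta(*noise.artifact_score_beta))
                inten = float(rng.lognormal(-1.0, 0.5))
                peaks.append(ObservedPeak(next_id, tuple(pos), conf, inten))
                origin.append(None)
                next_id += 1
        lists[sname] = ObservedPeakList(sname, peaks)
        truth_map[sname] = origin
    return lists, truth_map


# ---------------------------------------------------------------------------
# multi-domain concatenation

LINKER_LENGTH = 10  # glycines between consecutive domains


@dataclass
class Domain:
    sequence: ProteinSequence
    bundle: StructureBundle | None = None
    truth: TrueShifts | None = None
    peak_lists: dict[str, ObservedPeakList] = field(default_factory=dict)


@dataclass
class ConcatenatedProblem:
    sequence: ProteinSequence
    bundle: StructureBundle | None
    truth: TrueShifts
    peak_lists: dict[str, ObservedPeakList]
    domain_ranges: list[tuple[int, int]]


def concatenate_domains(
    domains: Sequence[Domain],
    max_residues: int = 500,
    domain_spacing: float = 4.0,
) -> ConcatenatedProblem:
    """Join >= 2 domains with 10-glycine linkers into one large system.

    Residues are renumbered contiguously; peak lists are merged with re-keyed
    ids; linker residues carry priors but no observed peaks; domain bundles
    are kept rigid and translated along the linker direction, with extended
    linker geometry built in between (no global packing optimization).
    """
    if len(domains) < 2:
        raise ValueError("need at least two domains to concatenate")
    total = sum(len(d.sequence) for d in domains) + LINKER_LENGTH * (len(domains) - 1)
    if total > max_residues:
        raise ValueError(f"combined size {total} exceeds the limit of {max_residues}")

    residues: list[str] = []
    offsets: list[int] = []  # old-number -> new-number shift per domain
    ranges: list[tuple[int, int]] = []
    for i, dom in enumerate(domains):
        start_new = len(residues) + 1
        offsets.append(start_new - dom.sequence.first_residue_number)
        residues.extend(dom.sequence.residues)
        ranges.append((start_new, len(residues)))
        if i < len(domains) - 1:
            residues.extend(["GLY"] * LINKER_LENGTH)
    combined_seq = ProteinSequence(tuple(residues), 1)

    truth: TrueShifts = {}
    for dom, off in zip(domains, offsets):
        for (num, name), val in (dom.truth or {}).items():
            key = (num + off, name)
            if key in truth:
                raise RuntimeError(f"atom key collision after renumbering: {key}")
            truth[key] = val

    peak_lists: dict[str, ObservedPeakList] = {}
    for dom in domains:
        for sname, plist in dom.peak_lists.items():
            merged = peak_lists.setdefault(sname, ObservedPeakList(sname, []))
            base = len(merged.peaks)
            for p in plist.peaks:
                merged.peaks.append(replace(p, id=base + len(merged.peaks) + 1))

    bundle = None
    if all(d.bundle is not None for d in domains):
        n_conf = min(len(d.bundle) for d in domains)
        rng = np.random.default_rng(0)
        conformers = []
        for m in range(n_conf):
            coords: dict[tuple[int, str], np.ndarray] = {}
            x_offset = 0.0
            for i, (dom, off) in enumerate(zip(domains, offsets)):
                conf = dom.bundle.conformers[m]
                xyz = np.array(list(conf.values()))
                lo, hi = xyz[:, 0].min(), xyz[:, 0].max()
                shift_vec = np.array([x_offset - lo, 0.0, 0.0])
                for (num, name), v in conf.items():
                    coords[(num + off, name)] = v + shift_vec
                x_offset += (hi - lo) + domain_spacing + 3.5 * LINKER_LENGTH
            # linker geometry: extended glycine stretches between domains
            linker_coords = _build_linkers(combined_seq, ranges, coords)
            coords.update(linker_coords)
            conformers.append(coords)
        # all conformers must share one key set
        common = set(conformers[0])
        for c in conformers[1:]:
            common &= set(c)
        bundle = StructureBundle([{k: c[k] for k in common} for c in conformers],
                                 label="predicted")
    return ConcatenatedProblem(combined_seq, bundle, truth, peak_lists, ranges)


def _build_linkers(sequence, ranges, coords):
    """Place linker glycines between domains on a raised two-segment path
    (over a waypoint above the gap) so the linker cannot cut back through
    either domain."""
    out: dict[tuple[int, str], np.ndarray] = {}
    all_xyz = np.array(list(coords.values()))
    z_top = all_xyz[:, 2].max() + 8.0
    for i in range(len(ranges) - 1):
        start = ranges[i][1] + 1
        end = ranges[i + 1][0] - 1
        a = coords[(ranges[i][1], "C")]
        b = coords[(ranges[i + 1][0], "N")]
        mid = 0.5 * (a + b)
        way = np.array([mid[0], mid[1], z_top])
        seg1, seg2 = way - a, b - way
        l1, l2 = np.linalg.norm(seg1), np.linalg.norm(seg2)
        total = l1 + l2

        def path(t: float) -> np.ndarray:
            d = t * total
            if d <= l1:
                return a + seg1 * (d / max(l1, 1e-9))
            return way + seg2 * ((d - l1) / max(l2, 1e-9))

        n_link = end - start + 1
        for j, num in enumerate(range(start, end + 1)):
            t0 = (j + 0.7) / (n_link + 1)
            base = path(t0)
            nxt = path(min(t0 + 0.3 / (n_link + 1), 1.0))
            step = nxt - base
            step = step / (np.linalg.norm(step) + 1e-9)
            perp = np.cross(step, [0.0, 0.0, 1.0])
            if np.linalg.norm(perp) < 1e-6:
                perp = np.cross(step, [0.0, 1.0, 0.0])
            perp = perp / np.linalg.norm(perp)
            out[(num, "N")] = base
            out[(num, "CA")] = base + step * 1.3 + perp * 0.5
            out[(num, "C")] = base + step * 2.4
            out[(num, "O")] = base + step * 2.4 + perp * 1.2
            out[(num, "HN")] = base - perp * 0.9
            out[(num, "HA2")] = base + step * 1.3 + perp * 1.5
            out[(num, "HA3")] = base + step * 1.3 - perp * 0.9
    return out
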