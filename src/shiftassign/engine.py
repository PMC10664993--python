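"""Evolutionary + local optimization mapping expected peaks onto observed peaks.

The optimization variable is one choice per expected peak: an observed peak
from its candidate list, or nothing.  Candidates are the observed peaks of
the same spectrum lying within (dimension tolerance + k·sd of the dimension
atom's prior) in every dimension — the priors thereby shrink the
combinatorial search space.  Chemical shifts are not free variables: the
shift of an atom is the tolerance-weighted mean of the positions of all
mapped peak dimensions attributed to it.

The objective rewards mapped peaks by their observation probability times a
Gaussian position kernel, penalizes unmapped peaks by λ·p, and adds a prior
kernel per assigned atom (weight β).  A mapped peak whose position deviates
from the implied shift by more than the tolerance in any dimension is
infeasible; a deterministic repair unmaps such peaks until a fixpoint is
reached, so every returned solution is feasible.

Optimization is layered from global to local: (1) spin-system *root
matching* — bonded atom pairs observed in 2D correlation spectra (amide
HN/N, aliphatic H/C) are assigned to observed 2D positions by a Hungarian
assignment over prior-typing costs, refined by a quadratic-assignment 2-opt
using amide-amide NOESY evidence, and iterated with soft pinning of the
previous round's side-chain shifts; (2) *shift-space coordinate ascent* —
atoms (or bonded pairs, jointly) are re-optimized over the finite candidate
values their dimensions offer; (3) Sinkhorn-style *soft-assign annealing*
restarts supplying diverse seeds; (4) an *evolutionary* population layer
with tournament selection, residue-block crossover and mutation, work
capped on very large problems.  Many-to-one mapping is allowed throughout:
peak overlap means two expected peaks may legitimately share one observed
peak.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .experiments import ExpectedPeak, ObservedPeakList, SpectrumDefinition, spectrum_definition
from .priors import PriorSet

_EPS = 1e-9


@dataclass
class EngineParams:
    population_size: int = 50
    generations: int = 200
    mutation_rate: float = 0.05
    tournament_size: int = 3
    unmapped_penalty: float = 0.2  # λ
    prior_weight: float = 0.5  # β
    prior_range_k: float = 3.0  # hard search-range half-width in prior SDs
    seed: int = 0
    patience: int = 30  # generations without improvement before stopping
    local_opt_passes: int = 3
    anneal_restarts: int = 6
    anneal_widths: int = 24
    max_candidates: int = 0  # optional per-peak cap (0 = unlimited)
    icm_sweeps: int = 6  # atom-wise coordinate-ascent sweeps

    def __post_init__(self) -> None:
        if min(self.population_size, self.generations, self.tournament_size) < 1:
            raise ValueError("population, generations and tournament must be positive")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be a probability")
        if self.unmapped_penalty < 0 or self.prior_weight < 0:
            raise ValueError("λ and β must be non-negative")


@dataclass
class MappingSolution:
    """A feasible peak mapping with implied shifts and its score."""

    mapping: dict[int, int]  # expected-peak index -> observed peak id
    shifts: dict[tuple[int, str], float]
    score: float


class _Problem:
    """Precomputed sparse candidate arrays for fast score evaluation.

    Layout: candidates of all peaks are concatenated; candidate t of peak e
    sits at flat index cand_start[e] + t and stores its per-dimension
    positions in cand_pos[flat, :ndim].  Per-dimension arrays (dim_*) are
    flattened over (peak, dimension).
    """

    def __init__(
        self,
        expected: Sequence[ExpectedPeak],
        observed: Mapping[str, ObservedPeakList],
        priors: PriorSet,
        params: EngineParams,
        spectra: Mapping[str, SpectrumDefinition] | None = None,
    ) -> None:
        self.expected = list(expected)
        self.params = params
        self.observed = observed
        self.priors = priors
        spectra = dict(spectra or {})
        self.spectra = spectra

        def sdef(name: str) -> SpectrumDefinition:
            if name not in spectra:
                spectra[name] = spectrum_definition(name)
            return spectra[name]

        # atom table
        atom_keys: list[tuple[int, str]] = []
        self.atom_index: dict[tuple[int, str], int] = {}
        mu, sigma = [], []
        for e in self.expected:
            for a in e.atoms:
                if a.key not in self.atom_index:
                    prior = priors.get(a)
                    if prior is None:
                        raise KeyError(f"expected peak references atom {a.key} without a prior")
                    self.atom_index[a.key] = len(atom_keys)
                    atom_keys.append(a.key)
                    mu.append(prior.mean)
                    sigma.append(prior.sd)
        self.atom_keys = atom_keys
        self.mu = np.array(mu, dtype=float)
        self.sigma = np.array(sigma, dtype=float)
        self.n_atoms = len(atom_keys)
        self.n_exp = len(self.expected)

        # flattened (peak, dim) table
        dim_peak, dim_atom, dim_tol, dim_pos = [], [], [], []
        self.peak_dims: list[list[int]] = []
        for ei, e in enumerate(self.expected):
            sd = sdef(e.spectrum)
            dims = []
            for d, a in enumerate(e.atoms):
                dims.append(len(dim_peak))
                dim_peak.append(ei)
                dim_atom.append(self.atom_index[a.key])
                dim_tol.append(sd.tolerances[d])
                dim_pos.append(d)
            self.peak_dims.append(dims)
        self.dim_peak = np.array(dim_peak, dtype=np.int64)
        self.dim_atom = np.array(dim_atom, dtype=np.int64)
        self.dim_tol = np.array(dim_tol, dtype=float)
        self.dim_pos = np.array(dim_pos, dtype=np.int64)
        self.dim_w = 1.0 / self.dim_tol ** 2
        self.n_dims = len(dim_peak)
        self.p_e = np.array([e.probability for e in self.expected], dtype=float)
        self.ndim_of_peak = np.bincount(self.dim_peak, minlength=self.n_exp)
        self.max_ndim = int(self.ndim_of_peak.max()) if self.n_exp else 0

        # candidates (sparse): joint window tol + k·sd around the prior mean
        k = params.prior_range_k
        cap = params.max_candidates
        obs_arrays: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
        okey_base = 0
        for sname, plist in observed.items():
            if plist.peaks:
                obs_arrays[sname] = (
                    np.array([p.id for p in plist.peaks], dtype=np.int64),
                    np.array([p.positions for p in plist.peaks], dtype=float),
                    okey_base,
                )
                okey_base += len(plist.peaks)
        self.n_obs_keys = okey_base
        self.cand_ids: list[np.ndarray] = []
        pos_blocks: list[np.ndarray] = []
        okey_blocks: list[np.ndarray] = []
        empty_ids = np.zeros(0, dtype=np.int64)
        for ei, e in enumerate(self.expected):
            if e.spectrum not in obs_arrays:
                self.cand_ids.append(empty_ids)
                continue
            oids, opos, base = obs_arrays[e.spectrum]
            tols = self.dim_tol[self.peak_dims[ei]]
            mus = self.mu[self.dim_atom[self.peak_dims[ei]]]
            sds = self.sigma[self.dim_atom[self.peak_dims[ei]]]
            win = tols + k * sds + _EPS
            zrel = np.abs(opos - mus[None, :]) / win[None, :]
            zmax = zrel.max(axis=1)
            inside = np.nonzero(zmax <= 1.0)[0]
            if cap and len(inside) > cap:
                inside = np.sort(inside[np.argsort(zmax[inside], kind="stable")[:cap]])
            self.cand_ids.append(oids[inside])
            if len(inside):
                block = np.zeros((len(inside), max(self.max_ndim, 1)))
                block[:, : opos.shape[1]] = opos[inside]
                pos_blocks.append(block)
                okey_blocks.append(base + inside)
        self.n_cand = np.array([len(c) for c in self.cand_ids], dtype=np.int64)
        self.cand_start = np.concatenate([[0], np.cumsum(self.n_cand)])[:-1]
        self.n_cand_total = int(self.n_cand.sum())
        self.cand_pos = (
            np.vstack(pos_blocks) if pos_blocks else np.zeros((0, max(self.max_ndim, 1)))
        )
        self.cand_okey = (
            np.concatenate(okey_blocks).astype(np.int64)
            if okey_blocks
            else np.zeros(0, dtype=np.int64)
        )
        self.cand_peak = np.repeat(np.arange(self.n_exp), self.n_cand)
        self.max_cand = int(self.n_cand.max()) if self.n_exp else 0

        # flattened (candidate, dim) table for annealing sweeps; dims of a
        # peak occupy a contiguous index range, so ranges can be broadcast
        dim_start = np.concatenate([[0], np.cumsum(self.ndim_of_peak)])[:-1]
        reps = self.ndim_of_peak[self.cand_peak]
        self.cd_cand = np.repeat(np.arange(self.n_cand_total), reps)
        starts = np.concatenate([[0], np.cumsum(reps)])[:-1]
        offs = np.arange(int(reps.sum())) - np.repeat(starts, reps)
        self.cd_dim = np.repeat(dim_start[self.cand_peak], reps) + offs
        self.cd_atom = self.dim_atom[self.cd_dim]
        self.cd_x = self.cand_pos[self.cd_cand, self.dim_pos[self.cd_dim]] if len(self.cd_dim) else np.zeros(0)

        # residue blocks (for crossover / mutation locality)
        res_of_peak = np.array(
            [min(a.residue_number for a in e.atoms) for e in self.expected], dtype=np.int64
        ) if self.n_exp else np.zeros(0, dtype=np.int64)
        self.block_res = res_of_peak
        self.residues = np.unique(res_of_peak)
        self.peaks_of_residue = {
            int(r): np.nonzero(res_of_peak == r)[0] for r in self.residues
        }

        self.is_throughbond = np.array(
            [spectra[e.spectrum].kind == "through-bond" for e in self.expected],
            dtype=bool,
        ) if self.n_exp else np.zeros(0, dtype=bool)

        self.empty_score = float(-params.unmapped_penalty * self.p_e.sum())

    # -- genome -> per-dimension positions ----------------------------------
    def _positions(self, genomes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(x, mask) of shape (P, J): candidate positions per dimension and
        the mapped mask (x is undefined where unmapped)."""
        if self.n_cand_total == 0:
            shape = (genomes.shape[0], self.n_dims)
            return np.zeros(shape), np.zeros(shape, dtype=bool)
        g = np.clip(genomes, 0, None)
        flat = self.cand_start[self.dim_peak][None, :] + g[:, self.dim_peak]
        flat = np.minimum(flat, self.n_cand_total - 1)
        x = self.cand_pos[flat, self.dim_pos[None, :]]
        mask = (genomes >= 0)[:, self.dim_peak]
        return x, mask

    # -- vectorized soft evaluation (violating peaks count as unmapped) ------
    def soft_scores(self, genomes: np.ndarray) -> np.ndarray:
        P = genomes.shape[0]
        lam, beta = self.params.unmapped_penalty, self.params.prior_weight
        if self.n_exp == 0:
            return np.zeros(P)
        x, dmask = self._positions(genomes)
        w = np.where(dmask, self.dim_w[None, :], 0.0)
        flat_atom = (np.arange(P)[:, None] * self.n_atoms + self.dim_atom[None, :]).ravel()
        num = np.bincount(flat_atom, weights=(w * x).ravel(), minlength=P * self.n_atoms)
        den = np.bincount(flat_atom, weights=w.ravel(), minlength=P * self.n_atoms)
        num = num.reshape(P, self.n_atoms)
        den = den.reshape(P, self.n_atoms)
        assigned = den > 0
        omega = np.where(assigned, num / np.where(assigned, den, 1.0), 0.0)

        dev = np.abs(x - omega[np.arange(P)[:, None], self.dim_atom[None, :]])
        tol = self.dim_tol[None, :]
        atom_bad = assigned & (np.abs(omega - self.mu[None, :]) >
                               self.params.prior_range_k * self.sigma[None, :] + _EPS)
        viol_dim = dmask & ((dev > tol + _EPS) |
                            atom_bad[np.arange(P)[:, None], self.dim_atom[None, :]])
        expo = np.where(dmask, -dev ** 2 / (2.0 * (tol / 2.0) ** 2), 0.0)

        flat_peak = (np.arange(P)[:, None] * self.n_exp + self.dim_peak[None, :]).ravel()
        peak_expo = np.bincount(flat_peak, weights=expo.ravel(), minlength=P * self.n_exp)
        peak_viol = np.bincount(flat_peak, weights=viol_dim.ravel(), minlength=P * self.n_exp)
        peak_expo = peak_expo.reshape(P, self.n_exp)
        peak_viol = peak_viol.reshape(P, self.n_exp) > 0

        mapped = genomes >= 0
        good = mapped & ~peak_viol
        peak_term = np.where(good, self.p_e[None, :] * np.exp(peak_expo),
                             -lam * self.p_e[None, :])
        prior_term = np.where(assigned & ~atom_bad,
                              np.exp(-(omega - self.mu[None, :]) ** 2 /
                                     (2.0 * self.sigma[None, :] ** 2)), 0.0)
        return peak_term.sum(axis=1) + beta * prior_term.sum(axis=1)

    # -- canonical evaluation with repair ------------------------------------
    def derive_shifts(self, genome: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x, dmask = self._positions(genome[None, :])
        x, dmask = x[0], dmask[0]
        w = np.where(dmask, self.dim_w, 0.0)
        num = np.bincount(self.dim_atom, weights=w * x, minlength=self.n_atoms)
        den = np.bincount(self.dim_atom, weights=w, minlength=self.n_atoms)
        assigned = den > 0
        omega = np.where(assigned, num / np.where(assigned, den, 1.0), np.nan)
        return omega, assigned

    def violations(self, genome: np.ndarray) -> np.ndarray:
        """Mapped peaks that breach a tolerance or whose atoms drift outside
        the hard prior range."""
        omega, assigned = self.derive_shifts(genome)
        x, dmask = self._positions(genome[None, :])
        x, dmask = x[0], dmask[0]
        with np.errstate(invalid="ignore"):
            dev = np.abs(x - omega[self.dim_atom])
        atom_bad = assigned & (np.abs(omega - self.mu) >
                               self.params.prior_range_k * self.sigma + _EPS)
        bad_dim = dmask & ((dev > self.dim_tol + _EPS) | atom_bad[self.dim_atom])
        out = np.zeros(self.n_exp, dtype=bool)
        out[self.dim_peak[bad_dim]] = True
        return out

    def repair(self, genome: np.ndarray) -> np.ndarray:
        g = genome.copy()
        while True:
            bad = self.violations(g)
            if not bad.any():
                return g
            g[bad] = -1

    def exact_score(self, genome: np.ndarray) -> float:
        """Score of a feasible genome (no repair applied here)."""
        return float(self.soft_scores(genome[None, :])[0])

    def evaluate(self, genome: np.ndarray) -> tuple[np.ndarray, float]:
        g = self.repair(genome)
        return g, self.exact_score(g)

    def solution(self, genome: np.ndarray) -> MappingSolution:
        g, sc = self.evaluate(genome)
        mapping = {
            int(ei): self.cand_ids[ei][int(g[ei])]
            for ei in range(self.n_exp)
            if g[ei] >= 0
        }
        omega, assigned = self.derive_shifts(g)
        shifts = {
            self.atom_keys[a]: float(omega[a])
            for a in range(self.n_atoms)
            if assigned[a]
        }
        return MappingSolution(mapping, shifts, sc)

    # -- soft-assign annealing ----------------------------------------------
    def anneal(
        self,
        omega0: np.ndarray,
        n_widths: int | None = None,
        sinkhorn_iters: int = 2,
        accept_z: float = 3.0,
        final_sweeps: int = 4,
    ) -> np.ndarray:
        """Soft correspondence annealing from starting shifts ``omega0``.

        Candidate weights m(e,t) ∝ p_e·exp(-Σ_d (Δ/w_d)²/2) are row
        normalized against a slack (unmapped) option and column-balanced so
        that concurrent claims on one observed peak compete; shifts are
        re-estimated from the soft weights; the kernel width w anneals from
        the prior SD to tol/2.  Hardened by per-peak argmax at the end.
        """
        if self.n_exp == 0:
            return np.zeros(0, dtype=np.int64)
        if self.n_cand_total == 0:
            return np.full(self.n_exp, -1, dtype=np.int64)
        n_widths = n_widths or self.params.anneal_widths
        lam = self.params.unmapped_penalty
        omega = omega0.copy()
        sigma_dim = self.sigma[self.dim_atom]
        tol_half = self.dim_tol / 2.0
        m = np.zeros(self.n_cand_total)
        for step in range(n_widths + final_sweeps):
            frac = min(step / max(n_widths - 1, 1), 1.0)
            width_dim = np.maximum(tol_half, sigma_dim * (1.0 - frac) ** 2)
            w_cd = width_dim[self.cd_dim]
            z = (self.cd_x - omega[self.cd_atom]) / w_cd
            logk = np.bincount(self.cd_cand, weights=-0.5 * z ** 2,
                               minlength=self.n_cand_total)
            m = self.p_e[self.cand_peak] * np.exp(np.maximum(logk, -60.0))
            # slack mass keeps hopeless peaks unmapped (λ acts as its weight)
            u = lam * self.p_e * np.exp(-0.5 * accept_z ** 2 * self.ndim_of_peak)
            for _ in range(sinkhorn_iters):
                col = np.bincount(self.cand_okey, weights=m, minlength=self.n_obs_keys)
                m = m / np.maximum(col[self.cand_okey], 1.0)
                row = np.bincount(self.cand_peak, weights=m, minlength=self.n_exp) + u
                m = m / row[self.cand_peak]
            # shift re-estimation from soft weights
            wd = 1.0 / width_dim ** 2
            mw = m[self.cd_cand] * wd[self.cd_dim]
            num = np.bincount(self.cd_atom, weights=mw * self.cd_x, minlength=self.n_atoms)
            den = np.bincount(self.cd_atom, weights=mw, minlength=self.n_atoms)
            assigned = den > 1e-12
            omega = np.where(assigned, num / np.where(assigned, den, 1.0), omega)
        # harden: best candidate per peak if within the acceptance range
        z = np.abs(self.cd_x - omega[self.cd_atom]) / tol_half[self.cd_dim]
        zmax = np.zeros(self.n_cand_total)
        np.maximum.at(zmax, self.cd_cand, z)
        order = np.argsort(m, kind="stable")  # ascending; later wins in assignment
        genome = np.full(self.n_exp, -1, dtype=np.int64)
        sel = order[(zmax[order] <= accept_z)]
        genome[self.cand_peak[sel]] = sel - self.cand_start[self.cand_peak[sel]]
        return genome


class _ShiftICM:
    """Atom-wise coordinate ascent in chemical-shift space.

    The state is one shift per atom; the peak mapping is implied (each peak
    takes its best candidate given the shifts, or stays unmapped when the
    kernel falls below the acceptance threshold).  Moves re-optimize one
    atom's shift over the finite set of candidate position values appearing
    in its dimensions; directly bonded atom pairs observed together in a 2D
    correlation spectrum (amide HN/N, aliphatic or aromatic H/C) move
    jointly onto observed 2D positions — re-rooting a whole spin system in
    one step.
    """

    def __init__(self, prob: _Problem, accept_z: float = 3.0, max_pair_trials: int = 200):
        self.prob = prob
        self.accept_z = accept_z
        self.thresh = -0.5 * accept_z ** 2  # per dimension, in (tol/2) units
        self.w_cd = (prob.dim_tol / 2.0)[prob.cd_dim]
        order_cd = np.argsort(prob.cd_atom, kind="stable")
        bounds = np.searchsorted(prob.cd_atom[order_cd], np.arange(prob.n_atoms + 1))
        self.cd_of_atom = [order_cd[bounds[a]: bounds[a + 1]] for a in range(prob.n_atoms)]
        self.peaks_of_atom = [
            np.unique(prob.dim_peak[prob.cd_dim[idx]]) for idx in self.cd_of_atom
        ]
        self.pair_trials = self._build_pair_trials(max_pair_trials)
        self._aff_cache: dict[tuple[int, ...], tuple] = {}

    def _build_pair_trials(self, cap: int) -> dict[tuple[int, int], np.ndarray]:
        prob = self.prob
        pair_vals: dict[tuple[int, int], set] = {}
        for ei in range(prob.n_exp):
            dims = prob.peak_dims[ei]
            if prob.n_cand[ei] == 0 or len(dims) != 2:
                continue  # root pairs come from the 2D correlation spectra
            a, b = int(prob.dim_atom[dims[0]]), int(prob.dim_atom[dims[1]])
            if a == b:
                continue
            key, (di, dj) = ((a, b), (0, 1)) if a < b else ((b, a), (1, 0))
            s = prob.cand_start[ei]
            rows = prob.cand_pos[s: s + prob.n_cand[ei]]
            for r in rows:
                pair_vals.setdefault(key, set()).add(
                    (round(float(r[prob.dim_pos[dims[di]]]), 4),
                     round(float(r[prob.dim_pos[dims[dj]]]), 4))
                )
        out: dict[tuple[int, int], np.ndarray] = {}
        k = prob.params.prior_range_k
        for (a, b), vals in pair_vals.items():
            arr = np.array(sorted(vals))
            ok = (np.abs(arr[:, 0] - prob.mu[a]) <= k * prob.sigma[a]) & (
                np.abs(arr[:, 1] - prob.mu[b]) <= k * prob.sigma[b]
            )
            arr = arr[ok]
            if len(arr):
                out[(a, b)] = arr[:cap]
        return out

    def _affected(self, atoms: tuple[int, ...]) -> tuple:
        if atoms in self._aff_cache:
            return self._aff_cache[atoms]
        prob = self.prob
        peaks = np.unique(np.concatenate([self.peaks_of_atom[a] for a in atoms]))
        segs = [
            np.arange(prob.cand_start[p], prob.cand_start[p] + prob.n_cand[p])
            for p in peaks
        ]
        aff_c = np.concatenate(segs) if segs else np.zeros(0, dtype=np.int64)
        seg_len = np.array([len(s) for s in segs], dtype=np.int64)
        seg_starts = np.concatenate([[0], np.cumsum(seg_len)])[:-1]
        lo = np.searchsorted(prob.cd_cand, aff_c, side="left")
        hi = np.searchsorted(prob.cd_cand, aff_c, side="right")
        cnt = hi - lo
        idx = (
            np.concatenate([np.arange(l, h) for l, h in zip(lo, hi)])
            if len(aff_c)
            else np.zeros(0, dtype=np.int64)
        )
        owner = np.repeat(np.arange(len(aff_c)), cnt)
        touched = np.unique(prob.cd_atom[idx]) if len(idx) else np.zeros(0, np.int64)
        owner_peak = np.repeat(np.arange(len(peaks)), seg_len)
        res = (peaks, seg_starts, idx, owner, len(aff_c), touched, aff_c, owner_peak)
        if len(self._aff_cache) < 6000:
            self._aff_cache[atoms] = res
        return res

    _ROOT_BOUND_Z = 2.45  # per-remaining-dimension rooting cutoff in tol/2 units

    def _eval_moves(
        self, atoms: list[int], trials: np.ndarray, logk_cd: np.ndarray
    ) -> np.ndarray:
        """Selection score of each trial shift vector for ``atoms``.

        Only *rooted* candidates — those whose non-moved dimensions already
        match the current shifts — can win a peak, so unrooted candidates
        are dropped before the trial matrix is built.  The rooting test does
        not depend on the trial, so the pruning is argmax-safe.
        """
        prob = self.prob
        lam, beta = prob.params.unmapped_penalty, prob.params.prior_weight
        peaks, seg_starts, idx, owner, n_aff, _t, _aff_c, owner_peak = self._affected(
            tuple(atoms)
        )
        T = len(trials)
        pri = np.zeros(T)
        for ai, a in enumerate(atoms):
            pri += beta * np.exp(
                -((trials[:, ai] - prob.mu[a]) ** 2) / (2 * prob.sigma[a] ** 2)
            )
        if n_aff == 0:
            return pri
        cd_at = prob.cd_atom[idx]
        which = np.full(len(idx), -1, dtype=np.int64)
        for ai, a in enumerate(atoms):
            which[cd_at == a] = ai
        is_m = which >= 0
        base = np.bincount(
            owner, weights=np.where(is_m, 0.0, logk_cd[idx]), minlength=n_aff
        )
        nd_owner = prob.ndim_of_peak[prob.cand_peak[_aff_c]].astype(float)
        n_moved = np.bincount(owner, weights=is_m.astype(float), minlength=n_aff)
        bound = -0.5 * self._ROOT_BOUND_Z ** 2 * np.maximum(nd_owner - n_moved, 0.5)
        keep = base >= bound
        if not keep.any():
            return pri  # nothing can map; peak terms constant across trials
        k_idx = np.nonzero(keep)[0]
        inv = np.full(n_aff, -1, dtype=np.int64)
        inv[k_idx] = np.arange(len(k_idx))
        m_pos = np.nonzero(is_m & keep[owner])[0]
        xm = prob.cd_x[idx[m_pos]]
        wm = self.w_cd[idx[m_pos]]
        om_owner = inv[owner[m_pos]]
        om_which = which[m_pos]
        vals_m = trials[:, om_which]
        contrib = -0.5 * ((xm[None, :] - vals_m) / wm[None, :]) ** 2
        stot = np.repeat(base[k_idx][None, :], T, axis=0)
        for t in range(T):
            np.add.at(stot[t], om_owner, contrib[t])
        # per-peak max over kept candidates (k_idx ascending keeps grouping)
        op = owner_peak[k_idx]
        seg = np.searchsorted(op, np.arange(len(peaks)))
        present = np.searchsorted(op, np.arange(len(peaks)), side="right") > seg
        pidx = np.nonzero(present)[0]
        best = np.maximum.reduceat(stot, seg[pidx], axis=1)
        nd = prob.ndim_of_peak[peaks[pidx]].astype(float)
        pk = prob.p_e[peaks[pidx]]
        term = np.where(
            best >= self.thresh * nd[None, :], pk[None, :] * np.exp(best),
            -lam * pk[None, :],
        )
        return term.sum(axis=1) + pri

    def _single_trials(
        self, a: int, logk_cd: np.ndarray, root_z: float = 1.5, max_trials: int = 120
    ) -> np.ndarray:
        """Trial shift values for a single-atom move: candidate positions in
        the atom's dimensions whose candidate is already *rooted* (its other
        dimensions match the current shifts within ``root_z``); falls back to
        the best-rooted positions when nothing is rooted."""
        prob = self.prob
        ka = self.cd_of_atom[a]
        if len(ka) == 0:
            return np.zeros(0)
        _p, _s, idx, owner, n_aff, _t, aff_c, _op = self._affected((a,))
        is_a = prob.cd_atom[idx] == a
        base = np.bincount(owner, weights=np.where(is_a, 0.0, logk_cd[idx]), minlength=n_aff)
        t_of_ka = prob.cd_cand[ka]
        owner_ka = np.searchsorted(aff_c, t_of_ka)
        base_ka = base[owner_ka]
        nd_ka = prob.ndim_of_peak[prob.cand_peak[t_of_ka]].astype(float)
        vals = prob.cd_x[ka]
        in_range = np.abs(vals - prob.mu[a]) <= prob.params.prior_range_k * prob.sigma[a]
        rooted = in_range & (base_ka >= -0.5 * root_z ** 2 * np.maximum(nd_ka - 1, 1))
        if rooted.any():
            out = np.unique(np.round(vals[rooted], 4))
        else:
            order = np.argsort(-base_ka[in_range])
            out = np.unique(np.round(vals[in_range][order][:max_trials], 4))
        if len(out) > max_trials:
            # keep the best-rooted values
            best_of_val: dict[float, float] = {}
            rounded = np.round(vals, 4)
            for v, b, ok in zip(rounded, base_ka, in_range):
                if ok:
                    best_of_val[v] = max(best_of_val.get(v, -np.inf), b)
            out = np.array(sorted(best_of_val, key=lambda v: -best_of_val[v])[:max_trials])
        return out

    def run(
        self,
        omega0: np.ndarray,
        rng: np.random.Generator,
        sweeps: int = 6,
        compete: bool = True,
        compete_gamma: float = 1.0,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Optimize shifts from ``omega0``; returns (genome, omega).

        With ``compete`` enabled, a pair move onto a 2D root position already
        claimed by another atom pair is discouraged by ``compete_gamma`` per
        claimant during move selection (the final score is unaffected); this
        breaks the degeneracy where several residues of the same type settle
        on one observed spin system.
        """
        prob = self.prob
        if prob.n_exp == 0 or prob.n_cand_total == 0:
            return np.full(prob.n_exp, -1, dtype=np.int64), omega0.copy()
        omega = omega0.copy()
        logk_cd = -0.5 * ((prob.cd_x - omega[prob.cd_atom]) / self.w_cd) ** 2
        occ: dict[tuple[float, ...], int] = {}
        claimed: dict[tuple[int, int], tuple[float, ...]] = {}
        pair_keys = list(self.pair_trials)
        paired = {a for k in pair_keys for a in k}
        singles = [
            a for a in range(prob.n_atoms)
            if len(self.cd_of_atom[a]) and a not in paired
        ]
        moves: list[tuple[str, object]] = [("p", k) for k in pair_keys] + [
            ("s", a) for a in singles
        ]
        move_atoms = [
            tuple(key) if kind == "p" else (int(key),) for kind, key in moves
        ]
        def coordinate_sweeps(n_sweeps: int) -> None:
            changed_atoms: set[int] | None = None  # None = first sweep, try all
            for _sweep in range(n_sweeps):
                changed = 0
                new_changed: set[int] = set()
                for mi in rng.permutation(len(moves)):
                    kind, key = moves[mi]
                    if changed_atoms is not None:
                        touched = self._affected(move_atoms[mi])[5]
                        if not changed_atoms.intersection(touched.tolist()):
                            continue
                    if kind == "p":
                        atoms = list(key)
                        trials = np.vstack([self.pair_trials[key], omega[atoms][None, :]])
                    else:
                        a = int(key)
                        vals = self._single_trials(a, logk_cd)
                        if len(vals) == 0:
                            continue
                        atoms = [a]
                        trials = np.vstack([vals[:, None], omega[[a]][None, :]])
                    sc = self._eval_moves(atoms, trials, logk_cd)
                    if kind == "p" and compete and occ:
                        pen = np.array([
                            compete_gamma * occ.get(tuple(np.round(t, 3)), 0)
                            for t in trials
                        ])
                        own = claimed.get(key)
                        if own is not None:
                            for t_i, t in enumerate(trials):
                                if tuple(np.round(t, 3)) == own:
                                    pen[t_i] -= compete_gamma
                        sc = sc - pen
                    ti = int(np.argmax(sc))
                    if ti != len(trials) - 1 and sc[ti] > sc[-1] + 1e-9:
                        for ai, a in enumerate(atoms):
                            if abs(trials[ti, ai] - omega[a]) > 1e-12:
                                omega[a] = trials[ti, ai]
                                ka = self.cd_of_atom[a]
                                logk_cd[ka] = -0.5 * (
                                    (prob.cd_x[ka] - omega[a]) / self.w_cd[ka]
                                ) ** 2
                                changed += 1
                                new_changed.add(int(a))
                        if kind == "p" and compete:
                            old = claimed.get(key)
                            if old is not None:
                                occ[old] = occ.get(old, 1) - 1
                            new = tuple(np.round(trials[ti], 3))
                            claimed[key] = new
                            occ[new] = occ.get(new, 0) + 1
                if changed == 0:
                    break
                changed_atoms = new_changed

        coordinate_sweeps(sweeps)
        return self.harden(logk_cd), omega

    # -- spin-system root matching ------------------------------------------
    def root_match_omega(
        self,
        rng: np.random.Generator,
        noise: float = 0.3,
        soft_pins: Mapping[int, float] | None = None,
    ) -> np.ndarray:
        """Starting shifts from global root matching.

        Bonded root pairs (amide HN/N, aliphatic H/C) are assigned to
        observed 2D correlation positions by solving one rectangular
        assignment problem per pair type (Hungarian algorithm): the cost of
        placing a residue's pair on a root is the prior-typing score of the
        attached third-dimension values of the through-bond peaks rooted
        there.  Amides are matched first; the attached values they pin
        (e.g. CA/CB of the preceding residue) then inform the aliphatic
        groups.  ``noise`` perturbs costs to diversify repeated runs.
        """
        from scipy.optimize import linear_sum_assignment

        prob = self.prob
        omega = prob.mu.copy()
        if not self.pair_trials:
            return omega + 0.1 * prob.sigma * rng.standard_normal(prob.n_atoms)
        pinned: dict[int, float] = dict(soft_pins or {})
        for i, v in pinned.items():
            omega[i] = v

        # through-bond >=3D peaks rooted at each pair
        keys_of_atom: dict[int, list[tuple[int, int]]] = {}
        for key in self.pair_trials:
            for a in key:
                keys_of_atom.setdefault(a, []).append(key)
        rooted: dict[tuple[int, int], list[tuple[int, list[int], list[int]]]] = {}
        for ei in range(prob.n_exp):
            if not prob.is_throughbond[ei] or prob.ndim_of_peak[ei] < 3:
                continue
            if prob.n_cand[ei] == 0:
                continue
            dims = prob.peak_dims[ei]
            atoms = [int(x) for x in prob.dim_atom[dims]]
            for key in {k for a in atoms for k in keys_of_atom.get(a, [])}:
                if key[0] in atoms and key[1] in atoms:
                    root_cols = [atoms.index(key[0]), atoms.index(key[1])]
                    other_cols = [i for i in range(len(atoms)) if i not in root_cols]
                    rooted.setdefault(key, []).append((ei, root_cols, other_cols))

        def pair_cost(key, trial):
            """(negative) evidence for placing this pair at the trial root,
            plus the attached values the best-matching candidates imply."""
            a, b = key
            s = 0.0
            for at, v in zip(key, trial):
                s += -0.5 * ((v - prob.mu[at]) / prob.sigma[at]) ** 2
            pins: list[tuple[int, float]] = []
            for ei, root_cols, other_cols in rooted.get(key, []):
                dims = prob.peak_dims[ei]
                s0 = prob.cand_start[ei]
                nc = int(prob.n_cand[ei])
                pos = prob.cand_pos[s0: s0 + nc]
                ok = np.ones(nc, dtype=bool)
                for rc, v in zip(root_cols, trial):
                    col = prob.dim_pos[dims[rc]]
                    ok &= np.abs(pos[:, col] - v) <= prob.dim_tol[dims[rc]] + _EPS
                if not ok.any():
                    s -= 1.0  # expected peak missing at this root
                    continue
                zsum = np.zeros(int(ok.sum()))
                sub = pos[ok]
                for oc in other_cols:
                    o_atom = int(prob.dim_atom[dims[oc]])
                    col = prob.dim_pos[dims[oc]]
                    if o_atom in pinned:
                        z = (sub[:, col] - pinned[o_atom]) / (2 * prob.dim_tol[dims[oc]])
                    else:
                        z = (sub[:, col] - prob.mu[o_atom]) / prob.sigma[o_atom]
                    zsum += -0.5 * z ** 2
                best = int(np.argmax(zsum))
                s += max(float(zsum[best]), -6.0)
                for oc in other_cols:
                    pins.append((int(prob.dim_atom[dims[oc]]),
                                 float(sub[best, prob.dim_pos[dims[oc]]])))
            return s, pins

        groups: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for key in self.pair_trials:
            names = (prob.atom_keys[key[0]][1], prob.atom_keys[key[1]][1])
            groups.setdefault(names, []).append(key)
        # amide roots first: the values they pin type the aliphatic systems
        ordered = sorted(groups.items(), key=lambda kv: 0 if "N" in kv[0] else 1)

        BIG = 1e6
        for names, keys in ordered:
            root_index: dict[tuple[float, float], int] = {}
            for key in keys:
                for t in np.round(self.pair_trials[key], 3):
                    root_index.setdefault((t[0], t[1]), len(root_index))
            n_roots = len(root_index)
            if n_roots == 0:
                continue
            width = max(n_roots, len(keys))
            cost = np.full((len(keys), width), BIG)
            pin_map: dict[tuple[int, int], list[tuple[int, float]]] = {}
            for pi, key in enumerate(keys):
                for t in self.pair_trials[key]:
                    ri = root_index[tuple(np.round(t, 3))]
                    s, pins = pair_cost(key, t)
                    c = -s + noise * rng.standard_normal()
                    if c < cost[pi, ri]:
                        cost[pi, ri] = c
                        pin_map[(pi, ri)] = pins
            rows, cols = linear_sum_assignment(cost)
            assign = {int(pi): int(ri) for pi, ri in zip(rows, cols)
                      if cost[pi, ri] < BIG and ri < n_roots}
            roots = list(root_index)
            if set(names) == {"HN", "N"}:
                assign = self._amide_qap(keys, roots, cost, assign)
            for pi, ri in assign.items():
                a, b = keys[pi]
                omega[a], omega[b] = roots[ri]
                pinned[a] = omega[a]
                pinned[b] = omega[b]
                for o_atom, v in pin_map.get((pi, ri), []):
                    if o_atom not in pinned:
                        omega[o_atom] = v
                        pinned[o_atom] = v
        return omega

    def _amide_qap(
        self,
        keys: list[tuple[int, int]],
        roots: list[tuple[float, float]],
        cost: np.ndarray,
        assign: dict[int, int],
        max_passes: int = 20,
    ) -> dict[int, int]:
        """Refine the amide root assignment with pairwise NOESY evidence.

        Expected amide-amide NOESY peaks (HN_j, N_i, HN_i) assert that the
        roots of spatially close residues must co-occur as an observed
        NOESY peak; a 2-opt local search over root exchanges maximizes
        unary typing + pairwise support (a quadratic assignment refinement).
        """
        prob = self.prob
        cache_key = tuple(keys)
        if getattr(self, "_qap_cache_key", None) == cache_key:
            terms = self._qap_cache_terms
            return self._qap_search(keys, roots, cost, assign, terms, max_passes)
        atom_pair_of = {}
        for pi, (a, b) in enumerate(keys):
            hn = a if prob.atom_keys[a][1] == "HN" else b
            n = b if hn == a else a
            atom_pair_of[(hn, n)] = pi
        hn_to_pi = {hn: pi for (hn, n), pi in atom_pair_of.items()}
        n_to_pi = {n: pi for (hn, n), pi in atom_pair_of.items()}
        # amide-amide NOESY peaks: all dims are amide HN/N atoms
        terms = []  # (pi_of_Hx, pi_of_root, expected idx, Hx col, N col, HN col)
        for ei in range(prob.n_exp):
            if prob.is_throughbond[ei] or prob.n_cand[ei] == 0:
                continue
            dims = prob.peak_dims[ei]
            atoms = [int(x) for x in prob.dim_atom[dims]]
            names = [prob.atom_keys[a][1] for a in atoms]
            if len(dims) == 3 and names.count("HN") == 2 and names.count("N") == 1:
                hx_col = 0 if names[0] == "HN" else (1 if names[1] == "HN" else 2)
                n_col = names.index("N")
                hn_col = [i for i in range(3) if i != hx_col and i != n_col][0]
                # identify which HN is the root (bonded to the N dim)
                n_atom = atoms[n_col]
                root_hn = None
                for c in (hx_col, hn_col):
                    pi = hn_to_pi.get(atoms[c])
                    if pi is not None and n_to_pi.get(n_atom) == pi:
                        root_hn = c
                hx = hn_col if root_hn == hx_col else hx_col
                pi_x = hn_to_pi.get(atoms[hx])
                pi_r = n_to_pi.get(n_atom)
                if pi_x is None or pi_r is None or root_hn is None:
                    continue
                terms.append((pi_x, pi_r, ei, hx, n_col, root_hn))
        self._qap_cache_key = cache_key
        self._qap_cache_terms = terms
        return self._qap_search(keys, roots, cost, assign, terms, max_passes)

    def _qap_search(self, keys, roots, cost, assign, terms, max_passes) -> dict[int, int]:
        prob = self.prob
        if not terms:
            return assign

        def term_value(t, ri_x, ri_r) -> float:
            pi_x, pi_r, ei, hx_col, n_col, hn_col = t
            hx_v = roots[ri_x][0]
            n_v, hn_v = roots[ri_r][1], roots[ri_r][0]
            dims = prob.peak_dims[ei]
            s0 = prob.cand_start[ei]
            pos = prob.cand_pos[s0: s0 + int(prob.n_cand[ei])]
            ok = (
                (np.abs(pos[:, prob.dim_pos[dims[hx_col]]] - hx_v) <= prob.dim_tol[dims[hx_col]] + _EPS)
                & (np.abs(pos[:, prob.dim_pos[dims[n_col]]] - n_v) <= prob.dim_tol[dims[n_col]] + _EPS)
                & (np.abs(pos[:, prob.dim_pos[dims[hn_col]]] - hn_v) <= prob.dim_tol[dims[hn_col]] + _EPS)
            )
            p = prob.p_e[ei]
            return p if ok.any() else -prob.params.unmapped_penalty * p

        terms_of_pi: dict[int, list] = {}
        for t in terms:
            terms_of_pi.setdefault(t[0], []).append(t)
            terms_of_pi.setdefault(t[1], []).append(t)

        def local_obj(pis, a) -> float:
            s = 0.0
            seen = set()
            for pi in pis:
                for t in terms_of_pi.get(pi, []):
                    tid = id(t)
                    if tid in seen:
                        continue
                    seen.add(tid)
                    ri_x, ri_r = a.get(t[0]), a.get(t[1])
                    if ri_x is None or ri_r is None:
                        continue
                    s += term_value(t, ri_x, ri_r)
            for pi in pis:
                if pi in a:
                    s -= cost[pi, a[pi]]
            return s

        pis_all = list(assign)
        for _ in range(max_passes):
            improved = False
            for i in range(len(pis_all)):
                for j in range(i + 1, len(pis_all)):
                    pi, pj = pis_all[i], pis_all[j]
                    if pi not in assign or pj not in assign:
                        continue
                    ri, rj = assign[pi], assign[pj]
                    if cost[pi, rj] >= 1e6 or cost[pj, ri] >= 1e6:
                        continue
                    before = local_obj((pi, pj), assign)
                    assign[pi], assign[pj] = rj, ri
                    after = local_obj((pi, pj), assign)
                    if after > before + 1e-9:
                        improved = True
                    else:
                        assign[pi], assign[pj] = ri, rj
            if not improved:
                break
        return assign

    def harden(self, logk_cd: np.ndarray) -> np.ndarray:
        """Best candidate per peak given per-(candidate, dim) log kernels."""
        prob = self.prob
        tot = np.bincount(prob.cd_cand, weights=logk_cd, minlength=prob.n_cand_total)
        genome = np.full(prob.n_exp, -1, dtype=np.int64)
        for e in range(prob.n_exp):
            nc = int(prob.n_cand[e])
            if nc == 0:
                continue
            s = prob.cand_start[e]
            seg = tot[s: s + nc]
            b = int(np.argmax(seg))
            if seg[b] >= self.thresh * prob.ndim_of_peak[e]:
                genome[e] = b
        return genome


def _root_seed(
    prob: _Problem, icm: "_ShiftICM", rng: np.random.Generator, rounds: int = 3
) -> np.ndarray:
    """Seed genome from iterated global root matching and coordinate ascent.

    Round 1 matches root pairs from priors alone; later rounds re-match with
    every non-amide shift from the previous round soft-pinned, which feeds
    sequential-linking information (e.g. CA/CB of the preceding residue)
    back into the amide assignment.  Returns the best genome found.
    """
    params = prob.params
    amide_atoms = {
        a for key in icm.pair_trials for a in key
        if prob.atom_keys[a][1] in ("HN", "N")
    }
    best_g: np.ndarray | None = None
    best_s = -np.inf
    om_prev: np.ndarray | None = None
    for _ in range(max(rounds, 1)):
        if om_prev is None:
            pins: dict[int, float] = {}
        else:
            pins = {
                i: float(om_prev[i])
                for i in range(prob.n_atoms)
                if i not in amide_atoms
            }
        om0 = icm.root_match_omega(rng, noise=0.15, soft_pins=pins)
        g, om_prev = icm.run(om0, rng, params.icm_sweeps)
        g2, s = prob.evaluate(g)
        if s > best_s + 1e-9:
            best_s, best_g = s, g2
        elif best_g is not None:
            break  # no further improvement from re-matching
    return best_g if best_g is not None else np.full(prob.n_exp, -1, dtype=np.int64)


# ---------------------------------------------------------------------------
# public operations

def score(
    solution: MappingSolution,
    expected: Sequence[ExpectedPeak],
    observed: Mapping[str, ObservedPeakList],
    priors: PriorSet,
    params: EngineParams | None = None,
    spectra: Mapping[str, SpectrumDefinition] | None = None,
) -> float:
    """Score a mapping solution; raises if a mapped peak breaks its tolerance."""
    params = params or EngineParams()
    prob = _Problem(expected, observed, priors, params, spectra)
    genome = _genome_from_mapping(prob, solution.mapping)
    if prob.violations(genome).any():
        raise ValueError("mapped peak violates a tolerance (infeasible solution)")
    return prob.exact_score(genome)


def _genome_from_mapping(prob: _Problem, mapping: Mapping[int, int]) -> np.ndarray:
    genome = np.full(prob.n_exp, -1, dtype=np.int64)
    for ei, oid in mapping.items():
        hits = np.nonzero(prob.cand_ids[ei] == oid)[0]
        if len(hits) == 0:
            raise ValueError(
                f"observed peak {oid} is not a candidate of expected peak {ei}"
            )
        genome[ei] = hits[0]
    return genome


def run_single(
    expected: Sequence[ExpectedPeak],
    observed: Mapping[str, ObservedPeakList],
    priors: PriorSet,
    params: EngineParams | None = None,
    spectra: Mapping[str, SpectrumDefinition] | None = None,
) -> MappingSolution:
    """One optimization run: annealed soft-assign and shift-space coordinate
    ascent seed an evolutionary population; the best individual is refined
    the same way.  Deterministic given params.seed."""
    params = params or EngineParams()
    if not expected:
        raise ValueError("at least one expected peak is required")
    prob = _Problem(expected, observed, priors, params, spectra)
    icm = _ShiftICM(prob)
    return _run_on_problem(prob, icm, params.seed)


def _run_on_problem(prob: _Problem, icm: "_ShiftICM", seed: int) -> MappingSolution:
    """One seeded optimization run on a prebuilt problem (lets callers amortize
    problem construction over the repeated consensus runs)."""
    params = prob.params
    rng = np.random.default_rng(seed)

    P, E = params.population_size, prob.n_exp
    pop = np.full((P, E), -1, dtype=np.int64)
    # greedy individual: best prior-kernel candidate per peak
    greedy = np.full(E, -1, dtype=np.int64)
    if prob.n_cand_total:
        zc = (prob.cd_x - prob.mu[prob.cd_atom]) / prob.sigma[prob.cd_atom]
        logk = np.bincount(prob.cd_cand, weights=-0.5 * zc ** 2,
                           minlength=prob.n_cand_total)
        for ei in range(E):
            if prob.n_cand[ei]:
                s = prob.cand_start[ei]
                greedy[ei] = int(np.argmax(logk[s : s + prob.n_cand[ei]]))
    pop[0] = greedy
    # annealed soft-assign from noisy prior-mean starts plus (when 2D root
    # pairs exist) an iterated root-matching seed: strong, diverse seeds —
    # this is where run-to-run stochasticity enters
    n_anneal = min(params.anneal_restarts if not icm.pair_trials else 1, P - 3)
    for p in range(2, 2 + n_anneal):
        omega0 = prob.mu + 0.5 * prob.sigma * rng.standard_normal(prob.n_atoms)
        pop[p] = prob.anneal(omega0)
    if P > 2 + n_anneal:
        pop[2 + n_anneal] = _root_seed(prob, icm, rng)
    # rest random, biased toward mapping
    for p in range(3 + n_anneal, P):
        r = rng.random(E)
        choice = (rng.random(E) * prob.n_cand).astype(np.int64)
        pop[p] = np.where((prob.n_cand > 0) & (r < 0.85), choice, -1)
    # pop[1] stays empty

    fitness = prob.soft_scores(pop)
    best_idx = int(np.argmax(fitness))
    best = pop[best_idx].copy()
    best_fit = float(fitness[best_idx])
    stall = 0
    residues = prob.residues
    # cap evolutionary work on very large problems; the seeds carry most of
    # the optimization there and the budget keeps runs responsive
    work_per_gen = P * max(prob.n_dims, 1)
    n_gens = min(params.generations, max(int(2e8 // work_per_gen), 10))
    for _gen in range(n_gens):
        new_pop = np.empty_like(pop)
        new_pop[0] = best
        for c in range(1, P):
            t1 = rng.integers(0, P, params.tournament_size)
            t2 = rng.integers(0, P, params.tournament_size)
            pa = pop[t1[np.argmax(fitness[t1])]]
            pb = pop[t2[np.argmax(fitness[t2])]]
            child = pa.copy()
            if len(residues) > 1:
                cut = residues[rng.integers(1, len(residues))]
                child = np.where(prob.block_res < cut, pa, pb)
            for r in residues:
                if rng.random() < params.mutation_rate:
                    idx = prob.peaks_of_residue[int(r)]
                    pick = (rng.random(len(idx)) * prob.n_cand[idx]).astype(np.int64)
                    keep = (prob.n_cand[idx] > 0) & (rng.random(len(idx)) < 0.85)
                    child[idx] = np.where(keep, pick, -1)
            new_pop[c] = child
        pop = new_pop
        fitness = prob.soft_scores(pop)
        gen_best = int(np.argmax(fitness))
        if fitness[gen_best] > best_fit + 1e-12:
            best_fit = float(fitness[gen_best])
            best = pop[gen_best].copy()
            stall = 0
        else:
            stall += 1
            if stall >= params.patience:
                break

    # polish: shift-space coordinate ascent from the best genome's implied
    # shifts, then peak-wise coordinate ascent
    omega_best, assigned = prob.derive_shifts(best)
    omega0 = np.where(assigned, omega_best, prob.mu)
    cand, _om = icm.run(omega0, rng, params.icm_sweeps)
    if float(prob.soft_scores(cand[None, :])[0]) > float(prob.soft_scores(best[None, :])[0]):
        best = cand
    if E <= 64:
        # tiny instances: exact peak-wise polish is affordable and ensures
        # the enumeration optimum is reached
        best = _local_optimize(prob, best, rng, params.local_opt_passes)
    sol = prob.solution(best)
    if sol.score < prob.empty_score:
        return MappingSolution({}, {}, prob.empty_score)
    return sol


_LOCAL_OPT_BUDGET = 10 ** 8  # rough flop budget per pass


def _local_optimize(
    prob: _Problem, genome: np.ndarray, rng: np.random.Generator, max_passes: int
) -> np.ndarray:
    """Peak-wise coordinate ascent on the soft score until a full pass yields
    no improvement (or the pass budget is exhausted).

    Each candidate evaluation costs O(n_dims); on large instances only the
    peaks with the weakest current contribution are revisited so a pass
    stays within a fixed work budget (the annealing sweeps already provide
    global peak-wise updates there).
    """
    if prob.n_exp == 0 or max_passes <= 0:
        return genome
    g = genome.copy()
    current = float(prob.soft_scores(g[None, :])[0])
    per_peak_cost = float(max(prob.max_cand, 1)) * prob.n_dims
    max_peaks = max(int(_LOCAL_OPT_BUDGET / max(per_peak_cost, 1.0)), 8)
    for _ in range(max_passes):
        improved = False
        if prob.n_exp <= max_peaks:
            order = rng.permutation(prob.n_exp)
        else:
            contrib = _peak_contributions(prob, g)
            order = np.argsort(contrib)[:max_peaks]
            order = order[rng.permutation(len(order))]
        for ei in order:
            nc = int(prob.n_cand[ei])
            if nc == 0:
                continue
            options = [c for c in range(-1, nc) if c != g[ei]]
            if not options:
                continue
            trials = np.tile(g, (len(options) + 1, 1))
            for t, c in enumerate(options):
                trials[t + 1, ei] = c
            scores = prob.soft_scores(trials)
            bi = int(np.argmax(scores))
            if bi > 0 and scores[bi] > scores[0] + 1e-12:
                g[ei] = options[bi - 1]
                improved = True
        new = float(prob.soft_scores(g[None, :])[0])
        if not improved or new <= current + 1e-12:
            current = max(current, new)
            break
        current = new
    return g


def _peak_contributions(prob: _Problem, genome: np.ndarray) -> np.ndarray:
    """Per-peak score contribution (kernel·p for well-mapped peaks, -λ·p for
    unmapped/violating ones) used to prioritize local-search moves."""
    omega, _assigned = prob.derive_shifts(genome)
    x, dmask = prob._positions(genome[None, :])
    x, dmask = x[0], dmask[0]
    with np.errstate(invalid="ignore"):
        dev = np.abs(x - omega[prob.dim_atom])
    dev = np.where(np.isnan(dev), 0.0, dev)
    expo = np.where(dmask, -dev ** 2 / (2.0 * (prob.dim_tol / 2.0) ** 2), 0.0)
    viol = dmask & (dev > prob.dim_tol + _EPS)
    peak_expo = np.bincount(prob.dim_peak, weights=expo, minlength=prob.n_exp)
    peak_viol = np.bincount(prob.dim_peak, weights=viol, minlength=prob.n_exp) > 0
    lam = prob.params.unmapped_penalty
    mapped = genome >= 0
    return np.where(mapped & ~peak_viol, prob.p_e * np.exp(peak_expo), -lam * prob.p_e)


def exhaustive_search(
    expected: Sequence[ExpectedPeak],
    observed: Mapping[str, ObservedPeakList],
    priors: PriorSet,
    params: EngineParams | None = None,
    spectra: Mapping[str, SpectrumDefinition] | None = None,
    max_combinations: int = 10 ** 6,
    allow_shared_observed: bool = True,
) -> MappingSolution:
    """Global optimum over all feasible mappings by enumeration (test oracle).

    Each expected peak maps to one of its candidates or to nothing.  With
    ``allow_shared_observed=False`` mappings where two expected peaks of the
    same spectrum share an observed peak are excluded.
    """
    params = params or EngineParams()
    prob = _Problem(expected, observed, priors, params, spectra)
    combos = 1
    for nc in prob.n_cand:
        combos *= nc + 1
        if combos > max_combinations:
            raise ValueError(f"instance too large for exhaustive search (> {max_combinations})")
    best_g = np.full(prob.n_exp, -1, dtype=np.int64)
    best_score = prob.exact_score(best_g) if prob.n_exp else 0.0
    spectrum_of = [e.spectrum for e in prob.expected]
    for combo in itertools.product(*[range(-1, int(nc)) for nc in prob.n_cand]):
        genome = np.array(combo, dtype=np.int64)
        if not allow_shared_observed:
            seen: set[tuple[str, int]] = set()
            clash = False
            for ei, c in enumerate(genome):
                if c >= 0:
                    key = (spectrum_of[ei], prob.cand_ids[ei][int(c)])
                    if key in seen:
                        clash = True
                        break
                    seen.add(key)
            if clash:
                continue
        g, sc = prob.evaluate(genome)
        if sc > best_score + 1e-12:
            best_score = sc
            best_g = g
    if prob.n_exp == 0:
        return MappingSolution({}, {}, 0.0)
    return prob.solution(best_g)
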