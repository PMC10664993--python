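# Methods

`shiftassign` automates protein NMR chemical-shift assignment: it maps
cross peaks *expected* from the sequence (and optionally a 3D structure)
onto cross peaks *observed* in multidimensional spectra, and reports one
chemical shift per atom with a reliability class.  This note documents the
model, the algorithms, the synthetic benchmark, and the numerical choices.

## Expected peaks

**Through-bond spectra.** Each experiment type is a magnetization-transfer
pathway template instantiated at every residue where all constituent atoms
exist.  For example HNCA yields (HN_i, N_i, CA_i) and (HN_i, N_i, CA_{i-1});
[1H,15N]-HSQC yields (HN_i, N_i); the TOCSY experiments enumerate proton or
carbon pairs within one residue's aliphatic network (transfers crossing a
sulfur are dropped — no C–C relay).  Prolines and the N-terminal residue
carry no amide proton, so amide-rooted peaks vanish there automatically.
Each pathway class carries an a-priori observation probability from an
editable library: 0.95 for one-bond/strong intra-residue transfers, 0.80
for sequential and long relay transfers.

**NOESY spectra.** Given a structure bundle, an expected NOESY cross peak is
generated for a proton pair exactly when their distance is below 6.0 Å in
*all* conformers.  The observation probability is tiered by the maximal
distance d_max over the bundle: 0.9 below 4 Å, then 0.8 / 0.7 / 0.6 / 0.5
in 0.5 Å steps up to 6 Å.  Diagonal peaks are excluded; both symmetric
partners of an amide–amide contact are emitted.  Hydroxyl, thiol and
lysine-ammonium protons are omitted (fast solvent exchange quenches their
NOESY peaks).  Without a structure, the same rule is applied to an
internally generated bundle of 20 random-torsion chains with ideal covalent
geometry; only short-range contacts survive the all-conformer test, which
reproduces the behaviour of assignment without structural knowledge.

## Priors

Every assignable atom carries a Gaussian shift prior.  Defaults come from a
bundled per-(residue type, atom name) mean/SD table with BMRB-like values
(e.g. ALA CA 52.5 ± 2.0 ppm).  Structure-based shift predictions, when
supplied, replace the priors of the six backbone atom names CA, CB, C', HN,
HA, N with N(predicted value, σ_pred), where σ_pred is the predictor's
published error per atom name (C' 0.85, CA 0.77, CB 0.86, HN 0.39, HA 0.20,
N 1.98 ppm; overridable).  The priors serve two purposes: they score
assignments, and they bound the search — an atom's shift may never leave
mean ± k·SD (k = 3 by default), which prunes each expected peak's candidate
observed peaks to a small window.

## Objective

A solution maps each expected peak e (observation probability p_e) to one
observed peak or to nothing.  Shifts are not free variables: the shift ω_a
of atom a is the 1/tol²-weighted mean of the positions of all mapped peak
dimensions attributed to a.  The score is

    Σ_mapped  p_e · Π_d exp(−Δ_{e,d}² / 2(tol_d/2)²)
  − λ · Σ_unmapped p_e
  + β · Σ_assigned exp(−(ω_a − μ_a)² / 2σ_a²)

with Δ_{e,d} the deviation of the observed position from the implied shift,
tolerances 0.03 ppm (1H) and 0.4 ppm (13C/15N), λ = 0.2 and β = 0.5.  A
mapped peak deviating by more than the tolerance in any dimension is
infeasible; a deterministic repair unmaps violators to a fixpoint, so every
returned solution is feasible.  Two expected peaks may map to one observed
peak (peak overlap).  This objective is this package's own surrogate for
the (unpublished) internal score of the reference method; all downstream
claims are made with respect to it.

## Optimization

Finding the global optimum is a large combinatorial search; the engine
layers four components, from global to local:

1. **Root matching.**  Directly bonded atom pairs observed together in 2D
   correlation spectra (amide HN/N, aliphatic H/C) are *roots* of spin
   systems.  Each pair type is assigned to observed 2D positions by solving
   a rectangular assignment problem (Hungarian algorithm) whose cost is the
   prior-typing score of the attached third-dimension values of peaks
   rooted there.  Amides are matched first; a quadratic-assignment 2-opt
   refinement exploits amide–amide NOESY peaks (spatially close residues
   must co-occur as observed peaks).  The attached values pinned by the
   amide stage (CA/CB of the preceding residue) then inform the aliphatic
   groups.  The matching is iterated: after a full coordinate-ascent pass,
   roots are re-matched with all side-chain shifts soft-pinned, feeding
   sequential-linking information back into the amide assignment.
2. **Shift-space coordinate ascent (the local optimization).**  The state
   is one shift per atom; the peak mapping is implied (each peak takes its
   best candidate given the shifts, or stays unmapped below an acceptance
   kernel threshold).  Atoms are visited in random order; each move
   re-optimizes one atom — or one bonded root pair jointly — over the
   finite set of candidate position values appearing in its dimensions.
   Only *rooted* candidates (whose other dimensions already match) can win
   a peak, which keeps each move evaluation sparse and fast.
3. **Soft-assign annealing.**  A soft correspondence between expected peaks
   and candidates (row-normalized against an unmapped slack, Sinkhorn
   column-balanced so peaks compete for observed peaks) is relaxed while
   the matching kernel width anneals from the prior SD down to tol/2,
   alternating with shift re-estimation.  Annealed restarts from noisy
   prior means give diverse population seeds.
4. **Evolutionary search.**  A population (default 50) holding the seeds
   above plus randomized individuals evolves by tournament selection,
   one-point crossover over residue blocks, and residue-block mutation;
   the best individual is polished by another coordinate-ascent pass.
   Evolutionary work is capped by an element-operation budget so very large
   problems remain responsive; the seeds carry most of the optimization
   there.

Each consensus run uses a different random seed, which perturbs the root
matching costs, the annealing starts and the move order — the source of
the run-to-run variability that the strong/weak classification measures.

**Known limitation.**  On dense noiseless benchmarks the optimizer
typically recovers 85–95 % of atoms per run rather than the exact global
optimum; residues of similar type with similar spatial context can remain
interchanged.  The consensus classification flags most such atoms as weak,
but a perfectly clean round trip is not guaranteed.

## Consensus and accuracy estimation

The engine runs R times (default 20) with identical input and different
seeds.  Per atom, the consensus shift is the center of the window of width
2·Δω (Δω = 0.03 ppm 1H, 0.4 ppm 13C/15N) covering the most per-run values,
searched exactly over member-anchored windows with ties resolved toward the
smaller member median; the reported shift is the mean of in-window values.
An atom is **strong** when at least 80 % of the values found for it lie in
the window — exactly 80 % qualifies — and it was found in at least half the
runs (the guard keeps one-run "unanimous" atoms out of the reliable class);
otherwise it is **weak**.  The support denominator is the number of runs in
which the atom was found; a strict divide-by-R variant is available.

From the percentage S of strong assignments (computed over assigned atoms)
the expected accuracy follows the calibrated linear forms
A = 0.89·S + 7.88 % (all assignments) and A_strong = 0.45·S + 51.49 %
(strong subset).

## Evaluation

An assigned atom with a reference value is correct when |ω − ref| is within
the per-nucleus tolerance.  Reported metrics: correct (strong), correct
(weak), correct (all), strong fraction, completeness (strong), and the
joint backbone-amide accuracy in which an HN/N pair counts only if both
members are within tolerance.  Empty denominators report NA, never 0 or
100.  Stereo leniency is on by default: a stereospecific assignment swapped
against the reference (HB2/HB3, Val/Leu methyl pairs, Phe/Tyr ring
symmetry) counts as correct, since reference stereo-assignments are often
arbitrary.

## Synthetic benchmark generator

The generator emulates the full data package of an assignment project:

- **Structures** are built in torsion space with ideal covalent geometry
  (NeRF construction; helix −57/−47, extended −120/120, or random
  torsions), rings as planar polygons (proline pucker and indole closure
  are approximate), conformers differing by small torsion noise (4°
  backbone, 12° side chain).  Random-coil conformers are re-sampled up to 8
  times to relieve steric clashes.
- **Decoys** at a target backbone RMSD are made by scaling Gaussian
  backbone-torsion noise by bisection until the Kabsch-superposed RMSD is
  within ±10 % of the target; three decoys with pairwise RMSD below 1 Å
  form a bundle.
- **True shifts** are drawn from the priors, truncated at ±3 SD.
  Magnetically equivalent atoms (methyl protons, Phe/Tyr ring-flip pairs,
  Lys NZ protons) share one value, as in real shift lists.
- **Peak lists** contain each expected peak with probability p_e (or
  always, when detection is off) at the true positions plus Gaussian jitter
  of one third of the dimension tolerance; Poisson-distributed artifact
  peaks (rate 0.1 per true peak) are placed uniformly over the occupied
  ppm box of each spectrum so they are confusable.  Confidence scores are
  Beta(8,2) for true peaks and Beta(2,8) for artifacts, placing most true
  peaks above the 0.1 NOESY threshold while exercising the top-K filter.
- **Multi-domain systems** concatenate domains with 10-glycine linkers,
  renumber residues contiguously, merge peak lists with fresh ids, and
  place the rigid domain structures along a raised linker path without
  inter-domain clashes; linker residues carry priors but no peaks.

What the generator does *not* emulate: relaxation-dependent linewidths and
peak overlap beyond coincidental proximity, solvent/exchange effects,
spectral folding, and correlated referencing errors.  Passing benchmarks
therefore demonstrate the combinatorial and statistical machinery, not
performance on raw experimental spectra.

## Benchmark scale

The bundled validation experiments run at desk scale, chosen so a complete
pass stays within minutes on one CPU: 12-residue proteins with 15N-centric
spectrum sets and 3–5 consensus runs for the comparative experiments
(noise robustness, structure benefit, decoy gradient, domain
concatenation), and a 30-residue protein with the full 7-spectrum set for
the noiseless round trip.  The observation-probability tiers, the
estimator and the consensus rule are scale-free and tested exactly.

## Numerical choices and degenerate inputs

- Tolerances and Δω default to 0.03 ppm (1H) and 0.4 ppm (13C/15N)
  everywhere; the score kernel uses half the tolerance as its SD.
- Ties in top-K confidence selection break by larger intensity, then
  smaller peak id; retained peaks keep their original order.
- The consensus window search anchors candidate windows at member values,
  which is sufficient for exactness and O(n²).
- Observed peaks with no candidate window, spectra with no expected peaks,
  and atoms found in no run degrade gracefully (skipped with a warning,
  never silently miscounted).
- All randomness flows from explicit integer seeds; identical inputs and
  seeds give bit-identical results.
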