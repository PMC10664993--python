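# shiftassign

Structure-informed automated protein NMR chemical-shift assignment.

Assigning chemical shifts — attributing a resonance frequency to every
1H/13C/15N atom of a protein — is the gateway to NMR studies of structure,
dynamics and interactions, and one of their most labor-intensive steps.
`shiftassign` automates it for users who have picked peak lists from
multidimensional spectra: it back-calculates the cross peaks *expected*
from the sequence (and, optionally, a 3D structure model), maps them onto
the *observed* peaks by stochastic combinatorial optimization under
Gaussian shift priors, classifies each assignment as strong or weak by
multi-run consensus, and estimates the overall accuracy without needing a
reference assignment.

The package targets protein NMR spectroscopists and methods developers.  A
synthetic benchmark generator produces complete, ground-truthed assignment
problems (structures, shift truths, noisy peak lists, decoy structure
bundles, multi-domain concatenations), so every stage is testable without
any experimental dataset.

## The model in brief

For expected peak e with observation probability p_e, mapped dimensions
deviating by Δ_{e,d} from the implied atom shifts ω (tolerance tol_d:
0.03 ppm for ¹H, 0.4 ppm for ¹³C/¹⁵N), priors N(μ_a, σ_a²):

```
score = Σ_mapped  p_e · Π_d exp(−Δ²_{e,d} / 2(tol_d/2)²)
      − λ Σ_unmapped p_e
      + β Σ_assigned exp(−(ω_a − μ_a)² / 2σ_a²)
```

Expected NOESY peaks come from a structure bundle: a proton pair generates
a peak when its distance is below 6.0 Å in **all** conformers, with
observation probability 0.9 / 0.8 / 0.7 / 0.6 / 0.5 tiered by the maximal
bundle distance (cuts at 4, 4.5, 5, 5.5 Å).  An assignment is **strong**
when at least 80 % of the shift values found for the atom across R
independent runs (default 20) agree within ω ± Δω (0.03 / 0.4 ppm).  From
the percentage S of strong assignments the accuracy estimates are

```
A        = 0.89 · S + 7.88   (all assignments, %)
A_strong = 0.45 · S + 51.49  (strong subset, %)
```

See `docs/methods.md` for the full account.

## Worked example

Simulate a small ground-truthed problem, assign it, and evaluate:

```sh
shiftassign simulate --length 8 --seed 3 --noiseless \
    --spectra N15HSQC --spectra HNCA --out demo
cat > demo/run.toml <<'EOF'
sequence = "protein.seq"
reference = "reference.prot"
runs = 5
seed = 1
spectra = [["N15HSQC", "N15HSQC.peaks"], ["HNCA", "HNCA.peaks"]]
EOF
shiftassign assign demo/run.toml --out demo/results
```

which prints

```
assigned atoms : 22
strong         : 22 (100.0%)
estimated accuracy        A = 96.88%
estimated strong accuracy A_strong = 96.49%
```

All 22 atoms touched by the HSQC/HNCA peaks (backbone amides and CA) were
assigned; every run agreed within tolerance, so all are classified strong
(S = 100 %), and the estimator translates S into an expected accuracy of
96.88 %.  `demo/results/shifts.prot` holds the shift table with the class
column, `report.json` the machine-readable summary, and
`shiftassign evaluate demo/results/shifts.prot demo/reference.prot`
compares against the known truth.

The same workflow runs on real data: XEASY or Sparky peak lists, a FASTA
or three-letter sequence file, an optional multi-model PDB (e.g. a
five-model predicted bundle) for NOESY back-calculation, and optional
predicted backbone shifts in the five-column prot format.

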