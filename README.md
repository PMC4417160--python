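# oligou

An analysis workbench for characterizing how an RNA recognition motif (RRM)
binds oligo(U)/polypyrimidine RNA — the recognition event by which the nuclear
exosome targeting (NEXT) complex, via its RBM7 subunit, is recruited to the
U-rich 3′-flanking regions of snRNA genes. The package bundles the six
quantitative analyses such a study needs, each usable on its own or through
the `workbench` CLI, plus seeded synthetic-data generators so the whole
pipeline runs and is tested without any downloads:

1. **Binding isotherms** (`oligou.isotherm`) — fit equilibrium fluorescence
   anisotropy titrations to the single-site model and report *K*<sub>d</sub>
   with uncertainty.
2. **Chemical-shift perturbation mapping** (`oligou.csp`) — per-residue
   combined amide CSPs between free and RNA-bound HSQC peak lists, with
   perturbed-residue calling.
3. **Ensemble quality accounting** (`oligou.ensemble`) — NOE restraint
   classification by sequence separation, upper-bound violation counting, and
   mean pairwise RMSD of multi-model PDB ensembles over backbone/heavy
   selections and secondary-structure regions.
4. **TTS motif density** (`oligou.motifs`) — strand-aware positional k-mer
   profiles and k-mer frequency rankings in windows anchored at feature 3′
   ends (transcription termination sites).
5. **Pulldown quantification** (`oligou.pulldown`) — peptide filtering, top-3
   label-free protein areas, and the ≥5-fold-in-≥2-replicates enrichment
   filter with explicit handling of bait-exclusive detections.
6. **ΔΔCt / RIP quantification** (`oligou.qpcr`) — reference-gene-normalized
   relative expression with paired t-tests, and RNA-immunoprecipitation
   enrichment over control beads normalized to input.

## The models at the core

**Binding with ligand depletion.** A labeled RNA at total concentration
*R*<sub>t</sub> titrated with protein at total concentration *P*<sub>t</sub>
binds a single site with dissociation constant *K*<sub>d</sub>. Because
*R*<sub>t</sub> is not always ≪ *K*<sub>d</sub>, the bound fraction is the
exact quadratic solution in total concentrations,

    f_b = [(R_t + P_t + K_d) − √((R_t + P_t + K_d)² − 4·R_t·P_t)] / (2·R_t),

and the observed anisotropy is r = r_free + (r_bound − r_free)·f_b. The
hyperbolic limit f_b = P_t/(K_d + P_t) is available for the dilute regime.

**Combined amide CSP.** For each assigned residue,
Δδ = √((ω_HN·Δδ_HN)² + (ω_N·Δδ_N)²) with ω_HN = 1 and ω_N = 0.154; peaks that
disappear on binding (exchange broadening) carry the sentinel value 1.0 ppm
and are excluded from the mean + SD calling threshold.

**ΔΔCt.** Per replicate ΔCt = Ct_target − Ct_reference;
ΔΔCt = ΔCt_condition − ΔCt_control; fold = 2^(−mean ΔΔCt), with a two-tailed
paired t-test on the replicate ΔCt pairs (α = 0.1). RIP enrichment is
2^−[(Ct_ELU,ab − Ct_INP,ab) − (Ct_ELU,beads − Ct_INP,beads)].

## Worked example

Simulate a noisy titration with true *K*<sub>d</sub> = 60 µM
(*R*<sub>t</sub> = 7.1 µM, 12 points to 400 µM, anisotropy noise SD 0.002)
and fit it:

```sh
$ workbench simulate titration --seed 11 --kd 60 --noise 0.002 --out wk
$ workbench fit-kd wk/titration.csv
{
  "kd_uM": 62.880523907230284,
  "r_free": 0.05131581719066841,
  "r_bound": 0.20143794120164782,
  "model": "depletion",
  "sse": 3.784873355053642e-05,
  "stderr_kd_uM": 3.917627897078359,
  "converged": true,
  "message": "`xtol` termination condition is satisfied."
}
```

The fitted *K*<sub>d</sub> of 62.9 ± 3.9 µM recovers the planted 60 µM within
its standard error; `r_free`/`r_bound` are the free- and bound-state
anisotropy plateaus, and `sse` is the residual sum of squares of the
depletion-model fit.

`workbench demo --out DIR --seed N` runs all six stages end-to-end on
synthetic fixtures and writes per-stage outputs, a JSON report with content
checksums (rerunning the same seed reproduces them byte-for-byte), and a
Markdown summary. For example, the motif stage plants a UUUUU motif 10 nt
downstream of every feature 3′ end and the positional profile finds exactly
one occurrence per feature at position +10.

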