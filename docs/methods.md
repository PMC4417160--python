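# Methods

This note documents the models, conventions, parameter choices and known
limitations behind each stage of the workbench, and what the synthetic-data
generators do and do not emulate.

## Binding isotherms

The single-site model is solved exactly in total concentrations. With labeled
RNA at total concentration R_t (µM), protein at P_t (µM) and dissociation
constant K_d (µM), mass balance gives the quadratic
R_t·f_b² − (R_t + P_t + K_d)·f_b + P_t = 0, whose physical root is

    f_b = [(R_t + P_t + K_d) − √((R_t + P_t + K_d)² − 4·R_t·P_t)] / (2·R_t).

This "ligand depletion" form matters whenever R_t is comparable to K_d: at
R_t ≈ 7 µM and K_d ≈ 60 µM the hyperbolic approximation misestimates the
bound fraction by several percent at low protein. The hyperbolic form
f_b = P_t/(K_d + P_t) is provided for the dilute regime and the two agree
within 1% once R_t ≤ K_d/100. R_t is a required per-series input, never a
hard-coded constant, because in practice it is known only as the nominal
amount of labeled RNA in the cuvette.

Fitting is plain non-linear least squares over (K_d, r_free, r_bound) via
`scipy.optimize.least_squares` (trust-region reflective, tolerances 1e-15 so
the optimum is machine-tight and invariant to point ordering and affine
rescaling of the anisotropy). Initialization: r_free and r_bound from the
lowest- and highest-concentration points, K_d from the half-amplitude
crossing — robust for monotone isotherms. K_d is bounded to [1e-4, 1e5] µM;
a fit pinned at a bound is reported `converged=false` (weak binders are
right-censored, e.g. "K_d ≫ 200 µM", rather than assigned a number). The K_d
standard error comes from the Gauss–Newton covariance sse/(n−p)·(JᵀJ)⁻¹. A
series with no resolvable amplitude (constant anisotropy) is flagged
unidentifiable rather than returning a silent bad fit. Equal quantum yields
of free and bound fluorophore are assumed — no intensity weighting — since
anisotropy-only data carry no information about yield changes.

Anisotropy normalization (r − r_free)/(r_bound − r_free) is computed only for
display; fitting always uses raw anisotropies.

## CSP mapping

Peak matching is by residue number (lists are assumed assigned); there is no
nearest-neighbour peak tracking. The combined CSP uses nucleus weights
ω_HN = 1 and ω_N = 0.154, the standard rescaling of ¹⁵N shift ranges onto the
¹H scale, so the quantity is in ppm on the ¹H scale. Residues present free
but absent bound are "disappeared" (intermediate-exchange broadening) and
carry the sentinel CSP 1.0 ppm. The calling rule is mean + 1·SD over measured
residues only — the sentinel is excluded because a handful of 1.0-ppm values
would otherwise inflate the threshold several-fold — and disappeared residues
are always in the called set. The 1-SD multiplier is a configurable field
convention, not a derived quantity; no numeric cutoff is canonical for this
kind of map.

## Ensemble accounting

NOE restraints are classified by sequence separation |i−j| with the
exhaustive convention intra = 0, sequential = 1, medium-range 2–4,
long-range ≥ 5, chosen so that the four classes always partition the total
(printed tables sometimes leave |i−j| = 4 and 5 unassigned between
"medium < 4" and "long > 5"; an exhaustive partition is the only convention
under which per-class counts can be checked against a printed total, and
2–4/≥5 is the common NOE bookkeeping choice).

Violation counting uses standard upper-bound semantics: the model distance of
a restraint is the minimum over all matching atom pairs (so ambiguous and
pseudo-atom restraints, e.g. `HB*`, are satisfied by any member), the
violation is distance − upper bound where positive, and a model's count is
the number of violations exceeding the threshold (default 0.2 Å). The report
carries per-model counts, their mean and sample SD, and the maximum excess.

Pairwise superposition is the SVD-based Kabsch solution with the determinant
correction that forbids reflections; fewer than three atoms or a collinear
selection is an error since the rotation is then not unique. Ensemble RMSD is
the mean ± SD over all n(n−1)/2 unordered model pairs, each superposed
independently on the requested selection. SD is the sample SD (ddof = 1),
matching how structure-statistics tables usually report ensemble spread.
"Backbone" means N, CA, C, O; "heavy" means all non-hydrogens.
Secondary-structure regions default to the HELIX/SHEET records of the input
PDB header when present, else user-supplied residue ranges. Both backbone and
heavy selections are reported by the pipeline because published spread values
are quoted over either, depending on the table.

## TTS motif density

Coordinates are BED 0-based half-open throughout; the 3′ anchor is `end` for
+ strand and `start` for − strand features, and oriented position 0 is the
first nucleotide downstream of the 3′ end on the feature's own strand. The
default window is 200 nt upstream / 600 nt downstream of the termination
site, the span in which U-rich tracts downstream of snRNA genes concentrate.
"Non-overlapping" removes both members of any intersecting pair
(strand-agnostic), the strictest reading that leaves no ambiguous records.

Motifs are accepted in RNA or DNA alphabet (U→T). Occurrences are counted at
every start position — a run of seven U contains three U₅ starts — because
homopolymer run length is exactly the signal of interest; collapsing runs
would change rankings. k-mers containing non-ACGT symbols are skipped
entirely. Windows clipped at chromosome ends are tracked per position, and
the per-position density divides counts by the number of windows whose
clipped sequence fully covers the k-mer starting there, so clipping cannot
masquerade as depletion. Rankings order k-mers by descending count with
lexicographic tie-break (`rank`), and `count_rank` gives the tie-sharing rank
of the count value. Profile smoothing is an edge-normalized centered moving
average, for display only.

## Pulldown quantification

Peptide-spectrum matches are kept when q-value < 0.01 (strict, per the
"< 1%" convention), search rank = 1 and peptide length ≥ 6. Protein abundance
per sample is the mean area of the three most intense peptides; with fewer
than three peptides the mean of what is available is used and flagged
low-evidence. Absence is always an explicit missing value, never a zero area,
so no fold is a division by zero. Per paired replicate the fold is
bait/control area; bait detected with control absent is EXCLUSIVE and counts
as passing (exclusive binders are the strongest candidates, not missing
data); bait-absent replicates never pass. A protein is called enriched when
at least 2 replicates pass at fold ≥ 5 (inclusive, per "at least five-fold").
No imputation and no cross-run normalization are applied — adding either
would change calls in ways the simple filter cannot justify. Overlap
reporting against reference lists compares gene symbols case-insensitively
after an optional identifier mapping.

## ΔΔCt and RIP

Amplification efficiency is fixed at 2 (100%); no standard-curve correction.
Replicates are aggregated on the log scale: fold = 2^(−mean ΔΔCt), i.e. the
geometric mean of per-replicate folds, with SEM of per-replicate log2 folds
as the error estimate. Log-scale aggregation is the self-consistent choice
for a ratio quantity (it makes Fold(A vs B)·Fold(B vs A) = 1 exactly and
makes plate shifts cancel identically); linear averaging of folds would bias
upward. Significance is a two-tailed paired t-test on per-replicate ΔCt pairs
at α = 0.1 (configurable). With fewer than 2 paired replicates, or zero
variance (noiseless synthetic data), the fold is still reported and the
p-value is marked unavailable with a note. RIP enrichment applies the same
machinery to elution-minus-input Ct differences of the specific antibody
versus control beads.

## Synthetic data

Every generator takes an explicit seed and draws from its own
`numpy.random.default_rng` stream; identical arguments and seed give
byte-identical output, and zero noise/jitter gives exact model values, so
every downstream estimator can be checked for exact recovery before any
noise is added.

- **Titrations** evaluate the depletion model and add Gaussian anisotropy
  noise (default study condition: R_t = 7.1 µM, plateaus 0.05/0.20, noise SD
  0.002, 12 points to 400 µM — a realistic anisotropy-instrument noise floor
  of ~1% of the binding amplitude).
- **Peak lists** draw free-state shifts uniformly over the amide region
  (¹H 7.5–9.5 ppm, ¹⁵N 105–130 ppm) and shift planted residues by exact
  deltas; optional per-nucleus noise models assignment scatter.
- **Ensembles** jitter a synthetic helix-like backbone trace (N, CA, C, O,
  CB per residue) with i.i.d. Gaussian displacements, then apply a random
  rigid motion per model so superposition is genuinely exercised. A 0.4–0.5 Å
  per-coordinate jitter yields mean pairwise RMSDs near 1 Å, the scale of a
  well-defined NMR ensemble.
- **Genomes** are i.i.d. uniform ACGT with non-overlapping features placed at
  full window clearance; the motif is planted at an exact oriented offset
  downstream of each 3′ end, and accidental background copies inside any
  scored window are resampled away so construction-based counts are exact.
  This deliberately removes the compositional structure of real genomes
  (GC skew, repeats, chromatin-shaped base composition): passing tests show
  the counting and strand logic is exact, not that real snRNA flanks are
  U-rich.
- **Quantification tables** give planted-enriched proteins bait/control
  ratios drawn from the configured fold range in every replicate and
  background proteins ratios in [0.5, 2]; control-side dropout is applied
  only to planted-enriched proteins, because dropping background controls
  would make them spuriously EXCLUSIVE and no filter could then recover the
  planted set exactly — real data do lose background controls, which is why
  the exclusive rule is a judgement call there.
- **Ct tables** satisfy Ct = baseline − log2(expression) + noise with the
  reference gene flat across conditions; the RIP variant plants a log2
  enrichment in the antibody elution.

The generators emit reduced data (tables, peak lists, coordinates), not raw
spectra, chromatograms or reads; upstream processing artifacts (baseline
drift, misassignment, peptide-identification bias) are out of scope.

## Pipeline

Stages run in a fixed order from a YAML config; each stage either reads the
given paths or simulates its inputs. Per-stage seeds are the global seed plus
a fixed stage offset, so adding or removing a stage never reshuffles the
randomness of the others. Outputs are recorded with SHA-256 checksums and a
rerun with the same config reproduces them exactly. The demo configuration
exercises every stage at the default study conditions in a few seconds.

## Problem sizes and numerical choices

The test suite and the acceptance script run the study conditions at sizes a
laptop handles in seconds: 50 titrations of 12 points for the Kd sweep;
90-residue peak lists; 10–20-model ensembles of 10–30 residues; toy genomes
of 30–80 kb with 3–20 features; 300-protein tables over 3 replicates; 3–4
qPCR replicates. Closed-form quantities are asserted to 1e-9–1e-15;
stochastic recoveries use the t-based intervals of their own replicate
spread. Known limitation: for true K_d well above the highest titration
point (here 400 µM), the relative K_d standard error grows to tens of
percent and single noisy titrations cannot pin K_d to 10% — the fit still
matches an exhaustive grid-search oracle, and such experiments are the
reason weak binders are reported as censored bounds rather than point
estimates.
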