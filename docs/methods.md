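# Methods

## Scope and model

`dsrisk` covers the computational half of a Tier-I dietary risk assessment
of an insecticidal dsRNA for a non-target soil arthropod: sequence-level
screening (how much contiguous identity does a surrogate species share with
the dsRNA?), worst-case exposure arithmetic (how does the tested dose
compare with field concentrations?), and the statistics of the supporting
assays (qPCR expression dynamics, dsRNA stability, life-history
endpoints). Wet-lab procedure, phylogenetics and transcriptome-wide
off-target scanning are out of scope; inputs are explicit sequence pairs,
Ct tables and replicate-level endpoint tables.

## Sequence identity and window selection

"Similarity" between two sequences is defined as the identical-column
fraction of their pairwise global alignment. Because that quantity depends
on the denominator, two modes exist:

- `all_columns` (default): every alignment column counts; gap columns are
  mismatches. This reproduces conventional whole-alignment identity.
- `exclude_terminal_gaps`: only columns between the first and last column
  where both rows are non-gap. Appropriate when one cDNA carries long
  RACE-derived UTR overhangs that would dilute ORF-level identity.

Window profiles are anchored in the *pest* reference's ungapped
coordinates: the designed dsRNA is a contiguous fragment of the pest
transcript, so each candidate window is a run of `window_length`
(default 400) consecutive pest bases, scored over its full alignment span
with surrogate gaps counted as mismatches. Region selection aggregates
per-species window identities by `mean` (default) or `min` (a conservative
worst-surrogate design); ties break to the smallest start. The ambiguity
code `N` never matches anything, including itself, in either identity or
run scanning — conservative for a risk screen.

Alignment is global with affine gaps via Biopython's `PairwiseAligner`
(match +2, mismatch −3, gap open −5, gap extend −2; NCBI-like nucleotide
defaults, configurable). Externally computed pairwise alignments (aligned
FASTA or Clustal) can be ingested instead, since practitioners often align
with a standalone tool.

## N-mer matching

A match run is a maximal stretch of alignment columns where both rows are
non-gap and identical. Counting an "N-mer" is ambiguous between two
semantics, and both are implemented:

- `maximal_runs` (default): number of runs of length ≥ N. This matches
  match-table listings of discrete runs with start/end coordinates, and
  published count profiles that decrease slowly with N.
- `sliding_windows`: Σ (L − N + 1) over runs with L ≥ N, i.e. every
  distinct N-nt window.

Counts are non-increasing in N in both modes, and sliding-window counts
dominate maximal-run counts; both facts are property-tested. Restricting
counting to a sub-region (e.g. the selected 400-nt window) truncates runs
at the region borders: a run straddling the boundary contributes only its
in-window portion. The screening predicate is "at least one run ≥ 21 nt",
the canonical contiguous-match trigger criterion for cross-species RNAi.

## Exposure arithmetic

Per-capita consumption is (dsRNA concentration in diet, μg/μg) × (diet
mass per feeding, μg) × (number of feedings) / (individuals per
container). With the published regimen values (0.83, 1.65, 14, 10) this
bracket evaluates to 1.9173 μg, whereas the figure reported alongside it
is 2.31 μg; the discrepancy is not resolvable from the printed numbers, so
the module computes from the regimen by default and accepts an explicit
override, flagging the source (`regimen`/`override`) in the report
provenance. Tissue margins use the reported 2.31 μg as an override.

A tissue fold margin is round_half_away_from_zero(consumption in ng ÷ EEC
in ng/g). Half-away-from-zero (not banker's) rounding is required for the
half-integer boundary cases such as 2310/0.224 = 10312.5 → 10313. The
quantity's units (grams of tissue equivalent) are stated in report
metadata. The LC50 margin is a plain unrounded ratio; the LC50 is a
config input, not a constant. The regulatory 10-fold assessment factor is
*not* applied to any output.

## qPCR

Standard curves are ordinary least squares of mean Ct on log10 template
amount; efficiency = 10^(−1/slope) − 1, so slope −1/log10(2) ≈ −3.3219 is
100%. Efficiency is reported for QC only; expression uses plain Livak
2^−ΔΔCt (no efficiency correction).

Technical replicates are averaged (arithmetic mean of Ct) before
biological-replicate statistics. Per biological replicate,
ΔCt = Ct_target − Ct_reference and ΔΔCt = ΔCt − mean ΔCt of the calibrator
condition. A condition's reported fold is 2^−(mean ΔΔCt) — the geometric
mean of per-replicate folds — which makes the calibrator's own fold
exactly 1 by construction; the arithmetic mean of per-replicate folds
would exceed 1 under noise (Jensen's inequality). The SE is computed
across the per-replicate folds on the 2^−ΔΔCt scale, matching how
mean ± SE fold changes are conventionally plotted. Reference-gene
stability is summarised (per-condition mean/SD, overall CV) without an
automatic accept/reject.

## Endpoint statistics

One-way ANOVA uses the classical SS decomposition (needed anyway for the
pooled MSE that Fisher's LSD reuses); it is cross-checked against
`scipy.stats.f_oneway` in the tests. Two-way ANOVA (treatment × day) is
fitted by OLS through statsmodels; balanced designs use the sequential
decomposition, unbalanced data fall back to Type II sums of squares. A
4 × 3 grid with 3 replicates per cell yields the df structure (3,24),
(2,24), (6,24) for treatment, day and interaction. Proportion endpoints
(survival, hatch rate) are analysed untransformed by default; an
arcsine-square-root transform is available but off.

Kruskal–Wallis H is computed from mid-ranks with the tie-correction factor
1 − Σ(t³−t)/(n³−n) applied by default (the behaviour of mainstream
statistical packages); the uncorrected statistic is available via a flag.
LSD post hoc p-values are deliberately unadjusted for multiplicity — that
is what the test means — and say so in the output schema. Tail functions
delegate to scipy's `chi2.sf`/`f.sf`. p-values are full precision in
machine output; display rounding to 3 decimals is the caller's concern.

## Synthetic data

The generators are pure functions of (spec, seed); every consumer seeds
explicitly.

**Homolog pairs.** Sequence B derives from A by per-site substitution at
rate 1 − background identity outside planted runs (substitutions always
differ from A); inside planted runs B = A; the single flanking position on
each side of a planted run is forced to mismatch so the planted lengths
are exactly the ground-truth maximal run lengths (otherwise chance
identity could extend a run and break exact-recovery tests). Pairs are
emitted substitution-only, hence pre-aligned gap-free; an indel mode
exists to exercise the aligner but carries no run ground truth. Recovery
tests use background identity ≤ 0.3, where the chance of a spurious ≥19-nt
background run is negligible (≈0.3¹⁹ per position); note that *re-aligning*
a low-identity pair with the global aligner can legitimately produce an
alignment that differs from the generative one, so exact-recovery claims
apply to the generative (gap-free) alignment.

**Life history.** Survival is Binomial(individuals, p)/individuals per
replicate cohort; development time and body length are Gaussian; fecundity
is negative binomial (gamma–Poisson); hatch rate is a binomial fraction of
eggs laid. Defaults (14 replicates × 10 individuals, survival p 0.95,
development 20 ± 1.5 d with a −1.5 d shift for the two active dsRNAs, body
length 1.6 ± 0.1 mm, fecundity mean 100, hatch p 0.85, arsenate positive
control all dead by day 8) are chosen as plausible magnitudes for a
28-day collembolan assay; they are config defaults, not measurements. What
the generator does *not* emulate: correlated endpoints within a replicate,
time-resolved mortality, density effects — so passing tests demonstrate
the statistics pipeline, not biological realism.

**Ct tables.** The reference gene is i.i.d. around its baseline across all
conditions (a stable reference by construction); the target adds a
per-treatment ΔCt shift (default 0, a null experiment) plus biological
(default SD 0.2) and technical (SD 0.1) Gaussian noise, on a grid of 4
treatments × 3 days plus an untreated day-0 calibrator, 3 biological × 3
technical replicates.

**Degradation series.** Exponential decay 2^(−t/half-life) plus Gaussian
noise floored at 0; an infinite half-life gives the stable-diet scenario.

## Numerical and design choices

- Coordinates in all reports are 1-based inclusive, each sequence in its
  own ungapped frame.
- U folds to T on input; residues outside {A,C,G,T,U,N} are errors naming
  the record and position.
- Window profiling is O(columns) via cumulative sums; it is verified
  against a quadratic brute-force rescorer.
- Ties in region selection break to the smallest start (deterministic
  reports); CLI runs with fixed seed and inputs are byte-identical.
- Monte-Carlo calibration checks use 2000 null simulations for the type-I
  error of one-way ANOVA and Kruskal–Wallis (expected within 0.05 ± 0.01),
  100 seeded pairs for N-mer ground-truth recovery, 200 random gapped
  alignments (≤ 2 kb) for oracle equivalence, 50 seeds for 400-nt window
  recovery, and 10 simulated qPCR experiments averaged for knockdown
  recovery; these sizes keep the default suite fast while leaving the
  Monte-Carlo standard errors well inside the asserted bands.

## Limitations

- Published whole-ORF identity or N-mer count figures for a specific
  pest/surrogate transcript pair can only be reproduced when those
  sequences are supplied; the suite substitutes seeded synthetic pairs
  with exact ground truth.
- No thermodynamic or seed-region siRNA scoring, no transcriptome-wide
  scanning, no environmental-fate or probabilistic exposure modelling, no
  survival-time (Kaplan–Meier/Cox) analysis.
- The Livak model assumes ~100% amplification efficiency for both genes;
  an efficiency-corrected mode is not implemented.
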