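# Methods

This note records the models implemented in `regulonml`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Promoters and coordinates

All coordinates are 0-based, half-open internally; GFF3 (1-based closed)
and BED (0-based half-open) are converted at the I/O boundary.  A promoter
is a fixed window of `upstream + downstream` bases around a transcription
start site (TSS), default 150 bp upstream and 50 bp downstream (200 bp
total), stored in the direction of transcription with the TSS base at index
`upstream` — i.e. the TSS base is counted in the downstream segment.  That
off-by-one convention is a declared choice: a fixed 200 bp window keeps all
feature blocks aligned.  Minus-strand promoters store the reverse
complement of `genome[tss − downstream + 1, tss + upstream + 1)`.  N bases
are allowed in genomes; promoters containing N are flagged, motif scoring
treats N as background (log-odds 0), and shape prediction rejects N (no
concrete pentamer exists).

## Motif scoring

A PSSM stores per-position log-odds in bits.  From aligned sites,
per-position probabilities are `(count + c·q_b) / (n + c)` with pseudocount
mass `c` (default 0.5) split by the background `q`; from a
letter-probability matrix, rows are smoothed as `(p + c·q) / (1 + c)`.
Log base 2 throughout so scores read as bits.  The motif score of a
promoter is the maximum window sum of log-odds; the implementation is a
vectorized sliding-window maximum and is tested for exact agreement with
brute-force enumeration over all windows and strands.  Defaults: scan both
strands with forward preference on ties (many bacterial TF sites are
palindromic; strand handling is otherwise underdetermined), leftmost window
on score ties.  Scores are not length-normalized across motifs; columns are
z-standardized during feature assembly instead.

Direct-repeat (DR-k) matrices concatenate a unit letter-probability matrix
k times with uniform gap columns (default gap 0 bp, configurable); uniform
columns contribute exactly 0 to every window score, so the repeats alone
carry the signal.  The DR site-calling cutoff is the mean scan score of
confirmed sites.

## Sigma-factor architecture

Placement is greedy and two-stage: the −10 box is the best forward-strand
window fully inside the 20 bp upstream of the TSS; the −35 box is the best
window inside the 40 bp upstream of the *placed −10 box* (not the TSS).
Anchoring the −35 search to the −10 box guarantees the −35 lies strictly
upstream and the spacer is non-negative; the alternative TSS anchor would
allow overlapping boxes.  Promoters are already transcription-oriented, so
sigma boxes are searched forward-strand only.  The feature block per sigma
factor is: −10/−35 scores, Hamming distances of the placed boxes to each
matrix's consensus, box distances to the TSS, spacer length, the maximum AT
fraction over 7 bp windows in the spacer (whole-spacer fraction if shorter
than 7, 0 if empty), and the AT fraction of the 4 bases immediately
upstream of the −10 box (the TG-extension region; reported missing, not 0,
when the sequence runs out).  Six sigma factors are configured by default
(70, 38, 32, 24, 54, 28) with soft-consensus default matrices built from
canonical textbook hexamers (85% consensus-base probability); users supply
alignment-derived matrices for real analyses.

## DNA shape

Shape parameters are looked up per pentamer.  Intra-base-pair parameters
(MGW, ProT, Buckle, Shear, Stretch, Stagger, Opening) assign each
pentamer's value to its central base; inter-base-pair parameters (Roll,
HelT, Shift, Slide, Rise, Tilt) assign it to the two central base-pair
steps, and steps covered by two adjacent pentamers are averaged.  Boundary
positions without full pentamer coverage are excluded rather than padded,
so an L-mer yields vectors of length L−4 (intra) and L−3 (inter) and
summaries are computed over fully supported positions only.  At a matched
binding site the window is the hit extended by a configurable flank plus
2 bp of context each side; sites within 2 bp of the promoter edge yield a
missing block (imputed later).  Each site contributes 13 parameters × 4
summaries (max, min, range, mean) = 52 features.  Profiles are computed on
the transcription-direction strand; no reverse-complement symmetry is
assumed.  The bundled table generator draws values uniformly within
parameter-plausible ranges (e.g. MGW 2.8–6.2 Å, HelT 30–40°); it carries
the format and statistical role of a published pentamer table, not its
physics, which is irrelevant to the correctness properties tested.

## Feature assembly

Per promoter: every TF/ICA/DR motif is scanned over [−150, +50) of the TSS
(score and hit distance recorded); sigma blocks are computed; shape blocks
are computed at each TF's best hit; strand direction (±1) is added.
Dimensionality reduction uses two-class LDA with diagonal shrinkage:
`w ∝ (Σ_w + s·diag(Σ_w))⁻¹ (μ₁ − μ₀)`, unit-norm, oriented so the positive
class projects higher; shrinkage defaults to 0.1 so the small-positive-class
regime and duplicated columns stay solvable.  The per-sigma LDA is fitted
against a sigmulon of the same name when one is supplied; otherwise the raw
sigma features are retained (the synthetic demo exercises this path).  The
per-TF shape LDA is fitted against the TF's regulon.  Missing values are
imputed by column median, all-constant columns are dropped with a warning,
and columns are z-standardized; imputation never alters observed values.

LDA projections fitted on the full dataset leak label information into the
features and inflate cross-validation estimates.  This mirrors how such
engineered features are commonly built, and the caveat is deliberate: a
strict mode (`ClassifierConfig(strict_lda=True)`) refits imputation,
standardization and every LDA block inside each training fold instead.

## Classification

Elastic-net logistic regression (scikit-learn saga solver, L1 ratio 0.5,
inverse regularization strength C = 1.0 — the conventional default; both
exposed in `ClassifierConfig`).  Cross-validation is stratified 5-fold with
promoter grouping: genes sharing a promoter (one TU) never straddle a fold
boundary; grouping is inviolable and stratification best-effort.  Regulons
with 2–4 positive promoters are handled by random-oversampling positives to
five and using as many folds as positive promoters; with fewer than 2
positives the regulon is reported data-limited, never silently skipped.
Class imbalance is corrected by SMOTE (synthetic minority points
`x + λ(x_nn − x)`, λ ~ U(0,1), among k = 5 minority nearest neighbors, to
exact balance) followed by Tomek-link cleaning (the majority member of
every mutual cross-class nearest-neighbor pair is removed).  Resampling is
applied inside training folds by default; pre-split resampling leaks
synthetic points into test folds, so it is available only behind
`resample_before_split=True` for comparability with protocols that resample before
splitting.  A singleton minority class falls back to duplication with a
warning.  AUROC is computed by the rank-sum identity U/(n₊n₋) with
half-credit ties; the 0.8 cutoff defines a good model.  SHAP values for the
linear model are exact on the log-odds scale, `φ_ij = w_j (x_ij − x̄_j)`
with the column means as background; rows satisfy the efficiency identity
to 1e-9 by construction, top-5 ties break lexicographically.

## Pan-regulons and expression

TUs map across strains by exact substring search on both strands (≥ 20 bp
guard against chance matches; palindromic hits counted once; multi-hit TUs
marked ambiguous and excluded).  Partition: core = present/regulated in all
strains, unique = exactly one, accessory = the rest; the three classes
always form a disjoint cover (asserted).  ChIP S/N grouping uses a cutoff
of 10 with the boundary assigned to the high group.  Expression change is
`log2((tpm_exp + 1)/(tpm_ctrl + 1))` (base and pseudocount are declared
choices).  Score–response association uses Spearman rank correlation with
tie-corrected p; constant inputs report an undefined correlation rather
than a number.

## Synthetic generators

The generators define the study conditions; all are pure functions of
(config, seed).  Defaults: 500 promoters (200 bp), 40 positives, one
planted 10 bp site per positive sampled from a PWM of 12 bits total
information, planted uniformly in [−100, −20) of the TSS; i.i.d. background
with GC fraction 0.5 (matching the uniform-background PSSM scoring); no
label noise (label flips, when requested, happen after planting, modelling
regulon mis-assignment); 70/20/10% of TUs carry 1/2/3 genes, giving the
group structure the CV contract needs.  PWM columns concentrate probability
on a random consensus base so each column hits the per-column information
target (bisection on the column entropy); requests outside [0, 2·length]
bits are rejected.

Strain families embed 12 TUs of 80 bp into 4 strains (both configurable)
with fractions 0.4/0.3/0.3 core/accessory/unique; with two strains the
accessory class is impossible and folds into core.  Core TUs carry the
planted consensus, accessory TUs PWM samples, unique TUs samples from an
information-degraded PWM (factor 0.35), producing the designed
core > accessory > unique site-strength gradient.  Genomes are background
with 60 bp spacers between embedded TUs; embedding uniqueness is verified
on both strands and rebuilt on collision (bounded retries).  Expression
responses are `slope · z(score) + N(0, noise_sd)` with default noise SD
0.5.

What the generators do *not* emulate: real base composition and
oligonucleotide correlation structure of any genome, multiple or
overlapping binding sites per promoter (multi-site planting exists but is
off by default), operonic read-through, condition-dependent regulon
activity, and physical shape values.  Passing tests therefore demonstrate
the correctness and statistical behavior of the machinery under controlled
signal, not performance on real regulons.

## Problem sizes and numerics

Tests and the acceptance script run the reference conditions above (n=500
promoters; 4-strain families of 12 TUs; 1000 scanner-oracle and 200
AUROC-oracle instances), sizes chosen so the full suite completes in well
under a minute per property while keeping the statistical checks
well-powered.  Tolerances: probability rows must sum to 1 within 1e-4 on
parse (1e-9 internally); LDA closed-form agreement to 1e-2 relative; SHAP
efficiency to 1e-9; scanner and AUROC oracles exact.  Degenerate inputs
(empty vectors, single-class labels, constant columns, empty spacers,
windows off the sequence end) raise or report missing values explicitly —
never a silent 0.

## Known limitations

- Sigma default matrices are soft consensus hexamers, not alignment-derived
  position weights; real analyses should supply measured matrices.
- The full-dataset LDA leakage described above is the default for
  comparability; strict mode is slower and changes feature values.
- Exact TU mapping cannot recover TUs with any cross-strain variation; that
  is inherent to the exact-match design, which trades recall for zero
  false orthology.
- The elastic-net solver's regularization path is not tuned; strength is a
  fixed conventional default.
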