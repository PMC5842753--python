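# Methods

`epiconnect` implements a spike-free EEG classification analysis for temporal
lobe epilepsy (TLE) as a fully synthetic, testable pipeline: simulate
source-space regional time series for three groups (healthy controls, left
TLE, right TLE), estimate directed functional connectivity with the weighted
partial directed coherence (wPDC), select a small set of discriminative
connections with balanced-random-forest permutation importance, quantify
pairwise feature interactions, and evaluate a sequential two-stage classifier
(diagnose, then lateralize) in leave-one-out cross-validation (LOOCV).

The clinical study this emulates worked on electrical-source-imaging time
courses of real patients, which cannot be shared.  The synthetic cohort
substitutes a multivariate autoregressive (MVAR) ground truth because PDC is
*exactly* defined on an MVAR process: every downstream stage can be checked
against a known answer (analytic PDC, planted group differences), which is
what the test suite and `scripts/acceptance.py` do.

## Synthetic cohort generator

Each subject's 14 regional signals (left/right hippocampus Hipp, amygdala
Amyg, parahippocampus PHipp, anterior/posterior cingulate ACC/PCC, olfactory
cortex Olf, medial temporal pole TPMid) follow a stable MVAR process

    x_t = A_1 x_{t-1} + ... + A_p x_{t-p} + e_t,   e_t ~ N(0, Sigma),

with per-region AR(2) oscillator diagonals (pole modulus 0.65, resonant
frequency drawn once per region from 4–25 Hz so that the theta, alpha and
beta bands all carry structure) and lag-1 directed couplings of strength
0.25 along a curated limbic edge list (Hipp -> Amyg/PHipp/ACC/TPMid,
ACC -> Amyg/PCC/Olf, PHipp -> TPMid, PCC -> Olf, instantiated in both
hemispheres).

Three design choices matter and are deliberate:

* **The edge set is acyclic.**  Cyclic lag-1 coupling between slow,
  near-real-pole oscillators amplifies non-normally: two mutually coupled
  oscillators with pole modulus 0.6 and coupling 0.2 are already unstable.
  A feedforward graph leaves the companion eigenvalues exactly at the
  oscillator poles, so couplings can be strong (hence estimable from 1-s
  epochs) without threatening stationarity.  A stability guard (companion
  spectral radius < 0.95, geometric shrinkage of couplings with a bounded
  number of attempts) remains for user-supplied networks.
* **Innovation variances are equalized** on the effect-free base (iterative
  Lyapunov solve, floor 0.05) so stationary channel power is comparable
  across regions, as it is for source-projected EEG.  Without this,
  downstream regions accumulate power multiplicatively and the sender-power
  weights of the wPDC (below) collapse for upstream regions.
* **Pathology is a partial outflow loss.**  The patient groups reduce the
  coefficients of a designated subset of hippocampal and ACC outflow
  projections (Hipp -> Amyg, Hipp -> ACC, ACC -> Amyg, ACC -> PCC) by the
  fraction `effect_size` on the ipsilateral side, and by
  `contralateral_fraction x effect_size` (default 0.5) on the contralateral
  side — bilateral network alteration with ipsilateral predominance, as
  described for TLE.  The two patient templates are exact mirror images.
  Reducing a *subset* of a sender's projections matters: PDC is normalized
  over the sender's outgoing column, so scaling the whole column largely
  cancels in the ratio near the sender's resonance.

Inter-subject variability is i.i.d. Gaussian jitter (sd 0.025, i.e. 10% of
the base coupling) on the nonzero coefficients only — the sparsity pattern is
population-constant — redrawn until the jittered model is stable.  Epochs are
simulated independently with a discarded burn-in of 10 x order samples, and
white observation noise (sd 0.1, about 1% of signal variance) is added.
Defaults mirror the study design: 35/20/20 subjects, 60 epochs of 1 s at
250 Hz.  A JSON manifest records every parameter and per-subject seed;
`cohort_from_manifest` reproduces the arrays bit-for-bit.

What the generator does *not* emulate: volume conduction / source leakage,
non-stationarity within or across epochs, artefacts, heterogeneous epilepsy
phenotypes, or any anatomical specificity of the 14 regions beyond their
labels.  Passing tests therefore demonstrate that the *pipeline* recovers
planted directed effects at realistic sample sizes and noise levels — not
that real TLE patients would be classified at these accuracies.

## Connectivity estimation

Per epoch, an MVAR model is fitted by ordinary least squares (each channel
regressed on p lags of all channels, no intercept; default p = 5 at 250 Hz,
i.e. 20 ms of history; AIC/BIC order selection is available and, when used,
is run on the subject's first epoch and reused for all epochs so features
stay comparable).  The spectral transfer quantity is

    Abar(f) = I - sum_r A_r exp(-i 2 pi f r / fs)

and the partial directed coherence from sender j to receiver i

    PDC(i<-j, f) = |Abar(f)_ij| / sqrt(sum_k |Abar(f)_kj|^2),

the standard sender-column-normalized form, so sum_i PDC(i<-j, f)^2 = 1
identically (asserted to 1e-9 in the tests).  The weighted variant multiplies
each sender column by the sender's mean-square amplitude in the epoch,
max-normalized within the epoch (weights in (0, 1], at least one exactly 1).
The exact weighting of the original method is not published in its main text;
sender-power weighting is this package's documented, configurable choice
(`weighted=False` gives plain PDC).  PDC magnitudes (not squares) are
averaged: across the 60 epochs on a 1-Hz grid (1–30 Hz), then within
theta = [4, 8), alpha = [8, 12), beta = [12, 30) Hz.  Closed-open intervals
assign shared edges (8, 12 Hz) to exactly one band.  Diagonal (self) terms
are retained throughout; the 14-region grid hence yields 14 x 14 x 3 = 588
named features (`band:SENDER->RECEIVER`), and an 82-region grid would yield
20,172.

## Balanced random forest

Both classifiers are forests of sklearn decision trees; every tree is grown
on a *balanced* bootstrap (an equal-count with-replacement resample from the
two classes, size 2 x the minority count), splits are chosen among
floor(log2 M) randomly drawn features, and prediction is by majority vote
with ties resolved toward the positive class (TLE for diagnosis, LTLE for
lateralization).  Default 1000 trees.  Out-of-bag (OOB) machinery drives
selection: a subject's OOB trees are those whose bootstrap omitted it.

**Permutation importance** is the loss of OOB accuracy when a feature's
column is permuted, with two flavours:

* `per_tree` (default; the classical randomForest measure): the drop is
  measured per tree on the tree's own OOB subjects and averaged over all
  trees.  This is the flavour the pipeline uses, because band-wPDC features
  carry heavily redundant signal and the ensemble majority vote barely moves
  when one of them is permuted.
* `ensemble`: the drop of the forest-level OOB vote accuracy.  On our
  cohorts this saturates to ~0 for every feature even at 97% OOB accuracy;
  it is retained for non-redundant settings and for its clean
  "importance = accuracy − chance" reading on a single decisive feature.

Importances are reported on the x 10^-2 scale.  A feature is *significantly*
important when its mean drop over the permutation repeats exceeds
z_(1-alpha) times the standard deviation of the repeats (one-sided,
alpha = 0.05, default 50 repeats).  Using the sd rather than the standard
error of the mean is deliberate: with the SE, any dataset-level chance
correlation becomes "significant" as repeats accumulate, and the empirical
type-I rate of screening under shuffled labels is inflated; with the sd rule
it measured 3.5% at nominal 5% (50 replicates).  A t-test variant
(`significance="ttest"`) is available.

## Feature selection

Two steps, rerun from scratch inside every LOOCV fold:

1. **Screening**: drop features whose importance is not significantly above
   zero (order preserved).  If nothing survives — an uninformative table —
   the single most important feature is carried forward so a classifier can
   still be trained.
2. **Minimal subset**: rank the survivors by mean importance (ties broken
   lexicographically by name), remove redundant information — walking the
   ranking, a candidate whose absolute Pearson correlation with an
   already-kept feature exceeds 0.8 is skipped — then evaluate the OOB error
   of the top-k prefixes for k = 1..cap and select the *smallest* prefix
   whose error is within `tol_se` (default 1) binomial standard errors of
   the best prefix error.  The cap is one feature per ten subjects —
   floor(n/10) computed on the cohort entering the cross-validation (7 for
   75 subjects, 4 for 40) and held fixed across folds.

The redundancy filter is essential with band-resolved connectivity features:
the top importance ranks are typically near-collinear variants of the same
edges (|r| > 0.9 across bands and neighbouring connections), and without the
filter the capped prefix is spent on copies of one signal — on our cohorts
the prefix OOB error then plateaus far above what the full table supports,
while with the filter it reaches the full-table error within 3–5 features.
The one-standard-error prefix rule is the package's reading of "the minimal
subset that contains the maximum amount of discriminant information": a
duplicated feature is removed by the filter, while a jointly-decisive pair
(e.g. an XOR pair, each member useless alone) is uncorrelated, survives the
filter, and is admitted because the error only drops once both members are
in the prefix.  A stepwise rule that requires every single added feature to
reduce the error would reject both members of such a pair.

Each selected feature is accompanied by a two-sided Mann-Whitney-Wilcoxon
p-value (exact U distribution when both classes have at most 20 subjects and
no ties; tie-corrected normal approximation otherwise).  Selected features
can be individually non-significant yet jointly decisive — which is the point
of the interaction analysis.

## Interaction effects

The interaction effect of feature f1 on f2 is the change in f2's permutation
importance when f1 is removed from the design by permuting its values.  Both
importances are measured within one fitted forest; the conditional one is
evaluated on data in which f1's column is held permuted (averaged over 20
permutations of f1, 5 importance repeats each; no refit).  Negative entries
mean f2's information is only usable while f1 is intact — on an XOR pair the
off-diagonal entries are about minus the full baseline importance.  Refitting
the forest without f1 was considered and rejected: it measures redundancy
competition (two features carrying the same signal show a large spurious
"interaction" because the refitted forest leans entirely on the survivor),
not joint information.  The diagonal is fixed at 0.

## Classification and evaluation

The clinical decision sequence is two two-class classifiers applied in
order: diagnosis (TLE vs controls, positive class TLE) and — only for
subjects diagnosed as TLE — lateralization (LTLE vs RTLE, positive class
LTLE).  All reported metrics come from LOOCV in which the held-out subject
never influences its fold's screening, subset selection or training.  For
patient folds the sequential system reuses the standalone lateralization
LOOCV model of that fold; for control folds the lateralization stage is a
single model trained on all patients (no patient is ever held out of it by a
control fold).  The metric panel reports accuracy, sensitivity, specificity,
PPV, NPV (percent, rounded to one decimal at the reporting layer only) and
the AUC of the positive-class vote fraction pooled over folds.  Collapsing
the LTLE/RTLE rows and columns of the three-class confusion matrix
reproduces the diagnosis-stage 2 x 2 matrix exactly, by construction.

## Problem sizes and reproducibility

Routine runs (the analysis scripts, the acceptance script, the end-to-end
test) use the `scaled_config` preset: the cohort at full study scale
(35/20/20 subjects, 60 x 1-s epochs, 14 regions, effect size 0.8) but
300-tree forests, 6 screening repeats per fold and 10 interaction
permutations, which keeps a complete
75-fold LOOCV with per-fold selection to a few minutes on one core; the
library defaults remain 1000 trees and 50 repeats.  All randomness descends
from one master seed (per-stage and per-fold seeds are spawned
deterministically), so a rerun of any config reproduces every artifact
byte-for-byte; cohort manifests additionally record every per-subject seed.

## Known limitations

* The wPDC weighting and the importance-significance rule are documented
  package choices where the original method's exact recipe is not public.
* Single-feature permutation importance under-ranks features whose signal is
  widely duplicated; the per-tree flavour mitigates but does not remove this.
* The prefix selection cannot skip a redundant high-importance feature in
  favour of a complementary lower-ranked one.
* Only first-order (pairwise) interactions are computed.
* Synthetic accuracies say nothing quantitative about clinical performance;
  see the generator's non-goals above.
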