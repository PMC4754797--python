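# Methods

`naccsubtypes` reimplements an unsupervised brain-subtyping-and-symptom-
association analysis for monetary incentive delay (MID) fMRI studies of
depression, end to end, on synthetic data.  This note documents the models,
the generator, the numerical choices, and the limits of what the passing
tests demonstrate.

## The analysis in outline

Each subject contributes a 4-dimensional *response pattern* per nucleus
accumbens (NAcc) ROI and task phase: the GLM betas of the four monetary
conditions (−$1.0, −$0.25, +$0.25, +$1.0) each contrasted with the
non-monetary $0 condition.  The pipeline

1. simulates a cohort (45 HC / 44 MDD by default) with latent response
   subtypes, MID task runs, ROI BOLD series and item-level symptom scores;
2. recovers the response patterns by GLM from the simulated BOLD;
3. describes their variation by PCA and clusters subjects with Ward's
   method, choosing the number of clusters with a mixed-model/BIC rule;
4. tests subtype/condition/diagnosis effects in a random-intercept linear
   mixed model (LMM) with containment degrees of freedom and Tukey
   post-hocs;
5. relates the subtypes to 59 symptom items (21 HAM-D, 14 HAM-A, 10 MADRS,
   14 SHAPS scored 1–4) in the MDD subgroup by shrinkage discriminant
   analysis (SDA) with cat-score recursive feature elimination (RFE),
   followed by per-item confirmatory models.

## Synthetic-data generator

The generator defines the study conditions; everything downstream is tested
against what it plants.

**Subtypes.** Default right-ROI anticipation means (beta units, % signal
change): hyperactive (0.25, 0.25, 0.30, 0.35), intermediate (0, 0, 0.10,
0.15), suppressed (−0.20, −0.20, −0.15, −0.15), mixed 0.30/0.45/0.25.  The
left ROI adds a "deactivated" profile (−0.15, −0.12, −0.10, 0) and uses
0.30/0.35/0.20/0.15.  These magnitudes are calibrated choices that reproduce
the qualitative profile shapes (hyperactive to both valences, gain-biased
intermediate, below-neutral suppressed); no published per-subtype beta
values exist.  Outcome-phase means are analogous small values with the
hyperactive profile reversing sign at loss feedback.  Subject patterns are
subtype mean + i.i.d. N(0, 0.08²) per condition, phases independent.
Subtype assignment is independent of diagnosis by construction.

**The fourth (left-ROI) profile is deliberately subtle** — 0.19 beta units
from the suppressed profile, about 2.4 noise SDs — and the level-selection
machinery merges it into three clusters at default noise.  This is an honest
property of the configuration, not a defect: the separations of the other
profiles are 5–6 noise SDs and are recovered essentially always.

**Symptoms.** Each item score is a latent Gaussian (mean = scale minimum +
10% of the span for HC, 40% for MDD, SD = 25% of the span), shifted by any
planted (item, subtype) effect, rounded and clipped into the scale range.
Defaults plant +1.5 on suicidal ideation (HAM-D) and +1.0 on one SHAPS
anhedonia item for both the hyperactive and suppressed subtypes, so the
intermediate subtype is the least symptomatic on those items.  A
clipped-rounded Gaussian was chosen over an ordinal-logit model: it is
simpler, trivially range-respecting, and sufficient for recovery testing.
Missing values are off by default (`missing_rate`); downstream analyses
reject incomplete rows rather than imputing.

**Task and BOLD.** One session is 75 trials (15 per condition) in seeded
random order; anticipation delay uniform 2.0–2.5 s, target ~0.3 s, feedback
1.5 s, inter-trial jitter 1.5–3.5 s, chosen so a session fits a 272-volume
scan at TR 2 s.  Target duration follows the task's 2-down/1-up staircase in
steps of one 75 Hz frame, floored at one frame; its equilibrium hit
probability p solves p² = 1/2 (≈0.71), close to the nominal two-thirds.
BOLD series are the design matrix (below) times the planted betas plus white
noise (0.1% signal default), embedded in a raw-signal scale of 1000 so the
percent-scaling step is exercised.  What the generator does *not* emulate:
temporally autocorrelated noise, scanner drift beyond what the polynomial
block absorbs, motion artefacts coupled to task events, and
between-condition noise correlation induced by a shared $0 baseline.
Passing tests therefore demonstrate correctness of the machinery under the
stated model, not robustness to real fMRI noise.

## GLM

Task regressors: variable-duration anticipation boxcars per condition,
target-onset and button-press deltas, feedback boxcars per condition split
by hit/miss (5 + 2 + 10).  Nuisance: 6 motion parameters + their first
differences, Legendre polynomial drift of orders 0–4, and a CSF time course
(35 columns in a single session).  Event streams are laid out on a 0.1 s
grid (variable-duration boxcars need sub-TR resolution), convolved with a
canonical double-gamma HRF (gamma shapes 6 and 16, scale 1 s: peak ≈ 5 s,
undershoot ≈ 15 s at 1/6 amplitude, peak normalized to 1), and sampled at
frame midpoints.  The first five pre-task volumes are dropped and onsets
shifted accordingly.  Fitting is OLS; all-zero columns (e.g. a condition
with no misses) are retained in the design but excluded from the fit with a
warning, and a missing required cell makes the corresponding contrast
undefined (the pipeline records it as missing rather than guessing).
Prewhitening is deliberately out of scope.

## Mixed models

The engine fits `y = Xβ + Zb + e` with a single random subject intercept by
profiling the (RE)ML criterion over the variance ratio θ = σ²_subject/σ²_resid
(golden-section search on log θ, compared against the θ = 0 boundary; GLS
and the residual scale are closed-form at each θ).  Fixed-effect designs are
built with patsy using treatment coding; F tests are marginal Wald tests of
each term's coefficients on the full model.

**Degrees of freedom** follow the containment (inner–outer) rule: terms
constant within subject are tested on `n_subjects − p_outer` df, terms
varying within subject on `n_obs − n_subjects − p_inner` df, where the p's
count the corresponding design columns including the intercept.  For the
89-subject × 4-condition group model this gives 79/243 (4 subtypes) and
81/249 (3 subtypes), and 39 for the 44-patient symptom model — the
df this study design prints.  Satterthwaite/Kenward–Roger approximations are
out of scope.

**BIC** is always `−2·ll_ML + k·log(n_obs)` with k = fixed coefficients + 2
variance parameters, computed at the ML optimum even when the reported fit
is REML: REML likelihoods are not comparable across fixed-effect structures,
and the level selection compares models that differ exactly there.

**Tukey post-hocs** compare estimated marginal means (balanced over the
other factors, covariates at their mean) with the studentized-range
distribution at the factor's containment df; with two groups this reduces
exactly to the two-sided t-test.  Families are per factor.

Degenerate inputs: a constant response yields zero variance estimates and
NaN F statistics with a warning; residual variance is floored at 1e-12 in
the likelihood so that noise-free (deterministic) data remain comparable
across models.

## Cluster-level selection

Similarity is the Euclidean distance between response vectors; the tree is
Ward's method in the ward.D2 convention (Lance–Williams update on
distances, as in `scipy.cluster.hierarchy.linkage(..., "ward")`).  PCA is on
mean-centered, unscaled betas (the four columns share units); jackknife SEs
come from the n delete-one refits, leave-one-out principal scores from
projecting each held-out subject on loadings fitted without it,
sign-aligned to the full-data loadings since eigenvector sign is arbitrary.

Choosing the cut level needs care.  Scoring *every* horizontal cut
k = 2..k_max with the significance + minimum-BIC rule is circular: Ward
picks, at each split, precisely the partition maximizing the between-group
sum of squares the mixed model then rewards, so the spurious likelihood gain
from splitting pure noise (≈50 in −2·ll for this design) always beats the
BIC penalty (≈23.5 per extra cluster) and the rule marches to k_max
regardless of the true structure.  The selection therefore runs in two
stages, mirroring pipelines that first extract candidate levels from the
tree itself:

1. **Candidate extraction** (`candidate_levels`): cutting into k clusters
   severs the merge with height h[n−k]; the deepest supported level k* is
   where the ratio h[n−k]/h[n−k−1] over k = 2..k_max is largest, and levels
   2..k* are proposed.  Separated clusters produce a sharp relative height
   drop just below their own level; the criterion is parameter-free given
   k_max (default 8).  At zero noise the ratio is infinite at the true K.
2. **LMM/BIC selection** (`select_optimal_level`): each proposed partition
   is scored by `response ~ cluster + condition + cluster:condition + age +
   gender` with a random subject intercept (diagnosis excluded here — the
   diagnosis terms belong to the post-selection group analysis); among
   levels with a significant cluster main effect (α = 0.05) the minimum-BIC
   level wins.  No significant level returns an explicit no-solution marker.

Known limitation: the largest-gap rule proposes a single deepest level, so
hierarchies with cluster structure at several well-separated scales would
only be explored down to the strongest scale.  And because the cluster
labels are functions of the same responses the LMM scores, the cluster-
effect p-value is descriptive, not a calibrated test — on structureless
data the gate can still pass at whatever shallow level the gap rule happens
to propose.  The no-solution behaviour is guaranteed only for partitions
that are genuinely unrelated to the responses.

## Symptom association

SDA standardizes items by the grand mean and pooled within-class SD and uses
the **pooled within-class** correlation matrix R (class-mean separation must
not leak into the matrix the discriminant inverts), shrunk as
P = (1−λ)R + λI with the analytic intensity
λ = Σ̂Var(r_ij)/Σr_ij² (off-diagonals, clipped to [0,1]) — the standard
variance-minimizing choice when 59 items exceed 44 subjects.  Discriminant
functions are LD_k(z) = μ̃ₖᵀP⁻¹z − ½μ̃ₖᵀP⁻¹μ̃ₖ + log πₖ with empirical
priors; at λ = 0 and ample n this is classical shared-covariance LDA, which
is the oracle the tests compare against.

Cat (correlation-adjusted t) scores are P^(−1/2)tₖ with
t_kj = (μ_kj − μ_j)/(m_k s_j), m_k = √(1/n_k − 1/n); the inverse square
root is by eigendecomposition with eigenvalues floored at 1e-12.  Multi-class
ranking aggregates by the sum of squared cat scores across classes.  RFE
removes the lowest-ranked item per step (ties to the earlier column),
re-ranking on the full data after each removal, while leave-one-out
cross-validation refits only the classifier; the best-accuracy step wins,
earliest (largest) set on ties.  Because the best step is chosen after
seeing all accuracies, the reported best accuracy is optimistic, and the
code says so in a warning.  A fold that reduces a class to a single member
proceeds with that one-subject mean and logs it.

Selected items are correlated (Pearson) with each LD output; the Bonferroni
family is items × classes at α = 0.05.  Flagged items get confirmatory
per-item models `item ~ subtype + age + gender` (one row per subject, so the
mixed model reduces to least squares on containment df), Bonferroni-corrected
over the number of items tested.  The association stage runs on MDD subjects
only; control subjects have little or no variance on these clinical items.

## Pipeline problem sizes and determinism

The default run simulates 89 subjects × 2 sessions × 272 volumes and
finishes in well under a minute on one core; the test suite uses a reduced
cohort (24 subjects, 1 session of 25 trials, 110 volumes) for the
end-to-end checks and standard sizes for the statistical ones.  Every stage
seed derives from the master seed via `numpy.random.SeedSequence`, outputs
are byte-identical across reruns with the same configuration, and each CSV
carries a `# seed=… config=…` comment header.
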