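# Methods

`kinsig` implements a biomarker-discovery pipeline for B-cell malignancies:
genes co-expressed with a panel of B-cell-receptor (BcR) signaling kinases
are screened across many expression studies with a robust correlation, the
resulting signature is evaluated against survival endpoints of a patient
cohort, and candidate markers are followed up with qPCR stage statistics and
drug-combination analysis. Every stage can be exercised end-to-end on
synthetic data with planted ground truth; this note records the models, the
defaults and the design choices.

## Robust correlation screen

Per dataset, the biweight midcorrelation (bicor) between every gene and
every panel kinase is computed. With `m = median(x)` and unscaled
`MAD = median(|x - m|)`:

    u_i = (x_i - m) / (9 MAD)
    a_i = (1 - u_i^2)^2 * 1[|u_i| < 1]
    x~_i = (x_i - m) a_i
    bicor(x, y) = sum(x~ y~) / (||x~|| ||y~||)

This is the standard WGCNA-ecosystem definition; samples more than 9 MADs
from the median get zero weight, which is what makes the estimate robust to
the gross outliers two-channel arrays produce. Numerical choices:

- Missing values are handled by pairwise deletion with a minimum overlap of
  8 complete pairs (robust estimates below that are meaningless; the bound
  is configurable).
- A vector with `MAD = 0` (more than half the values tied) falls back to
  Pearson for that pair and the record is flagged, mirroring the reference
  implementation's documented behaviour.
- The matrix fast path transforms each row once and obtains all
  correlations as one product; it is exactly equal (to machine precision)
  to the scalar routine, which the tests verify.
- Panel kinases are excluded from the candidate gene side, and the panel
  spelling `PI3KCD` is aliased to the HGNC symbol `PIK3CD`.

Consensus selection counts, per (gene, kinase), the datasets where
`|r| >= 0.5` (absolute threshold — both signs count). Stage 1 keeps genes
supported in >= 5 datasets for the anchor kinase (ZAP70) and for at least
one other kinase; stage 2 tightens to >= 2 other kinases. Support is
counted per kinase independently; a stricter "same datasets for anchor and
partner" mode is available (`same_datasets_anchor`) because the plain-text
selection rule is ambiguous on this point. Ranking is by total supporting-
dataset count summed over kinases, descending, ties broken alphabetically.

## Survival evaluation

Cox proportional-hazards models, `h_i(t) = h_0(t) exp(sum_g beta_g x_ig)`,
are fitted with `lifelines` (Efron tie handling — month-resolution survival
data routinely contain ties). The linear predictor is the prognostic index
(PI); cohorts are split into two equal-sized risk groups (+-1 for odd n) by
stable rank on (PI, sample id) — value-thresholding at the median cannot
guarantee equal groups under ties, rank splitting can. The signature HR is
the exponentiated Cox coefficient of the binary high-vs-low indicator with
a Wald 95% CI and a log-rank p, not the PI coefficient itself, matching how
dichotomized Kaplan–Meier analyses are conventionally reported.

Four per-gene analyses are provided for each endpoint (time-to-treatment
and overall survival): individual median-split HRs, the combined signature
HR, the refitted top-k signature, and leave-one-out contributions, where
the contribution of gene g is `HR_full - HR_without_g` and the "strongest
contributors" are the largest HR decreases upon removal. The gene set
common to all four top-k lists is the "emergence" set — a dual-endpoint
driver should be its unique member. The top-k cut in such analyses is
effect-driven (the genes whose HR exceeds a baseline marker's), not a
fixed quantile of the pool: a proportional cut demands the dual driver
out-rank same-endpoint drivers of nearly equal effect, which is rank
noise, not signal. `four_way_emergence` therefore defaults to a
per-endpoint k equal to the number of genes whose individual-HR Wald CI
lies above 1 (at least 1); on the default planted cohort this is the five
strong genes per endpoint (the dual driver plus four single-endpoint
drivers). An explicit k remains available.

Degenerate cases are flagged, not hidden: a risk group with zero events
yields an infinite/zero HR with a diagnostic, and monotone partial
likelihoods (no finite MLE, e.g. when all events in one group precede the
other group's) mark the fit as non-converged. Multivariate adjustment uses
gene high/low (median), IGHV mutation status (unknown excluded listwise —
no imputation is attempted) and the 17p13-deletion flag. No multiple-testing
correction is applied across per-gene HRs; this is deliberate (the ranked
lists are descriptive) and is a known limitation.

## qPCR stage statistics

Relative expression is `2^(Ct_ref - Ct_target)` against the housekeeping
gene ABL1 — the single-delta, 100%-efficiency model; no calibrator sample
exists in this design, so the delta-delta-Ct form is not computable. Stage
contrasts (Rai 0 vs III-IV, Rai I-II vs III-IV, Binet A vs B+C) use Welch's
two-sample t-test with Satterthwaite degrees of freedom on untransformed
relative expression; a `log2_transform` flag is provided since the choice
of scale is a genuine judgement call with skewed expression ratios.

## Enzyme activity and drug combinations

Kinetic traces (fluorescence every 60 s over 30 min) are reduced to the OLS
slope over the contiguous 10-point window with maximal R² — an automatic
stand-in for reading "the linear portion" off the graph. The inhibitor
effect is `(RFI_DI - RFI_u) / (RFI_u - RFI_Zn) * 100%`; the formula is
negative for inhibition, so both the signed score and its magnitude are
reported.

Dose-response curves follow the median-effect equation
`fa/fu = (D/Dm)^m`, fitted by regressing `log10(fa/(1-fa))` on `log10 D`
(exact on noise-free data, which the tests verify on a parameter grid).
The combination index is the two-term, mutually-exclusive form
`CI = d1/Dx1 + d2/Dx2`, `Dx = Dm (fa/(1-fa))^(1/m)`, evaluated
non-constant-ratio (each observed point at its own doses and fa) because
the supported experimental design fixes one agent while varying the other.
Points with fa at exactly 0 or 1 are excluded (no information on the
log-odds scale).

## Synthetic data: what it emulates and what it does not

The generators define the study conditions; each draws from its own child
stream of the master seed, so adding a generator never perturbs another,
and a seed fully determines every table.

**Expression collection** (default 14 datasets, 30–200 samples each, 2000
background genes + the 7-kinase panel, log2 scale ~ N(8, 1.2) after
rescaling): each dataset has a latent per-sample "BcR activity" factor f;
kinase j is `lambda f + sqrt(1-lambda^2) e_j` with loading `lambda = 0.9`,
so panel kinases are strongly mutually correlated — the screen's own
premise is that these kinases are co-regulated. A planted positive gene
(default 100 of them, in 6 of 14 datasets, strength rho = 0.85) is
generated against the standardized mean of its target-kinase set (default
3 kinases including the anchor). A gene cannot correlate at rho with s
mutually independent kinases beyond `rho <= 1/sqrt(s)`; the shared factor
is therefore a mathematical requirement of multi-kinase planting, not a
convenience, and its side effect — planted genes also correlate with
non-target kinases at slightly lower strength — is accepted and documented.
Optional gross outliers replace a fraction of samples with 10-fold-wider
draws. Probe-level structure, batch effects and normalization artifacts are
not simulated; passing tests say nothing about those failure modes.

**Survival cohort** (default 107 samples, mirroring a typical validation
cohort): event times are exponential with rate `h0 exp(PI)` per endpoint —
proportional hazards hold by construction (verified with Schoenfeld-type
tests) — with independent uniform censoring (windows 120/150 months,
baseline hazards 1/40 and 1/120 per month for time-to-treatment and overall
survival). Default planted effects: one dual-endpoint driver (DNPEP,
beta = 1.0 on both endpoints), four single-endpoint drivers per endpoint
(beta = 0.8) and three noise genes; IGHV-unmutated (45%, beta 0.8),
unknown IGHV 7%, del17p (8%, beta 0.9). Real cohorts have correlated gene
expression and non-exponential baselines; neither is emulated.

**qPCR table** (34 samples; Rai strata 20/10/4; Binet A 29 vs B+C 5,
derived deterministically from Rai): reference Ct ~ N(25, sigma), target
Ct = Ct_ref − log2(expression) + noise with stage shifts (0, +1, +2 log2
units for low/intermediate/high risk) and sigma = 0.5 cycles covering
biological plus technical spread. sigma = 0 gives exact noise-free
inversion, which tests exploit.

**Dose-response** (defaults: DNPEP inhibitor m=1.5, Dm=1.4 µM; BH3-mimetic
m=2.0, Dm=0.3 µM; 8 doses log-spaced around Dm): combination points fix the
second agent at its Dm and solve for fa such that
`d1/Dx1(fa) + d2/Dx2(fa) = s`, so the true CI equals the configured synergy
factor s exactly (1 = Loewe additivity). Optional logit-scale noise on fa.

## Problem sizes and test design

The test suite checks oracle equivalence (independent straight-line
transcriptions of the bicor weights and the Efron partial likelihood,
brute-force maximized), frozen hand-computed examples (Welch toy,
product-limit worked example, activity-score arithmetic), distributional
properties by seeded simulation, and planted-truth recovery end-to-end. The
acceptance-scale runs use the default 14 x 2000 collection, cohorts of
n = 500 for parameter-recovery and emergence simulations (50–200 seeds),
2000 null seeds for the log-rank level and 5000 for the Welch level —
sizes chosen to keep Monte-Carlo error well inside the asserted bands while
the whole suite stays quick on a single CPU.

## Known limitations

- Published headline numbers from real CLL screens of this kind (e.g. a
  32-gene signature selected from fourteen microarray collections, with
  its cohort-specific hazard ratios) depend on dataset collections that
  are not redistributable; the package validates the *method* by
  planted-truth recovery instead of reproducing any particular study's
  figures.
- Signature HRs on many-gene fits overfit at small n (quantified by the
  pure-noise test: median HR stays below 2 at n = 107 with 8 noise genes);
  the package does not cross-validate the prognostic index.
- The Welch test's exact level with n = 4 strata on skewed (log-normal)
  relative expression is a property of the t-test, not of this package;
  level checks are therefore run on the normal scale at the 20-vs-10
  contrast sizes.
- No time-varying covariates, competing risks or penalized Cox models.
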