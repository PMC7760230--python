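# Methods

## Setting and data model

A DSP protein experiment yields a nonnegative count matrix (ROIs ×
probes). Probes fall in three classes: targets, isotype-IgG controls
(no specific antigen; their counts estimate per-ROI nonspecific binding),
and housekeepers (Histone H3, S6, GAPDH; assumed biologically invariant).
ROIs carry metadata: compartment (Tumour / TME / NAT), patient identifier
(possibly missing — such ROIs join only unpaired analyses), area, nuclei
count and shape. Compartment labels are case-insensitive on input and
canonicalized on output. The default panel has 52 targets in five modules
plus the six controls (58 probes).

## QC and probe robustness

For ROI *r* with IgG-control mean `b_r > 0`, the signal-to-noise ratio of
probe *p* is `SNR(r,p) = count(r,p) / b_r`. ROIs with `b_r = 0` are
excluded from SNR with a warning. The per-probe robustness summary across
ROIs is the **median** by default; the mean is available because platform
reports use both conventions, and the summary used is recorded in every
output. A target is robust when its summary is ≥ the threshold (default
1.0 — signal at background). Housekeepers and IgG controls are summarized
but never filtered: downstream stages need them. Per-ROI median raw counts
below a flag threshold (default 50; advisory, since no canonical cutoff
exists) are flagged, never dropped silently — dropping is a config option.
Background subtraction is intentionally unsupported: for targets near
background it subtracts signal.

Filtering precedes normalization and differential testing, so weak probes
cannot distort either.

## Normalizer assessment and normalization

Candidate per-ROI factors: each housekeeper count, `hk_mean` (arithmetic
mean of Histone H3 and S6), `igg_mean`, area and nuclei. All pairwise
Pearson correlations are reported; constant factors (e.g. every ROI drawn
at the maximum geometry) are excluded from the recommendation with a
warning. The advisory recommendation is the housekeeper-derived factor
with the highest minimum correlation to the non-biological references
(IgG mean, area, nuclei).

Housekeeper normalization computes `f_r` = mean of the chosen housekeeper
counts in ROI *r* (arithmetic by default; geometric optional, as platform
conventions vary) and rescales counts by `gmean(f) / f_r`. Anchoring on
the grand geometric mean keeps outputs on the raw count scale and makes
the operation idempotent; the anchor choice is ours — any global constant
would do. ROIs with non-positive factors are excluded with a warning.

Global scaling alternatives, for data where one housekeeper rule would
systematically inflate a low-signal group (the depressed-NAT situation):

* **TMM** — per-ROI factor from the doubly trimmed (30% of each tail of
  the M log-ratios, 5% of each tail of the A intensities) precision-
  weighted mean of M-values against a reference ROI, chosen as the ROI
  whose upper-quartile count fraction is closest to the mean upper
  quartile. The trim conventions follow the method's published definition.
* **RLE** — per-ROI median ratio to the per-probe geometric mean over
  probes with no zero counts.

Both factor sets are rescaled to multiply to exactly 1. Zeros are handled
by dropping the affected probes from factor computation with a warning. A
config option normalizes within compartment groups instead of globally;
the global default matches common practice, but a single rule will
over-inflate a compartment whose counts are genuinely lower.

log2 transforms use a pseudo-count (default 1; the data are counts, so
+1 maps zero to zero).

## Differential expression

Testing operates on log2 normalized values by default (a linear option
exists; the scale choice is recorded). For matched compartments, multiple
ROIs of one patient and compartment are **averaged before pairing** — the
conservative choice when the pairing rule is otherwise unspecified — and a
two-sided paired t-test is applied per probe (differences with zero
variance yield NA with a warning). For unmatched groups the Mann–Whitney
U test is used at ROI level: exact null distribution for small tie-free
samples, otherwise the normal approximation with tie and continuity
corrections; the companion effect size is the difference of group medians
(rank tests pair naturally with medians). Benjamini–Hochberg step-up
adjustment is applied **within each comparison panel**, never jointly
across panels; NA p-values are excluded from the family size.

Probe–probe Pearson correlation matrices are computed per compartment
with two-sided p from the t transform and a significance mask at
p ≤ 0.001; constant probes give NA rows.

A mixed-effects formulation that models patient as a random effect would
respect the partial pairing more fully; it is documented as future work
and intentionally not implemented here.

## Clustering

"Relative expression" is the per-probe z-score of log2 expression across
ROIs (sample sd; constant probes dropped). ROI ordering uses Ward's
minimum-variance linkage in the squared-distance (D2) formulation on
Euclidean distances, as implemented by scipy's nearest-neighbour-chain
algorithm; heights are reported on the distance scale (√ of the
criterion) and are monotone. Tie-breaking follows scipy's chain order;
ties are measure-zero for continuous data. Class assignment uses k-means
(k-means++ seeding, Lloyd iterations, best of 10 restarts, seeded). k
defaults to 3 — with the default enrichment structure the classes align
with NAT-dominated, low-expression tumour/TME, and heterogeneous ROIs —
and is configurable since no canonical k exists.

## Survival screening

Per compartment, a patient's covariate is the mean log2 normalized
expression over that patient's ROIs of the compartment (continuous by
default; a median-split binary mode exists because "presence of cells
expressing" phrasings are ambiguous between the two). Each probe is fit
in a univariate Cox proportional-hazards model: Efron's approximation for
tied event times (follow-up on tissue cohorts is coarsely recorded, and
Efron is the more accurate default), Newton–Raphson with the analytic
gradient and observed information, step-halving to keep the partial
likelihood nondecreasing, convergence at |score| < 1e-9 within 50
iterations. |β| > 20 is treated as monotone-likelihood divergence and
flagged `converged=False` — never silently reported. Standard errors come
from the inverse observed information; Wald CIs and p-values are reported
and results ranked by HR. No multiplicity adjustment is applied by
default (the screen is exploratory and unadjusted by design); an optional
BH column can be emitted. The score test at β = 0 equals the log-rank
statistic for binary tie-free covariates, which the tests verify against
an independent implementation.

## Synthetic-data generator

The generator emulates the count regime of a single-slide tumour TMA run:

* **Layout.** 62 patients with compartment sets chosen so the default
  experiment has 96 ROIs (45 tumour / 32 TME / 19 NAT) and 18 tumour–TME,
  14 NAT–tumour, 8 TME–NAT matched pairs; fully matched two-compartment
  designs of any size are available for replicate studies.
* **Counts.** `count(r,p) ~ NB(mean = s_r · μ_{p,c} · b_{patient,p},
  α = 0.008)` with variance `μ + αμ²`. `s_r` is a log-normal per-ROI size
  factor (σ = 0.2) shared by all probes of the ROI — it stands in for
  area, cellularity and capture efficiency. `μ_{p,c}` is the deterministic
  per-probe baseline (named abundant structural markers at 850–3000
  counts, featured immune markers at 60–420, remaining targets log-spaced
  over 45–500 so a realistic subset sits below background) times
  `2^effect(p,c)` and, in NAT, times the depression factor 0.7.
  `b_{patient,p}` is a mean-one log-normal patient effect (σ = 0.4) on
  targets only, shared across a patient's compartments — it cancels in
  paired contrasts and provides the between-patient spread that survival
  models need. IgG probes draw from the background mean (100) times the
  size factor only; housekeepers from fixed means (1500/1200/800), with
  GAPDH given extra log-normal noise (σ = 0.35) because in practice it
  tracks abundance more loosely than Histone H3 or S6. Area and nuclei
  are noisy monotone transforms of the size factor (area capped at the
  maximum circular geometry), so the normalizer assessment has structure
  to find. The NB dispersion, size-factor spread and background mean were
  calibrated once, jointly, so the default design reproduces the target
  regime: per-ROI IgG means within 50–150 (central 90%), ROI median
  counts within 10²–10³, housekeeper-vs-IgG correlation above 0.8 and
  size-factor recovery above 0.9.
* **Survival.** Event times are exponential with rate `base_rate ·
  exp(Σ_p β_p · x_p)` where `x_p` is the patient's centred log2 true
  expression in the survival compartment (tumour by default); default
  protective markers CD3 (β = ln 0.5), CD34 (ln 0.53) and ICOS (ln 0.6)
  per log2 unit. Censoring is an independent exponential calibrated to
  the requested fraction under the baseline hazard; `censor_rate=0`
  yields all-event data exactly.
* **Seeding.** One master seed is split (`SeedSequence.spawn`) into named
  sub-streams — patient effects, counts, ROI covariates, survival,
  censoring — so identical designs are bit-identical and stages are
  independently reproducible.
* **Truth ledger.** Size factors, per-probe per-compartment expected
  counts, patient effects, per-patient log2 expression and log-hazards
  are returned for parameter-recovery testing and written beside the
  simulated files.

What the generator does **not** emulate: spatial coordinates or
morphology imagery, probe-specific antibody affinities, slide/batch
effects, count saturation, or non-proportional hazards. Passing tests
therefore demonstrate the pipeline's correctness and calibration under a
plausible count model, not robustness to every artefact of real slides.

## Problem sizes used in the checks

Replicate-based checks use 200 replicates of 18 pairs × 30 targets for
null false-discovery control, 100 replicates for power at a +2 log2
enrichment, 5 × 500 uncensored patients for hazard-ratio recovery and
50 × 200 for null HR coverage; simulator calibration uses 192 ROIs. These
sizes give binomial/standard errors comfortably below each margin of
interest while keeping the whole suite fast.

## Known limitations

* The t-test on 8–18 pairs assumes approximately normal paired
  differences; log2 NB counts satisfy this only approximately.
* Housekeeper normalization presumes the housekeepers are invariant; the
  generator honours this by construction, real data may not.
* The Cox screen fits one probe at a time and does not adjust for
  clinical covariates; with ~60 patients its confidence intervals are
  wide, as the worked example shows.
* The recommendation logic in the normalizer assessment is a heuristic
  ranking, not an inferential procedure.
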