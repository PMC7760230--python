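# dspforge

Analysis pipeline for **digital spatial profiling (DSP) protein counts** —
the antibody-barcode counts produced when UV-cleavable DNA tags are
collected from user-drawn regions of interest (ROIs) on a tissue slide and
counted. The package targets the tumour-profiling setting in which each
patient contributes up to three tissue compartments — tumour (PanCK+),
tumour microenvironment (TME, PanCK−/CD3+) and normal adjacent tissue
(NAT) — on a single tissue microarray.

It is written for bioinformaticians and platform users who need a
reproducible, scriptable alternative to point-and-click DSP analysis:

* **Probe QC against isotype-IgG background.** Each probe's count is
  divided by its ROI's mean IgG-control count; the per-probe median (or
  mean) of these signal-to-noise ratios across ROIs is compared with a
  threshold (default 1.0). Targets at or below background are filtered;
  background *subtraction* is deliberately not offered, because probes
  expressed near background would lose signal, not noise.
* **Empirical normalizer selection.** Candidate factors — GAPDH,
  Histone H3, S6, their pairwise means, the IgG mean, ROI area and nuclei
  count — are compared by Pearson correlation across ROIs; a factor is
  useful when it tracks the others while being unrelated to biology.
* **Housekeeper normalization.** Counts in ROI *r* are scaled by
  `gmean(f) / f_r` where `f_r` is the mean of Histone H3 and S6 in that
  ROI, keeping output on the raw-count scale. TMM and RLE global scaling
  are available for data with systematic compartment shifts.
* **Differential expression.** Paired t-tests on patient-matched
  compartments (multiple ROIs per patient averaged first) and
  Mann–Whitney tests on unmatched groups, each corrected per comparison
  by Benjamini–Hochberg; within-compartment probe–probe correlation
  matrices with p ≤ 0.001 masks.
* **Clustering.** Per-probe z-scores of log2 expression ("relative
  expression"), Ward-D2 linkage for the heatmap ordering, and k-means
  (default k = 3) ROI classes.
* **Survival screening.** Unadjusted univariate Cox proportional hazards
  per probe and compartment: per-patient mean log2 expression against
  overall survival, Efron tie handling, Newton–Raphson on the partial
  likelihood, ranked by hazard ratio (HR < 1 ⇒ longer survival).

Because public DSP protein datasets of this design are scarce, the package
ships a **synthetic-data generator** (`dspforge.synth`) with a ground-truth
ledger: negative-binomial counts with per-ROI log-normal size factors,
IgG background calibrated to 50–150 counts, ROI medians between 10² and
10³, depressed NAT signal, patient-matched compartment sets (default: 96
ROIs, 45/32/19 per compartment, 18/14/8 matched pairs) and exponential
survival whose log-hazard follows chosen markers. Every downstream stage
is tested against this generator's known truth.

Stages follow the sklearn estimator idiom (`SnrProbeFilter`,
`HousekeeperNormalizer`, `GlobalScalingNormalizer`, `ExpressionClustering`,
`CoxScreen` expose `fit`/`transform`/`get_params` with fitted `_`
attributes) and compose with sklearn pipelines; module-level functions are
thin wrappers.

## Worked example

```python
import dspforge as dsp
from dspforge.diffexp import run_comparison
from dspforge.survival import screen_compartment

design = dsp.default_design(seed=1)
counts, rois, truth = dsp.simulate_counts(design)
surv = dsp.simulate_survival(truth, design)

table = dsp.snr(counts, design.panel)                  # IgG-relative QC
robust = dsp.filter_probes(table, design.panel)
targets = [p for p in robust if design.panel.probe_class(p) == "target"]
print(f"robust targets: {len(targets)} of {len(design.panel.targets)}")

nm = dsp.normalize_hk(counts, design.panel)            # Histone H3/S6 factors
de = run_comparison(nm, rois, "TME_vs_Tumour", design="paired", probes=targets)
print(de.sort_values("p_adj").head(5)[["probe_id", "effect", "p_adj"]])

cox = screen_compartment(nm, rois, surv, "Tumour", probes=targets)
print(cox.head(3)[["probe_id", "hr", "ci_low", "ci_high", "p"]])
```

prints (seed 1):

```
robust targets: 39 of 52
probe_id    effect        p_adj
    CD68  1.441573 4.259098e-15
   EpCAM -1.500192 4.259098e-15
   CD163  1.526807 7.699505e-15
   PanCk -1.577106 1.706079e-13
    CD45  1.460089 2.076278e-13
 probe_id    hr  ci_low  ci_high     p
     CD34 0.597   0.336    1.061 0.078
FAP-alpha 0.639   0.344    1.188 0.157
    CD66b 0.642   0.343    1.202 0.166
```

Reading this output: 13 of the 52 targets sit at or below IgG background
and are filtered. The paired TME-vs-tumour test recovers the planted
immune enrichment — positive log2 effects for the myeloid/T-cell markers
(CD68, CD163, CD45), negative for the tumour markers (EpCAM, PanCk) — at
vanishing adjusted p. The tumour-compartment Cox screen ranks CD34 (a
planted protective marker, generating HR ≈ 0.53 per log2 unit) first,
though at 62 patients the confidence interval still crosses 1.

The same workflow runs from the shell:

```sh
dspforge simulate --seed 1 --out sim/
dspforge qc --counts sim/counts.tsv --panel sim/panel.tsv --out qc/
dspforge run --config run.yaml        # all stages + manifest.json
```

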