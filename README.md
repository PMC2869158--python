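# tamrisk

Bootstrap-stable biomarker prognostic modelling of breast-cancer recurrence
in tamoxifen-treated patients.

## The problem

The Nottingham Prognostic Index (NPI = 0.2·size(cm) + grade + nodal stage)
stratifies breast-cancer risk from three clinical variables, but cannot
isolate a group with low enough recurrence risk to forgo adjuvant therapy.
Tissue microarrays make dozens of candidate immunohistochemistry markers
(histoscores, 0–300) available per tumour — far too many, relative to ~110
recurrence events in a ~400-patient cohort, to drop into a Cox model
directly.  Histoscores are also right-skewed, often non-linearly related to
risk, and 1–11% missing per marker.

`tamrisk` implements, as a tested reusable pipeline, a four-step procedure
for this setting:

1. **Screen** each variable univariately and pick its risk-function form:
   fractional polynomials (FP1/FP2, powers from {−2, −1, 0, 0.5, 1, 2, 3})
   by closed test at α = 0.1, else a minimum-p threshold scan (log-rank at
   every cutpoint in the inner 80%, per-cut α = 0.005 ≈ family 0.1), else a
   non-ordinal quartile-range scan (4 comparisons, α = 0.1/4 = 0.025).
2. **Impute and resample**: m = 10 completed datasets by chained equations
   (predictive mean matching), screened transformations applied with frozen
   parameters, then B = 100 bootstrap samples per completed dataset →
   m × B = 1000 sample datasets.
3. **Refine by stability**: per-sample multivariable fractional-polynomial
   (MFP) backward elimination at P = 0.05 with re-search of polynomial
   forms; threshold/non-ordinal forms re-scanned per sample; variables with
   inclusion frequency < 50% are *unreliable*, variables whose form fails to
   re-manifest in ≥ 50% are *unstable*; both are dropped.
4. **Aggregate**: final fits on each completed dataset pooled by Rubin's
   rules (β̄ = mean; var = within + (1 + 1/m)·between), per-patient risk
   score = mean linear predictor across imputations, risk groups by
   quartiles (tertiles for the on-treatment endpoint), ties to the lower
   group.

Evaluation compares the aggregated model with NPI by Harrell's C,
Nagelkerke R², risk-group reclassification (net gain among events /
event-free patients, exact binomial among movers) and Kaplan–Meier
event-free rates at 3/5/7/10 years.  No real cohort is bundled: the
`cohort` module generates synthetic cohorts with a known generating model
(six true effects, one per form class, plus noise markers) so every stage
is testable for parameter recovery.  See `docs/methods.md` for the model
details, defaults and limitations.

## Worked example

The numbered drivers under `analysis/` run the whole study on one
paper-shaped synthetic cohort (n = 401, ~112 expected events, 17 candidate
variables offered, resampling at the desk scale m = 5 × B = 40):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_screen.py
python analysis/03_impute_and_resample.py
python analysis/04_stability.py
python analysis/05_aggregate_model.py
python analysis/06_evaluate.py
```

Output of a run (seed 1, abridged):

```
cohort: 401 patients, 107 recurrences (27%), median follow-up (censored) 4.4 y
screened 20 variables; 8 selected as candidates:
variable      form      n_available  p_value   method
   nodes    linear          362      2.3e-06   linear
   m_lin    linear          391      5.4e-06   fp
   m_fp1    fp2(-1,0)       394      9.4e-11   fp
   ...
fitted 200 sample models (0 flagged)
variable  inclusion_frequency_pct  verdict
   nodes   97.0   reliable-stable
   m_lin   96.5   reliable-stable
   m_fp1  100.0   reliable-stable
   m_fp2  100.0   unstable-form   b
   m_thr   64.5   reliable-stable
   m_non   80.5   reliable-stable
noise_01    8.5   unreliable      a
noise_11   33.5   unreliable      a
C-index: biomarker model 77% vs NPI 58%
reclassification net gain: events +28% (p=0.001), event-free +21% (p=0.000)
7-year event-free rate, lowest-risk group: model 94% vs NPI 82%
```

Reading this: five of the six true effects pass both 50% rules and enter
the final model; `m_fp2` is retained in every sample model but its FP2
degree class re-manifests in only 43% of them, so it is excluded as
*unstable* (key `b`) — the same fate the procedure assigns to unstable
polynomial markers in real cohorts; the two noise markers that slipped
through screening are excluded as *unreliable* (key `a`).  The pooled model
(`results/model.csv`) reports hazard ratios per 100 histoscore units for
raw-scale linear markers.  The biomarker model separates a lowest-risk
quartile with markedly higher 7-year recurrence-free survival than NPI's
lowest-risk group, and reclassifies both events (upward) and event-free
patients (downward) with positive net gains.

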