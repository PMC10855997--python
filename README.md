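# oculopheno

Visuo-cognitive phenotyping of early multiple sclerosis from ocular-motor,
afferent and cognitive visual-processing indicators.

Cognitive impairment in early MS is heterogeneous, and standard
neuropsychological tests (e.g. the Symbol Digit Modalities Test) confound
cognition with afferent (optic nerve) and efferent (ocular-motor) visual
dysfunction. This package implements a three-system phenotyping analysis
that separates those channels: saccadic metrics from four eye-movement
tasks index *cognitive* visual processing, retinal nerve fibre layer (RNFL)
thickness indexes the *afferent* pathway, and the versional dysconjugacy
index (VDI) indexes the *efferent* pathway. Patients are standardized
against healthy controls and clustered into latent visuo-cognitive
phenotypes.

Because no patient recordings are publicly available, the package ships a
first-class synthetic cohort generator that emulates the study conditions —
four task designs, a main-sequence saccade model with plantable latency,
errors, landing accuracy and binocular dysconjugacy, phenotype-conditional
indicator shifts, and missing-at-random withdrawal of the memory-guided
task — so every stage of the analysis is testable end to end.

## The method

1. **Saccade metrics.** Horizontal gaze at 500 Hz is segmented by
   velocity-threshold detection (|v| ≥ 30°/s, extended to local velocity
   minima). Per task the scored outcomes are latency (correct trials
   only), directional error rate (% of trials) and final eye position
   (spatial accuracy, % of target amplitude): visually guided (VG),
   antisaccade (AS), memory-guided (MG) and endogenously cued (EC) tasks.
2. **Dysconjugacy.** From binocular VG recordings,
   VDI_R = mean over rightward saccades of
   (abducting right-eye peak velocity) / (adducting left-eye peak
   velocity); VDI_L symmetric.
3. **Derived indicators.** Cognitive latencies are adjusted by VG latency
   via OLS (residual + fit at the mean VG latency, preserving the ms
   scale); ocular-motor indicators are z-scored against controls; RNFL is
   z-scored against a normative reference; Snellen acuity maps to LogMAR
   (log10 of the inverse fraction). Severity: z ∈ (1,2] mild, (2,3]
   moderate, > 3 severe; RNFL inverted (z < −1 impaired).
4. **Missing data.** Chained-equation multiple imputation with predictive
   mean matching; Rubin's rules pooling
   (T = W̄ + (1 + 1/m)·B).
5. **Factor structure.** Maximum-likelihood exploratory factor analysis of
   the ocular-motor indicators, minimizing
   F = ln|Σ(θ)| + tr(SΣ(θ)⁻¹) − ln|S| − p with Σ = ΛΛ′ + Ψ, oblimin
   rotation, χ²/CFI/TLI/RMSEA/SRMR fit indices and the |λ| > 0.4 loading
   rule.
6. **Phenotypes.** Latent profile analysis: Gaussian mixtures with
   profile-specific means and shared diagonal variances, fitted by
   multi-start EM (250 starts, 50 final-stage optimizations), selected by
   BIC with a parametric bootstrap likelihood-ratio test (BLRT), and
   described via relative entropy, average latent class probabilities and
   severity-labelled profile means.
7. **Post-hocs.** Kruskal–Wallis with η² = (H − k + 1)/(n − k), Dunn's
   multiple comparisons (Holm-adjusted), rank-sum tests with rank-biserial
   effect sizes, Spearman correlation matrices and profile prevalences.

## Worked example

```python
from oculopheno import (make_default_config, simulate_cohort,
                        zscore_metrics, lpa_sweep, select_model, entropy,
                        phenotype_prevalence, classify)

cfg = make_default_config(n_patients=1000, n_controls=4000, seed=7)
cohort = simulate_cohort(cfg)
m = cohort.metrics
z = zscore_metrics(m[m.group != "control"], m[m.group == "control"])

fits = lpa_sweep(z, range(1, 7), n_starts=250, n_final=50, seed=7)
best, trace = select_model(fits)
print(trace[["BIC", "entropy"]].round(2))
print("selected K =", best.K, " entropy =", round(entropy(best), 3))
```

prints

```
        BIC  entropy
K
1  39979.05      NaN
2  38367.91     0.99
3  36702.12     1.00
4  36025.05     0.98
5  36086.19     0.85
6  36146.49     0.84
selected K = 4  entropy = 0.981
```

BIC bottoms out at four profiles — the generator's four phenotypes (early
visual changes, efferent-cognitive, cognitive control,
afferent-processing speed) — and the near-unity entropy means posterior
class memberships are essentially deterministic, so modal assignments can
be treated as discrete phenotypes for post-hoc comparison. The fitted
profile means recover the generating z-shift profiles (e.g. the
efferent-cognitive profile's extreme rightward dysconjugacy, VDI_R ≈ 6.5
control SDs above the control mean).

The same analysis runs from a shell:

```bash
oculopheno run --seed 7 --out results/run1
oculopheno simulate --n-patients 140 --n-controls 25 --seed 7 --out cohort/
oculopheno phenotype --data zscores.csv --k 1:6 --starts 250 --final 50 \
    --seed 7 --out lpa/
```

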