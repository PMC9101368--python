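# lpmadc — Linear Poisson Modelling of ADC histograms

Quantitative, per-tumor detection of treatment response from
diffusion-weighted MRI, built for small-cohort preclinical imaging
studies.

## The problem

Apparent-diffusion-coefficient (ADC) maps resolve tumors into habitats —
viable tissue at low ADC, necrotic or therapy-affected tissue at higher
ADC — but conventional analysis collapses each tumor to a mean, 95th
percentile or volume and compares cohorts with t-tests. Between-tumor
heterogeneity (non-Gaussian, multi-modal histograms; natural-history
growth that mimics change) inflates the apparent noise, so subtle
responses are only detectable as group effects in large cohorts, if at
all.

Linear Poisson Modelling (LPM) works at the histogram level instead.
Each tumor's multi-visit ADC histogram is modelled as a nonnegative
mixture of learned probability-mass-function components with Poisson bin
noise:

```
H(A, V)  ≈  M(A, V | C=c) + M(A, V | C=t)
M(A, V | C=c) = Σ_c P(A, V | C=c) Q_c          (control behaviour)
M(A, V | C=t) = Σ_t P(A, V | C=t) Q_t          (additional treated behaviour)
```

where `A` indexes ADC bins, `V` visits, and the weights `Q` are voxel
counts. The control components are trained on a control cohort by
expectation-maximisation with multiple restarts; treatment components
are then added with the control shapes frozen, so they only capture
behaviour the control model cannot express. Model order is chosen by
leave-one-out generalisation with a χ²-per-degree-of-freedom sufficiency
check and a Bland–Altman residual test.

For any tumor, the treatment-attributed voxel count `QT = Σ_t Q_t` is a
lower bound on the volume affected by therapy. Its standard error σ
follows from the observed Fisher information of the extended Poisson
likelihood, giving a per-tumor significance `Z = QT/σ` (responder when
Z > 3) — no control cohort comparison is needed at assessment time, so
the power is set by the voxel count of the tumor, not by the cohort
size. Two closed-form power calculations support study design: the
attainable `Z = sqrt(Qtotal (T* − (1−T*−C*)²/4C*))` as a function of
voxel count and the control/treated distribution-overlap (ambiguity)
terms `T*, C*`; and the binomial probability `1 − (1−F)^N` of seeing at
least one responder in a cohort of `N` when a fraction `F` respond.

## Worked example

No public dataset accompanies the method, so the package ships a
ground-truth generator (`lpmadc.synthetic`) that emulates multi-visit
ADC studies: control habitats with Dirichlet-distributed per-tumor
weights plus a high-ADC treatment habitat with a known injected voxel
count.

```python
import lpmadc as L

cfg = L.TruthConfig(n_control=8, n_treated=4, voxels_per_tumor=2000, seed=7)
hists, truth, _ = L.generate_study(cfg, seed=7)
ctrl = [h for h in hists if h.cohort == "control"]
trt  = [h for h in hists if h.cohort == "treated"]

control = L.LinearPoissonModel(ctrl, L.LPMConfig(k_range=(1, 2, 3), restarts=8)).fit(seed=0)
full = control.extend(trt, seed=0)
print(full.summary())
print(full.fit_tumor(trt[0]).summary())
```

prints

```
Linear Poisson Model
====================
grid: 100 bins x 2 visit(s) ['V1', 'V2']
components: 3 (2 control, 1 treatment)
training log-likelihood: 16678.43
sufficient: True
component mass shares:
  c0: 0.282
  c1: 0.247
  t0: 0.471

Tumor trt000 (treated)
  total voxels: 1963
  QT = 1062.7 +/- 33.7   QC = 898.3
  Z = 31.54   p = 1.07e-218   responder: True
  fit value sqrt(chi2/df) = 0.909
  WARNING: 2 voxels in bins without model support
```

The model selected two control components and one treatment component;
for the first treated tumor it attributes 1063 ± 34 voxels to treatment
(the generator actually injected 1052 — within one standard error), a
Z score of 31.5, and a good per-tumor fit (√(χ²/d.f.) ≈ 0.91, i.e.
residuals at the Poisson noise level).

The same workflow is available from the shell:

```
lpmadc synthesize --out-histograms h.csv --out-truth truth.csv --seed 3
lpmadc fit-control   --histograms h.csv --out ctrl.json --seed 1
lpmadc fit-treatment --model ctrl.json --histograms h.csv --out full.json --seed 1
lpmadc assess        --model full.json --histograms h.csv --out assess.tsv
lpmadc simulate-cohorts --model full.json --histograms h.csv --n 5 --big-n 12 --out tpr.csv
lpmadc power-cohort --f 0.5 --target 0.95     # -> 5
lpmadc power-z --q-total 2000 --t-star 0.9 --c-star 0.9
```

Raw inputs can also be per-voxel ADC CSVs or NIfTI ADC volumes with
masks (`lpmadc.adc.extract_masked_adc`, `lpmadc.fit_adc_voxel` for
mono-exponential fitting of multi-b signals).

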