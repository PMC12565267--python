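# coro0d

Reduced-order (0D) coronary hemodynamics for functional stenosis assessment:
a lumped-parameter simulator of the aorta-plus-coronary-tree system with
patient-specific boundary conditions, rest and adenosine-hyperemia states,
per-lesion functional indices — FFR_CFD, translesional ΔP, hAPV, and the
computational hyperemic stenosis resistance index **cHSR** — wall-shear
metrics (TAWSS, OSI), and the diagnostic-evaluation statistics used to
benchmark such indices against revascularization decisions.

## Who this is for

Researchers in computational coronary physiology who need a fast, fully
scriptable surrogate for 3D CFD pipelines: prototyping boundary-condition
tuning schemes, studying how pressure–flow indices respond to lesion
geometry, or stress-testing diagnostic evaluation methodology on synthetic
cohorts with known ground truth. It is not a clinical tool.

## The model

The arterial tree is a rooted network of Poiseuille segments driven by a
periodic aortic inflow Q(t) (per-beat integral = stroke volume, ejection
window = systolic ejection time). A stenosed segment adds a Young–Tsai-type
loss

ΔP = K_v · 8μL/(πr_min⁴) · Q  +  K_t · ρ/2 · (A₀/A_s − 1)² · (Q/A₀)|Q/A₀|,

with an inertial K_u term available in the standalone element. Each systemic
outlet is a three-element Windkessel (R_p, C, R_d); each coronary outlet
carries arterial resistance and compliance (R_a, C_a), microvascular
resistance R_a-micro, intramyocardial compliance C_im referenced to a
ventricular-pressure-shaped P_im(t), and venous microvascular resistance
R_v-micro (venous compliance omitted). Outlet resistances are initialized
from myocardial-mass flow allocation (0.8 mL/min/g at rest, Murray r³ splits)
and mean-pressure quotients, then refined by proportional fixed-point tuning
against pressure and per-artery flow targets. Hyperemia multiplies the
microvascular resistances by 0.24.

Per lesion, under hyperemia:

- FFR_CFD = P̄_dist / P̄_aortic (time averages over the periodic cycle)
- ΔP = P̄_prox − P̄_dist across the lesion; hAPV = time average of 2·Q(t)/A_s
- **cHSR = ΔP / hAPV** in mmHg/(cm/s)
- TAWSS = (1/T)∫|τ|dt and OSI = ½(1 − |∫τ dt|/∫|τ|dt) over a 15 mm region
  of interest beyond the stenosis, with τ = 4μQ/(πr³)

Diagnostics: empirical ROC/AUC (Mann-Whitney, ties ½), Youden-optimal
cutoff, sensitivity/specificity/accuracy/PPV/NPV, DeLong's paired AUC test,
Bland–Altman limits of agreement, Pearson correlation.

## Worked example

```sh
coro0d demo --out demo_out --seed 1
```

runs the bundled single-patient fixture (70 bpm, 120/80 mmHg, SV 75 mL,
130 g myocardium; aorta + 55 %-stenosed LAD + RCA) through tuning, rest and
hyperemic solves, and index extraction. The run converges in 4 tuning
iterations and 5 cycles per solve, and `demo_out/lesion_indices.csv`
contains:

```
lesion_id,artery,percent_stenosis,ffr_cfd,delta_p_mmHg,hapv_cm_s,chsr,tawss_pa,osi,...
lesion0,LAD,55.0,0.9008,8.846,162.12,0.0546,2.119,0.0
```

Read: the 55 % LAD lesion drops 8.8 mmHg under hyperemia, giving
FFR_CFD = 0.90 (above the conventional 0.80 ischemia threshold, so
functionally non-significant), cHSR = 0.055 mmHg/(cm/s), and a
unidirectional post-stenotic shear field (OSI = 0) with TAWSS = 2.1 Pa.

A synthetic cohort with ground-truth labels and its evaluation:

```sh
coro0d cohort --seed 7 --n-patients 40 --max-lesions 50 --out cohort.csv
coro0d evaluate --table cohort.csv --score-column chsr --out eval_out
```

Other subcommands: `simulate` (YAML config pipeline), `tune`, `indices`.
Exit codes: 0 success, 2 validation error, 3 numerical failure.

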