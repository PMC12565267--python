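# Methods

## Model structure

The simulated domain is a rooted tree: inlet aorta, a systemic outlet, and
one or more epicardial coronary branches, each segment a rigid cylinder with
Poiseuille resistance 8μL/(πr⁴) (blood: Newtonian, μ = 0.04 P,
ρ = 1.06 g/cm³). The inflow is a prescribed periodic flow waveform; there is
no ventricle model. Segments are treated as *resistive only* inside the
network solve: the dynamic state of the system is the set of outlet
compliance-node pressures (one per Windkessel outlet; two per coronary
outlet). Segment inertance is exposed on the segment type and in the
standalone stenosis element (K_u term), but including it in the network
would turn the tree into an index-1 DAE; the quasi-steady resistive tree
keeps the system an ODE and keeps junction mass balance exact by
construction (branch flows are computed from leaf flows, so Kirchhoff
holds to round-off at every output instant).

### Stenosis element

A lesion adds ΔP = K_v·8μL/(πr_min⁴)·Q + K_t·(ρ/2)·(A₀/A_s − 1)²·(Q/A₀)|Q/A₀|
to its segment, the classical empirical expansion-loss form with the
quadratic term scaled by the *reference-lumen* velocity Q/A₀. Defaults
K_v = 1, K_t = 1.52, K_u = 1.2 (inertial term, standalone element only) are
the conventional empirical values; all are configurable per run. At 55 %
diameter stenosis and hyperemic flow this yields translesional gradients of
order 10 mmHg and FFR ≈ 0.9, consistent with clinical expectations; a
throat-velocity scaling (Q/A_s) would overpredict the loss by (A₀/A_s)² and
push every significant lesion to FFR ≈ 0.

### Outlet boundary conditions

Systemic: three-element Windkessel, dP_c/dt = (Q_in − (P_c − P_ref)/R_d)/C,
interface pressure P_c + R_p·Q_in. Coronary: arterial compliance node P_a,c
and intramyocardial node P_im,c with

- dP_a,c/dt = (Q_in − Q_micro)/C_a, Q_micro = (P_a,c − P_im,c)/R_a-micro
- dP_im,c/dt = (Q_micro − (P_im,c − P_v)/R_v-micro)/C_im + dP_im/dt

i.e. C_im is referenced to the intramyocardial pressure P_im(t), which
compresses the bed in systole and produces the diastolic-dominant coronary
flow pattern. Venous microcirculatory compliance is omitted. dP_im/dt is the
analytic derivative of the monotone piecewise-cubic (PCHIP) interpolant,
never a finite difference of samples.

## Waveforms

Shipped templates (population curves are not redistributable, so the
package generates canonical shapes): a half-sine ejection / zero-diastole
aortic flow template and a raised-cosine systolic bump for ventricular
pressure. File-supplied templates override both (CSV `time_s,value` with an
optional `# period=` line). Patient scaling warps the ejection window to the
patient's systolic ejection time, the remainder to diastole, and normalizes
the trapezoidal integral to the stroke volume (flow) or the peak to
territory_factor × systolic pressure (P_im). Body-surface-area scaling
enters through the stroke volume (a helper converts indexed SV). P_im
scaling is amplitude-only; whether timing should also scale with BSA is an
open modelling question and is deliberately not done. Territory factors
default to 1.0 for left-ventricular territories (LAD/LCx/LM) and 0.5 for
the RCA, reflecting weaker right-ventricular compression.

## Parameter initialization and tuning

Rest coronary flow is allocated as 0.8 mL/min per gram of myocardium times
the artery's mass fraction (an LM lesion perfuses the LM+LAD+LCx fraction
sum), split among an artery's outlets by Murray's r³ law. Each outlet's
total resistance is (MAP − P_v)/q with MAP = diastolic + pulse/3, split
(R_a, R_a-micro, R_v-micro) = (0.32, 0.52, 0.16)·R_tot. Compliances default
to C_a = 5·10⁻⁴ and C_im = 5·10⁻³ mL/mmHg per outlet. The systemic
Windkessel takes 96 % of cardiac output (coronary fraction 4 %),
R_p = 6 % of the total, C = 1.2 mL/mmHg. All defaults are keyword
arguments.

Tuning is a proportional fixed-point loop (cap 25 iterations, tolerance 5 %
per target, both configurable): after each periodic solve, coronary outlet
total resistance ×= simulated/target mean flow (split preserved), systemic
resistance ×= target/simulated MAP, systemic compliance ×= simulated/target
pulse pressure. The loop stops when every relative error is within
tolerance; on cap exhaustion the best iterate is returned with the report
flagged non-converged. The report records per-iteration errors. Exact
update rules used by 3D-CFD pipelines vary; this scheme is isolated in one
operation so it can be swapped.

Physiological states are multiplicative: hyperemia scales R_a-micro and
R_v-micro by 0.24 (adenosine acts on the microcirculation; epicardial R_a
and compliances untouched — pressure-only indices rely on this), exercise
ships as (0.5, heart-rate ×1.5) but is excluded from the index pipeline.
Because states multiply current values, a forward/inverse factor pair
restores parameters to within one ulp (floating multiplication is not
exactly invertible); the rest state is the exact identity.

## Numerical scheme

At each ODE right-hand-side evaluation the leaf flows and root pressure
solve a small nonlinear algebraic system (path pressure consistency plus
root conservation) by damped Newton with an analytic Jacobian and warm
starting; the quadratic stenosis term makes the system monotone, so 1–3
iterations suffice. Integration is cycle-by-cycle LSODA (stiff-capable;
`stiff=False` selects RK45) on a fixed output grid (default 1 ms, 5 ms for
cohort sweeps). Periodicity is declared when the relative L2 difference of
consecutive-cycle *state* trajectories (the compliance-node pressures) is
below 10⁻³ (default); node pressures are algebraic functions of these plus
the periodic forcing, so state periodicity implies node-pressure
periodicity. Because the slowest Windkessel RC mode makes the cycle map
near-geometric, an Aitken Δ² extrapolation of the cycle-start state is
applied every third cycle; convergence is still only declared after a
subsequent full-cycle comparison passes, so acceleration cannot produce a
false positive. Initial states come from a steady solve at the mean inflow.

Oracle (reference) FFR for labelling re-runs the converged hyperemic state
with the periodicity tolerance tightened 4× (continuation from the final
state, typically 1–2 extra cycles).

## Indices

ΔP is the difference of *time-averaged* pressures proximal/distal to the
lesion segment over the final hyperemic cycle (mean-based, matching the FFR
convention), not peak-to-peak. hAPV uses the parabolic-profile peak, twice
the mean velocity at the minimal lumen (Doppler average-peak-velocity
analogy); cHSR = ΔP/hAPV exactly, reported in mmHg/(cm/s). Wall shear is
the Poiseuille value 4μQ/(πr³) per segment, signed by flow direction; TAWSS
integrates |τ| (consistent with the OSI denominator); OSI is clipped to
[0, 0.5] only for floating-point spill ≤ 10⁻¹². ROI metrics length-weight
per-segment TAWSS/OSI over 15 mm (default) distal to the lesion; a lesion
at a leaf falls back to the lesion segment with a warning. FFR and related
indices refuse non-hyperemic results unless explicitly overridden (logged
via warning). ΔP and hAPV are taken from the *same* hyperemic solve.

## Synthetic cohort

The generator reproduces a chronic-coronary-syndrome lesion population:
diameter stenosis with observed moments 55.3 ± 11.2 % on [40, 80] %, lesion
length 18.0 ± 7.4 mm on [4, 40] mm, artery distribution
LAD/LCx/RCA/LM = 0.49/0.26/0.22/0.03 (each lesion drawn independently; two
lesions in one artery become separate single-stenosis cases). Truncated
normals are parametrized by their *post-truncation* moments, with parent
(μ, σ) solved by least-squares moment matching — a reported cohort mean is
a truncated-sample moment, and using it as the parent mean would bias the
generated mean upward by ≈1.5 points. An SD of 11.2 at mean 55.3 is not
attainable within the truncated-normal family on [40, 80]; the closest
(≈10.6) is used.

Patient hemodynamics are synthetic conventions (not cohort facts):
HR ~ N(70, 10) bpm, systolic N(130, 15), diastolic N(78, 10) mmHg
(pulse ≥ 25 mmHg enforced), SV N(75, 12) mL, BSA N(1.85, 0.2) m²,
myocardial mass N(130, 25) g, all truncated to physiological ranges;
mass fractions Dirichlet(27, 15, 15, 3) over LAD/LCx/RCA/LM; ejection time
0.33·√T, capped at 0.45·T. Each lesion is simulated in a single-artery
network (aorta + systemic Windkessel + three-segment branch whose distal
segment exceeds the WSS ROI). Labels: oracle FFR (finer-tolerance solve)
plus N(0, 0.03) measurement noise, positive iff ≤ 0.80. The single Gaussian
noise term stands in for a heterogeneous clinical decision basis
(pressure-wire FFR, perfusion imaging, ECG/wall-motion); a mixture noise
model is a documented extension point. Age and comorbidity covariates play
no role in any computation and are not generated.

What passing cohort tests show — and do not show: the pipeline's indices
discriminate lesions whose ground truth is generated *by the same physics*
with measurement noise; this validates internal consistency, monotone
index–severity relationships, and the evaluation stack, not clinical
accuracy on imaged patients (no plaque morphology, no segmentation error,
no microvascular disease heterogeneity, no silent-infarct territories).

## Problem sizes and determinism

Default runs: 1 ms output grid, ≤ 20 cycles; cohort sweeps: 5 ms grid,
rtol 10⁻⁵ (lesion FFR unchanged to 4 decimals versus defaults), 200-lesion
cohort as the standard end-to-end exercise. All randomness flows from a
single integer seed per cohort/config; reruns are byte-identical. The
acceptance script's targets are analytic limits of the OSI formula and are
deterministic by construction.

## Known limitations

Rigid walls, no vessel-wall motion, no autoregulation or pharmacokinetics
(hyperemia is an instantaneous resistance factor), no distributed 1D/3D
effects (wave propagation, curvature, side-branch steal beyond the lumped
splits), Poiseuille WSS (no 3D shear fields), and an empirical stenosis
law whose coefficients are geometry-independent defaults. The diagnostic
battery assumes a single binary endpoint per lesion and at most pairwise
AUC comparisons (no multiplicity correction beyond that).
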