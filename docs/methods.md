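# Methods

This note documents the models implemented in `hgsoc_kinetics`, the
parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical decisions inside the fitting
machinery.

## Growth laws and units

All kinetics are computed per month internally; days are converted at
the I/O boundary with 1 month = 30.4375 days (365.25/12). Volumes are
in cm³ and lesion initiation is a single cell, V₀ = 10⁻⁹ cm³.

The Gompertz law V(t) = V₀·exp[K(1 − e^(−βt))], K = ln(V∞/V₀), has two
free parameters per lesion once V∞ is fixed: the decay constant β
(per month) and — because scans start at an unknown lesion age — the
age at first scan t₁ (months). Its specific growth rate
(1/V)dV/dt = βK·e^(−βt) declines exponentially, so small lesions grow
fast and large lesions stall near V∞. The exponential law
V(t) = V₀·e^(αt) is kept both as the doubling-time model (its constant
rate is exactly what two scans measure without extrapolation) and as a
comparison back-projection model.

### Carrying capacity V∞

V∞ is not estimable from two scans per lesion, so it is fixed per site.
The default rule derives it from the data — the maximum observed volume
of that site in the loaded cohort — times a 1.05 headroom factor,
because the observation transform diverges exactly at V∞ and the
largest lesion must remain strictly inside its domain. Any fixed value
can be supplied instead (`vinf=` in `TumorGrowthNLME.from_cohort`).

This rule has a known consequence: when the cohort contains no
plateau-sized lesions, the data-derived V∞ underestimates the true
capacity, which compresses the transform for large lesions and biases
the back-projected population age *downward*. On the default synthetic
conditions the bias is roughly −18% (measured against generating truth
over 12 seeds; refitting with the generating V∞ removes it). Users with
external knowledge of plausible maximal burdens should pass V∞
explicitly.

## Eligibility screening and doubling times

A lesion series is analysed only if some successive scan pair shows at
least 10% volume increase and the first scan of that pair carries at
least 0.05 cm³ — both filters guard against segmentation artefacts
dominating the growth signal. With more than two scans, the earliest
qualifying successive pair is used. The burden floor is applied to the
site being analysed (not the patient's total burden). TVDT = ln2/α with
α = ln(V₂/V₁)/dt from that pair.

Group comparisons of doubling times use the two-sided
Wilcoxon–Mann–Whitney rank-sum test, exact for both groups ≤ 25
(without ties), normal approximation otherwise.

## Population model

On the transformed scale (y = −ln(1 − ln(V/V₀)/K) for Gompertz,
y = ln(V/V₀) for exponential) each trajectory is linear in time:
y = e^(θ₁) + e^(θ₂)·Δt with θ = (ln rate·t₁, ln rate) and Δt months
from the subject's first scan. Random effects are Gaussian on θ
(full 2×2 covariance D via its Cholesky factor; a diagonal-D option is
exposed), residual error is additive homoscedastic with scale λ on the
transformed observations, and the log parametrisation keeps rates and
ages positive.

Estimation alternates, in the classic linearisation scheme for
nonlinear mixed models:

1. **EB step** — per-subject posterior modes b᷈ᵢ of the random effects by
   penalised Gauss–Newton (batched across subjects, step-halving line
   search).
2. **LME step** — first-order expansion of the mean about θ^pop + b᷈ᵢ;
   the resulting linear mixed model's −2 log-likelihood, with θ^pop
   profiled out by GLS, is minimised over (Chol D, log λ) by L-BFGS-B
   with the analytic (envelope-theorem) gradient.

Convergence requires a relative objective change < 1e-8 and a
fixed-effect change < 1e-6; variance scales are bounded in
[1e-6, 1e3] on the standard-deviation scale. Two safeguards address
pathologies of the two-observations-per-subject design:

- *Step damping.* The relinearisation map can settle into a two-cycle
  (the D/λ decomposition is nearly unidentified with two observations
  per subject, and the inner optimum can hop between two basins). When
  successive update directions reverse, the step along (θ, modes) is
  halved, with a sticky cap so the damping persists.
- *Direct fallback.* If the alternation still fails to settle, the
  self-consistent linearised objective — with the EB modes and
  expansion point recomputed inside the objective — is minimised
  jointly over (θ, Chol D, log λ) by bounded Nelder–Mead. This removes
  the alternation entirely at ~10× the cost and resolved every
  observed non-convergence (0 failures in 120 fits across seeds,
  cohort sizes and both laws).

Fixed-effect covariance comes from the GLS information matrix at the
final linearisation; t₁^pop = exp(θ₁ − θ₂) with a 95% CI by the delta
method on g = θ₁ − θ₂ (se² = var θ₁ + var θ₂ − 2cov) exponentiated, so
the bounds are always positive. Individual ages use the EB modes:
t₁ⁱ = exp(θ₁ⁱ − θ₂ⁱ).

Initial values are per-subject OLS of y on Δt (the intercept is y at
the first scan, the slope the transformed growth rate), mapped to logs,
with moment estimates for θ^pop and D.

With exactly two observations per subject, individual β estimates are
noisy and the residual/random-effect split (λ vs D) is weakly
identified; population fixed effects remain well determined, which is
why the package reports population ages with CIs and treats individual
ages as ranking/plug-in quantities.

## Metastasis timing and screening windows

For dual-site patients the primary is the site with the larger
individual age t₁ (peritoneal-primary cases — omentum first — are
handled symmetrically), TTM = t₁,primary − t₁,secondary, and V_met is
the primary's modelled volume at the secondary's initiation. Detection
times invert the primary's own (EB) trajectory at the thresholds
US = 0.5 cm³ and CA125-equivalent = 0.015 cm³. WOO = TTM − detection
time is reported unclamped, so pre-detection metastases are the
negative-WOO cases. "Missed by annual screening" counts cases with
TTM < 12 months: even single-cell detection resolution cannot catch a
lesion whose entire pre-metastatic lifetime fits inside one screening
interval.

## Virtual-population simulation

Each of N virtual patients (default 10,000) receives a primary site
(omentum with probability p_om = 0.36), a decay rate β drawn log-normal
with log-mean (ln β)^pop and log-variance D[ln β, ln β] from that
site's Gompertz fit, and a V_met resampled with replacement from the
empirical pool of dual-site case estimates; V∞ stays fixed per site.
t_met and the detection times come from the trajectory inverse, and the
summary reports the fraction with WOO > 0 per modality plus the median
and IQR of the positive windows. Because detection and metastasis lie
on the same monotone trajectory, the detect-before-metastasis fraction
equals the share of the V_met pool above the threshold — a useful exact
cross-check that is asserted in the tests. Monte-Carlo error on the
fractions at N = 10,000 is below one percentage point.

## Synthetic cohort generator

The generator emulates a serial-CT HGSOC cohort: 34 patients split into
ovarian-only / omental-only / dual-site growers, two scans per patient
at log-normal intervals (median 31 days), Gompertz trajectories from a
single cell, and multiplicative log-normal measurement noise
(CV 5% — CT volumetry error scales with lesion size). Dual-site
patients are synthesised secondary-first: the secondary's age at first
scan (log-normal, median 9 months) and the TTM (log-normal, median
13.1 months) are drawn and the primary's age is their sum, which
guarantees both lesions are old enough to be measurable, as they were
in observed dual-site cases.

Two structural choices matter:

- **β/age anticorrelation** (ρ = −0.7 between ln β and ln t₁). With
  independent draws, old lesions with large β sit at the Gompertz
  plateau and never pass the 10% growth filter, so dual-site cases
  almost never had two growing lesions. A cohort of *observed growing*
  lesions cannot contain old fast-decelerators — the anticorrelation
  encodes that selection effect directly.
- **Calibrated site kinetics.** β medians (0.11/0.16 per month for
  ovary-pelvis/omentum, σ_ln = 0.4) and age medians (20.4/14.7 months,
  σ_ln = 0.25) were calibrated once, averaging 20 seeds, so that the
  default cohort reproduces the intended study conditions after
  filtering: eligible-lesion TVDT medians ≈ 2.2/1.8 months, an eligible
  split of roughly 13/10/11 patients, and a dual-case TTM median
  ≈ 13 months. The filter interacts with the spreads, so no closed-form
  single-trajectory solution gives these values.

What the generator does **not** emulate: segmentation error structure
(it uses i.i.d. log-normal noise, not slice-thickness or
contouring artefacts), non-growing or shrinking lesions beyond those
produced by the plateau, more than two disease sites, inter-lesion
correlation within a patient beyond the shared scan days, and
treatment effects. Passing tests therefore demonstrate that the
estimation machinery recovers known Gompertz ground truth under
realistic sampling and noise — not that real HGSOC follows a Gompertz
law, which two scans per lesion cannot decide.

## Problem sizes and tolerances in the test suite

Analytic oracles run at machine precision (round trips to 1e-10,
closed forms to 1e-12). Parameter-recovery experiments use 50 subjects
(model-scale data, recovery within 3 standard errors) and 200 patients
(volume-scale data, population age within 20% of the fitted subjects'
generating geometric-mean age). The study-conditions pipeline runs at
the default 34 patients with a fixed seed; TTM-median recovery is
additionally checked at 120 patients (within 35%), reflecting that a
median over ~10 dual cases, each a difference of two shrunken EB ages,
is the noisiest quantity in the pipeline. The simulation tests use
10,000 virtual patients and binomial-error bounds.

## Known limitations

- Two observations per lesion make every growth law fit equally well;
  model choice is an assumption, not an inference.
- The V∞-from-data rule biases ages downward on cohorts without
  plateau lesions (see above).
- Individual ages are EB-shrunken: their between-patient spread is
  compressed, and differences of two of them (TTM) inherit both
  shrinkage and both sites' noise.
- The CA125 threshold is a volume-equivalent proxy; actual CA125
  secretion kinetics are not modelled.
- Screening-policy variations (interval, adherence, sensitivity curves)
  and mortality benefit are out of scope.
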