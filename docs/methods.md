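# Methods

`perfquant` quantifies myocardial blood flow (MBF) from ROI-level dynamic
curves acquired simultaneously with dynamic contrast-enhanced MR and
13N-ammonia PET, and provides a digital perfusion phantom so the whole
chain is testable without any acquisition. This note records the models,
the defaults and why, the numerical choices, and the known limitations —
including one systematic effect the pipeline reproduces on purpose.

## The digital perfusion phantom

The phantom is a single well-mixed compartment of dispersion volume V_d
(mL) fed by an arterial input C_a(t) at volumetric flow Q = F·m (mL/min),
where F is the perfusion rate in mL/g/min and m the mass equivalent (g) of
the compartment:

    dC_m/dt = (Q / V_d) · (C_a(t) − C_m(t)).

Knowing V_d and m calibrates every recovered rate constant to mL/g/min,
which is exactly how the bench phantom it emulates is used. Defaults are
V_d = 45 mL and m = 45 g — a unit-ratio compartment in which F maps 1:1
onto the washout rate in min⁻¹. Only the ratio V_d/m enters the physics;
the absolute values are stand-ins, since the bench device's dispersion
volume is known to its operators but not published.

Boluses are peak-normalized gamma variates
g(t) = d·((t−t_a)/(αβ))^α·exp(α−(t−t_a)/β), the standard first-pass shape,
with α = 3, β = 4 s (first-pass width ≈ 15–20 s at a 4 mL/s injection).
One protocol run produces, on a single clock:

- a dilute gadolinium bolus (relative dose 1/10) just after the baseline
  dynamics, and a neat bolus (dose 1) an interbolus delay later
  (default 120 s, the phantom protocol's washout gap; 25 s is the in vivo
  spacing and is configurable);
- the tracer bolus co-injected with the neat contrast bolus;
- MR dynamics at one sample per heartbeat (60 bpm → 1 s) for 240 dynamics,
  through the SR-FLASH signal model below, with 8 pre-contrast baseline
  dynamics;
- PET activity with physical decay (13N half-life 9.96 min, reference =
  injection) binned into 60 × 3 s + 8 × 15 s frames (68 frames, 300 s).

Concentration scales are free parameters of the simulator (no published
values exist): the neat bolus peaks at 0.5 mmol/L arterially and the
dilute at 0.05 mmol/L, reflecting the large dilution volume of the bench
circuit and the dual-bolus design goal that the *measured* AIF stay in the
near-linear signal regime; the tracer bolus peaks at 100 kBq/mL (activity
units cancel in the kinetic model).

Noise models are the simplest that exercise the fitters' weighting:
additive Gaussian noise on MR signal (default σ = 0.1 a.u. against an M0
of 1000 — ROI-mean noise after averaging tens to hundreds of pixels) and
multiplicative Gaussian noise on PET frame means with a coefficient of
variation cv/√(duration) (default cv = 0.03 at 1 s), mimicking count
statistics. One integer seed drives all draws; zero noise parameters give
bit-reproducible datasets.

The tissue response is computed by *exact* integration of the exponential
kernel against the piecewise-linear interpolant of C_a (a one-step
recursion per sample, evaluated as an IIR filter on uniform grids). A
rectangle-rule convolution at 1-s sampling would bias the simulated curves
by more than the fitters' own error; with the exact kernel the recovery
error is dominated by the estimators, which is the point of the phantom.

What the phantom does **not** emulate: recirculation, multi-chamber
dispersion upstream of the compartment, motion and respiratory artefact,
pulsatile flow, tracer trapping or metabolites, pixel-level structure.
Passing tests therefore demonstrate correctness of the estimators under
clean single-compartment physics, not robustness to in vivo confounds.

## MR signal model and AIF handling

Signal is the analytic saturation-recovery FLASH expression

    S(C) = M0 · sin α · (1 − exp(−TI·R1)),   R1 = 1/T10 + r1·C,

with the phantom protocol TI 100 ms / flip 10° (saline T10 = 3000 ms) and
the volunteer protocol TI 115 ms / flip 14° (blood T10 = 1900 ms,
myocardium 1200 ms); gadobutrol relaxivity defaults to r1 = 5.0
L·mmol⁻¹·s⁻¹ at 3 T. A full Bloch simulation of the FLASH readout train is
deliberately out of scope: the closed form preserves the saturating
non-linearity that the conversion machinery exists to correct, and remains
invertible and testable. The readout-train correction is an extension
point (swap `srflash_signal` when building the lookup table). T2*/TE
effects are ignored (TE ≤ 1 ms).

Volunteer-mode conversion inverts a tabulated LUT of the forward model
(4096 points by default; round-trip error < 10⁻³ mmol/L), after a
proportional rescaling that matches the LUT's zero-concentration entry to
the measured baseline signal — receiver gain and M0 drop out. Samples
below baseline clamp to zero and are counted; samples above the ceiling
raise a saturation error naming the offending time points.

The dual-bolus surrogate AIF is the dilute-bolus passage scaled by the
neat:dilute dose ratio (10) and shifted so its foot lands at the neat
arrival. The foot is the first sustained crossing of 5% of peak on a
3-sample moving average; ties break to the earliest sample.

Phantom mode does not convert signal to concentration at all. Following
the bench analysis, baseline-corrected signal curves are used directly and
the AIF is rescaled so its time-integral matches the myocardial curve's —
for a conservative compartment sampled to complete washout,
∫C_a dt = ∫C_m dt, so integral matching fixes the AIF scale without
absolute calibration. Two pipeline details make this robust on a finite,
noisy acquisition:

1. **Washout-tail completion.** At low flow the washout time constant
   (60 s at 1 mL/g/min for the unit-ratio compartment) is comparable to
   the MR window remaining after the neat bolus (~110 s), so the
   trapezoidal ∫C_m misses up to ~18% of the indicator mass and would
   inflate the recovered flow by the same factor. The myocardial integral
   is therefore completed with the analytic tail A·e^(−kT)/k of an
   exponential fitted (linear-scale least squares, log-linear seeded) to
   the last third of the curve. The tail is exact for the compartment
   model and a mild approximation for real washout.
2. **Support cropping and re-baselining.** The surrogate AIF is zeroed
   outside its bolus support (foot − 2 s to foot + 50 s) so out-of-bolus
   noise does not accumulate in ∫C_a after ×10 scaling, and the myocardial
   window is re-baselined on the samples immediately before the neat
   arrival so residual dilute-bolus washout does not leak into the fit.

## CMR quantification: Fermi-constrained deconvolution

The myocardial curve is modelled as C_a ⊛ R with the Fermi impulse
response

    R(t) = F_A / (1 + exp(k·(t − τ0 − τd)))  for t ≥ τd,  0 before,

and MBF read at the onset, R(τd) = F_A/(1+e^(−k·τ0)), converted to
mL/g/min by ×60 and the V_d/m calibration (phantom) or a 1.05 g/mL density
convention (in vivo). Fitting is bounded nonlinear least squares
(`scipy.optimize.least_squares`, tolerances 10⁻¹², ≤500 evaluations per
start) over (F_A, k, τ0) with the delay handled as an integer-sample shift
of the AIF searched over {0, 1, 2} samples — keeping the objective smooth.
Deterministic multistart: amplitude from the central-volume ratio
max(tissue)/∫AIF, k ∈ {0.05, 0.2} s⁻¹, τ0 from the tissue time-to-peak;
best residual sum wins, ties break to the smaller parameter norm.
Convolution uses trapezoid-weighted discrete convolution on the uniform
dynamic grid (non-uniform grids are resampled and logged, not rejected).
The fit window defaults to the full curve; a first-pass cutoff is
available but not used by default, because short windows cannot separate
the plateau-onset and zero-width solution branches of the Fermi family and
the read-off becomes unstable.

**Known, deliberate property: the CMR arm under-reads on compartment
phantoms.** The impulse response of a well-mixed compartment is a pure
decaying exponential, R_true(t) = (Q/V_d)·e^(−(Q/V_d)t); the Fermi family
is flat near t = 0 and its least-squares best fit averages away the
immediate decay, reading ~6% low at 1 mL/g/min and ~12% low at 5 mL/g/min
on noise-free concentration curves — compounded by a few percent of MR
signal saturation of the neat-bolus myocardial curve in signal units. A
cost-surface check (refitting with the plateau width constrained upward)
shows this is a genuine data preference, not an optimizer ridge.
Alternatives evaluated and rejected during design — first-pass window
cutoffs (branch-jumping), fixing k from the washout tail, an area-one
constrained Fermi — were all less accurate or less stable. The result is
that across the 1–5 mL/g/min grid the two arms correlate almost perfectly
while CMR sits systematically below PET, the same direction and comparable
magnitude of disagreement that the physical phantom experiments show; in
vivo, where the tissue impulse response genuinely has a plateau (capillary
transit), the Fermi read-off is the validated standard. Users comparing
arms on compartment-like data should expect the negative CMR bias and
read the agreement report, not a single arm, as the result.

## PET quantification: one-tissue-compartment model

Frames are decay-corrected with the exact frame-average factor
f = λΔt·e^(λt₁)/(1 − e^(−λΔt)) (λ = ln2/T½, t₁ = frame start −
injection), implemented with `expm1` so arbitrarily long half-lives remain
exact; a truly constant source measured with decay corrects back to
machine precision, and a state flag prevents double correction.

The kinetic model is

    C_t(t) = (1 − Vb)·K1·∫₀ᵗ C_a(u)·e^(−k2(t−u)) du + Vb·C_a(t),

fitted to frames whose midpoints fall inside the window (default 240 s —
the conventional first-4-minutes cutoff that in vivo keeps metabolite
build-up out of the data; the phantom has no metabolites, so the window is
the whole mechanism and nothing more). Weights are √(frame duration),
matching frame-mean variances ∝ 1/duration. The continuous input is
rebuilt from the frame means at frame midpoints; the model is evaluated on
a 0.25-s grid with the exact exponential-kernel convolution and then
frame-averaged, consistent with the binner (fine-grid vs 68-frame fits
agree within 3%). Multistart is deterministic (K1 from an early-frame
slope estimate and twice it; k2 ∈ {0.1, 1.0} min⁻¹; Vb start 0.05 when
fitted). Vb is bounded [0, 0.5] and fixed to 0 in phantom mode (no
spillover geometry). MBF = K1 by default; an optional extraction-fraction
hook solves K1 = F·E(F) by bracketed root-finding for users who want the
~85% first-pass extraction of ammonia folded in, and is off by default to
match the implemented model. A window-sensitivity diagnostic reports fits
at 180/240/300 s side by side.

On the noise-free phantom the PET arm recovers the grid within ~1.5% and
the fitted k2 tracks the compartment washout Q/V_d within 10% — the
no-trapping check.

## Agreement statistics

Pearson r with a two-tailed p (t transform, n−2 df, via
`scipy.stats.pearsonr`); Bland–Altman bias = mean(CMR − PET) with
1.96·SD(n−1) limits (CMR under-reading ⇒ negative bias; no small-sample t
correction); and ICC(2,1) — two-way random effects, absolute agreement,
single measure — computed from the two-way ANOVA mean squares. ICC(2,1)
was chosen because the same coefficient serves both test–retest
repeatability and cross-modality agreement, where absolute agreement is
the defensible form; the form is recorded in every report. The
implementation is cross-checked in the tests against an independently
coded ANOVA-table oracle and against `pingouin`'s ICC(A,1).

Segment tables on the 16-segment AHA model aggregate by unweighted means
into LAD (1,2,7,8,13,14), RCA (3,4,9,10,15) and LCX (5,6,11,12,16)
territories plus a global mean; the mapping is configuration, so
alternative assignments are testable. Whether territory pairs should pool
segments across subjects or use per-subject territory means is a study
choice; both are possible through the `compare` interface and the report
carries the n used.

## Reproducibility and problem sizes

Everything stochastic flows from one integer seed
(`numpy.random.default_rng`); identical config + seed reproduces every
artifact byte-for-byte (timings live only in the log). The test suite and
the acceptance script run the phantom at its native problem sizes — 240 MR
dynamics, 68 PET frames, a 0.1-s simulation grid — and the replicate
studies use 50 noisy repeats per flow, sizes chosen so a full sweep of
both arms takes seconds on a single core while leaving the estimators'
sampling error well below the effects being measured.
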