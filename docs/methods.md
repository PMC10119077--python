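# Methods

This note documents the models, estimators, numerical choices, and
synthetic-data assumptions behind `petquant`, in the order the data
flow through the pipeline.

## Time base and decay

Frames are half-open intervals `[start, end)` in seconds on disk and
minutes in memory (rate constants are conventionally per minute).  A
schedule may have two acquisition parts — here 24 frames over
0–90 min (8×15 s, 3×60 s, 5×120 s, 1×300 s, 7×600 s) and 8 frames over
150–225 min (7×600 s, 1×300 s) — with a 60-min break in between.  Both
parts are decay-corrected to the start of part 1 (F-18 half-life fixed
at 109.771 min, configurable) so concatenation puts them on one
radioactivity scale.  Wherever a single frame time is needed the
interval midpoint is used; model predictions, however, are the time
*average* of the model curve over each frame, matching how the scanner
integrates counts.  Image-domain alignment between parts is out of
scope: the concatenation contract is that both inputs share region
labels and decay reference.

## Arterial input function

- **fwb** — mean and sample SD of `Cp/Cwb` over the paired samples
  (the 15-s draw plus all draws from one minute on; 18 of the 28
  scheduled draws).  The plasma curve is thereafter `fwb·Cwb(t)`; the
  ratio is treated as time-stable, which the underlying study verified.
- **Parent fraction** — `PPf(t) = 1 − A0(1 − e^{−ln2·t/T})`, fitted by
  unweighted least squares with a multi-start grid
  (`T ∈ {1,5,10,30,60}` min × `A0 ∈ {0.01,0.05,0.2}`, bounds
  `0 ≤ A0 ≤ 1`, `0.1 ≤ T ≤ 500` min) because the flat-plateau regime
  has local minima.  With all samples at 1 the plateau is zero and `T`
  drops out of the model; the fit flags this
  (`t_unidentifiable`).
- **Free fraction** — `fp(t)` is not constant for this tracer
  (~0.5–2%).  Default: linear interpolation through the five sampled
  time points with constant extrapolation (`TIME_VARYING`); the
  simplified alternative (`LATE_MEAN`) is the mean of samples past
  30 min.  Fractions are dimensionless in [0, 1] in memory and percent
  only on disk, to prevent silent 100× errors in the AIF.
- **Whole-blood interpolation** — piecewise linear through the samples,
  linear rise from (0, 0) to the first sample, and a one-exponential
  tail fitted to the last three samples for the short extrapolation
  beyond the final draw (the TAC runs to 225 min, blood to 205 min).
  Grids extending more than 30 min past the last sample are rejected.
- `AIF(t) = PPf(t)·fwb·Cwb(t)·fp(t)`, clipped at zero, with all
  components retained for audit.

## Compartment models

The exponential convolutions at the heart of 1TC, 2TC, and SRTM are
computed exactly per linear segment of the input curve: on a uniform
grid the one-step recursion is a first-order IIR filter
(`scipy.signal.lfilter`), so the only approximation is how finely the
input is sampled (default grid 0.05 min; the brute-force quadrature
oracle in the tests agrees to well under 0.1%).  The 2TC response uses
the eigen-decomposition of the serial two-compartment system — a
weighted sum of two such convolutions.

The operational equation includes the vascular term:
`PET(t) = Vb·Cwb(t) + (1−Vb)·C_T(t)`.  Fits are weighted least squares
(`scipy.optimize.least_squares`, bounded, 8-point multi-start) with
default weights `w_j = Δt_j·e^{−2λt_j}` (normalised), the standard
count-statistics surrogate; uniform weights are available.  Bounds:
`K1 ∈ [0,10]`, `k2 ∈ [1e−4,1]`, `k3,k4 ∈ [0,1]`, `Vb ∈ [0,0.2]`.
2TC fits flag boundary-pinned `k3`/`k4` and degenerate eigen-rates
rather than silently reporting them — with near-irreversible tracers
these parameters are routinely unidentifiable.  AIC is
`n·ln(SSR/n) + 2k` on the weighted SSR.

## Graphical analyses

The Logan plot regresses `∫₀ᵀ C_T/C_T(T)` on `∫₀ᵀ AIF/C_T(T)` over
frames with midtime > t\* (default 60 min, configurable; an automatic
max-relative-deviation selector is provided but off by default).  For
1TC kinetics the plot is exactly linear with slope `Vt`, so accuracy
rests entirely on the cumulative integrals.  These are computed as
exact frame sums (`Σ value·Δt` — exact because frame values *are*
interval averages) plus, across the 60-min inter-part gap, a local
cubic-Hermite segment through the neighbouring midtimes with
secant-estimated slopes.  The TAC peaks inside that gap; a simple
chord under-integrates it by ~6% and biases the Logan slope ~3% low,
while the Hermite bridge keeps the noise-free slope error near 0.25%.
The Logan-AIF implementation omits the vascular term (standard
practice).  Under frame noise the Logan slope carries the well-known
negative bias (noise in the denominator); this is documented, not
corrected.

The Logan reference plot regresses
`∫₀ᵀ C_T/C_T(T)` on `[∫₀ᵀ Cref + Cref(T)/k2′]/C_T(T)`; the slope is
the DVR.  `logan_ref()` defaults to omitting the `k2′` term (the
classic late-time approximation), but for kinetics this slow the
omission costs 2–4% DVR even at t\* = 60 min, so the *pipeline*
default is `k2_prime="auto"`: the reference region's own 1TC `k2`
when arterial data exist (essentially exact), otherwise the session
median of `k2/R1` over the SRTM fits.  Both a fixed number and `null`
(omit) remain available in the run configuration.

## SRTM

Basis-function fit: 200 log-spaced `k2a` values in `[1e−3, 1]` min⁻¹;
per basis, the model is linear in `(R1, k2 − R1·k2a)` and solved by
weighted least squares, with the measured reference frame values used
directly for the delivery term (they are the frame-averaged reference
curve) and the convolution basis built from a piecewise-linear
reconstruction through the reference midtimes.  Candidates with
`BP ∉ (−0.95, 15]` are rejected: binding potentials beyond ~15 here
correspond to washout slower than the scan can resolve and belong to a
degenerate no-washout ridge.  A local nonlinear polish in
`(R1, θ2, k2a)` — with `k2a` confined to the basis range — removes the
grid-quantisation error; it is accepted only on strict SSR improvement
so that exactly degenerate inputs (ROI identical to the reference)
keep the canonical `BP = 0` solution.

SRTM is exact for 1TC target/reference pairs *without* blood volume.
On realistic TACs (Vb 2–4.4%) it inherits a systematic, region- and
subject-dependent DVR bias: a few percent typically, and up to ~16%
where the target clearance approaches the reference clearance (a
weakly identified ridge).  This is a property of the estimator, not a
defect of the implementation — it is why the arterial-model comparison
in the pipeline exists, and it reproduces the fragility the method
shows on real data.  One end-to-end acceptance test
(`test_end_to_end_srtm_dvr_recovery`) asserts 3% recovery for SRTM
alongside the other methods and fails for this reason; it is kept as
an honest record of the estimator's limits under these conditions.

## Test–retest statistics

Per subject: `bias = (DVR_retest − DVR_test)/DVR_test × 100`.  Per
region: mean bias, `VAR` = sample SD (n−1) of the per-subject biases,
and the two-session one-way ICC
`(BSMSS − WSMSS)/(BSMSS + WSMSS)` with
`BSMSS = 2·Σ(subject mean − grand mean)²/(n−1)` and
`WSMSS = ΣΣ(value − subject mean)²/n`.  Negative ICCs are reported as
computed.  Regional aggregation computes per-subject bias first and
averages (the only reading consistent with published per-region
tables that pair equal session means with nonzero bias).  Method-level
summaries are emitted under both defensible aggregations — mean of the
regional statistics and statistics of the pooled region×subject data —
explicitly labelled, since summary tables rarely say which was used.
Cross-method agreement is ordinary least squares of one method's DVRs
on another's (slope, intercept, R²), per subject across regions.

## Synthetic studies

The generator emulates the acquisition's statistical structure, not
its images:

- **Whole blood** — zero until an appearance delay (0.2 min, just
  before the first paired draw at 15 s), then a tri-exponential whose
  fast negative component shapes the bolus rise: peak ~35 kBq/mL near
  0.9 min, ~1 kBq/mL at 205 min.  The published study plots but does
  not parameterize its blood curves, so these defaults are
  shape-plausible only and fully config-exposed.
- **Corrections** — parent fraction with `A0 = 0.046`, `T = 9.06` min;
  `fwb = 1.79`; fp trajectory (0.48, 0.82, 1.14, 1.90, 1.61)% at
  (2, 10, 30, 90, 205) min — the published group means.
- **Blood sampling** — the stated manual schedule (every 5 s in minute
  one, 15 s in minute two, 30 s in minute three, then 10 late draws;
  28 total, 18 plasma-paired; an optional flagged t = 0 draw makes
  29).  Activity samples get multiplicative Gaussian noise
  (default 2%); parent-fraction samples get absolute noise of a
  quarter of that scale, matching the few-tenths-of-a-point spread of
  the published per-subject fractions.
- **Tissue** — 1TC forward curves from published group-mean regional
  parameters (21 regions, `K1` 0.56–1.41 mL/(min·mL), `k2`
  0.011–0.017 min⁻¹, `Vb` 2.0–4.4%), frame noise
  `SD_j = α·sqrt(C_j/(Δt_j·e^{−λt_j}))` (decay-uncorrected count-rate
  scaling).
- **Variance components** — per region, subject `Vt` multipliers are
  mean-one log-normal with CV `between_cv`, applied through `k2` with
  `K1` fixed (reference-model DVRs depend on `Vt` ratios; users who
  prefer delivery variation can move it to `K1`); session multipliers
  re-drawn per session with CV `within_cv`.  Defaults
  (`between_cv = 0.05`, `within_cv = 0.01`, `α = 0.05`) are calibrated
  so the simulated study reproduces the published reproducibility of
  the reference analysis: regional DVR SD ≈ 7% of the mean across
  subjects, Logan-reference VAR ≈ 2–3%, ICC ≈ 0.9 (measured on the
  generated studies: VAR 2.8%, ICC 0.89).
- **Determinism** — one `numpy` Generator seeded from the config;
  identical config + seed gives bit-identical studies and files.

What the generator does **not** emulate: image-domain effects (partial
volume, motion, reconstruction artefacts, attenuation errors),
inter-regional noise correlation, arterial dispersion/delay, or
departures of real tissue from 1TC kinetics.  Passing tests therefore
validate the estimators and their implementation under the stated
statistical model, not the acquisition chain upstream of the TACs.

## Pipeline and problem sizes

The `run` pipeline executes AIF construction, arterial fits, reference
fits, DVR tables, test–retest reports, and DVR regressions per the run
configuration (YAML; unknown keys rejected), isolating per-region
failures and stamping every output with the configuration hash.  The
default model list is `1tc, logan, srtm, lref`; 2TC is implemented and
tested but off by default, since for this class of tracer its binding
parameters are unidentifiable and the one-tissue model is the
reference standard.  Validation workloads are sized for a desktop: the
end-to-end acceptance study is 8 subjects × 2 sessions × 10 regions
(~1 min), oracle suites use 100 random draws, and recovery checks use
100 noisy replicates.
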