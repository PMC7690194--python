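# Methods

This note documents the models, estimators, numerical choices and
limitations behind `oscferm`.  It is the package's own account of its
science; every number quoted here is computed by the test suite or the
analysis drivers.

## Chemostat mass balances

All rate computations assume a well-mixed continuous reactor at constant
working volume:

- biomass: `dX/dt = (mu − D) X`
- substrate: `dC_S/dt = D (S_f − C_S) − q_s X`
- liquid products: `dC_P/dt = q_P X − D C_P`
- dissolved gases: `dC_gas/dt = q_gas X − D_G C_gas`

Inverting these for the specific rates gives the formulas in the README.
Two points deserve note:

- **Substrate equation.** A variant of the uptake formula that multiplies
  `C_S` by `dX/dt` circulates in the fermentation literature; that term
  has units g²/(L²·h) and cannot be added to `D·S_f`.  We implement the
  dimensionally consistent balance `q_s = (1/X)(D·S_f − D·C_S −
  dC_S/dt)`, treating the inconsistent variant as a typographical slip
  of `D·C_S`.
- **Gas dilution rate.** `D_G` is a separate operating parameter (gas
  stripping is much faster than liquid dilution) and is never derivable
  from `D`; the API requires it explicitly wherever a gas channel is
  processed.  The presets use `D_G = 0.5 h⁻¹` as a plausible assumption
  — the value only scales the gas rates, not the concentration
  trajectories that the recovery tests target.

**Derivative estimation** is a degree-2 local polynomial fit over a
5-sample window by default (central differences at window 3), done in
time rather than index so irregular grids are handled.  Points with
biomass below `x_min = 10⁻³ g/L` are masked (NaN) rather than divided
through.

## Synthetic-data generator

The generator's role is to stand in for an unpublished bioreactor
campaign, so its defaults *are* the study conditions: feed 88 g/L and
D = 0.048 h⁻¹ for the oscillatory and steady presets, feed 44 g/L for
the damped regime, D = 0.096 h⁻¹ for the non-oscillatory control, 3-h
sampling (the campaign's sampling interval is not reported; a few hours
matches the figure resolution) and 2–3% multiplicative measurement
noise.

### Waveform family and why rates are derived, not primitive

Channels follow a piecewise raised cosine: within one period `T` the
value rises as a cosine half-wave over `rise_fraction·T` and falls over
the remainder.  The family is C¹ (continuous value and slope) with a
*curvature break* at each extremum — a deliberate, minimal encoding of
asymmetric cycles.  It only approximates the short "plateau" shoulders
seen in real rate curves.

The calibrated presets parametrize the *concentrations* (log-biomass,
substrate, products, gases) and derive the exact rate waveforms from the
balances analytically.  The alternative — raised cosines on the rates —
cannot produce asymmetric biomass stages at all: periodicity forces `mu`
to cross `D` at its time-average, and a raised cosine spends equal time
above and below its mean for *any* rise fraction.  Concentration-space
parametrization sidesteps this while keeping mass-balance consistency
exact.  `simulate_chemostat` still integrates the ODE system (LSODA,
rtol 10⁻⁸) with those rate waveforms and is cross-checked against the
closed form to ~10⁻⁶; rate-space waveforms remain available for generic
configurations.

### Oscillatory preset geometry

The encoded limit cycle uses period 53.4 h with stage I = 21.0 h and
stage II = 32.4 h.  The reported geometry is internally tense: the
headline mean period (51 h) is computed over a different window than the
printed stage-duration ranges (20–22 h and 32–41 h), which by themselves
imply cycles of 52–63 h.  The preset sits inside all three constraints
simultaneously — stage I at the middle of its range, stage II just
inside its lower bound, period within 5% of the 51-h mean.  Channel
extrema are encoded directly (H₂ 0.07–2.47 mmol/L, CO₂ 2.0–21.98
mmol/L, ORP −568 to −271 mV, glycerol 3–55 g/L) with peak offsets
relative to the biomass peak: lactate, formate and H₂ peak mid stage II
(+16.2 h), CO₂ and ORP peak mid stage I (−10.5 h).

The first simulated cycle is excluded from every recovery statistic.
With on-cycle initial conditions the ODE transient is negligible, but
the convention is kept so the protocol is meaningful for arbitrary
initial states; recovery runs simulate `n + 1.6` periods so that `n`
complete cycles (and `n` peak-to-peak intervals) sit strictly inside the
analysis window.

### Counts and assay plates

RNA-seq counts follow the five-time-point design (three falling-stage,
two rising-stage samples).  Type I genes are suppressed `stage_fold`-fold
on the falling stage, type II on the rising stage — mirroring by
suppression rather than amplification keeps library composition
balanced, so flat genes stay flat after within-sample normalization
(an early amplification-based profile dragged the entire flat background
into type I calls through the TPM denominator; the compositional artifact
is real, and worth remembering when interpreting TPM patterns).  Counts
are negative-binomial with user-set dispersion (Poisson at 0).

Assay plates are linear absorbance slopes (ΔA570/min) over standards at
0.01–0.05 mM with additive Gaussian noise; the blank slope is zero in
the noise-free default (the calibration intercept nonetheless remains a
free parameter when fitting, since real plates have reagent blanks).

## Oscillation estimators

- **Extrema**: `scipy.signal.find_peaks` with prominence ≥ 20% of the
  channel range, alternation enforced (between two peaks only the
  deepest trough survives; ties keep the earliest), sub-grid refinement
  by a parabola through the three neighboring samples.
- **Period**: mean of consecutive peak-to-peak intervals on the mildly
  smoothed (Savitzky–Golay, window 5, degree 2) channel.  Cycles whose
  interval deviates >30% from the running median are flagged irregular
  and excluded from the mean (campaigns contain irregular windows; the
  exclusion rule is ours).  The estimate is cross-checked against the
  first autocorrelation maximum, warning at >20% disagreement.
  Symmetric-parabola refinement biases *individual* peak times on
  asymmetric cycles, but the shift is common to consecutive peaks and
  cancels in the differences, so the period stays unbiased.
- **Cycle boundaries** are different: stage durations are differences of
  a *trough* and a *peak* time, whose refinement shifts have opposite
  sign, so the parabola bias does not cancel (≈ ±0.6 h at 3-h sampling
  for the preset's curvature ratio).  `segment_cycles` therefore refines
  boundaries with a two-sided polynomial (separate quadratic+cubic on
  each side of a free breakpoint, 11 samples) that accommodates the
  curvature break; noise-free bias is ≈0.3 h and the cycle-averaged
  stage durations recover the encoded values to a few tenths of an hour
  at 2% noise.  Biomass is log-transformed first when strictly positive
  (growth is multiplicative; monotone transforms leave extremum times
  unchanged).
- **Phase positions** are reported in [0, 1) with 0 at the stage-I
  trough and the stage boundary at `stage1_duration/period`.
- **Phase lags** are circular means of per-cycle peak-time differences,
  mapped to (−T/2, T/2]; antisymmetry and additivity hold by
  construction and are property-tested.
- **Regime**: "none" if fewer than two prominent peaks or if the median
  peak amplitude is below 4× a robust noise estimate (MAD of first
  differences) — without this guard, pure measurement noise on a steady
  channel is mistaken for oscillation.  Otherwise log peak amplitude is
  regressed on time; amplitude half-life ≤ 3 periods ⇒ "damped"
  (regimes that vanish within a few cycles), else "sustained".  The
  3-period threshold is our operationalization; no published criterion
  exists.

## Redox and expression conventions

- Calibration keeps its intercept; negative concentrations after blank
  correction are clipped to zero and flagged, quantifications beyond
  1.5× the top standard are flagged as extrapolated.
- FDH activity uses ε₃₄₀(NADH) = 6.22 mM⁻¹cm⁻¹ by default
  (configurable); one unit = 1 mmol NADH/min, following the assay's
  stated unit definition (three orders of magnitude larger than the
  conventional enzymology unit — values look correspondingly small).
- NAD⁺/NADH ratios mask NADH below 10⁻³ mM.
- ORP is summarized by the same cycle statistics as every other channel;
  there is no redox-specific extremum code.
- TPM uses annotated gene length (bacterial, unspliced; no
  effective-length correction).  TMM follows the published recipe (30%
  two-sided trim on M, 5% on A, inverse-variance weights, factors scaled
  to geometric mean 1) and is tested against edgeR's implementation.
- The DEG filter applies the fixed thresholds p_adj < 0.001 (BH) and
  |log2FC| ≥ 1 on top of an exact binomial two-library test of each
  gene's count split against the proportion implied by TMM-scaled
  library sizes.  This is a deliberate, documented substitute statistic:
  the thresholds are the analysis's substance, the original tool's
  internal MA-plot statistic is not reproduced.
- Pattern calls use max/min sample stages with a 2-fold minimum
  (pseudocount 0.5); fold changes use pseudocount 0.5.

## Genome statistics

N50 is the length at which the descending cumulative sum first reaches
half the total (the standard convention; assemblers differ on ties, so
it is stated).  GC% excludes ambiguity codes from the denominator by
default — they still count toward total length — with an all-bases
variant behind a flag, since reporting conventions vary.

## Numerical notes and degenerate inputs

- Raised cosines are C¹: finite-difference derivatives carry an O(h)
  error within one sample of each curvature break and an O(h²)
  third-derivative error inside steep segments.  Accuracy claims
  (round-trip <1% of amplitude; balance residuals <10⁻³ × scale) hold on
  1-h and 0.5-h grids respectively, away from the isolated break points;
  tests encode exactly that.
- Constant series produce no extrema (a relative-range floor of 10⁻¹²
  guards against float-epsilon wiggle), `classify_regime` returns
  "none", and `detect_period` returns no period.
- Negative ODE states abort the simulation; presets are chosen so all
  concentrations stay positive.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical configuration and seed give
  bitwise-identical datasets.

## What passing tests do and do not show

The generator reproduces the *geometry* of the observed oscillation —
periods, stage asymmetry, amplitudes, lags, regimes, balance-consistent
kinetics — plus multiplicative noise.  It does not emulate biological
cycle-to-cycle irregularity (the real campaign has windows of irregular
period), plateau-shaped rate curves beyond the cosine approximation,
sampling gaps, autocorrelated sensor drift, or any mechanistic coupling
between channels (the phase structure is imposed, not emergent — no
pyruvate-node or acetaldehyde model is included, deliberately).
Recovery of encoded quantities therefore validates the estimators, not
any biological hypothesis.  Problem sizes in tests and the acceptance
script (3–10 cycles, 3-h sampling, ~2×10³ genes × 5 samples) are
chosen to exercise the estimators at realistic campaign scale while
keeping each run to seconds.
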