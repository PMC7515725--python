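# Methods

`nucdyn` quantifies how a histone modification at the DNA–histone interface
changes nucleosome stability and DNA accessibility, from four kinds of raw
measurement: bulk FRET titrations (salt and LexA), single-molecule
optical-tweezers recordings (constant-position hopping and
constant-velocity pulling), and gel/blot band-intensity tables. This note
documents the models, the parameters that matter, the numerical choices,
and what the synthetic-data generators do and do not emulate.

## FRET efficiencies and titration midpoints

**(ratio)_A efficiency.** The acceptor-emission excitation-ratio method
estimates FRET efficiency from the acceptor channel under donor versus
direct acceptor excitation:

E = prefactor × [ (F_A(ν′)/F_A(ν″)) ε_A(ν″) − ε_A(ν′) ] / (ε_D(ν′) d⁺)

with ν′ the donor- and ν″ the acceptor-excitation wavelength and d⁺ the
donor labeling fraction. The `prefactor` defaults to 1 — the canonical
single-donor form. Some write-ups of the method carry a leading factor 2
with ambiguous bracketing; setting `prefactor=2` reproduces that variant.
The package exposes both and asserts neither; all ratio comparisons
(percent changes, t-tests) are invariant to the choice.

**Salt-induced disassembly (C1/2).** FRET versus NaCl follows a sigmoid

Y(X) = Y_min + (Y_max − Y_min) / (1 + exp((C1/2 − X)/b)),

where C1/2 is the salt concentration at half signal loss and b the width
(sign free: b < 0 decays, b > 0 rises, so one code path fits FRET decays
and bound-fraction elution curves in either orientation). Curves are
optionally normalized to percent between a high plateau (mean of the
`n_plateau` = 3 largest-y points; a single-point maximum is
noise-sensitive) and a low plateau (mean of the 3 highest-salt points).

**Site exposure (S1/2).** Normalized FRET versus [LexA] follows the
non-competitive binding curve E = E₀ + (E_F − E₀)/(1 + S1/2/[LexA]); the
x = 0 point is kept as the analytic limit E₀ and never enters a 1/[LexA]
term.

**Fitting.** Both models are least-squares fit (`scipy.optimize.curve_fit`)
with multi-start initialization — midpoint started at the 0.25/0.5/0.75
interior x quantiles, asymptotes from the three lowest/highest-x means,
both slope signs tried — keeping the lowest residual sum of squares (ties
broken by smallest |b|). S1/2 is optimized as log S1/2 so decades of
concentration are well conditioned. Standard errors come from the local
curvature (covariance) of the winning fit. Fits are per replicate;
condition comparisons (percent decrease, pooled-variance two-tailed
Student t-test with df = n_a + n_b − 2) act on replicate-level midpoints.
The pooled (not Welch) test matches the small, equal group sizes (n = 3)
these experiments use.

## Hopping analysis and outer-wrap energetics

A nucleosome held near its equilibrium force hops between a wrapped and an
unwrapped state of the outer DNA turn. The pipeline:

1. **Decimation** — non-overlapping boxcar mean (default factor 4,
   1 kHz → 250 Hz), trailing partial block dropped.
2. **Transition detection** — at every interior sample, a Welch t
   statistic between the two adjacent windows of `window` = 25 samples
   (0.1 s at 250 Hz); candidate change points are local maxima of |t|
   above `t_threshold` = 6; candidates closer than `min_dwell` = 10
   samples merge keeping the stronger. Segments are labeled by mean
   extension (higher = unwrapped); if two candidates would create adjacent
   same-state segments the weaker is dropped. The defaults were chosen so
   square-wave fixtures at SNR 5 are detected with sensitivity ≥ 0.95 and
   ≤ 0.05 false change points per second; all three are CLI flags.
3. **Dwells and rates** — first/last segments are censored and dropped by
   default (standard for exponential MLE). k_u = 1/mean(wrapped dwell),
   k_w = 1/mean(unwrapped dwell), s.e. = k/√n. Dwells shorter than the
   detector's dead time (min_dwell) are missed, biasing both rates
   slightly downward; the bias is nearly symmetric in the two states, so
   the equilibrium force below is robust to it (verified in the recovery
   tests).
4. **Bell fit** — ordinary least squares of ln k_u and ln k_w versus
   force. F_eq is the intersection; K_eq = exp fit value there. K_eq is
   dimensionful (a rate), so the free-energy logarithm is taken against a
   reference rate, 1 s⁻¹ by default and configurable.
5. **Energetics** — ΔG° = F_eq·Δx − ΔG_stretch − kT ln(K_eq/k_ref).
   Δx is the mean detected step amplitude in the trace(s) at the force
   nearest F_eq (per-force extrapolation available). The released contour
   is L = Δx/z(F_eq), the length whose WLC equilibrium extension at F_eq
   equals the observed step, and ΔG_stretch is the WLC stretching work of
   that released segment only; a whole-tether convention would be a
   different (larger) correction and is intentionally not the default.

**Worm-like chain.** Marko–Siggia interpolation
F = (kT/P)[1/(4(1−z)²) − 1/4 + z] with defaults P = 50 nm, stretch
modulus K = 1200 pN, kT = 4.114 pN·nm (298 K), rise 0.338 nm/bp. The
extensible correction replaces z by z − F/K; the resulting implicit
equation is solved by bracketed Brent iteration to 1e-12 pN, because the
naive fixed-point map loses contraction above roughly 15 pN. The inverse
map has the closed form z(F) = z_MS(F) + F/K. Stretching work is computed
as L·∫F dz_MS by interval-halving trapezoid refinement to a relative
tolerance of 1e-6 plus the exact elastic term L F²/(2K); the acceptance
suite checks it against a 10× finer fixed grid to 0.1%.

Unit conversion: 1 pN·nm = 0.6022 kJ/mol (stated to 4 significant
figures); every energy is reported in both systems.

## Pulling analysis

The extension of a pulling curve is converted to an apparent contour
length L_app = x/z(F) per sample; between rips L_app is constant, and a
rip is a between-adjacent-window increase of L_app whose extension-space
magnitude exceeds `jump_threshold` = 5 nm (window 5 samples at the 50 Hz
analysis rate). The boundary is refined to the single largest contour
step, and the jump is re-estimated from windows excluding one guard sample
on each side, since decimation leaves one mixed sample straddling the
jump. Rips at or below `boundary_force` = 8 pN are labeled outer, above it
inner — the outer rip lives in the 2–5 pN hopping regime while the inner
rip occurs at distinctly higher force; the boundary is a configurable
convention, not a fitted quantity.

## Gel quantification

**Digestion ("one-pot") assay.** At the reference time point (default
60 min, the endpoint; all time points are reported) each (site, replicate)
pair gives modified% = 100 × I(modified)/I(unmodified), so the unmodified
condition is identically 100%. Because that paired ratio leaves the
unmodified percentages with zero variance, the per-site t-test compares
the two conditions on the percent scale with the unmodified replicates
scaled by their own mean — mean exactly 100, replicate scatter preserved.
Sites with a missing condition or zero unmodified intensity are reported
as missing/unquantifiable rather than erroring the batch.

**Elution assay.** Bound fraction per salt aliquot = bound/(bound +
eluted), emitted as a titration series whose sigmoid midpoint is the
chromatin stability C1/2. A cumulative mode (bound relative to the
lowest-salt total of the replicate) is available behind `mode="total"` for
protocols that elute a single pool progressively.

## Synthetic data

Generators are pure functions of (parameters, seed) and always emit a
ground-truth sidecar. Defaults are the study conditions:

- **Salt titration**: 19 points, 0.1–1.9 M, truth C1/2 = 0.621 M,
  b = −0.05 M, Gaussian noise σ = 3 (percent units).
- **LexA titration**: log grid 10 nM–100 µM (17 points) plus 0, truth
  S1/2 = 2 µM, E₀ = 1.0, E_F = 0.3, σ = 0.02.
- **Hopping**: two-state continuous-time Markov chain with Bell rates
  k_u(F) = k_u0 e^{F x_u‡/kT}, k_w(F) = k_w0 e^{−F x_w‡/kT}; defaults
  k_u0 = 0.25 s⁻¹, k_w0 = 4.6 s⁻¹, x_u‡ = x_w‡ = 2.0 nm, giving
  F_eq ≈ 3.0 pN and dwell times of 0.2–2.5 s over the 2–5 pN window —
  rates resolvable at 250 Hz with the default detector, comparable to the
  real experiment. Step 21 nm, bead noise 6 nm at 1 kHz (≈ 3 nm after
  decimation), exact exponential dwell sampling before discretization.
  The generator and the analysis fitters share no code.
- **Force ramp**: linear force ramp 0.5–20 pN over 20 s at 200 Hz over a
  500 nm WLC tether; each rip trigger adds its contour release; noise
  2 nm.
- **Gel tables**: sigmoidal bound-fraction model (truth C1/2 = 0.50 M
  wild-type-like, 0.43 M mutant-like in the closures) and a saturating
  digestion time course with per-site effect multipliers; multiplicative
  log-normal noise, 10% CV by default (intensities are positive).

What the generators do **not** emulate: bead-relaxation autocorrelation
(an optional exponential-autocorrelation noise mode exists but white noise
is the default), instrument drift, trap-stiffness miscalibration,
gel-background structure, or pipetting covariance between replicates.
Passing recovery tests therefore demonstrates correctness of the
estimators under the assumed noise model, not robustness to every
instrumental artifact of real traces.

## Problem sizes in the shipped checks

The recovery harness uses 100 salt titrations (19 points each), 10
triplicate LexA titrations, five 700 s hopping traces at forces
2–5 pN (≥ 300 transitions per force, ~3000 total), one 40-step SNR-5
square wave, one two-rip ramp, and duplicate-free elution/digestion
tables — sizes at which every estimator's statistical error is several
times smaller than its acceptance tolerance.

## Known limitations

- Rates are not dead-time-corrected; at dwell times within ~2× the
  detector dead time (40 ms at defaults) both rates are biased low.
  F_eq largely cancels this; absolute rates do not.
- The linear Bell fit cannot represent curvature in ln k(F) (moving
  transition states).
- No hidden-Markov emission learning; heavily overlapping states (SNR
  below ~3) defeat the window t-test detector.
- No equilibrium free energy from irreversible pulling (no
  Crooks/Jarzynski estimators); pulling analysis reports rip forces and
  contour releases only.
- The (ratio)_A factor-2 ambiguity is exposed, not resolved.
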