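# Methods

This note documents the models, the numerical choices behind them, and what
the synthetic test bed does and does not establish.

## Freezing-point theory from composition

The colligative model treats the mix as water plus three classes of
depressants:

* **Sugars and polyols** (sucrose, dextrose/fructose, sorbitol, lactose,
  and — with configurable mean molecular weights — maltodextrin and inulin)
  are pooled into *sucrose equivalents*: SE_s = c_s · MW_sucrose/MW_s with
  c_s in g per 100 g water, i.e. mole-for-mole replacement by sucrose.
  Lactose carried in by milk is a colligative sugar (MW 342.30, factor 1).
  Fats, proteins and high-molecular-weight hydrocolloids are excluded: they
  are immiscible or too large to contribute measurably.
* **MSNF** (milk solids-non-fat, here the protein + ash + other non-lactose
  milk solids) contributes linearly: k_MSNF · (g MSNF / g water), default
  k_MSNF = 2.37 °C (a serum-solids coefficient of the classical ice-cream
  literature; configurable, since conventions differ on whether lactose is
  inside MSNF — here it is not, to avoid double counting).
* **NaCl** uses the ideal cryoscopic law with full dissociation,
  1.86 °C·kg/mol · 2 · molality.

FPt = −(sum of the three depressions).  The sucrose term is evaluated on a
packaged table of freezing-point depression vs g sucrose/100 g water
(`data/sucrose_fpd_v1.csv`, 0–200 g/100 g water in steps of 5).  The table
is generated by `scripts/make_sucrose_table.py` from the Norrish
water-activity equation for sucrose (K = 6.47) combined with the
ice–solution equilibrium condition using a temperature-dependent latent
heat (ΔH = 6009.5 J/mol at 0 °C, Δcp = 38 J/mol/K); the dilute limit
reproduces the cryoscopic constant 1.86 °C/molal and the model sits within
~0.2 °C of sucrose-equivalent estimates quoted in the ice-cream literature
over the relevant range — the same order as the method error reported for
the sucrose-equivalent approach itself.  A zero-intercept cubic is fitted
to the table once at load (max residual < 0.003 °C, strictly increasing on
the domain), so FPD(0) = 0 exactly.

The Weast interaction linear plot is an ordinary least-squares regression
of Mw/Ms (initial water g/100 g mix over sucrose equivalents g/100 g water)
on 1/|FP|; its intercept measures solute–solvent interaction strength and
its slope the dependence of the freezing point on dilution.

## Curve anatomy and event detection

All analysis runs in minutes and °C at the probe's native 1 Hz.  The
prescribed noise filter is a 3-point, order-1 Savitzky–Golay kernel (the
only non-degenerate choice for a 3-point window), with endpoints copied
unfiltered; it preserves linear trends to machine precision.  Replicate
agreement is summarized as twice the per-time standard deviation across
runs, flagged against the ±0.2 °C envelope of the measurement chain.

Detection proceeds in stages:

1. **Chilling line** — OLS over the samples above 0 °C (optionally skipping
   a leading transient); TP1 is the first sample at or below 0 °C.
2. **Δ statistic** — Δ(t) = (T_CL(t) − T_exp(t))²/max(|T_exp(t)|, ε) for
   t > TP1 (ε = 0.5 °C guards the denominator near 0 °C).  Δ ≈ 0 while the
   curve rides the chilling line and grows rapidly once latent heat bends
   it away; the first crossing of the threshold (default 10) opens the
   supercooling search window.
3. **Supercooling** — local minima of a more strongly smoothed trace
   (Savitzky–Golay window 9, order 2 — used for extremum *search* only)
   with prominence ≥ 0.2 °C (the uncertainty envelope), merged when closer
   than 0.25 min; the first is the (initial) supercooling S, the count is
   reported for multi-event curves.  A curve whose Δ never crosses the
   threshold, or whose minimum sits at the tail with no rebound, raises a
   detection error.
4. **IFP** — the highest temperature reached after S.  A regression line
   through the largest Δ values bounds the search window by its Δ = 0
   time-intercept; because the largest values cluster at the end of a run,
   the top set is grown beyond the minimum 10 points until it spans ≥ 1 min,
   and an intercept that falls before the first rebound peak is rejected in
   favour of the maximum over the whole post-S curve.  The IFP *level* is
   not the single argmax sample (a selected-high, hence biased, estimator
   under noise) but the lower-quartile-trimmed mean of the smoothed trace
   within ±0.35 min of the located maximum; trimming only the lower tail is
   appropriate because contamination at a local maximum is one-sided (the
   rebound corner and the later decline can only pull the window down).
   This choice reduced the median level error from ≈ +0.06 °C to below
   0.01 °C and the downstream median parameter biases to a few tenths of a
   percent in the closed-loop study.
5. **Calibration** — offset = IFP − FPt is subtracted from the whole
   profile (the probe sits between the cold wall and the warm bulk, so the
   measured equilibrium overestimates the true one); a negative offset is
   allowed with a warning.  Calibration is a pure shift: intervals and
   temperature differences are preserved and the calibrated IFP equals FPt
   identically.

Segment labels partition the samples into chilling, dynamic nucleation,
IFP (single sample), steady state, IFP_eff (single sample) and dynamic ice
crystallization; a curve truncated before the kinetic fit gets the partial
labelling with a warning.

## Freezable-water kinetics

With SE0 the sucrose concentration whose tabulated depression equals −FPt
(so *all* colligative contributions are expressed on the sucrose scale and
the map starts at the calibrated IFP), removing a water fraction w leaves a
solution at SE0/(1−w).  Fourteen levels (w = 5…70 % in 5 % steps; at most
70 % of the water is treated as freezable, which keeps the equivalent-
sucrose description valid) plus the unfrozen anchor (w = 0) are simulated
and a fourth-order polynomial WF = P(FPD) is fitted.  The quartic leaves a
residual of ~0.005 at the anchor — intrinsic to a degree-4 fit of this
curvature; a weighted fit was tried and rejected because it destroyed
monotonicity — so "WF ≈ 0 at the IFP" holds to about half a percent of the
water.  Self-inversion of the map (brentq on the fitted polynomial) round-
trips to < 1e−3 over the domain.

WF(t) is evaluated on the calibrated window [t_IFP, t_exit], with FPD
values clipped to the map domain and the result clamped to [0, 0.70]
(samples warmer than FPt map to zero with a warning); an isotonic cleanup
is available behind a flag and off by default.

The kinetic model is the re-parameterized (Zwietering-style) Gompertz
function WF(t) = WFmax·exp(−exp(GRmax·e/WFmax·(HNT − t) + 1)) with the
asymptote WFmax (fraction of the initial water, bounded by 0.70), the
maximum rate GRmax (min⁻¹) and the lag HNT (min) as directly interpretable
parameters; the constant e is Euler's number exactly.  Fitting is bounded
nonlinear least squares (trust-region reflective) started from the observed
maximum, the largest finite-difference slope and the 5 %-rise time, with
five jittered restarts before declaring failure.

With k = GRmax·e/WFmax and u(t) = exp(k(HNT − t) + 1), the derivative
landmarks are closed-form: u = 1 at the inflection (GR_time = HNT + 1/k,
rate GRmax, WF = WFmax/e), and u = (3 ± √5)/2 at the extrema of the second
derivative — maximum acceleration (IFP_eff, the effective freezing point)
and maximum deceleration (tT_whipp, where air incorporation overtakes ice
growth).  The tests verify these against high-precision numerical
differentiation (mpmath) to 1e−6 min.  Landmark temperatures are read from
the fitted smooth model through the inverse map (not from the raw curve)
for noise robustness; FW_max is the fitted WF at t_exit.

### Lack of fit

The reported E% is the **mean of squared relative errors** × 100, residuals
divided by the fitted value, excluding points with fitted WF < 1e−3; a
rooted variant and alternative denominators are selectable
(`error_pct(..., root=True, denominator=...)`).  The mean (not root) form
is the default because the statistic is defined as a *squared* relative
mean error and because only this reading keeps E% below 2 % under
realistic noise on series that start near zero.  Note the metric's
character: relative errors weight the induction tail heavily, so on
pipeline output at the default synthetic sensor noise (0.1 °C, which maps
to WF noise of ~0.01–0.03 near the anchor) E% is dominated by near-zero
fitted values and can reach tens of percent even when the parameters are
recovered to ~2 %; on WF series observed directly at noise σ = 0.005 it
stays below ~0.3 %.

## Product quality

Melting uses the same Gompertz form with unit asymptote (all mass
eventually melts): m_D/m_0 = exp(−exp(Mrate·e·(LAGTIME − t) + 1)), fitted
to ≥ 4 weighings (first drop, then 15/30/45 min in the standard protocol).
Overrun is 100·(w_mix − w_ice)/w_ice at equal volume; negative values are
returned but flagged as implausible.  The liking level credits desired and
debits undesired attributes per judge, normalized by the sum of the desired
attributes' maximum scores (the reading consistent with a 0–100 scale when
no defects are perceived), then averages over the panel.  Score
standardization is scale-only (division by the per-attribute SD, no
centering), exactly as the protocol prescribes.

## Synthetic test bed

`CurveScenario` encodes a run: chilling from 20 °C at −16 °C/min (batch
runs are reported between about −15 and −18 °C/min), a dip at 2.5 min to
−2.8 °C with a 0.3 min cubic rebound, FPt = −2.9 °C, probe offset 0.7 °C,
Gompertz truth (0.55, 0.12 min⁻¹, 3.8 min), exit at 8 min, 1 Hz sampling,
Gaussian sensor noise σ = 0.1 °C (inside the ±0.2 °C envelope).  The lag
default leaves ~1 min of genuinely constant steady state between the
rebound and the acceleration of ice growth, as the curve anatomy demands —
without it the nominal probe offset is not realisable by any calibration.
The nucleation descent is a monotone quadratic with zero slope at the dip
(start slope ≈ −4.5 °C/min, within the reported nucleation-rate range);
the equilibrium branch inverts the same quartic FPD–WF map the analysis
evaluates forward, so the closed loop tests detection, calibration and
fitting, *not* the polynomial against an external curve family.  Additional
dips are superposed as quartic bumps.  The exit temperature of the default
scenario (≈ −5.5 to −6 °C) lands in the typical drawing range.

What the closed loop shows: over 100 seeds, median relative bias of
(WFmax, GRmax, HNT) below 1 %, IFP within the ±0.2 °C envelope, event
ordering TP1 < S < IFP on every run.  What it does not show: robustness to
drift or non-Gaussian probe error, multi-event interference beyond two
dips, real SSHE spatial gradients, or the accuracy of the packaged sucrose
table against any particular laboratory's osmometry — the table is a
documented thermodynamic model, not a transcription of a measured dataset.

## Degenerate inputs and tie-breaks

Curves shorter than 30 samples are rejected for event analysis (smoothing
needs only 3).  A curve that never rises above / never crosses 0 °C, or
whose Δ never crosses threshold, raises a detection error; an interior
minimum with sub-prominence rebound degrades to a flagged weak event; a
supercooling with no samples after it degrades IFP to S with a warning.
Equal-height plateau samples resolve to the earliest (argmax convention)
before level averaging.  Fits degrade through multistart before raising;
constant WF or drip series are fit errors, not crashes.
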