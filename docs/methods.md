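# Methods

## Scope and model of the assay

`coagkit` analyses in vitro coagulotoxicity data of the kind produced by
an automated coagulation analyser, a fluorogenic plate reader and a
thromboelastography (TEG) instrument. The central object is the
clotting-time concentration curve: a venom (optionally preincubated
with an antivenom or enzyme inhibitor) is serially diluted, mixed into a
fixed 250 µl reaction (50 µl venom stock, 25 µl buffer or treatment,
50 µl CaCl₂, 50 µl phospholipid, 75 µl plasma), and the time to clot is
recorded at each final concentration, in triplicate. All public
concentrations are final reaction concentrations; with the standard
100 µg/ml working stock and the 1, 1/2, 1/5, 1/12.5, 1/30, 1/80, 1/160,
1/400 dilution series the curve spans 20 down to 0.05 µg/ml.

The analyser cannot report beyond a ceiling (999 s by default).
Readings at the ceiling are kept *at* the ceiling and flagged censored,
never dropped: anticoagulant and non-clotting runs are exactly the runs
where the ceiling carries the information. Downstream statistics
integrate censored values at the ceiling and propagate a
`censored_fraction`; a venom curve censored everywhere yields a
`saturated` flag on its shift result (there is nothing left to
neutralize) rather than an error.

## The neutralization statistic

Antivenom/inhibitor efficacy is quantified as the X-fold magnitude of
shift

    shift = AUC(venom + treatment) / AUC(venom) − 1,

where AUC is the trapezoid area under clotting time vs concentration.
0 means no neutralization; positive values mean clotting was slowed
back toward the spontaneous time. Two conventions are deliberately
configurable because commercial curve-fitting software leaves them
implicit:

* **Axis** — linear concentration axis by default (the 0-concentration
  limit needs no transform); log₁₀ axis as an option.
* **Replicate handling** — AUCs are computed per replicate and shifts
  paired by replicate index, giving mean ± SD across triplicates (this
  reproduces "mean ± SD of N = 3" error bars); the AUC-of-mean-curve
  alternative is computable from the same primitives but is not the
  default.

The default neutralization verdict threshold is 0 (any positive mean
shift counts), widenable by callers.

On the standard 8-point grid the trapezoid AUC tracks adaptive
quadrature of the generating curve to ~2% when the curve is shallow
relative to the grid (e.g. EC50 ≳ 5 µg/ml or Hill slope ≲ 0.7) and to
~10% for the steepest curves the generator produces; this is grid
resolution, shared by any software integrating the same 8 points, and
is pinned down in the test suite.

## Zymogen activation scoring

The plate assay (300 cycles × 10 s by default) uses five well roles:
blank, activated-enzyme control (FXa or thrombin), zymogen control,
venom-without-zymogen, venom-with-zymogen. Correction is algebraic:
blank is subtracted from every well, then venom-without-zymogen from
venom-with-zymogen, so a venom that cleaves the fluorogenic substrate
directly — without activating anything — scores exactly zero. Because
the blank cancels in that difference, corrections are invariant to any
constant offset applied to the whole plate (a property test).

The published description does not state *which* scalar is normalized
against the control. The default here is the whole-curve AUC ratio,
100·AUC(corrected venom)/AUC(corrected control), which is robust to
sampling phase; endpoint-RFU and maximum-slope variants are selectable
(`scalar="endpoint"|"slope"`). This is a convention, not a reproduction
of any published figure axis. Negative corrected values are kept in the
traces (they carry drift/quenching information) and floored only in the
headline percentage. FX and prothrombin share one code path; the target
is a label.

## Factor inhibition

For anticoagulant venoms, the factor-inhibition assay preincubates venom
with one exogenous factor (thrombin, FIXa, FXa, FXIa, FXIIa) and
measures plasma clotting time against a no-venom control. The readout
is deliberately the same ratio−1 statistic as the AUC shift
(time_with/time_control − 1; shared code path, asserted equal in a unit
test), so 0 always reads "no effect". A difference-in-seconds variant
exists but is non-default. A factor is *called* inhibited when its mean
shift exceeds a configurable threshold (default 0.2) and no other factor
does; two or more factors above threshold give an "ambiguous" call.
The threshold is an artifact convention for turning shifts into a
qualitative call, not an empirical constant.

## TEG parameterization

Amplitude maps to elasticity by G = 5000·A/(100 − A). From a trace the
package derives SP (first time A exceeds the detection threshold,
default 0.2 mm), R (first time A ≥ 2 mm), MA (max amplitude), MRTG and
TMRTG (max of dG/dt and its time, the latter in minutes), and TGG
(terminal elasticity G(end), which equals ∫dG/dt when G starts at 0).
Velocity uses a centered moving average (default 5 points) followed by
central finite differences, one-sided at the ends. Two deliberate
choices:

* the MRTG/TMRTG search is restricted to t ≥ SP, so baseline noise
  before clot onset cannot masquerade as thrombus generation — this also
  guarantees the ordering invariants SP ≤ R and TMRTG·60 ≥ SP on noisy
  traces;
* the derivative is taken on elasticity (standard); an amplitude-based
  derivative is available for comparison with instruments that use it.

Thresholds never crossed (flat negative-control traces) yield absent
parameters (`None`/empty CSV fields), not errors.

## Statistics

Replicate summaries use the sample SD (n−1); printed "±" values are
assumed to be sample SDs. One-way ANOVA is available from raw replicate
lists (delegating to `scipy.stats.f_oneway`) and, equivalently, from
summary statistics alone via SS_between = Σnᵢ(mᵢ−m̄)², SS_within =
Σ(nᵢ−1)sᵢ² — the two paths agree to 1e−10 on random data (a test). The
summary path matters because published tables often provide only
mean ± SD and n. Pairwise comparisons use Tukey HSD from the pooled
within-group mean square and the studentized-range distribution
(Tukey–Kramer SE for unequal n), cross-checked against
`statsmodels.pairwise_tukeyhsd`. On the bundled 18-group published
clotting-time table (n = 3 per group), Tukey reproduces 151/153
(98.7%) of the reported pairwise significance pattern; the two
discrepant pairs sit just above α = 0.05 (p ≈ 0.081 and 0.056) and are
consistent with the source having used a different or no multiplicity
adjustment, which it does not name.

## Synthetic generators

The generators stand in for the instruments, with ground truth exposed
for recovery testing. They emulate curve shapes, replicate noise and
censoring — not any instrument's absolute calibration.

* **Clotting curves** — a four-parameter Hill-type family:
  procoagulant CT(c) = t_floor + (t_spont − t_floor)/(1 + (c/EC50)^h);
  anticoagulant CT(c) = t_spont·(1 + (c/EC50)^h). A phenomenological
  model is preferred over a mechanistic cascade ODE because the
  analyses consume only clotting times and this family spans the
  observed shapes (near-flat through saturating). Defaults: t_spont
  645.2 s (the published spontaneous control), t_floor 16 s and EC50
  0.5 µg/ml (a fast, potently procoagulant curve within the published
  15.4–359.8 s range at 20 µg/ml), h = 1, ceiling 999 s, noise CV 5%
  multiplicative lognormal (times are positive; published replicate SDs
  scale roughly with means). Censoring is applied after noise, so the
  censored fraction is itself stochastic. Treatments neutralize a
  fraction e of venom (c_eff = c(1−e)); a capacity-limited variant
  c_eff = max(0, c − B) is included, non-default.
* **Activation plates** — first-order activation: enzyme(t) =
  Z0(1 − e^(−k_act·t)); signal = k_sub·∫enzyme dt on a 300 × 10 s grid;
  the activated control is linear (k_sub·E0·t); venom-alone wells add a
  direct-cleavage ramp; blanks drift linearly; additive Gaussian noise.
* **TEG traces** — A(t) = MA(1 − e^(−k(t − t0))) for t > t0, 1-s grid
  over 1800 s, additive noise clipped to [0, 100) mm. R and MRTG have
  closed forms, used as analytic oracles.

All generators require explicit seeds and are bit-reproducible.

What the generators do **not** emulate: instrument-specific absolute
values and drift, venom degradation over a run, inter-donor plasma
variation, substrate depletion, fibrinolysis. Passing recovery tests
therefore demonstrates correctness of the analysis arithmetic under the
stated noise model, not robustness to every artefact of real data.

## Dose–response fitting

`fit_concentration_response` fits the procoagulant Hill model to all
uncensored measurements by bounded least squares with a deterministic
initialization (t_spont ← max time, t_floor ← min time, EC50 ←
geometric mid-grid, h ← 1), so the fit is a pure function of the data.
Curves with fewer than five uncensored distinct concentrations (e.g.
fully censored anticoagulant runs) return a flagged non-converged
result rather than raising. Under the standard design (8 points,
triplicate, CV 5%) recovery over 20 seeds gives a median relative EC50
error of ~10% and median t_spont error of ~4%; t_spont is mildly
extrapolated because the standard design's lowest concentration is
0.05 µg/ml, not 0.

## Problem sizes in the test suite

Monte-Carlo checks use 20–100 seeds and the standard 8 × 3 design;
the TEG invariant sweep uses 1000 random traces at 1-s resolution over
30 min. These sizes make every stochastic property comfortably stable
across reruns while keeping the suite fast.

## Known limitations

* The AUC-ratio activation scalar and the ratio−1 inhibition shift are
  conventions where the source descriptions are silent; both are
  configurable and flagged as conventions.
* Censored values integrated at the ceiling bias AUCs of partially
  censored curves downward relative to the unobservable truth; the
  `censored_fraction` field exists so consumers can judge.
* Tukey HSD is one defensible choice of multiplicity adjustment for the
  published worked example; the two borderline disagreements above are
  irreducible without knowing the original procedure.
* No lysis parameters (LY30 etc.), no enzyme-kinetic constants (Km,
  kcat), no mechanistic clotting-cascade model, no in vivo
  extrapolation.
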