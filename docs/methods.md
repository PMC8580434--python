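# Methods

This note documents the statistical model, the numerical choices and the
synthetic-data generator behind `tentacular`, and states what the test
suite does and does not establish about real behavioural data.

## Coordinate conventions

Landmark coordinates are pixels in image convention (y grows downward);
world angles are measured in the standard mathematical sense after
flipping the y-axis.  Body-frame angles are anatomical: 0° ventral, 90°
posterior, 180° dorsal, 270° anterior.  Because the two experiment types
may be filmed from opposite sides of the arena, the body frame carries a
chirality factor (+1 viewed from above, −1 from below):

    body_angle = chirality · (world_angle − ventral_axis_angle)  (mod 360)

so that body angles always increase ventral → posterior → dorsal →
anterior regardless of camera side.  Files and reports use degrees in
[0, 360); computation is in radians.

A tentacle yields two candidate angles: its *heading* (base → tip
direction) and its *positional angle* (where its base sits around the
shell margin).  Both are computed for every observation.  The static
pipeline defaults to headings — the behavioural claim is that tentacles
*point* at stimuli — while the rotation pipeline defaults to positional
angles, because a travelling wave of extension is a pattern over
positions.  Both defaults are arguments (`angle_mode`) rather than
constants, since the distinction is genuinely ambiguous for this kind
of experiment.

## Moore's modified Rayleigh test

For n vectors with headings θᵢ and magnitudes ℓᵢ, the magnitudes are
replaced by ascending ranks rᵢ (average ranks on ties — the standard
rank-statistic convention) and

    R* = |Σ rᵢ e^{iθᵢ}| / n^{3/2},   φ* = arg Σ rᵢ e^{iθᵢ}.

Using ranks rather than raw lengths makes the statistic invariant to
monotone rescaling of the lengths, which matters because absolute
tentacle extension varies widely between animals.

Critical values are obtained by Monte Carlo rather than from printed
tables: under the null the headings are iid uniform and independent of
the magnitudes, so ranks may be fixed at 1..n and the (1 − α) quantile
of R* estimated from simulated samples (default 100 000 replicates,
fixed default seed, memoised in process and optionally persisted to a
TSV cache keyed by (n, α, reps, seed)).  This works for any n and any
tie pattern.  Two checks pin the simulation down: the asymptotic null
distribution of R*² is exponential with mean 1/3 (each resultant
component has variance ½Σrᵢ² ≈ n³/6), giving a large-n 95% critical
value of √(ln 20 / 3) ≈ 0.9993, which the Monte Carlo reproduces at
n = 500; and at small n it matches an independently coded brute-force
simulation.  Note the small-n critical values are *larger* (≈ 1.05 at
n = 10) and decrease toward the asymptote.

An exactly balanced sample (zero resultant) has no defined φ*; the
implementation snaps resultants at rounding-noise level to zero and
flags φ* as NaN.  Such trials are dropped from treatment summaries with
a warning — on real data a zero resultant is a measure-zero event.

## von Mises fitting and model selection

The weighted fit uses the closed-form ML mean direction and solves
A₁(κ) = I₁(κ)/I₀(κ) = R̄ (weighted mean resultant length) by Newton
iteration from the standard piecewise initial approximation, with
A₁'(κ) = 1 − A₁/κ − A₁².  Scaled Bessel functions (`i0e`, `i1e`) keep
the ratio and the log-normaliser stable at large κ.  κ is capped at 500
with a `degenerate` flag, since the MLE diverges as R̄ → 1 (all angles
identical).  The inversion agrees with direct numeric root-finding to
better than 1e-6 across R̄ ∈ [0.01, 0.99].

Model selection compares the uniform null (k = 0, log-likelihood
−n ln 2π) with the unimodal von Mises (k = 2) by small-sample AICc;
ΔAICc < 2 counts as retained ("good") support, and AICc weights
w ∝ exp(−Δ/2) are reported.  AICc requires n ≥ 4 for k = 2 (the
correction denominator n − k − 1 must be positive); treatment summaries
therefore need at least four trials with defined φ*.

## Homogeneity, counts and the offset regression

Concentration homogeneity across treatments uses Fisher's (1993)
three-regime procedure, with the regime chosen by the pooled mean
resultant length (< 0.45: arcsine-transformed; < 0.70:
asinh-transformed; otherwise a Bartlett-type test on circular
dispersions), referred to χ²(g − 1).  Pairwise comparisons report raw
p-values by default, with an optional Bonferroni flag.  Under its null
(3 groups of 30 angles at κ = 2) the test rejects at 0.039–0.046 at
nominal 0.05 in the calibration suite — slightly conservative, as
expected from the approximations.

The Friedman test is implemented directly with the tie-corrected
rank-sum formula (within-subject average ranks), because counts are
discrete and heavily tied, and because the two-treatment case should
work; it matches `scipy.stats.friedmanchisquare` exactly where both
apply.  Counting precedes the ≥ 3-tentacle exclusion filter so that
zero-tentacle trials contribute zeros; animals with incomplete
treatment sets are dropped with a warning.

The directedness regression projects the stimulus angle and φ* on the
unit circle and regresses R* on the chord distance
z = 2|sin(Δ/2)| ∈ [0, 2] by OLS (statsmodels), reporting the F-test,
R², 95% coefficient CIs and the Shapiro–Wilk p of the residuals.
Control trials have no stimulus and are excluded by construction.  The
regression pools all analysable stimulus-present trials passed to it;
callers can restrict to a single experiment by filtering trials first.

## Rotating-stimulus analysis

Frames are downsampled to 1 fps by keeping the first frame of each
interval — the simplest deterministic rule.  Relative length divides
each tentacle's per-frame length by that tentacle's own mean over the
frames where it was observed, so each tentacle's observed relative
lengths average exactly 1 and the extension *wave* is comparable across
tentacles of different resting lengths.  Per frame, a von Mises fit
weighted by relative lengths (frames with fewer than 3 extended
tentacles are missing, not errors) yields φ₁(t), κ₁(t); the Cartesian
pair (κ₁ cos φ₁, κ₁ sin φ₁) is what gets tabulated and plotted against
the unit-circle stimulus track.  The stimulus track defaults to the
rotation metadata (θ_s(t) = start + direction·6·rpm·t), with per-frame
stimulus landmarks as an alternative source when they were digitised.

The tracking verdict is a quantitative surrogate for what is otherwise
an eyeball judgement on the component plots, and every piece is
configurable: frames with κ₁ ≥ 0.5 (the κ floor excludes frames where
the fitted direction is meaningless) enter a Fisher–Lee
circular-circular correlation against θ_s(t); the trial is *tracked*
when the correlation is ≥ 0.5 **and** φ₁(t) rotates in the stimulus
direction (sign of the circular-linear slope of unwrapped φ₁ against
time).  At least 10 valid frames are required, otherwise the trial is
"not classifiable" (and counts as not tracked).  Because the Fisher–Lee
coefficient is invariant to fixed angular offsets, the lag is estimated
separately: over a 0–60 s grid in 1 s steps (stimulus assumed to lead,
since tentacles extend and retract slowly), the lag maximises the mean
circular agreement cos(φ₁(t) − θ_s(t − L)).  The recovered angular
velocity is the linear slope of the unwrapped φ₁(t) over valid frames.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not images or biomechanics.  A simulated animal has 32 tentacles (the
top of the observed 0–32 range) rooted at even spacing over a
configurable arc; the default 270° ventral-centred arc leaves the
dorsal hinge bare, as on the real animal.  A single von Mises-shaped
tuning profile exp(κ_t(cos Δ − 1)) of the root-to-stimulus angular
distance drives both extension probability and extra length — the
simplest mechanism that produces both the directedness and the
width-dependent concentration effects.  Defaults: extension probability
0.5 per tentacle, tuning κ_t = 2 (4 in the strongly responsive position
design), pointing gain 0.8 of the root→stimulus offset clipped at 60°
(tentacles cannot point backwards through the shell), heading noise von
Mises κ = 8 (≈ 23° sd), lengths 60 + 40·tuning ± 8 px truncated
positive.  Extension probabilities are rescaled under their [0, 1]
bound so the *expected tentacle count is identical across treatments*,
matching the finding that counts do not depend on the stimulus — the
rescale is solved by bisection because clipping removes probability
mass.

Rotating trials run 130 s at 1 fps with the stimulus at 0.5 r.p.m.
(3°/s, sweeping ≈ 390°).  Each tentacle's continuous extension state
relaxes first-order (τ = 1 s) toward the tuning profile centred on the
stimulus direction 10 s in the past (the generative lag); tentacles
above a visibility threshold of 0.3 are emitted as landmarks for that
frame.  The small τ adds ≈ 1 s to the effective lag, which is why
recovered lags centre on 10–11 s.

Per-trial seeds derive deterministically from the master seed via
`numpy` seed sequences; the same seed reproduces byte-identical CSV
output.  Truth JSONs record the per-trial seed, parameters, root
angles, extension sets, stimulus angles and lag — sufficient to score
every pipeline verdict without reading generator code.

**A geometric caveat discovered during development and worth knowing
about:** with the anatomical 270° arc, the arc itself has a net
resultant pointing ventrally, so even stimulus-blind trials produce φ*
values clustered around 0° and the unimodal model wins for purely
geometric reasons.  The packaged experiment designs
(`position_design`, `width_design`, `rotating_design`) therefore use
full 360° coverage so that null treatments (control, unresponsive
dorsal) are geometrically unbiased and the behavioural effect is the
only signal; the 270° arc remains the `ScallopSim` default so the
rooted-arc regime can be studied deliberately.

## What the tests show — and what they do not

The synthetic data are well-specified by construction: independent
tentacles, exact von Mises tuning and noise, a rigid body frame, no
digitisation error, no curvature (tentacles are straight segments), no
temporal correlation beyond first-order relaxation, and no
animal-to-animal heterogeneity.  Passing tests therefore demonstrate
that the *estimators and decision rules are correct and calibrated
under their assumptions* — not that real scallop data satisfy those
assumptions.  In particular the tracking criterion (correlation ≥ 0.5,
κ floor 0.5) is this package's operationalisation of a qualitative
judgement and should be sensitivity-checked on real data.

## Problem sizes and tolerances

Simulation sizes used by the test suite and the acceptance script were
chosen to make binomial/Monte Carlo error comfortably smaller than the
asserted margins while keeping a full run in tens of seconds: 2000
replicates for test-calibration rates (binomial sd ≈ 0.005 at p = 0.05),
500 for model-selection rates, 1000 for CI coverage, 100 (50 in the
script) rotating trials per condition, and 100 000 Monte Carlo
replicates for critical values (quantile sd ≈ 0.002).  Numerical
tolerances: Newton inversion to |A₁(κ) − R̄| < 1e-13, oracle agreement
asserted at 1e-12 for the Moore statistic and 1e-6 for κ; file
round-trips are exact (floats are written at full precision and parsed
with round-trip precision).
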