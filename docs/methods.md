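# Methods

## Data model

A cohort is a pair of tables. `subjects.csv` holds one row per volunteer
(site, sex, age; height and weight optional — missing values stay missing
and are excluded per field from summaries, never imputed).
`measurements.csv` holds one row per subject × gradient axis × rise time ×
z-offset cell with a status:

* `threshold` — the lowest zero-to-peak amplitude (mT/m) at which the
  volunteer reported stimulation, found by a coarse 20 mT/m sweep followed
  by a 2 mT/m refinement;
* `no_pns` — no sensation up to the highest amplitude the hardware reaches
  at that rise time, `min(Gmax, slew·τ)` — a right-censored lower bound,
  not a threshold;
* `not_tested` — the axis was skipped for that volunteer.

Amplitudes are zero-to-peak throughout. The stimulus train alternates
polarity, so each switch delivers an excursion of 2ΔG over 2τ; that factor
is deliberately never applied, because every recorded threshold and every
fitted curve uses the zero-to-peak convention.

The default hardware envelope is 900 mT/m/ms slew, 200 mT/m amplitude, and
an 85 mT/m nominal (thermal) limit for EPI readouts. The bundled in-scanner
table contains one threshold a single refinement step above the nominal
slew-limited cap (92 mT/m at 0.1 ms), so its loader validates with a
2 mT/m tolerance; the factory table contains values up to 15 mT/m above the
nominal cap at short rise times (91 at 0.1 ms, 195 at 0.2 ms), evidence
that the factory rig's reachable amplitudes differed slightly, so that
loader checks only the 200 mT/m amplitude limit.

## From censored thresholds to binary observations

The logistic model consumes Bernoulli rows, not thresholds. The titration
protocol guarantees exactly two facts per measured threshold g: stimulation
at g, and no stimulation at g − 2 mT/m. Each threshold row therefore
becomes the pair (g, S=1), (g − 2, S=0) (the sub-threshold point is dropped
if non-positive). This uses all and only the information the protocol
provides; an interval-censored likelihood is a documented extension point,
not implemented.

Censored (`no_pns`) rows are controlled by `censored_handling`:

* `omit` (default) — censored cells contribute no rows;
* `zero_at_cap` — one S=0 row at the reachable cap;
* `cap_plus_one` — a conservative pseudo-threshold at cap + 1 mT/m,
  expanded like a measured threshold and flagged.

The default deserves justification, because `zero_at_cap` looks like the
natural encoding. The paired construction pins the fitted 50% contour to
the cluster of observed thresholds: every amplitude with an S=1 row also
has an S=0 row 2 mT/m below it. Adding censored S=0 mass at the top of the
amplitude range then teaches the model that high amplitudes do not
stimulate, and on heavily censored cohorts (over half the factory cohort
never stimulated on the x axis at any rise time) the fitted amplitude
coefficient turns negative — stimulation probability *decreasing* in
amplitude, which is nonphysical, and the threshold-line slope turns
negative with it. The same construction also fails parameter recovery
dramatically in simulation (57% median intercept error versus 3% for
`omit` and the 10% design bound). `cap_plus_one` keeps censored subjects
and stays physical but attenuates the z-offset effect under heavy
censoring (24% median error, outside the 15% bound). `omit` is physical on
every measured axis, recovers generating parameters within a few percent,
and its selection bias (dropping high-threshold subjects pulls curves
down) is bounded by the weighting described next. Both alternatives remain
one keyword away.

Fitting weights: every observation in an (axis, rise time, z-offset) cell
receives the fraction of that cell's *tested* volunteers who stimulated —
19/29 for the in-scanner x axis at 0.1 ms, for example. Weights are
computed from the measurement table (so omitted censored subjects still
count in the denominator) and uniformly down-weight heavily censored
cells, which is where the omission bias would otherwise concentrate.
Cells where nobody stimulated get weight zero and drop out with a logged
notice. A `uniform` scheme is available for sensitivity checks.

## Weighted logistic fit

P(S=1) = logistic(β₀ + β₁τ + β₂ΔG + Σₙ [β₁₊₂ₙφ′ₙ + β₂₊₂ₙφ′ₙτ]), with
φ′ₙ = φₙ − φ̄ₙ. Centers are subject-level means over the fitted data
(pooled across sites for combined fits); the z-offset center is pinned at
0 so the baseline curve refers to isocenter. Sex is coded F=0, M=1.
Because the model is linear in φ′ₙ, derived threshold curves are invariant
to the centering choice (a property test asserts this).

The weighted Bernoulli log-likelihood Σ wᵢ[Sᵢηᵢ − log(1+e^ηᵢ)] is
maximized by Newton scoring (IRLS) with step-halving; convergence requires
the largest absolute score component below 1e-8 within 100 iterations.
Standard errors come from the inverse weighted Fisher information,
p-values from two-sided Wald z-tests without multiplicity correction. An
optional ridge (default 0) penalizes the non-intercept coefficients;
leaving the intercept unpenalized keeps the separable-pair midpoint
property exact. Complete separation — all fitted probabilities saturated
at an unpenalized optimum — is detected and reported as `converged=False`
with a logged diagnostic rather than returning a spuriously "converged"
diverging solution.

Numerical notes: the linear predictor enters the likelihood through
`logaddexp`, so saturated probabilities cannot overflow; the oracle tests
compare IRLS against direct maximization (Nelder–Mead polished by a
trust-region Newton step) of the identical objective, and against a
reference GLM with variance weights on the real cohort.

## Threshold curves and sensitivities

Setting the linear predictor to zero gives ΔG(τ) = ΔGmin + τ·SRmin with

    ΔGmin = −β₀/β₂ − Σₙ (β₁₊₂ₙ/β₂)φ′ₙ
    SRmin = −β₁/β₂ − Σₙ (β₂₊₂ₙ/β₂)φ′ₙ.

β₂ = 0 is a degenerate-model error; β₂ < 0 warns (nonphysical). The
z-offset sensitivity is the derivative of the curve in z at a reference
rise time, −β_z/β₂ − (β_zτ/β₂)·τ_ref, reported at τ_ref = 0.3 ms; positive
values mean thresholds rise as the subject moves toward the feet. Pooled
z-covariate fits are the default for multi-offset data; refitting each
offset independently is possible by filtering the measurements.

Per-subject straight-line fits (amplitude on rise time, OLS) support the
individual-variability view; censored points enter at cap + 1 mT/m under
the conservative `cap_plus_one` rule (default there, mirroring how
individual trend lines are usually drawn) or are omitted. The +1
substitution is never used in population logistic fits.

## Synthetic cohorts

Each simulated subject i carries a latent line aᵢ + bᵢτ with
aᵢ ~ N(60 + 0.5·(ageᵢ − 52) + 0·sexᵢ, 12²) mT/m and bᵢ ~ N(150, 30²)
mT/m/ms, truncated positive; ages ~ N(52, 17²) clipped to [18, 100], sex
Bernoulli(½), and a z-offset effect of 20 mT/m per cm added to the latent
threshold. Defaults were chosen once to emulate the measured cohorts: the
intercept/slope means put thresholds in the 75–135 mT/m range over
0.1–0.5 ms (the bulk of the measured in-scanner values), the between-subject
SDs reproduce the visible spread, the age distribution matches the
in-scanner cohort, and the age and z effects take the directions and
magnitudes the measured data exhibit. The titration replay walks the exact
protocol: coarse multiples of 20 mT/m ascending to the reachable cap (the
cap itself is probed last), then 2 mT/m steps ascending from the bottom of
the bracketing interval. In deterministic response mode this guarantees
0 ≤ recorded − latent < 2 mT/m and censoring exactly when the latent
threshold exceeds the cap; the ascending refinement direction was chosen
over descending precisely because it yields that one-sided bias bound. A
logistic response mode (stimulation probability expit(κ(ΔG − t*)) per
presentation) adds trial-to-trial noise; κ has no measured anchor and
defaults to 1 per mT/m.

What the generator does *not* emulate: habituation across the 128-pulse
trains, intra-subject test–retest variability structure, reporting
latency, site-specific rig differences, or any electromagnetic/neuro-
dynamic field modelling. Passing recovery tests therefore demonstrate
that the estimation pipeline is consistent for data matching its own
assumptions — not that the model is correct for real physiology.

Recovery study sizes: 20 cohorts × 30 subjects × 4 rise times × 3
z-offsets, chosen to mirror the measured cohort scale while keeping the
whole study a few seconds of compute. Median absolute errors at the
defaults: ~3% for ΔGmin (bound 10%), ~5% for the z effect (bound 15%).

## EPI echo spacing

For isotropic in-plane resolution r the readout must traverse a k-space
width 1/r, requiring gradient-time area A = 10³/(r·γ̄) mT/m·ms with
γ̄ = 42.577 MHz/T (so A ≈ 39.1 at 0.6 mm). With no ramp sampling one echo
spacing is ESP = 2τ + A/G. On the slew-limited locus τ = G/SR this is
convex in G with minimizer G* = √(A·SR/2) — the corner point beyond which
more amplitude buys nothing; amplitude limits clip G* and ESP is
re-evaluated there. The planner models the readout purely by this
resolution-driven k-width: matrix, FOV, partial Fourier and parallel
imaging are out of scope, so published minimum echo spacings computed
under other assumptions are not comparable targets. A (G, τ) grid
intersects the operating region with a population threshold curve
(PNS-feasible iff G ≤ ΔG(τ)) and reports whether PNS forces the minimum
echo spacing above the hardware corner; at 0.6 mm, against the in-scanner
x-axis curve, it does (≈0.71 ms versus 0.59 ms).

## Known limitations

* No interval-censored or random-effects likelihood; observations from the
  same subject are treated as independent, so Wald standard errors
  understate between-subject correlation.
* The stimulated-fraction weights are a heuristic inherited from the
  measurement design, not derived from a probability model; weighted
  "likelihood" inference is approximate.
* The factory-rig envelope is not documented beyond what the data imply;
  its censoring caps are taken at the nominal envelope when expanding,
  which can misstate a censored bound by a few mT/m at short rise times.
* Threshold curves extrapolated outside the measured rise-time grid
  (0.1–0.5 ms in-scanner, 0.1–0.8 ms factory) are linear extrapolations
  with no data support.
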