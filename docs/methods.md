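# Methods

## The model

`postflux` estimates postprandial fluxes of central carbon metabolism
from plasma isotopologue time courses measured after an oral meal
carrying a 2% uniformly ¹³C-labeled carbohydrate tracer. Two
interventions are compared throughout: a glucose drink (GLC) and a
wheat porridge (WP), matched to 50 g of available carbohydrate. The
labeled species tracked are glucose M6, pyruvate M3, lactate M3,
alanine M3 and citrate M2, plus a lumped dietary-protein pool
reconstructed from four fully labeled amino-acid isotopologues
(glutamate M5, glutamine M5, valine M5, threonine M4) weighted by their
mol% abundance in wheat gluten, 100/(31.9 + 5.4 + 2.8).

The kinetic model is a four-state linear ODE system over the labeled
pools of pyruvate, lactate, alanine and citrate:

    dC_pyr/dt = k_GLY·C_glc(t) + k_LDHb·C_lac + k_ALTb·C_ala
                − (k_LDHf + k_ALTf + k_TCA + d_pyr)·C_pyr
    dC_lac/dt = k_LDHf·C_pyr − (k_LDHb + d_lac)·C_lac
    dC_ala/dt = k_ALTf·C_pyr + k_Pro·C_pro(t) − (k_ALTb + d_ala)·C_ala
    dC_cit/dt = k_TCA·C_pyr − d_cit·C_cit

Rates `k` (1/min) are explicit interconversions (glycolysis from
glucose, forward/backward lactate dehydrogenase and alanine
aminotransferase, citrate synthesis, protein hydrolysis); rates `d`
lump all unmodelled disposal of each pool. `C_glc(t)` and `C_pro(t)`
are measured drivers, linearly interpolated and fed directly into the
model; queries outside the measured grid clamp to the nearest endpoint
so no negative concentrations can be extrapolated. The glucose driver
is used as measured on the blood side, which is how the measured curve
enters the equation. The modelled states are intracellular; a
time-interpolated blood/intracellular ratio s(t) — breakpoints
(0, 120, 360) min with values (s_pa, s_a, s_pa) — converts them to the
blood side for comparison with plasma data. Both scaling factors
default to 1.0 and must be set explicitly for real analyses; no
literature constants are baked in.

Assumptions worth stating plainly: kinetics are first order in the
labeled pools (reasonable at 2% enrichment, far from saturating any
enzyme); there is no positional isotopomer resolution, no glycogen or
gluconeogenic return, and no tissue-resolved compartments; the whole
body is a single well-mixed intracellular pool facing a blood pool.
Labeled material is absent before ingestion, so every simulation starts
from the zero state at t = 0.

## Numerical integration

The default integrator is LSODA (stiff-capable, adaptive) at rtol 1e-8
and atol 1e-10 µM. Because the system is linear with piecewise-linear
drivers, the solution is also available in closed form per input
segment via a 6×6 augmented matrix exponential; this exact propagator
(vectorized Padé-13 with scaling and squaring across segments) is what
the fitting and sampling inner loops use, and it is cross-checked
against LSODA and against an independent constant-input closed form in
the tests. Machine-precision agreement between the two routes is part
of the test suite, so the speed of the exact path costs no fidelity.

## Preprocessing

Raw data are tidy tables of replicate-level isotopologue concentrations
(µM). The pipeline:

1. **Outlier removal**: values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR]
   within each (intervention, time, metabolite, isotopologue) group are
   removed, quartiles by the linear-interpolation convention. Fences
   are recomputed and the filter reapplied until nothing more is
   removed, making the operation a projection (applying it twice equals
   applying it once); groups smaller than 4 pass through and are
   logged. A classic single pass is available (`max_passes=1`).
2. **Replicate reduction**: technical replicates collapse to their
   median per subject — robust to a single bad injection.
3. **Protein pool**: reconstructed per subject and time point from the
   four amino-acid isotopologues with the mol% weighting above.
4. **Baseline**: the mean pre-ingestion (t < 0) signal is subtracted
   per subject and species, clipped at zero, and a t = 0 anchor of
   exactly zero is inserted — labeled species cannot pre-date the meal.
5. **Subject averaging**: across-subject mean (configurably median)
   with the across-subject standard deviation as σ for the fit.

σ is floored at a purely numerical max(1e-6 µM, 0 × peak). The floor
only exists so the weighted cost stays defined for noise-free synthetic
data; any real across-subject scatter is orders of magnitude larger.
An inflated floor (e.g. 1% of peak) acts as an artificial error model
that widens and skews the posterior of weakly identified rates, which
is why it is kept negligible.

## Fitting

Both interventions are fitted jointly by minimizing

    cost = Σ_i (y_i − ŷ_i)² / σ_i²

summed over interventions, modelled species and window time points —
a weighted sum of squared residuals kept exactly in this printed form
(no root, no mean; any monotone transform ranks fits identically).

Constraints are enforced by construction, never by clipping: the
optimizer works on log10 of the ten GLC rates plus log10 of the WP/GLC
ratio per rate, ratios bounded in [0.1, 10] (symmetric), and k_Pro —
which exists only for WP — parameterized as k_GLY(WP) times a ratio
with the same bound. Log-rate bounds default to [−5, 1] (1/min).
That gives a 21-dimensional box.

Optimization is differential evolution (best/1/bin, recombination 0.9,
population 60, configured to favor local search) followed by a bounded
trust-region least-squares polish per restart, restarted from
independent seeds (50 by default, as in the study protocol; scaled-down
counts are used in the test suite) with the best kept. The best point
then gets one long least-squares refinement: the cost surface has long,
gently sloped valleys along weakly identified rate combinations (d_pyr
trades against the dominant pyruvate-consuming rates at the percent
level) that a capped polish cannot descend; the deep refinement
reliably drives zero-noise fits from ~1e-3 to ~1e-25.

**Window scan.** The postprandial phase splits into an absorptive and a
post-absorptive window. Candidate split points {75, 90, 105, 120, 150}
min are scanned: the whole window [0, 360] is fitted once, then each
candidate is fitted as two independent windows — the early window from
the zero state, the late window initialized from the data at the split
divided by s(split), because the windows are fitted separately. Window
fits are warm-started from the whole-window optimum. A candidate is
sane when its two-window cost sum does not exceed the whole-window cost
(a nested-model check); the lowest sum wins, ties within 1e-6 relative
resolved to the earliest candidate and logged. The split point belongs
to both windows (closed intervals).

## Posterior sampling

The fitted cost defines an unnormalised posterior exp(−cost/2) under
uniform priors on the bounded log parameters — the weighted sum of
squares treated as a chi-square deviance. Sampling uses a
differential-evolution MCMC ensemble: each chain proposes
x′ = x + γ(x_a − x_b) + ε(x_c − x_d) with chains a–d drawn from the
ensemble, γ = 2.38/√(2d) times an adaptive factor tuned during burn-in
to keep acceptance in [0.15, 0.40], and a 10% fraction of γ = 1
mode-jumping proposals. Both the main step and the small ε jitter are
chain differences, so proposals inherit the posterior's scale and
correlation in every direction — an isotropic jitter is rejected almost
surely once the target is tight and correlated.

Chains initialize from the Laplace (Gauss-Newton) approximation at the
fit optimum — covariance (JᵀJ)⁻¹ of the residual Jacobian, standard
deviations along weakly identified eigendirections capped at one decade.
This matters: a fixed-fraction-of-the-box jitter leaves the ensemble
stranded far from sharp posteriors (burn-in would need ~10⁵
generations), while the Laplace ensemble starts on scale and
equilibrates within the default burn-in. Burn-in is at least 50% of
draws and at least 1000 generations; retained draws are thinned by 8
(configurable) because unthinned retained samples of the default size
are autocorrelated enough to inflate the per-parameter AUC noise floor
above 0.6. Exactly n samples (default 10,000) are retained. Acceptance
outside [0.05, 0.6] after adaptation triggers a warning; an ensemble
with no finite-density chain is an error.

The ensemble size defaults to twice the parameter dimension. For
discrimination analyses on a scaled-down retained sample (n = 2,000), a
larger ensemble (three times the dimension or more) is used: per-rate
AUC compares the medians of the paired GLC/WP marginals, and with a
small, autocorrelated retained sample the median jitter alone can push
AUC above 0.6 even when the two marginals are identical. More chains,
each initialized near-independently from the Laplace approximation,
resolve the medians well below the posterior width.

## Discrimination and fluxes

Per rate shared by both interventions, a univariate logistic regression
of the intervention label on the posterior samples is scored by ROC-AUC
(equivalently the Mann–Whitney pair-count statistic, which the tests
verify exactly); reported AUC is max(AUC, 1−AUC) so label order is
irrelevant, and AUC ≥ 0.75 flags a strongly regulated rate. k_Pro is
not scored: it is structurally zero for GLC, so a label comparison of
it is degenerate.

Rate samples convert to fluxes per sample as

    v = k · median(C_substrate over the window's measured times) · (1/s) · 50

with s = s_a in the early window and s = s_pa in the late window (a
switch reproduces the literal alternative of using s_a late), and the
factor 50 undoing the 2% tracer dilution. Substrates follow the
network: k_GLY→glucose M6; k_LDHf, k_ALTf, k_TCA, d_pyr→pyruvate M3;
k_LDHb, d_lac→lactate M3; k_ALTb, d_ala→alanine M3; k_Pro→protein;
d_cit→citrate M2. Net fluxes are forward − backward per sample
(positive toward lactate/alanine production); exchange fluxes are
min(forward, backward). Summaries are posterior medians with equal-tail
90% credible intervals.

## Synthetic studies

The generator reproduces the study design: 2 interventions × 11
subjects × 3 technical replicates × 19 sampling times (−60…360 min),
2% tracer, 50 g carbohydrate. Drivers use a scaled gamma-density shape
(zero before ingestion, one interior peak, then decay) — glucose M6
peaking at 80 µM around 60 min for GLC and 70 µM around 75 min for WP,
and a WP-only protein pool peaking at 2 µM around 100 min. Default
ground-truth rates are chosen so the implied fluxes land in the
low-to-mid µM/min range typical of postprandial central carbon
metabolism, with every WP/GLC ratio inside [0.1, 10]; kinetics switch
abruptly between an early and a late parameter set at 90 min. Noise is
per-replicate multiplicative Gaussian truncated at zero (CV 0.10),
per-subject lognormal multipliers on every rate (σ 0.15), and a small
absolute baseline noise (0.02 µM) for pre-ingestion samples.

What the generator does not emulate: natural-abundance correction
artifacts, drift between GC-MS batches, additive detection-limit noise
on post-ingestion samples, correlated errors across metabolites from a
shared injection, or subject-level differences in absorption kinetics
(only rates vary by subject). Passing recovery tests therefore shows
the estimator is correct under the stated noise model, not that real
plasma data are this well behaved.

## Scaled-down problem sizes

The test suite and the results script run the full pipeline at sizes
chosen for a single CPU: 2–5 optimizer restarts instead of 50, MCMC
n = 2,000 instead of 10,000, and the early window only where a single
window suffices. These sizes are stated in each test; the defaults in
the package remain the full study protocol.

## Known limitations

- d_pyr, d_ala and the LDH/ALT exchange magnitudes are weakly
  identified: they enter as small differences between large rates, so
  their posteriors are wide and skewed at realistic noise (their 90%
  intervals are honest about this — expect decade-wide intervals for
  exchange fluxes at 10% CV).
- The two-window treatment makes rates piecewise constant; real
  kinetics vary smoothly, so window-edge estimates inherit some bias.
- The ratio constraint couples the interventions; a true ratio outside
  [0.1, 10] would be clipped to the boundary by construction.
- Flux conversion uses the median substrate concentration over a
  window, so within-window concentration dynamics do not propagate into
  the flux uncertainty.
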