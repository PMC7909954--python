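# Methods

## Scope and model

`gpcrbias` quantifies transducer bias of GPCR agonists from two-pathway
concentration–response data using the Black–Leff operational model,

E(A) = Em·(τA)ⁿ / ((A+K_A)ⁿ + (τA)ⁿ),

and carries the companion analyses of a typical biased-opioid program:
competition radioligand binding (Cheng–Prusoff), tail-withdrawal
antinociception (%MPE, ED50), place-preference difference scores,
vehicle-normalised respiration/locomotion binning, and MD salt-bridge
contact occupancy. Everything operates on tabular, normalised signals; raw
plate reads (luminescence counts, photon channels) are out of scope except
for the BRET acceptor/donor ratio, which is provided as its own operation.

## Fitting conventions

**Normalisation.** Each panel is rescaled so the reference agonist's fitted
logistic top is 100 and its fitted bottom 0, per receptor and pathway
(DAMGO at MOR, U50,488h at KOR by default). The system maximum `Em` for
operational fits is the reference's fitted top on that scale. Because the
reference is a high-efficacy but finite-τ agonist, its fitted top slightly
underestimates the true `Em`; the induced offset in log(τ/K_A) is common to
every ligand in the pathway and cancels exactly in Δlog, so ΔΔlog and bias
factors are unaffected.

**Hill slopes.** Fixed at 1 for the agonist logistic and the operational
transducer slope (the three-parameter convention; no slopes are estimated
unless overridden), and at −1 for one-site competition binding. The ED50
fit estimates its slope freely because in-vivo dose–response curves are not
constrained by a receptor-level mechanism.

**Optimiser.** Bounded trust-region least squares with multi-start (initial
log-EC50/log-IC50/log-R at the min, median and max observed log
concentration; lowest residual sum of squares wins). Covariances come from
the SVD-regularised Jacobian at the optimum. A fit whose location parameter
lands at the search bound is flagged unconverged rather than raised.

**Operational parameterisation.** The default fit estimates
(log10(τ/K_A), log10 τ) directly, so the transduction coefficient's SE is
read off the covariance with no delta step; a joint (log τ, log K_A)
parameterisation is available and agrees to ≤1e-6 on noise-free data (the
closed-form n=1 identity log(τ/K_A) = log(Emax_obs/Em) − log EC50_obs is
the referee, cross-checked in the tests). When the fitted τ implies an
observed top ≥95% of Em the result is flagged: τ and K_A are then on an
identifiability ridge and only their ratio is meaningful.

**Per-experiment SEs.** By default each independent experiment is fitted
separately and the SEM of per-experiment log(τ/K_A) values is used,
matching the N-independent-experiments structure of the assays; pooled
fitting with asymptotic SEs is available. ΔΔlog significance uses a
two-sided t with df = (number of experiments entering the four estimates) −
2; the t reference was chosen over z because N is typically 3.

**Low-signal screen.** A ligand/pathway panel is fit only if its
concentration-mean span is ≥10% of the reference maximum and the
span-to-noise ratio is ≥3 (noise = pooled within-concentration replicate
SD). Failing panels yield `not_determined` — a first-class outcome that
propagates through Δlog/ΔΔlog and is never coerced to a number. The
numeric thresholds are package defaults, not facts about any assay, and are
configurable.

**Biphasic curves.** Arrestin reporter curves occasionally rise again at
the highest concentrations (a second signalling wave, plausibly from
intracellular receptor pools). The default policy masks, from the top
concentration down (at most 3 points), any point whose mean exceeds the
plateau of a logistic fitted to the remaining data by more than 3 residual
SEs, and records the masked concentrations in the result flags; a
"fit-all" policy is available. No standard fitting rule exists for these
curves; masking keeps the monophasic model honest about the first wave.

**ED50 confidence intervals.** Computed as 10^(logED50 ± t·SE) with
df = n−2: symmetric in log dose, hence asymmetric on the dose axis, which
is the shape such intervals are conventionally printed in (e.g. a morphine
ED50 of 4.77 with CI 1.49–28.8 nmol is log-symmetric).

**%MPE.** 100·(test − baseline)/(cutoff − baseline) with the 15 s cutoff;
latencies at the cutoff score exactly 100 (censoring), sub-baseline
latencies are clamped at −100 with a flag rather than rejected (the assay
definition is silent on hyperalgesia). The score is invariant to the time
unit.

**Contact occupancy.** A frame is in contact with a residue when the
minimum over its carboxylate-oxygen distances is ≤ the 4.5 Å cutoff (the
minimum is the standard salt-bridge convention); "either-residue" contact
ORs across residues, since the donor can switch partners while remaining
bridged. Cumulative occupancy is the frame-weighted pool over runs —
an exact arithmetic identity with per-run fractions, tested as such. Both
per-residue and either-residue figures are reported because published
occupancy numbers do not always say which convention they use. The running
average drawn on distance traces uses a fixed-width centred window shifted
inward at the edges (so a window as long as the series returns the global
mean); the default window corresponds to 10 ns of frames.

## Synthetic data: what it emulates and what it does not

The generators start at the normalised-response level and are parameterised
to the study conditions of the assays they stand in for:

- **Concentration–response** (`gen_conc_response`, `gen_bias_panel`):
  operational-model means plus additive Gaussian well noise, default SD 5%
  of the reference maximum; triplicate wells, three independent
  experiments; the generic grid is half-log from 1 pM to 10 µM, while bias
  panels use 8 half-log points from 10^−9.5 to 10^−6 M so that a ~1 nM
  reference EC50 and arrestin curves attenuated up to ~100-fold both stay
  inside the sampled range (curves must be measurable for a bias factor to
  be computable at all). The assays report only mean ± SEM, so constant
  variance is assumed; an optional lognormal day-effect multiplier on τ
  (geometric SD, e.g. 1.2) is off by default. Test-ligand truths for a
  requested bias factor keep the reference's G-protein parameters and place
  the whole gap in the arrestin pathway — as attenuated recruitment (Emax
  pinned at 40% of Em) for G-biased ligands, as increased functional
  affinity at full recruitment for arrestin-biased ones, mirroring how the
  two phenotypes present experimentally.
- **Competition binding**: one-site mass action with
  IC50 = Ki·(1+[hot]/Kd), hot ligand ~0.1 nM, plus total and nonspecific
  control wells; noise scales with the specific window.
- **Tail withdrawal**: per-mouse baselines ~N(3.0, 0.5) s, %MPE means
  logistic in log dose (floor 0, ceiling 100), per-mouse %MPE noise SD 15,
  conversion back to latency through each mouse's own baseline, censoring
  at 15 s applied after noise.
- **Distance series**: a two-state Markov chain per run with stationary
  bridged probability p and switching propensity 0.1/frame; while bridged
  the donor partners with one acceptor residue chosen at random per frame
  (the fluctuating switch); state-conditional Gaussian distances
  (3.0 ± 0.4 Å in contact, 8.0 ± 1.0 Å out, floored at 1.5 Å — a van der
  Waals lower bound) chosen so the state implies contact at 4.5 Å almost
  surely.

Passing recovery tests on these data shows the estimators are unbiased and
correctly calibrated **under the generator's assumptions**. Real assay data
differ in ways the generator deliberately omits: heteroscedastic and
plate-correlated noise, day effects on potency as well as efficacy,
receptor reserve differences between cell lines, incomplete curves for
low-potency ligands, hot-ligand depletion in binding, latency floors and
observer rounding in vivo, and autocorrelated anharmonic MD dynamics.
Recovery at the defaults therefore validates the pipeline's arithmetic and
statistics, not the biology of any particular dataset.

## Problem sizes

Recovery suites use 200 seeded replicates for the headline checks (ED50
cohorts of 40 mice; bias panels of 2 ligands × 2 pathways × 3 experiments
× 8 concentrations × 3 wells) and 20–200 replicates for secondary property
checks — sizes at which the Monte-Carlo error of a median or geometric mean
is a few percent, comfortably inside the assertion tolerances, while the
full test suite stays in the minutes range.

## Known limitations

- τ and K_A are reported separately only when the ligand is clearly
  partial; for full agonists only log(τ/K_A) is meaningful (flagged).
- The Cheng–Prusoff correction ignores radioligand depletion; the hot-ligand
  Kd used in reports is an input, not something the competition fit can
  estimate.
- Bias factors compare exactly two pathways against one reference; no
  multi-pathway simultaneous analysis.
- No four/five-parameter asymmetric logistics, Schild analysis, saturation
  or kinetic binding, PK modelling, or ANOVA post-hoc machinery (Welch's t
  is the only hypothesis test shipped).
- The optional PDB reader computes donor–acceptor distances only; it is not
  a trajectory-analysis framework.
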