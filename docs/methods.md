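# Methods

`tapdose` implements the analysis chain used in preclinical evaluation of a
²¹²Pb-labeled GRPR-targeting peptide: decay-chain physics, biodistribution
analytics, MIRD-style RBE-weighted dosimetry with mouse-to-human projection,
saturation-binding affinity estimation, and survival/welfare endpoints, all
exercised against a seeded synthetic-data generator. This note records the
models, the defaults, and the design choices where the design was genuinely
open.

## Decay-chain physics

The ²¹²Pb chain is Pb-212 (β⁻, T½ = 10.64 h) → Bi-212 (60.55 min), which
branches 64.06 % β⁻ to Po-212 (0.299 µs, α 8.785 MeV) and 35.94 % α
(≈6.05 MeV) to Tl-208 (3.05 min, β⁻), both terminating at stable Pb-208.
Nuclear data ship as a versioned plain-text table
(`data/pb212_chain.csv`) with half-lives and branching from NNDC/ENSDF and
mean per-mode emission energies condensed from ICRP-107-style listings;
compilations differ in the third significant figure, and the table is
user-overridable.

Chain activities come from the analytic Bateman solution, represented as
sums of exponentials propagated down the chain with branching. Po-212 is
five orders of magnitude shorter-lived than anything else in the chain and
is treated as decaying in step with its Bi-212 parent (activity = 64.06 %
of Bi-212 activity); this removes stiffness at no meaningful cost — the
transient it ignores lasts microseconds. Degenerate (equal) decay constants
raise an error rather than being perturbed; the bundled chain has none.

At equilibrium every head decay yields one Bi-212 decay and the branched
daughter decays, giving per-Pb-212-decay energies

    E_α = 7.802 MeV,  E_e = 0.861 MeV,  E_γ = 1.457 MeV.

## Biodistribution

Counts are background-subtracted upstream; the table stores net counts.
%ID/g is defined decay-corrected to injection time: organ and standard
counts are both corrected to the reference time, the standard (counted at a
known fraction of the injected dose, default 1.0) sets the dose equivalent,
and %ID/g = %ID / organ mass. This makes %ID/g independent of when the
standard was counted; the dosimetry layer re-applies physical decay.

Group summaries report sample mean and SD (n − 1) per organ × timepoint;
single-sample cells report SD as undefined. Group contrasts use a
two-sided Welch t test by default (a pooled Student test is an option) —
the unequal-variance form is the robust default when per-cell n = 5.
Exactly identical groups return p = 1. Tumor-size analysis reports Pearson
correlations of tumor volume against %ID/g and against %ID; an exactly flat
uptake variable is reported as correlation 0 rather than an error, while
zero-variance volumes are rejected.

Radiochemical purity is the percent of chromatogram counts inside the
main-peak window. When no window is supplied, a Gaussian is fitted to the
tallest peak (seeded by its FWHM) and ±3σ is used; the ±3σ convention
intrinsically concedes ~0.3 % of peak area to the tails.

Molar masses use IUPAC standard atomic weights (via Biopython); the default
formula C77H119N23O17 gives 1638.9 g/mol, so a 370 kBq / 280 ng dose is
1.32 kBq/ng and 0.171 nmol.

## Dosimetry

Time–activity curves are A_o(t) = (%ID/g · m_o/100) · 2^(−t/T½). A t = 0
anchor of 0 (tissues) or a configurable blood-pool value (whole body) is
prepended before integration: the interval from injection to the first
harvest is otherwise unconstrained, and anchoring at zero is bounded and
conservative for tissues; the dense-sampling round-trip test quantifies the
residual error. The time-integrated activity coefficient (TIAC) is the
trapezoid over observed points plus an analytic tail A(t_last)/λ assuming
pure physical decay after the last observation (no biological clearance in
the tail — the conservative convention; a biological+physical tail is a
config option, not the default). For a convex decaying curve the trapezoid
overestimates, so sparse schedules bias TIACs high; with the 5-point
schedule (0.5, 1, 4, 8, 24 h) used in tests the bias stays under 10 %, and
under 0.5 % with dense sampling.

Human projection uses the relative-concentration method: the
organ-to-whole-body concentration ratio R(t) measured in the mouse is
assumed to hold in the human, with the human whole-body fraction curve
taken equal to the mouse one. The mouse whole-body curve defaults to the
sum of measured organ activity fractions (include a remainder/carcass
compartment for completeness). Phantom masses are bundled: ICRP-89-style
reference adults (female kidneys 0.275 kg, body 60 kg; male 0.310 kg,
73 kg) and ~25 g laboratory mice; all overridable via YAML.

Absorbed-dose coefficients follow the local-equilibrium assumption
(daughters decay where the parent sits — the standard preclinical
convention absent daughter-redistribution data):

    D_o [Gy/GBq] = TIAC_o·3600 [s] · (RBE·E_α + E_e + φ·E_γ)·1.602×10⁻¹³ [J] / m_o [kg] · 10⁹

RBE weights α emissions only (electrons and photons weight 1); 3 and 5 are
the shipped presets but any positive value is accepted. The default photon
absorbed fraction is φ = 0: organ-scale volumes absorb essentially all α
and electron energy but little of the 2.6 MeV-dominated photon emission.
This choice is validated by the published RBE-3/RBE-5 activity-limit pair:
re-weighting the RBE-5 kidney coefficient (0.308 Gy at 0.111 GBq) by
(3E_α + E_e)/(5E_α + E_e) with φ = 0 puts the 23 Gy kidney threshold at
13.62 GBq, matching the reported 13.6 GBq; at RBE 5 the same coefficient
gives 8.29 GBq. Red marrow is treated as a generic organ with a
user-supplied activity surrogate (blood fraction by default); there is no
specialized marrow model.

The published RBE-5 human-projected dose table is bundled as an *input*
(`data/grpr1_reference_doses.csv`): its absolute coefficients cannot be
re-derived without the underlying animal-level data, so the reproducible
surface is the linear dose scaling, the limiting-organ/activity-limit
arithmetic, the RBE re-weighting, and the safety margins built on it.

## Binding

Specific binding is the paired difference of total and cold-blocked well
means per concentration; negative values are flagged, not clipped. The
one-site model B(c) = Bmax·c/(Kd + c) is fitted by bounded nonlinear least
squares with Bmax₀ = max observed signal and Kd₀ = concentration nearest
half of Bmax₀, with deterministic jittered restarts on non-convergence.
Standard errors come from the Jacobian-based covariance; the ±-value
reported with a Kd is treated as that SE. Nonspecific binding is modeled
as measured (paired subtraction), not as a fitted linear component;
radioligand depletion is ignored (incubation volumes unknown). At the
study design (0.5–64 nM, triplicates, 5 % CV) simulation shows the
estimator essentially unbiased (≲0.5 %) with Wald-CI coverage near but
slightly under the nominal 95 % (≈90 % — the usual small-sample optimism
of linearized intervals).

## Outcomes

Tumor volume is the caliper product length × width × height. Survival uses
the Kaplan–Meier product-limit estimator (lifelines) with the median taken
as the earliest time at which S(t) ≤ 0.5 (with a 1e-12 tolerance so exact
halves are not lost to floating-point products); ties between events and
censoring at a time are processed events-first. No between-group test is
run by default; log-rank is available in lifelines for callers who want
one. Humane-endpoint rules: volume ≥ 1000 mm³; >15 % below initial weight
on two consecutive measurement days; ≥20 % below initial weight at any
point; other welfare observations enter as externally supplied flags.

## Synthetic data

The generators define the study conditions and are not tuned per test.

**Biodistribution.** Each organ follows a bi-exponential biological
retention U_o·Σwᵢ2^(−t/τᵢ) with instantaneous uptake at t = 0⁺. Defaults
are calibrated once to the study's summary observations: pancreas ≈35 %ID/g
at 1 h (28 ng) washing out below 2 %ID/g by 24 h, tumor plateau ≈5 %ID/g
from 1–24 h, kidneys ≈10 %ID/g at 1 h, blood clearing fast. Receptor
self-blocking scales blockable-organ uptake by 1/(1 + m/K_block) with
K_block = 560 ng, chosen so 280 vs 28 ng reduces pancreas uptake by 30 % —
a single-saturable-site calibration, not a mechanistic occupancy claim.
Whatever the named organs do not take up sits in a mono-exponentially
clearing remainder/carcass compartment; excretion is the balance, so
organs + remainder + excreted = 100 %ID at every time by construction.
Counts include physical decay to the euthanasia time and unit-mean
lognormal noise (CV 10 % by default, counts stay positive); 5 animals per
timepoint at 1, 4 and 24 h. Tumor-size cohorts hold absolute tumor uptake
flat while mass scales with volume, emulating necrotic cores diluting
concentration in large tumors.

**Binding plates.** One-site specific signal (defaults Kd 3.93 nM, Bmax
2×10⁴ counts) plus a nonspecific component linear in concentration (5 % of
Bmax at 64 nM), triplicates over 0.5–64 nM, lognormal 5 % CV.

**Survival.** Per-group Weibull event times with administrative censoring
at 28 weeks. Presets share shape 2.5 with scales set so group medians sit
at 9.4/10.5/14.7/16/18.9 weeks. A single Weibull cannot simultaneously
match those medians and the reported survivor fractions at termination;
the medians are the calibration target and survivor fractions are
approximate — a known limitation of the emulation, not of the estimator.

**Chromatograms.** A main Gaussian peak (300 s, σ = 12 s) and an
earlier-eluting oxidation satellite (180 s) on a 6 s fraction grid with
Poisson counting noise; the default window runs from the inter-peak valley
to the end of the run so the noise-free purity equals the main-area
fraction exactly.

What passing tests therefore show: the pipeline recovers parameters it
generated under lognormal/Poisson noise and exponential kinetics. What they
do not show: robustness to inter-animal kinetic heterogeneity, compartment
redistribution of daughters, detector saturation or plate-edge effects —
none of which the generator emulates.

## Problem sizes and numerics

Test and report workloads are sized for quick iteration: 500-replicate
Monte Carlo for Kd bias, 1000 replicate cohorts for survival-median
calibration, 100 random times for the Bateman-vs-ODE comparison, ~1400
timepoints for dense TIAC round trips. Durations are hours internally;
1 MeV = 1.602176634×10⁻¹³ J exactly. CSV outputs fix floats at six
significant digits and carry a version/config-hash header, making reruns
byte-identical.
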