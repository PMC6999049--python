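# Methods

## Scope and data model

The package analyzes fast chlorophyll-*a* fluorescence rise curves
(OJIP transients): time-ordered traces of fluorescence intensity from
the onset of saturating actinic light, sampled from ~10 µs to 1–2 s.
Time zero is light onset and every landmark time is absolute from it:
F_O at 20 µs, F_L at 150 µs, F_270 at 270 µs, F_K at 300 µs, F_J at
2 ms, F_I at 30 ms.  F_M is the maximum of the *recorded samples* (not
of any interpolant) and t_FM its time, first occurrence on ties.  Input
is plain two-column delimited text (the form instrument software
exports); no binary formats are parsed.

Fixed-time landmarks are read by interpolation.  The default rule is
piecewise linear in linear time: PEA-class instruments sample every
10 µs over the early rise, so the rule contributes ~0.1% at most, but it
must be pinned for reproducibility.  A geometric alternative (log F
linear in log t, useful on sparse early grids) is available as
`rule="log"`.  Both are exact at sample points, and interpolation is
monotone between ordered samples.

## Derived parameters

All JIP-test quantities follow the standard energy-flux formulation; see
the README for the formula block.  Numerical decisions that the formulas
alone do not fix:

* **Area / S_m.**  The complementary area ∫(F_M − F_t)dt is trapezoidal
  on the raw sample grid from onset to t_FM, with no resampling.
  Samples after t_FM are excluded, and F is capped at F_M.
* **M_0** uses the 270 µs sample exactly (not the 300 µs K-step
  approximation sometimes seen elsewhere).
* **ABS/CS proxy.**  The absorption flux per cross-section has no direct
  estimator from a transient; the conventional proxy ABS/CS ≈ F_O is the
  default (F_M optional) and the choice is recorded in every result so
  RC/CS values are never compared across proxies silently.
* **Saturated J step.**  When V_J ≥ 0.95 (configurable) the J level is
  within measurement noise of the peak — the regime a complete
  Q_A→Q_B block (e.g. DCMU) produces.  The electron-transport odds
  ψ_Eo/(1−ψ_Eo) and δ_Ro are then numerically meaningless: the record is
  flagged `saturated_J`, performance indexes report 0, δ_Ro is NaN,
  while ψ_Eo and φ_Eo keep their computed near-zero values.  A trace
  with F_M ≤ F_O raises a degenerate-transient error instead.
* **R_J** is computed from group-mean V_J values (one occupancy estimate
  per treatment, matching how a concentration series is reported);
  per-sample values against the control mean are also emitted for
  dispersion.  The raw value can be slightly negative when the treated
  mean sits below control; the headline field clips to [0, 1] — it
  estimates an occupancy fraction — and the raw value is kept alongside.
  Relative ("spider-plot") parameters are ratios of group means, not
  means of per-pair ratios.
* **Quenching parameters** use the standard saturation-pulse
  definitions.  F_O′ is not measured by the emulated protocol, so
  qP defaults to using dark-adapted F_O (an explicit F_O′ can be
  passed); ETR defaults to absorptance 0.84 and PSII fraction 0.5,
  both exposed.

## Band analysis

Double normalizations V_t, W_OK, W_OJ, W_OI, W_IP are computed on each
transient's own grid; difference kinetics (treated − control) are taken
on the union grid restricted to the overlapping range.  Band summaries
report the signed largest-magnitude value and its time within fixed
windows bracketing the named steps: L-band in 100–300 µs, K-band in
200–500 µs, and the ΔV_t extremum in the 1–3 ms J region (the value
exactly at 2 ms is reported as well, since either convention appears in
practice).  W_IP is analyzed on 30–530 ms; its half-time is the first
upward crossing of 0.5, linearly interpolated, NaN-flagged when no
crossing exists (a curve that never completes its half-rise has no
half-time).  A vanished landmark denominator (e.g. F_K = F_O) flags
only that curve; the others are still produced.

## MR (820 nm reflection) features

MR_0 is interpolated at 0.7 ms, the first reliable sample.  MR_min is
the global minimum within the fast-phase window (default 0.7–200 ms —
the balance point between PSII-driven re-reduction and PSI oxidation
varies, so the upper bound is configurable and t_min is always reported
for audit).  MR_max is the maximum after t_min up to 2 s.  Amplitudes
are normalized by MR_0, making all features invariant to the arbitrary
instrument scale.  Because MR_min is an extremum statistic it is biased
low on noisy traces; an optional moving-median presmoother (default
off) mitigates this.  A slow amplitude ≤ 10⁻³ of MR_0 is flagged
`slow_phase_absent` — the methyl-viologen-like plateau and the fully
blocked (DCMU-like) monotone decay both land here.

## Dose-response and phytotoxicity

I₅₀ is estimated by a two-parameter log-logistic fit
U/(1 + (d/I₅₀)^h) with the upper asymptote U fixed at the control mean
and lower asymptote 0, least squares over (log I₅₀, log h); a
model-free interpolation of mean inhibition vs log dose across the 50%
crossing is always computed as a cross-check and as the fit's starting
point.  Series with no dose past 50% inhibition (or responses that rise
with dose) yield NaN with an explanatory flag rather than an
extrapolated number.  Replicates aggregate as arithmetic mean ± SE.

Lesion diameters map to pathogenicity symbols as: “+” for d < 1.0 mm,
“++” for 1.0 ≤ d ≤ 3.0 mm, “+++” for d > 3.0 mm (strict outer cutoffs,
consistent with every row of the bundled 30-row survey).

## The synthetic generator

The generator exists to make every stage testable without instrument
data; it targets the phenomenology the JIP-test reads — an ordered
O-J-I-P rise with tunable J level, I timing and I→P amplitude — not
photosynthetic realism.  Per reaction center (times in ms):

* a blocked fraction B accumulates Q_A⁻ without reoxidation,
  dC_b/dt = k_L(1 − C_b);
* the active remainder is photoreduced at k_L and reoxidized at k_AB
  while oxidized PQ remains, dC_a/dt = k_L(1 − C_a) − k_AB·C_a·g(P),
  with g(P) = P/(P + 0.02·N_PQ) a smooth availability factor;
* the oxidized-PQ pool (initial N_PQ) is regenerated by a PSI-side
  drain, k_FNR·a(t)·(N_PQ − P)·h(R), whose activation
  a(t) = 1 − e^(−k_FNR·t) emulates the FNR activation delay shaping the
  I step and whose capacity R (initial S_PSI) exhausts to release the
  final I→P rise.

Fluorescence follows the total closed fraction through the
antenna-connectivity transform F = F_O + (F_M−F_O)·C(1−p)/(1−pC);
`antenna_loss` attenuates both levels jointly (pure antenna damage moves
the per-cross-section fluxes without touching any normalized ratio).
Noise is multiplicative Gaussian, fully seeded.

Defaults were chosen once to mimic a healthy dark-adapted sample under
saturating red light: k_L = 3.0 ms⁻¹ and k_AB = 2.8 ms⁻¹ put the
control J level near 0.5 and saturate the J step within 2 ms when
B = 1; N_PQ = 10 electron equivalents places the I step near 30 ms;
k_FNR = 0.055 ms⁻¹ and S_PSI = 120 equivalents give an I plateau near
V ≈ 0.8 and a peak at a few hundred ms (S_PSI is an *effective*
capacity lumping all PSI-side sinks during induction, hence larger than
literature NADP⁺/ferredoxin pool sizes); F levels 500/2500 and 1%
relative noise match typical instrument output.  Integration uses fixed
explicit stepping with an exponential update for the fast Q_A state and
a step growing ∝ t (capped at 0.5 ms); `substep_scale` refines all
steps for convergence checks, and halving changes V_J by < 10⁻⁵.

What the generator does **not** emulate: S-state cycling of the
oxygen-evolving complex (no genuine K-band physics), membrane-potential
and NPQ effects, state transitions, light-gradient heterogeneity, and
detector nonlinearity.  Tests passing on synthetic data therefore
demonstrate correctness of the *estimators* under the stated kinetic
assumptions, not instrument-level fidelity on real leaves.

The MR generator is the parametric two-phase form
1 − fast_amp·(1 − e^(−k_fast(t−0.7))) + slow_amp·σ(k_slow(t − t_onset)),
referenced to the 0.7 ms MR_0 point so programmed amplitudes are on the
scale the extractor reads.  Dose series come from the same log-logistic
family the fitter assumes (recovery tests are parameter recovery, not
model-misspecification tests).  The synthetic lesion table fabricates
species names, spans all three classes and always contains the
boundary-adjacent diameters 0.99/1.0/3.0/3.01 mm.

## Batch pipeline

A TSV manifest (path, group, type ∈ {ojip, mr, dose, lesion}) drives the
run; one group is the control.  Per-sample failures are logged and
skipped — a run only fails when the control group ends up empty.  Group
band curves are differences of group-mean normalized curves (analysis of
averaged curves, as multi-replicate protocols do); per-sample JIP
parameters are reported individually with group means formed downstream,
and an opt-in `average_curves` mode exists for protocols that average
before analysis.  Outputs are deterministic given inputs + config +
seed, written with 9 significant digits, and every run records a config
hash.  The correlation report fits V_J, PI_ABS and S_m/t_FM against
φ_Eo, and S_m/t_FM against R_J, across ≥ 3 concentration levels
(slope, intercept, Pearson r; zero-variance input is flagged rather
than fitted).

## Verification problem sizes

The test suite and the acceptance script run entirely on generated
data: 1,000-record randomized identity audits, instrument-like grids of
~180 points per transient, ≤ 15 simulated transients per property
sweep, 30-replicate averaging only where a noisy extremum statistic is
under test.  These sizes keep the full suite under a few seconds while
leaving every estimator's error an order of magnitude inside its
asserted tolerance.

## Known limitations

* The F_O landmark is the interpolated 20 µs value; instruments that
  fit the origin from 10–50 µs samples will differ by up to ~1% on
  steep rises.
* R_J assumes the control J level is representative; with saturated
  controls (V_J → 1) the statistic is undefined and refused.
* The I₅₀ fit fixes the lower asymptote at 0 — partial-inhibition
  plateaus bias it; inspect the reported fit SSE and the interpolation
  cross-check.
* Lesion classification applies fixed universal cutoffs; it does not
  model species- or assay-specific severity scales.
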