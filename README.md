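# ojipkit

Analysis of fast chlorophyll-*a* fluorescence induction (OJIP) transients
and related photosynthesis assays, aimed at phenotyping photosystem II
inhibition — e.g. screening natural or synthetic herbicides that occupy
the Q_B site of the D1 protein.

When a dark-adapted leaf, algal suspension, or thylakoid preparation is
exposed to strong actinic light, chlorophyll fluorescence rises from a
minimal level **O** (~20 µs) through inflections **J** (2 ms) and **I**
(30 ms) to a peak **P** within a second.  The shape of this polyphasic
rise encodes the redox state of the PSII acceptor side: an inhibitor
that blocks electron transfer from Q_A⁻ to Q_B raises the J step, and a
shrinking I→P amplitude reflects a smaller pool of PSI end electron
acceptors.  `ojipkit` implements the JIP-test, which converts the
landmark fluorescence values into quantum yields and energy fluxes:

    V_J   = (F_2ms − F_O)/(F_M − F_O)          relative variable fluorescence at J
    φ_Po  = 1 − F_O/F_M                        max. yield of primary photochemistry
    ψ_Eo  = 1 − V_J                            electron transfer beyond Q_A⁻
    φ_Eo  = φ_Po·ψ_Eo                          yield of electron transport
    δ_Ro  = (1 − V_I)/(1 − V_J)                intersystem → PSI end acceptors
    M_0   = 4(F_270µs − F_O)/(F_M − F_O)       initial slope (ms⁻¹)
    S_m   = Area/(F_M − F_O)                   normalized complementary area
    PI_ABS   = [γ_RC/(1−γ_RC)]·[φ_Po/(1−φ_Po)]·[ψ_Eo/(1−ψ_Eo)]
    PI_total = PI_ABS·δ_Ro/(1−δ_Ro)

and the treated-vs-control statistics built on them, most importantly the
Q_B-site occupancy estimate

    R_J = [V_J(treated) − V_J(control)] / [1 − V_J(control)],

the fraction of PSII reaction centers whose Q_B site is filled by the
inhibitor.  The package also covers double-normalized difference
kinetics (L-band, K-band, W_OI, W_IP and its half-time), feature
extraction from modulated 820 nm reflection (MR) traces that track
plastocyanin/P700 oxidation, log-logistic I₅₀ dose-response fits,
saturation-pulse quenching parameters (F_V/F_M, Yield, qP, ETR), and a
lesion-diameter phytotoxicity classifier.

Because raw instrument exports are rarely published, `ojipkit` ships a
kinetic simulator of inhibitor-treated PSII transients (and two-phase MR
curves, dose series, lesion tables) so the whole pipeline is testable
end to end; every analysis stage is validated against closed forms or
generator-parameter recovery.

## Worked example

```python
from ojipkit import (SyntheticScenario, simulate_ojip, extract_steps,
                     compute_areas, compute_jip, compare_groups,
                     normalize_curves, wip_half_time)

def analyze(scn):
    tr = simulate_ojip(scn)
    steps = extract_steps(tr)
    return tr, steps, compute_jip(steps, compute_areas(tr, steps))

control = SyntheticScenario(p=0.0, noise_sd=0.0)   # healthy sample
treated = control.with_(B=0.5)                     # half the Q_B sites blocked

tr_c, st_c, jip_c = analyze(control)
tr_t, st_t, jip_t = analyze(treated)
comp = compare_groups([jip_t], [jip_c])

for name, j in (("control", jip_c), ("treated", jip_t)):
    print(f"{name}:  V_J={j.V_J:.3f}  phi_Po={j.phi_Po:.3f}  "
          f"PI_ABS={j.PI_ABS:.3f}  Sm/tFM={j.Sm_over_tFM:.4f}")
print(f"R_J = {comp.R_J:.3f}   (fraction of Q_B sites occupied)")
print(f"PI_ABS fell to {100*comp.relative_params['PI_ABS']:.1f}% of control")
print(f"control W_IP half-time = "
      f"{wip_half_time(normalize_curves(tr_c, st_c)):.1f} ms")
```

prints

```
control:  V_J=0.495  phi_Po=0.755  PI_ABS=0.779  Sm/tFM=0.1307
treated:  V_J=0.746  phi_Po=0.754  PI_ABS=0.325  Sm/tFM=0.0698
R_J = 0.497   (fraction of Q_B sites occupied)
PI_ABS fell to 41.7% of control
control W_IP half-time = 264.6 ms
```

Blocking half of the Q_B sites raises the J step (V_J 0.50 → 0.75) while
leaving primary photochemistry φ_Po untouched — the signature of an
acceptor-side inhibitor — and the occupancy statistic R_J recovers the
programmed blocked fraction (0.497 vs 0.5).  The performance index
PI_ABS, the most stress-sensitive parameter, falls to 42% of control,
and S_m/t_FM (average fraction of open centers) halves.

Batch work goes through the CLI: `ojipkit simulate` writes a synthetic
fixture set, `ojipkit analyze manifest.tsv -o out/` produces per-sample
and group tables, `ojipkit compare`/`ojipkit report` give quick
occupancy and correlation summaries.  Real Handy-PEA-style exports
(two-column delimited text) are read with `read_transient`.

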