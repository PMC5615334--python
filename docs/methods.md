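# Methods

## Model

The package tracks normal (`n`) and therapy-induced premalignant (`m`)
cells in an organ at risk through a treatment course:

```
dn/dt = λ n (1 − n/N) − G(t) n − R(t) n
dm/dt = r λ m (1 − n/N) − G(t) m + R(t) n
```

Assumptions: homeostatic (logistic) regulation of the normal
compartment with carrying capacity `N`; premalignant cells repopulate
at the relative rate `r` and are killed by treatment exactly like
normal cells; mutation induction is proportional to the instantaneous
dose rate and moves cells from `n` to `m`; demographic and latency
modifiers are absorbed into a constant per-organ factor `g`, so
`ERR = g·M` and `RR = 1 + ERR` with `M` the premalignant count at the
evaluation time. Bell-shaped dose-response emerges when cell kill of
the premalignant pool outruns its repopulation advantage.

## Parameters

| parameter | meaning | unit | breast | lung | thyroid |
|---|---|---|---|---|---|
| λ | normal-cell proliferation | /day | 0.4 | 0.4 | 0.4 |
| r | relative premalignant growth | – | 0.76 | 0.96 | 0.68 |
| N | homeostatic cell number | cells | 1e6 | 1e6 | 1e6 |
| α_R | radiation cell kill | /Gy | 0.18 | 0.18 | 0.25 |
| γ_R | radiation mutation induction | /Gy | 1e-6 | 1e-6 | 1e-6 |
| α_C | chemo cell kill | /(mg/m²) | 0.2 | 0.2 | 0.2 |
| γ_C | chemo mutation induction | /(mg/m²) | 1e-9 | 0.5e-6 | 0.9e-7 |
| α_d | drug clearance | /day | 0.1333 | 0.1333 | 0.1333 |
| g | ERR proportionality | – | 1.2 | 0.18 | 1.0 |

Treatment defaults: 2 Gy fractions, 5 per week with weekends skipped
(day 0 is a Monday); 30-day chemotherapy cycles of 12 mg/m²
mechlorethamine-equivalent; concurrent radiotherapy starts on day 1 of
chemotherapy cycle 1. Cycle-group counts follow the cohort groupings:
3/6/10 cycles for breast and lung, 5/10 for the thyroid low-medium and
high exposure tertiles; concurrent scenario doses are 25/20/20 Gy for
breast/lung/thyroid with 5 cycles (10 for thyroid high).

## Delivery conventions (the load-bearing choices)

Published table values constrain several conventions that the model
family leaves open. The shipped defaults were selected by a
calibration pass against the full set of published model columns
(chemo-only and concurrent tables simultaneously); each alternative
remains available for comparison.

1. **Radiation pulses.** The default integrator applies the exact
   impulse limit of a pulse of width τ → 0:
   `n → n·e^{−(α_R+γ_R)d}`, `m → (m + γ_R d n)·e^{−α_R d}`. Newly
   initiated cells are created *during* the pulse and therefore see the
   same pulse's kill — this is what the continuous pulse ODE gives
   analytically, and the finite-pulse mode (τ = 1 minute, dose rate
   d/τ) agrees with the map to ~1e-5 relative. The variant in which
   new mutants escape their own fraction's kill over-predicts the
   concurrent breast risk by ~30% and is not shipped as default.
2. **Chemotherapy kill.** Each cycle's dose acts as a hazard
   `α_C (d_C/T) e^{−α_d (t−t_i)}` per day, i.e., the cycle dose enters
   at its mean daily rate `d_C/T` and decays with first-order
   clearance; the clock resets at each cycle start. The integrated
   kill per cycle is `α_C d_C/(α_d T)` ≈ 0.6 — comparable to a few
   radiotherapy fractions. Interpreting `α_C d_C` as a per-day rate
   instead gives an integrated kill of ≈ 18 per cycle, which
   annihilates the tissue and suppresses all excess risk; that
   convention is incompatible with every published table value.
3. **Chemotherapy mutation.** The mutation flux `γ_C d_C` per cycle is
   spread uniformly over the cycle window with no clearance factor
   (the kill term carries the decay, the mutation term does not).
   Front-loading it as a cycle-start impulse makes new mutants absorb
   the whole cycle's kill and under-predicts thyroid risks by ~10–17%.
4. **Interaction.** In the default `dose_multiplier` mode the
   radio-sensitization factor ε multiplies the radiation dose in the
   *kill* terms of both compartments (not in the mutation term), on
   fraction days that fall inside an ongoing chemotherapy cycle;
   ε ∈ {0, 1} means no interaction. The alternative `extra_kill_rate`
   mode applies an extra integrated kill ε per concurrent fraction to
   both compartments. The multiplier mode with ε = 2.6 reproduces the
   published interaction table within 8%.
5. **Evaluation time.** `M` is taken after post-treatment repopulation
   (`plateau` rule): once every kill source has ended, the closed form
   `M = m·(N/n)^r` amplifies `m` by the remaining treatment-free
   regrowth. The `end_of_treatment` rule (no further repopulation) is
   available in configuration; with it the published magnitudes are
   not reachable for radiotherapy courses, whose last fraction leaves
   the tissue maximally depleted.
6. **Dose → fractions.** Scenario doses use 2 Gy fractions with
   `K_R = round(D/2)` (ties round to even, so 25 Gy → 12 fractions).
   Dose-response *curves* default to a fixed 20-fraction schedule with
   `d = D/20`, which makes ERR smooth in dose; under the 2-Gy rule the
   weekday/weekend structure makes the curve jagged at the 1-Gy grid
   scale.

## Numerics

Between treatment events the treatment-free system has an exact
solution (logistic `n`; `m` multiplied by `(n₂/n₁)^r`), used whenever
no chemotherapy hazard is active — this also makes homeostasis an
exact fixed point. Intervals with an active chemotherapy hazard are
integrated with LSODA at rtol 1e-8 / atol 1e-10; integration failure
raises rather than returning NaN. All simulations and fits are
deterministic.

Fits minimize unweighted SSE on the ERR/RR scale (inverse-variance CI
weighting is available as a flag) with a 64-point grid pre-scan
followed by bounded scalar refinement between the best grid point's
neighbours; `γ_C` is searched on a log10 scale over [1e-10, 1e-5].
Flat objectives (e.g., all-null data) are flagged non-identifiable
instead of returning an arbitrary interior point.

## Synthetic cohorts

`synthetic_data` emulates the *shape* of the published summaries:
ERR-vs-dose points and RR-vs-cycle-group points generated from a known
truth parameter set, with optional multiplicative lognormal noise
(`σ = sqrt(log(1+cv²))`, default cv 0.3, matching the ratio-scaled
width of published confidence intervals) applied to the excess risk so
that noisy RRs can drop below 1 without breaking the null floor. It
does not emulate person-year weighting, latency, censoring, dose
reconstruction error, or between-study heterogeneity — so passing
recovery tests demonstrate identifiability under the model's own
assumptions, not robustness to real-cohort artefacts.

Recovery test sizes: noise-free recovery of `r`, `γ_C`, `ε` at the
thyroid truth values, plus 50 seeded lognormal replicates (cv 0.1) per
parameter with 2–6 design points each — desk-scale sizes chosen to
match the handful of summary points the published fits themselves use.

## Known limitations

- The thyroid `r = 0.68` ships as the published extracted value; the
  ERR-vs-dose scatter behind it is not published, so it is validated
  by synthetic parameter recovery only. With `g` assumed 1.0, the
  pair (r, g) is jointly identifiable only given that scatter.
- `g` is a constant per organ: no age-, sex- or latency-resolved risk,
  and no time-dependence of RR after treatment (lifetime risk only).
- Chemotherapy pharmacokinetics are a single exponential; multi-drug
  regimens are reduced to the mechlorethamine-equivalent dose.
- The two thyroid concurrent scenarios are mapped to 5 vs 10 cycles at
  a fixed 20 Gy; the source tables do not state this mapping
  explicitly, and it is recorded in the fixture CSVs, not hard-coded.
- Hormonal/ovarian-dose effects on breast risk and bystander/abscopal
  radiation effects are out of scope.
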