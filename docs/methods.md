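# Methods

## Model structure and assumptions

`rosecost` chains three sub-models.  The **sampling model** treats each
needle pass as an independent Bernoulli trial with constant per-pass
adequacy probability `p`.  This is the standard binomial approximation;
in reality each pass disturbs the target and `p` may decline with pass
number, but the constant-`p` model fits observed FNAB adequacy data well
and its predictions are robust to moderate declines.  Under the fixed
protocol all `n_fixed` passes are taken regardless; under ROSE the
on-site call is an imperfect classifier with sensitivity `sn` and
specificity `sp` judged against the final laboratory assessment, and
sampling stops at the `n_rose`-th positive call.  `n_rose` is preset
before the procedure; adaptive stopping informed by earlier passes is
out of scope.

The ROSE failure semantics matter and are easy to get wrong: a procedure
*succeeds* when at least one **truly** adequate sample was collected,
whether or not the cytologist called it positive — a false-negative call
costs an extra pass, but the miscalled sample still reaches the
laboratory and rescues the case.  Only under this reading does the
event-level process reproduce the closed form
`A̅ᴿ = 1 − [(1−sp)(1−p)/(1−sp(1−p))]^n_rose`; the alternative reading
(only positively-called samples count) does not, and the simulator test
grid would detect the discrepancy immediately.

The **operational model** splits each procedure into a setup period
(identical for both protocols) and a sampling period equal to expected
passes × per-pass time.  Only two periods are modelled; cleanup or
step-down periods would be additional terms of the same form.  The
**cost model** is micro-costing: an effective hourly rate applied to the
whole procedure duration, a fixed per-procedure cost (supplies, final
cytopathology), and an expected per-needle-pass cost `c_np` that bundles
per-pass supplies with probability-weighted adverse-event costs (no
explicit adverse-event sub-model).  Failed procedures are repeated —
never escalated to a more expensive salvage procedure — so per-case cost
is per-procedure cost divided by adequacy.  This makes the estimated
ROSE savings conservative wherever failures would in practice trigger
costlier follow-ups.

## Parameters, units, defaults

Durations are minutes, rates are currency per hour (the division by 60
happens exactly once, at the rate product), and currency is an abstract
unit.  The packaged `paper-base` configuration defines the defaults:

| symbol | meaning | base (range) |
|---|---|---|
| `p` | per-pass adequacy | low 0.3 (0.2–0.4), high 0.6 (0.5–0.7) |
| `sn`, `sp` | cytologist accuracy | 0.95 (0.90–1.00), 0.975 (0.95–1.00) |
| `n_F`, `n_R` | stopping rules | 3 (2–5), 1 (1–2) |
| `t_pass_F`, `t_pass_R` | minutes per pass | 2 (1–3), 9 (6–12) |
| `t_setup` | setup minutes | simple 4 (3–5), complex 30 (20–30) |
| `c_var_o` | non-cytologist team, $/hr | simple 30 (20–40), complex 260 (190–330) |
| `c_var_c` | cytologist, $/hr | 100 (75–125) |
| `c_pat` | patient time, $/hr | 20 (15–25), societal perspective only |
| `c_np` | per-pass cost | simple 0, complex 30 (15–45) |
| `c_fixed` | per-procedure cost | simple 150 (100–200), complex 300 (150–450) |

Rate composition is a staffing rule, not plain addition.  For complex
(image-guided) procedures the fixed-protocol rate is `c_var_o` and ROSE
adds the cytologist (`c_var_o + c_var_c`).  For simple (palpation-guided)
procedures the cytologist performs the aspiration, so both protocols run
at `c_var_o + c_var_c` and ROSE adds no hourly cost; the config flag
`rose_adds_cytologist: false` expresses this, which keeps the composed
totals coherent when sensitivity analysis perturbs the components.  A
config may instead pin a protocol's pre-patient total directly
(`c_var_R_total_per_hr`, used by the `paper-prose-variant` fixture).  The
patient wage is added on top under the societal perspective and dropped
under the provider perspective.

The default analytic perspective is societal, the guideline-recommended
choice; the provider view is a flag away.

## Sensitivity analysis

One-way analysis moves each of the nine continuous parameters to the
ends of its range with everything else at base and reports the ΔTC span,
sorted descending (ties broken by parameter name) — the bars of a
tornado diagram.  The integer stopping rules are deliberately excluded:
changing `n_F` or `n_R` changes *which policies are being compared*, not
how uncertain the comparison is, and the scenario grid already
enumerates them.  The cytologist's accuracy is likewise held at base:
ΔTC depends on eleven parameters, and `sn`/`sp` enter only through the
sampling closed forms shared by every scenario.

Probabilistic sensitivity analysis draws the nine continuous parameters
independently and uniformly over their ranges — the minimal-information
choice when only ranges are stated — with the distribution family
pluggable per parameter.  The default 100,000 draws run through a
vectorized closed-form pipeline in milliseconds; a unit test pins the
vectorized route to the scalar dataclass pipeline draw by draw.

Comparative statics worth knowing when reading tornado output: ΔTC falls
as `c_fixed` rises (repeat procedures are ROSE's advantage), rises with
`t_pass_R` and `c_var_c`, and its response to `t_setup` has the sign of
`c_varᴿ·N̄_procᴿ − c_varᶠ·N̄_procᶠ` — longer setup favours ROSE only
where ROSE's fewer repeats outweigh its pricier hour (always true under
equal-rate staffing, true for complex procedures at low `p`, false at
high `p`).

## The simulator as oracle and synthetic-data generator

`rosecost.simulate` replays the process event by event — per-pass
adequacy Bernoulli draws, per-pass miscall draws, stopping, repeat
procedures — and never reuses the closed forms, so it is an independent
check on them.  The acceptance-grade test sweeps p ∈ {0.1,…,0.9},
sn, sp ∈ {0.8, 0.9, 0.95, 1.0}, n_R ∈ {1, 2}, n_F ∈ {1,…,5} at 100,000
cases per configuration and requires empirical adequacy, mean passes per
procedure and mean procedures per case to sit within four Monte Carlo
standard errors of the closed forms (exact equality where the statistic
is degenerate).  With roughly a thousand four-sigma comparisons under a
fixed seed, a single marginal exceedance has a few-percent a-priori
probability; the seed was fixed once, up front.

What the simulator emulates is exactly the model's world: constant `p`,
independent passes, a memoryless cytologist, identical repeat
procedures.  Passing tests therefore demonstrate internal consistency of
closed forms and event semantics — not that real FNAB services behave
this way.  Declining per-pass success, cytologist learning or fatigue,
correlated passes within a lesion, and failure pathways that escalate
rather than repeat are all outside what these tests can establish.

Safety caps (10,000 passes per procedure, 1,000 procedures per case)
bound degenerate parameter corners; truncation is counted and reported,
never silent, and is absent at default settings.

## Numerical choices and degenerate inputs

* Validation rejects out-of-range inputs rather than clamping: `p`, `sn`,
  `sp` must lie in (0, 1] (`p = 1` is a legitimate degenerate case — the
  no-repeat limit — and is used by the simulator's exactness tests);
  `p = 0` and a stopping rule that can never fire (`sn = 0`) are
  rejected because expected passes diverge.
* All arithmetic runs at full double precision end to end; report
  rendering rounds exactly once, at output (costs to whole units,
  passes/durations to one decimal, rates to two).  Differences are
  computed at full precision and then rounded, so a rendered difference
  can differ by one unit in the last digit from the difference of the
  rendered operands.
* Tornado ties break lexicographically by parameter name; zero-width
  ranges yield span 0 and stay in the listing (simple procedures'
  `c_np`).
* Monte Carlo draws consume the generator in a fixed parameter order, so
  a given seed is reproducible across runs and platforms; report files
  contain no timestamps and reruns are byte-identical.

## Known limitations

The two-period time model and single effective hourly rate per protocol
are deliberate simplifications; institutions with strongly time-varying
resource profiles should extend the period structure.  The model prices
one procedure type at a time and does not optimize stopping rules — it
evaluates the 32 given combinations.  Costs of downstream escalation,
faster diagnosis, and sample triage to ancillary testing (real benefits
of ROSE) are not captured, so cost comparisons here are conservative
toward ROSE.
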