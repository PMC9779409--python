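# Methods

## Governing model and assumptions

The package treats a single well-mixed air volume: the activity concentration
of every nuclide is spatially uniform, gas enters at a constant rate, nothing
leaves except by decay and by filtration of aerosol-attached progeny.  The
cascade

    dC1/dt = S1 − λ1·C1,   dCi/dt = −(R_D + λi)·Ci + εi·λi·Ci−1   (i > 1)

with `S1 = E1/V` and `R_D = F·Q_D/V` is linear with constant coefficients on
each schedule segment, so each `Cᵢ(t)` is an exact sum of exponentials.  The
implementation evaluates, per nuclide, the generic cascade solution along its
ancestry path: a homogeneous Bateman term for every ancestor's initial
concentration and a particular term for the constant source,

    Cᵢ(t) = Σⱼ C₀ⱼ·(Πₘ εₘλₘ)·Σₚ e^(−μₚt)/Πq≠p(μq−μp)
          + S1·(Πₘ εₘλₘ)·Σₚ [(1−e^(−μₚt))/μₚ]/Πq≠p(μq−μp)

with effective rates `μ1 = λ1` (the noble gas passes the filter) and
`μᵢ = λᵢ + R_D` for progeny.  The thoron chain's parallel terminus is handled
as two independent applications of the last-index formula with ε = 0.638
(Po-212) and 0.362 (Tl-208).  `(1−e^(−μt))/μ` is computed with `expm1` and
taken as `t` in the μ → 0 limit, which is exercised by the constant-parent
regime (gas decay fully compensated: λ1 replaced by 0, giving true
equilibrium even for thoron).

Excluded physics: aerosol deposition (diffusion, inertial impaction,
gravitational settling, plate-out), continuous air exchange other than the
filtering device, and dosimetric conversion of PAEC to effective dose.  If
deposition losses are material in a real chamber, simulated progeny
concentrations are upper bounds.

## Nuclear data

Half-lives follow ICRP Publication 107 (Rn-222 3.8235 d, Po-218 3.098 min,
Pb-214 26.8 min, Bi-214 19.9 min, Po-214 164.3 µs; Rn-220 55.6 s, Po-216
0.145 s, Pb-212 10.64 h, Bi-212 60.55 min, Po-212 0.299 µs, Tl-208
3.053 min) and live in one auditable CSV (`src/radonchamber/data/nuclides.csv`).
Alpha energies are principal-line values; Bi-212's entry is the
branch-weighted expectation per decay (0.362 × 6.05 MeV), so the recursive
per-atom sum `E_p` needs no branch special-casing and gives
`E_p(Pb-212) = 0.362·6.05 + 0.638·8.78486 ≈ 7.795 MeV`.  PAEC coefficients
`E_p/λ` (J/Bq) are derived at load time rather than hardcoded, so they track
any table revision.  The radon chain is truncated after Po-214 (Pb-210's
22-year half-life decouples it from chamber timescales).

## Parameters

| parameter | units | default | meaning |
|---|---|---|---|
| `V` | m³ | — | chamber volume (> 0) |
| `E1` | Bq/s | 0 | constant gas inflow |
| `Q_D` | m³/s | 0 | device flow (`with_device` accepts L/min) |
| `F` | – | 0 | filtration efficiency, 0–1 |
| `GAS_APPROACH_FRACTION` | – | 0.999 | "steady state reached" threshold for the gas (≈ 38 d radon, ≈ 9.2 min thoron) |
| `CHAIN_EQUILIBRATION_FRACTION` | – | 0.99 | equilibration threshold for progeny (≈ 3.9 h radon chain, ≈ 70.7 h Pb-212) |

The two fraction thresholds operationalize "approximately reached"; they are
module constants in `metrics`, not hardcoded into the solvers.  Internal time
is seconds and all rates s⁻¹; hours, days and L/min appear only at the
interface layer (presets, config files, CSV output).

## Singularities and numerical choices

Progeny denominators `λᵢ − λ1 + R_D` vanish for the thoron chain at the
critical flows `Q = V(λ1 − λᵢ)/F` (Pb-212, Bi-212, Tl-208; impossible for
radon, whose progeny all decay faster than the gas).  A denominator is
treated as near-singular when `|μᵢ − μⱼ| < 1e-9·max(λᵢ, λⱼ)`; inside that
band the query transparently falls back to the numerical engine instead of
using confluent (L'Hôpital) closed forms — the band is vanishingly narrow and
the fallback is exact, which keeps the kernel algebra simple.  Outside the
band, cancellation error in the paired exponentials scales like
`eps/(δ·t)` and stays below 1e-9 at the band edge for times of practical
interest; the test suite checks continuity of the closed forms into the
singular point at offsets down to 1e-7·λ1.

The reference engine integrates the same cascade two independent ways: a
matrix exponential of the source-augmented rate matrix evaluated in 40-digit
arithmetic (mpmath; double-precision scaling-and-squaring loses ~10 digits
when `‖A‖·t` reaches 10¹²), and stiff Radau integration at rtol 1e-10 with an
analytic Jacobian.  Both paths agree with each other and with the closed
forms to better than 1e-8 relative across randomized parameter sweeps; the
oracle is the authority in any disagreement.  Closed-form outputs are clipped
at zero to absorb roundoff-negative values, and the t = 0 row is returned as
the initial state exactly.

## Schedules

Segments are left-closed/right-open; a sampled time exactly on a boundary
reports the incoming segment's end state, and when the next segment carries
an instantaneous injection a second row at the same time is emitted with
`post_injection = True`, so jumps are explicit and testable.  An
"instantaneous release" is an injection into a segment with `E1 = 0`, not a
separate code path.  The default output grid is 1000 equal sub-intervals over
the total duration, which is also the cap per requested interval.  Because
segments chain exact closed forms through their end states, splitting a
segment is a bit-level no-op up to floating-point associativity (tested at
1e-10 relative).

Bundled presets pair a gas (radon or thoron), a chamber (20 or 1 m³), a
1 Bq/s inflow and a 10 L/min, 100%-efficiency device that is off, always on,
or on during a fixed window (hours 4–6 for the radon scenarios, 40–60 for
thoron).  Captions-level parameters fix everything except total duration,
which was chosen to cover the interesting dynamics: 24 h for the
continuously-filtered radon run, 12 h for the radon device-window runs
(effects decay within ~2 h of switch-off), 100 h for all thoron runs
(equilibration completes near 70 h).

## Metrics

PAEC is `Σᵢ Cᵢ·E_p,ᵢ/λᵢ` over progeny; shares are reported for every progeny
even though Po-216, Po-212 and Tl-208 carry negligible or zero coefficients —
that they can be ignored is an output of the model, not an assumption.  The
equilibrium factor divides the actual PAEC by the PAEC of a reference state
with every progeny activity equal to the gas concentration; for radon the
normalized weights are ≈ 0.105 (Po-218), 0.515 (Pb-214), 0.380 (Bi-214).
`time_to_fraction` brackets the first crossing by doubling and refines it
with Brent's method to 1e-6 relative time precision; a non-monotone approach
(possible after large injections) returns the first crossing with a warning.

## What the tests do and do not show

The randomized closed-form-versus-oracle sweeps (200 scenarios, volumes
0.1–100 m³, inflows 0.01–100 Bq/s, device flows 0–100 L/min, times 1 s–30 d)
demonstrate that the analytic kernels solve the stated cascade exactly, and
the preset-level checks reproduce the canonical chamber behaviors
(radon ≈ 38 d / thoron ≈ 9.2 min to gas steady state, radon progeny secular
equilibrium at ≈ 3.9 h, Pb-212 equilibration at ≈ 70.7 h, asymptotic PAEC
shares ≈ 91%/9% Pb-212/Bi-212, critical flows ≈ 14,900/10,400 L/min at 20 m³
and ≈ 747/521 L/min at 1 m³).  None of this validates the model against a
physical chamber: real systems add deposition losses, imperfect mixing and
source fluctuation, all outside the model's scope.

## Known limitations

- Only the two bundled sub-series; no user-defined chains.
- Piecewise-constant parameters only; continuously varying `S1(t)` or
  `R_D(t)` must be approximated by segments.
- The equilibrium factor is reported even for thoron, where the field more
  commonly works with progeny concentrations or PAEC directly.
- The oracle engines favor accuracy over speed (tens of ms per expm call);
  they are for validation and cross-checks, not production trajectories.
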