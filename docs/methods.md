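# Methods

## The equilibrium problem

A neutral-form weakly ionizable compound added in excess to pure water
defines a closed system: solid ⇌ neutral species ⇌ charged protonation
states, plus water autoprotolysis, optional strong titrant (HCl/NaOH) and
optional dissolved CO₂. All equilibria are written as cumulative formation
constants against the fully deprotonated form A (charge
z_A = max_cation_charge − n_pKa), which makes charge bookkeeping exact for
every topology from hexaprotic acids to triprotic ampholytes:

- log β_k (k = 0..n) is the sum of the k largest stepwise pKa values;
- the solid is one more "species", log β_solid = log β_k_neutral + pS0,
  with unit activity;
- for a monoprotic neutral acid this collapses to the familiar identity
  log β_solid = pKa + pS0.

Constants are stored on the concentration scale at a stated ionic-strength
basis ("constant ionic medium" convention), by default the physiological
reference I_ref = 0.15 M, and moved to any other basis through
activity-coefficient log ratios (one ratio per participating species).

## Activity model

Charged species use a three-term Stokes–Robinson hydration-theory form:

    log10 f_j = −A(T) z_j² √I / (1 + B(T) å_j √I)      (1: ion–ion)
                − h_j log10 a_w(I)                      (2: ion–solvent)
                − log10(1 − 0.018 Σ_k h_k c_k)          (3: bound water)

Term 1 is the extended Debye–Hückel contribution (A ≈ 0.509 at 25 °C,
0.523 at 37 °C, linear in T; B ≈ 0.328–0.332 Å⁻¹M^−1/2). Term 2 rewards
strongly hydrated ions as added electrolyte depresses the water activity;
a_w is estimated for a generic 1:1 electrolyte in the ideal colligative
limit, ln a_w = −0.036·I. Term 3 accounts for the free-solvent volume lost
to *all* solvation shells in the actual solution; it is identical for every
ionic solute, so it cancels exactly whenever a constant is transformed
between bases and matters only for reported single-ion coefficients. The
free-water fraction is clipped at 0.1 (with a warning) in the multi-molar
regime where the bookkeeping loses physical meaning.

Neutral dissolved species use the Setschenow form log10 f_0 = K_salt·I —
the package's deliberate modification of legacy SRHT, whose hydration terms
understate the salt effect on uncharged molecules. Consequently the
intrinsic-solubility shift between bases is exactly
pS0^I = pS0^ref + K_salt(I − I_ref), reproducing both the small salting-out
shifts of dilute suspensions (+0.02 log for acetaminophen) and the apparent
salting-*in* of L-lysine, whose suspension ionic strength exceeds 0.15 M
(shift ≈ −K_salt(I_w − I_ref) < 0). Solid phases have unit activity.

### Parameters

| parameter | default | units | why |
|---|---|---|---|
| A(T), B(T) | 0.509→0.523, 0.3283→0.3316 over 25→37 °C | —, Å⁻¹M^−1/2 | textbook water values, linear interpolation over the 20–40 °C window used |
| å(H⁺) | 7.42 | Å | calibrated once so f_H = 0.828 in 0.15 M 1:1 medium at 37 °C (conventional single-ion value); close to the classic 9 Å Kielland entry |
| å(drug ion, &#124;z&#124;=1) | 4.93 | Å | calibrated once so f = 0.769 under the same conditions; a typical mid-size organic ion |
| å per extra charge | +1.5 | Å | fitted to the multivalent pKa shifts of the packaged benzene-polycarboxylate series (rms-optimal between 1.0 and 1.5) |
| å(Na⁺/Cl⁻/OH⁻/HCO₃⁻/CO₃²⁻) | 4.0/3.0/3.5/4.0/4.5 | Å | Kielland-style values |
| h (hydration numbers) | H⁺ 7, Cl⁻ 1, Na⁺ 3.5, OH⁻ 3, drug ions 2·&#124;z&#124; | — | H⁺/Cl⁻ are the standard hydration-theory values; drug-ion defaults matter only above ~1 M and are tentative there |
| K_salt | per compound (0–0.64 M⁻¹ in the fixtures) | M⁻¹ | tabulated; `estimate_k_salt` serves fixture values and otherwise instructs the caller to supply one (a structure-based predictor is out of scope) |
| pKw(T) | 4470.99/T − 6.0875 + 0.01706·T (T in K) | log units | Harned–Owen-type fit: 13.997 (25 °C), 13.62 (37 °C) |
| carbonate pK₁/pK₂ | 6.35 / 10.33 (25 °C, I→0) | log units | textbook; transformed to the local basis like every other constant |

The two calibrated ion sizes are the only fitted scalars in the package;
they were fixed against the two conventional single-ion coefficients above
and never revisited. With them, the model independently reproduces the
dilute-limit coefficient 0.997 at ~6 µM, the high-salt coefficients at
0.5 M HCl, and the ionic-strength dependence of the lysine pKa₂ at 0.7 M.

## Solver

Inner problem: at fixed ionic strength the charge-balance residual
Q(p_cH) = [H⁺] − [OH⁻] + [Na⁺] − [Cl⁻] + Σ z_k[AH_k] − (CO₂ anions) is
strictly decreasing in p_cH and is bracketed on [−2, 16], solved by Brent's
method to machine tolerance (converged states carry charge residuals below
1e−10·max(I, 1e−7) and mass balance exact to construction).

Saturated branch: the neutral-species concentration is pinned at S0^I and
every other state follows from the cumulative constants. If the implied
dissolved total exceeds the amount added (×(1+1e−12)), the problem is
re-solved without solid, distributing the added amount over the
protonation states. Both branches are exercised by the packaged
acetaminophen pair (25 mg/mL saturated vs 20 mg/mL subsaturated).

Outer problem: the ionic strength implied by the solved speciation feeds a
damped fixed point, I_{n+1} = 0.5·I_n + 0.5·I_new, tolerance
1e−9 M absolute + 1e−6 relative, at most 200 iterations — the damping is
what keeps the multi-molar lysine/mellitic systems from oscillating.
Non-convergence raises `ConvergenceError` carrying the last state.

Inverse problem (measured S_w → S_0): instead of pinning S0, the dissolved
*total* is pinned at S_w; the same charge balance is solved, S0^I is read
off the solved speciation, and the reference-basis value follows from the
Setschenow shift (exact in this model). A synthetic round trip (forward
S_w from a known pS0, then inversion) recovers pS0 to better than 1e−6 over
hundreds of random compounds.

Counter-ion bookkeeping: titrant contributes Na⁺ or Cl⁻ to both balances;
the drug carries no counter-ions (free acid/base added — drug salts are out
of scope). Volume is constant (molarity basis, no density/molality
correction); states with more than 0.5 M total added carry a flag noting
the approximation. A consequence worth stating plainly: at constant volume
with unit solid activity, the equilibrium cannot depend on the amount of
*excess* solid, so the two packaged excess variants of mellitic acid and
lysine solve identically; resolving their small tabulated differences would
require the density/molality treatment that is explicitly out of scope.

## Profile generation

The log S–pH curve is generated on a uniform p_cH grid (default 0–13,
step 0.05). The charge balance is linear in the titrant amount, so at a
fixed target pH the required titrant is obtained in closed form inside the
usual ionic-strength fixed point; forward re-solving the suspension with
that titrant reproduces the target pH within the fixed-point tolerance
(~1e−7 pH), which guarantees every grid point lies on a physically
realizable constant-volume titration path. Points needing more than 20 M
of titrant are omitted with a warning; points where the solid is exhausted
are marked unsaturated and excluded from the solubility curve. Buffer
capacity is the centered difference d(base titrant)/d(pH) on adjacent grid
points (one-sided at the edges, with a warning).

The Henderson–Hasselbalch reference curve uses the I_ref-basis constants
with no activity corrections; with corrections disabled the simulated
profile equals it to 1e−9 over the grid (a test asserts this), so every
deviation between the two curves is attributable to the activity model.

## Closed-form cross-checks

Explicit saturation-pH expressions are carried solely as oracles:
monoprotic acid [H]² = K_a·S0 + K_w, monoprotic base
[OH]² = K_w(1 + S0/K_a), and the diprotic cubics in [H⁺]
(h³ − (K₁S0 + K_w)h − 2K₁K₂S0 = 0 for acids, and its base analogue). A
separate brute-force grid scan over p_cH shares only the
constant-transformation rules with the production solver. Corrections-off,
the three routes agree to ≤1e−5 pH across random mono-/diprotic compounds.

## The fixture table and the random-compound generator

The packaged table transcribes the 32 published compound records (16
acids, 10 bases, 6 ampholytes; mellitic acid and L-lysine in two
excess-solid variants, plus the terfenadine CO₂ example) with their
measured log S_w, harmonized pKa sets, temperatures, and salting-out
constants, and — as regression anchors — the published pH_w, log S0 and
I_w analyses. Molecular weights are package-supplied constants, each
cross-checked against the published (log S_w, mg/mL) pair to ~0.01 log
units. Two records (brigatinib, imatinib) carry an `uncertain_topology`
flag: their maximum cationic charge is not published and was assigned as
fully basic (+4), the only topology consistent with their tabulated pH_w
lying above every pKa. Where the published table resolves a quantity
inconsistently with its own constants (a handful of pH_w cells), the
regression tests widen their band by exactly the internal inconsistency,
measured at run time from the published constants themselves. Terfenadine's
unpublished K_salt is set to 0.40 M⁻¹, the tabulated average for bases.

`generate_random_compound` draws property-test inputs: ascending pKa in
[1, 12] with ≥0.3 spacing, pS0 in [−1, 8], K_salt in [0, 0.7] M⁻¹ (the
span of the tabulated per-class averages), topology fixed by class. These
synthetic compounds exercise the solver across regimes (including ones no
real drug occupies); they do not emulate measurement noise, impurities,
aggregation, or electrode artefacts, so passing property tests demonstrate
internal consistency of the equilibrium model, not robustness to real
assay error.

## Numerical choices and degenerate inputs

- p_cH bracket [−2, 16]; Brent tolerance at machine precision.
- Unionizable limit (pKa far outside 0–14): the inverse problem returns
  S_0 = S_w and the pure-water pH, with no special casing.
- Pure water (nothing added): charge balance gives p_cH = ½pKw when
  corrections are off.
- The p_aH ↔ p_cH conversion (operational to concentration scale) is the
  arithmetic p_cH = p_aH + log10 f_H + junction term, with the junction
  term an optional input (its measurement is out of scope).
- Problem sizes: property sweeps use 500+ random compounds; each
  suspension solve costs milliseconds, a full 261-point profile well under
  a second, so the whole suite and the acceptance script run in minutes.

## Known limitations

- No molality↔molarity/density correction: results above ~0.5 M total
  added (lysine, mellitic acid) inherit the constant-volume approximation,
  and excess-solid amounts cannot influence the equilibrium.
- Hydration numbers for drug ions are tentative defaults (2·|z|); they
  only matter above ~1 M, precisely where the model is least certain.
- Salting-out constants must be supplied; the structure-based estimator is
  not implemented.
- Drug salts, aggregation, complexation, cocrystals, disproportionation,
  buffered media and mixed solvents are out of scope; the
  Henderson–Hasselbalch assumption is taken as valid throughout.
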