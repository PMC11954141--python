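# puresol

Turn a *single* measured water solubility of a weakly ionizable drug into a
physiologically referenced solubility–pH profile.

When a neutral-form acid, base, or ampholyte is equilibrated with pure
water, the measured solubility S_w is generally **not** the intrinsic
solubility S_0: the dissolving drug shifts the suspension to its own
saturation pH (pH_w), partially ionizes, and — for soluble or polyprotic
compounds — raises the ionic strength I_w well above the near-zero value
naively assumed. Meanwhile the pKa values used to interpret the measurement
are usually referenced to the physiological ionic strength I_ref = 0.15 M.
`puresol` closes that gap for solubility and physchem profiling work:

1. **pH_w** — solves the full mass-action / charge-balance system of the
   saturated suspension, iterating the ionic strength to self-consistency;
2. **S_0** — extracts the intrinsic solubility at both the suspension ionic
   strength (S_0^I) and on the 0.15 M reference basis (S_0^ref);
3. **log S–pH profile** — forward-simulates a constant-volume HCl/NaOH
   titration from pH_w across pH 0–13 ("analytic continuation"),
   re-transforming every equilibrium constant to the local ionic strength
   at each point, alongside the ideal Henderson–Hasselbalch reference curve.

## Model

Equilibria are held in cumulative form against the fully deprotonated
species A (charge z_A = max cation charge − n):

    A + k H⁺ ⇌ AH_k           log β_k = Σ of the k largest pKa
    A + k_n H⁺ ⇌ AH_kn (s)    log β_s = log β_kn + pS0

Constants move between ionic-strength bases by activity-coefficient log
ratios, log β^I = log β^ref + Δlog f_A + k·Δlog f_H − Δlog f_AHk, with a
three-term Stokes–Robinson hydration-theory (SRHT) model for ions

    log f_j = −A(T) z_j² √I / (1 + B(T) å_j √I)   (ion–ion)
              − h_j log a_w(I)                     (ion–solvent)
              − log(1 − 0.018 Σ h_k c_k)           (bound water)

and the Setschenow salting-out form log f_0 = K_salt·I for neutral
species (solids have unit activity). The Henderson–Hasselbalch relation
S(pH) = S_0 (1 + Σ cumulative ionization ratios) is assumed valid — no
aggregation, salt precipitation, or complexation. Because the bound-water
term is a property of the solution (not the basis), it cancels in every
constant transformation; it appears only in reported single-ion
coefficients. See `docs/methods.md` for parameter values and rationale.

## Worked example

Glibenclamide: the only inputs are the published water solubility
(log S_w = −4.18 at 37 °C), the pKa 5.18 referenced to 0.15 M, and the
salting-out constant 0.41 M⁻¹ — all carried by the built-in fixture table:

```
$ puresol derive --fixture glibenclamide
Glibenclamide: pH_w = 4.86  log S0_ref = -4.34  log S0_I = -4.28  I_w = 0.01372 mM
```

The suspension settles 0.3 pH units *below* the pKa (the dissolving acid
overwhelms water's buffering), the suspension ionic strength is a mere
14 µM, and the intrinsic solubility harmonized to 0.15 M is 0.06 log units
*below* the measured S_w — the combined ionization and salting-out
correction a naive S_w ≈ S_0 reading would miss.

Transforming a constant set by hand — acetaminophen's pKa and solid
constant from the 0.15 M basis to its 6.6 µM suspension:

```
$ puresol transform --pka 9.41 --ps0 0.87 --from 0.15 --to 6.6e-6 --ksalt 0.117 --temp 37
pKa at I = 6.6e-06 M: 9.632
log beta_solid = 10.484  pS0 = 0.852
```

The acid weakens by 0.22 log units at near-zero salt, and the local
intrinsic solubility (10^−0.852 ≈ 140 mM) sits 0.02 above the reference
value. A full profile:

```
$ puresol profile --fixture glibenclamide --out glibenclamide.csv
Glibenclamide: pH_w = 4.86, 261 profile points
```

writes pH, local log S, the HH reference curve, local ionic strength,
buffer capacity, and titrant amount per grid point as CSV. In Python the
same objects are available directly:

```python
from puresol import SuspensionSpec, get_fixture, derive_intrinsic_from_sw

ps0_i, ps0_ref, ph_w, i_w = derive_intrinsic_from_sw(get_fixture("crocetin"))
# (6.996, 7.053, 5.561, 3.78e-06): a 20-fold S_w/S0 gap for this diacid
```

The 32-compound fixture table (`puresol fixtures`) carries the published
measurements used as regression anchors, including the high-ionic-strength
stress cases (mellitic acid, L-lysine) and the CO₂-impurity example
(terfenadine, where 10 µM of dissolved CO₂ moves the apparent log S_0 of a
poorly soluble base by half a log unit).

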