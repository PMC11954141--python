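"""Built-in compound table: 16 acids, 10 bases, 6 ampholytes.

Each record carries the published log S_w (molarity), the stepwise pKa set
harmonized to I_ref = 0.15 M at the measurement temperature, the salting-out
constant, and — under ``expected`` — the tabulated analysis results
(pH_w, log S0 on the reference and suspension bases, suspension ionic
strength in mM, and the pKa set transformed to the suspension ionic
strength) used as regression anchors by the test suite.

Molecular weights are implementation-supplied constants (g/mol); each is
cross-checked against the published (log S_w, mg/mL) pair.  Mellitic acid
and L-lysine appear in two excess-solid variants differing only in
``total_added``.  ``uncertain_topology`` flags compounds whose maximum
cationic charge had to be assigned from the compound class and pKa count
(brigatinib, imatinib: 4 pKa treated as 4 basic sites, the assignment that
reproduces their tabulated pH_w, which lies above every pKa).
"""

from __future__ import annotations

from .io import CompoundSpec

__all__ = ["builtin_fixture_table", "get_fixture"]

# name, class, pKa_ref, max_cat, T, log_Sw, mg/mL, MW, K_salt, expected
_ROWS = [
    # --- weak acids -------------------------------------------------------
    ("Crocetin", "acid", (4.47, 5.00), 0, 23, -5.74, 0.0006, 328.40, 0.38,
     dict(pH_w=5.56, logS0_ref=-7.04, logS0_I=-6.99, I_mM=0.004,
          pKa_I=(4.71, 5.35))),
    ("Isotretinoin", "acid", (4.52,), 0, 25, -4.77, 0.005, 300.44, 0.46,
     dict(pH_w=5.02, logS0_ref=-5.26, logS0_I=-5.19, I_mM=0.011,
          pKa_I=(4.76,))),
    ("Quercetin", "acid", (7.12, 8.43, 9.67, 10.63), 0, 23, -4.07, 0.026,
     302.24, 0.11,
     dict(pH_w=6.07, logS0_ref=-4.11, logS0_I=-4.09, I_mM=0.004,
          pKa_I=(7.31, 8.80, None, None))),
    ("Indomethacin", "acid", (4.02,), 0, 37, -4.14, 0.026, 357.79, 0.34,
     dict(pH_w=4.39, logS0_ref=-4.55, logS0_I=-4.50, I_mM=0.046,
          pKa_I=(4.24,))),
    ("Glibenclamide", "acid", (5.18,), 0, 37, -4.18, 0.033, 494.00, 0.41,
     dict(pH_w=4.81, logS0_ref=-4.33, logS0_I=-4.26, I_mM=0.017,
          pKa_I=(5.40,))),
    ("Phenytoin", "acid", (8.14,), 0, 37, -3.65, 0.056, 252.27, 0.25,
     dict(pH_w=5.14, logS0_ref=-3.69, logS0_I=-3.66, I_mM=0.005,
          pKa_I=(8.36,))),
    ("Naproxen", "acid", (4.19,), 0, 37, -3.38, 0.097, 230.26, 0.27,
     dict(pH_w=4.00, logS0_ref=-3.55, logS0_I=-3.51, I_mM=0.112,
          pKa_I=(4.40,))),
    ("Acetaminophen", "acid", (9.41,), 0, 37, -0.85, 21.0, 151.16, 0.12,
     dict(pH_w=5.06, logS0_ref=-0.87, logS0_I=-0.85, I_mM=0.010,
          pKa_I=(9.62,))),
    ("Benzoic acid", "acid", (3.99,), 0, 25, -1.55, 3.5, 122.12, 0.15,
     dict(pH_w=2.92, logS0_ref=-1.59, logS0_I=-1.57, I_mM=1.4,
          pKa_I=(4.17,))),
    ("2-Phthalic acid", "acid", (2.71, 4.90), 0, 25, -1.36, 7.3, 166.13, 0.11,
     dict(pH_w=2.20, logS0_ref=-1.46, logS0_I=-1.44, I_mM=7.6,
          pKa_I=(2.85, 5.14))),
    ("Trimellitic acid", "acid", (2.34, 3.71, 5.10), 0, 25, -1.00, 21.0,
     210.14, 0.08,
     dict(pH_w=1.82, logS0_ref=-1.10, logS0_I=-1.09, I_mM=19,
          pKa_I=(2.43, 3.89, 5.39))),
    ("Hemimellitic acid", "acid", (2.60, 3.78, 5.45), 0, 25, -0.62, 51.0,
     210.14, 0.08,
     dict(pH_w=1.73, logS0_ref=-0.67, logS0_I=-0.66, I_mM=23,
          pKa_I=(2.69, 3.95, 5.71))),
    ("Pyromellitic acid", "acid", (1.86, 2.74, 4.28, 5.33), 0, 25, -1.37,
     11.0, 254.15, 0.04,
     dict(pH_w=1.79, logS0_ref=-1.61, logS0_I=-1.61, I_mM=20,
          pKa_I=(1.94, 2.90, 4.54, 5.69))),
    ("Mellophanic acid", "acid", (2.00, 3.11, 4.51, 5.91), 0, 25, 0.02,
     264.0, 254.15, 0.04,
     dict(pH_w=1.14, logS0_ref=-0.02, logS0_I=-0.02, I_mM=102,
          pKa_I=(2.01, 3.15, 4.57, 5.99))),
    ("Benzenepentacarboxylic acid", "acid", (1.74, 2.60, 3.76, 4.97, 6.10),
     0, 25, -0.05, 271.0, 298.16, 0.00,
     dict(pH_w=1.06, logS0_ref=-0.11, logS0_I=-0.11, I_mM=128,
          pKa_I=(1.75, 2.61, 3.78, 5.00, 6.14))),
    ("Mellitic acid (10-fold excess)", "acid",
     (1.10, 1.69, 2.75, 4.00, 5.05, 6.04), 0, 25, 0.45, 988.0, 342.17, -0.04,
     dict(pH_w=0.40, logS0_ref=0.32, logS0_I=0.33, I_mM=381,
          pKa_I=(1.09, 1.63, 2.64, 3.85, 4.83, 5.77)),
     dict(total_added_g_per_mL=9.5)),
    ("Mellitic acid (2-fold excess)", "acid",
     (1.10, 1.69, 2.75, 4.00, 5.05, 6.04), 0, 25, 0.45, 988.0, 342.17, -0.04,
     dict(pH_w=0.36, logS0_ref=0.36, logS0_I=0.37, I_mM=485,
          pKa_I=(1.09, 1.62, 2.62, 3.80, 4.77, 5.69)),
     dict(total_added_g_per_mL=1.9)),
    # --- weak bases -------------------------------------------------------
    ("Atenolol", "base", (9.19,), 1, 37, -1.09, 22.0, 266.34, 0.24,
     dict(pH_w=10.82, logS0_ref=-1.13, logS0_I=-1.09, I_mM=1.7,
          pKa_I=(9.14,))),
    ("Bedaquiline", "base", (8.77,), 1, 23, -5.62, 0.0013, 555.50, 0.58,
     dict(pH_w=8.32, logS0_ref=-6.25, logS0_I=-6.16, I_mM=0.002,
          pKa_I=(8.68,))),
    ("Brigatinib", "base", (1.73, 3.65, 4.72, 8.04), 4, 23, -1.73, 11.0,
     584.10, 0.58,
     dict(pH_w=10.16, logS0_ref=-1.82, logS0_I=-1.73, I_mM=0.12,
          pKa_I=(1.27, 3.35, 4.57, 7.95)), dict(uncertain_topology=True)),
    ("Carvedilol", "base", (7.78,), 1, 37, -4.10, 0.032, 406.47, 0.37,
     dict(pH_w=8.62, logS0_ref=-4.21, logS0_I=-4.16, I_mM=0.009,
          pKa_I=(7.72,))),
    ("Emtricitibine", "base", (2.67,), 1, 25, -0.38, 104.0, 247.25, 0.14,
     dict(pH_w=8.15, logS0_ref=-0.40, logS0_I=-0.38, I_mM=0.001,
          pKa_I=(2.63,))),
    ("Imatinib", "base", (1.71, 3.10, 3.88, 8.03), 4, 23, -4.69, 0.010,
     493.60, 0.46,
     dict(pH_w=8.65, logS0_ref=-4.85, logS0_I=-4.78, I_mM=0.004,
          pKa_I=(1.19, 2.76, 3.71, 7.96)), dict(uncertain_topology=True)),
    ("Imiquimod", "base", (3.55, 6.54), 2, 25, -4.60, 0.0061, 240.30, 0.28,
     dict(pH_w=7.97, logS0_ref=-4.65, logS0_I=-4.61, I_mM=0.001,
          pKa_I=(3.33, 6.48))),
    ("Ketoconazole", "base", (3.32, 6.17), 2, 37, -4.82, 0.0080, 531.43, 0.50,
     dict(pH_w=7.48, logS0_ref=-4.92, logS0_I=-4.84, I_mM=0.001,
          pKa_I=(3.16, 6.09))),
    ("Lamotrigine", "base", (5.24,), 1, 37, -2.87, 0.34, 256.09, 0.22,
     dict(pH_w=8.01, logS0_ref=-2.91, logS0_I=-2.88, I_mM=0.002,
          pKa_I=(5.19,))),
    ("Lumefanatrine", "base", (9.35,), 1, 23, -5.28, 0.0028, 528.94, 0.64,
     dict(pH_w=8.71, logS0_ref=-6.05, logS0_I=-5.96, I_mM=0.004,
          pKa_I=(9.25,))),
    # --- ampholytes -------------------------------------------------------
    ("Celecoxib", "ampholyte", (2.11, 9.37), 1, 37, -5.10, 0.003, 381.37,
     0.34,
     dict(pH_w=6.71, logS0_ref=-5.16, logS0_I=-5.11, I_mM=0.0002,
          pKa_I=(2.05, 9.59))),
    ("Enrofloxacin", "ampholyte", (6.17, 7.70), 1, 37, -3.08, 0.30, 359.39,
     0.31,
     dict(pH_w=7.04, logS0_ref=-3.22, logS0_I=-3.18, I_mM=0.090,
          pKa_I=(6.11, 7.91))),
    ("Lysine, L- (2-fold excess)", "ampholyte", (2.20, 9.12, 10.64), 2, 27,
     0.60, 585.0, 146.19, 0.10,
     dict(pH_w=10.01, logS0_ref=0.53, logS0_I=0.47, I_mM=695,
          pKa_I=(2.36, 9.24, None)), dict(total_added_g_per_mL=1.2)),
    ("Lysine, L- (1.1-fold excess)", "ampholyte", (2.20, 9.12, 10.64), 2, 27,
     0.60, 585.0, 146.19, 0.10,
     dict(pH_w=9.98, logS0_ref=0.50, logS0_I=0.45, I_mM=612,
          pKa_I=(2.34, 9.22, None)), dict(total_added_g_per_mL=0.6)),
    ("Mycophenolate mofetil", "ampholyte", (5.64, 8.26), 1, 37, -2.93, 0.51,
     433.49, 0.51,
     dict(pH_w=7.06, logS0_ref=-3.03, logS0_I=-2.96, I_mM=0.038,
          pKa_I=(5.56, 8.50))),
    ("Piroxicam", "ampholyte", (1.84, 5.13), 1, 37, -4.02, 0.032, 331.35,
     0.20,
     dict(pH_w=4.77, logS0_ref=-4.14, logS0_I=-4.11, I_mM=0.019,
          pKa_I=(1.80, 5.33))),
    ("Sulfamethoxazole", "ampholyte", (1.97, 5.65), 1, 37, -3.36, 0.11,
     253.28, 0.20,
     dict(pH_w=4.68, logS0_ref=-3.42, logS0_I=-3.39, I_mM=0.024,
          pKa_I=(1.92, 5.86))),
    # CO2-impurity worked example; K_salt not published, set to the stated
    # average for bases (0.40 1/M); reported log S0 for 0/10 uM CO2.
    ("Terfenadine", "base", (9.77,), 1, 25, -4.87, 0.0064, 471.67, 0.40,
     dict(logS0_co2=[(0.0, -5.7), (10e-6, -6.3)], pH_w_co2=[(0.0, 9.2),
          (10e-6, 8.5)])),
]

_TABLE: tuple | None = None


def builtin_fixture_table() -> tuple:
    """All built-in compounds as an immutable tuple of CompoundSpec."""
    global _TABLE
    if _TABLE is None:
        out = []
        for row in _ROWS:
            name, klass, pka, maxcat, T, logsw, mg, mw, ks, expected = row[:10]
            extra = row[10] if len(row) > 10 else {}
            out.append(CompoundSpec(
                name=name, compound_class=klass, pKa_ref=pka,
                max_cation_charge=maxcat, T=float(T), log_Sw=float(logsw),
                Sw_mg_per_mL=None, MW=float(mw), k_salt=float(ks),
                expected={**expected, "Sw_mg_per_mL": float(mg)}, **extra))
        _TABLE = tuple(out)
    return _TABLE


def get_fixture(name: str) -> CompoundSpec:
    """Look up a built-in compound by (case-insensitive, partial) name."""
    key = name.strip().lower()
    table = builtin_fixture_table()
    for spec in table:
        if spec.name.lower() == key:
            return spec
    matches = [s for s in table if key in s.name.lower()]
    if len(matches) == 1:
        return matches[0]
    if len(matches) > 1:
        # prefer the first (10-/2-fold excess ordering follows the tables)
        exact_base = [s for s in matches if s.name.lower().startswith(key)]
        if exact_base:
            return exact_base[0]
        return matches[0]
    raise KeyError(f"no fixture compound matching {name!r}")
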