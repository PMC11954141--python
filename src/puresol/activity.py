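"""Activity coefficients for charged and neutral solutes.

Charged species are treated with a three-term Stokes-Robinson hydration-theory
(SRHT) model:

    log10 f_j = -A(T) z_j^2 sqrt(I) / (1 + B(T) a_j sqrt(I))   (ion-ion)
                - h_j log10 a_w(I)                             (ion-solvent)
                - log10 (1 - 0.018 SUM_k h_k c_k)              (bound water)

The first term is the extended Debye-Hueckel electrostatic contribution with a
per-species ion-size parameter ``a_j`` (angstrom).  The second term accounts
for the water sequestered into the solvation shell of the ion itself (h_j
water molecules withdrawn per ion): as the water activity a_w drops with
added electrolyte, a strongly hydrated ion is stabilised and its activity
coefficient rises.  The third term converts for the loss of free solvent
volume to *all* hydration shells in the actual solution; it is a property of
the solution composition, identical for every charged solute in it, and
therefore cancels whenever a constant is transformed between two ionic-
strength bases (see :mod:`puresol.constants`).

Neutral (uncharged, dissolved) species use the Setschenow salting-out form
``log10 f_0 = K_salt * I`` instead of the hydration terms; solid phases have
unit activity by convention.

The water activity entering the second term is estimated for a generic 1:1
electrolyte at the stated ionic strength from the ideal colligative limit,
``ln a_w = -0.018 * 2I``.

Ion-size defaults: the model has two free parameters with no literature
consensus for drug-like ions - the ion size of H3O+ and of a generic singly
charged drug ion.  They are fixed once (A_H = 7.42 A, A_DRUG = 4.93 A) so
that the model reproduces the conventional single-ion coefficients
f_H = 0.828 and f_(-1) = 0.769 in a 0.15 M 1:1 medium at 37 C; multivalent
drug ions grow by 1.5 A per unit charge, in line with Kielland-style tables
for polyvalent organic ions.  Hydration numbers default to h = 7 (H+),
1 (Cl-), 3.5 (Na+), 3 (OH-) and 2|z| for drug ions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

__all__ = [
    "SpeciesDescriptor",
    "ActivityContext",
    "debye_huckel_slope",
    "debye_huckel_b",
    "debye_huckel_log_f",
    "log10_water_activity",
    "basis_log_f",
    "bound_water_log_term",
    "srht_log_f",
    "neutral_log_f",
    "estimate_k_salt",
    "default_hydration_number",
    "default_ion_size",
    "species_for_ion",
    "HYDRATION_NUMBERS",
    "ION_SIZES",
]

# Debye-Hueckel limiting slope of water, log10 basis, and the denominator
# coefficient B (A^-1 M^-1/2); linear in T over the 20-40 C window used here.
_A_25, _A_37 = 0.509, 0.523
_B_25, _B_37 = 0.3283, 0.3316

# Calibrated ion-size parameters (angstrom); see module docstring.
A_H = 7.42
A_DRUG = 4.93
A_DRUG_PER_CHARGE = 1.5

# -log10 a_w per molar ionic strength for a generic 1:1 electrolyte
# (ideal colligative limit: ln a_w = -0.018 * 2 I).
_LOG10_AW_PER_I = 0.018 * 2.0 / math.log(10.0)

#: Hydration numbers (waters sequestered per ion) for the inorganic
#: background species; drug ions default to 2|z|.
HYDRATION_NUMBERS = {"H": 7.0, "OH": 3.0, "Na": 3.5, "Cl": 1.0,
                     "HCO3": 2.0, "CO3": 4.0}

#: Ion-size parameters (angstrom) for the background species.
ION_SIZES = {"H": A_H, "OH": 3.5, "Na": 4.0, "Cl": 3.0,
             "HCO3": 4.0, "CO3": 4.5}


def default_hydration_number(label: str, z: int) -> float:
    """Default hydration number: tabulated background ions, else 2|z|."""
    return HYDRATION_NUMBERS.get(label, 2.0 * abs(z))


def default_ion_size(label: str, z: int) -> float:
    """Default ion-size parameter in angstrom."""
    if label in ION_SIZES:
        return ION_SIZES[label]
    if z == 0:
        return 0.0
    return A_DRUG + A_DRUG_PER_CHARGE * (abs(z) - 1)


@dataclass(frozen=True)
class SpeciesDescriptor:
    """One dissolved or solid species.

    Parameters
    ----------
    label : str
        Species name ("H", "OH", "Cl", "XH2+", ...).
    z : int
        Signed charge.
    h : float
        Hydration number (waters sequestered in the solvation shell), >= 0.
    k_salt : float
        Setschenow salting-out constant, 1/M; used only when ``z == 0``.
    is_solid : bool
        Solid phases have unit activity at every ionic strength.
    ion_size : float
        Debye-Hueckel ion-size parameter, angstrom.
    """

    label: str
    z: int = 0
    h: float | None = None
    k_salt: float = 0.0
    is_solid: bool = False
    ion_size: float | None = None

    def __post_init__(self):
        if self.h is None:
            object.__setattr__(self, "h",
                               default_hydration_number(self.label, self.z))
        if self.ion_size is None:
            object.__setattr__(self, "ion_size",
                               default_ion_size(self.label, self.z))
        if self.h < 0:
            raise ValueError(f"hydration number must be >= 0, got {self.h}")
        if abs(self.z) > 6:
            raise ValueError(f"|z| <= 6 supported, got z={self.z}")


@dataclass(frozen=True)
class ActivityContext:
    """Temperature / ionic-strength context for activity evaluation.

    ``corrections_enabled=False`` forces every activity coefficient to
    exactly one (the ideal Henderson-Hasselbalch limit).
    """

    temperature: float = 25.0          # degrees C
    ionic_strength: float = 0.0        # M
    reference_ionic_strength: float = 0.15  # M
    corrections_enabled: bool = True

    def __post_init__(self):
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be >= 0")
        if self.reference_ionic_strength <= 0:
            raise ValueError("reference ionic strength must be > 0")

    def at(self, ionic_strength: float) -> "ActivityContext":
        return replace(self, ionic_strength=ionic_strength)


def debye_huckel_slope(temperature: float) -> float:
    """Debye-Hueckel limiting slope A(T) of water (log10 basis)."""
    return _A_25 + (_A_37 - _A_25) * (temperature - 25.0) / 12.0


def debye_huckel_b(temperature: float) -> float:
    """Debye-Hueckel denominator coefficient B(T), A^-1 M^-1/2."""
    return _B_25 + (_B_37 - _B_25) * (temperature - 25.0) / 12.0


def debye_huckel_log_f(z: int, ctx: ActivityContext,
                       ion_size: float = A_DRUG) -> float:
    """Electrostatic (ion-ion) term of log10 f for a species of charge z.

    Scales exactly with z^2 at fixed ion size; 0 for neutral species and in
    the infinite-dilution limit.
    """
    if ctx.ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    if z == 0 or ctx.ionic_strength == 0 or not ctx.corrections_enabled:
        return 0.0
    sqrt_i = math.sqrt(ctx.ionic_strength)
    a = debye_huckel_slope(ctx.temperature)
    b = debye_huckel_b(ctx.temperature)
    return -a * z * z * sqrt_i / (1.0 + b * ion_size * sqrt_i)


def log10_water_activity(ionic_strength: float) -> float:
    """log10 a_w of a generic 1:1 electrolyte at ionic strength I."""
    return -_LOG10_AW_PER_I * ionic_strength


def basis_log_f(species: SpeciesDescriptor, ctx: ActivityContext) -> float:
    """Basis part of log10 f: electrostatic + single-ion hydration terms.

    This is the part of the SRHT model that depends on the ionic-strength
    basis; the solution-composition (bound-water) term is excluded because it
    cancels in every transformation between bases.  Neutral species return
    the Setschenow term; solids return 0.
    """
    if not ctx.corrections_enabled or species.is_solid:
        return 0.0
    if species.z == 0:
        return neutral_log_f(species.k_salt, ctx.ionic_strength)
    elec = debye_huckel_log_f(species.z, ctx, species.ion_size)
    hydration = -species.h * log10_water_activity(ctx.ionic_strength)
    return elec + hydration

# Missing hydration numbers only matter above ~1 M; warn once per label.
_warned_h: set[str] = set()


def bound_water_log_term(solution: list[tuple[SpeciesDescriptor, float]],
                         ctx: ActivityContext | None = None) -> float:
    """Free-water volume-fraction term, -log10(1 - 0.018 SUM h_k c_k).

    ``solution`` lists the charged species actually present with their
    molarities.  Shared by every ionic solute in the solution; clipped at a
    free-water fraction of 0.1 (with a warning) in the multi-molar regime
    where the hydration bookkeeping loses meaning.
    """
    if ctx is not None and not ctx.corrections_enabled:
        return 0.0
    bound = 0.018 * sum(sp.h * c for sp, c in solution
                        if sp.z != 0 and not sp.is_solid and c > 0)
    free = 1.0 - bound
    if free < 0.1:
        warnings.warn("free-water fraction clipped at 0.1 (multi-molar "
                      "ionic strength); bound-water term is unreliable here")
        free = 0.1
    return -math.log10(free)


def srht_log_f(species: SpeciesDescriptor,
               solution: list[tuple[SpeciesDescriptor, float]],
               ctx: ActivityContext) -> float:
    """Full SRHT log10 activity coefficient of one species in a solution.

    Charged species: electrostatic + hydration + bound-water terms.  Neutral
    non-solid species: Setschenow salting-out.  Solids: 0.
    """
    if not ctx.corrections_enabled or species.is_solid:
        return 0.0
    if species.z == 0:
        return neutral_log_f(species.k_salt, ctx.ionic_strength)
    if species.h == 0 and ctx.ionic_strength > 1.0:
        if species.label not in _warned_h:
            _warned_h.add(species.label)
            warnings.warn(
                f"species {species.label!r} has no hydration number at "
                f"I > 1 M; falling back to h = {2 * abs(species.z)}")
        species = replace(species, h=float(2 * abs(species.z)))
    return basis_log_f(species, ctx) + bound_water_log_term(solution, ctx)


def neutral_log_f(k_salt: float, ionic_strength: float) -> float:
    """Setschenow form for a neutral solute: log10 f = K_salt * I."""
    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    return k_salt * ionic_strength


def estimate_k_salt(name: str | None = None, *,
                    descriptors: dict | None = None) -> float:
    """Salting-out constant for a compound, 1/M.

    The structure-based predictor requires molecular descriptors that are not
    part of this package; compounds from the built-in fixture table are
    served from their tabulated constants, anything else raises with
    instructions to supply ``K_salt`` directly.
    """
    if descriptors is not None:
        raise ValueError(
            "descriptor-based salting-out prediction is not implemented; "
            "supply K_salt directly (fixture compounds carry tabulated values)")
    if name is not None:
        from .fixtures import builtin_fixture_table
        key = name.strip().lower()
        for spec in builtin_fixture_table():
            if spec.name.lower() == key or key in spec.name.lower():
                return spec.k_salt
    raise ValueError(
        "no tabulated salting-out constant for this compound; supply K_salt")


def species_for_ion(label: str, z: int, k_salt: float = 0.0) -> SpeciesDescriptor:
    """Convenience constructor with the package defaults filled in."""
    return SpeciesDescriptor(label=label, z=z, k_salt=k_salt)
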