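"""Cumulative mass-action constants and their ionic-strength transformation.

All drug equilibria are written in cumulative form against a single base
component A, the fully deprotonated form of the compound:

    A + k H  <->  A H_k          log beta_k  (k = 0..n, beta_0 = 0)
    A + k_n H <->  A H_kn (s)    log beta_solid

where n is the number of ionizable protons and k_n is the proton count of
the *neutral* species (n - max_cation_charge).  With that bookkeeping the
charge of species k is exact: z_k = z_A + k, z_A = max_cation_charge - n.
For a monoprotic neutral acid the identity log beta_solid = pKa + pS0 holds.

Transformation between ionic-strength bases follows the activity-coefficient
log-ratio rule: for a cumulative constant whose formation reaction is
A + kH -> X,

    log beta^I = log beta^ref + dlog f_A + k dlog f_H - dlog f_X,

with dlog f the basis part of the SRHT model for ions (the shared
bound-water term cancels), the Setschenow term K_salt*(I - I_ref) for
neutral species, and zero for the solid.  The intrinsic solubility follows
as pS0 = log beta_solid - log beta_{k_n}, which reduces to the Setschenow
shift pS0^I = pS0^ref + K_salt (I - I_ref) at low ionic strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .activity import (ActivityContext, SpeciesDescriptor, basis_log_f,
                       neutral_log_f, species_for_ion)

__all__ = [
    "SpeciesStoichiometry",
    "ConstantSet",
    "build_constant_set",
    "transform_constant_set",
    "water_pkw",
    "pah_to_pch",
    "pch_to_pah",
    "CARBONATE_PK1",
    "CARBONATE_PK2",
]

# Carbonate impurity constants at 25 C, I -> 0 (textbook values); transformed
# like every other constant before use.
CARBONATE_PK1 = 6.35
CARBONATE_PK2 = 10.33


@dataclass(frozen=True)
class SpeciesStoichiometry:
    """Formation stoichiometry of one species from the base components."""

    reactant_counts: dict  # {"A": 1, "H": k}
    product_label: str
    product_charge: int

    def __post_init__(self):
        z_a = self.reactant_counts.get("_zA", 0)
        z = z_a * self.reactant_counts.get("A", 0) + self.reactant_counts.get("H", 0)
        if "_zA" in self.reactant_counts and z != self.product_charge:
            raise ValueError("charge bookkeeping violated: "
                             f"{z} != {self.product_charge}")


@dataclass(frozen=True)
class ConstantSet:
    """Cumulative constants of one compound at a stated ionic strength."""

    ionic_strength_basis: float          # M
    temperature: float                   # C
    pKa_values: tuple                    # stepwise, ascending
    max_cation_charge: int
    log_beta: tuple                      # cumulative, k = 0..n
    log_beta_solid: float
    pS0: float                           # -log10 S_0, molarity
    pKw: float                           # concentration-scale, this basis
    k_salt: float = 0.0                  # 1/M, neutral drug species
    impurity_constants: tuple | None = None  # (pK1, pK2) carbonate, this basis

    @property
    def n_protons(self) -> int:
        return len(self.pKa_values)

    @property
    def z_base(self) -> int:
        """Charge of the fully deprotonated base component A."""
        return self.max_cation_charge - self.n_protons

    @property
    def k_neutral(self) -> int:
        """Proton count (relative to A) of the neutral species."""
        return -self.z_base

    def species_charge(self, k: int) -> int:
        return self.z_base + k

    def drug_species(self) -> list[SpeciesDescriptor]:
        """Descriptors for every dissolved protonation state, k = 0..n."""
        out = []
        for k in range(self.n_protons + 1):
            z = self.species_charge(k)
            out.append(SpeciesDescriptor(label=f"XH{k}", z=z,
                                         k_salt=self.k_salt if z == 0 else 0.0))
        return out


def build_constant_set(pKa_ref, pS0_ref: float, max_cation_charge: int,
                       T: float, *, I_ref: float = 0.15,
                       k_salt: float = 0.0,
                       with_carbonate: bool = False,
                       corrections: bool = True) -> ConstantSet:
    """Assemble the cumulative constant set on the reference basis.

    ``pKa_ref`` is the ascending stepwise list at I_ref; cumulative
    log beta_k sums the k *largest* pKa values (protonation proceeds from the
    most basic site).  The solid-formation constant adds pS0 onto the
    cumulative constant of the neutral state.
    """
    pKa = tuple(float(p) for p in pKa_ref)
    if len(pKa) == 0:
        raise ValueError("pKa list must be nonempty")
    if any(b <= a for a, b in zip(pKa, pKa[1:])):
        raise ValueError("pKa values must be strictly increasing")
    if not (0 <= max_cation_charge <= len(pKa)):
        raise ValueError("0 <= max_cation_charge <= n_pka required")
    if not math.isfinite(pS0_ref):
        raise ValueError("pS0 must be finite")
    log_beta = [0.0]
    for k in range(1, len(pKa) + 1):
        log_beta.append(log_beta[-1] + pKa[len(pKa) - k])
    k_neutral = len(pKa) - max_cation_charge
    log_beta_solid = log_beta[k_neutral] + pS0_ref
    pkw0 = water_pkw(T)
    if corrections:
        h_ion = species_for_ion("H", 1)
        oh_ion = species_for_ion("OH", -1)
        ctx_ref = ActivityContext(temperature=T, ionic_strength=I_ref)
        ctx_0 = ActivityContext(temperature=T, ionic_strength=0.0)
        # anchor the concentration-scale ion product at the reference basis
        pkw_ref = pkw0 \
            + (basis_log_f(h_ion, ctx_ref) - basis_log_f(h_ion, ctx_0)) \
            + (basis_log_f(oh_ion, ctx_ref) - basis_log_f(oh_ion, ctx_0))
    else:
        pkw_ref = pkw0
    impurity = None
    if with_carbonate:
        impurity = _carbonate_at_basis(I_ref, T, corrections)
    return ConstantSet(
        ionic_strength_basis=I_ref, temperature=T, pKa_values=pKa,
        max_cation_charge=max_cation_charge, log_beta=tuple(log_beta),
        log_beta_solid=log_beta_solid, pS0=pS0_ref, pKw=pkw_ref,
        k_salt=k_salt, impurity_constants=impurity)


def _dlog_f(sp: SpeciesDescriptor, i_from: float, i_to: float,
            T: float, corrections: bool = True) -> float:
    """Basis-part log f change of one species between two ionic strengths."""
    if not corrections or sp.is_solid:
        return 0.0
    if sp.z == 0:
        return neutral_log_f(sp.k_salt, i_to) - neutral_log_f(sp.k_salt, i_from)
    c_to = ActivityContext(temperature=T, ionic_strength=i_to)
    c_from = ActivityContext(temperature=T, ionic_strength=i_from)
    return basis_log_f(sp, c_to) - basis_log_f(sp, c_from)


def _carbonate_at_basis(I: float, T: float,
                        corrections: bool = True) -> tuple:
    """Carbonate pK1/pK2 transformed from the I->0, 25 C anchor."""
    h = species_for_ion("H", 1)
    hco3 = species_for_ion("HCO3", -1)
    co3 = species_for_ion("CO3", -2)
    # dissociation form: pK^I = pK^0 - dlogf(products) + dlogf(reactant)
    d_h = _dlog_f(h, 0.0, I, T, corrections)
    d_hco3 = _dlog_f(hco3, 0.0, I, T, corrections)
    d_co3 = _dlog_f(co3, 0.0, I, T, corrections)
    pk1 = CARBONATE_PK1 + d_h + d_hco3            # H2CO3 (neutral) -> H + HCO3
    pk2 = CARBONATE_PK2 + d_h + d_co3 - d_hco3    # HCO3 -> H + CO3
    return (pk1, pk2)


def transform_constant_set(cs: ConstantSet, target_I: float,
                           ctx: ActivityContext | None = None,
                           species: list | None = None) -> ConstantSet:
    """Transform every constant to a new ionic-strength basis.

    Exact identity at ``target_I == cs.ionic_strength_basis``; invertible to
    machine precision.  ``species`` may override the default drug-species
    descriptors; ``ctx.corrections_enabled=False`` returns the set unchanged
    apart from the recorded basis.
    """
    if target_I < 0:
        raise ValueError("target ionic strength must be >= 0")
    T = cs.temperature
    corrections = True if ctx is None else ctx.corrections_enabled
    i_from = cs.ionic_strength_basis
    sp = species if species is not None else cs.drug_species()
    h_ion = species_for_ion("H", 1)
    oh_ion = species_for_ion("OH", -1)
    d_a = _dlog_f(sp[0], i_from, target_I, T, corrections)
    d_h = _dlog_f(h_ion, i_from, target_I, T, corrections)
    new_beta = []
    for k in range(cs.n_protons + 1):
        d_x = _dlog_f(sp[k], i_from, target_I, T, corrections)
        new_beta.append(cs.log_beta[k] + d_a + k * d_h - d_x)
    kn = cs.k_neutral
    new_solid = cs.log_beta_solid + d_a + kn * d_h  # f(solid) = 1
    new_ps0 = new_solid - new_beta[kn]
    new_pka = tuple(new_beta[k] - new_beta[k - 1]
                    for k in range(cs.n_protons, 0, -1))
    new_pkw = cs.pKw + _dlog_f(h_ion, i_from, target_I, T, corrections) \
                     + _dlog_f(oh_ion, i_from, target_I, T, corrections)
    impurity = cs.impurity_constants
    if impurity is not None:
        impurity = _carbonate_at_basis(target_I, T, corrections)
    return replace(cs, ionic_strength_basis=target_I,
                   pKa_values=tuple(sorted(new_pka)), log_beta=tuple(new_beta),
                   log_beta_solid=new_solid, pS0=new_ps0, pKw=new_pkw,
                   impurity_constants=impurity)


def water_pkw(T: float) -> float:
    """-log10 Kw of pure water at T (C), infinite-dilution activity scale.

    Harned-Owen-type correlation; 13.997 at 25 C, 13.62 at 37 C.
    """
    if not (0.0 < T < 100.0):
        raise ValueError("temperature must be in (0, 100) C")
    tk = T + 273.15
    return 4470.99 / tk - 6.0875 + 0.017060 * tk


def pah_to_pch(p_ah: float, ctx: ActivityContext,
               junction_term: float = 0.0,
               solution: list | None = None) -> float:
    """Operational (activity-scale) pH to concentration-scale p_cH.

    p_cH = p_aH + log10 f_H + junction_term, with f_H the full SRHT
    coefficient of H+ at the context ionic strength.
    """
    from .activity import srht_log_f
    h_ion = species_for_ion("H", 1)
    log_fh = srht_log_f(h_ion, solution if solution is not None else
                        _reference_medium(ctx.ionic_strength), ctx)
    return p_ah + log_fh + junction_term


def pch_to_pah(p_ch: float, ctx: ActivityContext,
               junction_term: float = 0.0,
               solution: list | None = None) -> float:
    """Inverse of :func:`pah_to_pch` (exact round trip)."""
    from .activity import srht_log_f
    h_ion = species_for_ion("H", 1)
    log_fh = srht_log_f(h_ion, solution if solution is not None else
                        _reference_medium(ctx.ionic_strength), ctx)
    return p_ch - log_fh - junction_term


def _reference_medium(I: float) -> list:
    """Generic 1:1 (Na,Cl) medium of ionic strength I."""
    return [(species_for_ion("Na", 1), I), (species_for_ion("Cl", -1), I)]
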