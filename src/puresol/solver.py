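"""Coupled mass/charge-balance solver for single-compound suspensions.

The equilibrium problem: a neutral-form compound added to pure water (plus
optional HCl/NaOH titrant and dissolved CO2) establishes a pH and ionic
strength of its own making.  For a given ionic strength I the constants are
transformed to the local basis and the charge balance

    [H+] - [OH-] + [Na+] - [Cl-] + SUM_k z_k [XH_k] + (CO2 charges) = 0

is solved for p_cH by bracketed root finding (the residual is strictly
decreasing in p_cH).  When solid is present the neutral-species
concentration is pinned at S0^I and every other protonation state follows
from the cumulative constants; when the implied dissolved total exceeds the
amount added, the problem is re-solved without solid (mass balance on the
dissolved total instead).  The ionic strength implied by the solved
speciation feeds a damped fixed-point outer iteration
(I_{n+1} = (1-l) I_n + l I_new, l = 0.5) until self-consistency.

The inverse problem (``derive_intrinsic_from_sw``) pins the *dissolved
total* at the measured S_w instead of pinning S0, solves the same charge
balance, and reads the intrinsic solubility off the solved speciation —
reporting it both at the suspension ionic strength and re-expressed on the
0.15 M reference basis.

Closed-form saturation-pH expressions for mono- and diprotic compounds and
a brute-force grid oracle are provided as independent cross-checks; the
production path never uses them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .activity import ActivityContext, species_for_ion, srht_log_f
from .constants import (ConstantSet, build_constant_set,
                        transform_constant_set, water_pkw)
from .io import CompoundSpec

logger = logging.getLogger("puresol")

__all__ = [
    "SuspensionSpec",
    "SuspensionState",
    "solve_suspension",
    "derive_intrinsic_from_sw",
    "co2_adjusted_intrinsic",
    "closed_form_monoprotic_phw",
    "diprotic_phw_cubic",
    "grid_search_oracle",
    "ConvergenceError",
]

_I_DAMP = 0.5
_I_TOL_ABS = 1e-9
_I_TOL_REL = 1e-6
_I_MAX_ITER = 200
_PCH_LO, _PCH_HI = -2.0, 16.0


class ConvergenceError(RuntimeError):
    """Raised when the ionic-strength fixed point fails; carries last state."""

    def __init__(self, message, state=None):
        super().__init__(message)
        self.state = state


@dataclass(frozen=True)
class SuspensionSpec:
    """One suspension (or solution) problem.

    ``titrant_added`` is mol/L of HCl (negative means NaOH).  ``total_added``
    overrides the compound's own amount; if neither is given, twice the
    measured solubility is assumed (enough to saturate, dilute regime).
    """

    compound: CompoundSpec
    total_added: float | None = None   # M
    titrant_added: float = 0.0         # M HCl; < 0 means NaOH
    co2_total: float = 0.0             # M

    def __post_init__(self):
        if self.co2_total < 0:
            raise ValueError("co2_total must be >= 0")

    @property
    def c_tot(self) -> float:
        if self.total_added is not None:
            return self.total_added
        ta = self.compound.total_added_molar
        if ta is not None:
            return ta
        sw = self.compound.sw_molar
        if sw is not None:
            return 2.0 * sw
        return 0.0


@dataclass(frozen=True)
class SuspensionState:
    """Self-consistent equilibrium of one suspension."""

    p_cH: float
    p_aH: float
    species_concentrations: dict
    activity_coefficients: dict
    ionic_strength: float
    solid_remaining: float
    saturated: bool
    iterations: int
    converged: bool
    dissolved_total: float
    pS0_local: float
    constants: ConstantSet
    charge_residual: float = 0.0
    volume_warning: bool = False

    @property
    def pH(self) -> float:
        return self.p_cH


def _ref_constants(compound: CompoundSpec, ctx: ActivityContext,
                   pS0_ref: float | None = None,
                   with_carbonate: bool = False) -> ConstantSet:
    ps0 = pS0_ref if pS0_ref is not None else compound.pS0_ref
    if ps0 is None:
        raise ValueError(
            f"{compound.name}: pS0_ref unknown; run derive_intrinsic_from_sw "
            "on the measured S_w first")
    return build_constant_set(compound.pKa_ref, ps0,
                              compound.max_cation_charge, ctx.temperature,
                              I_ref=ctx.reference_ionic_strength,
                              k_salt=compound.k_salt,
                              with_carbonate=with_carbonate,
                              corrections=ctx.corrections_enabled)


def _drug_ratios(cs: ConstantSet, pch: float):
    """Concentration of each protonation state relative to the neutral one."""
    kn = cs.k_neutral
    lb = cs.log_beta
    return np.array([10.0 ** (lb[k] - lb[kn] - (k - kn) * pch)
                     for k in range(cs.n_protons + 1)])


def _drug_fractions(cs: ConstantSet, pch: float):
    """Mole fraction of each protonation state among dissolved drug."""
    lb = np.array(cs.log_beta)
    k = np.arange(cs.n_protons + 1)
    ex = lb - k * pch
    ex -= ex.max()
    w = 10.0 ** ex
    return w / w.sum()


def _carbonate_charges(cs: ConstantSet, pch: float, co2_total: float):
    """(net negative charge, per-species concentrations) of total CO2."""
    if co2_total <= 0 or cs.impurity_constants is None:
        return 0.0, {}
    pk1, pk2 = cs.impurity_constants
    r1 = 10.0 ** (pch - pk1)
    r2 = r1 * 10.0 ** (pch - pk2)
    denom = 1.0 + r1 + r2
    c_h2co3 = co2_total / denom
    c_hco3 = c_h2co3 * r1
    c_co3 = c_h2co3 * r2
    return c_hco3 + 2.0 * c_co3, {"H2CO3": c_h2co3, "HCO3": c_hco3,
                                  "CO3": c_co3}


def _charge_residual(pch: float, cs: ConstantSet, spec: SuspensionSpec,
                     saturated: bool, sw_pin: float | None = None):
    """Charge-balance residual; strictly decreasing in p_cH."""
    h = 10.0 ** (-pch)
    oh = 10.0 ** (pch - cs.pKw)
    na = max(0.0, -spec.titrant_added)
    cl = max(0.0, spec.titrant_added)
    z = np.array([cs.species_charge(k) for k in range(cs.n_protons + 1)])
    if sw_pin is not None:
        ratios = _drug_ratios(cs, pch)
        s0 = sw_pin / ratios.sum()
        conc = s0 * ratios
    elif saturated:
        s0 = 10.0 ** (-cs.pS0)
        conc = s0 * _drug_ratios(cs, pch)
    elif spec.c_tot > 0:
        conc = spec.c_tot * _drug_fractions(cs, pch)
    else:
        conc = np.zeros(cs.n_protons + 1)
    co2_neg, _ = _carbonate_charges(cs, pch, spec.co2_total)
    return h - oh + na - cl + float((z * conc).sum()) - co2_neg


def _solve_pch(cs: ConstantSet, spec: SuspensionSpec, saturated: bool,
               sw_pin: float | None = None) -> float:
    fn = lambda pch: _charge_residual(pch, cs, spec, saturated, sw_pin)
    lo, hi = _PCH_LO, _PCH_HI
    flo, fhi = fn(lo), fn(hi)
    if flo < 0 or fhi > 0:
        raise ConvergenceError(
            "charge balance has no root in the p_cH bracket; the inputs "
            "(S_w, pKa, titrant) are mutually inconsistent")
    return brentq(fn, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)


def _ionic_strength(cs: ConstantSet, spec: SuspensionSpec, pch: float,
                    saturated: bool, sw_pin: float | None = None) -> float:
    h = 10.0 ** (-pch)
    oh = 10.0 ** (pch - cs.pKw)
    na = max(0.0, -spec.titrant_added)
    cl = max(0.0, spec.titrant_added)
    z = np.array([cs.species_charge(k) for k in range(cs.n_protons + 1)])
    if sw_pin is not None:
        ratios = _drug_ratios(cs, pch)
        conc = (sw_pin / ratios.sum()) * ratios
    elif saturated:
        conc = 10.0 ** (-cs.pS0) * _drug_ratios(cs, pch)
    elif spec.c_tot > 0:
        conc = spec.c_tot * _drug_fractions(cs, pch)
    else:
        conc = np.zeros(cs.n_protons + 1)
    _, carb = _carbonate_charges(cs, pch, spec.co2_total)
    i = h + oh + na + cl + float(((z ** 2) * conc).sum())
    i += carb.get("HCO3", 0.0) + 4.0 * carb.get("CO3", 0.0)
    return 0.5 * i


def _iterate_ionic_strength(cs_ref: ConstantSet, spec: SuspensionSpec,
                            ctx: ActivityContext, saturated: bool,
                            sw_pin: float | None = None):
    """Damped fixed point on I around the inner p_cH solve."""
    i_local = 0.0
    cs = cs_ref
    pch = None
    for it in range(1, _I_MAX_ITER + 1):
        cs = transform_constant_set(cs_ref, i_local, ctx)
        pch = _solve_pch(cs, spec, saturated, sw_pin)
        i_new = _ionic_strength(cs, spec, pch, saturated, sw_pin)
        logger.debug("outer %d: I=%.6g -> %.6g, p_cH=%.6f",
                     it, i_local, i_new, pch)
        if abs(i_new - i_local) <= _I_TOL_ABS + _I_TOL_REL * i_new:
            cs = transform_constant_set(cs_ref, i_new, ctx)
            pch = _solve_pch(cs, spec, saturated, sw_pin)
            return cs, pch, i_new, it, True
        i_local = (1.0 - _I_DAMP) * i_local + _I_DAMP * i_new
    return cs, pch, i_local, _I_MAX_ITER, False


def _assemble_state(cs: ConstantSet, spec: SuspensionSpec,
                    ctx: ActivityContext, pch: float, i_local: float,
                    saturated: bool, iters: int, converged: bool,
                    sw_pin: float | None = None) -> SuspensionState:
    kn = cs.k_neutral
    if sw_pin is not None:
        ratios = _drug_ratios(cs, pch)
        conc = (sw_pin / ratios.sum()) * ratios
    elif saturated:
        conc = 10.0 ** (-cs.pS0) * _drug_ratios(cs, pch)
    elif spec.c_tot > 0:
        conc = spec.c_tot * _drug_fractions(cs, pch)
    else:
        conc = np.zeros(cs.n_protons + 1)
    dissolved = float(conc.sum())
    local_ctx = replace(ctx, ionic_strength=i_local)
    h_sp = species_for_ion("H", 1)
    oh_sp = species_for_ion("OH", -1)
    conc_map = {"H": 10.0 ** (-pch), "OH": 10.0 ** (pch - cs.pKw)}
    if spec.titrant_added > 0:
        conc_map["Cl"] = spec.titrant_added
    elif spec.titrant_added < 0:
        conc_map["Na"] = -spec.titrant_added
    drug_species = cs.drug_species()
    for k, sp in enumerate(drug_species):
        conc_map[sp.label] = float(conc[k])
    _, carb = _carbonate_charges(cs, pch, spec.co2_total)
    conc_map.update(carb)
    sol = []
    all_species = {"H": h_sp, "OH": oh_sp,
                   "Na": species_for_ion("Na", 1),
                   "Cl": species_for_ion("Cl", -1),
                   "HCO3": species_for_ion("HCO3", -1),
                   "CO3": species_for_ion("CO3", -2),
                   "H2CO3": species_for_ion("H2CO3", 0)}
    all_species.update({sp.label: sp for sp in drug_species})
    for label, c in conc_map.items():
        if label in all_species and all_species[label].z != 0:
            sol.append((all_species[label], c))
    fmap = {label: 10.0 ** srht_log_f(all_species[label], sol, local_ctx)
            for label in conc_map if label in all_species}
    solid = max(0.0, spec.c_tot - dissolved) if saturated else 0.0
    residual = _charge_residual(pch, cs, spec, saturated, sw_pin)
    log_fh = math.log10(fmap.get("H", 1.0)) if fmap.get("H") else 0.0
    return SuspensionState(
        p_cH=pch, p_aH=pch - log_fh, species_concentrations=conc_map,
        activity_coefficients=fmap, ionic_strength=i_local,
        solid_remaining=solid, saturated=saturated, iterations=iters,
        converged=converged, dissolved_total=dissolved, pS0_local=cs.pS0,
        constants=cs, charge_residual=residual,
        volume_warning=spec.c_tot > 0.5)


def solve_suspension(spec: SuspensionSpec,
                     ctx: ActivityContext | None = None) -> SuspensionState:
    """Solve a suspension to self-consistency in p_cH and ionic strength.

    Tries the saturated branch first (solid present, neutral species pinned
    at S0^I); if the implied dissolved total exceeds the amount added, the
    unsaturated problem (free dissolved total = C_tot) is solved instead.
    """
    compound = spec.compound
    ctx = ctx or ActivityContext(temperature=compound.T)
    if ctx.temperature != compound.T:
        ctx = replace(ctx, temperature=compound.T)
    c_tot = spec.c_tot
    if c_tot == 0:
        # no compound: pure water (+ titrant/CO2) solved unsaturated
        cs_ref = _ref_constants(compound, ctx, pS0_ref=compound.pS0_ref or 0.0,
                                with_carbonate=spec.co2_total > 0)
        cs, pch, i_local, iters, ok = _iterate_ionic_strength(
            cs_ref, spec, ctx, saturated=False)
        if not ok:
            raise ConvergenceError("ionic-strength iteration did not converge")
        return _assemble_state(cs, spec, ctx, pch, i_local, False, iters, True)
    cs_ref = _ref_constants(compound, ctx,
                            with_carbonate=spec.co2_total > 0)
    cs, pch, i_local, iters, ok = _iterate_ionic_strength(
        cs_ref, spec, ctx, saturated=True)
    if not ok:
        raise ConvergenceError(
            "ionic-strength iteration did not converge",
            state=_assemble_state(cs, spec, ctx, pch, i_local, True,
                                  iters, False))
    state = _assemble_state(cs, spec, ctx, pch, i_local, True, iters, True)
    if state.dissolved_total > c_tot * (1.0 + 1e-12):
        logger.debug("saturated solve exceeds C_tot (%.4g > %.4g); "
                     "re-solving unsaturated", state.dissolved_total, c_tot)
        cs, pch, i_local, iters, ok = _iterate_ionic_strength(
            cs_ref, spec, ctx, saturated=False)
        if not ok:
            raise ConvergenceError(
                "ionic-strength iteration did not converge (unsaturated)",
                state=_assemble_state(cs, spec, ctx, pch, i_local, False,
                                      iters, False))
        state = _assemble_state(cs, spec, ctx, pch, i_local, False,
                                iters, True)
    logger.info("%s: p_cH=%.4f I=%.4g M %s (%d outer iterations)",
                compound.name, state.p_cH, state.ionic_strength,
                "saturated" if state.saturated else "unsaturated",
                state.iterations)
    return state


def derive_intrinsic_from_sw(compound: CompoundSpec,
                             ctx: ActivityContext | None = None,
                             co2_total: float = 0.0):
    """Intrinsic solubility and saturation pH from a measured S_w.

    Returns ``(pS0_I, pS0_ref, pH_w, I_w)``: the intrinsic solubility at the
    suspension ionic strength and on the reference basis, the saturation
    p_cH, and the suspension ionic strength.  The full solved state is
    available via :func:`derive_intrinsic_state`.
    """
    state = derive_intrinsic_state(compound, ctx, co2_total)
    i_ref = (ctx.reference_ionic_strength if ctx is not None else 0.15)
    ps0_i = state.pS0_local
    if ctx is not None and not ctx.corrections_enabled:
        ps0_ref = ps0_i
    else:
        ps0_ref = ps0_i - compound.k_salt * (state.ionic_strength - i_ref)
    return ps0_i, ps0_ref, state.p_cH, state.ionic_strength


def derive_intrinsic_state(compound: CompoundSpec,
                           ctx: ActivityContext | None = None,
                           co2_total: float = 0.0) -> SuspensionState:
    """Full solved state of the inverse (S_w pinned) problem."""
    ctx = ctx or ActivityContext(temperature=compound.T)
    if ctx.temperature != compound.T:
        ctx = replace(ctx, temperature=compound.T)
    sw = compound.sw_molar
    if sw is None:
        raise ValueError(f"{compound.name}: measured S_w required")
    # pS0 placeholder 0: the inverse solve pins dissolved total, the solved
    # speciation then fixes pS0 at the local basis
    cs_ref = build_constant_set(compound.pKa_ref, 0.0,
                                compound.max_cation_charge, ctx.temperature,
                                I_ref=ctx.reference_ionic_strength,
                                k_salt=compound.k_salt,
                                with_carbonate=co2_total > 0,
                                corrections=ctx.corrections_enabled)
    spec = SuspensionSpec(compound=compound, total_added=sw,
                          co2_total=co2_total)
    cs, pch, i_local, iters, ok = _iterate_ionic_strength(
        cs_ref, spec, ctx, saturated=True, sw_pin=sw)
    if not ok:
        raise ConvergenceError("inverse problem did not converge")
    ratios = _drug_ratios(cs, pch)
    s0_local = sw / float(ratios.sum())
    ps0_local = -math.log10(s0_local)
    # rebuild the constant set carrying the solved pS0 (local basis)
    cs = replace(cs, pS0=ps0_local,
                 log_beta_solid=cs.log_beta[cs.k_neutral] + ps0_local)
    state = _assemble_state(cs, spec, ctx, pch, i_local, True, iters, True,
                            sw_pin=sw)
    return state


def co2_adjusted_intrinsic(compound: CompoundSpec, co2_total: float,
                           ctx: ActivityContext | None = None):
    """Inverse problem with dissolved CO2 in the balances.

    Returns ``(pH_w, log_S0_ref)``; identical to
    :func:`derive_intrinsic_from_sw` at ``co2_total = 0``.
    """
    ps0_i, ps0_ref, ph_w, i_w = derive_intrinsic_from_sw(
        compound, ctx, co2_total=co2_total)
    return ph_w, -ps0_ref


def closed_form_monoprotic_phw(pKa: float, pS0: float, pKw: float,
                               kind: str = "acid") -> float:
    """Explicit saturation pH of a monoprotic compound, corrections off.

    Acid:  [H]^2 = Ka S0 + Kw.   Base:  [OH]^2 = Kw (1 + S0/Ka).
    """
    ka = 10.0 ** (-pKa)
    s0 = 10.0 ** (-pS0)
    kw = 10.0 ** (-pKw)
    if kind == "acid":
        return -0.5 * math.log10(ka * s0 + kw)
    if kind == "base":
        oh = math.sqrt(kw * (1.0 + s0 / ka))
        return pKw + math.log10(oh)
    raise ValueError("kind must be 'acid' or 'base'")


def diprotic_phw_cubic(pKa1: float, pKa2: float, pS0: float, pKw: float,
                       kind: str = "acid") -> float:
    """Saturation pH of a diprotic compound from the cubic in [H+].

    Acid (H2A solid): h^3 - (K1 S0 + Kw) h - 2 K1 K2 S0 = 0.
    Base (B solid):   (2 S0/(Ka1 Ka2)) h^3 + (1 + S0/Ka2) h^2 - Kw = 0,
    with Ka the conjugate-acid constants (Ka1 < Ka2 numerically as pKa).
    """
    if not pKa1 < pKa2:
        raise ValueError("pKa1 < pKa2 required")
    s0 = 10.0 ** (-pS0)
    kw = 10.0 ** (-pKw)
    if kind == "acid":
        k1 = 10.0 ** (-pKa1)
        k2 = 10.0 ** (-pKa2)
        coeffs = [1.0, 0.0, -(k1 * s0 + kw), -2.0 * k1 * k2 * s0]
    elif kind == "base":
        ka1 = 10.0 ** (-pKa1)
        ka2 = 10.0 ** (-pKa2)
        coeffs = [2.0 * s0 / (ka1 * ka2), 1.0 + s0 / ka2, 0.0, -kw]
    else:
        raise ValueError("kind must be 'acid' or 'base'")
    roots = np.roots(coeffs)
    real = [r.real for r in roots if abs(r.imag) < 1e-12 * max(1.0, abs(r))
            and r.real > 0]
    if not real:
        raise ValueError("no physically admissible root")
    return -math.log10(min(real) if kind == "base" else max(real))


def grid_search_oracle(spec: SuspensionSpec, ctx: ActivityContext | None = None,
                       grid_step: float = 1e-3) -> SuspensionState:
    """Brute-force saturation solve: scan p_cH, refine by bisection.

    Shares only the constant-transformation rules with the production path;
    the root location itself is a plain scan + bisection.  Test use only.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    compound = spec.compound
    ctx = ctx or ActivityContext(temperature=compound.T)
    if ctx.temperature != compound.T:
        ctx = replace(ctx, temperature=compound.T)
    cs_ref = _ref_constants(compound, ctx,
                            with_carbonate=spec.co2_total > 0)

    def inner(cs, saturated):
        grid = np.arange(-1.0, 15.0 + grid_step, grid_step)
        vals = [_charge_residual(p, cs, spec, saturated) for p in grid]
        idx = None
        for i in range(len(grid) - 1):
            if vals[i] >= 0 >= vals[i + 1]:
                idx = i
                break
        if idx is None:
            raise ConvergenceError("grid oracle found no sign change")
        lo, hi = grid[idx], grid[idx + 1]
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if _charge_residual(mid, cs, spec, saturated) >= 0:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-14:
                break
        return 0.5 * (lo + hi)

    saturated = True
    i_local = 0.0
    for it in range(1, _I_MAX_ITER + 1):
        cs = transform_constant_set(cs_ref, i_local, ctx)
        pch = inner(cs, saturated)
        i_new = _ionic_strength(cs, spec, pch, saturated)
        if abs(i_new - i_local) <= _I_TOL_ABS + _I_TOL_REL * i_new:
            break
        i_local = (1.0 - _I_DAMP) * i_local + _I_DAMP * i_new
    else:
        raise ConvergenceError("grid oracle did not converge")
    state = _assemble_state(cs, spec, ctx, pch, i_new, True, it, True)
    if state.dissolved_total > spec.c_tot * (1.0 + 1e-12):
        saturated = False
        i_local = 0.0
        for it in range(1, _I_MAX_ITER + 1):
            cs = transform_constant_set(cs_ref, i_local, ctx)
            pch = inner(cs, saturated)
            i_new = _ionic_strength(cs, spec, pch, saturated)
            if abs(i_new - i_local) <= _I_TOL_ABS + _I_TOL_REL * i_new:
                break
            i_local = (1.0 - _I_DAMP) * i_local + _I_DAMP * i_new
        state = _assemble_state(cs, spec, ctx, pch, i_new, False, it, True)
    return state
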