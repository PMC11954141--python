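"""log S-pH profiles by simulated titration ("analytic continuation").

Starting from the solved saturation point pH_w, the full solubility-pH
curve is generated by locating, for each target pH on a grid, the amount of
strong titrant (HCl downwards, NaOH upwards; constant volume) whose solved
suspension lands on that pH.  Because the charge balance is linear in the
titrant amount, the titrant at a fixed p_cH is obtained in closed form
inside the usual ionic-strength fixed-point loop; re-solving the suspension
forward with that titrant reproduces the target pH exactly, so the path is
a physically realizable titration.  At every point all equilibrium
constants are re-transformed to the local ionic strength, so the curve
carries the activity distortions that the ideal Henderson-Hasselbalch (HH)
reference curve — evaluated with the I_ref-basis constants and no
corrections — does not.  Points where the solid is exhausted are marked
unsaturated and excluded from the log S curve (solubility is defined only
at saturation).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .activity import ActivityContext
from .constants import build_constant_set, transform_constant_set
from .io import CompoundSpec
from .solver import (SuspensionSpec, SuspensionState, solve_suspension,
                     ConvergenceError, _carbonate_charges, _drug_ratios,
                     _drug_fractions, _ref_constants, _I_DAMP, _I_TOL_ABS,
                     _I_TOL_REL, _I_MAX_ITER)

logger = logging.getLogger("puresol")

__all__ = [
    "ProfilePoint",
    "SolubilityProfile",
    "analytic_continuation_profile",
    "hh_reference_curve",
    "salting_shift",
    "buffer_capacity",
]

_TITRANT_MAX = 20.0  # mol/L; beyond this a grid pH is deemed unreachable


@dataclass(frozen=True)
class ProfilePoint:
    pH: float                    # p_cH
    log_S_local: float           # log10 M, activity-corrected at local I
    log_S_hh_ref: float          # ideal HH curve at I_ref constants
    I_local: float               # M
    pKa_local: tuple             # transformed to I_local
    buffer_capacity: float       # mol/(L*pH)
    titrant_added: float         # M HCl (<0: NaOH)
    saturated: bool = True


@dataclass(frozen=True)
class SolubilityProfile:
    points: tuple
    compound: CompoundSpec
    pH_w: float
    I_w: float

    def as_arrays(self):
        p = self.points
        return {k: np.array([getattr(pt, k) for pt in p])
                for k in ("pH", "log_S_local", "log_S_hh_ref", "I_local",
                          "buffer_capacity", "titrant_added", "saturated")}


def hh_reference_curve(pKa_ref, pS0_ref: float, max_cation_charge: int, pH):
    """Ideal Henderson-Hasselbalch log10 S at the reference constants.

    Multiprotic generalization S(pH) = S0 (1 + SUM of cumulative ionization
    ratios); reduces to S = S0 (1 + 10^(pH - pKa)) for a monoprotic acid.
    """
    cs = build_constant_set(pKa_ref, pS0_ref, max_cation_charge, 25.0)
    kn = cs.k_neutral
    lb = np.array(cs.log_beta)
    k = np.arange(cs.n_protons + 1)
    scalar = np.ndim(pH) == 0
    ph = np.atleast_1d(np.asarray(pH, dtype=float))
    ex = (lb - lb[kn])[:, None] - np.outer(k - kn, ph)
    out = -pS0_ref + np.log10((10.0 ** ex).sum(axis=0))
    return float(out[0]) if scalar else out


def salting_shift(pS0_I: float, k_salt: float, I_w: float,
                  I_ref: float = 0.15) -> float:
    """Re-express pS0 from the suspension basis on the reference basis.

    pS0_ref = pS0_I - K_salt (I_w - I_ref); the sign flips naturally when
    I_w exceeds I_ref (the lysine salting-in appearance).
    """
    return pS0_I - k_salt * (I_w - I_ref)


def _point_at_ph(cs_ref, compound, c_tot, co2, target_pch, ctx):
    """Titrant and speciation that land the suspension on a target p_cH.

    Charge balance is linear in titrant: t(HCl) = +residual-without-titrant.
    Iterates ionic strength to self-consistency like the forward solver.
    Returns (titrant, dissolved_total, I, constants, saturated) or None if
    the required titrant is unphysical.
    """
    i_local = 0.0
    for _ in range(_I_MAX_ITER):
        cs = transform_constant_set(cs_ref, i_local, ctx)
        h = 10.0 ** (-target_pch)
        oh = 10.0 ** (target_pch - cs.pKw)
        z = np.array([cs.species_charge(k) for k in range(cs.n_protons + 1)])
        saturated = True
        conc = 10.0 ** (-cs.pS0) * _drug_ratios(cs, target_pch)
        if conc.sum() > c_tot * (1.0 + 1e-12):
            saturated = False
            conc = c_tot * _drug_fractions(cs, target_pch)
        co2_neg, carb = _carbonate_charges(cs, target_pch, co2)
        t = h - oh + float((z * conc).sum()) - co2_neg   # HCl-positive
        if abs(t) > _TITRANT_MAX:
            return None
        i_new = 0.5 * (h + oh + abs(t) + float(((z ** 2) * conc).sum())
                       + carb.get("HCO3", 0.0) + 4.0 * carb.get("CO3", 0.0))
        if abs(i_new - i_local) <= _I_TOL_ABS + _I_TOL_REL * i_new:
            return t, float(conc.sum()), i_new, cs, saturated
        i_local = (1.0 - _I_DAMP) * i_local + _I_DAMP * i_new
    raise ConvergenceError("profile point did not converge")


def analytic_continuation_profile(spec: SuspensionSpec,
                                  pH_range=(0.0, 13.0), step: float = 0.05,
                                  ctx: ActivityContext | None = None
                                  ) -> SolubilityProfile:
    """Simulated-titration log S-pH profile on a uniform p_cH grid.

    With activity corrections disabled the profile coincides with the HH
    reference curve wherever solid remains.
    """
    lo, hi = pH_range
    if not (lo < hi and step > 0):
        raise ValueError("need lo < hi and step > 0")
    compound = spec.compound
    ctx = ctx or ActivityContext(temperature=compound.T)
    if ctx.temperature != compound.T:
        ctx = replace(ctx, temperature=compound.T)
    if compound.pS0_ref is None:
        # fix the intrinsic solubility from the measured S_w first
        from .solver import derive_intrinsic_from_sw
        _, ps0_ref, _, _ = derive_intrinsic_from_sw(compound, ctx,
                                                    spec.co2_total)
        compound = replace(compound, pS0_ref=ps0_ref)
    c_tot = spec.c_tot
    base = solve_suspension(SuspensionSpec(
        compound=compound, total_added=c_tot,
        co2_total=spec.co2_total), ctx)
    ph_w, i_w = base.p_cH, base.ionic_strength
    ps0_ref = _ps0_ref_of(compound, base, ctx)
    cs_ref = _ref_constants(compound, ctx, pS0_ref=compound.pS0_ref
                            if compound.pS0_ref is not None else ps0_ref,
                            with_carbonate=spec.co2_total > 0)
    grid = np.arange(lo, hi + 0.5 * step, step)
    points = []
    skipped = 0
    for target in grid:
        try:
            res = _point_at_ph(cs_ref, compound, c_tot, spec.co2_total,
                               float(target), ctx)
        except ConvergenceError:
            res = None
        if res is None:
            skipped += 1
            continue
        t_star, dissolved, i_loc, cs, saturated = res
        hh = hh_reference_curve(compound.pKa_ref, ps0_ref,
                                compound.max_cation_charge, float(target))
        points.append(ProfilePoint(
            pH=float(target),
            log_S_local=math.log10(dissolved) if dissolved > 0
            else float("-inf"),
            log_S_hh_ref=float(hh), I_local=i_loc,
            pKa_local=tuple(cs.pKa_values),
            buffer_capacity=float("nan"), titrant_added=t_star,
            saturated=saturated))
    if skipped:
        warnings.warn(f"{skipped} grid pH value(s) unreachable with "
                      f"|titrant| <= {_TITRANT_MAX} M; omitted")
    points = _with_buffer_capacity(points)
    return SolubilityProfile(points=tuple(points), compound=compound,
                             pH_w=ph_w, I_w=i_w)


def _ps0_ref_of(compound: CompoundSpec, base: SuspensionState,
                ctx: ActivityContext) -> float:
    if compound.pS0_ref is not None:
        return compound.pS0_ref
    if not ctx.corrections_enabled:
        return base.pS0_local
    return salting_shift(base.pS0_local, compound.k_salt,
                         base.ionic_strength, ctx.reference_ionic_strength)


def _with_buffer_capacity(points):
    """Centered-difference d(base titrant)/d(pH) along the profile."""
    out = []
    n = len(points)
    for i, p in enumerate(points):
        lo = max(0, i - 1)
        hi = min(n - 1, i + 1)
        if hi == lo:
            beta = float("nan")
        else:
            dph = points[hi].pH - points[lo].pH
            # titrant is HCl-positive; buffer capacity uses base-positive
            dtit = -(points[hi].titrant_added - points[lo].titrant_added)
            beta = dtit / dph if dph != 0 else float("nan")
        out.append(replace(p, buffer_capacity=beta))
    return out


def buffer_capacity(profile: SolubilityProfile, at_pH: float) -> float:
    """Buffer capacity (mol/(L*pH)) at a pH on the profile grid.

    Centered difference on the two adjacent points; one-sided (with a
    warning) at the grid edges.
    """
    pts = profile.points
    if not pts:
        raise ValueError("empty profile")
    phs = np.array([p.pH for p in pts])
    if not (phs.min() - 1e-9 <= at_pH <= phs.max() + 1e-9):
        raise ValueError("at_pH outside profile range")
    i = int(np.argmin(np.abs(phs - at_pH)))
    if i in (0, len(pts) - 1):
        warnings.warn("buffer capacity at grid edge: one-sided difference")
        j = 1 if i == 0 else len(pts) - 2
        dph = pts[i].pH - pts[j].pH
        return -(pts[i].titrant_added - pts[j].titrant_added) / dph
    return pts[i].buffer_capacity
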