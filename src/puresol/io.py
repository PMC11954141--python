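"""Compound records, config file round trip, and result writers.

A compound is described by ~15 scalars (protonation topology, reference
constants, measured water solubility, salting-out constant).  The on-disk
format is flat YAML, one document per compound; every field is a plain
scalar with stated units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import yaml

__all__ = [
    "CompoundSpec",
    "RunConfig",
    "load_compound_config",
    "save_compound_config",
    "compound_from_dict",
    "compound_to_dict",
    "generate_random_compound",
    "write_results",
]

_CLASSES = ("acid", "base", "ampholyte")


@dataclass(frozen=True)
class CompoundSpec:
    """One weakly ionizable compound and its measured water solubility.

    ``pKa_ref`` are stepwise ionization constants (ascending, proton-
    association convention: each is the pKa of the conjugate acid) on the
    I_ref = 0.15 M concentration-scale basis at temperature ``T``.
    ``max_cation_charge`` fixes the absolute charge of every protonation
    state; the fully protonated species carries that charge.  Exactly one of
    ``log_Sw`` or (``Sw_mg_per_mL`` + ``MW``) must determine the measured
    solubility (if both are given they must agree).
    """

    name: str
    compound_class: str                      # acid | base | ampholyte
    pKa_ref: tuple                           # log units, ascending
    max_cation_charge: int
    T: float                                 # C
    log_Sw: float | None = None              # log10 M
    Sw_mg_per_mL: float | None = None
    MW: float | None = None                  # g/mol
    k_salt: float = 0.0                      # 1/M
    pS0_ref: float | None = None             # -log10 M, known intrinsic sol.
    total_added: float | None = None         # M (solid + dissolved)
    total_added_g_per_mL: float | None = None
    co2_total: float = 0.0                   # M dissolved CO2
    uncertain_topology: bool = False
    expected: dict | None = None             # tabulated reference results

    def __post_init__(self):
        if self.compound_class not in _CLASSES:
            raise ValueError(f"compound_class must be one of {_CLASSES}")
        pka = tuple(float(p) for p in self.pKa_ref)
        object.__setattr__(self, "pKa_ref", pka)
        if len(pka) == 0:
            raise ValueError("pKa_ref must be nonempty")
        if any(b <= a for a, b in zip(pka, pka[1:])):
            raise ValueError("pKa_ref must be strictly increasing")
        if not (0 <= self.max_cation_charge <= len(pka)):
            raise ValueError("0 <= max_cation_charge <= n_pka required")
        has_log = self.log_Sw is not None
        has_mg = self.Sw_mg_per_mL is not None
        if has_mg and self.MW is None:
            raise ValueError("Sw_mg_per_mL requires MW")
        if not has_log and not has_mg and self.pS0_ref is None:
            raise ValueError("one of log_Sw / Sw_mg_per_mL+MW / pS0_ref "
                             "must be provided")
        if has_log and has_mg:
            if abs(self.log_Sw - math.log10(self.Sw_mg_per_mL / self.MW)) > 1e-3:
                raise ValueError(
                    f"{self.name}: log_Sw and Sw_mg_per_mL/MW disagree by "
                    ">1e-3 log units")
        if self.co2_total < 0:
            raise ValueError("co2_total must be >= 0")

    @property
    def n_pka(self) -> int:
        return len(self.pKa_ref)

    @property
    def sw_molar(self) -> float | None:
        """Measured water solubility in mol/L."""
        if self.log_Sw is not None:
            return 10.0 ** self.log_Sw
        if self.Sw_mg_per_mL is not None:
            return self.Sw_mg_per_mL / self.MW
        return None

    @property
    def total_added_molar(self) -> float | None:
        """Total compound added, mol/L, if stated."""
        if self.total_added is not None:
            return self.total_added
        if self.total_added_g_per_mL is not None:
            if self.MW is None:
                raise ValueError("total_added_g_per_mL requires MW")
            return 1000.0 * self.total_added_g_per_mL / self.MW
        return None


@dataclass(frozen=True)
class RunConfig:
    """Run-level switches shared by the CLI subcommands."""

    I_ref: float = 0.15
    corrections_enabled: bool = True
    pH_lo: float = 0.0
    pH_hi: float = 13.0
    pH_step: float = 0.05
    i_tol_abs: float = 1e-9
    i_tol_rel: float = 1e-6
    seed: int = 0
    output: str | None = None

    def __post_init__(self):
        if self.I_ref <= 0:
            raise ValueError("I_ref must be > 0")
        if self.i_tol_abs <= 0 or self.i_tol_rel <= 0:
            raise ValueError("tolerances must be > 0")


_FIELDS = {
    "name": str, "compound_class": str, "max_cation_charge": int,
    "T": float, "log_Sw": float, "Sw_mg_per_mL": float, "MW": float,
    "k_salt": float, "pS0_ref": float, "total_added": float,
    "total_added_g_per_mL": float, "co2_total": float,
    "uncertain_topology": bool,
}


def compound_to_dict(spec: CompoundSpec) -> dict:
    d = {"name": spec.name, "compound_class": spec.compound_class,
         "pKa_ref": [float(p) for p in spec.pKa_ref],
         "max_cation_charge": spec.max_cation_charge, "T": spec.T}
    for key in ("log_Sw", "Sw_mg_per_mL", "MW", "k_salt", "pS0_ref",
                "total_added", "total_added_g_per_mL", "co2_total"):
        val = getattr(spec, key)
        if val is not None and not (key in ("k_salt", "co2_total") and val == 0.0):
            d[key] = float(val)
    if spec.uncertain_topology:
        d["uncertain_topology"] = True
    return d


def compound_from_dict(d: dict) -> CompoundSpec:
    d = dict(d)
    if "pKa_ref" not in d:
        raise ValueError("missing required field 'pKa_ref'")
    for req in ("name", "compound_class", "max_cation_charge", "T"):
        if req not in d:
            raise ValueError(f"missing required field '{req}'")
    kwargs = {"pKa_ref": tuple(float(p) for p in d.pop("pKa_ref"))}
    for key, typ in _FIELDS.items():
        if key in d:
            kwargs[key] = typ(d.pop(key))
    d.pop("expected", None)
    if d:
        raise ValueError(f"unknown fields in compound record: {sorted(d)}")
    return CompoundSpec(**kwargs)


def load_compound_config(path) -> CompoundSpec:
    """Read one compound record from a flat YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat key-value document")
    try:
        return compound_from_dict(data)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def save_compound_config(spec: CompoundSpec, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(compound_to_dict(spec), fh, sort_keys=True,
                       default_flow_style=False)


def generate_random_compound(seed: int, n_pka: int,
                             compound_class: str = "acid") -> CompoundSpec:
    """Deterministic random compound for property tests.

    pKa values ascending in [1, 12] with spacing >= 0.3; pS0 in [-1, 8];
    K_salt in [0, 0.7] (the span of the tabulated per-class averages).
    """
    import numpy as np
    if not (1 <= n_pka <= 6):
        raise ValueError("n_pka must be in 1..6")
    if compound_class not in _CLASSES:
        raise ValueError(f"compound_class must be one of {_CLASSES}")
    rng = np.random.default_rng(seed)
    gaps = rng.uniform(0.3, (12.0 - 1.0) / n_pka, size=n_pka)
    start = rng.uniform(1.0, 12.0 - float(gaps.sum()))
    pka = [float(start)]
    for g in gaps[1:]:
        pka.append(pka[-1] + float(g))
    if compound_class == "acid":
        max_cat = 0
    elif compound_class == "base":
        max_cat = n_pka
    else:
        max_cat = int(rng.integers(1, n_pka)) if n_pka > 1 else 1
    ps0 = float(rng.uniform(-1.0, 8.0))
    return CompoundSpec(
        name=f"random-{compound_class}-{seed}",
        compound_class=compound_class, pKa_ref=tuple(pka),
        max_cation_charge=max_cat, T=25.0, pS0_ref=ps0,
        log_Sw=None, k_salt=float(rng.uniform(0.0, 0.7)),
        MW=float(rng.uniform(150.0, 600.0)))


def _fmt(x) -> str:
    if isinstance(x, bool):
        return "1" if x else "0"
    if isinstance(x, float):
        return format(x, ".10g")
    return str(x)


def write_results(result, path, *, config: RunConfig | None = None,
                  seed: int | None = None) -> None:
    """Write a solved state or profile as delimited text.

    Header lines (prefixed ``#``) record run metadata; identical inputs
    produce byte-identical files.
    """
    from . import __version__
    cfg = config or RunConfig()
    lines = [f"# puresol {__version__}",
             f"# I_ref={_fmt(cfg.I_ref)} corrections={_fmt(cfg.corrections_enabled)}"
             f" i_tol_abs={_fmt(cfg.i_tol_abs)} i_tol_rel={_fmt(cfg.i_tol_rel)}"
             f" seed={_fmt(seed if seed is not None else cfg.seed)}"]
    rows = getattr(result, "points", None)
    if rows is not None:                       # SolubilityProfile
        lines.append("pH,logS_local,logS_HH_ref,I_local,buffer_capacity,"
                     "titrant_added,saturated")
        for p in rows:
            lines.append(",".join(_fmt(v) for v in (
                p.pH, p.log_S_local, p.log_S_hh_ref, p.I_local,
                p.buffer_capacity, p.titrant_added, p.saturated)))
    elif hasattr(result, "p_cH"):              # SuspensionState
        st = result
        lines.append("p_cH,p_aH,ionic_strength,dissolved_total,"
                     "solid_remaining,saturated,pS0_I,converged")
        lines.append(",".join(_fmt(v) for v in (
            st.p_cH, st.p_aH, st.ionic_strength, st.dissolved_total,
            st.solid_remaining, st.saturated, st.pS0_local, st.converged)))
    elif isinstance(result, dict):             # derive-style result
        keys = sorted(result)
        lines.append(",".join(keys))
        lines.append(",".join(_fmt(result[k]) for k in keys))
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
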