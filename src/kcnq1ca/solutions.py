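"""Chelator equilibria, Nernst potentials and liquid junction potentials.

``free_ion_concentrations`` solves the coupled Ca2+/Mg2+/EGTA/ATP/H+
equilibria of a pipette solution the way the classic on-line chelator
calculators do: stepwise proton and metal association constants (shipped in
``data/chelator_constants.json``, referenced to ionic strength 0.15 M) are
temperature-corrected by van't Hoff and collapsed at the stated pH into
apparent constants, and the two free metal concentrations are found by a
damped fixed-point iteration with a bisection fallback.

``henderson_ljp`` evaluates the Henderson equation from a table of limiting
equivalent conductivities, returning the potential of the pipette interior
relative to the bath (the value to add to command potentials as a
correction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

R_GAS = 8.31446
FARADAY = 96485.33


class SolutionError(ValueError):
    """Raised for invalid solution compositions."""


class ChelatorConvergenceError(RuntimeError):
    """Raised when the chelator equilibrium solver does not converge."""

    def __init__(self, msg: str, residual: float):
        super().__init__(f"{msg} (residual {residual:.3e})")
        self.residual = residual


KNOWN_SPECIES = {
    "Na", "K", "Cl", "Mg_total", "Ca_total",
    "EGTA", "ATP", "HEPES", "aspartate", "glucose",
}


@dataclass(frozen=True)
class SolutionComposition:
    """Total (analytical) composition of an intra- or extracellular solution.

    Concentrations in mM; pH dimensionless; temperature in Celsius.
    """

    species: dict
    pH: float
    temperature_C: float = 21.0
    name: str = ""

    def __post_init__(self) -> None:
        for k, v in self.species.items():
            if k not in KNOWN_SPECIES:
                raise SolutionError(f"unknown species {k!r}; known: {sorted(KNOWN_SPECIES)}")
            if v < 0:
                raise SolutionError(f"negative concentration for {k}")
        if not (0 < self.pH < 14):
            raise SolutionError("pH must be in (0, 14)")

    def get(self, name: str) -> float:
        return float(self.species.get(name, 0.0))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "pH": self.pH,
            "temperature_C": self.temperature_C,
            "species": dict(self.species),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SolutionComposition":
        return cls(
            species=d["species"], pH=d["pH"],
            temperature_C=d.get("temperature_C", 21.0), name=d.get("name", ""),
        )


@dataclass(frozen=True)
class EquilibriumResult:
    free_ca: float  # molar
    free_mg: float  # molar
    bound_fractions: dict  # ligand -> fraction of total metal bound, per metal
    convergence_residual: float


# -- shipped solution presets (the published recipes) -----------------------

def standard_ics_low_ca() -> SolutionComposition:
    """Standard pipette solution, about 20 nM free Ca2+ at 21 C."""
    return SolutionComposition(
        species={
            "K": 160.0,  # 125 K-aspartate + 20 KCl + 10 from K2-ATP + ~5 KOH
            "aspartate": 125.0,
            "Cl": 24.0,  # 20 KCl + MgCl2 + CaCl2
            "Mg_total": 1.0,
            "Ca_total": 1.0,
            "HEPES": 10.0,
            "EGTA": 10.0,
            "ATP": 5.0,
        },
        pH=7.2,
        temperature_C=21.0,
        name="ICS-low-Ca",
    )


def ics_high_ca() -> SolutionComposition:
    """High-Ca2+ pipette solution, about 5 uM free Ca2+ at 21 C."""
    return SolutionComposition(
        species={
            "K": 165.0,  # 130 K-aspartate + 10 from K2-ATP + ~25 KOH... nominal
            "aspartate": 130.0,
            "Cl": 21.5,  # MgCl2 + CaCl2
            "Mg_total": 1.0,
            "Ca_total": 9.76,
            "HEPES": 10.0,
            "EGTA": 10.0,
            "ATP": 5.0,
        },
        pH=7.2,
        temperature_C=21.0,
        name="ICS-high-Ca",
    )


def standard_ringer() -> SolutionComposition:
    """Standard external Ringer solution."""
    return SolutionComposition(
        species={
            "Na": 144.0,  # 140 NaCl + ~4 NaOH
            "K": 5.0,
            "Cl": 148.6,  # NaCl + KCl + MgCl2 + CaCl2
            "Mg_total": 0.8,
            "Ca_total": 1.0,
            "HEPES": 10.0,
            "glucose": 5.0,
        },
        pH=7.35,
        temperature_C=21.0,
        name="Ringer",
    )


def egta_ringer() -> SolutionComposition:
    """Low-Ca2+ EGTA-Ringer bath used for pre-incubation."""
    base = standard_ringer().to_dict()
    base["species"]["EGTA"] = 2.5
    base["species"]["Na"] = 150.0  # extra NaOH to neutralize the added EGTA
    base["name"] = "EGTA-Ringer"
    return SolutionComposition.from_dict(base)


SOLUTION_PRESETS = {
    "ics-low-ca": standard_ics_low_ca,
    "ics-high-ca": ics_high_ca,
    "ringer": standard_ringer,
    "egta-ringer": egta_ringer,
}


# -- chelator equilibria ----------------------------------------------------

def _load_constants() -> dict:
    with resources.files("kcnq1ca.data").joinpath("chelator_constants.json").open() as fh:
        return json.load(fh)


def _vant_hoff(logK_ref: float, dH_kJ: float, t_ref_C: float, t_C: float) -> float:
    T1 = t_ref_C + 273.15
    T2 = t_C + 273.15
    return logK_ref - dH_kJ * 1000.0 / (np.log(10.0) * R_GAS) * (1.0 / T2 - 1.0 / T1)


def _apparent_constants(sol: SolutionComposition, table: dict) -> dict:
    """Collapse the constants at (pH, T) into per-ligand apparent constants.

    Returns {ligand: {"alpha_H": .., "K_Ca": .., "K_Mg": .., "total_M": ..}}
    with K_M the effective association constant of metal per fully
    deprotonated free ligand (includes the protonated MHL complexes).
    """
    h = 10.0 ** (-sol.pH)  # proton activity
    t_ref = table["reference"]["temperature_C"]
    out = {}
    for lig, cons in table["ligands"].items():
        total = sol.get(lig)
        pKs = [
            _vant_hoff(pk, dh, t_ref, sol.temperature_C)
            for pk, dh in zip(cons["pK_H"], cons["dH_H_kJ"])
        ]
        # cumulative protonation terms: K1 h + K1 K2 h^2 + ...
        alpha = 1.0
        cum = 0.0
        for j, pk in enumerate(pKs):
            cum += pk
            alpha += 10.0 ** cum * h ** (j + 1)
        kk = {}
        for metal, mc in cons["metals"].items():
            k_ml = 10.0 ** _vant_hoff(mc["logK_ML"], mc["dH_ML_kJ"], t_ref, sol.temperature_C)
            k_mhl = 10.0 ** _vant_hoff(mc["logK_MHL"], mc["dH_MHL_kJ"], t_ref, sol.temperature_C)
            # MHL forms from the singly protonated ligand
            kk[metal] = k_ml + k_mhl * (10.0 ** pKs[0]) * h
        out[lig] = {"alpha_H": alpha, "K_Ca": kk.get("Ca", 0.0),
                    "K_Mg": kk.get("Mg", 0.0), "total_M": total / 1000.0}
    return out


def _free_metals_residual(ca: float, mg: float, ca_tot: float, mg_tot: float,
                          ligs: dict) -> tuple[float, float, float, float]:
    """One fixed-point update; returns (ca_new, mg_new, ca_resid, mg_resid)."""
    bound_coef_ca = 0.0
    bound_coef_mg = 0.0
    for L in ligs.values():
        if L["total_M"] <= 0:
            continue
        lu = L["total_M"] / (L["alpha_H"] + L["K_Ca"] * ca + L["K_Mg"] * mg)
        bound_coef_ca += L["K_Ca"] * lu
        bound_coef_mg += L["K_Mg"] * lu
    ca_new = ca_tot / (1.0 + bound_coef_ca)
    mg_new = mg_tot / (1.0 + bound_coef_mg)
    ca_res = abs(ca * (1.0 + bound_coef_ca) - ca_tot) / max(ca_tot, 1e-300)
    mg_res = abs(mg * (1.0 + bound_coef_mg) - mg_tot) / max(mg_tot, 1e-300)
    return ca_new, mg_new, ca_res, mg_res


def free_ion_concentrations(
    sol: SolutionComposition,
    rtol: float = 1e-12,
    max_iter: int = 2000,
    damping: float = 0.5,
) -> EquilibriumResult:
    """Free Ca2+ and Mg2+ of a chelator-buffered solution (molar)."""
    table = _load_constants()
    ligs = _apparent_constants(sol, table)
    ca_tot = sol.get("Ca_total") / 1000.0
    mg_tot = sol.get("Mg_total") / 1000.0

    ca = ca_tot if ca_tot > 0 else 0.0
    mg = mg_tot if mg_tot > 0 else 0.0
    resid = 0.0
    for _ in range(max_iter):
        ca_new, mg_new, ca_res, mg_res = _free_metals_residual(ca, mg, ca_tot, mg_tot, ligs)
        resid = max(ca_res if ca_tot > 0 else 0.0, mg_res if mg_tot > 0 else 0.0)
        if resid < rtol:
            break
        # damped geometric update keeps the iteration strictly positive
        ca = ca ** (1 - damping) * ca_new ** damping if ca > 0 else ca_new
        mg = mg ** (1 - damping) * mg_new ** damping if mg > 0 else mg_new
    else:
        ca, mg, resid = _bisect_fallback(ca_tot, mg_tot, ligs, rtol)
        if resid > 1e-9:
            raise ChelatorConvergenceError("chelator equilibrium did not converge", resid)

    bound = {}
    for lig, L in ligs.items():
        if L["total_M"] <= 0:
            continue
        lu = L["total_M"] / (L["alpha_H"] + L["K_Ca"] * ca + L["K_Mg"] * mg)
        bound[lig] = {
            "Ca": (L["K_Ca"] * lu * ca) / ca_tot if ca_tot > 0 else 0.0,
            "Mg": (L["K_Mg"] * lu * mg) / mg_tot if mg_tot > 0 else 0.0,
        }
    return EquilibriumResult(
        free_ca=float(ca), free_mg=float(mg),
        bound_fractions=bound, convergence_residual=float(resid),
    )


def _bisect_fallback(ca_tot, mg_tot, ligs, rtol):
    """Nested bisection on log10 free Ca with inner Mg fixed point."""

    def mg_given_ca(ca):
        mg = mg_tot
        for _ in range(500):
            _, mg_new, _, mg_res = _free_metals_residual(ca, mg, ca_tot, mg_tot, ligs)
            if mg_res < rtol:
                break
            mg = 0.5 * (mg + mg_new)
        return mg

    def g(log_ca):
        ca = 10.0 ** log_ca
        mg = mg_given_ca(ca)
        ca_new, _, _, _ = _free_metals_residual(ca, mg, ca_tot, mg_tot, ligs)
        return np.log10(ca_new) - log_ca

    if ca_tot <= 0:
        mg = mg_given_ca(0.0)
        _, _, _, mg_res = _free_metals_residual(0.0, mg, ca_tot, mg_tot, ligs)
        return 0.0, mg, mg_res if mg_tot > 0 else 0.0
    lo, hi = np.log10(ca_tot) - 15.0, np.log10(ca_tot)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
    ca = 10.0 ** (0.5 * (lo + hi))
    mg = mg_given_ca(ca)
    _, _, ca_res, mg_res = _free_metals_residual(ca, mg, ca_tot, mg_tot, ligs)
    return ca, mg, max(ca_res, mg_res if mg_tot > 0 else 0.0)


# -- Nernst -----------------------------------------------------------------

def nernst_potential(
    ion_valence: int, conc_in: float, conc_out: float, temperature: float = 21.0
) -> float:
    """Equilibrium potential E = (RT/zF) ln(out/in), in mV."""
    if conc_in <= 0 or conc_out <= 0:
        raise SolutionError("concentrations must be > 0")
    if ion_valence == 0:
        raise SolutionError("ion valence must be nonzero")
    T = temperature + 273.15
    return 1000.0 * R_GAS * T / (ion_valence * FARADAY) * np.log(conc_out / conc_in)


def potassium_reversal(
    pipette: SolutionComposition, bath: SolutionComposition
) -> float:
    """E_K (mV) from the K+ contents of pipette and bath."""
    return nernst_potential(1, pipette.get("K"), bath.get("K"), pipette.temperature_C)


# -- Henderson liquid junction potential ------------------------------------

#: limiting equivalent conductivities at 25 C (S cm^2 / equiv); for the LJP
#: only relative magnitudes matter, so no temperature scaling is applied
LIMITING_CONDUCTIVITY = {
    "Na": (1, 50.11),
    "K": (1, 73.50),
    "Cl": (-1, 76.35),
    "Ca": (2, 59.50),
    "Mg": (2, 53.06),
    "aspartate": (-1, 30.7),
    "HEPES": (-1, 22.05),
    "EGTA": (-2, 24.0),
    "ATP": (-2, 24.0),
}

#: fraction of HEPES carrying a negative charge, from its pKa of 7.5
def _hepes_anion_fraction(pH: float) -> float:
    return 1.0 / (1.0 + 10.0 ** (7.5 - pH))


def _ionic_breakdown(sol: SolutionComposition) -> dict:
    """Map a composition to charged species concentrations (mM) for the LJP."""
    out = {}
    for name, conc in sol.species.items():
        if conc == 0:
            continue
        if name == "glucose":
            continue
        key = {"Mg_total": "Mg", "Ca_total": "Ca"}.get(name, name)
        if key == "HEPES":
            conc = conc * _hepes_anion_fraction(sol.pH)
        if key not in LIMITING_CONDUCTIVITY:
            raise SolutionError(f"no mobility entry for species {key!r}")
        out[key] = out.get(key, 0.0) + conc
    return out


def henderson_ljp(
    pipette: SolutionComposition,
    bath: SolutionComposition,
    temperature: float | None = None,
) -> float:
    """Henderson liquid junction potential (mV).

    Returns the potential of the pipette interior relative to the bath; this
    is the value to ADD to command potentials as the junction correction.
    Raises SolutionError for species without a mobility entry.
    """
    t = temperature if temperature is not None else pipette.temperature_C
    T = t + 273.15
    cp = _ionic_breakdown(pipette)
    cb = _ionic_breakdown(bath)
    species = sorted(set(cp) | set(cb))
    A = B = 0.0
    s_p = s_b = 0.0
    for sp in species:
        z, lam = LIMITING_CONDUCTIVITY[sp]
        u = lam / abs(z)  # mobility proportional to lambda / |z|
        c1 = cp.get(sp, 0.0)
        c2 = cb.get(sp, 0.0)
        A += z * u * (c2 - c1)
        B += z * z * u * (c2 - c1)
        s_p += z * z * u * c1
        s_b += z * z * u * c2
    if s_p == 0 or s_b == 0:
        raise SolutionError("solutions contain no charged species")
    if B == 0:  # identical ionic strengths term; junction potential vanishes
        return 0.0
    rt_f = 1000.0 * R_GAS * T / FARADAY
    e_bath_minus_pip = -rt_f * (A / B) * np.log(s_b / s_p)
    return float(-e_bath_minus_pip)
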