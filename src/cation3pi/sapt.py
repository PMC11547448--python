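"""Bookkeeping over symmetry-adapted perturbation theory (SAPT) tables.

SAPT partitions the interaction energy between two monomers — here the
(M⁺-mW)⊗2Bz-2nW complex and the departing Bz-nW unit, at the geometry of
the full complex — into four physically meaningful components:

    E_tot = E_elst + E_exch + E_ind + E_disp

electrostatics (Coulombic multipole–multipole interaction and charge-
distribution overlap), exchange (wavefunction-overlap repulsion), induction
(mutual polarization and charge transfer), and dispersion (intermonomer
electron correlation).  The SAPT computation itself is external; this
module ingests its component tables, verifies the four-term identity, and
classifies how hydration at each site shifts every component relative to
the gas-phase complex (more negative = strengthened).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "SaptComponents",
    "SiteEffect",
    "sapt_total",
    "hydration_shift",
    "classify_site_pattern",
    "load_sapt_csv",
]

COMPONENTS = ("e_elst", "e_exch", "e_ind", "e_disp")

#: printed-table rounding tolerance, kcal/mol
PRINT_TOL = 0.02


@dataclass(frozen=True)
class SaptComponents:
    """One SAPT row: four components plus total, kcal/mol, with its label."""

    system: str
    cation: str
    e_elst: float
    e_exch: float
    e_ind: float
    e_disp: float
    e_tot: float

    @classmethod
    def from_components(cls, system, cation, e_elst, e_exch, e_ind, e_disp):
        """Construct with the total assembled exactly from the four terms."""
        return cls(system, cation, e_elst, e_exch, e_ind, e_disp,
                   e_elst + e_exch + e_ind + e_disp)

    def verify_identity(self, tol: float = PRINT_TOL) -> float:
        """Deviation of the stored total from the four-term sum; raises if > tol."""
        dev = self.e_tot - sapt_total(self)
        if abs(dev) > tol:
            raise ValueError(
                f"{self.system}/{self.cation}: E_tot off the component sum by "
                f"{dev:+.4f} kcal/mol (tolerance {tol})"
            )
        return dev


def sapt_total(components: SaptComponents) -> float:
    """E_elst + E_exch + E_ind + E_disp, kcal/mol."""
    return (components.e_elst + components.e_exch
            + components.e_ind + components.e_disp)


@dataclass(frozen=True)
class SiteEffect:
    """Per-component change of a hydrated row relative to the gas-phase row.

    ``direction`` tags the total: negative Δe_tot = strengthened binding.
    """

    cation: str
    site_system: str
    d_elst: float
    d_exch: float
    d_ind: float
    d_disp: float
    d_tot: float

    @property
    def direction(self) -> str:
        if self.d_tot < 0:
            return "strengthened"
        if self.d_tot > 0:
            return "weakened"
        return "unchanged"

    def deltas(self) -> dict[str, float]:
        return {"e_elst": self.d_elst, "e_exch": self.d_exch,
                "e_ind": self.d_ind, "e_disp": self.d_disp}


def hydration_shift(site_row: SaptComponents, gas_row: SaptComponents) -> SiteEffect:
    """Component-wise Δ = hydrated − gas for one cation."""
    if site_row.cation != gas_row.cation:
        raise ValueError(
            f"cation mismatch: {site_row.cation!r} vs {gas_row.cation!r}"
        )
    return SiteEffect(
        cation=site_row.cation,
        site_system=site_row.system,
        d_elst=site_row.e_elst - gas_row.e_elst,
        d_exch=site_row.e_exch - gas_row.e_exch,
        d_ind=site_row.e_ind - gas_row.e_ind,
        d_disp=site_row.e_disp - gas_row.e_disp,
        d_tot=site_row.e_tot - gas_row.e_tot,
    )


def classify_site_pattern(effects: list[SiteEffect]) -> dict:
    """Sign unanimity of each component's shift across the three cations.

    For every component the record reports ``+``/``-`` when the sign of Δ
    agrees for all cations, or ``mixed`` otherwise (Δ = 0 counts as mixed).
    The electrostatic entry is the headline: its sign separates cation-side
    hydration (positive, weakening) from ring-side hydration (negative,
    strengthening).
    """
    if len(effects) < 3:
        raise ValueError("need one SiteEffect per cation (three records)")
    record: dict[str, str] = {}
    for comp in (*COMPONENTS, "e_tot"):
        key = "d_tot" if comp == "e_tot" else "d_" + comp[2:]
        signs = {(-1 if getattr(e, key) < 0 else (1 if getattr(e, key) > 0 else 0))
                 for e in effects}
        if signs == {1}:
            record[comp] = "+"
        elif signs == {-1}:
            record[comp] = "-"
        else:
            record[comp] = "mixed"
    record["unanimous"] = {c: record[c] in "+-" for c in (*COMPONENTS, "e_tot")}
    return record


def load_sapt_csv(path, tol: float = PRINT_TOL) -> list[SaptComponents]:
    """Read a SAPT component CSV (``system,cation,e_elst,e_exch,e_ind,e_disp[,e_tot]``).

    A missing ``e_tot`` column is recomputed exactly; a present one is
    verified against the four-term sum to ``tol`` (printed rounding).
    """
    df = pd.read_csv(path)
    required = {"system", "cation", *COMPONENTS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"SAPT CSV missing columns: {sorted(missing)}")
    rows = []
    for rec in df.to_dict("records"):
        if "e_tot" in df.columns and pd.notna(rec.get("e_tot")):
            row = SaptComponents(
                rec["system"], rec["cation"],
                float(rec["e_elst"]), float(rec["e_exch"]),
                float(rec["e_ind"]), float(rec["e_disp"]), float(rec["e_tot"]),
            )
            row.verify_identity(tol)
        else:
            row = SaptComponents.from_components(
                rec["system"], rec["cation"],
                float(rec["e_elst"]), float(rec["e_exch"]),
                float(rec["e_ind"]), float(rec["e_disp"]),
            )
        rows.append(row)
    return rows
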