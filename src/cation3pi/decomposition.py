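"""One-benzene-binding energy and the five-component decomposition.

The stability of a hydrated cation⊗3π complex (M⁺-mW)⊗3Bz-3nW is measured
by the one-benzene-binding (OBB) energy: the cost of separating one benzene
plus its n waters from the complex, leaving the two-benzene complex behind::

    E_binding = E(full) − E(reduced) − E(Bz) − n·E(W)

where *full* is the (M⁺-mW)⊗3Bz-3nW complex and *reduced* the
(M⁺-mW)⊗2Bz-2nW complex.  The same quantity is decomposed into five
supermolecular components, each a difference of 3-ring and 2-ring
interaction energies built from subsystem totals at frozen geometry:

    E_M⁺-π = E_M⁺-3π − E_M⁺-2π          (cation–π)
    E_π-π  = E_3π − E_2π                  (π–π)
    E_W-π  = E_W-3π − E_W-2π              (water–π)
    E_W-W  = E_mW-3nW − E_mW-2nW          (water–water)
    E_W-M⁺ = E_M⁺-mW-3nW − E_M⁺-mW-2nW   (water–cation)

and their sum E_Sum is compared against E_binding.  With a strictly
pairwise energy backend and a frozen reduced geometry the two agree
exactly (every pair term appears once on each side); many-body effects —
polarization in the surrogate, electron correlation in ab initio totals —
or a separately relaxed reduced complex open a gap, which is what makes
the component sum only a rough estimate of the binding energy.

Subsystem labels use an ASCII rendering of the complex notation::

    Na+2W@3Bz-9W   cation, 2 coordinated waters, 3 benzenes, 9 ring waters
    Na+@2Bz        cation + two benzenes
    3Bz / 2Bz / Bz benzenes only
    2W-9W          coordinated + ring waters, no cation or benzene
    Na+-2W-9W      cation + all waters
    W / Na+        monomers

Component subsystems are always evaluated at the frozen sub-geometry of
the full complex.  The OBB reference energy E(reduced) defaults to the
same frozen sub-geometry; attaching a relaxed (separately optimised,
lower-energy) two-benzene complex switches *only that one term* to the
relaxed geometry — the convention under which the study's reference
complexes are optimised while the decomposition scaffold stays frozen.
The relaxed-geometry subsystem is labeled with a ``~opt`` suffix
(``Na+2W@2Bz~opt``) so tabulated workflows can carry both energies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .backends import (
    EnergyTable,
    SubsystemSelector,
    SurrogateParameters,
    surrogate_energy,
    tabulated_energy,
)
from .geometry import ComplexModel, Fragment

__all__ = [
    "ComplexPair",
    "Subsystem",
    "DecompositionResult",
    "SurrogateBackend",
    "TabulatedBackend",
    "make_pair",
    "subsystem_label",
    "complex_label",
    "enumerate_subsystems",
    "obb_energy",
    "decompose",
    "consistency_report",
]


def subsystem_label(
    cation: str | None, n_benzene: int, m: int, w: int, relaxed: bool = False
) -> str:
    """Canonical ASCII label for a subsystem composition (see module docs).

    ``relaxed=True`` appends the ``~opt`` provenance suffix marking the
    separately optimised two-benzene reference geometry.
    """
    suffix = "~opt" if relaxed else ""
    if n_benzene > 0:
        bz = "Bz" if n_benzene == 1 else f"{n_benzene}Bz"
        prefix = ""
        if cation:
            prefix = f"{cation}+" + (f"{m}W" if m else "") + "@"
        elif m:
            prefix = f"{m}W@"
        tail = f"-{w}W" if w else ""
        return prefix + bz + tail + suffix
    parts = []
    if cation:
        parts.append(f"{cation}+")
    if m:
        parts.append(f"{m}W")
    if w:
        parts.append(f"{w}W")
    if not parts:
        raise ValueError("empty subsystem has no label")
    if not cation and len(parts) == 1:
        total = m + w
        return ("W" if total == 1 else f"{total}W") + suffix
    return "-".join(parts) + suffix


def complex_label(cation: str, n_benzene: int, m: int, n: int) -> str:
    """Display label of a complex, e.g. ``Na+2W@3Bz-9W`` (w = n·n_benzene)."""
    return subsystem_label(cation, n_benzene, m, n * n_benzene)


@dataclass(frozen=True)
class Subsystem:
    """A labeled fragment subset: label, host geometry, and selector."""

    label: str
    base: str  # "full" or "reduced"
    selector: SubsystemSelector


@dataclass(frozen=True)
class ComplexPair:
    """A full 3-benzene complex and its 2-benzene reference.

    The default (frozen) reduced complex is the sub-geometry of the full
    complex with one benzene and its attached waters removed; attaching
    ``relaxed_reduced`` switches the reference to an independently supplied
    (typically separately optimised) 2-benzene complex.
    """

    full: ComplexModel
    reduced: ComplexModel
    removed_benzene: int
    relaxed_reduced: ComplexModel | None = None

    @property
    def reference(self) -> ComplexModel:
        return self.relaxed_reduced if self.relaxed_reduced is not None else self.reduced

    @property
    def frozen(self) -> bool:
        return self.relaxed_reduced is None


def make_pair(
    full: ComplexModel,
    removed_benzene: int | None = None,
    relaxed_reduced: ComplexModel | None = None,
) -> ComplexPair:
    """Build the (full, reduced) pair by removing one benzene and its waters.

    ``removed_benzene`` defaults to the ring whose centroid has the largest
    z coordinate, ties broken toward the lowest fragment index.
    """
    benzene_indices = full.fragment_indices("benzene")
    if len(benzene_indices) != 3:
        raise ValueError("the full complex must contain exactly 3 benzenes")
    if removed_benzene is None:
        zs = [full.fragments[i].heavy_centroid()[2] for i in benzene_indices]
        zmax = max(zs)
        removed_benzene = min(
            i for i, z in zip(benzene_indices, zs) if abs(z - zmax) < 1e-12
        )
    if removed_benzene not in benzene_indices:
        raise ValueError(f"fragment {removed_benzene} is not a benzene")

    drop = {removed_benzene} | {
        i for i, f in enumerate(full.fragments) if f.attached_to == removed_benzene
    }
    keep = [i for i in range(len(full.fragments)) if i not in drop]
    remap = {old: new for new, old in enumerate(keep)}
    reduced_fragments = []
    for old in keep:
        frag = full.fragments[old]
        att = frag.attached_to
        reduced_fragments.append(
            Fragment(frag.kind, frag.atoms, frag.site_label,
                     None if att is None else remap[att])
        )
    reduced = ComplexModel(full.cation_species, tuple(reduced_fragments))

    if relaxed_reduced is not None:
        if (relaxed_reduced.n_benzene, relaxed_reduced.m, relaxed_reduced.n) != (
            2, full.m, full.n,
        ):
            raise ValueError("relaxed reduced complex composition does not match the pair")
    return ComplexPair(full, reduced, removed_benzene, relaxed_reduced)


def _water_groups(model: ComplexModel) -> tuple[list[int], list[int]]:
    coord = [i for i, f in enumerate(model.fragments) if f.site_label == "coordinated"]
    ring = [i for i, f in enumerate(model.fragments) if f.site_label in ("hollow", "bridge")]
    return coord, ring


def enumerate_subsystems(pair: ComplexPair) -> list[Subsystem]:
    """The minimal labeled subsystem set required by the decomposition.

    15 distinct subsystems in the general (m, n > 0) case; degenerate
    compositions merge when m or n is zero (6 labels at m = n = 0).
    Every component subsystem is a selection into the full complex at
    frozen geometry.  With a relaxed reduced complex attached, one extra
    subsystem — the ``~opt``-tagged OBB reference — selects into that
    geometry; everything else stays frozen.
    """
    full = pair.full
    m, n = full.m, full.n
    species = full.cation_species
    c = full.cation_index
    benzenes = full.fragment_indices("benzene")
    kept_b = [b for b in benzenes if b != pair.removed_benzene]
    coord_w, ring_w = _water_groups(full)
    kept_ring_w = [i for i in ring_w if full.fragments[i].attached_to != pair.removed_benzene]
    waters = coord_w + ring_w
    kept_w = coord_w + kept_ring_w
    w3, w2 = 3 * n, 2 * n

    subs: dict[str, Subsystem] = {}

    def add(label, base, indices):
        if indices and label not in subs:
            subs[label] = Subsystem(label, base, SubsystemSelector(tuple(indices)))

    add(subsystem_label(species, 3, m, w3), "full", [c, *benzenes, *waters])
    if pair.frozen:
        add(subsystem_label(species, 2, m, w2), "full", [c, *kept_b, *kept_w])
    else:
        add(subsystem_label(species, 2, m, w2, relaxed=True), "reduced",
            range(len(pair.relaxed_reduced.fragments)))
        add(subsystem_label(species, 2, m, w2), "full", [c, *kept_b, *kept_w])
    add(subsystem_label(species, 3, 0, 0), "full", [c, *benzenes])
    add(subsystem_label(species, 2, 0, 0), "full", [c, *kept_b])
    add(subsystem_label(None, 3, 0, 0), "full", benzenes)
    add(subsystem_label(None, 2, 0, 0), "full", kept_b)
    add(subsystem_label(None, 1, 0, 0), "full", [pair.removed_benzene])
    if waters:
        add("W", "full", [waters[0]])
        add(subsystem_label(None, 3, m, w3), "full", [*benzenes, *waters])
        add(subsystem_label(None, 2, m, w2), "full", [*kept_b, *kept_w])
        add(subsystem_label(None, 0, m, w3), "full", waters)
        add(subsystem_label(None, 0, m, w2), "full", kept_w)
        add(subsystem_label(species, 0, m, w3), "full", [c, *waters])
        add(subsystem_label(species, 0, m, w2), "full", [c, *kept_w])
    add(f"{species}+", "full", [c])
    return list(subs.values())


class SurrogateBackend:
    """Evaluates subsystem energies with the classical surrogate potential."""

    def __init__(self, params: SurrogateParameters | None = None):
        self.params = params or SurrogateParameters()

    def energy(self, pair: ComplexPair, subsystem: Subsystem) -> float:
        model = pair.full if subsystem.base == "full" else pair.reference
        return surrogate_energy(model, subsystem.selector, self.params)


class TabulatedBackend:
    """Pure label → energy lookup over an ingested :class:`EnergyTable`."""

    def __init__(self, table: EnergyTable):
        self.table = table

    def energy(self, pair: ComplexPair, subsystem: Subsystem) -> float:
        return tabulated_energy(self.table, subsystem.label)


@dataclass(frozen=True)
class DecompositionResult:
    """One decomposition: five components, their sum, and the OBB energy.

    All energies kcal/mol.  ``intermediates`` retains the 3π/2π-side terms
    and ``subsystem_energies`` the raw labeled totals, for audit.
    """

    system: str
    cation: str
    m: int
    n: int
    e_cation_pi: float
    e_pi_pi: float
    e_water_pi: float
    e_water_water: float
    e_water_cation: float
    e_sum: float
    e_binding: float
    intermediates: dict[str, float] = field(default_factory=dict, compare=False)
    subsystem_energies: dict[str, float] = field(default_factory=dict, compare=False)

    def components(self) -> dict[str, float]:
        return {
            "e_cation_pi": self.e_cation_pi,
            "e_pi_pi": self.e_pi_pi,
            "e_water_pi": self.e_water_pi,
            "e_water_water": self.e_water_water,
            "e_water_cation": self.e_water_cation,
        }

    def to_row(self) -> dict:
        """Row dict in the component-table column order."""
        return {
            "complex": self.system,
            "e_cation_pi": self.e_cation_pi,
            "e_pi_pi": self.e_pi_pi,
            "e_water_pi": self.e_water_pi,
            "e_water_water": self.e_water_water,
            "e_water_cation": self.e_water_cation,
            "e_sum": self.e_sum,
            "e_binding": self.e_binding,
        }

    def audit_json(self, path=None) -> str:
        payload = {
            "system": self.system,
            "components": self.components(),
            "e_sum": self.e_sum,
            "e_binding": self.e_binding,
            "intermediates": self.intermediates,
            "subsystem_energies": self.subsystem_energies,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def obb_energy(pair: ComplexPair, backend) -> float:
    """OBB energy E(full) − E(reduced) − E(Bz) − n·E(W), kcal/mol.

    E(reduced) is the ``~opt`` relaxed reference when one is attached,
    otherwise the frozen sub-geometry of the full complex.
    """
    full = pair.full
    m, n = full.m, full.n
    subs = {s.label: s for s in enumerate_subsystems(pair)}
    species = full.cation_species

    def get(cation, nb, mm, ww, relaxed=False):
        label = subsystem_label(cation, nb, mm, ww, relaxed)
        return backend.energy(pair, subs[label]) if label in subs else 0.0

    e_full = get(species, 3, m, 3 * n)
    e_reduced = get(species, 2, m, 2 * n, relaxed=not pair.frozen)
    e_bz = get(None, 1, 0, 0)
    e_w = backend.energy(pair, subs["W"]) if "W" in subs else 0.0
    return e_full - e_reduced - e_bz - n * e_w


def decompose(pair: ComplexPair, backend) -> DecompositionResult:
    """Five-component decomposition of the OBB energy over any backend.

    The component sum ``e_sum`` is assembled exactly as the sum of the five
    component floats; ``e_binding`` is the directly computed OBB energy.
    """
    full = pair.full
    m, n = full.m, full.n
    species = full.cation_species
    subsystems = enumerate_subsystems(pair)
    energies = {s.label: backend.energy(pair, s) for s in subsystems}

    def get(cation, nb, mm, ww, relaxed=False):
        return energies.get(subsystem_label(cation, nb, mm, ww, relaxed), 0.0)

    e_w = energies.get("W", 0.0)
    e_cat = energies.get(f"{species}+", 0.0)
    w3, w2 = 3 * n, 2 * n

    e_m_3pi = get(species, 3, 0, 0) - e_cat - get(None, 3, 0, 0)
    e_m_2pi = get(species, 2, 0, 0) - e_cat - get(None, 2, 0, 0)
    e_cation_pi = e_m_3pi - e_m_2pi

    e_3pi = get(None, 3, 0, 0) - 3 * get(None, 1, 0, 0)
    e_2pi = get(None, 2, 0, 0) - 2 * get(None, 1, 0, 0)
    e_pi_pi = e_3pi - e_2pi

    if m or n:
        e_w_3pi = get(None, 3, m, w3) - get(None, 3, 0, 0) - get(None, 0, m, w3)
        e_w_2pi = get(None, 2, m, w2) - get(None, 2, 0, 0) - get(None, 0, m, w2)
        e_water_pi = e_w_3pi - e_w_2pi
        e_mw_3nw = get(None, 0, m, w3) - (m + w3) * e_w
        e_mw_2nw = get(None, 0, m, w2) - (m + w2) * e_w
        e_water_water = e_mw_3nw - e_mw_2nw
        e_m_mw_3nw = get(species, 0, m, w3) - get(None, 0, m, w3) - e_cat
        e_m_mw_2nw = get(species, 0, m, w2) - get(None, 0, m, w2) - e_cat
        e_water_cation = e_m_mw_3nw - e_m_mw_2nw
    else:
        e_w_3pi = e_w_2pi = e_mw_3nw = e_mw_2nw = e_m_mw_3nw = e_m_mw_2nw = 0.0
        e_water_pi = e_water_water = e_water_cation = 0.0

    e_sum = e_cation_pi + e_pi_pi + e_water_pi + e_water_water + e_water_cation
    e_binding = (
        get(species, 3, m, w3)
        - get(species, 2, m, w2, relaxed=not pair.frozen)
        - get(None, 1, 0, 0) - n * e_w
    )

    return DecompositionResult(
        system=complex_label(species, 3, m, n),
        cation=species,
        m=m,
        n=n,
        e_cation_pi=e_cation_pi,
        e_pi_pi=e_pi_pi,
        e_water_pi=e_water_pi,
        e_water_water=e_water_water,
        e_water_cation=e_water_cation,
        e_sum=e_sum,
        e_binding=e_binding,
        intermediates={
            "E_M+-3pi": e_m_3pi, "E_M+-2pi": e_m_2pi,
            "E_3pi": e_3pi, "E_2pi": e_2pi,
            "E_W-3pi": e_w_3pi, "E_W-2pi": e_w_2pi,
            "E_mW-3nW": e_mw_3nw, "E_mW-2nW": e_mw_2nw,
            "E_M+-mW-3nW": e_m_mw_3nw, "E_M+-mW-2nW": e_m_mw_2nw,
        },
        subsystem_energies=dict(energies),
    )


def consistency_report(result: DecompositionResult, threshold: float = 2.0) -> dict:
    """Gap between the component sum and the OBB energy.

    Δ = e_sum − e_binding; |Δ| above ``threshold`` (kcal/mol) flags the
    decomposition as a rough estimate only (many-body and/or relaxation
    effects are significant).  Negative Δ means the component sum
    overestimates the binding strength.
    """
    delta = result.e_sum - result.e_binding
    return {
        "system": result.system,
        "delta": delta,
        "sign": "overestimates" if delta < 0 else ("exact" if delta == 0 else "underestimates"),
        "flagged": abs(delta) > threshold,
        "threshold": threshold,
    }


def results_to_frame(results) -> pd.DataFrame:
    """Stack decomposition results into a component table (input order)."""
    return pd.DataFrame([r.to_row() for r in results])
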