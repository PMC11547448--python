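"""Total-energy providers for frozen-geometry fragment subsets.

Two backends feed the decomposition engine:

* a classical **surrogate potential** — fixed point charges (Coulomb),
  a 12-6 repulsion–dispersion term, and an optional polarization term that
  introduces controllable many-body (non-pairwise) character.  Fragments
  are rigid, so intra-fragment energy is defined as zero and every monomer
  energy is exactly 0; this makes the pairwise telescoping identities of
  the decomposition exact and testable.
* a **tabulated backend** — a pure label → energy lookup for externally
  computed (e.g. ab initio) subsystem totals.

The polarization term places an isotropic responder at each non-cation
fragment's charge centroid: with response strength α the subsystem gains
−½·α·k·|F|² per fragment, where F is the summed electric field of all other
selected fragments at that centroid.  Because the gain is quadratic in a
*sum* of per-source fields, its cross terms couple fragment triples, so the
energy is no longer a sum over pairs; for a subsystem of the cation plus a
single fragment it reduces to the plain cation-field expression.
"""

from __future__ import annotations

import difflib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ComplexModel

__all__ = [
    "COULOMB_KCAL",
    "SubsystemSelector",
    "SurrogateParameters",
    "EnergyTable",
    "surrogate_energy",
    "tabulated_energy",
    "rigid_scan",
]

#: Coulomb constant, kcal·Å/(mol·e²); pinned for reproducibility.
COULOMB_KCAL = 332.0637

# Default partial charges, e, keyed by (fragment kind, element).
# Benzene: quadrupole-bearing 12-site model; water: 3-site model.
DEFAULT_CHARGES = {
    ("benzene", "C"): -0.115,
    ("benzene", "H"): +0.115,
    ("water", "O"): -0.834,
    ("water", "H"): +0.417,
    ("cation", "Li"): +1.0,
    ("cation", "Na"): +1.0,
    ("cation", "K"): +1.0,
}

# Default 12-6 well depths (kcal/mol) and diameters (Å), same keying;
# Lorentz–Berthelot combination across sites.
DEFAULT_LJ = {
    ("benzene", "C"): (0.070, 3.550),
    ("benzene", "H"): (0.030, 2.420),
    ("water", "O"): (0.152, 3.151),
    ("water", "H"): (0.0, 0.0),
    ("cation", "Li"): (0.018, 1.800),
    ("cation", "Na"): (0.0874, 2.430),
    ("cation", "K"): (0.100, 3.140),
}


@dataclass(frozen=True)
class SubsystemSelector:
    """An ordered subset of fragment indices at the parent's frozen geometry."""

    fragment_indices: tuple[int, ...]

    def __post_init__(self):
        idx = tuple(int(i) for i in self.fragment_indices)
        if len(set(idx)) != len(idx):
            raise ValueError(f"duplicate fragment indices in selector: {idx}")
        object.__setattr__(self, "fragment_indices", idx)

    def validate(self, model: ComplexModel) -> None:
        for i in self.fragment_indices:
            if not (0 <= i < len(model.fragments)):
                raise IndexError(f"fragment index {i} out of range for this complex")


@dataclass(frozen=True)
class SurrogateParameters:
    """Charges, 12-6 parameters and polarization strength for the surrogate.

    ``polarization_strength`` (α, Å³-like response units) = 0 makes the
    potential strictly pairwise over fragments.
    """

    charges: dict = field(default_factory=lambda: dict(DEFAULT_CHARGES))
    lj: dict = field(default_factory=lambda: dict(DEFAULT_LJ))
    polarization_strength: float = 0.0

    def __post_init__(self):
        if self.polarization_strength < 0:
            raise ValueError("polarization_strength must be >= 0")

    def charge(self, kind: str, element: str) -> float:
        try:
            return self.charges[(kind, element)]
        except KeyError as exc:
            raise KeyError(f"no charge defined for {element!r} in a {kind} fragment") from exc

    def lj_params(self, kind: str, element: str) -> tuple[float, float]:
        try:
            return self.lj[(kind, element)]
        except KeyError as exc:
            raise KeyError(f"no 12-6 parameters for {element!r} in a {kind} fragment") from exc


def _fragment_arrays(model, index, params):
    frag = model.fragments[index]
    pos = frag.positions
    q = np.array([params.charge(frag.kind, a.element) for a in frag.atoms])
    eps = np.array([params.lj_params(frag.kind, a.element)[0] for a in frag.atoms])
    sig = np.array([params.lj_params(frag.kind, a.element)[1] for a in frag.atoms])
    return pos, q, eps, sig


def _pair_energy(pos_a, q_a, eps_a, sig_a, pos_b, q_b, eps_b, sig_b) -> float:
    diff = pos_a[:, None, :] - pos_b[None, :, :]
    r = np.sqrt((diff**2).sum(axis=-1))
    coulomb = COULOMB_KCAL * (q_a[:, None] * q_b[None, :] / r).sum()
    eps = np.sqrt(eps_a[:, None] * eps_b[None, :])
    sig = 0.5 * (sig_a[:, None] + sig_b[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        sr6 = np.where(eps > 0, (sig / r) ** 6, 0.0)
    lj = (4.0 * eps * (sr6**2 - sr6)).sum()
    return float(coulomb + lj)


def _charge_centroid(pos: np.ndarray, q: np.ndarray) -> np.ndarray:
    w = np.abs(q)
    if w.sum() <= 0:
        return pos.mean(axis=0)
    return (pos * w[:, None]).sum(axis=0) / w.sum()


def surrogate_energy(
    model: ComplexModel, selector: SubsystemSelector, params: SurrogateParameters
) -> float:
    """Surrogate total energy (kcal/mol) of the selected fragments.

    Intra-fragment terms are excluded (rigid fragments), so a single
    fragment has energy 0 exactly.  With ``polarization_strength = 0`` the
    result is the plain sum of inter-fragment pair energies.
    """
    selector.validate(model)
    indices = selector.fragment_indices
    if not indices:
        warnings.warn("empty subsystem selector: energy is 0 by convention", stacklevel=2)
        return 0.0
    arrays = {i: _fragment_arrays(model, i, params) for i in indices}
    energy = 0.0
    for a_pos, a in enumerate(indices):
        for b in indices[a_pos + 1 :]:
            energy += _pair_energy(*arrays[a], *arrays[b])

    alpha = params.polarization_strength
    if alpha > 0 and len(indices) > 1:
        for f in indices:
            if model.fragments[f].kind == "cation":
                continue
            pos_f, q_f, _, _ = arrays[f]
            centroid = _charge_centroid(pos_f, q_f)
            field_vec = np.zeros(3)
            for g in indices:
                if g == f:
                    continue
                pos_g, q_g, _, _ = arrays[g]
                diff = centroid[None, :] - pos_g
                r3 = (diff**2).sum(axis=-1) ** 1.5
                field_vec += (q_g[:, None] * diff / r3[:, None]).sum(axis=0)
            energy -= 0.5 * alpha * COULOMB_KCAL * float(field_vec @ field_vec)
    return energy


@dataclass
class EnergyTable:
    """Subsystem label → total energy (kcal/mol) mapping.

    Canonical labels follow the ASCII rendering of the complex notation,
    e.g. ``Na+2W@3Bz-9W``, ``Na+@2Bz``, ``3Bz``, ``2W-9W``, ``Na+-2W-9W``,
    ``Bz``, ``W``, ``Na+`` (see the decomposition module for the grammar).
    """

    energies: dict[str, float]

    def __post_init__(self):
        for label, value in self.energies.items():
            if not math.isfinite(value):
                raise ValueError(f"non-finite energy for label {label!r}")

    @classmethod
    def from_csv(cls, path) -> "EnergyTable":
        df = pd.read_csv(path)
        expected = {"label", "energy_kcal_mol"}
        if not expected.issubset(df.columns):
            raise ValueError(f"energy table CSV must have columns {sorted(expected)}")
        if df["label"].duplicated().any():
            dupes = df.loc[df["label"].duplicated(), "label"].tolist()
            raise ValueError(f"duplicate labels in energy table: {dupes}")
        return cls(dict(zip(df["label"], df["energy_kcal_mol"].astype(float))))

    @classmethod
    def from_json(cls, path) -> "EnergyTable":
        return cls({str(k): float(v) for k, v in json.loads(Path(path).read_text()).items()})

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {"label": list(self.energies), "energy_kcal_mol": list(self.energies.values())}
        )
        df.to_csv(path, index=False, float_format="%.10f")


def tabulated_energy(table: EnergyTable, label: str) -> float:
    """Stored total energy for ``label``; unknown labels raise with hints."""
    try:
        return table.energies[label]
    except KeyError:
        close = difflib.get_close_matches(label, table.energies, n=3, cutoff=0.4)
        hint = f"; closest canonical labels: {close}" if close else ""
        raise KeyError(f"no energy tabulated for label {label!r}{hint}") from None


def _displace_rings(model: ComplexModel, d: float) -> ComplexModel:
    """Move each ring (with its attached waters) radially to centroid distance d."""
    cation_pos = model.fragments[model.cation_index].atoms[0].position
    shifts = {}
    for i, frag in enumerate(model.fragments):
        if frag.kind != "benzene":
            continue
        out = frag.heavy_centroid() - cation_pos
        d_cur = np.linalg.norm(out)
        shifts[i] = (d - d_cur) * out / d_cur
    new_fragments = []
    for i, frag in enumerate(model.fragments):
        if i in shifts:
            new_fragments.append(frag.translated(shifts[i]))
        elif frag.attached_to in shifts:
            new_fragments.append(frag.translated(shifts[frag.attached_to]))
        else:
            new_fragments.append(frag)
    return ComplexModel(model.cation_species, tuple(new_fragments))


def rigid_scan(
    model: ComplexModel, grid, params: SurrogateParameters
) -> tuple[float, float]:
    """1-D rigid scan of the cation–centroid distance over ``grid`` (Å).

    All rings (plus their attached waters) are displaced radially as rigid
    bodies; returns ``(d*, E(d*))`` at the grid minimum, ties broken toward
    the smaller distance.
    """
    grid = [float(d) for d in grid]
    if not grid:
        raise ValueError("scan grid must be non-empty")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("scan grid must be strictly increasing")
    selector = SubsystemSelector(tuple(range(len(model.fragments))))
    best_d, best_e = None, math.inf
    for d in grid:  # increasing order + strict improvement ⇒ ties keep smaller d
        e = surrogate_energy(_displace_rings(model, d), selector, params)
        if e < best_e:
            best_d, best_e = d, e
    return best_d, best_e
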