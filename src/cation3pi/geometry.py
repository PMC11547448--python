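"""Cartesian builders for cation⊗Nπ complexes and their hydration shells.

A cation⊗3π complex is one alkali cation (Li⁺, Na⁺ or K⁺) held inside a
triangular arrangement of three benzene rings — the idealised "aromatic box"
motif.  Water molecules can be attached at three canonical hydration sites:

* ``coordinated`` — bound directly to the cation (first solvation shell),
* ``hollow``      — above a ring centroid, on the face away from the cation,
* ``bridge``      — above the midpoint of a ring C–C bond, same face.

All builders work in Å, in a right-handed frame with the cation at the
origin and the three-fold symmetry axis along +z.  Ring centroids sit in the
xy-plane with the ring normals passing through the cation, so the "outer"
face of each ring points radially away from the axis.

Complexes are frozen-geometry objects: adding hydration never moves atoms
that already exist, mirroring the rigid-scaffold convention under which the
benzene/cation framework is kept at its gas-phase arrangement while waters
are attached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Atom",
    "Fragment",
    "ComplexModel",
    "BoxParameters",
    "make_benzene",
    "make_water",
    "build_triangular_box",
    "add_hydration",
    "DEFAULT_D_CENTROID",
    "DEFAULT_O_CATION_DISTANCE",
]

ALLOWED_ELEMENTS = frozenset({"Li", "Na", "K", "C", "H", "O"})
CATION_ELEMENTS = frozenset({"Li", "Na", "K"})
SITE_LABELS = ("none", "coordinated", "hollow", "bridge")

# Standard gas-phase benzene monomer geometry.
R_CC = 1.397  # ring radius == C-C neighbour distance for a regular hexagon, Å
R_CH = 1.087  # C-H bond length, Å
R_H = R_CC + R_CH  # H distance from the ring centroid, Å

# Rigid water monomer.
R_OH = 0.9572  # Å
ANGLE_HOH = 104.52  # degrees

#: Default cation–centroid distances (Å) for the triangular box, per cation.
DEFAULT_D_CENTROID = {"Li": 2.5, "Na": 2.6, "K": 2.9}

#: Default O–M⁺ distance (Å) for coordinated waters, per cation.
DEFAULT_O_CATION_DISTANCE = {"Li": 1.9, "Na": 2.3, "K": 2.7}

#: Default O heights above the ring plane for benzene-face waters, Å.
DEFAULT_HOLLOW_HEIGHT = 3.2
DEFAULT_BRIDGE_HEIGHT = 3.3

# Coordinated waters go axially through the two open ends of the box (±z):
# the polar axis is the only uncrowded direction once three rings occupy
# the equator, and M⁺(H₂O)₂ is near-linear for the alkali cations anyway.


@dataclass(frozen=True)
class Atom:
    """One atom: chemical symbol plus Cartesian position in Å."""

    element: str
    position: np.ndarray

    def __post_init__(self):
        if self.element not in ALLOWED_ELEMENTS:
            raise ValueError(f"unsupported element {self.element!r}")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"position must be a finite 3-vector, got {self.position!r}")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class Fragment:
    """A rigid molecular unit: the cation, one benzene, or one water.

    ``site_label`` records the hydration site for waters (``none`` for
    anything else); ``attached_to`` is the index of the fragment the water
    hydrates (its benzene for hollow/bridge, the cation for coordinated),
    used when a benzene is removed together with "its" waters.
    """

    kind: str
    atoms: tuple[Atom, ...]
    site_label: str = "none"
    attached_to: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(self.atoms))
        if self.site_label not in SITE_LABELS:
            raise ValueError(f"unknown site label {self.site_label!r}")
        if self.kind == "cation":
            if len(self.atoms) != 1 or self.atoms[0].element not in CATION_ELEMENTS:
                raise ValueError("cation fragment must be a single Li/Na/K atom")
        elif self.kind == "benzene":
            elems = sorted(a.element for a in self.atoms)
            if len(self.atoms) != 12 or elems != ["C"] * 6 + ["H"] * 6:
                raise ValueError("benzene fragment must contain 6 C and 6 H atoms")
        elif self.kind == "water":
            elems = sorted(a.element for a in self.atoms)
            if elems != ["H", "H", "O"]:
                raise ValueError("water fragment must contain 1 O and 2 H atoms")
        else:
            raise ValueError(f"unknown fragment kind {self.kind!r}")
        if self.kind != "water" and self.site_label != "none":
            raise ValueError("site_label is only meaningful for water fragments")

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def heavy_centroid(self) -> np.ndarray:
        """Centroid of non-hydrogen atoms (ring centroid for benzene)."""
        pts = [a.position for a in self.atoms if a.element != "H"]
        return np.mean(pts, axis=0)

    def translated(self, shift: np.ndarray) -> "Fragment":
        shift = np.asarray(shift, dtype=float)
        return replace(
            self, atoms=tuple(Atom(a.element, a.position + shift) for a in self.atoms)
        )


@dataclass(frozen=True)
class ComplexModel:
    """A (M⁺-mW)⊗NBz-Nn'W complex: cation + N benzenes + m + N·n waters.

    ``m`` is the number of cation-coordinated waters (0 or 2); ``n`` the
    per-benzene water count (0–3).  Benzene waters are attached to their
    ring, so removing one ring removes its n waters with it.
    """

    cation_species: str
    fragments: tuple[Fragment, ...]
    permissive: bool = field(default=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "fragments", tuple(self.fragments))
        cations = [f for f in self.fragments if f.kind == "cation"]
        if not self.permissive:
            if len(cations) != 1:
                raise ValueError(f"expected exactly one cation fragment, got {len(cations)}")
            if cations[0].atoms[0].element != self.cation_species:
                raise ValueError("cation_species does not match the cation fragment")
            if self.n_benzene not in (2, 3):
                raise ValueError(f"expected 2 or 3 benzene fragments, got {self.n_benzene}")
            if self.m not in (0, 2):
                raise ValueError(f"m (coordinated waters) must be 0 or 2, got {self.m}")
            n_waters = sum(1 for f in self.fragments if f.kind == "water")
            if n_waters != self.m + self.n_benzene * self.n:
                raise ValueError("water count inconsistent with m + n_benzene*n")

    @property
    def n_benzene(self) -> int:
        return sum(1 for f in self.fragments if f.kind == "benzene")

    @property
    def m(self) -> int:
        return sum(1 for f in self.fragments if f.site_label == "coordinated")

    @property
    def n(self) -> int:
        ring_waters = [f for f in self.fragments if f.site_label in ("hollow", "bridge")]
        if self.n_benzene == 0:
            return 0
        n, rem = divmod(len(ring_waters), self.n_benzene)
        if rem and not self.permissive:
            raise ValueError("benzene waters are not evenly distributed over rings")
        return n

    def fragment_indices(self, kind: str) -> list[int]:
        return [i for i, f in enumerate(self.fragments) if f.kind == kind]

    @property
    def cation_index(self) -> int:
        return self.fragment_indices("cation")[0]

    def all_positions(self) -> np.ndarray:
        return np.vstack([f.positions for f in self.fragments])

    def n_atoms(self) -> int:
        return sum(len(f.atoms) for f in self.fragments)


@dataclass(frozen=True)
class BoxParameters:
    """Rigid placement parameters for the triangular benzene box.

    d_centroid : cation-to-ring-centroid distance, Å (> 0)
    tilt       : angle between each ring normal and the cation→centroid
                 axis, degrees (0 ⇒ normals pass through the cation)
    twist      : in-plane rotation of each ring, degrees
    """

    d_centroid: float
    tilt: float = 0.0
    twist: float = 0.0

    def __post_init__(self):
        if not self.d_centroid > 0:
            raise ValueError(f"d_centroid must be positive, got {self.d_centroid}")
        for name in ("tilt", "twist"):
            v = getattr(self, name)
            if not (0.0 <= v < 360.0):
                raise ValueError(f"{name} must lie in [0, 360), got {v}")


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if abs(norm - 1.0) > 1e-8:
        raise ValueError(f"{what} must have unit length (|v| = {norm:.6g})")
    return v / norm


def _orthonormal_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane perpendicular to ``normal``."""
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, normal)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = seed - np.dot(seed, normal) * normal
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return u, v


def make_benzene(centroid, normal, twist: float = 0.0) -> Fragment:
    """Regular-hexagon benzene in the plane through ``centroid`` ⟂ ``normal``.

    Carbons sit at radius 1.397 Å from the centroid, hydrogens collinear
    outward at 2.484 Å.  ``twist`` rotates the ring in its own plane.
    """
    centroid = np.asarray(centroid, dtype=float)
    normal = _unit(normal, "normal")
    u, v = _orthonormal_frame(normal)
    atoms = []
    for k in range(6):
        theta = math.radians(twist + 60.0 * k)
        direction = math.cos(theta) * u + math.sin(theta) * v
        atoms.append(Atom("C", centroid + R_CC * direction))
        atoms.append(Atom("H", centroid + R_H * direction))
    return Fragment("benzene", tuple(atoms))


def make_water(
    o_position,
    oh_direction,
    plane_normal,
    site_label: str = "none",
    attached_to: int | None = None,
) -> Fragment:
    """Rigid water with O at ``o_position`` and one O–H along ``oh_direction``.

    The second hydrogen is placed at the H-O-H angle of 104.52° from the
    first, in the plane spanned by ``oh_direction`` and its component
    perpendicular to ``plane_normal``.
    """
    o = np.asarray(o_position, dtype=float)
    d1 = _unit(oh_direction, "oh_direction")
    pn = _unit(plane_normal, "plane_normal")
    perp = np.cross(pn, d1)
    nrm = np.linalg.norm(perp)
    if nrm < 1e-8:
        raise ValueError("plane_normal must not be parallel to oh_direction")
    perp /= nrm
    ang = math.radians(ANGLE_HOH)
    d2 = math.cos(ang) * d1 + math.sin(ang) * perp
    atoms = (
        Atom("O", o),
        Atom("H", o + R_OH * d1),
        Atom("H", o + R_OH * d2),
    )
    return Fragment("water", atoms, site_label=site_label, attached_to=attached_to)


def build_triangular_box(cation_species: str, params: BoxParameters) -> ComplexModel:
    """Cation at the origin inside three benzenes related by 120° about +z.

    Ring centroids are placed at ``params.d_centroid`` from the origin in
    the xy-plane; with ``tilt = 0`` each ring normal points at the cation,
    so the complex is exactly C3-symmetric by construction.
    """
    if cation_species not in CATION_ELEMENTS:
        raise ValueError(f"cation_species must be one of Li/Na/K, got {cation_species!r}")
    cation = Fragment("cation", (Atom(cation_species, np.zeros(3)),))
    fragments = [cation]
    tilt = math.radians(params.tilt)
    for k in range(3):
        phi = math.radians(120.0 * k)
        radial = np.array([math.cos(phi), math.sin(phi), 0.0])
        tangent = np.array([-math.sin(phi), math.cos(phi), 0.0])
        centroid = params.d_centroid * radial
        # tilt rotates the inward-pointing normal about the ring's in-plane
        # tangent axis; tilt=0 leaves it aimed at the cation.
        normal = -math.cos(tilt) * radial + math.sin(tilt) * np.array([0.0, 0.0, 1.0])
        del tangent
        fragments.append(make_benzene(centroid, normal, twist=params.twist))
    return ComplexModel(cation_species, tuple(fragments))


def _ring_outward(model: ComplexModel, benzene: Fragment) -> np.ndarray:
    """Unit vector from the cation through the ring centroid (outer face)."""
    cation_pos = model.fragments[model.cation_index].atoms[0].position
    out = benzene.heavy_centroid() - cation_pos
    return out / np.linalg.norm(out)


def add_hydration(
    model: ComplexModel,
    site: str,
    count_per_target: int,
    o_distance: float | None = None,
) -> ComplexModel:
    """Attach waters at one hydration site, leaving existing atoms untouched.

    ``coordinated`` places ``count_per_target`` (= 2) waters on the cation,
    one through each open end of the box (±z), hydrogens pointing away from
    the cation.  ``hollow`` puts one water above each ring centroid on the outer
    face, one O–H aimed at the centroid.  ``bridge`` puts waters above C–C
    bond midpoints of each ring, outer face.  ``o_distance`` overrides the
    default O–cation distance (coordinated) or O height (hollow/bridge).
    """
    if site not in ("coordinated", "hollow", "bridge"):
        raise ValueError(f"unknown hydration site {site!r}")
    if count_per_target < 1:
        raise ValueError("count_per_target must be >= 1")
    new_fragments = list(model.fragments)

    if site == "coordinated":
        if count_per_target != 2:
            raise ValueError("coordinated hydration uses exactly 2 waters on the cation")
        d = o_distance if o_distance is not None else DEFAULT_O_CATION_DISTANCE[model.cation_species]
        cation_idx = model.cation_index
        cation_pos = model.fragments[cation_idx].atoms[0].position
        for sign in (-1.0, +1.0):
            u = np.array([0.0, 0.0, sign])
            o = cation_pos + d * u
            # H bisector along u (away from the cation): aim the first O-H
            # half the H-O-H angle off the bisector, in the u/z plane.
            rot = math.radians(ANGLE_HOH / 2.0)
            perp = np.cross(np.array([0.0, 1.0, 0.0]), u)
            perp /= np.linalg.norm(perp)
            d1 = math.cos(rot) * u + math.sin(rot) * perp
            new_fragments.append(
                make_water(o, d1, np.array([0.0, 1.0, 0.0]),
                           site_label="coordinated", attached_to=cation_idx)
            )
        return ComplexModel(model.cation_species, tuple(new_fragments))

    if site == "hollow" and count_per_target != 1:
        raise ValueError("hollow hydration allows one water per ring face")
    if site == "bridge" and count_per_target > 3:
        raise ValueError("at most 3 bridge waters per ring")

    height = o_distance if o_distance is not None else (
        DEFAULT_HOLLOW_HEIGHT if site == "hollow" else DEFAULT_BRIDGE_HEIGHT
    )
    for idx, frag in enumerate(model.fragments):
        if frag.kind != "benzene":
            continue
        outward = _ring_outward(model, frag)
        centroid = frag.heavy_centroid()
        if site == "hollow":
            anchors = [centroid]
        else:
            carbons = [a.position for a in frag.atoms if a.element == "C"]
            # midpoints of opposite ring bonds: (C0,C1), (C3,C4), (C1,C2)
            bond_pairs = [(0, 1), (3, 4), (1, 2)][:count_per_target]
            anchors = [(carbons[i] + carbons[j]) / 2.0 for i, j in bond_pairs]
        zhat = np.array([0.0, 0.0, 1.0])
        plane_normal = np.cross(outward, zhat)
        plane_normal /= np.linalg.norm(plane_normal)
        for anchor in anchors:
            o = anchor + height * outward
            new_fragments.append(
                make_water(o, -outward, plane_normal, site_label=site, attached_to=idx)
            )
    return ComplexModel(model.cation_species, tuple(new_fragments))
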