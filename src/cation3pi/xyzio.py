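"""XYZ and extended-XYZ reading/writing.

Standard two-header-line XYZ dialect.  For complexes, the comment line
carries the fragment structure as semicolon-separated ``key=value`` tokens::

    21
    cation=Na;m=0;n=0;fragments=cation:1:none:-1,benzene:12:none:-1,...
    Na 0.0000000000 0.0000000000 0.0000000000
    ...

Each ``fragments`` entry is ``kind:natoms:site_label:attached_to`` (−1 for
no attachment).  Files without recognised metadata are segmented by atomic
composition: Li/Na/K → cation, a C followed by 11 ring atoms → benzene,
O H H → water.

Trajectories are concatenated XYZ blocks (extended-XYZ accepted: per-atom
extra columns and ``Lattice=...`` tokens are ignored); the frame time in ps
is read from a ``time=<ps>`` token on the comment line.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterator

import numpy as np

from .geometry import ALLOWED_ELEMENTS, Atom, ComplexModel, Fragment

__all__ = ["read_xyz", "write_xyz", "read_xyz_frames", "write_xyz_frames", "XYZFormatError"]

_FLOAT_FMT = "%.10f"

# trajectories may carry aromatic-ring nitrogens (e.g. tryptophan indole)
TRAJ_ELEMENTS = ALLOWED_ELEMENTS | {"N"}


class XYZFormatError(ValueError):
    """Malformed XYZ input; message names the offending line."""


def _parse_atom_lines(
    lines: list[str], start_line: int, allowed: frozenset | set = ALLOWED_ELEMENTS
) -> tuple[list[str], np.ndarray]:
    elements: list[str] = []
    coords: list[list[float]] = []
    for off, raw in enumerate(lines):
        toks = raw.split()
        lineno = start_line + off
        if len(toks) < 4:
            raise XYZFormatError(f"line {lineno}: expected 'element x y z', got {raw!r}")
        el = toks[0].capitalize() if len(toks[0]) > 1 else toks[0].upper()
        if el not in allowed:
            raise XYZFormatError(f"line {lineno}: unknown element {toks[0]!r}")
        try:
            xyz = [float(t) for t in toks[1:4]]
        except ValueError as exc:
            raise XYZFormatError(f"line {lineno}: bad coordinate in {raw!r}") from exc
        elements.append(el)
        coords.append(xyz)
    return elements, np.array(coords).reshape(-1, 3)


def _parse_comment_tokens(comment: str) -> dict[str, str]:
    meta: dict[str, str] = {}
    for token in comment.strip().split(";"):
        if "=" in token:
            key, _, value = token.partition("=")
            meta[key.strip()] = value.strip()
    return meta


def _segment_by_composition(
    elements: list[str], coords: np.ndarray
) -> list[Fragment]:
    """Greedy in-order segmentation of a bare atom list into fragments."""
    fragments: list[Fragment] = []
    i, n = 0, len(elements)
    while i < n:
        el = elements[i]
        if el in ("Li", "Na", "K"):
            fragments.append(Fragment("cation", (Atom(el, coords[i]),)))
            i += 1
        elif el == "C":
            block = elements[i : i + 12]
            if sorted(block) != ["C"] * 6 + ["H"] * 6:
                raise XYZFormatError(
                    f"atom {i + 1}: carbon not part of a recognisable C6H6 block"
                )
            atoms = tuple(Atom(e, coords[j]) for j, e in zip(range(i, i + 12), block))
            fragments.append(Fragment("benzene", atoms))
            i += 12
        elif el == "O":
            block = elements[i : i + 3]
            if block != ["O", "H", "H"]:
                raise XYZFormatError(f"atom {i + 1}: oxygen not part of an O H H block")
            atoms = tuple(Atom(e, coords[j]) for j, e in zip(range(i, i + 3), block))
            fragments.append(Fragment("water", atoms))
            i += 3
        else:
            raise XYZFormatError(f"atom {i + 1}: stray {el} atom outside any fragment")
    return fragments


def read_xyz(path, permissive: bool = False) -> ComplexModel:
    """Read one complex from an XYZ file.

    With fragment metadata on the comment line the exact fragment structure
    (kinds, site labels, attachments) is restored; otherwise fragments are
    inferred from atomic composition.  ``permissive=True`` skips the
    complex-level invariants (one cation, 2–3 benzenes, water bookkeeping).
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise XYZFormatError("line 1: empty file")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise XYZFormatError(f"line 1: malformed atom-count line {lines[0]!r}") from exc
    if len(lines) < 2 + count:
        raise XYZFormatError(f"line {len(lines)}: expected {count} atom lines, file truncated")
    comment = lines[1]
    elements, coords = _parse_atom_lines(lines[2 : 2 + count], start_line=3)

    meta = _parse_comment_tokens(comment)
    if "fragments" in meta:
        fragments: list[Fragment] = []
        cursor = 0
        for entry in meta["fragments"].split(","):
            try:
                kind, natoms_s, site, attached_s = entry.split(":")
                natoms, attached = int(natoms_s), int(attached_s)
            except ValueError as exc:
                raise XYZFormatError(f"line 2: bad fragment entry {entry!r}") from exc
            atoms = tuple(
                Atom(elements[j], coords[j]) for j in range(cursor, cursor + natoms)
            )
            fragments.append(
                Fragment(kind, atoms, site_label=site,
                         attached_to=None if attached < 0 else attached)
            )
            cursor += natoms
        if cursor != count:
            raise XYZFormatError("line 2: fragment metadata does not cover all atoms")
    else:
        fragments = _segment_by_composition(elements, coords)

    cation_frags = [f for f in fragments if f.kind == "cation"]
    species = meta.get("cation") or (
        cation_frags[0].atoms[0].element if cation_frags else "Na"
    )
    return ComplexModel(species, tuple(fragments), permissive=permissive)


def write_xyz(model: ComplexModel, path) -> None:
    """Write a complex as XYZ with full fragment metadata on line 2."""
    entries = []
    for frag in model.fragments:
        att = -1 if frag.attached_to is None else frag.attached_to
        entries.append(f"{frag.kind}:{len(frag.atoms)}:{frag.site_label}:{att}")
    comment = (
        f"cation={model.cation_species};m={model.m};n={model.n};"
        f"fragments={','.join(entries)}"
    )
    lines = [str(model.n_atoms()), comment]
    for frag in model.fragments:
        for atom in frag.atoms:
            x, y, z = atom.position
            lines.append(
                f"{atom.element} {_FLOAT_FMT % x} {_FLOAT_FMT % y} {_FLOAT_FMT % z}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


_TIME_RE = re.compile(r"\btime=([-+0-9.eE]+)")


def read_xyz_frames(path) -> Iterator[tuple[float | None, list[str], np.ndarray]]:
    """Iterate over (time_ps, elements, positions) frames of a trajectory.

    ``time_ps`` is None when the comment line carries no ``time=`` token.
    """
    lines = Path(path).read_text().splitlines()
    i, frame = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].split()[0])
        except ValueError as exc:
            raise XYZFormatError(
                f"line {i + 1}: malformed atom-count line {lines[i]!r}"
            ) from exc
        if i + 2 + count > len(lines):
            raise XYZFormatError(f"frame {frame}: truncated at line {i + 1}")
        match = _TIME_RE.search(lines[i + 1])
        time_ps = float(match.group(1)) if match else None
        elements, coords = _parse_atom_lines(
            lines[i + 2 : i + 2 + count], start_line=i + 3, allowed=TRAJ_ELEMENTS
        )
        yield time_ps, elements, coords
        i += 2 + count
        frame += 1


def write_xyz_frames(frames, path) -> None:
    """Write (time_ps, elements, positions) triples as an extended-XYZ file."""
    out: list[str] = []
    for time_ps, elements, coords in frames:
        out.append(str(len(elements)))
        out.append(f"time={_FLOAT_FMT % time_ps}" if time_ps is not None else "")
        for el, (x, y, z) in zip(elements, np.asarray(coords, dtype=float)):
            out.append(f"{el} {_FLOAT_FMT % x} {_FLOAT_FMT % y} {_FLOAT_FMT % z}")
    Path(path).write_text("\n".join(out) + "\n")
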