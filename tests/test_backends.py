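"""Surrogate potential physics and the tabulated-energy contract."""

import math

import numpy as np
import pytest

from cation3pi import (
    Atom,
    ComplexModel,
    EnergyTable,
    Fragment,
    SubsystemSelector,
    SurrogateParameters,
    add_hydration,
    rigid_scan,
    surrogate_energy,
    tabulated_energy,
)
from cation3pi.backends import COULOMB_KCAL

from conftest import random_rotation


def brute_force_energy(model, indices, params):
    """Independent oracle: explicit double loop over inter-fragment atom pairs."""
    total = 0.0
    for ai, a in enumerate(indices):
        for b in indices[ai + 1 :]:
            fa, fb = model.fragments[a], model.fragments[b]
            for atom_a in fa.atoms:
                for atom_b in fb.atoms:
                    r = math.dist(atom_a.position, atom_b.position)
                    qa = params.charge(fa.kind, atom_a.element)
                    qb = params.charge(fb.kind, atom_b.element)
                    total += COULOMB_KCAL * qa * qb / r
                    ea, sa = params.lj_params(fa.kind, atom_a.element)
                    eb, sb = params.lj_params(fb.kind, atom_b.element)
                    eps, sig = math.sqrt(ea * eb), 0.5 * (sa + sb)
                    if eps > 0:
                        total += 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6)
    return total


def test_single_fragment_energy_is_zero(na_box):
    params = SurrogateParameters()
    assert surrogate_energy(na_box, SubsystemSelector((1,)), params) == 0.0


def test_empty_selector_warns_and_returns_zero(na_box):
    with pytest.warns(UserWarning, match="empty subsystem"):
        assert surrogate_energy(na_box, SubsystemSelector(()), SurrogateParameters()) == 0.0


def _two_point_charges(distance):
    """Cation (+1) and a bare −1 'oxygen' with all 12-6 terms disabled."""
    cation = Fragment("cation", (Atom("Na", np.zeros(3)),))
    water = Fragment(
        "water",
        (
            Atom("O", np.array([distance, 0.0, 0.0])),
            Atom("H", np.array([distance + 50.0, 0.0, 0.0])),
            Atom("H", np.array([distance, 50.0, 0.0])),
        ),
    )
    params = SurrogateParameters(
        charges={("cation", "Na"): 1.0, ("water", "O"): -1.0, ("water", "H"): 0.0},
        lj={("cation", "Na"): (0.0, 0.0), ("water", "O"): (0.0, 0.0), ("water", "H"): (0.0, 0.0)},
    )
    model = ComplexModel("Na", (cation, water), permissive=True)
    return model, params


def test_coulomb_closed_form_two_unit_charges():
    model, params = _two_point_charges(3.320637)
    e = surrogate_energy(model, SubsystemSelector((0, 1)), params)
    assert e == pytest.approx(-100.0, abs=1e-9)


@pytest.mark.parametrize("seed", [0, 1])
def test_three_fragment_energy_matches_brute_force_pair_sum(na_box, seed):
    params = SurrogateParameters()
    rng = np.random.default_rng(seed)
    indices = tuple(rng.choice(4, size=3, replace=False))
    fast = surrogate_energy(na_box, SubsystemSelector(indices), params)
    slow = brute_force_energy(na_box, indices, params)
    assert fast == pytest.approx(slow, abs=1e-8)


def test_rigid_body_motion_leaves_energy_unchanged(na_box):
    params = SurrogateParameters(polarization_strength=0.3)
    sel = SubsystemSelector(tuple(range(4)))
    e0 = surrogate_energy(na_box, sel, params)
    rng = np.random.default_rng(11)
    for _ in range(3):
        rot = random_rotation(rng)
        shift = rng.normal(scale=5.0, size=3)
        moved = ComplexModel(
            "Na",
            tuple(
                Fragment(
                    f.kind,
                    tuple(Atom(a.element, rot @ a.position + shift) for a in f.atoms),
                    f.site_label,
                    f.attached_to,
                )
                for f in na_box.fragments
            ),
        )
        assert surrogate_energy(moved, sel, params) == pytest.approx(e0, abs=1e-9)


def _additivity_gap(model, params):
    """E(ABC) − [E(AB)+E(AC)+E(BC)] with all monomer energies zero."""
    trip = surrogate_energy(model, SubsystemSelector((0, 1, 2)), params)
    pair_sum = sum(
        surrogate_energy(model, SubsystemSelector(p), params)
        for p in [(0, 1), (0, 2), (1, 2)]
    )
    return trip - pair_sum


def test_pairwise_additivity_holds_then_breaks_with_polarization(na_box):
    assert _additivity_gap(na_box, SurrogateParameters()) == pytest.approx(0.0, abs=1e-10)
    gaps = [
        abs(_additivity_gap(na_box, SurrogateParameters(polarization_strength=a)))
        for a in (0.1, 0.5, 1.0)
    ]
    assert all(g > 1e-6 for g in gaps)
    assert gaps[0] < gaps[1] < gaps[2]


def test_tabulated_energy_is_a_pure_lookup_and_names_near_misses():
    table = EnergyTable({"Bz": -0.0, "3Bz": -3.0, "Na+@3Bz": -10.0})
    assert tabulated_energy(table, "Bz") == 0.0
    assert tabulated_energy(table, "Na+@3Bz") == -10.0
    with pytest.raises(KeyError, match="Na\\+@3Bz"):
        tabulated_energy(table, "Na+@3Bz-3W")


def test_energy_table_csv_round_trip(tmp_path):
    table = EnergyTable({"Bz": 0.0, "Na+@3Bz": -10.123456789})
    path = tmp_path / "energies.csv"
    table.to_csv(path)
    back = EnergyTable.from_csv(path)
    assert back.energies["Na+@3Bz"] == pytest.approx(-10.123456789, abs=1e-9)
    assert set(back.energies) == set(table.energies)


def test_rigid_scan_matches_brute_force_argmin(na_box):
    params = SurrogateParameters()
    grid = [round(2.0 + 0.1 * k, 1) for k in range(21)]
    d_star, e_star = rigid_scan(na_box, grid, params)

    from cation3pi.backends import _displace_rings

    sel = SubsystemSelector(tuple(range(4)))
    energies = [surrogate_energy(_displace_rings(na_box, d), sel, params) for d in grid]
    assert d_star == grid[int(np.argmin(energies))]
    assert e_star == pytest.approx(min(energies), abs=1e-10)


def test_rigid_scan_moves_attached_waters_with_their_ring(na_box):
    hydrated = add_hydration(na_box, "hollow", 1)
    params = SurrogateParameters()
    from cation3pi.backends import _displace_rings

    moved = _displace_rings(hydrated, 3.0)
    for frag in moved.fragments:
        if frag.kind == "water":
            ring = moved.fragments[frag.attached_to]
            d = np.linalg.norm(frag.atoms[0].position - ring.heavy_centroid())
            assert d == pytest.approx(3.2, abs=1e-9)
    del params


def test_rigid_scan_tie_breaks_toward_smaller_distance(na_box):
    # all-zero parameters give a flat scan: every grid point ties at 0
    flat = SurrogateParameters(
        charges={k: 0.0 for k in SurrogateParameters().charges},
        lj={k: (0.0, 0.0) for k in SurrogateParameters().lj},
    )
    d_star, e_star = rigid_scan(na_box, [2.0, 3.0, 4.0], flat)
    assert d_star == 2.0 and e_star == 0.0


def test_rigid_scan_rejects_bad_grids(na_box):
    with pytest.raises(ValueError):
        rigid_scan(na_box, [], SurrogateParameters())
    with pytest.raises(ValueError):
        rigid_scan(na_box, [3.0, 2.0], SurrogateParameters())
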