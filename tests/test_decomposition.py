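"""Subsystem enumeration, OBB energy, five-component decomposition."""

import numpy as np
import pytest

from cation3pi import (
    EnergyTable,
    SurrogateBackend,
    SurrogateParameters,
    TabulatedBackend,
    consistency_report,
    decompose,
    enumerate_subsystems,
    make_pair,
    obb_energy,
    subsystem_label,
)
from cation3pi.decomposition import complex_label
from cation3pi.fixtures import load_table2
from cation3pi.synthetic import build_site_complex

from test_backends import brute_force_energy


def test_label_grammar_concrete_examples():
    assert subsystem_label("Na", 3, 2, 9) == "Na+2W@3Bz-9W"
    assert subsystem_label("Na", 2, 2, 6) == "Na+2W@2Bz-6W"
    assert subsystem_label(None, 3, 0, 0) == "3Bz"
    assert subsystem_label(None, 1, 0, 0) == "Bz"
    assert subsystem_label(None, 0, 2, 9) == "2W-9W"
    assert subsystem_label("Na", 0, 2, 9) == "Na+-2W-9W"
    assert subsystem_label(None, 0, 0, 1) == "W"
    assert subsystem_label(None, 0, 2, 0) == "2W"
    assert subsystem_label("Na", 2, 2, 0, relaxed=True) == "Na+2W@2Bz~opt"


def test_gas_phase_pair_enumerates_six_merged_labels(na_gas_pair):
    labels = {s.label for s in enumerate_subsystems(na_gas_pair)}
    assert labels == {"Na+@3Bz", "Na+@2Bz", "3Bz", "2Bz", "Bz", "Na+"}


def test_hydrated_pair_enumerates_fifteen_distinct_labels():
    pair = make_pair(build_site_complex("K", "total"))  # m=2, n=3
    labels = [s.label for s in enumerate_subsystems(pair)]
    assert len(labels) == len(set(labels)) == 15
    assert "K+2W@3Bz-9W" in labels and "K+2W@2Bz-6W" in labels
    assert "2W-9W" in labels and "K+-2W-6W" in labels


def test_every_selector_is_a_subset_of_its_host_complex(complex_suite):
    for _, _, pair in complex_suite:
        n_full = len(pair.full.fragments)
        for sub in enumerate_subsystems(pair):
            host = pair.full if sub.base == "full" else pair.reference
            assert all(0 <= i < len(host.fragments) for i in sub.selector.fragment_indices)
            if sub.base == "full":
                assert len(set(sub.selector.fragment_indices)) <= n_full


def test_obb_energy_arithmetic_on_a_tabulated_mini_table(na_bridge_pair):
    # n=2 pair: E(full)=-20, E(reduced)=-5, E(Bz)=-1, E(W)=-2
    table = EnergyTable(
        {"Na+@3Bz-6W": -20.0, "Na+@2Bz-4W": -5.0, "Bz": -1.0, "W": -2.0}
    )
    assert obb_energy(na_bridge_pair, TabulatedBackend(table)) == pytest.approx(-10.0)
    zeros = EnergyTable({"Na+@3Bz-6W": 0.0, "Na+@2Bz-4W": 0.0, "Bz": 0.0, "W": 0.0})
    assert obb_energy(na_bridge_pair, TabulatedBackend(zeros)) == 0.0


def test_obb_energy_matches_brute_force_pair_sum(pairwise_backend):
    pair = make_pair(build_site_complex("Na", "hollow"))  # n=1
    e = obb_energy(pair, pairwise_backend)
    # independent oracle: pairs between the removed {benzene + its water}
    # and the rest, plus pairs inside the removed set
    full = pair.full
    removed = [pair.removed_benzene] + [
        i for i, f in enumerate(full.fragments) if f.attached_to == pair.removed_benzene
    ]
    kept = [i for i in range(len(full.fragments)) if i not in removed]
    params = pairwise_backend.params
    expected = 0.0
    for r in removed:
        for k in kept:
            expected += brute_force_energy(full, (r, k), params)
    for i, r in enumerate(removed):
        for r2 in removed[i + 1 :]:
            expected += brute_force_energy(full, (r, r2), params)
    assert e == pytest.approx(expected, abs=1e-8)


def test_decompose_reproduces_the_worked_mini_table(na_gas_pair):
    table = EnergyTable(
        {"Na+@3Bz": -10.0, "Na+@2Bz": -6.0, "3Bz": -3.0, "2Bz": -1.0, "Bz": 0.0, "Na+": 0.0}
    )
    res = decompose(na_gas_pair, TabulatedBackend(table))
    assert res.e_cation_pi == pytest.approx(-2.0)
    assert res.e_pi_pi == pytest.approx(-2.0)
    assert res.e_sum == pytest.approx(-4.0)
    assert res.e_binding == pytest.approx(-4.0)


def test_zero_water_components_vanish_exactly(na_gas_pair, pairwise_backend):
    res = decompose(na_gas_pair, pairwise_backend)
    assert res.e_water_pi == 0.0
    assert res.e_water_water == 0.0
    assert res.e_water_cation == 0.0
    assert res.e_sum == res.e_cation_pi + res.e_pi_pi


def test_component_sum_is_assembled_exactly(complex_suite, pairwise_backend):
    for _, _, pair in complex_suite:
        res = decompose(pair, pairwise_backend)
        resum = (
            res.e_cation_pi + res.e_pi_pi + res.e_water_pi
            + res.e_water_water + res.e_water_cation
        )
        assert res.e_sum == resum  # exact: assembled, not approximated


def test_telescoping_for_pairwise_backend_and_frozen_geometry(
    complex_suite, pairwise_backend
):
    for cation, site, pair in complex_suite:
        res = decompose(pair, pairwise_backend)
        assert abs(res.e_sum - res.e_binding) < 1e-8, (cation, site)


def test_many_body_term_opens_a_monotone_gap():
    pair = make_pair(build_site_complex("Na", "total"))
    gaps = []
    for alpha in (0.1, 0.5, 1.0):
        backend = SurrogateBackend(SurrogateParameters(polarization_strength=alpha))
        res = decompose(pair, backend)
        gaps.append(abs(res.e_sum - res.e_binding))
    assert all(g > 1e-6 for g in gaps)
    assert gaps[0] < gaps[1] < gaps[2]


def test_relaxed_reduced_reference_breaks_the_telescoping(pairwise_backend):
    """The study convention: the OBB reference is separately optimised while
    the component subsystems stay at the frozen scaffold, so the component
    sum no longer telescopes onto the binding energy."""
    full = build_site_complex("Na", "coordinated")
    frozen = make_pair(full)
    # an independently supplied reference: same composition, shifted ring
    shifted = list(frozen.reduced.fragments)
    for i, frag in enumerate(shifted):
        if frag.kind == "benzene":
            shifted[i] = frag.translated(np.array([0.15, 0.0, 0.0]))
            break
    relaxed = type(frozen.reduced)("Na", tuple(shifted))
    pair = make_pair(full, relaxed_reduced=relaxed)
    labels = {s.label for s in enumerate_subsystems(pair)}
    assert "Na+2W@2Bz~opt" in labels  # the relaxed reference is tagged
    res = decompose(pair, pairwise_backend)
    res_frozen = decompose(frozen, pairwise_backend)
    assert abs(res.e_sum - res.e_binding) > 1e-6
    assert res.e_sum == pytest.approx(res_frozen.e_sum)  # components unchanged


def test_consistency_report_flags_large_discrepancies():
    # printed row: Li coordinated, e_sum -5.10 vs e_binding -1.31
    t2 = load_table2().frame
    row = t2[(t2.cation == "Li") & (t2.site == "coordinated")].iloc[0]
    from cation3pi.decomposition import DecompositionResult

    res = DecompositionResult(
        system=row["complex"], cation="Li", m=2, n=0,
        e_cation_pi=row.e_cation_pi, e_pi_pi=row.e_pi_pi,
        e_water_pi=row.e_water_pi, e_water_water=row.e_water_water,
        e_water_cation=row.e_water_cation,
        e_sum=row.e_sum, e_binding=row.e_binding,
    )
    report = consistency_report(res)
    assert report["delta"] == pytest.approx(-3.79, abs=1e-9)
    assert report["flagged"] and report["sign"] == "overestimates"

    exact = DecompositionResult("x", "Na", 0, 0, -1, -2, 0, 0, 0, -3.0, -3.0)
    report = consistency_report(exact)
    assert report["delta"] == 0.0 and not report["flagged"]


def test_decompose_rejects_tables_with_missing_subsystems(na_gas_pair):
    table = EnergyTable({"Na+@3Bz": -10.0, "3Bz": -3.0})
    with pytest.raises(KeyError, match="Na\\+@2Bz"):
        decompose(na_gas_pair, TabulatedBackend(table))


def test_removed_benzene_defaults_to_lowest_index_on_ties(na_gas_pair):
    # the equatorial box puts all three centroids at z = 0: a three-way tie
    assert na_gas_pair.removed_benzene == min(
        na_gas_pair.full.fragment_indices("benzene")
    )


def test_complex_labels_render_like_the_study_notation():
    assert complex_label("Li", 3, 0, 0) == "Li+@3Bz"
    assert complex_label("Na", 3, 2, 3) == "Na+2W@3Bz-9W"
    assert complex_label("K", 3, 0, 2) == "K+@3Bz-6W"
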