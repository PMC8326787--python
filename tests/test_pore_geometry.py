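"""Axis estimation, pore profiles, gate radius, prime notation, hydration."""

import numpy as np
import pytest

import pentagate as pg

from conftest import apply_rigid, random_rigid_motion


# ---------------------------------------------------------------------------
# estimate_pore_axis
# ---------------------------------------------------------------------------

def test_axis_on_ideal_fixture_is_z(ideal_axis):
    assert abs(ideal_axis.direction @ [0, 0, 1] - 1.0) < 1e-12


def test_axis_equivariant_under_rotation(ideal_model):
    rot, trans = random_rigid_motion(np.random.default_rng(2))
    moved = apply_rigid(ideal_model, rot, trans)
    axis = pg.estimate_pore_axis(moved)
    expected = rot @ np.array([0.0, 0.0, 1.0])
    angle = np.arccos(np.clip(axis.direction @ expected, -1, 1))
    assert angle < 1e-6


def test_axis_robust_to_coordinate_noise(ideal_model):
    rng = np.random.default_rng(42)
    noisy = ideal_model.copy()
    noisy.coord = noisy.coord + rng.normal(0.0, 0.1, size=noisy.coord.shape)
    axis = pg.estimate_pore_axis(noisy)
    angle = np.degrees(np.arccos(np.clip(abs(axis.direction[2]), -1, 1)))
    assert angle < 1.0


def test_axis_undetermined_with_single_ring(ideal_model):
    with pytest.raises(pg.GeometryError, match="ring"):
        pg.estimate_pore_axis(ideal_model, pg.Selection.ca((233, 233)))


# ---------------------------------------------------------------------------
# residue_prime
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("residue,prime", [(233, 9), (237, 13), (224, 0),
                                           (222, -2), (247, 23)])
def test_residue_prime_mapping(residue, prime):
    assert pg.residue_prime(residue) == prime


@pytest.mark.parametrize("residue", [221, 248, 35])
def test_residue_prime_out_of_range(residue):
    with pytest.raises(ValueError):
        pg.residue_prime(residue)


# ---------------------------------------------------------------------------
# pore_profile / gate_radius
# ---------------------------------------------------------------------------

def test_profile_recovers_ring_radii_and_z_order(ideal_model, ideal_axis):
    prof = pg.pore_profile(ideal_model, ideal_axis)
    zs = [e.z for e in prof.entries]
    assert zs == sorted(zs)
    for res in (222, 233, 247):
        expected = 2.9 + 0.35 * abs(res - 233)
        assert prof.radius_of(res) == pytest.approx(expected, abs=1e-9)
    e233 = next(e for e in prof.entries if e.residue_number == 233)
    assert e233.prime_index == 9


def test_profile_mean_with_one_perturbed_atom(ideal_model, ideal_axis):
    """One of five ring atoms pushed +1 A radially: radius = mean{...} = r+0.2."""
    model = ideal_model.copy()
    a = model.atoms
    i = model.atom_index("A", 230, "CA")
    xy = model.coord[i, :2]
    model.coord[i, :2] += xy / np.linalg.norm(xy)
    prof = pg.pore_profile(model, pg.PoreAxis(np.zeros(3), [0, 0, 1]),
                           residues=(230, 230))
    base = 2.9 + 0.35 * 3
    assert prof.radius_of(230) == pytest.approx(base + 0.2, abs=1e-9)


def test_profile_excludes_residue_missing_in_two_chains(ideal_model):
    a = ideal_model.atoms
    kill = (
        (a.res_id == 240) & (a.atom_name == "CA")
        & np.isin(a.chain_id, ["A", "B"])
    )
    model = pg.PentamerModel(a[~kill], list(ideal_model.chains),
                             coord=ideal_model.coord[~kill])
    with pytest.warns(UserWarning, match="240"):
        prof = pg.pore_profile(model, pg.PoreAxis(np.zeros(3), [0, 0, 1]))
    assert all(e.residue_number != 240 for e in prof.entries)


def test_gate_radius_default_and_on_axis(ideal_model, ideal_axis):
    assert pg.gate_radius(ideal_model, ideal_axis) == pytest.approx(2.9, abs=1e-9)
    onaxis = ideal_model.copy()
    a = onaxis.atoms
    cb = (a.res_id == 233) & (a.atom_name == "CB")
    onaxis.coord[cb, :2] = 0.0
    assert pg.gate_radius(onaxis, ideal_axis) == pytest.approx(0.0, abs=1e-12)


def test_gate_radius_incomplete_ring_raises(ideal_model, ideal_axis):
    a = ideal_model.atoms
    kill = (a.chain_id == "B") & (a.res_id == 233) & (a.atom_name == "CB")
    model = pg.PentamerModel(a[~kill], list(ideal_model.chains),
                             coord=ideal_model.coord[~kill])
    with pytest.raises(pg.GeometryError, match="incomplete"):
        pg.gate_radius(model, ideal_axis)


def test_gate_radius_ca_consistent_with_profile(ideal_model, ideal_axis):
    prof = pg.pore_profile(ideal_model, ideal_axis)
    ca_gate = pg.gate_radius(ideal_model, ideal_axis, 233, "CA")
    assert ca_gate == pytest.approx(prof.radius_of(233), abs=1e-12)


def test_profile_zero_ring_variance_on_c5_model(ideal_model, ideal_axis):
    a = ideal_model.atoms
    for res in (225, 233, 245):
        mask = ideal_model.protein_mask & (a.res_id == res) & (a.atom_name == "CA")
        r = ideal_axis.radial(ideal_model.coord[mask])
        assert np.ptp(r) < 1e-9


# ---------------------------------------------------------------------------
# water occupancy
# ---------------------------------------------------------------------------

def test_water_occupancy_construction(default_spec):
    spec = pg.SyntheticSpec(n_waters_in_pore=7, n_waters_bulk=3, seed=5)
    model = pg.generate_pentamer(spec)
    axis = pg.estimate_pore_axis(model)
    assert pg.water_occupancy(model, axis) == 7


def test_water_on_bounding_plane_is_counted(ideal_model):
    spec = pg.SyntheticSpec(n_waters_in_pore=1, seed=1)
    model = pg.generate_pentamer(spec)
    axis = pg.estimate_pore_axis(model)
    # move the single pore water exactly onto the upper bounding plane
    from pentagate.pore_geometry import _ring_z

    z_up = max(_ring_z(model, axis, 233), _ring_z(model, axis, 237))
    w = model.water_mask
    model.coord[w] = axis.point + z_up * axis.direction
    assert pg.water_occupancy(model, axis) == 1
    model.coord[w] = axis.point + (z_up + 1e-6) * axis.direction
    assert pg.water_occupancy(model, axis) == 0


def test_water_occupancy_matches_brute_force(ideal_model):
    spec = pg.SyntheticSpec(n_waters_bulk=50, seed=9)
    model = pg.generate_pentamer(spec)
    axis = pg.estimate_pore_axis(model)
    rng = np.random.default_rng(123)
    w = model.water_mask
    model.coord[w] = rng.uniform([-10, -10, -20], [10, 10, 20], size=(50, 3))
    cutoff = 6.0
    from pentagate.pore_geometry import _ring_z

    z1, z2 = sorted((_ring_z(model, axis, 233), _ring_z(model, axis, 237)))
    expected = 0
    for pt in model.coord[w]:
        z = axis.axial(pt)[0]
        r = axis.radial(pt)[0]
        if z1 <= z <= z2 and r <= cutoff:
            expected += 1
    assert pg.water_occupancy(model, axis, radial_cutoff=cutoff) == expected


def test_water_occupancy_no_waters_warns(ideal_model, ideal_axis):
    with pytest.warns(UserWarning, match="no water"):
        assert pg.water_occupancy(ideal_model, ideal_axis) == 0


def test_observables_invariant_under_rigid_motion():
    spec = pg.SyntheticSpec(n_waters_in_pore=5, n_waters_bulk=5, seed=8)
    model = pg.generate_pentamer(spec)
    axis = pg.estimate_pore_axis(model)
    rot, trans = random_rigid_motion(np.random.default_rng(21))
    moved = apply_rigid(model, rot, trans)
    maxis = pg.estimate_pore_axis(moved)
    assert pg.gate_radius(moved, maxis) == pytest.approx(
        pg.gate_radius(model, axis), abs=1e-6
    )
    p0 = pg.pore_profile(model, axis)
    p1 = pg.pore_profile(moved, maxis)
    assert np.allclose([e.radius for e in p0.entries],
                       [e.radius for e in p1.entries], atol=1e-6)
    assert pg.water_occupancy(moved, maxis) == pg.water_occupancy(model, axis)
    assert pg.ecd_spread(moved, maxis) == pytest.approx(
        pg.ecd_spread(model, axis), abs=1e-6
    )
    assert pg.domain_twist(moved) == pytest.approx(
        pg.domain_twist(model), abs=1e-6
    )
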