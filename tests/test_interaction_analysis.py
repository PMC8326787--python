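"""Ion coordination, contact statistics, interface distances, bootstraps."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import pentagate as pg
from pentagate.interaction_analysis import salt_bridge_series

from conftest import apply_rigid, random_rigid_motion


def _one_frame_traj(model):
    return pg.TrajectoryFrameSet(model.copy(), model.coord[None], np.zeros(1))


def _ion_model(distance):
    """One ion placed exactly `distance` from an E35 OE1 atom of chain A."""
    spec = pg.SyntheticSpec(n_ions=1, seed=4)
    model = pg.generate_pentamer(spec)
    oe1 = model.atom_index("A", 35, "OE1")
    ion = model.ion_mask
    direction = np.array([0.0, 0.0, 1.0])
    model.coord[ion] = model.coord[oe1] + distance * direction
    return model


# ---------------------------------------------------------------------------
# ion coordination
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("distance,count", [(4.9, 1), (5.0, 1), (5.1, 0)])
def test_ion_cutoff_boundary_inclusive(distance, count):
    model = _ion_model(distance)
    series = pg.ion_coordination_series(_one_frame_traj(model), stride_ns=None)
    assert series.values[0, 0] == count
    assert series.values[0, 1:].sum() == 0


def test_ion_counts_match_exhaustive_oracle():
    spec = pg.SyntheticSpec(n_ions=20, seed=17)
    model = pg.generate_pentamer(spec)
    rng = np.random.default_rng(99)
    ion = model.ion_mask
    # scatter ions around the E35 belt so some fall inside the cutoff
    oe = model.coord[model.atom_index("A", 35, "OE1")]
    model.coord[ion] = oe + rng.uniform(-8, 8, size=(20, 3))
    series = pg.ion_coordination_series(_one_frame_traj(model), stride_ns=None)
    a = model.atoms
    for ci, c in enumerate(model.chains):
        ox = np.flatnonzero((a.chain_id == c) & (a.res_id == 35)
                            & np.isin(a.atom_name, ["OE1", "OE2"]))
        d = cdist(model.coord[ion], model.coord[ox])
        assert series.values[0, ci] == int(np.any(d <= 5.0, axis=1).sum())


def test_ion_series_requires_carboxylate():
    model = pg.generate_pentamer(pg.SyntheticSpec(n_ions=1, seed=2))
    traj = _one_frame_traj(model)
    with pytest.raises(pg.SelectionError, match="carboxylate"):
        pg.ion_coordination_series(traj, residue=158)  # THR stand-in


def test_ion_series_stride_sampling():
    spec = pg.SyntheticSpec(n_ions=2, n_frames=40, frame_dt_ns=1.0, seed=6)
    traj, _ = pg.generate_trajectory(spec)
    series = pg.ion_coordination_series(traj, stride_ns=10.0)
    assert np.allclose(series.frame_times, [0, 10, 20, 30])


# ---------------------------------------------------------------------------
# min_group_distance
# ---------------------------------------------------------------------------

def test_min_distance_two_single_atoms(ideal_model):
    i = ideal_model.atom_index("A", 100, "CA")
    j = ideal_model.atom_index("A", 120, "CA")
    ideal_model.coord[j] = ideal_model.coord[i] + [7.25, 0.0, 0.0]
    assert pg.min_group_distance(
        ideal_model, np.array([i]), np.array([j])
    ) == pytest.approx(7.25, abs=1e-12)


def test_min_distance_synthetic_markers(ideal_model):
    e243 = pg.Selection(((243, 243),), frozenset({"OE1", "OE2"}))
    k248 = pg.Selection(((248, 248),), frozenset({"NZ"}))
    assert pg.min_group_distance(ideal_model, k248, e243) == (
        pytest.approx(2.8, abs=1e-9)
    )
    e35 = pg.Selection(((35, 35),), frozenset({"OE1", "OE2"}))
    t158 = pg.Selection(((158, 158),), frozenset({"OG1"}))
    assert pg.min_group_distance(ideal_model, e35, t158) == (
        pytest.approx(3.2, abs=1e-9)
    )


def test_min_distance_empty_group_raises(ideal_model):
    with pytest.raises(pg.SelectionError):
        pg.min_group_distance(ideal_model, np.array([], dtype=int),
                              np.array([0]))


# ---------------------------------------------------------------------------
# contact fraction
# ---------------------------------------------------------------------------

def test_contact_fraction_examples():
    assert pg.contact_fraction([1, 0, 1, 1, 0]) == pytest.approx(0.6)
    assert pg.contact_fraction(np.zeros(10)) == 0.0
    with pytest.raises(pg.InsufficientDataError):
        pg.contact_fraction([])


def test_contact_fraction_monotone_in_cutoff():
    spec = pg.SyntheticSpec(n_frames=200, contact_k_on=0.2, contact_k_off=0.2,
                            seed=31, n_residues_per_chain=261)
    traj, _ = pg.generate_trajectory(spec)
    fractions = [
        pg.contact_fraction(salt_bridge_series(traj, cutoff=c))
        for c in (6.0, 4.0, 2.0, 1.0)
    ]
    assert all(a >= b for a, b in zip(fractions, fractions[1:]))


def test_contact_fraction_recovers_markov_stationary_probability():
    """Two-state process with k_on/(k_on+k_off) = 0.35: the measured contact
    fraction over 1e4 frames x 5 subunits lands within 3 standard errors of
    the stationary probability (SE corrected for chain autocorrelation)."""
    k_on, k_off, n = 0.14, 0.26, 10_000
    spec = pg.SyntheticSpec(n_frames=n, contact_k_on=k_on, contact_k_off=k_off,
                            seed=3, n_residues_per_chain=261)
    traj, truth = pg.generate_trajectory(spec)
    series = salt_bridge_series(traj)
    assert np.array_equal(series.values.astype(bool), truth.contact_state)
    p = k_on / (k_on + k_off)
    rho = 1.0 - k_on - k_off
    se = np.sqrt(p * (1 - p) * (1 + rho) / (1 - rho) / (5 * n))
    assert abs(pg.contact_fraction(series) - p) <= 3 * se


def test_contact_series_all_or_nothing_without_switching():
    spec = pg.SyntheticSpec(n_frames=50, contact_initial="formed",
                            n_residues_per_chain=261)
    traj, _ = pg.generate_trajectory(spec)
    assert pg.contact_fraction(salt_bridge_series(traj)) == 1.0
    spec2 = pg.SyntheticSpec(n_frames=50, contact_initial="broken",
                             n_residues_per_chain=261)
    traj2, _ = pg.generate_trajectory(spec2)
    assert pg.contact_fraction(salt_bridge_series(traj2)) == 0.0


# ---------------------------------------------------------------------------
# intersubunit distances
# ---------------------------------------------------------------------------

def test_intersubunit_distance_construction(ideal_model):
    d = pg.intersubunit_ca_distance(ideal_model, 35, 158)
    assert np.allclose(d, 9.0, atol=1e-9)


def test_intersubunit_distance_rigid_invariant(ideal_model):
    rot, trans = random_rigid_motion(np.random.default_rng(13))
    moved = apply_rigid(ideal_model, rot, trans)
    assert np.allclose(
        pg.intersubunit_ca_distance(moved, 35, 158), 9.0, atol=1e-6
    )


def test_intersubunit_distance_matches_pairing_oracle():
    spec = pg.SyntheticSpec(noise_sigma=0.05, seed=77)
    model = pg.generate_pentamer(spec)
    d = pg.intersubunit_ca_distance(model, 35, 158)
    axis = pg.estimate_pore_axis(model)
    order = pg.subunit_order(model, axis)
    for i in range(5):
        pa = model.coord[model.atom_index(order[i], 35, "CA")]
        pb = model.coord[model.atom_index(order[(i + 1) % 5], 158, "CA")]
        assert d[i] == pytest.approx(np.linalg.norm(pa - pb), abs=1e-9)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_degenerate_inputs():
    stat = pg.bootstrap_median_ci([4.2, 4.2, 4.2, 4.2], seed=0)
    assert (stat.median, stat.ci_low, stat.ci_high) == (4.2, 4.2, 4.2)
    single = pg.bootstrap_median_ci([1.7], seed=0)
    assert (single.median, single.ci_low, single.ci_high) == (1.7, 1.7, 1.7)
    with pytest.raises(pg.InsufficientDataError):
        pg.bootstrap_median_ci([])


def test_bootstrap_matches_independent_resampling_oracle():
    samples = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    seed, n_boot = 1234, 5000
    stat = pg.bootstrap_median_ci(samples, n_boot=n_boot, seed=seed)
    rng = np.random.default_rng(seed)
    meds = np.array([
        np.median(samples[rng.integers(0, 5, 5)]) for _ in range(n_boot)
    ])
    # oracle draws row-by-row; the implementation draws one block — the same
    # generator stream gives identical index sequences either way
    lo, hi = np.percentile(meds, [2.5, 97.5])
    assert stat.median == 3.0
    assert stat.ci_low == pytest.approx(min(lo, 3.0))
    assert stat.ci_high == pytest.approx(max(hi, 3.0))


def test_bootstrap_ci_width_shrinks_as_samples_agree():
    wide = pg.bootstrap_median_ci([1, 5, 2, 8, 3], seed=0)
    narrow = pg.bootstrap_median_ci([3.0, 3.01, 2.99, 3.0, 3.02], seed=0)
    assert (narrow.ci_high - narrow.ci_low) < (wide.ci_high - wide.ci_low)


def test_bootstrap_coverage_near_nominal_level():
    """Coverage of the 95% bootstrap median CI over seeded Gaussian draws
    stays within 5 percentage points of nominal."""
    rng = np.random.default_rng(2024)
    n_rep, n, n_boot = 200, 15, 10_000
    hits = 0
    for rep in range(n_rep):
        x = rng.normal(0.0, 1.0, size=n)
        stat = pg.bootstrap_median_ci(x, n_boot=n_boot, seed=rep)
        hits += stat.ci_low <= 0.0 <= stat.ci_high
    assert abs(hits / n_rep - 0.95) <= 0.05
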