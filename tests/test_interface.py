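import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from desolvscan import (
    Ensemble,
    SystemTopology,
    distance_profile,
    estimate_teq,
    hydrogen_bonds,
    representative_frame,
    rmsd_series,
    salt_bridges,
    vdw_contacts,
)
from desolvscan.interface import superpose_rmsd
from tests.conftest import micro_atom


def _pair_topology(d, names=("CA", "CA"), charges=(0.0, 0.0)):
    atoms = [
        micro_atom(0, names[0], ("A", 1, "R1"), [0.0, 0.0, 0.0], charges[0]),
        micro_atom(1, names[1], ("B", 1, "L1"), [d, 0.0, 0.0], charges[1]),
    ]
    return SystemTopology(atoms, {"A"}, {"B"})


@pytest.mark.parametrize("d,expected", [(3.9, 1), (4.0, 1), (4.1, 0)])
def test_contact_distance_boundary(d, expected):
    top = _pair_topology(d)
    assert len(vdw_contacts(top.positions, top)) == expected


def test_contacts_ignore_hydrogens():
    top = _pair_topology(3.0, names=("HA", "HB1"))
    assert vdw_contacts(top.positions, top) == []


def _hbond_system(da_dist, angle_deg):
    """Donor N with bonded H, acceptor O at given distance/donor angle."""
    ang = np.deg2rad(angle_deg)
    h_pos = [np.cos(ang), np.sin(ang), 0.0]  # 1.0 A from donor
    atoms = [
        micro_atom(0, "N", ("A", 1, "R1"), [0.0, 0.0, 0.0], -0.3),
        micro_atom(1, "H", ("A", 1, "R1"), h_pos, 0.3),
        micro_atom(2, "O", ("B", 1, "L1"), [da_dist, 0.0, 0.0], -0.5),
    ]
    return SystemTopology(atoms, {"A"}, {"B"})


@pytest.mark.parametrize(
    "dist,angle,present",
    [(2.9, 10.0, True), (3.6, 10.0, False), (2.9, 40.0, False),
     (3.5, 10.0, True), (2.9, 30.0, True)],
)
def test_hbond_geometric_criteria(dist, angle, present):
    top = _hbond_system(dist, angle)
    ens = Ensemble(top, top.positions[None], [0.0])
    bonds = hydrogen_bonds(ens)
    assert bool(bonds) == present


def test_hbond_occupancy_counts_frames():
    """Present in 40 of 100 frames -> occupancy 0.40."""
    top = _hbond_system(2.9, 10.0)
    coords = np.repeat(top.positions[None], 100, axis=0)
    coords[40:, 2, 0] += 5.0  # acceptor pulled away
    ens = Ensemble(top, coords, 10.0 * np.arange(100))
    bonds = hydrogen_bonds(ens)
    assert len(bonds) == 1
    assert bonds[0].occupancy == pytest.approx(0.40)


def _bridge_system(d):
    atoms = [
        micro_atom(0, "NZ", ("A", 1, "LYS"), [0.0, 0.0, 0.0], 1.0),
        micro_atom(1, "OD1", ("B", 1, "ASP"), [d, 0.0, 0.0], -1.0),
        micro_atom(2, "OD2", ("B", 1, "ASP"), [d + 1.0, 0.0, 0.0], -1.0),
    ]
    return SystemTopology(atoms, {"A"}, {"B"})


def test_salt_bridge_present_with_occupancy_and_mean():
    top = _bridge_system(3.0)
    coords = np.repeat(top.positions[None], 4, axis=0)
    ens = Ensemble(top, coords, 10.0 * np.arange(4))
    rec = salt_bridges(ens)
    assert len(rec) == 1
    assert rec[0].occupancy == 1.0
    assert rec[0].mean_distance == pytest.approx(3.0)


def test_salt_bridge_absent_beyond_cutoff():
    top = _bridge_system(4.5)
    ens = Ensemble(top, top.positions[None], [0.0])
    assert salt_bridges(ens) == []


def test_salt_bridge_mean_distance_over_presence_frames_only():
    top = _bridge_system(3.0)
    coords = np.repeat(top.positions[None], 10, axis=0)
    coords[5:, 0, 0] -= 3.0  # NZ moved away: min distance 6.0
    ens = Ensemble(top, coords, 10.0 * np.arange(10))
    rec = salt_bridges(ens)
    assert rec[0].occupancy == pytest.approx(0.5)
    assert rec[0].mean_distance == pytest.approx(3.0)


def test_rmsd_identical_and_translated_frames(toy_top):
    coords = np.stack([
        toy_top.positions,
        toy_top.positions,
        toy_top.positions + np.array([3.0, -2.0, 1.0]),
    ])
    ens = Ensemble(toy_top, coords, [0.0, 10.0, 20.0])
    out = rmsd_series(ens)
    np.testing.assert_allclose(out, 0.0, atol=1e-7)


def test_rmsd_two_atom_axial_displacement_closed_form():
    """One atom displaced by d along the bond axis: fitted RMSD = d/2."""
    L, d = 3.0, 0.8
    ref = np.array([[0.0, 0, 0], [L, 0, 0]])
    mob = np.array([[0.0, 0, 0], [L + d, 0, 0]])
    assert superpose_rmsd(ref, mob) == pytest.approx(d / 2, abs=1e-12)


def test_fitted_rmsd_never_exceeds_unfitted(toy_ens):
    ref = toy_ens.coords[0]
    for c in toy_ens.coords:
        raw = np.sqrt(((c - ref) ** 2).sum(axis=1).mean())
        assert superpose_rmsd(ref, c) <= raw + 1e-12


def test_teq_constant_series_is_first_frame():
    times = 10.0 * np.arange(50)
    flat = np.ones(50)
    t_eq, ok = estimate_teq(times, flat, flat)
    assert t_eq == 0.0
    assert ok


def test_teq_step_function_settles_after_step():
    times = 10.0 * np.arange(100)
    step = np.where(np.arange(100) < 30, 5.0, 1.0)
    flat = np.ones(100)
    with pytest.warns(UserWarning, match="never stabilizes"):
        # the start-anchored accumulated mean keeps drifting after a step
        t_eq, ok = estimate_teq(times, step, flat)
    assert t_eq >= times[30]


def test_teq_linear_drift_flags_warning():
    times = 10.0 * np.arange(50)
    drift = np.linspace(0.0, 10.0, 50)
    with pytest.warns(UserWarning, match="never stabilizes"):
        t_eq, ok = estimate_teq(times, drift, drift)
    assert not ok


def test_representative_all_identical_frames(toy_top):
    coords = np.repeat(toy_top.positions[None], 6, axis=0)
    ens = Ensemble(toy_top, coords, 10.0 * np.arange(6))
    idx, sizes = representative_frame(ens, rmsd_cutoff=0.5)
    assert idx == 0
    assert sizes == [6]


def test_representative_comes_from_majority_conformer(toy_top):
    rng = np.random.default_rng(4)
    conf_a = toy_top.positions
    conf_b = toy_top.positions + rng.normal(0, 2.0, toy_top.positions.shape)
    frames = [conf_a + rng.normal(0, 0.02, conf_a.shape) for _ in range(6)]
    frames += [conf_b + rng.normal(0, 0.02, conf_a.shape) for _ in range(4)]
    ens = Ensemble(toy_top, np.stack(frames), 10.0 * np.arange(10))
    idx, sizes = representative_frame(ens, rmsd_cutoff=0.5)
    assert idx < 6  # member of the 60% cluster
    assert sorted(sizes, reverse=True)[:2] == [6, 4]


def test_single_cluster_when_cutoff_exceeds_spread(toy_ens):
    idx, sizes = representative_frame(toy_ens, rmsd_cutoff=100.0)
    assert sizes == [toy_ens.n_frames]


def test_distance_profile_cases(toy_top):
    coords = np.repeat(toy_top.positions[None], 5, axis=0)
    ens = Ensemble(toy_top, coords, 10.0 * np.arange(5))
    d01 = np.linalg.norm(toy_top.positions[0] - toy_top.positions[1])
    np.testing.assert_allclose(distance_profile(ens, 0, 1), d01)
    np.testing.assert_allclose(distance_profile(ens, 3, 3), 0.0)
    with pytest.raises(ValueError, match="unknown atom"):
        distance_profile(ens, 0, 10**6)


def test_distance_profile_monotone_approach():
    """Fixture approaching from 5.7 to 2.7 A: monotone decreasing."""
    top = _pair_topology(5.7)
    n = 30
    coords = np.repeat(top.positions[None], n, axis=0)
    coords[:, 1, 0] -= np.linspace(0.0, 3.0, n)
    ens = Ensemble(top, coords, 10.0 * np.arange(n))
    prof = distance_profile(ens, 0, 1)
    assert prof[0] == pytest.approx(5.7)
    assert prof[-1] == pytest.approx(2.7)
    assert np.all(np.diff(prof) < 0)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(perm_seed=st.integers(0, 10**6))
def test_occupancy_invariant_under_frame_reordering(perm_seed):
    top = _bridge_system(3.0)
    coords = np.repeat(top.positions[None], 12, axis=0)
    coords[::3, 0, 0] -= 3.0  # break the bridge in every third frame
    order = np.random.default_rng(perm_seed).permutation(12)
    ens = Ensemble(top, coords[order], 10.0 * np.arange(12))
    rec = salt_bridges(ens)
    assert rec[0].occupancy == pytest.approx(2 / 3)
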