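import numpy as np
import pytest

from desolvscan import (
    COULOMB_CONSTANT,
    Ensemble,
    FixtureSpec,
    classify_spot,
    effective_born_radii,
    make_born_ion,
    make_toy_complex,
    pairwise_decomposition,
    per_residue_decomposition,
    polar_split,
)
from desolvscan.decompose import _residue_frame_values, polar_split_frame
from desolvscan.energy import frame_delta_matrices
from desolvscan.sasa import sasa_numeric


# --------------------------------------------------------------------------
# brute-force oracle: explicit scalar double loops over the tiny complex
# (effective radii come from the engine; their own correctness is covered by
# the numeric descreening-integral oracle in test_gb.py)
# --------------------------------------------------------------------------

def _gb_pair(qi, qj, Ri, Rj, r, params):
    f = np.sqrt(r**2 + Ri * Rj * np.exp(-(r**2) / (4 * Ri * Rj)))
    kap = params.kappa * params.kappa_scale
    return (
        -COULOMB_CONSTANT * qi * qj
        * (1 / params.eps_in - np.exp(-kap * f) / params.eps_w) / f
    )


def _gb_self(qi, Ri, params):
    kap = params.kappa * params.kappa_scale
    return (
        -0.5 * COULOMB_CONSTANT * qi**2
        * (1 / params.eps_in - np.exp(-kap * Ri) / params.eps_w) / Ri
    )


def _lj_pair(top, i, j, r):
    rmin = top.lj_rmin_half[i] + top.lj_rmin_half[j]
    eps = np.sqrt(top.lj_epsilon[i] * top.lj_epsilon[j])
    sr6 = (rmin / r) ** 6
    return eps * (sr6**2 - 2 * sr6)


def _coulomb_pair(top, i, j, r, params):
    return COULOMB_CONSTANT * top.charges[i] * top.charges[j] / (params.eps_in * r)


def brute_force_tiny(top, params):
    """Hand-expanded delta terms for the 2-atom receptor / 1-atom ligand."""
    pos = top.positions
    r01 = np.linalg.norm(pos[0] - pos[1])
    r02 = np.linalg.norm(pos[0] - pos[2])
    r12 = np.linalg.norm(pos[1] - pos[2])
    R_c = effective_born_radii(pos, top.gb_radii, top.gb_screens, params)
    R_rec = effective_born_radii(pos[:2], top.gb_radii[:2],
                                 top.gb_screens[:2], params)
    R_lig = top.gb_radii[2:] - params.radius_offset  # isolated atom

    q = top.charges
    d_self = [
        _gb_self(q[0], R_c[0], params) - _gb_self(q[0], R_rec[0], params),
        _gb_self(q[1], R_c[1], params) - _gb_self(q[1], R_rec[1], params),
        _gb_self(q[2], R_c[2], params) - _gb_self(q[2], R_lig[0], params),
    ]
    d_gb01 = (_gb_pair(q[0], q[1], R_c[0], R_c[1], r01, params)
              - _gb_pair(q[0], q[1], R_rec[0], R_rec[1], r01, params))
    gb02 = _gb_pair(q[0], q[2], R_c[0], R_c[2], r02, params)
    gb12 = _gb_pair(q[1], q[2], R_c[1], R_c[2], r12, params)
    el02 = _coulomb_pair(top, 0, 2, r02, params)
    el12 = _coulomb_pair(top, 1, 2, r12, params)
    vw02 = _lj_pair(top, 0, 2, r02)
    vw12 = _lj_pair(top, 1, 2, r12)
    return {
        "d_self": d_self, "d_gb01": d_gb01, "gb02": gb02, "gb12": gb12,
        "el02": el02, "el12": el12, "vw02": vw02, "vw12": vw12,
    }


def _dsa_atoms(top):
    _, sa_c = sasa_numeric(top.positions, top.gb_radii, elements=top.elements)
    _, sa_r = sasa_numeric(top.positions[:2], top.gb_radii[:2],
                           elements=top.elements[:2])
    _, sa_l = sasa_numeric(top.positions[2:], top.gb_radii[2:],
                           elements=top.elements[2:])
    dsa = sa_c.copy()
    dsa[:2] -= sa_r
    dsa[2:] -= sa_l
    return dsa


def test_per_residue_matches_brute_force(tiny_complex, params, nonpolar):
    """prEFED on a one-residue-per-chain toy equals the hand-expanded sum."""
    top = tiny_complex
    bf = brute_force_tiny(top, params)
    dsa = _dsa_atoms(top)
    cross_r1 = (bf["vw02"] + bf["vw12"] + bf["el02"] + bf["el12"]
                + bf["gb02"] + bf["gb12"])
    g_r1 = (0.5 * cross_r1 + bf["d_gb01"] + bf["d_self"][0] + bf["d_self"][1]
            + nonpolar.gamma_sa * (dsa[0] + dsa[1]))
    g_l1 = (0.5 * cross_r1 + bf["d_self"][2] + nonpolar.gamma_sa * dsa[2])

    ens = Ensemble(top, top.positions[None], [0.0])
    res = per_residue_decomposition(ens, params, nonpolar)
    by_key = {r.residue_key: r for r in res}
    assert by_key[("A", 1, "R1")].G_res == pytest.approx(g_r1, abs=1e-8)
    assert by_key[("B", 1, "L1")].G_res == pytest.approx(g_l1, abs=1e-8)
    # G_sc of R1 restricts to the CB atom
    g_sc = (0.5 * (bf["vw12"] + bf["el12"] + bf["gb12"]) + 0.5 * bf["d_gb01"]
            + bf["d_self"][1] + nonpolar.gamma_sa * dsa[1])
    assert by_key[("A", 1, "R1")].G_sc == pytest.approx(g_sc, abs=1e-8)


def test_pairwise_matches_brute_force(tiny_complex, params):
    top = tiny_complex
    bf = brute_force_tiny(top, params)
    ens = Ensemble(top, top.positions[None], [0.0])
    pairs = pairwise_decomposition(ens, params)
    assert len(pairs) == 1
    p = pairs[0]
    assert p.E_vw_pair == pytest.approx(bf["vw02"] + bf["vw12"], abs=1e-8)
    assert p.E_el_pair == pytest.approx(bf["el02"] + bf["el12"], abs=1e-8)
    assert p.G_gb_pair == pytest.approx(bf["gb02"] + bf["gb12"], abs=1e-8)
    # halving recovers the symmetric double-counting convention
    assert 0.5 * p.G_total_pair == pytest.approx(p.G_total_pair / 2)


def test_polar_split_matches_brute_force(tiny_complex, params):
    top = tiny_complex
    bf = brute_force_tiny(top, params)
    ens = Ensemble(top, top.positions[None], [0.0])
    split = polar_split(ens, params)
    g_ds = sum(bf["d_self"]) + bf["d_gb01"]
    g_sc = bf["el02"] + bf["el12"] + bf["gb02"] + bf["gb12"]
    assert split.G_ds == pytest.approx(g_ds, abs=1e-8)
    assert split.G_el_sc == pytest.approx(g_sc, abs=1e-8)


# --------------------------------------------------------------------------
# conservation identities on the noisy toy ensemble, per frame
# --------------------------------------------------------------------------

def test_conservation_identities_every_frame(toy_ens, params, nonpolar):
    top = toy_ens.topology
    for coords in toy_ens.coords:
        d = frame_delta_matrices(coords, top, params, nonpolar)
        g_res, g_sc, g_sa, _ = _residue_frame_values(d, top, nonpolar)
        assert g_res.sum() == pytest.approx(d.breakdown.G_eff, abs=1e-6)
        assert g_sa.sum() == pytest.approx(d.breakdown.G_SA, abs=1e-6)
        g_ds, g_el_sc = polar_split_frame(d, top)
        assert g_ds + g_el_sc == pytest.approx(
            d.breakdown.E_el + d.breakdown.G_GB, abs=1e-6
        )
        # pair totals: all receptor x ligand cross energy
        r, l = top.receptor_mask, top.ligand_mask
        pair_sum = 2.0 * (d.dM_vw + d.dM_el + d.dM_gb)[np.ix_(r, l)].sum()
        assert pair_sum == pytest.approx(
            d.breakdown.E_vw + g_el_sc, abs=1e-6
        )


def test_charge_free_complex_reduces_to_lj_plus_sa(params, nonpolar):
    spec = FixtureSpec(planted_motifs=frozenset({"hydrophobic_pocket"}))
    top = make_toy_complex(spec)
    top.charges[:] = 0.0  # engine reads the vectorized arrays
    ens = Ensemble(top, top.positions[None], [0.0])
    res = per_residue_decomposition(ens, params, nonpolar)
    d = frame_delta_matrices(top.positions, top, params, nonpolar)
    assert d.breakdown.E_el == 0.0
    assert d.breakdown.G_GB == 0.0
    for r in res:
        atoms = top.atoms_of_residue(r.residue_key)
        expected = (d.dM_vw[atoms, :].sum()
                    + nonpolar.gamma_sa * d.dsa_atoms[atoms].sum())
        assert r.G_res == pytest.approx(expected, abs=1e-8)


def test_neutral_ligand_pairs_have_no_polar_terms(params):
    spec = FixtureSpec(planted_motifs=frozenset({"hydrophobic_pocket"}))
    top = make_toy_complex(spec)
    # neutralize the ligand chain
    top.charges[top.ligand_mask] = 0.0
    ens = Ensemble(top, top.positions[None], [0.0])
    pairs = pairwise_decomposition(ens, params)
    for p in pairs:
        assert p.E_el_pair == 0.0
        assert p.G_gb_pair == 0.0
    split = polar_split(ens, params)
    from desolvscan import NonpolarParams

    d = frame_delta_matrices(top.positions, top, params, NonpolarParams(),
                             sasa_method="skip")
    assert split.G_el_sc == pytest.approx(0.0, abs=1e-10)
    assert split.G_ds == pytest.approx(d.breakdown.G_GB, abs=1e-8)


def test_gly_residues_have_zero_side_chain_contribution(toy_ens, params,
                                                        nonpolar):
    res = per_residue_decomposition(toy_ens, params, nonpolar)
    gly = [r for r in res if r.residue_key[2] == "GLY"]
    assert gly
    for r in gly:
        assert r.G_sc == 0.0


def test_polar_split_refuses_unpartitioned_system(params):
    ion = make_born_ion(1.0, 2.0)
    ens = Ensemble(ion, np.zeros((1, 1, 3)), [0.0])
    with pytest.raises(ValueError, match="single-trajectory"):
        polar_split(ens, params)


@pytest.mark.parametrize(
    "value,expected",
    [(-1.5, "hot"), (-1.0, "hot"), (-0.7, "warm"), (-0.4, "warm"),
     (-0.2, "none"), (0.3, "none")],
)
def test_classify_spot_thresholds(value, expected):
    assert classify_spot(value) == expected
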