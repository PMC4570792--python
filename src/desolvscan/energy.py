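"""Per-frame single-trajectory MM-GBSA effective free energies.

Under the single-trajectory (ST) approach the receptor and ligand
coordinates are extracted from the complex frame, so every Delta term is
value(complex) - value(receptor) - value(ligand) on identical coordinates.
Internal (bonded) energies cancel exactly (dE_int = 0) and the Coulomb and
LJ differences reduce to inter-chain pair sums; the GB and SA terms do not
reduce, because effective Born radii and exposed areas change when the
partner is removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import gb as _gb
from . import sasa as _sasa
from .gb import GBModelParams, NonpolarParams
from .topology import Ensemble, SystemTopology


@dataclass
class EnergyBreakdown:
    """Delta energy components of one frame (kcal/mol).

    ``G_eff = E_vw + E_el + G_GB + G_SA`` holds by construction
    (entropy omitted; dE_int = 0 under the single-trajectory approach).
    """

    E_vw: float
    E_el: float
    G_GB: float
    G_SA: float

    @property
    def G_eff(self) -> float:
        return self.E_vw + self.E_el + self.G_GB + self.G_SA


@dataclass
class FrameDeltas:
    """Per-atom-pair Delta matrices of one frame.

    Matrices follow the halved-off-diagonal convention of :mod:`.gb`
    (``matrix.sum()`` is the total Delta energy of that term); ``dsa_atoms``
    holds per-atom SASA changes (A^2, complex minus monomer).
    """

    dM_vw: np.ndarray
    dM_el: np.ndarray
    dM_gb: np.ndarray
    dsa_atoms: np.ndarray
    breakdown: EnergyBreakdown


def _zero_intra(matrix: np.ndarray, top: SystemTopology) -> np.ndarray:
    """Keep only inter-chain entries (ST cancellation of intra terms)."""
    out = matrix.copy()
    r = top.receptor_mask
    l = top.ligand_mask
    out[np.ix_(r, r)] = 0.0
    out[np.ix_(l, l)] = 0.0
    return out


def frame_delta_matrices(
    coords: np.ndarray,
    topology: SystemTopology,
    params: GBModelParams,
    nonpolar: NonpolarParams,
    sasa_method: str = "numeric",
    sasa_points: int = 960,
) -> FrameDeltas:
    """All Delta pair matrices and the energy breakdown for one frame."""
    coords = np.asarray(coords, dtype=float)
    top = topology
    r = top.receptor_mask
    l = top.ligand_mask

    _, M_el = _gb.coulomb_energy(coords, top.charges, params.eps_in)
    _, M_vw = _gb.lj_energy(coords, top.lj_rmin_half, top.lj_epsilon)
    dM_el = _zero_intra(M_el, top)
    dM_vw = _zero_intra(M_vw, top)

    # GB: complex and isolated monomers on the same coordinates
    dM_gb = _gb_delta_matrix(coords, top, params)

    dsa_atoms = _dsa_per_atom(coords, top, nonpolar, sasa_method, sasa_points)
    g_sa = _gb.nonpolar_energy(float(dsa_atoms.sum()), nonpolar)

    breakdown = EnergyBreakdown(
        E_vw=float(dM_vw.sum()),
        E_el=float(dM_el.sum()),
        G_GB=float(dM_gb.sum()),
        G_SA=g_sa,
    )
    return FrameDeltas(dM_vw, dM_el, dM_gb, dsa_atoms, breakdown)


def _gb_delta_matrix(
    coords: np.ndarray, top: SystemTopology, params: GBModelParams
) -> np.ndarray:
    radii_c = _gb.effective_born_radii(
        coords, top.gb_radii, top.gb_screens, params
    )
    _, M_c = _gb.gb_polar_energy(coords, top.charges, radii_c, params)
    dM = M_c.copy()
    for mask in (top.receptor_mask, top.ligand_mask):
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        radii_m = _gb.effective_born_radii(
            coords[idx], top.gb_radii[idx], top.gb_screens[idx], params
        )
        _, M_m = _gb.gb_polar_energy(
            coords[idx], top.charges[idx], radii_m, params
        )
        dM[np.ix_(idx, idx)] -= M_m
    return dM


def _dsa_per_atom(
    coords: np.ndarray,
    top: SystemTopology,
    nonpolar: NonpolarParams,
    method: str,
    n_points: int,
) -> np.ndarray:
    if method == "skip":  # callers that need only the pair matrices
        return np.zeros(top.n_atoms)
    _, sa_c = _sasa.sasa(
        coords, top.gb_radii, top.elements, nonpolar, method, n_points
    )
    dsa = sa_c.copy()
    for mask in (top.receptor_mask, top.ligand_mask):
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        _, sa_m = _sasa.sasa(
            coords[idx], top.gb_radii[idx], top.elements[idx],
            nonpolar, method, n_points,
        )
        dsa[idx] -= sa_m
    return dsa


def frame_effective_energy(
    coords: np.ndarray,
    topology: SystemTopology,
    params: GBModelParams,
    nonpolar: NonpolarParams,
    sasa_method: str = "numeric",
) -> EnergyBreakdown:
    """Single-trajectory Delta-energy breakdown of one frame."""
    return frame_delta_matrices(
        coords, topology, params, nonpolar, sasa_method
    ).breakdown


def mean_sem(values: np.ndarray) -> tuple[float, float]:
    """Ensemble mean and standard error (frames treated as independent)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        return float(v.mean()), 0.0
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(len(v)))


def ensemble_energies(
    ensemble: Ensemble,
    params: GBModelParams,
    nonpolar: NonpolarParams,
    sasa_method: str = "numeric",
) -> dict:
    """Per-frame breakdowns plus means +/- SEM over the ensemble."""
    frames = [
        frame_effective_energy(c, ensemble.topology, params, nonpolar, sasa_method)
        for c in ensemble.coords
    ]
    summary = {}
    for term in ("E_vw", "E_el", "G_GB", "G_SA", "G_eff"):
        vals = np.array([getattr(f, term) for f in frames])
        summary[term] = {"mean": mean_sem(vals)[0], "sem": mean_sem(vals)[1]}
    return {"frames": frames, "summary": summary, "times": ensemble.times}
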