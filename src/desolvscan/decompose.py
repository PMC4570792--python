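"""Decomposition of the effective free energy.

Three views of the same frame-level Delta pair matrices:

* per-residue (prEFED): half of every cross term touching the residue, plus
  the residue's GB self-term differences and its share of the nonpolar SA
  term; the per-residue values sum exactly to dG_eff each frame. The
  side-chain restriction dG_sc (used for warm/hot-spot calling) limits the
  atom sums to non-backbone atoms.
* pair-wise (pwEFED): full (unhalved) receptor-residue x ligand-residue
  interaction energies; their sum equals dE_vw + dG_el^sc each frame.
* polar split: the polar energy dE_el + dG_GB repartitioned into the
  desolvation penalty dG_ds (self terms plus intra-chain GB cross terms)
  and the screened electrostatics dG_el^sc (inter-chain Coulomb + GB cross
  terms). Valid only under the single-trajectory approach, where
  intra-chain Coulomb differences vanish.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import FrameDeltas, frame_delta_matrices, mean_sem
from .gb import GBModelParams, NonpolarParams, nonpolar_energy
from .topology import Ensemble, SystemTopology

#: Side-chain contribution thresholds (kcal/mol) for interface spot calling.
HOT_THRESHOLD = -1.0
WARM_THRESHOLD = -0.4


@dataclass
class ResidueContribution:
    residue_key: tuple[str, int, str]
    G_res: float  # kcal/mol, ensemble mean
    G_res_sem: float
    G_sc: float  # side-chain-only restriction
    G_sc_sem: float
    G_sa_res: float  # per-residue nonpolar term
    dSA_res: float  # A^2
    self_gb: float  # per-residue GB self-term differences


@dataclass
class PairContribution:
    r1: tuple[str, int, str]  # receptor residue
    r2: tuple[str, int, str]  # ligand residue
    E_vw_pair: float
    E_el_pair: float
    G_gb_pair: float

    @property
    def G_total_pair(self) -> float:
        return self.E_vw_pair + self.E_el_pair + self.G_gb_pair


@dataclass
class PolarSplit:
    G_ds: float
    G_ds_sem: float
    G_el_sc: float
    G_el_sc_sem: float


def classify_spot(G_sc: float) -> str:
    """Warm/hot-spot call from the side-chain contribution (kcal/mol).

    hot iff G_sc <= -1.0; warm iff -1.0 < G_sc <= -0.4; none otherwise.
    Both boundaries classify into the stronger category.
    """
    if G_sc <= HOT_THRESHOLD:
        return "hot"
    if G_sc <= WARM_THRESHOLD:
        return "warm"
    return "none"


def _residue_frame_values(
    deltas: FrameDeltas, top: SystemTopology, nonpolar: NonpolarParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-residue (G_res, G_sc, G_sa_res, self_gb) for one frame.

    With the halved symmetric matrix convention, the row sums over a
    residue's atoms yield exactly half the cross terms plus the full
    self terms of those atoms.
    """
    dM = deltas.dM_vw + deltas.dM_el + deltas.dM_gb
    row = dM.sum(axis=1)  # per-atom: half cross terms + own self term
    self_gb_atom = np.diag(deltas.dM_gb)
    sa_atom = nonpolar.gamma_sa * deltas.dsa_atoms
    # beta is a per-molecule constant; attribute it to no residue (beta=0 by
    # default) but keep the conservation identity by adding it to G_SA totals
    n_res = len(top.residues)
    g_res = np.zeros(n_res)
    g_sc = np.zeros(n_res)
    g_sa = np.zeros(n_res)
    self_gb = np.zeros(n_res)
    for k in range(n_res):
        atoms = np.flatnonzero(top.residue_index == k)
        sc = atoms[~top.is_backbone[atoms]]
        g_res[k] = row[atoms].sum() + sa_atom[atoms].sum()
        g_sc[k] = row[sc].sum() + sa_atom[sc].sum()
        g_sa[k] = sa_atom[atoms].sum()
        self_gb[k] = self_gb_atom[atoms].sum()
    return g_res, g_sc, g_sa, self_gb


def per_residue_decomposition(
    ensemble: Ensemble,
    params: GBModelParams,
    nonpolar: NonpolarParams,
    sasa_method: str = "numeric",
) -> list[ResidueContribution]:
    """prEFED: per-residue contributions, ensemble means +/- SEM."""
    top = ensemble.topology
    per_frame = []
    for coords in ensemble.coords:
        deltas = frame_delta_matrices(coords, top, params, nonpolar, sasa_method)
        per_frame.append(_residue_frame_values(deltas, top, nonpolar))
    g_res = np.array([f[0] for f in per_frame])
    g_sc = np.array([f[1] for f in per_frame])
    g_sa = np.array([f[2] for f in per_frame])
    self_gb = np.array([f[3] for f in per_frame])
    out = []
    for k, key in enumerate(top.residues):
        m_res, s_res = mean_sem(g_res[:, k])
        m_sc, s_sc = mean_sem(g_sc[:, k])
        sa_mean = float(g_sa[:, k].mean())
        out.append(
            ResidueContribution(
                residue_key=key,
                G_res=m_res,
                G_res_sem=s_res,
                G_sc=m_sc,
                G_sc_sem=s_sc,
                G_sa_res=sa_mean,
                dSA_res=sa_mean / nonpolar.gamma_sa if nonpolar.gamma_sa else 0.0,
                self_gb=float(self_gb[:, k].mean()),
            )
        )
    return out


def pairwise_decomposition(
    ensemble: Ensemble,
    params: GBModelParams,
    nonpolar: NonpolarParams | None = None,
    sasa_method: str = "numeric",
) -> list[PairContribution]:
    """pwEFED: full receptor-residue x ligand-residue interaction energies.

    The 1/2 double-counting factor is deliberately dropped so each pair
    carries its full interaction energy; halving every value recovers the
    symmetric convention.
    """
    top = ensemble.topology
    nonpolar = nonpolar or NonpolarParams()
    rec_res = [k for k, key in enumerate(top.residues)
               if key[0] in top.receptor_chain_ids]
    lig_res = [k for k, key in enumerate(top.residues)
               if key[0] in top.ligand_chain_ids]
    acc = {
        (a, b): np.zeros((ensemble.n_frames, 3)) for a in rec_res for b in lig_res
    }
    for f, coords in enumerate(ensemble.coords):
        deltas = frame_delta_matrices(
            coords, top, params, nonpolar, sasa_method="skip"
        )
        for a in rec_res:
            ia = np.flatnonzero(top.residue_index == a)
            for b in lig_res:
                ib = np.flatnonzero(top.residue_index == b)
                # full pair energy: both symmetric halved slots
                acc[(a, b)][f, 0] = 2.0 * deltas.dM_vw[np.ix_(ia, ib)].sum()
                acc[(a, b)][f, 1] = 2.0 * deltas.dM_el[np.ix_(ia, ib)].sum()
                acc[(a, b)][f, 2] = 2.0 * deltas.dM_gb[np.ix_(ia, ib)].sum()
    return [
        PairContribution(
            r1=top.residues[a],
            r2=top.residues[b],
            E_vw_pair=float(acc[(a, b)][:, 0].mean()),
            E_el_pair=float(acc[(a, b)][:, 1].mean()),
            G_gb_pair=float(acc[(a, b)][:, 2].mean()),
        )
        for a in rec_res
        for b in lig_res
    ]


def polar_split_frame(deltas: FrameDeltas, top: SystemTopology) -> tuple[float, float]:
    """(G_ds, G_el_sc) of one frame from its Delta matrices."""
    r = top.receptor_mask
    l = top.ligand_mask
    g_ds = float(np.diag(deltas.dM_gb).sum())
    off_gb = deltas.dM_gb - np.diag(np.diag(deltas.dM_gb))
    g_ds += float(off_gb[np.ix_(r, r)].sum() + off_gb[np.ix_(l, l)].sum())
    g_el_sc = 2.0 * float(
        (deltas.dM_el + deltas.dM_gb)[np.ix_(r, l)].sum()
    )
    return g_ds, g_el_sc


def polar_split(
    ensemble: Ensemble,
    params: GBModelParams,
    nonpolar: NonpolarParams | None = None,
) -> PolarSplit:
    """Repartition dE_el + dG_GB into desolvation and screened terms.

    Requires both partitions to be non-empty (single-trajectory complex);
    the identity G_ds + G_el_sc = dE_el + dG_GB holds per frame.
    """
    top = ensemble.topology
    if not top.receptor_mask.any() or not top.ligand_mask.any():
        raise ValueError(
            "polar split requires a partitioned complex under the "
            "single-trajectory approach"
        )
    nonpolar = nonpolar or NonpolarParams()
    ds, sc = [], []
    for coords in ensemble.coords:
        deltas = frame_delta_matrices(
            coords, top, params, nonpolar, sasa_method="skip"
        )
        a, b = polar_split_frame(deltas, top)
        ds.append(a)
        sc.append(b)
    m_ds, s_ds = mean_sem(np.array(ds))
    m_sc, s_sc = mean_sem(np.array(sc))
    return PolarSplit(m_ds, s_ds, m_sc, s_sc)
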