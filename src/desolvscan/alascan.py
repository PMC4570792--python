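"""Computational alanine scanning under the single-trajectory approach.

The mutant trajectory is generated from the native one by truncating the
target side chain on every frame: atoms beyond C-beta are removed and a
hydrogen is placed along the C-beta -> C-gamma direction at 1.09 A from
C-beta. Cys, Pro, Gly and Ala are excluded (mutation to Ala is structurally
forbidden or meaningless). The relative free energy is

    ddG = dG_eff(native complex) - dG_eff(mutated complex),

so a negative ddG marks a favorable native contribution of the scanned
side chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .energy import frame_effective_energy, mean_sem
from .gb import GBModelParams, NonpolarParams
from .topology import AtomSpec, Ensemble, SystemTopology

logger = logging.getLogger(__name__)

EXCLUDED_RESIDUES = frozenset({"CYS", "PRO", "GLY", "ALA"})

#: Alanine partial charges (backbone + C-beta + aliphatic H), applied to the
#: mutated residue in charge mode "ala". The placed hydrogen takes the
#: C-beta-hydrogen charge.
ALA_CHARGES = {
    "N": -0.4157, "H": 0.2719, "CA": 0.0337, "HA": 0.0823,
    "CB": -0.1825, "HB": 0.0603, "C": 0.5973, "O": -0.5679, "OXT": -0.8055,
}
#: Generic aliphatic-hydrogen LJ parameters for the placed H.
ALIPHATIC_H_LJ = (1.487, 0.0157)
H_GB = (1.20, 0.85)
CH_BOND = 1.09  # A


class AlanineScanError(ValueError):
    pass


@dataclass
class CASResult:
    residue_key: tuple[str, int, str]
    ddG: float  # kcal/mol, mean over frames
    ddG_sem: float
    native_G_eff: float
    mutant_G_eff: float
    net_charge_change: float


def truncate_to_ala(
    topology: SystemTopology,
    ensemble: Ensemble,
    residue_key: tuple[str, int, str],
    charge_mode: str = "ala",
) -> tuple[SystemTopology, Ensemble]:
    """Side-chain truncation of one residue, applied to every frame.

    ``charge_mode``:
      * ``"ala"`` (default): the kept atoms of the mutated residue take the
        bundled alanine partial charges (unlisted names keep their own).
      * ``"keep"``: kept atoms retain their native charges; only the placed
        hydrogen receives the alanine C-beta-hydrogen charge.

    The net-charge change of the system is logged.
    """
    if charge_mode not in ("ala", "keep"):
        raise AlanineScanError(f"unknown charge mode {charge_mode!r}")
    res_name = residue_key[2]
    if res_name in EXCLUDED_RESIDUES:
        raise AlanineScanError(
            f"residue {residue_key} is {res_name}: Cys, Pro, Gly and Ala are "
            "excluded from alanine scanning"
        )
    res_atoms = topology.atoms_of_residue(residue_key)
    names = {topology.names[i]: i for i in res_atoms}
    if "CB" not in names:
        raise AlanineScanError(f"residue {residue_key} has no CB atom")
    if "CG" not in names:
        raise AlanineScanError(f"residue {residue_key} has no CG atom")
    cb_i, cg_i = names["CB"], names["CG"]

    # keep backbone + CB (+ its hydrogens) of the target residue
    keep = np.ones(topology.n_atoms, dtype=bool)
    for i in res_atoms:
        nm = topology.names[i]
        if nm in ("CB",) or topology.is_backbone[i] or nm.startswith("HB"):
            continue
        keep[i] = False

    new_atoms: list[AtomSpec] = []
    old_charge = float(topology.charges.sum())
    mapping = {}
    for i in np.flatnonzero(keep):
        a = topology.atoms[i]
        if a.residue_key == residue_key:
            new_name = a.name
            q = a.charge
            if charge_mode == "ala":
                q = ALA_CHARGES.get(
                    "HB" if new_name.startswith("HB") else new_name, a.charge
                )
            a = replace(
                a, charge=q, residue_key=(residue_key[0], residue_key[1], "ALA")
            )
        mapping[i] = len(new_atoms)
        new_atoms.append(replace(a, atom_id=len(new_atoms)))
    # placed hydrogen replacing CG
    hb_q = ALA_CHARGES["HB"]
    cb_pos0 = topology.positions[cb_i]
    cg_pos0 = topology.positions[cg_i]
    direction0 = (cg_pos0 - cb_pos0) / np.linalg.norm(cg_pos0 - cb_pos0)
    new_atoms.append(
        AtomSpec(
            atom_id=len(new_atoms), name="HB9", element="H",
            residue_key=(residue_key[0], residue_key[1], "ALA"),
            position=cb_pos0 + CH_BOND * direction0, charge=hb_q,
            gb_radius=H_GB[0], gb_screen=H_GB[1],
            lj_rmin_half=ALIPHATIC_H_LJ[0], lj_epsilon=ALIPHATIC_H_LJ[1],
        )
    )
    mut_top = SystemTopology(
        new_atoms, topology.receptor_chain_ids, topology.ligand_chain_ids
    )
    dq = float(mut_top.charges.sum()) - old_charge
    logger.info(
        "truncated %s to ALA: net charge change %+.4f e", residue_key, dq
    )

    kept_idx = np.flatnonzero(keep)
    n_frames = ensemble.n_frames
    coords = np.empty((n_frames, mut_top.n_atoms, 3))
    coords[:, : len(kept_idx), :] = ensemble.coords[:, kept_idx, :]
    cb = ensemble.coords[:, cb_i, :]
    cg = ensemble.coords[:, cg_i, :]
    u = cg - cb
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    coords[:, -1, :] = cb + CH_BOND * u
    mut_top._net_charge_change = dq  # type: ignore[attr-defined]
    return mut_top, Ensemble(mut_top, coords, ensemble.times)


def cas_ddg(
    ensemble: Ensemble,
    residue_key: tuple[str, int, str],
    params: GBModelParams,
    nonpolar: NonpolarParams,
    sasa_method: str = "numeric",
    charge_mode: str = "ala",
) -> CASResult:
    """Frame-matched ddG = dG_eff(native) - dG_eff(mutant) for one residue."""
    top = ensemble.topology
    mut_top, mut_ens = truncate_to_ala(top, ensemble, residue_key, charge_mode)
    native, mutant = [], []
    for f in range(ensemble.n_frames):
        native.append(
            frame_effective_energy(
                ensemble.coords[f], top, params, nonpolar, sasa_method
            ).G_eff
        )
        mutant.append(
            frame_effective_energy(
                mut_ens.coords[f], mut_top, params, nonpolar, sasa_method
            ).G_eff
        )
    diff = np.asarray(native) - np.asarray(mutant)
    m, s = mean_sem(diff)
    return CASResult(
        residue_key=residue_key,
        ddG=m,
        ddG_sem=s,
        native_G_eff=float(np.mean(native)),
        mutant_G_eff=float(np.mean(mutant)),
        net_charge_change=getattr(mut_top, "_net_charge_change", 0.0),
    )
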