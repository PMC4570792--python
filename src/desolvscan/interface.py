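"""Geometric trajectory analysis at the complex interface.

Criteria follow the usual MD-analysis conventions for protein-protein
interfaces: van der Waals contacts are inter-chain residue pairs with any
heavy-atom distance within 4 A; hydrogen bonds require a donor-acceptor
distance <= 3.5 A and an angle <= 30 deg at the donor between the
donor->acceptor and donor->hydrogen directions; salt bridges are
oppositely-charged side-chain groups whose minimum N-O distance falls
within 4 A in at least one frame, with the mean distance over the presence
frames reported as a measure of bridge strength. Occupancy is the fraction
of analyzed frames in which the criterion holds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .topology import Ensemble, SystemTopology

CONTACT_CUTOFF = 4.0  # A, heavy atoms
HBOND_DIST_CUTOFF = 3.5  # A, donor-acceptor
HBOND_ANGLE_CUTOFF = 30.0  # deg, at the donor
SALT_BRIDGE_CUTOFF = 4.0  # A, min distance between charged groups
BONDED_H_CUTOFF = 1.2  # A, donor-hydrogen covalent inference

#: Side-chain atoms carrying the formal charge, by residue name.
POSITIVE_GROUPS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
NEGATIVE_GROUPS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


@dataclass
class InteractionRecord:
    kind: str  # contact | hbond | salt_bridge
    r1: tuple[str, int, str]
    r2: tuple[str, int, str]
    atoms: tuple[str, ...]  # participating atom names (donor/H/acceptor ...)
    presence: np.ndarray = field(default=None)  # per-frame bool flags
    occupancy: float = 1.0
    mean_distance: float = float("nan")


def _heavy_idx(top: SystemTopology, mask: np.ndarray) -> np.ndarray:
    return np.flatnonzero(mask & (top.elements != "H"))


def vdw_contacts(
    coords: np.ndarray, topology: SystemTopology, cutoff: float = CONTACT_CUTOFF
) -> list[InteractionRecord]:
    """Inter-chain residue pairs with any heavy-atom pair within ``cutoff``."""
    coords = np.asarray(coords, dtype=float)
    rec = _heavy_idx(topology, topology.receptor_mask)
    lig = _heavy_idx(topology, topology.ligand_mask)
    out = []
    d = np.linalg.norm(
        coords[rec][:, None, :] - coords[lig][None, :, :], axis=-1
    )
    seen = {}
    for a, b in np.argwhere(d <= cutoff):
        key = (topology.atoms[rec[a]].residue_key, topology.atoms[lig[b]].residue_key)
        dist = d[a, b]
        if key not in seen or dist < seen[key][0]:
            seen[key] = (dist, topology.names[rec[a]], topology.names[lig[b]])
    for (k1, k2), (dist, n1, n2) in sorted(seen.items()):
        out.append(
            InteractionRecord(
                kind="contact", r1=k1, r2=k2, atoms=(n1, n2),
                presence=np.array([True]), occupancy=1.0,
                mean_distance=float(dist),
            )
        )
    return out


def _find_donors(top: SystemTopology, coords: np.ndarray) -> list[tuple[int, int]]:
    """(donor, hydrogen) index pairs: N/O with a covalently bonded H."""
    donors = []
    h_idx = np.flatnonzero(top.elements == "H")
    for i in np.flatnonzero(np.isin(top.elements, ("N", "O"))):
        if h_idx.size == 0:
            continue
        d = np.linalg.norm(coords[h_idx] - coords[i], axis=1)
        for h in h_idx[d <= BONDED_H_CUTOFF]:
            donors.append((int(i), int(h)))
    return donors


def hydrogen_bonds(
    ensemble: Ensemble,
    dist_cutoff: float = HBOND_DIST_CUTOFF,
    angle_cutoff: float = HBOND_ANGLE_CUTOFF,
) -> list[InteractionRecord]:
    """Inter-chain hydrogen bonds with per-frame presence and occupancy.

    Donor-H pairs are inferred from the first frame; both geometric criteria
    are re-evaluated every frame.
    """
    top = ensemble.topology
    coords0 = ensemble.coords[0]
    donors = _find_donors(top, coords0)
    acceptors = np.flatnonzero(np.isin(top.elements, ("N", "O")))
    candidates = []
    for d_i, h_i in donors:
        d_rec = top.receptor_mask[d_i]
        for a_i in acceptors:
            if a_i == d_i or top.receptor_mask[a_i] == d_rec:
                continue
            candidates.append((d_i, h_i, int(a_i)))
    out = []
    for d_i, h_i, a_i in candidates:
        presence = np.zeros(ensemble.n_frames, dtype=bool)
        dists = np.zeros(ensemble.n_frames)
        for f, coords in enumerate(ensemble.coords):
            da = coords[a_i] - coords[d_i]
            dist = np.linalg.norm(da)
            dists[f] = dist
            if dist > dist_cutoff:
                continue
            dh = coords[h_i] - coords[d_i]
            cosang = np.dot(da, dh) / (dist * np.linalg.norm(dh))
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            presence[f] = angle <= angle_cutoff
        if presence.any():
            a_d, a_h, a_a = top.atoms[d_i], top.atoms[h_i], top.atoms[a_i]
            out.append(
                InteractionRecord(
                    kind="hbond", r1=a_d.residue_key, r2=a_a.residue_key,
                    atoms=(a_d.name, a_h.name, a_a.name),
                    presence=presence,
                    occupancy=float(presence.mean()),
                    mean_distance=float(dists[presence].mean()),
                )
            )
    return out


def _charged_groups(top: SystemTopology):
    """(residue_key, sign, atom indices) for every charged side-chain group."""
    groups = []
    for key in top.residues:
        res_name = key[2]
        for sign, table in ((+1, POSITIVE_GROUPS), (-1, NEGATIVE_GROUPS)):
            if res_name in table:
                atoms = top.atoms_of_residue(key)
                sel = atoms[np.isin(top.names[atoms], table[res_name])]
                if sel.size:
                    groups.append((key, sign, sel))
    return groups


def salt_bridges(
    ensemble: Ensemble, cutoff: float = SALT_BRIDGE_CUTOFF
) -> list[InteractionRecord]:
    """Oppositely-charged inter-chain pairs within ``cutoff`` in >= 1 frame."""
    top = ensemble.topology
    groups = _charged_groups(top)
    out = []
    for i, (k1, s1, a1) in enumerate(groups):
        for k2, s2, a2 in groups[i + 1:]:
            if s1 * s2 >= 0:
                continue
            if (k1[0] in top.receptor_chain_ids) == (k2[0] in top.receptor_chain_ids):
                continue
            mins = np.array(
                [
                    np.linalg.norm(
                        c[a1][:, None, :] - c[a2][None, :, :], axis=-1
                    ).min()
                    for c in ensemble.coords
                ]
            )
            presence = mins <= cutoff
            if presence.any():
                out.append(
                    InteractionRecord(
                        kind="salt_bridge", r1=k1, r2=k2,
                        atoms=tuple(top.names[a1]) + tuple(top.names[a2]),
                        presence=presence,
                        occupancy=float(presence.mean()),
                        mean_distance=float(mins[presence].mean()),
                    )
                )
    return out


# ---------------------------------------------------------------------------
# RMSD, equilibration time, clustering, distance profiles
# ---------------------------------------------------------------------------

def superpose_rmsd(ref: np.ndarray, mob: np.ndarray) -> float:
    """Least-squares (Kabsch) fitted RMSD between two coordinate sets."""
    ref = ref - ref.mean(axis=0)
    mob = mob - mob.mean(axis=0)
    with warnings.catch_warnings():
        # collinear selections have a degenerate (but valid) optimal rotation
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(ref, mob)
    fitted = rot.apply(mob)
    return float(np.sqrt(((fitted - ref) ** 2).sum(axis=1).mean()))


def rmsd_series(
    ensemble: Ensemble,
    reference_frame: int = 0,
    atom_selection: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame fitted RMSD (A) to a reference frame."""
    sel = (
        np.arange(ensemble.topology.n_atoms)
        if atom_selection is None
        else np.asarray(atom_selection)
    )
    if sel.size == 0:
        raise ValueError("empty atom selection")
    ref = ensemble.coords[reference_frame][sel]
    return np.array([superpose_rmsd(ref, c[sel]) for c in ensemble.coords])


def running_mean(series: np.ndarray) -> np.ndarray:
    s = np.asarray(series, dtype=float)
    return np.cumsum(s) / np.arange(1, len(s) + 1)


def _stabilization_index(
    series: np.ndarray, tol_fraction: float, window_fraction: float
) -> tuple[int, bool]:
    """Earliest index from which the accumulated running mean stays within
    tolerance through the end of the series; at least ``window_fraction`` of
    the frames must remain after the index. Returns (index, stabilized?);
    a never-stabilizing series yields the last admissible index and False."""
    n = len(series)
    acc = running_mean(series)
    spread = float(series.max() - series.min())
    tol = tol_fraction * spread if spread > 0 else 0.0
    w = max(2, int(np.ceil(window_fraction * n)))
    for k in range(0, n - w + 1):
        tail = acc[k:]
        if tail.max() - tail.min() <= tol:
            return k, True
    return n - w, False


def estimate_teq(
    times: np.ndarray,
    g_eff_series: np.ndarray,
    rmsd_series_values: np.ndarray,
    tol_fraction: float = 0.05,
    window_fraction: float = 0.2,
) -> tuple[float, bool]:
    """Equilibration time from accumulated means of dG_eff and RMSD.

    Returns ``(t_eq in ps, stabilized flag)``; t_eq is the later of the two
    per-series stabilization times. A never-stabilizing series yields the
    last window start and ``stabilized=False`` with a warning.
    """
    if len(times) < 10:
        raise ValueError("need at least 10 frames to estimate t_eq")
    k1, ok1 = _stabilization_index(np.asarray(g_eff_series), tol_fraction,
                                   window_fraction)
    k2, ok2 = _stabilization_index(np.asarray(rmsd_series_values), tol_fraction,
                                   window_fraction)
    stabilized = ok1 and ok2
    if not stabilized:
        warnings.warn("series never stabilizes within tolerance", stacklevel=2)
    return float(np.asarray(times)[max(k1, k2)]), stabilized


def representative_frame(
    ensemble: Ensemble,
    atom_selection: np.ndarray | None = None,
    rmsd_cutoff: float = 1.0,
) -> tuple[int, list[int]]:
    """Gromos-style neighbor-count clustering on pairwise fitted RMSD.

    Returns the representative frame index (the member with most neighbors
    in the largest cluster, ties broken by earliest time) and the cluster
    sizes in extraction order.
    """
    sel = (
        np.arange(ensemble.topology.n_atoms)
        if atom_selection is None
        else np.asarray(atom_selection)
    )
    n = ensemble.n_frames
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = superpose_rmsd(
                ensemble.coords[i][sel], ensemble.coords[j][sel]
            )
    remaining = np.ones(n, dtype=bool)
    clusters: list[tuple[int, np.ndarray]] = []
    while remaining.any():
        neigh = ((d <= rmsd_cutoff) & remaining[None, :]).sum(axis=1)
        neigh[~remaining] = -1
        center = int(np.argmax(neigh))  # argmax takes the earliest on ties
        members = np.flatnonzero((d[center] <= rmsd_cutoff) & remaining)
        clusters.append((center, members))
        remaining[members] = False
    sizes = [len(m) for _, m in clusters]
    best = int(np.argmax(sizes))
    return clusters[best][0], sizes


def distance_profile(
    ensemble: Ensemble, atom_a: int, atom_b: int
) -> np.ndarray:
    """Per-frame Euclidean distance (A) between two atoms, no fitting."""
    n = ensemble.topology.n_atoms
    if not (0 <= atom_a < n and 0 <= atom_b < n):
        raise ValueError("unknown atom index")
    return np.linalg.norm(
        ensemble.coords[:, atom_a, :] - ensemble.coords[:, atom_b, :], axis=1
    )
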