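"""Deterministic toy complexes and pseudo-trajectories.

The generator builds a two-chain mini-complex out of simplified residues
(4-8 atoms, hand-assigned charges/radii/LJ parameters) and plants the
interaction motifs the analysis stages assume:

* a Lys-like / Asp-like salt bridge with the NZ-OD1 pair at 3.0 A,
* a Ser-like donor-H-acceptor hydrogen bond at 2.9 A / 10 deg to a
  backbone carbonyl oxygen,
* an apolar Leu-like contact cluster with heavy-atom pairs under 4 A.

Pseudo-trajectories add iid isotropic Gaussian coordinate noise per frame
and can rigidly displace a designated side chain from a given frame onward,
emulating a mid-trajectory conformational switch of the P1-like side chain
out of its binding pocket. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .topology import AtomSpec, Ensemble, SystemTopology, element_from_name

# per-element GB parameters: (intrinsic radius A, descreening scale)
_GB = {"N": (1.55, 0.79), "C": (1.70, 0.72), "O": (1.50, 0.85), "H": (1.20, 0.85)}
# per-element LJ parameters: (rmin/2 A, epsilon kcal/mol)
_LJ = {"N": (1.824, 0.17), "C": (1.908, 0.1094), "O": (1.6612, 0.21),
       "H": (0.600, 0.0157)}
_LJ_APOLAR_C = (1.908, 0.1100)

# backbone template: (name, charge, local offset from the residue origin)
_BACKBONE = [
    ("N", -0.20, np.array([0.00, 0.00, 0.0])),
    ("CA", 0.20, np.array([1.45, 0.00, 0.0])),
    ("C", 0.50, np.array([2.35, 1.10, 0.0])),
    ("O", -0.50, np.array([1.75, 2.05, 0.0])),
]

# side-chain templates: (name, charge, offset); `d` flips the y direction so
# side chains point toward the partner chain
def _sidechain(res_name: str, d: float) -> list[tuple[str, float, np.ndarray]]:
    ca = np.array([1.45, 0.0, 0.0])
    cb = ca + np.array([-0.5, 1.05 * d, 0.9])
    cg = cb + np.array([0.0, 1.3 * d, 0.8])
    if res_name == "GLY":
        return []
    if res_name == "LYS":
        nz = cg + np.array([0.0, 1.4 * d, 0.0])
        hz = nz + np.array([0.0, 1.0 * d, 0.0])
        return [("CB", 0.0, cb), ("CG", 0.0, cg), ("NZ", 0.35, nz),
                ("HZ1", 0.65, hz)]
    if res_name == "ASP":
        od1 = cg + np.array([0.0, 1.2 * d, 0.5])
        od2 = cg + np.array([0.0, 1.2 * d, -0.5])
        return [("CB", -0.10, cb), ("CG", 0.30, cg), ("OD1", -0.60, od1),
                ("OD2", -0.60, od2)]
    if res_name == "LEU":
        cd1 = cg + np.array([0.0, 1.1 * d, 0.9])
        cd2 = cg + np.array([0.0, 1.1 * d, -0.9])
        return [("CB", 0.0, cb), ("CG", 0.0, cg), ("CD1", 0.0, cd1),
                ("CD2", 0.0, cd2)]
    if res_name == "SER":
        og = cb + np.array([0.0, 1.2 * d, 0.6])
        hg = og + np.array([0.0, 0.95 * d, 0.0])
        return [("CB", 0.10, cb), ("OG", -0.55, og), ("HG", 0.45, hg)]
    raise ValueError(f"unknown toy residue {res_name!r}")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic complex and its pseudo-trajectory."""

    seed: int = 0
    n_receptor_residues: int = 4
    n_ligand_residues: int = 3
    planted_motifs: frozenset = frozenset(
        {"salt_bridge", "hbond", "hydrophobic_pocket"}
    )
    noise_sigma: float = 0.1  # A; planted motifs persist with occupancy > 0.9
    n_frames: int = 100
    switch_frame: int | None = None
    switch_vector: tuple[float, float, float] = (0.0, 0.0, 4.0)

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.switch_frame is not None and not (
            0 <= self.switch_frame < self.n_frames
        ):
            raise ValueError("switch_frame must lie inside the trajectory")
        object.__setattr__(self, "planted_motifs", frozenset(self.planted_motifs))


def make_born_ion(charge: float, radius: float) -> SystemTopology:
    """Single-atom 'ligand' used by the GB engine's closed-form tests."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    atom = AtomSpec(
        atom_id=0, name="X", element="X", residue_key=("B", 1, "ION"),
        position=np.zeros(3), charge=charge, gb_radius=radius,
        gb_screen=0.8, lj_rmin_half=0.0, lj_epsilon=0.0,
    )
    return SystemTopology([atom], {"A"}, {"B"})


def _make_atom(atom_id, name, charge, pos, residue_key, apolar=False):
    element = element_from_name(name)
    gb_r, gb_s = _GB[element]
    rmin, eps = _LJ_APOLAR_C if (apolar and element == "C") else _LJ[element]
    return AtomSpec(
        atom_id=atom_id, name=name, element=element, residue_key=residue_key,
        position=np.asarray(pos, dtype=float), charge=charge,
        gb_radius=gb_r, gb_screen=gb_s, lj_rmin_half=rmin, lj_epsilon=eps,
    )


_SPACING = 5.0  # A between residue origins along x
_CHAIN_GAP = 14.0  # baseline y offset of the ligand chain


def _build_residue(res_name, chain, res_num, origin, d, apolar=False):
    key = (chain, res_num, res_name)
    atoms = []
    for name, q, off in _BACKBONE + _sidechain(res_name, d):
        atoms.append((name, q, origin + off, key, apolar))
    return atoms


def make_toy_complex(spec: FixtureSpec) -> SystemTopology:
    """Two mini-chains with the requested planted interface motifs.

    Receptor chain A lies at y=0 with side chains pointing +y; ligand chain
    B at y=14 with side chains pointing -y. Motif residues of the ligand are
    rigidly translated toward their receptor partner until the key atom
    pair sits at the planted separation (3.0 A salt bridge, 2.9 A hydrogen
    bond, 3.8 A closest apolar pair). Deterministic: no randomness enters
    the construction.
    """
    motifs = spec.planted_motifs
    rec_names = ["LYS" if "salt_bridge" in motifs else "GLY",
                 "GLY",
                 "LEU" if "hydrophobic_pocket" in motifs else "GLY"]
    lig_names = ["ASP" if "salt_bridge" in motifs else "GLY",
                 "SER" if "hbond" in motifs else "GLY",
                 "LEU" if "hydrophobic_pocket" in motifs else "GLY"]
    while len(rec_names) < spec.n_receptor_residues:
        rec_names.append("GLY")
    if spec.n_receptor_residues >= 4:
        # scannable neutral probe far from the interface
        rec_names[-1] = "LEU"
    while len(lig_names) < spec.n_ligand_residues:
        lig_names.append("GLY")
    rec_names = rec_names[: max(spec.n_receptor_residues, 3)]
    lig_names = lig_names[: max(spec.n_ligand_residues, 3)]

    raw = []
    for i, rn in enumerate(rec_names):
        origin = np.array([_SPACING * i, 0.0, 0.0])
        raw += _build_residue(rn, "A", i + 1, origin, +1.0, apolar=(rn == "LEU"))
    lig_start = len(raw)
    lig_res_slices = []
    for j, rn in enumerate(lig_names):
        origin = np.array([_SPACING * j, _CHAIN_GAP, 0.0])
        start = len(raw)
        raw += _build_residue(rn, "B", j + 1, origin, -1.0, apolar=(rn == "LEU"))
        lig_res_slices.append((start, len(raw)))

    def find(chain_slice, res_idx, name):
        lo, hi = chain_slice[res_idx]
        for k in range(lo, hi):
            if raw[k][0] == name:
                return k
        raise KeyError(name)

    rec_slices = []
    pos = 0
    for rn in rec_names:
        n = 4 + len(_sidechain(rn, 1.0))
        rec_slices.append((pos, pos + n))
        pos += n

    def pull_residue(res_idx, lig_atom, rec_atom, target):
        """Translate ligand residue res_idx in -y until |a-b| = target."""
        ka = find(lig_res_slices, res_idx, lig_atom)
        kb = find(rec_slices, res_idx, rec_atom)
        pa, pb = raw[ka][2], raw[kb][2]
        dx, dz = pa[0] - pb[0], pa[2] - pb[2]
        reach2 = target**2 - dx**2 - dz**2
        if reach2 <= 0:
            raise ValueError("planted separation unreachable")
        new_dy = np.sqrt(reach2)
        shift = (pa[1] - pb[1]) - new_dy
        lo, hi = lig_res_slices[res_idx]
        for k in range(lo, hi):
            raw[k] = (raw[k][0], raw[k][1], raw[k][2] - np.array([0.0, shift, 0.0]),
                      raw[k][3], raw[k][4])

    if "salt_bridge" in motifs:
        pull_residue(0, "OD1", "NZ", 3.0)
    if "hbond" in motifs:
        pull_residue(1, "OG", "O", 2.9)
        # re-place the hydroxyl H at 10 deg off the donor->acceptor axis
        kog = find(lig_res_slices, 1, "OG")
        khg = find(lig_res_slices, 1, "HG")
        ko = find(rec_slices, 1, "O")
        u = raw[ko][2] - raw[kog][2]
        u = u / np.linalg.norm(u)
        perp = np.cross(u, [1.0, 0.0, 0.0])
        perp = perp / np.linalg.norm(perp)
        ang = np.deg2rad(10.0)
        hpos = raw[kog][2] + 0.95 * (np.cos(ang) * u + np.sin(ang) * perp)
        raw[khg] = (raw[khg][0], raw[khg][1], hpos, raw[khg][3], raw[khg][4])
    if "hydrophobic_pocket" in motifs:
        pull_residue(2, "CD1", "CD1", 3.8)

    atoms = [
        _make_atom(k, name, q, p, key, apolar)
        for k, (name, q, p, key, apolar) in enumerate(raw)
    ]
    return SystemTopology(atoms, {"A"}, {"B"})


def switch_atom_indices(topology: SystemTopology) -> np.ndarray:
    """Atoms displaced by the conformational switch: the side chain of the
    first receptor residue (the planted Lys-like P1 analog)."""
    key = topology.residues[0]
    atoms = topology.atoms_of_residue(key)
    return atoms[~topology.is_backbone[atoms]]


def make_pseudo_trajectory(
    topology: SystemTopology, spec: FixtureSpec, dt_ps: float = 10.0
) -> Ensemble:
    """Gaussian-noise pseudo-trajectory, optionally with a side-chain switch.

    Frame k = base coordinates + iid N(0, noise_sigma) per coordinate; from
    ``switch_frame`` onward the designated side chain is rigidly displaced
    by ``switch_vector``. Bitwise reproducible for a given spec.
    """
    if spec.n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(spec.seed)
    base = topology.positions
    coords = np.empty((spec.n_frames, topology.n_atoms, 3))
    switch_idx = (
        switch_atom_indices(topology) if spec.switch_frame is not None else None
    )
    vec = np.asarray(spec.switch_vector, dtype=float)
    for k in range(spec.n_frames):
        frame = base + rng.normal(0.0, spec.noise_sigma, size=base.shape)
        if switch_idx is not None and k >= spec.switch_frame:
            frame[switch_idx] += vec
        coords[k] = frame
    times = dt_ps * np.arange(spec.n_frames)
    return Ensemble(topology, coords, times)


def write_fixture(spec: FixtureSpec, prefix: str | Path) -> dict[str, Path]:
    """Write topology/params/ensemble files for a fixture spec."""
    from .topology import write_ensemble, write_topology

    prefix = Path(prefix)
    top = make_toy_complex(spec)
    ens = make_pseudo_trajectory(top, spec)
    paths = {
        "topology": prefix.with_suffix(".pqr"),
        "params": prefix.with_suffix(".params.tsv"),
        "ensemble": prefix.with_suffix(".pdb"),
    }
    write_topology(top, paths["topology"], paths["params"])
    write_ensemble(ens, paths["ensemble"])
    return paths
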