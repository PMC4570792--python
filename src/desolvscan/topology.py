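"""Complex topologies and conformational ensembles.

A two-chain (receptor:ligand) complex is described by an extended PQR text
file -- one whitespace-separated record per atom with columns

    atom_id  name  res_name  chain  res_num  x  y  z  charge  gb_radius

(coordinates in Angstrom, charge in elementary charges, intrinsic Born
radius in Angstrom) -- plus a TSV parameter table keyed by
``(res_name, atom_name)`` supplying the Lennard-Jones well depth and
half-rmin and the dimensionless GB descreening scale of every atom.
Conformational ensembles are multi-model PDB files over a fixed topology;
frame times are metadata (default 10 ps spacing), never parsed from the PDB.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure.io.pdb import PDBFile

#: Atom names treated as backbone; everything else is side chain.
#: Glycine consequently has an empty side chain.
BACKBONE_NAMES = frozenset({"N", "H", "CA", "HA", "HA2", "HA3", "C", "O", "OXT"})


class TopologyError(ValueError):
    """Malformed or inconsistent topology/ensemble input."""


def element_from_name(name: str) -> str:
    """Leading alphabetic character of the atom name (NZ -> N, HB1 -> H)."""
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise TopologyError(f"cannot infer element from atom name {name!r}")


@dataclass(frozen=True)
class AtomSpec:
    """One atom of the complex with its electrostatic and LJ parameters."""

    atom_id: int
    name: str
    element: str
    residue_key: tuple[str, int, str]  # (chain, residue number, residue name)
    position: np.ndarray  # (3,) Angstrom
    charge: float  # e
    gb_radius: float  # intrinsic Born radius rho_i, Angstrom
    gb_screen: float  # dimensionless descreening scale S_i
    lj_rmin_half: float  # Angstrom
    lj_epsilon: float  # kcal/mol

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_NAMES

    def __post_init__(self):
        if self.gb_radius <= 0:
            raise TopologyError(
                f"atom {self.atom_id} ({self.name}): gb_radius must be > 0"
            )
        if self.lj_epsilon < 0:
            raise TopologyError(
                f"atom {self.atom_id} ({self.name}): lj_epsilon must be >= 0"
            )
        if not self.element:
            raise TopologyError(f"atom {self.atom_id}: empty element")


class SystemTopology:
    """Atoms of a receptor:ligand complex partitioned into two chain sets.

    Exposes vectorized parameter arrays (``charges``, ``gb_radii`` ...) and
    boolean masks (``receptor_mask``, ``ligand_mask``) used throughout the
    energy engine. Residue keys are opaque ``(chain, resnum, resname)``
    labels in order of first appearance.
    """

    def __init__(
        self,
        atoms: list[AtomSpec],
        receptor_chain_ids: set[str],
        ligand_chain_ids: set[str],
    ):
        if not atoms:
            raise TopologyError("topology has no atoms")
        receptor_chain_ids = set(receptor_chain_ids)
        ligand_chain_ids = set(ligand_chain_ids)
        if receptor_chain_ids & ligand_chain_ids:
            raise TopologyError("receptor and ligand chain sets overlap")
        ids = [a.atom_id for a in atoms]
        if ids != list(range(len(atoms))):
            dupes = {i for i in ids if ids.count(i) > 1}
            if dupes:
                raise TopologyError(f"duplicate atom ids: {sorted(dupes)}")
            raise TopologyError("atom ids must be contiguous from 0")
        for a in atoms:
            chain = a.residue_key[0]
            if chain not in receptor_chain_ids and chain not in ligand_chain_ids:
                raise TopologyError(
                    f"atom {a.atom_id} ({a.name}): chain {chain!r} is in "
                    "neither the receptor nor the ligand partition"
                )
        self.atoms = list(atoms)
        self.receptor_chain_ids = receptor_chain_ids
        self.ligand_chain_ids = ligand_chain_ids

        self.positions = np.array([a.position for a in atoms], dtype=float)
        self.charges = np.array([a.charge for a in atoms])
        self.gb_radii = np.array([a.gb_radius for a in atoms])
        self.gb_screens = np.array([a.gb_screen for a in atoms])
        self.lj_rmin_half = np.array([a.lj_rmin_half for a in atoms])
        self.lj_epsilon = np.array([a.lj_epsilon for a in atoms])
        self.elements = np.array([a.element for a in atoms])
        self.names = np.array([a.name for a in atoms])
        self.is_backbone = np.array([a.is_backbone for a in atoms])
        self.receptor_mask = np.array(
            [a.residue_key[0] in receptor_chain_ids for a in atoms]
        )
        self.ligand_mask = ~self.receptor_mask

        self.residues: list[tuple[str, int, str]] = []
        seen: dict[tuple[str, int, str], int] = {}
        res_index = np.empty(len(atoms), dtype=int)
        for a in atoms:
            if a.residue_key not in seen:
                seen[a.residue_key] = len(self.residues)
                self.residues.append(a.residue_key)
            res_index[a.atom_id] = seen[a.residue_key]
        self.residue_index = res_index

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atoms_of_residue(self, key: tuple[str, int, str]) -> np.ndarray:
        """Indices of the atoms of a residue, in topology order."""
        idx = self.residues.index(key)
        return np.flatnonzero(self.residue_index == idx)

    def subset(self, mask: np.ndarray) -> "SystemTopology":
        """Topology restricted to ``mask`` atoms (ids renumbered from 0)."""
        chains = {a.residue_key[0] for a, m in zip(self.atoms, mask) if m}
        atoms = [
            replace(a, atom_id=k)
            for k, a in enumerate(a for a, m in zip(self.atoms, mask) if m)
        ]
        return SystemTopology(
            atoms,
            self.receptor_chain_ids & chains or {"__r__"},
            self.ligand_chain_ids & chains or {"__l__"},
        )


@dataclass
class Ensemble:
    """Ordered coordinate frames (times in ps) over a fixed topology."""

    topology: SystemTopology
    coords: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    times: np.ndarray  # (n_frames,), ps

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TopologyError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"frames have {self.coords.shape[1]} atoms, topology has "
                f"{self.topology.n_atoms}"
            )
        if len(self.times) != len(self.coords):
            raise TopologyError("one time per frame required")
        if len(self.times) == 0:
            raise TopologyError("ensemble has zero frames")
        if np.any(np.diff(self.times) <= 0):
            raise TopologyError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def __iter__(self):
        return iter(self.coords)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_params(path: str | Path) -> dict[tuple[str, str], tuple[float, float, float]]:
    """Parameter table: (res_name, atom_name) -> (screen, rmin/2, epsilon)."""
    table: dict[tuple[str, str], tuple[float, float, float]] = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) != 5:
            raise TopologyError(
                f"{path}: line {ln}: expected 5 columns "
                "(res_name atom_name gb_screen lj_rmin_half lj_epsilon), "
                f"got {len(cols)}"
            )
        try:
            table[(cols[0], cols[1])] = (
                float(cols[2]), float(cols[3]), float(cols[4])
            )
        except ValueError as exc:
            raise TopologyError(f"{path}: line {ln}: {exc}") from exc
    return table


def read_topology(
    path: str | Path,
    params_path: str | Path,
    receptor_chain_ids: set[str] | None = None,
    ligand_chain_ids: set[str] | None = None,
) -> SystemTopology:
    """Read an extended-PQR topology plus its LJ/GB parameter table.

    If the chain partitions are not given, the first chain encountered is the
    receptor and all remaining chains form the ligand. Atoms missing from the
    parameter table raise a :class:`TopologyError` naming the atom.
    """
    params = read_params(params_path)
    atoms: list[AtomSpec] = []
    chain_order: list[str] = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) != 10:
            raise TopologyError(
                f"{path}: line {ln}: expected 10 columns, got {len(cols)}"
            )
        try:
            atom_id = int(cols[0])
            name, res_name, chain = cols[1], cols[2], cols[3]
            res_num = int(cols[4])
            pos = np.array([float(cols[5]), float(cols[6]), float(cols[7])])
            charge = float(cols[8])
            gb_radius = float(cols[9])
        except ValueError as exc:
            raise TopologyError(f"{path}: line {ln}: {exc}") from exc
        key = (res_name, name)
        if key not in params:
            raise TopologyError(
                f"atom {atom_id} ({res_name} {res_num} {name}, chain {chain}) "
                "is missing from the parameter table"
            )
        screen, rmin_half, eps = params[key]
        if chain not in chain_order:
            chain_order.append(chain)
        atoms.append(
            AtomSpec(
                atom_id=atom_id,
                name=name,
                element=element_from_name(name),
                residue_key=(chain, res_num, res_name),
                position=pos,
                charge=charge,
                gb_radius=gb_radius,
                gb_screen=screen,
                lj_rmin_half=rmin_half,
                lj_epsilon=eps,
            )
        )
    if not atoms:
        raise TopologyError(f"{path}: no atom records")
    if receptor_chain_ids is None:
        receptor_chain_ids = {chain_order[0]}
        ligand_chain_ids = set(chain_order[1:])
    if not ligand_chain_ids:
        raise TopologyError("ligand partition is empty")
    return SystemTopology(atoms, set(receptor_chain_ids), set(ligand_chain_ids))


def write_topology(
    topology: SystemTopology, path: str | Path, params_path: str | Path
) -> None:
    """Write the extended-PQR file and its parameter table."""
    with open(path, "w") as fh:
        fh.write("# atom_id name res_name chain res_num x y z charge gb_radius\n")
        for a in topology.atoms:
            chain, res_num, res_name = a.residue_key
            fh.write(
                f"{a.atom_id} {a.name} {res_name} {chain} {res_num} "
                f"{a.position[0]:.6f} {a.position[1]:.6f} {a.position[2]:.6f} "
                f"{a.charge:.6f} {a.gb_radius:.6f}\n"
            )
    seen: set[tuple[str, str]] = set()
    with open(params_path, "w") as fh:
        fh.write("# res_name atom_name gb_screen lj_rmin_half lj_epsilon\n")
        for a in topology.atoms:
            key = (a.residue_key[2], a.name)
            if key in seen:
                continue
            seen.add(key)
            fh.write(
                f"{key[0]} {key[1]} {a.gb_screen:.6f} "
                f"{a.lj_rmin_half:.6f} {a.lj_epsilon:.6f}\n"
            )


def read_ensemble(
    path: str | Path,
    topology: SystemTopology,
    dt_ps: float = 10.0,
    t0_ps: float = 0.0,
) -> Ensemble:
    """Read a multi-model PDB into an :class:`Ensemble`.

    Models are taken in MODEL-index order; frame k receives time
    ``t0_ps + k * dt_ps``. Every model must contain exactly one atom per
    topology atom, in topology order.
    """
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise TopologyError(f"{path}: zero models")
    frames = []
    for m in range(1, n_models + 1):
        coords = pdb.get_coord(model=m)
        if coords.shape[0] != topology.n_atoms:
            raise TopologyError(
                f"{path}: model {m} has {coords.shape[0]} atoms, "
                f"topology has {topology.n_atoms}"
            )
        frames.append(coords)
    times = t0_ps + dt_ps * np.arange(n_models)
    return Ensemble(topology, np.array(frames), times)


def write_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write the ensemble as a multi-model PDB (biotite)."""
    top = ensemble.topology
    template = AtomArray(top.n_atoms)
    for i, a in enumerate(top.atoms):
        template.chain_id[i] = a.residue_key[0]
        template.res_id[i] = a.residue_key[1]
        template.res_name[i] = a.residue_key[2]
        template.atom_name[i] = a.name
        template.element[i] = a.element
        template.hetero[i] = False
    stack = AtomArrayStack(ensemble.n_frames, top.n_atoms)
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = ensemble.coords.astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def restrict_frames(ensemble: Ensemble, t_start: float, t_end: float) -> Ensemble:
    """Frames with ``t_start <= t <= t_end`` (the productive window)."""
    if t_start >= t_end:
        raise TopologyError("t_start must be < t_end")
    mask = (ensemble.times >= t_start) & (ensemble.times <= t_end)
    if not mask.any():
        raise TopologyError(
            f"window [{t_start}, {t_end}] ps selects no frames "
            f"(ensemble spans [{ensemble.times[0]}, {ensemble.times[-1]}] ps)"
        )
    return Ensemble(ensemble.topology, ensemble.coords[mask], ensemble.times[mask])
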