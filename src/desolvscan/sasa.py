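"""Solvent-accessible surface areas.

Two routes are provided: ``numeric`` is Shrake-Rupley sphere-point sampling
(the independent oracle, also used for per-residue SA attribution) and
``lcpo`` is the Linear Combination of Pairwise Overlaps approximation with
the published parameter set keyed by element and bonded-heavy-neighbor
count. Both operate on heavy atoms by default (hydrogens carry negligible
area and the LCPO parameterization omits them); atom radii are the
intrinsic Born radii plus the solvent probe radius.
"""

from __future__ import annotations

import warnings

import numpy as np

from .gb import NonpolarParams

#: LCPO parameters (P1, P2, P3, P4) keyed by (element, n bonded heavy atoms).
#: Standard published values for sp3 C/N, carbonyl/ether O and S.
LCPO_PARAMS: dict[tuple[str, int], tuple[float, float, float, float]] = {
    ("C", 1): (0.77887, -0.28063, -0.0012968, 0.00039328),
    ("C", 2): (0.56482, -0.19608, -0.0010219, 0.0002658),
    ("C", 3): (0.23348, -0.072627, -0.00020079, 0.00007967),
    ("C", 4): (0.00000, 0.00000, 0.00000, 0.00000),
    ("N", 1): (0.78602, -0.29198, -0.0006537, 0.00036247),
    ("N", 2): (0.22599, -0.036648, -0.0012297, 0.000080038),
    ("N", 3): (0.051481, -0.012603, -0.00032006, 0.000024774),
    ("O", 1): (0.68563, -0.18680, -0.00135573, 0.00023743),
    ("O", 2): (0.49392, -0.16038, -0.00015512, 0.00016453),
    ("S", 1): (0.77220, -0.26393, 0.0010629, 0.0002179),
    ("S", 2): (0.54581, -0.19477, -0.0012873, 0.00029247),
}

#: Distance below which two heavy atoms count as covalently bonded (A).
BOND_CUTOFF = 1.6


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def sasa_numeric(
    coords: np.ndarray,
    radii: np.ndarray,
    nonpolar: NonpolarParams | None = None,
    elements: np.ndarray | None = None,
    n_points: int = 960,
    include_hydrogens: bool = False,
) -> tuple[float, np.ndarray]:
    """Shrake-Rupley SASA: total and per-atom areas (A^2).

    ``radii`` are intrinsic atom radii; the probe radius from ``nonpolar``
    (default 1.4 A) is added. Hydrogens (by ``elements``) are excluded from
    both the surface and the occlusion set unless ``include_hydrogens``.
    Per-atom areas are non-negative by construction.
    """
    nonpolar = nonpolar or NonpolarParams()
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(radii)
    keep = np.ones(n, dtype=bool)
    if elements is not None and not include_hydrogens:
        keep = np.asarray(elements) != "H"
    areas = np.zeros(n)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        return 0.0, areas
    pos = coords[idx]
    R = radii[idx] + nonpolar.probe_radius
    sphere = _fibonacci_sphere(n_points)
    for a, i in enumerate(idx):
        pts = pos[a] + R[a] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for b in range(len(idx)):
            if b == a:
                continue
            d2 = ((pts - pos[b]) ** 2).sum(axis=1)
            accessible &= d2 > R[b] ** 2
        areas[i] = 4.0 * np.pi * R[a] ** 2 * accessible.mean()
    return float(areas.sum()), areas


def _buried_area(Ri: float, Rj: float, d: float) -> float:
    """Area of sphere i buried inside overlapping sphere j (A_ij of LCPO)."""
    return 2.0 * np.pi * Ri * (Ri - d / 2.0 - (Ri**2 - Rj**2) / (2.0 * d))


def heavy_neighbor_counts(
    coords: np.ndarray, elements: np.ndarray, cutoff: float = BOND_CUTOFF
) -> np.ndarray:
    """Bonded heavy-atom counts inferred geometrically (d < cutoff)."""
    coords = np.asarray(coords, dtype=float)
    heavy = np.asarray(elements) != "H"
    counts = np.zeros(len(coords), dtype=int)
    hidx = np.flatnonzero(heavy)
    for i in hidx:
        d = np.linalg.norm(coords[hidx] - coords[i], axis=1)
        counts[i] = int(((d > 1e-6) & (d < cutoff)).sum())
    return counts


def sasa_lcpo(
    coords: np.ndarray,
    radii: np.ndarray,
    elements: np.ndarray,
    nonpolar: NonpolarParams | None = None,
) -> tuple[float, np.ndarray]:
    """LCPO approximation to the SASA: total and per-atom areas (A^2).

    A_i = P1*S1 + P2*sum_j A_ij + P3*sum_{j,k} A_jk + P4*sum_j A_ij*sum_k A_jk
    over overlapping neighbor spheres, with parameters looked up by
    (element, bonded-heavy-neighbor count). Atoms with no published class
    fall back to the numeric estimate with a warning. Hydrogens carry zero
    LCPO area.
    """
    nonpolar = nonpolar or NonpolarParams()
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    elements = np.asarray(elements)
    heavy = elements != "H"
    idx = np.flatnonzero(heavy)
    n = len(idx)
    areas = np.zeros(len(coords))
    if n == 0:
        return 0.0, areas
    pos = coords[idx]
    R = radii[idx] + nonpolar.probe_radius
    bond_counts = heavy_neighbor_counts(coords, elements)[idx]

    # overlap neighbor lists and pairwise buried areas among heavy atoms
    d = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1))
    overlap = (d < R[:, None] + R[None, :]) & (d > 1e-6)
    A = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if overlap[a, b]:
                A[a, b] = _buried_area(R[a], R[b], d[a, b])
    A = np.clip(A, 0.0, None)

    fallback: list[int] = []
    for a in range(n):
        key = (str(elements[idx[a]]), int(bond_counts[a]))
        if key not in LCPO_PARAMS:
            fallback.append(a)
            continue
        p1, p2, p3, p4 = LCPO_PARAMS[key]
        nb = np.flatnonzero(overlap[a])
        s1 = 4.0 * np.pi * R[a] ** 2
        term2 = A[a, nb].sum()
        term3 = 0.0
        term4 = 0.0
        for j in nb:
            shared = nb[overlap[j, nb]]
            ajk = A[j, shared].sum()
            term3 += ajk
            term4 += A[a, j] * ajk
        areas[idx[a]] = max(0.0, p1 * s1 + p2 * term2 + p3 * term3 + p4 * term4)
    if fallback:
        warnings.warn(
            f"no LCPO class for {len(fallback)} atom(s); using numeric areas",
            stacklevel=2,
        )
        _, num = sasa_numeric(coords, radii, nonpolar, elements)
        for a in fallback:
            areas[idx[a]] = num[idx[a]]
    return float(areas.sum()), areas


def sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    elements: np.ndarray,
    nonpolar: NonpolarParams | None = None,
    method: str = "lcpo",
    n_points: int = 960,
) -> tuple[float, np.ndarray]:
    """Dispatch to :func:`sasa_lcpo` or :func:`sasa_numeric`."""
    if method == "lcpo":
        return sasa_lcpo(coords, radii, elements, nonpolar)
    if method == "numeric":
        return sasa_numeric(coords, radii, nonpolar, elements, n_points=n_points)
    raise ValueError(f"unknown SASA method {method!r}")
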