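"""Generalized-Born (OBC), Coulomb and Lennard-Jones energies.

Implements the implicit-solvent polar term of the MM-GBSA post-processing
pipeline: pairwise-descreening effective Born radii with the OBC tanh
rescaling, the Still pairwise GB energy with Debye-Hueckel salt screening,
plus the vacuum Coulomb and 12-6 Lennard-Jones (Lorentz-Berthelot) terms.

Pair matrices follow one convention throughout: the diagonal holds self
terms, off-diagonal entries hold *half* of the full pair energy in each of
the two symmetric slots, so that ``matrix.sum()`` equals the total energy.
``pair_energy_between(matrix, mask_a, mask_b)`` recovers the full cross
energy between two disjoint atom groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Electrostatic conversion constant, kcal*A/(mol*e^2).
COULOMB_CONSTANT = 332.0636

#: OBC tanh-rescaling coefficient sets (alpha, beta, gamma).
OBC_COEFFICIENTS = {
    "OBC1": (0.8, 0.0, 2.909125),
    "OBC2": (1.0, 0.8, 4.85),
}


class EnergyError(ValueError):
    """Non-finite or ill-posed energy evaluation."""


@dataclass
class GBModelParams:
    """Settings of the GB-OBC polar-solvation model.

    ``salt_molar`` enters through the Debye screening constant
    ``kappa = 0.329 * sqrt(salt)`` (1/Angstrom, aqueous solution at 298 K),
    attenuated by ``kappa_scale`` (0.73) inside the exponential as in common
    GB implementations. ``rgbmax`` truncates only the descreening sum used
    for effective radii; Coulomb and LJ are evaluated without cutoff.
    """

    model: str = "OBC2"
    eps_in: float = 1.0
    eps_w: float = 78.3
    salt_molar: float = 0.0
    rgbmax: float = 25.0
    radius_offset: float = 0.09
    kappa_scale: float = 0.73
    alpha: float = field(init=False)
    beta_obc: float = field(init=False)
    gamma_obc: float = field(init=False)

    def __post_init__(self):
        if self.model not in OBC_COEFFICIENTS:
            raise EnergyError(
                f"unknown GB model {self.model!r}; choose from "
                f"{sorted(OBC_COEFFICIENTS)}"
            )
        if not (self.eps_w > self.eps_in >= 1.0):
            raise EnergyError("require eps_w > eps_in >= 1")
        if self.rgbmax <= 0:
            raise EnergyError("rgbmax must be > 0")
        if self.salt_molar < 0:
            raise EnergyError("salt_molar must be >= 0")
        self.alpha, self.beta_obc, self.gamma_obc = OBC_COEFFICIENTS[self.model]

    @property
    def kappa(self) -> float:
        """Debye screening constant, 1/Angstrom."""
        return 0.329 * np.sqrt(self.salt_molar)


@dataclass
class NonpolarParams:
    """Surface-area nonpolar solvation term G_SA = gamma*SA + beta."""

    gamma_sa: float = 0.0072  # kcal/(A^2 mol)
    beta_sa: float = 0.0  # kcal/mol
    probe_radius: float = 1.4  # Angstrom

    def __post_init__(self):
        if self.gamma_sa < 0:
            raise EnergyError("gamma_sa must be >= 0")


# ---------------------------------------------------------------------------
# effective Born radii
# ---------------------------------------------------------------------------

def _descreening_integral(rho_i: np.ndarray, s_j: np.ndarray, r: np.ndarray):
    """Analytic pairwise-descreening (HCT) integral H(r_ij, s_j * rho_j).

    ``rho_i`` are the offset-reduced intrinsic radii of the descreened atoms,
    ``s_j`` the scaled radii of the descreening spheres, ``r`` the distances;
    all arrays broadcast together. Fully engulfed descreeners contribute 0;
    the piecewise correction applies when atom i sits inside the descreening
    sphere.
    """
    L = np.maximum(np.abs(r - s_j), rho_i)
    U = r + s_j
    with np.errstate(divide="ignore", invalid="ignore"):
        core = 0.5 * (
            1.0 / L
            - 1.0 / U
            + 0.25 * (r - s_j**2 / r) * (1.0 / U**2 - 1.0 / L**2)
            + 0.5 / r * np.log(L / U)
        )
        inside = 2.0 * (1.0 / rho_i - 1.0 / L)
    H = np.where(rho_i < U, core, 0.0)
    H = H + np.where(rho_i < s_j - r, inside, 0.0)
    return H


def effective_born_radii(
    coords: np.ndarray,
    gb_radii: np.ndarray,
    gb_screens: np.ndarray,
    params: GBModelParams,
) -> np.ndarray:
    """Per-atom effective Born radii R_i (Angstrom) via OBC.

    R_i = [rho_t^-1 - rho^-1 * tanh(alpha*Psi - beta*Psi^2 + gamma*Psi^3)]^-1
    with rho_t = rho - offset and Psi = rho_t * sum_j H(r_ij, S_j*rho_t_j),
    the sum truncated at ``rgbmax``.
    """
    coords = np.asarray(coords, dtype=float)
    rho = np.asarray(gb_radii, dtype=float)
    if np.any(rho <= params.radius_offset):
        bad = np.flatnonzero(rho <= params.radius_offset)
        raise EnergyError(
            f"gb_radius must exceed the radius offset for atoms {bad.tolist()}"
        )
    rho_t = rho - params.radius_offset
    n = len(rho)
    if n == 1:
        psi_sum = np.zeros(1)
    else:
        diff = coords[:, None, :] - coords[None, :, :]
        r = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(r, np.inf)
        s_j = (gb_screens * rho_t)[None, :]
        H = _descreening_integral(rho_t[:, None], s_j, r)
        H = np.where(r <= params.rgbmax, H, 0.0)
        psi_sum = H.sum(axis=1)
    psi = rho_t * psi_sum
    tanh_arg = (
        params.alpha * psi
        - params.beta_obc * psi**2
        + params.gamma_obc * psi**3
    )
    inv_R = 1.0 / rho_t - np.tanh(tanh_arg) / rho
    if np.any(inv_R <= 0) or not np.all(np.isfinite(inv_R)):
        bad = np.flatnonzero((inv_R <= 0) | ~np.isfinite(inv_R))
        raise EnergyError(
            f"non-positive/non-finite effective radius for atoms {bad.tolist()}"
            " (overlapping identical atoms?)"
        )
    return 1.0 / inv_R


def descreening_integral_numeric(
    rho_i: float, s_j: float, r: float, n_r: int = 400, n_theta: int = 400
) -> float:
    """Direct numerical Coulomb-field integral over one descreening sphere.

    Independent oracle for :func:`_descreening_integral`: evaluates
    (1/4pi) * Int r'^-4 dV over the part of the sphere of radius ``s_j``
    centred at distance ``r`` that lies outside the atom's own sphere
    ``rho_i``, by midpoint quadrature in spherical coordinates around atom i.
    """
    lo = max(rho_i, r - s_j)
    hi = r + s_j
    if hi <= lo:
        return 0.0
    rr = np.linspace(lo, hi, n_r + 1)
    rr = 0.5 * (rr[1:] + rr[:-1])
    dr = (hi - lo) / n_r
    mu = np.linspace(-1.0, 1.0, n_theta + 1)
    mu = 0.5 * (mu[1:] + mu[:-1])
    dmu = 2.0 / n_theta
    R2, MU = np.meshgrid(rr, mu, indexing="ij")
    # distance from the descreener centre (on the z axis at distance r)
    d2 = R2**2 + r**2 - 2.0 * R2 * r * MU
    inside = d2 <= s_j**2
    integrand = np.where(inside, 1.0 / R2**2, 0.0)
    return 0.5 * float((integrand * dr * dmu).sum())


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

def _pair_distances(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(-1))


def gb_polar_energy(
    coords: np.ndarray,
    charges: np.ndarray,
    born_radii: np.ndarray,
    params: GBModelParams,
) -> tuple[float, np.ndarray]:
    """GB polar-solvation energy and its pair matrix (kcal/mol).

    Pair term: -k_e * q_i q_j * (1/eps_in - exp(-kappa*scale*f)/eps_w) / f
    with f_GB = sqrt(r^2 + R_i R_j exp(-r^2 / (4 R_i R_j))); the self term
    uses f = R_i and a 1/2 factor. Matrix convention: diagonal = self terms,
    off-diagonal slots each hold half a pair term, so the matrix sums to the
    total.
    """
    coords = np.asarray(coords, dtype=float)
    q = np.asarray(charges, dtype=float)
    R = np.asarray(born_radii, dtype=float)
    r = _pair_distances(coords)
    RiRj = np.outer(R, R)
    f = np.sqrt(r**2 + RiRj * np.exp(-(r**2) / (4.0 * RiRj)))
    np.fill_diagonal(f, R)
    kap = params.kappa * params.kappa_scale
    dielec = 1.0 / params.eps_in - np.exp(-kap * f) / params.eps_w
    E = -COULOMB_CONSTANT * np.outer(q, q) * dielec / f
    matrix = 0.5 * E  # halves off-diagonal; 1/2 self factor on the diagonal
    total = float(matrix.sum())
    if not np.isfinite(total):
        raise EnergyError("non-finite GB energy")
    return total, matrix


def coulomb_energy(
    coords: np.ndarray, charges: np.ndarray, eps_in: float = 1.0
) -> tuple[float, np.ndarray]:
    """Vacuum (eps_in-scaled) Coulomb energy and pair matrix, no cutoff."""
    coords = np.asarray(coords, dtype=float)
    q = np.asarray(charges, dtype=float)
    r = _pair_distances(coords)
    qq = np.outer(q, q)
    coincident = (r < 1e-9) & (np.abs(qq) > 0)
    np.fill_diagonal(coincident, False)
    if coincident.any():
        i, j = np.argwhere(coincident)[0]
        raise EnergyError(f"coincident charged atoms {i} and {j}")
    np.fill_diagonal(r, np.inf)
    matrix = 0.5 * COULOMB_CONSTANT * qq / (eps_in * r)
    np.fill_diagonal(matrix, 0.0)
    return float(matrix.sum()), matrix


def lj_energy(
    coords: np.ndarray, rmin_half: np.ndarray, epsilon: np.ndarray
) -> tuple[float, np.ndarray]:
    """12-6 Lennard-Jones energy and pair matrix (Lorentz-Berthelot)."""
    coords = np.asarray(coords, dtype=float)
    r = _pair_distances(coords)
    np.fill_diagonal(r, np.inf)
    rmin = np.add.outer(rmin_half, rmin_half)
    eps = np.sqrt(np.outer(epsilon, epsilon))
    with np.errstate(divide="ignore", over="ignore"):
        sr6 = np.where(eps > 0, (rmin / r) ** 6, 0.0)
    matrix = 0.5 * eps * (sr6**2 - 2.0 * sr6)
    np.fill_diagonal(matrix, 0.0)
    return float(matrix.sum()), matrix


def pair_energy_between(
    matrix: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray
) -> float:
    """Full cross energy between two disjoint atom groups."""
    return 2.0 * float(matrix[np.ix_(mask_a, mask_b)].sum())


def nonpolar_energy(delta_sa: float, nonpolar: NonpolarParams) -> float:
    """Nonpolar solvation term gamma * dSA + beta (kcal/mol)."""
    return nonpolar.gamma_sa * delta_sa + nonpolar.beta_sa
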