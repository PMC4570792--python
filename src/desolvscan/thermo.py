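"""Thermodynamic conversions and agreement statistics.

Relative binding free energies and inhibition-constant ratios are related
by ddG = RT ln(Ki1/Ki2) with R = 1.9872e-3 kcal/(mol K) and T = 298 K by
default; errors on exp transforms propagate to first order (delta method).
Also provides the hydrophobicity regression of per-residue GB self-energy
changes against buried surface area, and Pearson/Spearman agreement
statistics between alanine-scan and per-residue decomposition estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ThermoConstants:
    R: float = 1.9872e-3  # kcal/(mol K)
    T: float = 298.0  # K

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("T must be > 0")

    @property
    def RT(self) -> float:
        return self.R * self.T


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_p: float  # Pearson
    r_s: float  # Spearman (average ranks on ties)
    n: int


def ki_ratio_from_ddg(
    ddg: float, sem: float = 0.0, const: ThermoConstants = ThermoConstants()
) -> tuple[float, float]:
    """Ki ratio exp(ddG/RT) with first-order propagated error ratio*sem/RT."""
    ratio = float(np.exp(ddg / const.RT))
    return ratio, ratio * sem / const.RT


def ddg_from_ki(
    ki_1: float, ki_2: float, const: ThermoConstants = ThermoConstants(),
    sem_1: float = 0.0, sem_2: float = 0.0,
) -> tuple[float, float]:
    """ddG = RT ln(ki_1/ki_2) (kcal/mol) with propagated relative errors."""
    if ki_1 <= 0 or ki_2 <= 0:
        raise ValueError("inhibition constants must be positive")
    ddg = const.RT * float(np.log(ki_1 / ki_2))
    err = const.RT * float(np.hypot(sem_1 / ki_1, sem_2 / ki_2))
    return ddg, err


def predict_missing_ki(
    ki_known: float, ddg_calc: float, const: ThermoConstants = ThermoConstants()
) -> float:
    """Unknown Ki from a known one and ddG = G(variant) - G(wild-type):
    ki_unknown = ki_known / exp(ddg_calc/RT)."""
    if ki_known <= 0:
        raise ValueError("ki_known must be positive")
    return ki_known / float(np.exp(ddg_calc / const.RT))


def entropy_gap(ddg_calc: float, ddg_exp: float) -> float:
    """T*ddS that would reconcile a calculated and an experimental ddG."""
    return ddg_calc - ddg_exp


def apply_entropy_gap(ddg: float, gap: float) -> float:
    """Entropy-corrected ddG: subtract a T*ddS gap from another estimate."""
    return ddg - gap


def difference_with_error(
    a: float, sem_a: float, b: float, sem_b: float
) -> tuple[float, float]:
    """a - b with errors combined in quadrature (component arithmetic)."""
    return a - b, float(np.hypot(sem_a, sem_b))


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate (zero-variance) abscissa")
    res = stats.linregress(x, y)
    r_s = stats.spearmanr(x, y).statistic
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept),
        r_p=float(res.rvalue), r_s=float(r_s), n=len(x),
    )


def hydrophobicity_regression(
    points_by_class: dict[str, tuple[np.ndarray, np.ndarray]],
    ratio_classes: tuple[str, str] = ("charged", "apolar"),
) -> tuple[dict[str, RegressionResult], float]:
    """Per-class OLS of dG_GB self-energy vs buried area (-dSA_res).

    ``points_by_class`` maps a residue class to ``(x, y)`` arrays; returns
    the fits and the slope ratio slope(charged)/slope(apolar) -- the factor
    by which desolvating 1 A^2 of charged surface costs more than apolar
    surface.
    """
    fits = {name: _ols(x, y) for name, (x, y) in points_by_class.items()}
    a, b = ratio_classes
    ratio = float("nan")
    if a in fits and b in fits and fits[b].slope != 0:
        ratio = fits[a].slope / fits[b].slope
    return fits, ratio


def agreement_stats(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(Pearson r_p, Spearman r_s) between two per-residue estimates."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with >= 3 points")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero-variance input")
    r_p = float(stats.pearsonr(x, y).statistic)
    r_s = float(stats.spearmanr(x, y).statistic)
    return r_p, r_s
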