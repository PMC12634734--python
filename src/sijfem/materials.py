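"""Density-based bone material mapping.

CT intensity is linearly calibrated to apparent density, density is mapped
to Young's modulus through the empirical power law E = 6.950 * rho^1.49
(rho in g/cm^3, E in GPa), and the element-wise moduli are discretized
into a fixed number of equal-width material classes.  Internally the model
works in MPa to stay consistent with the mm/N unit system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Power-law coefficients: E [GPa] = MODULUS_COEFF * rho^MODULUS_EXP
MODULUS_COEFF = 6.950
MODULUS_EXP = 1.49

#: Default HU calibration anchors: (HU, g/cm^3)
DEFAULT_CALIBRATION = ((0.0, 1.0), (1600.0, 2.0))

DEFAULT_POISSON = 0.3
DEFAULT_N_CLASSES = 40


class MaterialError(ValueError):
    pass


@dataclass
class MaterialModel:
    """Per-element elastic properties after class binning.

    ``modulus`` holds the class-representative Young's modulus in MPa.
    """

    modulus: np.ndarray            # per-element E (MPa), class representative
    poisson: float
    class_index: np.ndarray        # 0..n_classes-1 per element
    class_moduli: np.ndarray       # representative modulus per class (MPa)

    @property
    def n_classes(self) -> int:
        return int(self.class_moduli.shape[0])


def hu_to_density(hu, calibration=DEFAULT_CALIBRATION, rho_min: float = 0.05):
    """Linear HU -> density map through two anchor pairs, clamped below.

    Parameters
    ----------
    hu : array-like
        CT intensity in Hounsfield units.
    calibration : ((hu0, rho0), (hu1, rho1))
        Two anchor pairs defining the line.
    rho_min : float
        Lower clamp for extrapolated densities (g/cm^3), must be > 0.
    """
    (h0, r0), (h1, r1) = calibration
    if h0 == h1:
        raise MaterialError("calibration anchors must have distinct HU values")
    if rho_min <= 0:
        raise MaterialError("rho_min must be > 0")
    rho = r0 + (np.asarray(hu, dtype=float) - h0) * (r1 - r0) / (h1 - h0)
    return np.maximum(rho, rho_min)


def density_to_modulus(rho):
    """Young's modulus in GPa from apparent density in g/cm^3."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise MaterialError("density must be non-negative")
    return MODULUS_COEFF * rho ** MODULUS_EXP


def bin_material_classes(
    modulus_mpa, n_classes: int = DEFAULT_N_CLASSES, poisson: float = DEFAULT_POISSON
) -> MaterialModel:
    """Discretize element moduli into equal-width classes.

    Bins span [min E, max E]; each element is assigned its bin midpoint as
    the representative modulus, so |E - E_class| <= bin_width / 2.
    """
    E = np.asarray(modulus_mpa, dtype=float).ravel()
    if E.size == 0:
        raise MaterialError("empty modulus array")
    if n_classes < 1:
        raise MaterialError(f"n_classes must be >= 1, got {n_classes}")
    lo, hi = float(E.min()), float(E.max())
    if hi == lo:
        mids = np.full(n_classes, lo)
        idx = np.zeros(E.size, dtype=int)
        return MaterialModel(np.full(E.size, lo), poisson, idx, mids[:1])
    width = (hi - lo) / n_classes
    idx = np.minimum(((E - lo) / width).astype(int), n_classes - 1)
    mids = lo + (np.arange(n_classes) + 0.5) * width
    return MaterialModel(mids[idx], poisson, idx, mids)


def material_from_density(
    rho, n_classes: int = DEFAULT_N_CLASSES, poisson: float = DEFAULT_POISSON
) -> MaterialModel:
    """Convenience: density field -> binned MaterialModel in MPa."""
    return bin_material_classes(
        density_to_modulus(rho) * 1000.0, n_classes=n_classes, poisson=poisson
    )
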