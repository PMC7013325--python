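"""Photobleaching-corrected singlet-oxygen dose model for ALA-induced PpIX.

The accumulated singlet-oxygen concentration produced at a point receiving
fluence rate ``phi`` (W/cm^2) for time ``T`` (s) is

    D_SO = A * Phi * C0 * beta * (1 - exp(-phi*T / beta))        [mol/L]

with the photon-absorption prefactor

    A = 1000 * epsilon * ln(10) * lambda / (h * c * N_A)         [(J/cm^2)^-1]

where epsilon is the PpIX molar extinction coefficient (/cm/M), lambda the
excitation wavelength (cm), Phi the singlet-oxygen quantum yield, C0 the
initial PpIX concentration (mol/L) and beta the photobleaching fluence
constant (J/cm^2): the photosensitizer decays as exp(-F/beta) with the
delivered fluence F = phi*T.  The factor 1000 converts cm^3 to liters.  A
is the number of moles of photons absorbed per liter, per unit fluence, per
unit photosensitizer concentration.  With bleaching disabled the dose is
linear in fluence, D_SO = A * Phi * C0 * F.

The model assumes ample tissue oxygenation (no oxygen depletion): Phi is
constant in time and identical for tumor and normal tissue.

Besides the forward model this module provides its inversions: the fluence
required to reach a cytotoxicity threshold, the minimum initial PpIX
concentration, the minimum bleaching coefficient, and the saturation dose
``A*Phi*C0*beta`` that bounds the bleached model at infinite fluence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .grid import VoxelGrid
from .phantom import TissueModel

__all__ = [
    "PhotophysicalParams",
    "DoseMap",
    "UnreachableDoseError",
    "dose_prefactor",
    "singlet_oxygen_dose",
    "numeric_dose_integral",
    "dose_map",
    "saturation_dose",
    "required_fluence",
    "min_initial_concentration",
    "min_bleaching_coefficient",
]


class UnreachableDoseError(ValueError):
    """The requested dose threshold cannot be reached under the given model.

    With photobleaching the dose saturates at ``A*Phi*C0*beta``; thresholds
    at or above the saturation value are unreachable at any fluence.
    """


@dataclass(frozen=True)
class PhotophysicalParams:
    """Photophysical constants of the singlet-oxygen dose model.

    Defaults are the standard values for ALA-induced PpIX excited at
    635 nm: epsilon = 5000 /cm/M, Phi = 0.77, beta = 13.5 J/cm^2
    (literature values for beta span roughly 4.5 to 33 J/cm^2).  The
    physical constants are deliberately stored at the rounded precision
    commonly used in this dosimetry literature (c = 3.0e10 cm/s,
    N_A = 6.0e23 /mol) rather than CODATA values.
    """

    epsilon: float = 5000.0          # molar extinction coefficient, /cm/M
    wavelength: float = 635e-7       # excitation wavelength, cm
    phi_quantum: float = 0.77        # singlet-oxygen quantum yield
    beta: float = 13.5               # photobleaching fluence constant, J/cm^2
    h: float = 6.626e-34             # Planck constant, J*s
    c_light: float = 3.0e10          # speed of light, cm/s
    n_avogadro: float = 6.0e23       # Avogadro constant, /mol
    bleaching_enabled: bool = True

    def __post_init__(self) -> None:
        for name in ("epsilon", "wavelength", "phi_quantum", "beta",
                     "h", "c_light", "n_avogadro"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.phi_quantum > 1:
            raise ValueError("phi_quantum (quantum yield) must be <= 1")

    def with_(self, **kwargs) -> "PhotophysicalParams":
        return replace(self, **kwargs)


@dataclass
class DoseMap:
    """Per-voxel accumulated singlet-oxygen concentration, mol/L."""

    grid: VoxelGrid
    d_so: np.ndarray

    def __post_init__(self) -> None:
        self.d_so = np.ascontiguousarray(self.d_so, dtype=np.float64)
        if self.d_so.shape != self.grid.dims:
            raise ValueError("d_so shape does not match grid dims")
        if not np.all(np.isfinite(self.d_so)):
            raise ValueError("d_so must be finite")
        if np.any(self.d_so < 0):
            raise ValueError("d_so must be >= 0")

    @property
    def d_so_mM(self) -> np.ndarray:
        return self.d_so * 1e3


def dose_prefactor(params: PhotophysicalParams) -> float:
    """Photon-absorption rate constant A, per (J/cm^2) per (mol/L) of PpIX.

    ``A = 1000 * epsilon * ln(10) * lambda / (h * c * N_A)``; with the
    default parameters A is about 61.3 (J/cm^2)^-1.
    """
    return (
        1000.0
        * params.epsilon
        * math.log(10.0)
        * params.wavelength
        / (params.h * params.c_light * params.n_avogadro)
    )


def singlet_oxygen_dose(fluence_rate, time, c0, params: PhotophysicalParams):
    """Accumulated singlet-oxygen concentration, mol/L.

    Parameters
    ----------
    fluence_rate
        Local fluence rate, W/cm^2 (scalar or array).
    time
        Irradiation time, s.
    c0
        Initial PpIX concentration, mol/L (scalar or array broadcastable
        against ``fluence_rate``).
    params
        Photophysical parameter set; ``params.bleaching_enabled`` selects
        the saturating or the linear (no-bleaching) model.
    """
    fluence_rate = np.asarray(fluence_rate, dtype=float)
    c0 = np.asarray(c0, dtype=float)
    if np.any(fluence_rate < 0) or np.any(c0 < 0) or time < 0:
        raise ValueError("fluence_rate, time and c0 must be >= 0")
    a = dose_prefactor(params)
    fluence = fluence_rate * time  # J/cm^2
    if params.bleaching_enabled:
        out = a * params.phi_quantum * c0 * params.beta * (
            -np.expm1(-fluence / params.beta)
        )
    else:
        out = a * params.phi_quantum * c0 * fluence
    return out if out.ndim else float(out)


def numeric_dose_integral(
    fluence_rate: float,
    time: float,
    c0: float,
    params: PhotophysicalParams,
    dt: float,
) -> float:
    """Time-stepped evaluation of the dose integral (validation oracle).

    Trapezoidal integration of ``A*Phi*phi*C0*exp(-phi*t/beta)`` over
    [0, T]; converges to :func:`singlet_oxygen_dose` as ``dt -> 0``.  Kept
    independent of the closed form on purpose.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if fluence_rate < 0 or time < 0 or c0 < 0:
        raise ValueError("fluence_rate, time and c0 must be >= 0")
    a = dose_prefactor(params)
    n_steps = max(1, int(math.ceil(time / dt)))
    t = np.linspace(0.0, time, n_steps + 1)
    if params.bleaching_enabled:
        integrand = a * params.phi_quantum * fluence_rate * c0 * np.exp(
            -fluence_rate * t / params.beta
        )
    else:
        integrand = np.full_like(t, a * params.phi_quantum * fluence_rate * c0)
    return float(np.trapezoid(integrand, t))


def dose_map(
    fluence,
    time: float,
    model: TissueModel,
    params: PhotophysicalParams,
) -> DoseMap:
    """Apply the dose model voxelwise to a fluence map.

    ``fluence.phi`` is in mW/cm^2 (the transport module's output unit) and
    is converted to W/cm^2 internally; c0 comes from ``model.c0_field``.
    """
    if fluence.grid != model.grid:
        raise ValueError("fluence and tissue model grids do not match")
    d_so = singlet_oxygen_dose(fluence.phi * 1e-3, time, model.c0_field, params)
    return DoseMap(model.grid, np.asarray(d_so))


def saturation_dose(c0: float, params: PhotophysicalParams) -> float:
    """Limit of the bleached dose as fluence -> infinity: A*Phi*C0*beta, mol/L.

    Photobleaching exhausts the photosensitizer, so no amount of additional
    light raises the dose beyond this value.
    """
    if not params.bleaching_enabled:
        raise ValueError("saturation dose is unbounded without photobleaching")
    if c0 < 0:
        raise ValueError("c0 must be >= 0")
    return dose_prefactor(params) * params.phi_quantum * c0 * params.beta


def required_fluence(threshold: float, c0: float, params: PhotophysicalParams) -> float:
    """Fluence F (J/cm^2) at which the dose reaches ``threshold`` (mol/L).

    Inverts the closed-form dose-fluence relation:
    ``F = -beta * ln(1 - threshold / (A*Phi*C0*beta))`` with bleaching, or
    ``F = threshold / (A*Phi*C0)`` without.

    Raises
    ------
    UnreachableDoseError
        If the threshold is at or above the saturation dose (bleaching on),
        or c0 = 0.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if c0 < 0:
        raise ValueError("c0 must be >= 0")
    a = dose_prefactor(params)
    if c0 == 0:
        raise UnreachableDoseError("c0 = 0: no dose at any fluence")
    if not params.bleaching_enabled:
        return threshold / (a * params.phi_quantum * c0)
    sat = saturation_dose(c0, params)
    if threshold >= sat:
        raise UnreachableDoseError(
            f"threshold {threshold:.4g} mol/L >= saturation dose {sat:.4g} mol/L "
            f"(C0 = {c0:.4g} mol/L, beta = {params.beta:.4g} J/cm^2)"
        )
    return -params.beta * math.log1p(-threshold / sat)


def min_initial_concentration(
    threshold: float,
    fluence: float,
    params: PhotophysicalParams,
) -> float:
    """Minimum C0 (mol/L) reaching ``threshold`` at the given fluence (J/cm^2).

    ``fluence = math.inf`` gives the saturation limit
    ``threshold / (A*Phi*beta)`` — the concentration below which no voxel
    can be treated no matter how much light is delivered.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if fluence <= 0:
        raise ValueError("fluence must be > 0 (or inf for the saturation limit)")
    a = dose_prefactor(params)
    if not params.bleaching_enabled:
        if math.isinf(fluence):
            return 0.0
        return threshold / (a * params.phi_quantum * fluence)
    if math.isinf(fluence):
        return threshold / (a * params.phi_quantum * params.beta)
    eff = params.beta * -math.expm1(-fluence / params.beta)
    return threshold / (a * params.phi_quantum * eff)


def min_bleaching_coefficient(
    threshold: float,
    fluence: float,
    c0: float,
    params: PhotophysicalParams,
    rtol: float = 1e-6,
) -> float:
    """Smallest beta (J/cm^2) for which ``fluence`` reaches ``threshold``.

    Solves ``beta * (1 - exp(-F/beta)) = threshold / (A*Phi*C0)`` for beta.
    The left side increases monotonically from 0 (beta -> 0) to F
    (beta -> inf), so a root exists iff the threshold is achievable in the
    no-bleaching limit, i.e. ``A*Phi*C0*F > threshold``.

    Raises
    ------
    UnreachableDoseError
        If even the unbleached model cannot reach the threshold at this
        fluence.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if fluence <= 0:
        raise ValueError("fluence must be > 0")
    if c0 <= 0:
        raise UnreachableDoseError("c0 = 0: no dose at any fluence")
    a = dose_prefactor(params)
    target = threshold / (a * params.phi_quantum * c0)  # J/cm^2
    if target >= fluence:
        raise UnreachableDoseError(
            f"threshold {threshold:.4g} mol/L unreachable at F = {fluence:.4g} "
            "J/cm^2 even without photobleaching"
        )

    def residual(beta: float) -> float:
        return beta * -math.expm1(-fluence / beta) - target

    lo, hi = 1e-6, 1e6
    # residual(lo) ~ -target < 0; residual(hi) ~ F - target > 0
    root = brentq(residual, lo, hi, xtol=1e-15, rtol=max(rtol, 1e-12))
    return float(root)
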