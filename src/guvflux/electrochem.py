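"""Electrodiffusion of protons across the bilayer: GHK flux, its
inversion for the transmembrane potential, and the proton motive force.

Conventions
-----------
* Flux density J is inward-positive, mol/cm^2/s.
* The transmembrane potential is dpsi = psi_in - psi_out (volts).
* With u = dpsi * F / (R*T), the Goldman–Hodgkin–Katz flux density of a
  monovalent cation is

      J = P * u * (C_o - C_i * e^u) / (e^u - 1),

  which reduces to Fick's law J = P * (C_o - C_i) at dpsi = 0 and is
  strictly decreasing in dpsi (an interior-positive potential opposes
  cation entry) — the basis for unique root-finding inversion.
* For a monovalent anion the same expression applies with u -> -u.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .constants import DEFAULT_TEMPERATURE, FARADAY, GAS_CONSTANT

LN10 = math.log(10.0)
_U_SERIES = 1e-6  # below this |u| the direct form is replaced by its series

__all__ = [
    "ghk_flux",
    "invert_ghk",
    "pmf",
    "unstirred_layer_time",
    "decompose_weak_acid",
    "dissociation_ratio",
    "PotentialTrace",
    "DecompositionResult",
]


def ghk_flux(P, dpsi, H_i, H_o, T: float = DEFAULT_TEMPERATURE):
    """GHK flux density (mol/cm^2/s, inward positive) of a monovalent cation.

    For |u| < 1e-6 the second-order series
    J = P*(H_o - H_i) - P*u*(H_o + H_i)/2 is used so the expression is
    smooth and finite through u = 0.
    """
    P = np.asarray(P, dtype=float)
    dpsi = np.asarray(dpsi, dtype=float)
    H_i = np.asarray(H_i, dtype=float)
    H_o = np.asarray(H_o, dtype=float)
    if not (np.all(np.isfinite(P)) and np.all(np.isfinite(dpsi))
            and np.all(np.isfinite(H_i)) and np.all(np.isfinite(H_o))):
        raise ValueError("ghk_flux: non-finite input")
    if np.any(P < 0):
        raise ValueError("ghk_flux: P must be >= 0")
    if np.any(H_i <= 0) or np.any(H_o <= 0):
        raise ValueError("ghk_flux: concentrations must be > 0")
    u = dpsi * FARADAY / (GAS_CONSTANT * T)
    small = np.abs(u) < _U_SERIES
    u_safe = np.where(small, 1.0, u)
    with np.errstate(over="ignore", invalid="ignore"):
        direct = P * u_safe * (H_o - H_i * np.exp(u_safe)) / np.expm1(u_safe)
    series = P * (H_o - H_i) - P * u * (H_o + H_i) / 2.0
    out = np.where(small, series, direct)
    return float(out) if out.ndim == 0 else out


def invert_ghk(J: float, P: float, H_i: float, H_o: float,
               T: float = DEFAULT_TEMPERATURE,
               bracket: tuple[float, float] = (-0.3, 0.3)) -> float:
    """Solve ghk_flux(P, dpsi, H_i, H_o, T) = J for dpsi (volts).

    The GHK flux is strictly monotone (decreasing) in dpsi at fixed
    concentrations, so the root is unique when it exists within the
    bracket (default +/-0.3 V).  Raises ValueError identifying the
    violated bound if J is not attainable over the bracket.
    """
    if P <= 0:
        raise ValueError("invert_ghk: P must be > 0")
    lo, hi = bracket
    f_lo = ghk_flux(P, lo, H_i, H_o, T) - J
    f_hi = ghk_flux(P, hi, H_i, H_o, T) - J
    # flux decreases with dpsi: f_lo is the max, f_hi the min
    if f_lo < 0:
        raise ValueError(
            f"invert_ghk: J={J:.4g} exceeds the maximum attainable flux "
            f"{ghk_flux(P, lo, H_i, H_o, T):.4g} at dpsi={lo:g} V"
        )
    if f_hi > 0:
        raise ValueError(
            f"invert_ghk: J={J:.4g} is below the minimum attainable flux "
            f"{ghk_flux(P, hi, H_i, H_o, T):.4g} at dpsi={hi:g} V"
        )
    return brentq(lambda x: ghk_flux(P, x, H_i, H_o, T) - J, lo, hi,
                  xtol=1e-9, rtol=8.9e-16)


def pmf(dpsi, pH_i, pH_o, T: float = DEFAULT_TEMPERATURE):
    """Proton motive force pmf = dpsi - ln(10)*(R*T/F)*(pH_i - pH_o), volts."""
    dpsi = np.asarray(dpsi, dtype=float)
    dpH = np.asarray(pH_i, dtype=float) - np.asarray(pH_o, dtype=float)
    out = dpsi - LN10 * GAS_CONSTANT * T / FARADAY * dpH
    return float(out) if out.ndim == 0 else out


def unstirred_layer_time(r: float, D: float) -> float:
    """Diffusion time r^2/(6 D) from the membrane to the vesicle centre (s)."""
    if r <= 0 or D <= 0:
        raise ValueError("r and D must be positive")
    return r * r / (6.0 * D)


def dissociation_ratio(pH, pKa):
    """[A-]/[HA] = 10^(pH - pKa) for a monoprotic acid."""
    out = 10.0 ** (np.asarray(pH, dtype=float) - np.asarray(pKa, dtype=float))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PotentialTrace:
    """Per-vesicle time series of transmembrane potential and pmf."""

    vesicle_id: int
    times: np.ndarray  # s
    dpsi: np.ndarray  # V
    pmf: np.ndarray  # V
    dpH: np.ndarray  # pH_i - pH_o

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.dpsi) == len(self.pmf) == len(self.dpH) == n):
            raise ValueError("all series must share the length of times")


@dataclass(frozen=True)
class DecompositionResult:
    """Split of a weak-acid permeability into ionic and neutral routes."""

    P_total: float  # cm/s, slope of the weak-acid flux profile
    P_Hplus: float  # cm/s, slope of the strong-acid (H+-only) profile
    P_HA: float  # cm/s, neutral-acid contribution (= P_total - P_Hplus)
    ratio: float  # P_HA / P_Hplus
    fraction_ionic: float  # P_Hplus / P_total


def decompose_weak_acid(P_total: float, P_Hplus: float) -> DecompositionResult:
    """Decompose a weak acid's total proton-delivery permeability.

    Under the assumptions that the strong-acid profile measures the pure
    H+ route and the conjugate anion is far less permeant than the
    neutral acid, the neutral-route permeability is the difference of
    the two fitted slopes: P_HA = P_total - P_Hplus.
    """
    if not (0 < P_Hplus <= P_total):
        raise ValueError(
            "decompose_weak_acid: require 0 < P_Hplus <= P_total "
            "(a negative neutral-acid flux is unphysical)"
        )
    P_HA = P_total - P_Hplus
    return DecompositionResult(
        P_total=P_total,
        P_Hplus=P_Hplus,
        P_HA=P_HA,
        ratio=P_HA / P_Hplus,
        fraction_ionic=P_Hplus / P_total,
    )
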