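"""Pyranine intensity <-> pH calibration and buffer capacity.

The lumenal pH probe (pyranine/HPTS) is modelled as a single-site
titration sigmoid: fluorescence rises from a fully quenched level
``I_min`` to a fully deprotonated plateau ``I_max`` around an apparent
pKa.  Because the dye quenches completely at low pH, intensities can
only be converted back to pH inside a resolvable window (default
6.0 < pH < 7.6); readings outside the window are returned with an
explicit ``resolvable=False`` flag rather than silently.

The buffer capacity beta(pH) — mol of strong acid per cm^3 needed to
lower the pH by one unit — is computed analytically from the
Henderson–Hasselbalch speciation of the buffer components plus the
water terms.  A tabulated beta(pH) curve (two-column CSV) can be used
instead when an empirically measured curve is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .constants import DEFAULT_TEMPERATURE, water_ion_product

LN10 = math.log(10.0)

__all__ = [
    "CalibrationCurve",
    "CalibrationRangeError",
    "BufferComponent",
    "BufferSystem",
    "PhReading",
    "ph_to_intensity",
    "intensity_to_ph",
    "buffer_capacity",
    "acid_to_titrate",
    "load_table",
    "interpolate_table",
]


class CalibrationRangeError(ValueError):
    """Intensity outside the invertible range of the calibration curve."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Single-site sigmoid mapping pH to fluorescence intensity.

    Parameters
    ----------
    apparent_pKa : pH at which the intensity is midway between the
        quenched and deprotonated plateaus.
    I_min, I_max : intensities at full quench / full deprotonation
        (arbitrary units).
    ph_low, ph_high : resolvable window; the probe quenches completely
        below ``ph_low`` and saturates above ``ph_high``.
    """

    apparent_pKa: float = 7.3
    I_min: float = 100.0
    I_max: float = 4000.0
    ph_low: float = 6.0
    ph_high: float = 7.6

    def __post_init__(self) -> None:
        if not (self.I_max > self.I_min >= 0):
            raise ValueError("require I_max > I_min >= 0")
        if not (0 < self.ph_low < self.ph_high < 14):
            raise ValueError("resolvable range must satisfy 0 < low < high < 14")


class PhReading(NamedTuple):
    """A pH value with a flag marking whether it lies in the resolvable window."""

    pH: np.ndarray | float
    resolvable: np.ndarray | bool


def ph_to_intensity(pH, curve: CalibrationCurve = CalibrationCurve()):
    """Forward calibration: intensity of the probe at a given pH.

    I = I_min + (I_max - I_min) / (1 + 10^(pKa - pH)); strictly
    increasing in pH with asymptotes at the two plateaus.
    """
    pH = np.asarray(pH, dtype=float)
    frac = 1.0 / (1.0 + 10.0 ** (curve.apparent_pKa - pH))
    out = curve.I_min + (curve.I_max - curve.I_min) * frac
    return out if out.ndim else float(out)


def intensity_to_ph(I, curve: CalibrationCurve = CalibrationCurve()) -> PhReading:
    """Invert the calibration sigmoid.

    Raises
    ------
    CalibrationRangeError
        If any intensity is at or beyond a plateau (I <= I_min or
        I >= I_max) — beyond the quench bound the pH cannot be resolved.

    Returns
    -------
    PhReading
        The algebraic inverse, together with a boolean flag that is
        False wherever the result falls outside the resolvable window.
    """
    I = np.asarray(I, dtype=float)
    if np.any(I <= curve.I_min) or np.any(I >= curve.I_max):
        raise CalibrationRangeError(
            "intensity at or beyond a calibration plateau: the probe is fully "
            f"quenched below pH {curve.ph_low:g} (I_min={curve.I_min:g}) and "
            f"saturated above pH {curve.ph_high:g} (I_max={curve.I_max:g}); "
            "the pH cannot be resolved there"
        )
    span = curve.I_max - curve.I_min
    pH = curve.apparent_pKa - np.log10(span / (I - curve.I_min) - 1.0)
    ok = (pH > curve.ph_low) & (pH < curve.ph_high)
    if pH.ndim == 0:
        return PhReading(float(pH), bool(ok))
    return PhReading(pH, ok)


@dataclass(frozen=True)
class BufferComponent:
    name: str
    pKa: float
    concentration: float  # total concentration, mol/cm^3

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError(f"{self.name}: concentration must be > 0")
        if not math.isfinite(self.pKa):
            raise ValueError(f"{self.name}: pKa must be finite")


@dataclass(frozen=True)
class BufferSystem:
    """Aqueous buffer: a list of monoprotic components plus water.

    An optional tabulated beta(pH) curve overrides the analytic buffer
    capacity when set (``beta_table`` is an (n, 2) array of
    (pH, beta in mol/cm^3/pH) rows; linear interpolation between rows).
    """

    components: tuple[BufferComponent, ...] = ()
    temperature: float = DEFAULT_TEMPERATURE
    beta_table: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        object.__setattr__(self, "components", tuple(self.components))

    @classmethod
    def hepes(cls, concentration_mM: float = 10.0, pKa: float = 7.5,
              temperature: float = DEFAULT_TEMPERATURE) -> "BufferSystem":
        """The assay buffer: HEPES (default 10 mM, pKa 7.5 at 21 degC)."""
        return cls(
            components=(BufferComponent("HEPES", pKa, concentration_mM * 1e-6),),
            temperature=temperature,
        )

    @classmethod
    def with_beta_table(cls, table: np.ndarray,
                        temperature: float = DEFAULT_TEMPERATURE) -> "BufferSystem":
        arr = np.asarray(table, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
            raise ValueError("beta table must have >= 2 rows of (pH, beta)")
        return cls(components=(), temperature=temperature,
                   beta_table=tuple(map(tuple, arr)))


def buffer_capacity(pH, buffer: BufferSystem):
    """Buffer capacity beta(pH) in mol/cm^3 per pH unit.

    beta = ln(10) * ( [H+] + K_w/[H+] + sum_i C_i Ka_i [H+] / (Ka_i + [H+])^2 )

    with every concentration in mol/cm^3.  An empty component list gives
    the water-only capacity (valid, not an error).
    """
    pH = np.asarray(pH, dtype=float)
    if np.any(pH <= 0) or np.any(pH >= 14):
        raise ValueError("pH must lie in (0, 14)")
    if buffer.beta_table is not None:
        tab = np.asarray(buffer.beta_table)
        out = np.interp(pH, tab[:, 0], tab[:, 1])
        return out if out.ndim else float(out)
    H = 10.0 ** (-pH) / 1000.0
    kw = water_ion_product(buffer.temperature)
    beta = H + kw / H
    for comp in buffer.components:
        Ka = 10.0 ** (-comp.pKa) / 1000.0
        beta = beta + comp.concentration * Ka * H / (Ka + H) ** 2
    out = LN10 * beta
    return out if out.ndim else float(out)


def acid_to_titrate(buffer: BufferSystem, ph_from: float, ph_to: float,
                    acid_pKa: float | None = None) -> float:
    """Total acid (mol/cm^3) that must be added to move the buffer's pH.

    Derived from the charge balance: the added acid's dissociated
    fraction must account for the change in protonated buffer species
    plus the changes in free [H+] and [OH-].  ``acid_pKa=None`` means a
    fully dissociated (strong) acid; for a weak acid the requirement is
    divided by its dissociated fraction at the final pH.
    """
    H0 = 10.0 ** (-ph_from) / 1000.0
    H1 = 10.0 ** (-ph_to) / 1000.0
    kw = water_ion_product(buffer.temperature)
    demand = (H1 - H0) - (kw / H1 - kw / H0)
    for comp in buffer.components:
        Ka = 10.0 ** (-comp.pKa) / 1000.0
        demand += comp.concentration * (H1 / (Ka + H1) - H0 / (Ka + H0))
    if acid_pKa is None:
        return demand
    Ka_acid = 10.0 ** (-acid_pKa) / 1000.0
    f_diss = Ka_acid / (Ka_acid + H1)
    return demand / f_diss


def load_table(path) -> np.ndarray:
    """Read a two-column (x, y) CSV table, skipping '#' comment lines."""
    arr = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    if arr.shape[1] != 2:
        raise ValueError("expected a two-column CSV (x, y)")
    return arr


def interpolate_table(x, table: np.ndarray):
    """Linear interpolation in a two-column table."""
    table = np.asarray(table, dtype=float)
    out = np.interp(np.asarray(x, dtype=float), table[:, 0], table[:, 1])
    return out if np.ndim(out) else float(out)
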