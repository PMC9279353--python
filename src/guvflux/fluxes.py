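"""From pH time series to flux profiles and permeability coefficients.

The analysis chain mirrors the single-vesicle assay: the cumulative
concentration of permeated protons is reconstructed from the lumenal pH
fall and the buffer capacity, [H+]T_in(t) = sum beta(pH) * dpH_i; the
inward flux density follows from its time derivative scaled by the
volume-to-area ratio V/A = r/3; and the permeability coefficient is the
slope of J against the proton gradient Δ[H+] = [H+]_o − [H+]_i in the
linear (small-gradient) regime where the transmembrane potential is
negligible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .calibration import BufferSystem, buffer_capacity

__all__ = [
    "FluxProfile",
    "PermeabilityEstimate",
    "cumulative_permeated_protons",
    "smooth_series",
    "compute_flux",
    "build_flux_profile",
    "fit_permeability_linear",
]

DEFAULT_WINDOW = 9
DEFAULT_ORDER = 2
DEFAULT_ARRIVAL_DROP = 0.02  # pH below baseline marking proton arrival
DEFAULT_DPH_THRESHOLD = 0.1  # pH per frame
DEFAULT_LINEAR_FRACTION = 0.1  # of the profile's max gradient


@dataclass(frozen=True)
class FluxProfile:
    """Paired (Δ[H+], J) series for one vesicle.

    Entries are restricted to frames after proton arrival where both pH
    values are resolvable.  V_over_A is the vesicle's volume-to-area
    ratio r/3 in cm.
    """

    vesicle_id: int
    times: np.ndarray  # s
    delta_H: np.ndarray  # mol/cm^3
    J: np.ndarray  # mol/cm^2/s
    pH_i: np.ndarray
    pH_o: np.ndarray
    radius: float  # cm
    cum_protons: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("delta_H", "J", "pH_i", "pH_o"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must match the length of times")

    @property
    def V_over_A(self) -> float:
        return self.radius / 3.0


@dataclass(frozen=True)
class PermeabilityEstimate:
    """Linear-regime permeability fit P = J / Δ[H+]."""

    P: float  # cm/s
    se: float  # cm/s, standard error of the slope
    n_points: int
    dpH_threshold: float  # per-frame gate used
    linear_fraction: float  # gradient gate used
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if not math.isfinite(self.P):
            raise ValueError("P must be finite")
        if self.n_points < 3:
            raise ValueError("a permeability fit needs at least 3 points")


def cumulative_permeated_protons(pH_i: np.ndarray,
                                 buffer: BufferSystem) -> np.ndarray:
    """Cumulative [H+]T_in (mol/cm^3) from the lumenal pH series.

    Per frame interval the permeated amount is beta(pH_mid) times the pH
    drop, with beta evaluated at the interval midpoint; the series
    starts at zero and increases while the lumen acidifies.
    """
    pH_i = np.asarray(pH_i, dtype=float)
    if pH_i.size < 2:
        raise ValueError("need at least 2 frames to accumulate protons")
    dpH = pH_i[:-1] - pH_i[1:]
    beta_mid = buffer_capacity(0.5 * (pH_i[:-1] + pH_i[1:]), buffer)
    return np.concatenate([[0.0], np.cumsum(beta_mid * dpH)])


def smooth_series(y: np.ndarray, window: int = DEFAULT_WINDOW,
                  order: int = DEFAULT_ORDER) -> np.ndarray:
    """Local least-squares polynomial (Savitzky–Golay) smoothing.

    Reproduces any polynomial of degree <= order exactly; edges are
    handled by fitting the boundary window's polynomial.
    """
    y = np.asarray(y, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if not (window > order >= 1):
        raise ValueError("require window > order >= 1")
    if window > y.size:
        raise ValueError("window exceeds series length")
    return savgol_filter(y, window, order, mode="interp")


def compute_flux(cum: np.ndarray, times: np.ndarray,
                 radius: float) -> np.ndarray:
    """Inward flux density J = d[H+]T_in/dt * (r/3), mol/cm^2/s.

    Central finite differences in the interior; one-sided second-order
    differences at the edges.  The input is expected to be smoothed.
    """
    times = np.asarray(times, dtype=float)
    cum = np.asarray(cum, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    return np.gradient(cum, times, edge_order=2) * (radius / 3.0)


def build_flux_profile(times: np.ndarray, pH_i: np.ndarray, pH_o: np.ndarray,
                       buffer: BufferSystem, radius: float, *,
                       vesicle_id: int = 0,
                       window: int = DEFAULT_WINDOW,
                       order: int = DEFAULT_ORDER,
                       arrival_drop: float = DEFAULT_ARRIVAL_DROP,
                       ph_low: float = 6.0,
                       ph_high: float = 7.6) -> FluxProfile:
    """Compose accumulation, smoothing and differentiation into a profile.

    Frames before proton arrival (external pH within ``arrival_drop`` of
    its baseline) and from the first frame where either pH leaves the
    resolvable window onwards are discarded.
    """
    times = np.asarray(times, dtype=float)
    pH_i = np.asarray(pH_i, dtype=float)
    pH_o = np.asarray(pH_o, dtype=float)
    baseline = pH_o[0]
    arrived = pH_o < baseline - arrival_drop
    if not np.any(arrived):
        raise ValueError("no resolvable window: protons never arrive")
    k0 = int(np.argmax(arrived))
    # The hard resolvability limit is the quench bound: below ph_low the
    # dye is dark and pH cannot be read.  Measured values marginally
    # above ph_high (noise around the baseline, where the run starts)
    # still invert through the calibration sigmoid and are retained;
    # a small tolerance above the window accommodates them.
    upper = ph_high + 0.5 * (ph_high - ph_low)
    resolvable = (pH_i > ph_low) & (pH_i < upper) & \
                 (pH_o > ph_low) & (pH_o < upper)
    bad = ~resolvable[k0:]
    k1 = k0 + int(np.argmax(bad)) if np.any(bad) else len(times)
    if k1 - k0 < max(window, 3):
        raise ValueError("no resolvable window: too few frames after arrival")
    sl = slice(k0, k1)
    cum = cumulative_permeated_protons(pH_i[sl], buffer)
    J = compute_flux(smooth_series(cum, window, order), times[sl], radius)
    delta_H = 10.0 ** (-pH_o[sl]) / 1000.0 - 10.0 ** (-pH_i[sl]) / 1000.0
    return FluxProfile(
        vesicle_id=vesicle_id, times=times[sl], delta_H=delta_H, J=J,
        pH_i=pH_i[sl], pH_o=pH_o[sl], radius=radius, cum_protons=cum,
    )


def _qualifying_mask(profile: FluxProfile, dpH_threshold: float,
                     linear_fraction: float) -> np.ndarray:
    """Frames belonging to the linear (small-gradient) regime."""
    pH_i = profile.pH_i
    dpH = np.abs(np.diff(pH_i))
    per_frame = np.concatenate([dpH, dpH[-1:]])  # last frame reuses previous
    mask = (per_frame < dpH_threshold) & (profile.delta_H > 0)
    if linear_fraction < 1.0 and np.any(profile.delta_H > 0):
        mask &= profile.delta_H <= linear_fraction * profile.delta_H.max()
    return mask


def fit_permeability_linear(profiles: Sequence[FluxProfile],
                            dpH_threshold: float = DEFAULT_DPH_THRESHOLD,
                            linear_fraction: float = DEFAULT_LINEAR_FRACTION,
                            ) -> PermeabilityEstimate:
    """Pooled linear-regime fit of J = P * Δ[H+] through the origin.

    Points are pooled across profiles ("concatenate fit") and restricted
    to frames in the linear regime: per-frame lumenal pH change below
    ``dpH_threshold`` and gradient below ``linear_fraction`` of each
    profile's maximum (the regime where the transmembrane potential is
    negligible and the flux is Fick-like).  Returns the OLS slope and
    its standard error.
    """
    if isinstance(profiles, FluxProfile):
        profiles = [profiles]
    xs, ys = [], []
    for prof in profiles:
        m = _qualifying_mask(prof, dpH_threshold, linear_fraction)
        xs.append(prof.delta_H[m])
        ys.append(prof.J[m])
    x = np.concatenate(xs) if xs else np.array([])
    y = np.concatenate(ys) if ys else np.array([])
    n = x.size
    if n < 3:
        raise ValueError(
            f"fit_permeability_linear: only {n} qualifying points "
            "(need >= 3) within the linear-regime gates"
        )
    sxx = float(np.dot(x, x))
    P = float(np.dot(x, y)) / sxx
    resid = y - P * x
    se = math.sqrt(float(np.dot(resid, resid)) / ((n - 1) * sxx)) if n > 1 else 0.0
    ss_tot = float(np.dot(y, y))  # through-origin R^2
    r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot if ss_tot > 0 else float("nan")
    return PermeabilityEstimate(P=P, se=se, n_points=n,
                                dpH_threshold=dpH_threshold,
                                linear_fraction=linear_fraction,
                                r_squared=r2)
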