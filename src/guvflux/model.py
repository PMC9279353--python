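"""Model/Results interface for single-vesicle proton permeation.

`ProtonPermeationModel` is built from per-vesicle pH time series —
either directly from simulator traces (trace-level mode) or from an
image-analysis track table via the fluorescence calibration
(image-level mode).  `fit()` performs the linear-regime permeability
regression (pooled "concatenate" fit plus per-vesicle fits) and returns
a `ProtonPermeationResults` carrying the estimates, their standard
errors and diagnostics; GHK inversion of the flux profiles for the
transmembrane potential, proton motive force traces, weak-acid
decomposition and plotting hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import BufferSystem, CalibrationCurve, intensity_to_ph
from .constants import DEFAULT_TEMPERATURE
from .electrochem import (DecompositionResult, PotentialTrace,
                          decompose_weak_acid, invert_ghk, pmf)
from .fluxes import (DEFAULT_DPH_THRESHOLD, DEFAULT_LINEAR_FRACTION,
                     DEFAULT_WINDOW, FluxProfile,
                     PermeabilityEstimate, build_flux_profile,
                     fit_permeability_linear)
from .simulate import TimeSeriesTrace

__all__ = ["ProtonPermeationModel", "ProtonPermeationResults"]


class ProtonPermeationModel:
    """Proton-permeation analysis of a cohort of vesicles.

    Parameters
    ----------
    profiles : flux profiles, one per vesicle (see
        :func:`guvflux.fluxes.build_flux_profile`).
    buffer : the lumenal buffer system used for proton accounting.
    temperature : kelvin, used for GHK inversion and pmf.
    """

    def __init__(self, profiles: Sequence[FluxProfile], buffer: BufferSystem,
                 temperature: float = DEFAULT_TEMPERATURE) -> None:
        if len(profiles) == 0:
            raise ValueError("at least one flux profile is required")
        self.profiles = list(profiles)
        self.buffer = buffer
        self.temperature = temperature

    # ------------------------------------------------------------------
    @classmethod
    def from_traces(cls, traces: Sequence[TimeSeriesTrace] | pd.DataFrame,
                    buffer: BufferSystem,
                    temperature: float = DEFAULT_TEMPERATURE,
                    **profile_kwargs) -> "ProtonPermeationModel":
        """Trace-level constructor: pH series are taken as measured."""
        from .simulate import frame_to_traces

        if isinstance(traces, pd.DataFrame):
            traces = frame_to_traces(traces)
        profiles = [
            build_flux_profile(tr.times, tr.pH_i, tr.pH_o, buffer, tr.radius,
                               vesicle_id=tr.vesicle_id, **profile_kwargs)
            for tr in traces
        ]
        return cls(profiles, buffer, temperature)

    @classmethod
    def from_tracks(cls, tracks: pd.DataFrame, curve: CalibrationCurve,
                    buffer: BufferSystem, pixel_size: float,
                    temperature: float = DEFAULT_TEMPERATURE,
                    min_track_length: int = DEFAULT_WINDOW,
                    **profile_kwargs) -> "ProtonPermeationModel":
        """Image-level constructor from a `measure_stack` track table.

        Lumen and background intensities are converted to pH through the
        calibration curve; frames whose reading falls outside the
        resolvable window are handled by the profile builder's trimming.
        The vesicle radius is the track's median radius (px) scaled by
        the pixel size (um/px).
        """
        profiles = []
        for vid, g in tracks.groupby("vesicle_id", sort=True):
            g = g.sort_values("frame")
            if len(g) < min_track_length:
                continue
            pH_i, _ = intensity_to_ph(g["lumen_intensity"].to_numpy(), curve)
            pH_o, _ = intensity_to_ph(
                g["background_intensity"].to_numpy(), curve)
            radius_cm = float(np.median(g["radius_px"])) * pixel_size * 1e-4
            profiles.append(build_flux_profile(
                g["t_s"].to_numpy(), pH_i, pH_o, buffer, radius_cm,
                vesicle_id=int(vid), **profile_kwargs))
        return cls(profiles, buffer, temperature)

    # ------------------------------------------------------------------
    def fit(self, dpH_threshold: float = DEFAULT_DPH_THRESHOLD,
            linear_fraction: float = DEFAULT_LINEAR_FRACTION,
            ) -> "ProtonPermeationResults":
        """Linear-regime permeability fit (pooled and per vesicle)."""
        pooled = fit_permeability_linear(self.profiles, dpH_threshold,
                                         linear_fraction)
        rows = []
        for prof in self.profiles:
            try:
                est = fit_permeability_linear([prof], dpH_threshold,
                                              linear_fraction)
                rows.append({"vesicle_id": prof.vesicle_id, "P": est.P,
                             "se": est.se, "n_points": est.n_points})
            except ValueError:
                rows.append({"vesicle_id": prof.vesicle_id, "P": np.nan,
                             "se": np.nan, "n_points": 0})
        per_vesicle = pd.DataFrame(rows).set_index("vesicle_id")
        return ProtonPermeationResults(self, pooled, per_vesicle)


@dataclass
class ProtonPermeationResults:
    """Results of the linear-regime permeability fit.

    Attributes
    ----------
    pooled : the concatenate fit across all vesicles.
    per_vesicle : DataFrame (vesicle_id -> P, se, n_points).
    """

    model: ProtonPermeationModel
    pooled: PermeabilityEstimate
    per_vesicle: pd.DataFrame

    # -- scalar views ---------------------------------------------------
    @property
    def P(self) -> float:
        """Pooled permeability coefficient, cm/s."""
        return self.pooled.P

    @property
    def bse(self) -> float:
        """Standard error of the pooled slope, cm/s."""
        return self.pooled.se

    @property
    def nobs(self) -> int:
        return self.pooled.n_points

    @property
    def P_median(self) -> float:
        """Median of the per-vesicle permeability coefficients."""
        return float(self.per_vesicle["P"].median())

    @property
    def P_mean(self) -> float:
        return float(self.per_vesicle["P"].mean())

    # -- potential / pmf ------------------------------------------------
    def invert_potential(self, P: float | None = None,
                         bracket: tuple[float, float] = (-0.3, 0.3),
                         ) -> list[PotentialTrace]:
        """GHK-invert each flux profile for the transmembrane potential.

        By default each vesicle's own fitted P is used ("per-vesicle"
        mode); pass a scalar ``P`` to use one coefficient for all
        profiles (e.g. the pooled estimate or a known ground truth).
        Frames whose flux leaves the attainable GHK range over the
        bracket are returned as NaN.
        """
        T = self.model.temperature
        out = []
        for prof in self.model.profiles:
            P_v = P if P is not None else float(
                self.per_vesicle.loc[prof.vesicle_id, "P"])
            if not np.isfinite(P_v) or P_v <= 0:
                raise ValueError(
                    f"no usable permeability for vesicle {prof.vesicle_id}")
            H_i = 10.0 ** (-prof.pH_i) / 1000.0
            H_o = 10.0 ** (-prof.pH_o) / 1000.0
            dpsi = np.full(len(prof.times), np.nan)
            for k in range(len(prof.times)):
                try:
                    dpsi[k] = invert_ghk(prof.J[k], P_v, H_i[k], H_o[k], T,
                                         bracket)
                except ValueError:
                    pass
            dpH = prof.pH_i - prof.pH_o
            out.append(PotentialTrace(
                vesicle_id=prof.vesicle_id, times=prof.times, dpsi=dpsi,
                pmf=pmf(dpsi, prof.pH_i, prof.pH_o, T), dpH=dpH))
        return out

    def max_mean_pmf(self, potential_traces: list[PotentialTrace] | None = None,
                     ) -> float:
        """Maximum over time of the cohort-mean pmf, volts.

        The per-frame mean is taken across vesicles on the common time
        grid (frames where a vesicle has no value are ignored).
        """
        traces = potential_traces or self.invert_potential()
        frames: dict[float, list[float]] = {}
        for tr in traces:
            for t, v in zip(tr.times, tr.pmf):
                if np.isfinite(v):
                    frames.setdefault(round(float(t), 9), []).append(v)
        means = [np.mean(v) for v in frames.values() if v]
        if not means:
            raise ValueError("no finite pmf values to average")
        return float(np.max(means))

    # -- decomposition ---------------------------------------------------
    def decompose_against(self, ionic: "ProtonPermeationResults",
                          ) -> DecompositionResult:
        """Weak-acid decomposition using this fit as the total-permeation
        cohort and ``ionic`` as the strong-acid (H+-only) cohort."""
        return decompose_weak_acid(self.P, ionic.P)

    # -- presentation ----------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Proton permeation linear-regime fit",
            "===================================",
            f"vesicles:            {len(self.model.profiles):d}",
            f"pooled points:       {self.nobs:d}",
            f"P (pooled):          {self.P:.4g} cm/s",
            f"SE (pooled):         {self.bse:.2g} cm/s",
            f"R^2 (through origin):{self.pooled.r_squared:9.4f}",
            f"P (median vesicle):  {self.P_median:.4g} cm/s",
            f"P (mean vesicle):    {self.P_mean:.4g} cm/s",
            f"gates: |dpH_i| < {self.pooled.dpH_threshold:g}/frame, "
            f"delta_H <= {self.pooled.linear_fraction:g} x max",
            "",
            "Per-vesicle estimates (cm/s)",
            "----------------------------",
        ]
        for vid, row in self.per_vesicle.iterrows():
            lines.append(f"  vesicle {vid:>3}:  P = {row['P']:.4g}"
                         f"  (se {row['se']:.2g}, n={int(row['n_points'])})")
        return "\n".join(lines)

    def plot_flux_profiles(self, ax=None):
        """Flux against proton gradient, one line per vesicle, with the
        pooled linear fit overlaid (the Fick prediction P*delta_H)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for prof in self.model.profiles:
            ax.plot(prof.delta_H, prof.J, ".-", ms=3,
                    label=f"vesicle {prof.vesicle_id}")
        x = np.linspace(0, max(p.delta_H.max() for p in self.model.profiles),
                        50)
        ax.plot(x, self.P * x, "k--", label=f"P = {self.P:.3g} cm/s")
        ax.set_xlabel(r"$\Delta[\mathrm{H}^+]$ (mol/cm$^3$)")
        ax.set_ylabel(r"$J_{H^+}$ (mol/cm$^2$/s)")
        ax.legend(fontsize="small")
        return ax

    def plot_potential(self, potential_traces=None, ax=None):
        """Transmembrane potential and pmf buildup over time."""
        import matplotlib.pyplot as plt

        traces = potential_traces or self.invert_potential()
        if ax is None:
            _, ax = plt.subplots()
        for tr in traces:
            ax.plot(tr.times, tr.dpsi * 1e3, label=f"vesicle {tr.vesicle_id}")
        ax.set_xlabel("t (s)")
        ax.set_ylabel(r"$\Delta\psi$ (mV)")
        ax.legend(fontsize="small")
        return ax
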