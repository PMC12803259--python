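"""Chemoattractant gradient formation and quantification.

Each migration channel connects a chemoattractant chamber (held at the
loading concentration, 100 nM by default) to the central chamber, which the
large media reservoir keeps at effectively zero concentration. Transport
along the long narrow channel is well approximated by 1-D diffusion with
fixed-concentration boundaries; its steady state is the linear profile
c(x) = C_source + (C_sink - C_source) x / L, whose slope is independent of
the diffusivity — which is why two chemoattractants of different molecular
weight (fMLP, 438 Da; LTB4, 336 Da) form gradients of equal slope once
equilibrated.

Diffusivities, when not supplied, are scaled from a reference molecule by
the Stokes-Einstein-like cube-root law D = D_ref (MW_ref / MW)^(1/3)
(hydrodynamic radius grows roughly as the cube root of molecular mass).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, StabilityError

#: Molecular weights (Da) of the species used in this assay.
MOLECULAR_WEIGHTS = {"fMLP": 438.0, "LTB4": 336.0, "dextran": 10000.0}


@dataclass(frozen=True)
class DiffusionSpec:
    """Physical and numerical parameters of one species' channel diffusion."""

    species: str = "fMLP"
    molecular_weight: float = 438.0   # Da
    diffusivity: float = 300.0        # um^2/s (small-molecule scale)
    source_concentration: float = 100.0  # nM at the chemoattractant chamber
    sink_concentration: float = 0.0      # nM at the central chamber
    channel_length: float = 500.0     # um
    grid_spacing: float = 5.0         # um
    time_step: float = 0.02           # s

    def __post_init__(self):
        if self.diffusivity <= 0:
            raise ParameterError("diffusivity must be positive")
        if self.channel_length <= 0 or self.grid_spacing <= 0:
            raise ParameterError("channel_length and grid_spacing must be > 0")
        if self.time_step <= 0:
            raise ParameterError("time_step must be positive")

    @property
    def cfl(self) -> float:
        return self.diffusivity * self.time_step / self.grid_spacing ** 2


@dataclass
class GradientProfile:
    """Concentration (or intensity) samples along a channel, with linear fit."""

    positions: np.ndarray   # um, from source (0) to sink (L)
    values: np.ndarray
    time: float = np.nan    # s
    slope: float = np.nan   # value units per um
    intercept: float = np.nan
    r_squared: float = np.nan


def diffusivity_from_mw(molecular_weight: float,
                        reference: tuple[float, float]) -> float:
    """Scale a diffusivity from (MW_ref, D_ref) by the cube-root MW law."""
    mw_ref, d_ref = reference
    if molecular_weight <= 0 or mw_ref <= 0 or d_ref <= 0:
        raise ParameterError("molecular weights and diffusivity must be > 0")
    return d_ref * (mw_ref / molecular_weight) ** (1.0 / 3.0)


def simulate_channel_diffusion(spec: DiffusionSpec,
                               times: np.ndarray | list[float],
                               ) -> list[GradientProfile]:
    """Explicit finite-difference solution of 1-D diffusion along a channel.

    Boundary conditions: fixed source concentration at x = 0, fixed sink
    concentration at x = L. Initial condition: sink concentration everywhere
    except the source node (a step). Returns one profile per requested time
    (seconds, ascending); each profile carries its linear fit. Converges to
    the linear steady state for large times.
    """
    if spec.cfl > 0.5:
        dt_max = 0.5 * spec.grid_spacing ** 2 / spec.diffusivity
        raise StabilityError(
            f"CFL number {spec.cfl:.3f} > 0.5: reduce time_step to "
            f"<= {dt_max:.4g} s")
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0 or np.any(np.diff(times) < 0):
        raise ParameterError("times must be a non-empty ascending 1-D array")

    n = int(round(spec.channel_length / spec.grid_spacing)) + 1
    x = np.linspace(0.0, spec.channel_length, n)
    c = np.full(n, spec.sink_concentration)
    c[0] = spec.source_concentration

    profiles = []
    t = 0.0
    alpha = spec.cfl
    for target in times:
        n_steps = max(0, int(round((target - t) / spec.time_step)))
        for _ in range(n_steps):
            c[1:-1] = c[1:-1] + alpha * (c[2:] - 2 * c[1:-1] + c[:-2])
        t += n_steps * spec.time_step
        prof = GradientProfile(positions=x.copy(), values=c.copy(), time=t)
        fit = quantify_gradient(prof)
        profiles.append(fit)
    return profiles


def quantify_gradient(profile: GradientProfile | None = None,
                      *,
                      image: np.ndarray | None = None,
                      channel_roi: tuple[slice, slice] | None = None,
                      positions: np.ndarray | None = None,
                      axis: int = 1) -> GradientProfile:
    """Ordinary least-squares line fit of value versus axial position.

    Accepts either a :class:`GradientProfile` or an image plus a channel ROI
    (rows x cols slices); for images, the value at each axial position is
    the mean intensity across the channel width. The returned slope is
    signed — negative when the value decreases from source (position 0)
    toward sink, by convention.
    """
    if profile is None:
        if image is None or channel_roi is None:
            raise ParameterError("need a profile, or an image with a ROI")
        patch = np.asarray(image, dtype=float)[channel_roi]
        values = patch.mean(axis=0 if axis == 1 else 1)
        if positions is None:
            positions = np.arange(len(values), dtype=float)
        profile = GradientProfile(positions=np.asarray(positions, float),
                                  values=values)
    pos = np.asarray(profile.positions, dtype=float)
    val = np.asarray(profile.values, dtype=float)
    if len(pos) < 3 or len(pos) != len(val):
        raise ParameterError("need >= 3 (position, value) samples")
    if np.ptp(pos) == 0:
        raise ParameterError("constant positions: line fit undefined")

    slope, intercept = np.polyfit(pos, val, 1)
    pred = slope * pos + intercept
    ss_res = float(np.sum((val - pred) ** 2))
    ss_tot = float(np.sum((val - val.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return GradientProfile(positions=pos, values=val, time=profile.time,
                           slope=float(slope), intercept=float(intercept),
                           r_squared=float(r2))


def steady_state_slope(spec: DiffusionSpec) -> float:
    """Analytic steady-state slope (C_sink - C_source) / L, nM per um."""
    return (spec.sink_concentration - spec.source_concentration) \
        / spec.channel_length


def analytic_transient_profile(spec: DiffusionSpec, time: float,
                               n_terms: int = 200) -> GradientProfile:
    """Closed-form Fourier-series solution of the same boundary-value problem.

    Independent of the finite-difference path; used as the oracle for
    transient-accuracy checks. c(x,t) = steady(x) + series of decaying sine
    modes matching the step initial condition.
    """
    n = int(round(spec.channel_length / spec.grid_spacing)) + 1
    x = np.linspace(0.0, spec.channel_length, n)
    L = spec.channel_length
    c0, cL = spec.source_concentration, spec.sink_concentration
    steady = c0 + (cL - c0) * x / L
    series = np.zeros_like(x)
    # initial condition (interior) is c = cL, so the transient part is
    # u(x,0) = cL - steady(x) = (c0 - cL)(x/L - 1); b_n = -2 (c0-cL)/(n pi)
    for k in range(1, n_terms + 1):
        b_k = -2.0 * (c0 - cL) / (k * np.pi)
        series += b_k * np.sin(k * np.pi * x / L) * np.exp(
            -spec.diffusivity * (k * np.pi / L) ** 2 * time)
    return GradientProfile(positions=x, values=steady + series, time=time)
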