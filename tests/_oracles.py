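"""Independent numerical oracles for the heat-transport tests.

These deliberately share no code with the package's Green's-function
superposition: an explicit finite-difference integrator of the heat equation
on a 3-D grid, and a radial quadrature solution of the steady spherically
symmetric conduction problem.
"""

from __future__ import annotations

import numpy as np


def gaussian_source_density(coords_m: np.ndarray, w_m: float, power_w: float,
                            dx_m: float) -> np.ndarray:
    """Isotropic Gaussian volumetric heating (W/m^3), renormalized so the
    discrete sum deposits exactly ``power_w``."""
    x = coords_m[None, None, :]
    y = coords_m[None, :, None]
    z = coords_m[:, None, None]
    g = np.exp(-(x**2 + y**2 + z**2) / w_m**2)
    return power_w * g / (g.sum() * dx_m**3)


def solve_heat_fd(
    q_w_m3: np.ndarray,
    medium,
    dx_m: float,
    dt_s: float,
    n_steps: int,
    on_window=None,
):
    """Explicit (FTCS) integration of dT/dt = alpha*lap(T) + q/(rho*c).

    Dirichlet dT=0 boundaries.  ``on_window(t)`` gates the source (evaluated
    at the step midpoint); default always on.  Stability requires
    dt <= dx^2 / (6*alpha).
    """
    alpha = medium.thermal_diffusivity
    rho_c = medium.volumetric_heat_capacity
    assert dt_s <= dx_m**2 / (6.0 * alpha) * (1 + 1e-12), "unstable FD step"
    T = np.zeros_like(q_w_m3)
    src = dt_s * q_w_m3 / rho_c
    c = dt_s * alpha / dx_m**2
    for step in range(n_steps):
        lap = (
            T[2:, 1:-1, 1:-1] + T[:-2, 1:-1, 1:-1]
            + T[1:-1, 2:, 1:-1] + T[1:-1, :-2, 1:-1]
            + T[1:-1, 1:-1, 2:] + T[1:-1, 1:-1, :-2]
            - 6.0 * T[1:-1, 1:-1, 1:-1]
        )
        T[1:-1, 1:-1, 1:-1] += c * lap
        t_mid = (step + 0.5) * dt_s
        if on_window is None or on_window(t_mid):
            T[1:-1, 1:-1, 1:-1] += src[1:-1, 1:-1, 1:-1]
    return T


def radial_steady_profile(r_eval_m: np.ndarray, power_w: float, medium,
                          w_m: float, r_max_m: float = 2e-4, n: int = 40000):
    """Steady spherically symmetric conduction with a Gaussian source.

    Integrates k * dT/dr = -Q(r) / (4*pi*r^2) inward from ``r_max_m`` (where
    T is set to 0), with Q(r) the heating enclosed within radius r; returns
    T(r_eval) - T(r_max).  Pure quadrature; no closed-form heat formulas.
    """
    k = medium.thermal_conductivity
    r = np.linspace(1e-9, r_max_m, n)
    # enclosed power: cumulative integral of q(r)*4*pi*r^2 with q ~ exp(-r^2/w^2)
    shell = np.exp(-(r**2) / w_m**2) * 4.0 * np.pi * r**2
    q_cum = np.concatenate([[0.0], np.cumsum(0.5 * (shell[1:] + shell[:-1]) * np.diff(r))])
    q_enclosed = power_w * q_cum / q_cum[-1]
    dT_dr = -q_enclosed / (4.0 * np.pi * k * r**2)
    # T(r) - T(r_max) = -int_r^{rmax} dT/dr dr'
    seg = 0.5 * (dT_dr[1:] + dT_dr[:-1]) * np.diff(r)
    t_from_end = np.concatenate([[0.0], np.cumsum(seg[::-1])])[::-1]
    profile = -t_from_end
    return np.interp(r_eval_m, r, profile)
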