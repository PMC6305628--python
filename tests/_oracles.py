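"""Independent oracles used by the test suite.

Everything here is deliberately written from closed forms or brute-force
numerics, independent of the implementation paths it checks.
"""

import numpy as np


def staircase_fourier_coefficient(angles, signs, n, n_points=200001):
    """b_n of the quarter-wave staircase by direct numerical integration.

    Builds the continuous staircase level(theta) on [0, pi/2] from the
    switching angles and integrates (4/pi) int_0^{pi/2} level sin(n theta)
    dtheta with the trapezoidal rule.
    """
    theta = np.linspace(0.0, np.pi / 2, n_points)
    level = np.zeros_like(theta)
    for a, s in zip(angles, signs):
        level += s * (theta >= a - 1e-15)
    integrand = level * np.sin(n * theta)
    return 4.0 / np.pi * np.trapezoid(integrand, theta)


def record_fundamental(x, cycles):
    """Peak amplitude of the fundamental of a sampled periodic record."""
    n = len(x)
    ph = np.exp(-2j * np.pi * cycles * np.arange(n) / n)
    return 2.0 * abs(np.dot(np.asarray(x, float), ph)) / n


def oneil_onaxis_pressure(z, k, focal_length, aperture_radius, rho_c, u0):
    """Closed-form on-axis |p| of a focused bowl (apex at z = 0).

    O'Neil's spherical-cap solution: with D_e the distance from the rim to
    the axial point and h the cap depth,

        |p| = 2 rho c u0 |sin(k (D_e - z) / 2)| / |1 - z / R|

    with the finite focal limit rho c u0 k h.
    """
    z = np.asarray(z, float)
    R = focal_length
    theta = np.arcsin(aperture_radius / R)
    h = R * (1 - np.cos(theta))
    De = np.sqrt(aperture_radius**2 + (z - h) ** 2)
    denom = 1.0 - z / R
    out = np.empty_like(z)
    reg = np.abs(denom) > 1e-9
    out[reg] = (2 * rho_c * u0 / np.abs(denom[reg])
                * np.abs(np.sin(k * (De[reg] - z[reg]) / 2)))
    out[~reg] = rho_c * u0 * k * h
    return out


def heat_kernel_gaussian(r, z, zc, amp0, sigma0, kappa, t):
    """3-D isotropic Gaussian temperature pulse after conduction time t."""
    var = sigma0**2 + 2 * kappa * t
    rho2 = r[:, None] ** 2 + (z[None, :] - zc) ** 2
    return amp0 * (sigma0**2 / var) ** 1.5 * np.exp(-rho2 / (2 * var))


def phasor_true_power(voltage_amplitudes, impedances):
    """Per-harmonic phasor power sum: sum |V_h|^2 Re(1/Z_h) / 2."""
    v = np.asarray(voltage_amplitudes)
    z = np.asarray(impedances)
    return float(np.sum(np.abs(v) ** 2 * np.real(1.0 / z) / 2.0))
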