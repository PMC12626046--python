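"""Diffusion-theory forward models for a semi-infinite homogeneous medium.

Two solutions are provided:

* time-resolved diffuse reflectance R(rho, t) with the extrapolated-boundary
  (image dipole) condition — the model convolved with the instrument
  response function during DTOF fitting;
* the normalized field autocorrelation g1(tau) of the correlation-diffusion
  equation with Brownian dynamics (BFI = alpha * Db), used inside the Siegert
  relation g2 = 1 + beta |g1|^2.

Units: lengths cm, times ns for reflectance and s for correlation lags,
optical coefficients cm^-1.
"""

from __future__ import annotations

import numpy as np

from .geometry import C_LIGHT_CM_NS


def effective_reflection_coefficient(n: float) -> float:
    """Internal-reflection parameter R_eff(n) (Groenhuis/Haskell polynomial)."""
    return -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n


def _dipole_depths(mua: float, musp: float, n: float) -> tuple[float, float]:
    """Source depth z0 and extrapolated-boundary offset zb (cm)."""
    D = 1.0 / (3.0 * musp)
    z0 = 1.0 / musp
    reff = effective_reflection_coefficient(n)
    zb = 2.0 * D * (1.0 + reff) / (1.0 - reff)
    return z0, zb


def _validate_props(mua: float, musp: float, rho_cm: float) -> None:
    if mua <= 0 or musp <= 0:
        raise ValueError(f"optical properties must be positive (mua={mua}, musp={musp})")
    if rho_cm <= 0:
        raise ValueError("rho must be positive")


def semi_infinite_reflectance(
    t_ns: np.ndarray,
    mua: float,
    musp: float,
    rho_cm: float,
    refractive_index: float = 1.4,
) -> np.ndarray:
    """Time-resolved reflectance R(rho, t) of a semi-infinite medium.

    Image-dipole solution of the diffusion equation with an extrapolated
    boundary.  The late-time behaviour is dominated by exp(-mua * v * t), so
    the asymptotic log-slope equals -mua * v.  Amplitude carries the
    conventional (4 pi D v)^{-3/2} / 2 prefactor but is otherwise arbitrary
    (the fit profiles an amplitude out).

    Returns photons per unit time (arbitrary scale), zero for t <= 0.
    """
    _validate_props(mua, musp, rho_cm)
    n = refractive_index
    v = C_LIGHT_CM_NS / n
    D = 1.0 / (3.0 * musp)
    z0, zb = _dipole_depths(mua, musp, n)

    t = np.asarray(t_ns, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    four_dvt = 4.0 * D * v * tp
    with np.errstate(over="ignore", under="ignore"):
        log_common = (
            -2.5 * np.log(tp)
            - mua * v * tp
            - rho_cm**2 / four_dvt
            + np.log(0.5 * (4.0 * np.pi * D * v) ** -1.5)
        )
        dipole = z0 * np.exp(-(z0**2) / four_dvt) + (z0 + 2.0 * zb) * np.exp(
            -((z0 + 2.0 * zb) ** 2) / four_dvt
        )
        out[pos] = np.exp(log_common) * dipole
    return out


def log_reflectance(
    t_ns: np.ndarray,
    mua: float,
    musp: float,
    rho_cm: float,
    refractive_index: float = 1.4,
) -> np.ndarray:
    """log R(rho, t) evaluated stably for very late times (t must be > 0)."""
    _validate_props(mua, musp, rho_cm)
    n = refractive_index
    v = C_LIGHT_CM_NS / n
    D = 1.0 / (3.0 * musp)
    z0, zb = _dipole_depths(mua, musp, n)
    t = np.asarray(t_ns, dtype=float)
    if np.any(t <= 0):
        raise ValueError("log_reflectance requires t > 0")
    four_dvt = 4.0 * D * v * t
    dipole = z0 * np.exp(-(z0**2) / four_dvt) + (z0 + 2.0 * zb) * np.exp(
        -((z0 + 2.0 * zb) ** 2) / four_dvt
    )
    return (
        -2.5 * np.log(t)
        - mua * v * t
        - rho_cm**2 / four_dvt
        + np.log(0.5 * (4.0 * np.pi * D * v) ** -1.5)
        + np.log(dipole)
    )


def g1_semi_infinite(
    tau_s: np.ndarray,
    mua: float,
    musp: float,
    bfi_cm2_s: float,
    rho_cm: float,
    wavelength_nm: float = 785.0,
    refractive_index: float = 1.4,
) -> np.ndarray:
    """Normalized field autocorrelation g1(tau) for a semi-infinite medium.

    Correlation-diffusion solution with Brownian red-blood-cell dynamics:
    the decay wavenumber is K(tau)^2 = 3 mua musp + 6 musp^2 k0^2 BFI tau
    with k0 = 2 pi n / lambda.  Normalized so g1(0) = 1; strictly
    decreasing in tau.
    """
    _validate_props(mua, musp, rho_cm)
    if bfi_cm2_s < 0:
        raise ValueError("BFI must be nonnegative")
    tau = np.asarray(tau_s, dtype=float)
    n = refractive_index
    k0 = 2.0 * np.pi * n / (wavelength_nm * 1e-7)  # cm^-1
    z0, zb = _dipole_depths(mua, musp, n)
    r1 = np.hypot(rho_cm, z0)
    rb = np.hypot(rho_cm, z0 + 2.0 * zb)

    def green(k):
        return np.exp(-k * r1) / r1 - np.exp(-k * rb) / rb

    k_tau = np.sqrt(3.0 * mua * musp + 6.0 * musp**2 * k0**2 * bfi_cm2_s * tau)
    k_zero = np.sqrt(3.0 * mua * musp)
    return green(k_tau) / green(k_zero)


def g2_siegert(g1: np.ndarray, beta: float) -> np.ndarray:
    """Siegert relation: g2 = 1 + beta |g1|^2."""
    if not 0 < beta <= 1:
        raise ValueError("beta must lie in (0, 1]")
    return 1.0 + beta * np.abs(g1) ** 2
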