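"""Chromophore absorption data.

Molar extinction coefficients of oxy- and deoxyhemoglobin in
cm^-1 / (mol/L), linearly interpolated to the device wavelengths from the
standard Gratzer/Kollias compilation (Prahl's tabulation).  Conversion to an
absorption coefficient uses mua = ln(10) * eps * C with C in mol/L, so for
concentrations in micromolar:

    mua [cm^-1] = ln(10) * 1e-6 * (eps_HbO * [HbO] + eps_HbR * [HbR])

Water absorption (cm^-1, pure water, Hale & Querry scale) is applied as a
fixed-fraction offset mua_water * water_fraction before inversion.
"""

from __future__ import annotations

import numpy as np

LN10 = float(np.log(10.0))

#: wavelength -> (eps_HbO2, eps_HbR) in cm^-1/M
EXTINCTION_HEMOGLOBIN: dict[float, tuple[float, float]] = {
    685.0: (283.0, 2229.9),
    785.0: (736.5, 997.0),
    828.0: (958.4, 692.4),
}

#: wavelength -> mua of pure water, cm^-1 (approximate literature values)
WATER_ABSORPTION: dict[float, float] = {
    685.0: 0.0047,
    785.0: 0.0247,
    828.0: 0.0319,
}


def extinction_matrix(wavelengths: tuple[float, float]) -> np.ndarray:
    """2x2 matrix mapping (HbO, HbR) in uM to mua (cm^-1) at two wavelengths."""
    rows = []
    for wl in wavelengths:
        if wl not in EXTINCTION_HEMOGLOBIN:
            raise KeyError(f"no extinction data at {wl} nm")
        eps_hbo, eps_hbr = EXTINCTION_HEMOGLOBIN[wl]
        rows.append([eps_hbo, eps_hbr])
    return LN10 * 1e-6 * np.asarray(rows)


def mua_from_chromophores(
    hbo_um: float,
    hbr_um: float,
    wavelength_nm: float,
    water_fraction: float = 0.0,
) -> float:
    """Absorption coefficient (cm^-1) from chromophore concentrations (uM)."""
    eps_hbo, eps_hbr = EXTINCTION_HEMOGLOBIN[wavelength_nm]
    mua = LN10 * 1e-6 * (eps_hbo * hbo_um + eps_hbr * hbr_um)
    return mua + water_fraction * WATER_ABSORPTION[wavelength_nm]
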