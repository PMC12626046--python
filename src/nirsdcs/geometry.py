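"""Probe geometry and forward-model discretization.

The probe places all source-detector pairs at a single effective separation
``rho_cm`` (2.5 cm by default).  The DCS dual-injection arrangement — two
injection points 3.5 mm apart, centred on the same separation — is collapsed
to one effective source; the intensity doubling it provides enters only as a
count-rate factor in the synthetic-data module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: speed of light in vacuum, cm/ns
C_LIGHT_CM_NS = 29.9792458


def default_time_edges(rep_rate_mhz: float = 53.0, n_bins: int = 2048) -> np.ndarray:
    """Bin edges (ns) spanning one laser period at the given repetition rate."""
    period_ns = 1.0e3 / rep_rate_mhz
    return np.linspace(0.0, period_ns, n_bins + 1)


def default_lag_grid(n: int = 128, tau_min_s: float = 1e-7, tau_max_s: float = 1e-2) -> np.ndarray:
    """Logarithmically spaced correlation lag grid (s)."""
    return np.logspace(np.log10(tau_min_s), np.log10(tau_max_s), n)


@dataclass(frozen=True, eq=False)
class ProbeGeometry:
    """Optical probe geometry.

    Parameters
    ----------
    rho_cm : source-detector separation in cm.
    dual_source_arc_mm : arc between the two DCS injection points, mm.
    wavelengths_nm : pulsed (TD-NIRS) emission wavelengths.
    dcs_wavelength_nm : CW wavelength used for DCS.
    rep_rate_mhz : pulsed-laser repetition rate.
    """

    rho_cm: float = 2.5
    dual_source_arc_mm: float = 3.5
    wavelengths_nm: tuple[float, float] = (685.0, 828.0)
    dcs_wavelength_nm: float = 785.0
    rep_rate_mhz: float = 53.0

    def __post_init__(self) -> None:
        if self.rho_cm <= 0:
            raise ValueError("source-detector separation must be positive")
        if self.rep_rate_mhz <= 0:
            raise ValueError("repetition rate must be positive")

    @property
    def laser_period_ns(self) -> float:
        return 1.0e3 / self.rep_rate_mhz


@dataclass(frozen=True, eq=False)
class ForwardModelSpec:
    """Discretization and medium constants for the forward models.

    ``time_edges_ns`` spans one laser period so the histogram can be treated
    as circular; ``lag_grid_s`` is the correlator lag grid.
    """

    refractive_index: float = 1.4
    time_edges_ns: np.ndarray = field(default_factory=default_time_edges)
    lag_grid_s: np.ndarray = field(default_factory=default_lag_grid)

    def __post_init__(self) -> None:
        edges = np.asarray(self.time_edges_ns, dtype=float)
        lags = np.asarray(self.lag_grid_s, dtype=float)
        if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("time_edges_ns must be strictly increasing with >= 2 edges")
        if lags.ndim != 1 or lags.size == 0 or np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
            raise ValueError("lag_grid_s must be positive and strictly increasing")
        if self.refractive_index <= 1.0:
            raise ValueError("refractive index must exceed 1")
        object.__setattr__(self, "time_edges_ns", edges)
        object.__setattr__(self, "lag_grid_s", lags)

    @property
    def speed_in_tissue_cm_ns(self) -> float:
        """Speed of light in the medium, cm/ns (c / n)."""
        return C_LIGHT_CM_NS / self.refractive_index

    @property
    def bin_centers_ns(self) -> np.ndarray:
        e = self.time_edges_ns
        return 0.5 * (e[:-1] + e[1:])
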