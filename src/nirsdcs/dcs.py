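"""DCS analysis: g2 curve handling, block averaging to the TD-NIRS cadence,
and inversion to blood-flow index and coherence factor.

The fit model is the Siegert relation 1 + beta |g1(tau; BFI)|^2 with g1 the
semi-infinite correlation-diffusion field autocorrelation (Brownian
dynamics); beta and BFI are fitted jointly, with the optical properties at
785 nm supplied by the TD-NIRS stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .forward import g1_semi_infinite
from .geometry import ProbeGeometry
from .tdnirs import OpticalProperties


@dataclass
class G2Curve:
    """Normalized intensity autocorrelation on a lag grid with its count rate."""

    lag_s: np.ndarray
    g2: np.ndarray
    count_rate_khz: float
    timestamp_s: float = 0.0
    avg_time_s: float = 1.0

    def __post_init__(self) -> None:
        self.lag_s = np.asarray(self.lag_s, dtype=float)
        self.g2 = np.asarray(self.g2, dtype=float)
        if self.lag_s.size == 0:
            raise ValueError("empty lag grid")
        if np.any(np.diff(self.lag_s) <= 0):
            raise ValueError("lag grid must be strictly increasing")
        if self.g2.size != self.lag_s.size:
            raise ValueError("g2 and lag grids differ in length")
        if self.avg_time_s <= 0:
            raise ValueError("averaging time must be positive")
        if self.count_rate_khz < 0:
            raise ValueError("count rate must be nonnegative")


@dataclass
class DCSFitResult:
    """Joint (BFI, beta) fit of one g2 curve.

    ``model`` records that the internal field autocorrelation is the
    semi-infinite correlation-diffusion solution.
    """

    bfi_cm2_s: float
    beta: float
    reduced_chi2: float
    converged: bool
    n_lags_used: int = 0
    model: str = "semi-infinite correlation diffusion, Brownian dynamics"


@dataclass
class DCSQualityReport:
    beta_median: float
    beta_sd: float
    count_rate_median_khz: float
    count_rate_sd_khz: float
    flags: list[str]
    window_s: tuple[float, float] = (0.0, 60.0)


def block_average_g2(curves: list[G2Curve], target_rate_hz: float = 1.0) -> list[G2Curve]:
    """Block-average raw g2 curves a posteriori to ``target_rate_hz``.

    Each output curve is the unweighted mean of all input curves whose
    timestamp falls in [k/rate, (k+1)/rate); count rates are averaged the
    same way and empty windows are omitted.
    """
    if not curves:
        return []
    lag0 = curves[0].lag_s
    for c in curves:
        if c.lag_s.size != lag0.size or not np.allclose(c.lag_s, lag0):
            raise ValueError("curves do not share a lag grid")
    window = 1.0 / target_rate_hz
    keys = np.floor(np.array([c.timestamp_s for c in curves]) / window).astype(int)
    out: list[G2Curve] = []
    for k in np.unique(keys):
        members = [c for c, kk in zip(curves, keys) if kk == k]
        g2 = np.mean([c.g2 for c in members], axis=0)
        cr = float(np.mean([c.count_rate_khz for c in members]))
        out.append(
            G2Curve(
                lag_s=lag0.copy(),
                g2=g2,
                count_rate_khz=cr,
                timestamp_s=float(k * window),
                avg_time_s=window,
            )
        )
    return out


def estimate_beta_intercept(curve: G2Curve, n_lags: int = 3) -> float:
    """Siegert intercept estimate: mean of the earliest lags minus one."""
    return float(np.mean(curve.g2[:n_lags]) - 1.0)


def _select_fit_lags(curve: G2Curve, beta0: float, threshold: float) -> np.ndarray:
    """Lags where the (estimated) squared field correlation exceeds threshold."""
    if beta0 <= 0:
        return np.ones(curve.lag_s.size, dtype=bool)
    g1sq = (curve.g2 - 1.0) / beta0
    mask = g1sq > threshold
    mask[: min(20, mask.size)] = True  # always keep the early-lag plateau
    return mask


def fit_g2(
    curve: G2Curve,
    props_785: OpticalProperties,
    geom: ProbeGeometry,
    refractive_index: float = 1.4,
    decay_threshold: float = 0.01,
    bfi0: float = 1e-8,
    max_iterations: int = 200,
) -> DCSFitResult:
    """Fit beta and BFI jointly to one g2 curve.

    Lags where the estimated |g1|^2 falls below ``decay_threshold`` are
    excluded (they carry no flow information, only noise).  A curve with no
    measurable decay returns ``converged=False`` instead of raising.
    """
    if curve.lag_s.size < 20:
        raise ValueError("g2 curve must span the decay with at least 20 lags")
    beta0 = estimate_beta_intercept(curve)
    if beta0 < 0.01:
        return DCSFitResult(0.0, max(beta0, 0.0), float("nan"), converged=False)
    beta0 = min(beta0, 1.0)
    mask = _select_fit_lags(curve, beta0, decay_threshold)
    tau = curve.lag_s[mask]
    y = curve.g2[mask]

    # no decay within the lag range -> flat curve, unfittable
    plateau = np.mean(y[:5])
    tail = np.mean(y[-5:])
    if plateau - tail < 0.05 * beta0:
        return DCSFitResult(0.0, beta0, float("nan"), converged=False)

    def residuals(x):
        log_bfi, beta = x
        g1 = g1_semi_infinite(
            tau,
            props_785.mua,
            props_785.musp,
            np.exp(log_bfi),
            geom.rho_cm,
            props_785.wavelength_nm,
            refractive_index,
        )
        return 1.0 + beta * g1**2 - y

    result = optimize.least_squares(
        residuals,
        x0=np.array([np.log(bfi0), beta0]),
        bounds=([np.log(1e-13), 1e-3], [np.log(1e-4), 1.0]),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        max_nfev=max_iterations * 3,
    )
    bfi = float(np.exp(result.x[0]))
    beta = float(result.x[1])
    dof = max(tau.size - 2, 1)
    return DCSFitResult(
        bfi_cm2_s=bfi,
        beta=beta,
        reduced_chi2=float(2.0 * result.cost / dof),
        converged=bool(result.success),
        n_lags_used=int(tau.size),
    )


def dcs_quality(
    curves: list[G2Curve],
    baseline_window_s: tuple[float, float] = (0.0, 60.0),
    integration_s: float = 10.0,
    beta_floor: float = 0.4,
    count_rate_band_khz: tuple[float, float] | None = (10.0, 200.0),
) -> DCSQualityReport:
    """Baseline DCS quality: beta and count-rate statistics.

    The raw curves inside the window are integrated into ``integration_s``
    blocks; beta is read per block from the Siegert intercept, and its median
    and standard deviation are reported together with the count-rate median
    and standard deviation (kHz).  Flags are raised when any block beta drops
    below ``beta_floor`` or the count rate leaves the configured band.
    """
    t0, t1 = baseline_window_s
    if t1 - t0 < integration_s:
        raise ValueError("baseline window shorter than one integration block")
    selected = [c for c in curves if t0 <= c.timestamp_s < t1]
    if not selected:
        raise ValueError("no curves inside the baseline window")
    blocks = block_average_g2(selected, target_rate_hz=1.0 / integration_s)
    betas = np.array([estimate_beta_intercept(b) for b in blocks])
    rates = np.array([c.count_rate_khz for c in selected])

    flags: list[str] = []
    if np.any(betas < beta_floor):
        flags.append("beta_drop")
    if count_rate_band_khz is not None:
        lo, hi = count_rate_band_khz
        if np.any(rates < lo) or np.any(rates > hi):
            flags.append("count_rate_out_of_band")
    return DCSQualityReport(
        beta_median=float(np.median(betas)),
        beta_sd=float(betas.std(ddof=1)) if betas.size > 1 else 0.0,
        count_rate_median_khz=float(np.median(rates)),
        count_rate_sd_khz=float(rates.std(ddof=1)) if rates.size > 1 else 0.0,
        flags=flags,
        window_s=baseline_window_s,
    )
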